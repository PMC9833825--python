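"""The three measurement procedures of the study.

1. Maximal growth rate: the steepest ordinary-least-squares slope of
   ln(OD600) versus time over a sliding window (20 datapoints at 10-minute
   spacing by default).
2. Efficiency-corrected relative copy number by qPCR: primer efficiencies
   from dilution-series standard curves, combined by the Pfaffl ratio
   E_target^dCq_target / E_ref^dCq_ref (target within the selected gene,
   reference outside the amplified region).
3. Amplicon divergence: exact 39-bp motif counting in reads covering the
   promoter region (ancestral motif versus motifs carrying known adaptive
   SNPs), with contaminant-read exclusion, plus a sequencing-error control
   based on single-mismatch matches to a coding-region motif.

Coordinate convention for motifs: positions are 1-based distances 5' of the
start codon, so position -1 adjoins the A of ATG; the upstream window spans
[-39, -1] and the downstream control window [+1, +39] of the coding strand.
Position -n maps to 0-based index (39 - n) within the upstream motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.Seq import reverse_complement

__all__ = [
    "GrowthCurve",
    "QPCRRun",
    "AmpliconMotifSet",
    "MotifCounts",
    "max_growth_rate",
    "qpcr_efficiency",
    "pfaffl_ratio",
    "copy_number_from_qpcr",
    "build_motif_set",
    "count_motifs",
    "divergence_fractions",
    "single_snp_control",
]

MOTIF_LENGTH = 39


@dataclass(frozen=True)
class GrowthCurve:
    """An OD time series: strictly increasing times (hours), positive OD."""

    time_h: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_h", np.asarray(self.time_h, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.time_h.shape != self.od.shape or self.time_h.ndim != 1:
            raise ValueError("time_h and od must be equal-length 1-D arrays")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("OD values must be > 0")


def max_growth_rate(curve: GrowthCurve, window: int = 20) -> float:
    """Steepest sliding-window OLS slope of ln(OD) vs time, per hour.

    Every contiguous window of ``window`` points is fitted by ordinary least
    squares and the maximum slope is returned (ties broken by the earliest
    window).  Invariant to scaling OD by a positive constant and to shifting
    the time axis.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(curve.od)
    if n < window:
        raise ValueError(f"curve has {n} points, need at least window={window}")
    t = curve.time_h
    y = np.log(curve.od)
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    return float(slopes[int(np.argmax(slopes))])


@dataclass(frozen=True)
class QPCRRun:
    """Cq readout of one sample/calibrator pair plus standard curves.

    ``*_cq_*`` arrays hold technical replicates.  Each standard curve is a
    pair of arrays (log10_dilution, cq) with at least 3 distinct dilutions.
    """

    target_cq_sample: np.ndarray
    target_cq_calibrator: np.ndarray
    ref_cq_sample: np.ndarray
    ref_cq_calibrator: np.ndarray
    target_series: tuple[np.ndarray, np.ndarray]
    ref_series: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        for name in ("target_cq_sample", "target_cq_calibrator", "ref_cq_sample", "ref_cq_calibrator"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr <= 0):
                raise ValueError("Cq values must be > 0")
            object.__setattr__(self, name, arr)


def qpcr_efficiency(log10_dilution: np.ndarray, cq: np.ndarray) -> float:
    """Primer-pair efficiency (fold per cycle) from a dilution series.

    OLS fit Cq = a + s * log10(dilution); efficiency = 10^(-1/s).  A perfect
    doubling per cycle gives slope -3.3219 and efficiency 2.0.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(cq, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("dilution series needs >= 3 distinct dilutions")
    s = np.polyfit(x, y, 1)[0]
    if abs(s) < 1e-6:
        raise ValueError("degenerate standard curve: slope ~ 0")
    return float(10.0 ** (-1.0 / s))


def pfaffl_ratio(e_target: float, dcq_target: float, e_ref: float, dcq_ref: float) -> float:
    """Efficiency-corrected relative quantity: E_t^dCq_t / E_r^dCq_r.

    dCq = Cq(calibrator) - Cq(sample) per channel.  Efficiencies must lie in
    (1, 3] (1 would mean no amplification; 2 is perfect doubling).
    """
    for e in (e_target, e_ref):
        if not 1.0 < e <= 3.0:
            raise ValueError(f"efficiency out of range (1, 3]: {e}")
    return float(e_target**dcq_target / e_ref**dcq_ref)


def copy_number_from_qpcr(run: QPCRRun) -> float:
    """Relative copy number of one sample from a full qPCR run.

    Efficiencies come from the run's own standard curves; dCq per channel is
    mean Cq(calibrator) - mean Cq(sample) over technical replicates.
    """
    e_t = qpcr_efficiency(*run.target_series)
    e_r = qpcr_efficiency(*run.ref_series)
    dcq_t = float(run.target_cq_calibrator.mean() - run.target_cq_sample.mean())
    dcq_r = float(run.ref_cq_calibrator.mean() - run.ref_cq_sample.mean())
    return pfaffl_ratio(e_t, dcq_t, e_r, dcq_r)


@dataclass(frozen=True)
class AmpliconMotifSet:
    """The fixed-length motifs used for allele counting.

    ``ancestral`` spans the upstream window [-39, -1]; each entry of
    ``evolved`` is the same window with one or more known adaptive SNPs
    applied; ``control`` spans [+1, +39] of the coding sequence (no adaptive
    mutations are expected there, so mismatches to it measure sequencing
    error).  ``contaminants`` are motifs identifying reads from other
    amplicon libraries, excluded before any counting.
    """

    ancestral: str
    evolved: Mapping[str, str]
    control: str
    contaminants: tuple[str, ...] = ()
    length: int = MOTIF_LENGTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "evolved", dict(self.evolved))
        object.__setattr__(self, "contaminants", tuple(self.contaminants))
        for seq in [self.ancestral, self.control, *self.evolved.values(), *self.contaminants]:
            if len(seq) != self.length:
                raise ValueError(f"all motifs must have length {self.length}, got {len(seq)}")
            if set(seq) - set("ACGT"):
                raise ValueError(f"motif contains non-ACGT characters: {seq}")
        for name, seq in self.evolved.items():
            if seq == self.ancestral:
                raise ValueError(f"evolved motif {name!r} equals the ancestral motif")

    def p0_motifs(self) -> dict[str, str]:
        """Ancestral plus evolved upstream motifs, keyed by name."""
        return {"ancestral": self.ancestral, **self.evolved}


@dataclass
class MotifCounts:
    """Read tallies per motif plus excluded/unassigned bookkeeping.

    assigned + unassigned + excluded = total reads.
    """

    counts: dict[str, int]
    excluded: int = 0
    unassigned: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.excluded


def build_motif_set(
    reference: str,
    start_codon_offset: int,
    snp_specs: Mapping[int, tuple[str, str]],
    contaminants: Iterable[str] = (),
    length: int = MOTIF_LENGTH,
) -> AmpliconMotifSet:
    """Construct the motif set from a reference sequence around a start codon.

    ``start_codon_offset`` is the 0-based index of the A of ATG in
    ``reference``.  ``snp_specs`` maps upstream positions (negative, -1
    adjoining ATG) to (ref_base, alt_base).  One evolved motif is built per
    single SNP, plus the full combination when more than one SNP is given
    (names like "-30T>A" and "-37C>T,-30T>A").
    """
    reference = reference.upper()
    if start_codon_offset < length or len(reference) < start_codon_offset + length:
        raise ValueError(f"reference must cover [-{length}, +{length}] around the start codon")
    anc = reference[start_codon_offset - length : start_codon_offset]
    control = reference[start_codon_offset : start_codon_offset + length]

    def apply(specs: Mapping[int, tuple[str, str]]) -> str:
        seq = list(anc)
        for pos, (ref_base, alt_base) in specs.items():
            if not -length <= pos <= -1:
                raise ValueError(f"SNP position {pos} outside the upstream window [-{length}, -1]")
            idx = length + pos  # -39 -> 0 ... -1 -> 38
            if seq[idx] != ref_base:
                raise ValueError(
                    f"reference base at position {pos} is {seq[idx]}, expected {ref_base}"
                )
            seq[idx] = alt_base
        return "".join(seq)

    def snp_name(pos: int, spec: tuple[str, str]) -> str:
        return f"{pos}{spec[0]}>{spec[1]}"

    evolved: dict[str, str] = {}
    for pos, spec in sorted(snp_specs.items()):
        evolved[snp_name(pos, spec)] = apply({pos: spec})
    if len(snp_specs) > 1:
        name = ",".join(snp_name(pos, spec) for pos, spec in sorted(snp_specs.items()))
        evolved[name] = apply(snp_specs)
    return AmpliconMotifSet(anc, evolved, control, tuple(s.upper() for s in contaminants), length)


def _read_sequences(reads) -> Iterable[str]:
    for rec in reads:
        yield str(getattr(rec, "seq", rec)).upper()


def count_motifs(reads, motifs: AmpliconMotifSet) -> MotifCounts:
    """Assign each read to a motif by exact substring match on either strand.

    A read matching any contaminant motif (forward or reverse complement) is
    excluded before anything else.  Otherwise it is assigned to the unique
    upstream motif (ancestral or evolved) it contains; the single-SNP motifs
    differ inside a common window, so at most one can match at a given
    offset.  Reads containing only the downstream control motif are counted
    under "control"; reads matching nothing are unassigned.  No mismatches
    are tolerated, so sequencing errors land in "unassigned" rather than
    being miscalled as alleles.

    ``reads`` may be Bio.SeqIO records, plain strings, or a path to a FASTQ
    file.
    """
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        reads = read_fastq(reads)
    p0 = motifs.p0_motifs()
    counts = {name: 0 for name in [*p0, "control"]}
    excluded = 0
    unassigned = 0
    for seq in _read_sequences(reads):
        rc = reverse_complement(seq)
        if any(c in seq or c in rc for c in motifs.contaminants):
            excluded += 1
            continue
        hits = [name for name, motif in p0.items() if motif in seq or motif in rc]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1:  # cannot happen for motifs differing within one window
            unassigned += 1
        elif motifs.control in seq or motifs.control in rc:
            counts["control"] += 1
        else:
            unassigned += 1
    return MotifCounts(counts, excluded=excluded, unassigned=unassigned)


def divergence_fractions(counts: MotifCounts) -> dict[str, float]:
    """Per-motif divergence: evolved-read count over ancestral-read count.

    Normalizing to the ancestral count (rather than total reads) makes the
    metric comparable across samples with different sequencing depth;
    unassigned and excluded reads never enter.  Note the metric deliberately
    under-weights SNPs sitting inside amplified arrays: a cell with one
    mutant copy out of k contributes m=1 evolved and k-1 ancestral
    templates, mirroring the 1-in-k chance that the mutant copy survives
    array collapse.
    """
    anc = counts.counts.get("ancestral", 0)
    if anc == 0:
        raise ValueError("ancestral read count is zero; divergence undefined")
    return {
        name: c / anc for name, c in counts.counts.items() if name not in ("ancestral", "control")
    }


_BASE_TO_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


def _min_hamming(read: str, motif_arr: np.ndarray) -> int:
    """Minimum Hamming distance of motif over all alignments within read."""
    n, L = len(read), len(motif_arr)
    if n < L:
        return L
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    return int((windows != motif_arr).sum(axis=1).min())


def single_snp_control(reads, control_motif: str) -> float:
    """Sequencing-error control: single-mismatch over exact-match read odds.

    For each read, the best (minimum-Hamming) alignment of the control motif
    is found over all offsets on both strands.  The statistic is the count
    of reads at distance exactly 1 divided by the count at distance 0.  With
    per-base error rate e over a window of length L this approximates
    L*e / (1 - L*e) for small e.
    """
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        reads = read_fastq(reads)
    motif = control_motif.upper()
    fwd = np.frombuffer(motif.encode(), dtype=np.uint8)
    rev = np.frombuffer(reverse_complement(motif).encode(), dtype=np.uint8)
    n0 = 0
    n1 = 0
    for seq in _read_sequences(reads):
        d = min(_min_hamming(seq, fwd), _min_hamming(seq, rev))
        if d == 0:
            n0 += 1
        elif d == 1:
            n1 += 1
    if n0 == 0:
        raise ValueError("no exact control-motif matches; control fraction undefined")
    return n1 / n0
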