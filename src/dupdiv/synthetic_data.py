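"""Synthetic data shaped like the study's four measurement outputs.

Every generator emits data with known ground truth so each downstream stage
(growth-rate estimation, fraction classification, motif counting, qPCR copy
number) can be round-trip tested without any external download:

* plate-reader growth curves (10-minute OD sampling, lag/exponential/
  saturation phases);
* daily plate endpoint fluorescence for up to 96 wells;
* amplicon reads (FASTQ-shaped) whose template pool reflects gene dosage:
  a cell of class (k, m) contributes m evolved and k - m ancestral promoter
  templates, so the divergence metric's copy-number dilution is generated,
  not assumed;
* qPCR Cq tables with per-channel dilution series and technical replicates.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .assays import MOTIF_LENGTH, AmpliconMotifSet, GrowthCurve, QPCRRun, build_motif_set
from .model_core import AlleleParams, Genotype
from .reporter import ReporterParams, _lognormal_mean1, population_fluorescence

__all__ = [
    "SynthSpec",
    "AmpliconReference",
    "default_reference",
    "DEFAULT_SNPS",
    "gen_growth_curve",
    "gen_plate_timeseries",
    "gen_amplicon_reads",
    "gen_qpcr_run",
]

# the two adaptive promoter SNPs scored in the divergence assay
DEFAULT_SNPS: dict[int, tuple[str, str]] = {-30: ("T", "A"), -37: ("C", "T")}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthSpec:
    """Noise levels, sizes and seed shared by the generators.

    od_noise_sd: multiplicative Gaussian noise on OD readings.
    fluor_noise_cv: lognormal CV of single-cell fluorescence (flow events).
    bulk_noise_cv: lognormal CV of bulk plate fluorescence — much smaller
    than the single-cell CV because a well reading averages ~1e6 cells and
    retains only instrument/well-to-well variation.  error_rate: per-base
    substitution rate of the read simulator.  cq_noise_sd: additive Gaussian
    noise on Cq values (cycles).
    """

    od_noise_sd: float = 0.02
    fluor_noise_cv: float = 0.25
    bulk_noise_cv: float = 0.05
    error_rate: float = 0.001
    cq_noise_sd: float = 0.1
    n_events: int = 6000
    n_reads: int = 10000
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_events, self.n_reads, self.read_length) < 1:
            raise ValueError("sizes must be >= 1")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.read_length < MOTIF_LENGTH:
            raise ValueError(f"read_length must be >= motif length {MOTIF_LENGTH}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_growth_curve(
    r: float,
    lag_hours: float,
    k_over_od0: float,
    spec: SynthSpec,
    od0: float = 0.01,
    duration_hours: float = 24.0,
    rng: np.random.Generator | None = None,
) -> tuple[GrowthCurve, dict]:
    """Three-phase OD curve sampled at 10-minute intervals.

    Flat at od0 during the lag, then logistic growth at intrinsic rate ``r``
    towards carrying capacity ``k_over_od0 * od0`` (a huge capacity gives a
    pure exponential).  Multiplicative Gaussian noise of sd ``od_noise_sd``
    is applied per reading.  Returns the curve and a ground-truth dict.
    """
    if r < 0:
        raise ValueError("growth rate must be >= 0")
    rng = spec.rng() if rng is None else rng
    t = np.arange(0.0, duration_hours + 1e-9, 1.0 / 6.0)  # 10-min spacing
    tau = np.maximum(t - lag_hours, 0.0)
    if r == 0:
        od = np.full_like(t, od0)
    else:
        od = k_over_od0 * od0 / (1.0 + (k_over_od0 - 1.0) * np.exp(-r * tau))
    if spec.od_noise_sd > 0:
        od = od * (1.0 + spec.od_noise_sd * rng.standard_normal(od.shape))
        od = np.maximum(od, od0 * 1e-3)
    truth = {"r": r, "lag_hours": lag_hours, "k_over_od0": k_over_od0, "od0": od0}
    return GrowthCurve(t, od), truth


_WELLS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def gen_plate_timeseries(
    trajectories: Sequence,
    a: AlleleParams,
    p: ReporterParams,
    spec: SynthSpec,
    rng: np.random.Generator | None = None,
    endpoint_od: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily endpoint plate readings for up to 96 replicate trajectories.

    For every trajectory snapshot, the bulk normalized fluorescence is
    perturbed by lognormal noise (CV ``bulk_noise_cv``); OD carries
    multiplicative Gaussian noise around ``endpoint_od``.  Wells are
    assigned A1..H12 in row-major order.  Returns (plate, truth): the plate
    table (well, day, od, yfp, cfp) and the noiseless ground truth
    (well, day, yfp_norm, cfp_norm).
    """
    if len(trajectories) > 96:
        raise ValueError("at most 96 populations fit on one plate")
    rng = spec.rng() if rng is None else rng
    rows, truth_rows = [], []
    for i, traj in enumerate(trajectories):
        well = _WELLS[i]
        for st in traj.states:
            yn, cn = population_fluorescence(st, a, p)
            eps = _lognormal_mean1(spec.bulk_noise_cv, 2, rng)
            od = endpoint_od * (1.0 + spec.od_noise_sd * rng.standard_normal())
            rows.append((well, st.day, od, yn * eps[0], cn * eps[1]))
            truth_rows.append((well, st.day, yn, cn))
    plate = pd.DataFrame(rows, columns=["well", "day", "od", "yfp", "cfp"])
    truth = pd.DataFrame(truth_rows, columns=["well", "day", "yfp_norm", "cfp_norm"])
    return plate, truth


@dataclass(frozen=True)
class AmpliconReference:
    """A synthetic amplicon locus: reference sequence plus known SNPs.

    ``sequence`` covers the upstream promoter window and the start of the
    coding region; ``start_codon_offset`` is the 0-based index of the A of
    ATG.  ``snp_specs`` are the adaptive promoter SNPs; the evolved template
    carries all of them.  ``contaminant`` is a full-length unrelated
    amplicon standing in for cross-library contamination.
    """

    sequence: str
    start_codon_offset: int
    snp_specs: Mapping[int, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_SNPS))
    contaminant: str = ""

    def evolved_sequence(self) -> str:
        seq = list(self.sequence)
        off = self.start_codon_offset
        for pos, (ref_base, alt_base) in self.snp_specs.items():
            idx = off + pos
            if seq[idx] != ref_base:
                raise ValueError(f"reference base at {pos} is {seq[idx]}, expected {ref_base}")
            seq[idx] = alt_base
        return "".join(seq)

    def motif_set(self) -> AmpliconMotifSet:
        contaminants = ()
        if self.contaminant:
            off = self.start_codon_offset
            contaminants = (self.contaminant[off - MOTIF_LENGTH : off],)
        return build_motif_set(self.sequence, self.start_codon_offset, self.snp_specs, contaminants)


def default_reference(length: int = 150, upstream: int = 75) -> AmpliconReference:
    """The shipped default locus: a synthetic random reference.

    The true junction between the random promoter and the start codon in the
    real strain is not reconstructible here, so the default reference is
    synthetic: random sequence with ATG at the given offset and the
    reference bases of the two canonical SNPs (-30 T, -37 C) planted.  A
    second, unrelated random amplicon serves as the synthetic contaminant.
    Deterministic (internal fixed seed); real-data use should supply the
    true sequence instead.
    """
    if upstream < MOTIF_LENGTH + 1 or length - upstream < MOTIF_LENGTH + 3:
        raise ValueError("reference must cover both 39-base windows")
    rng = np.random.default_rng(987654321)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    seq[upstream : upstream + 3] = "ATG"
    for pos, (ref_base, _alt) in DEFAULT_SNPS.items():
        seq[upstream + pos] = ref_base
    contaminant = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return AmpliconReference("".join(seq), upstream, dict(DEFAULT_SNPS), contaminant)


def _normalize_composition(composition) -> list[tuple[Genotype, float]]:
    if isinstance(composition, Mapping):
        composition = list(composition.items())
    pairs = [(g if isinstance(g, Genotype) else Genotype(*g), float(f)) for g, f in composition]
    tot = sum(f for _, f in pairs)
    if tot <= 0:
        raise ValueError("composition is empty")
    return [(g, f / tot) for g, f in pairs]


def _mutate_reads(arr: np.ndarray, e: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution errors on a (n_reads, L) uint8 base array."""
    if e <= 0:
        return arr
    mask = rng.random(arr.shape) < e
    n_err = int(mask.sum())
    if n_err == 0:
        return arr
    # substitute with one of the three other bases, uniformly
    codes = np.zeros(arr.shape, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        codes[arr == b] = i
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    new_codes = (codes[mask] + shift) % 4
    out = arr.copy()
    out[mask] = _BASES[new_codes]
    return out


def gen_amplicon_reads(
    composition,
    reference: AmpliconReference,
    spec: SynthSpec,
    contaminant_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], dict]:
    """Simulate an amplicon read pool from a population composition.

    Template molecules are drawn in proportion to cell frequency times copy
    number: a cell of class (k, m) contributes m evolved-promoter and k - m
    ancestral-promoter templates.  A ``contaminant_fraction`` of reads comes
    from the unrelated contaminant amplicon.  Reads are the full template
    (trimmed to ``read_length`` by a random window if shorter than the
    template), carry per-base substitution errors at ``error_rate``, and
    half are reverse-complemented.  Returns (sequences, ground_truth).
    """
    if not 0 <= contaminant_fraction < 1:
        raise ValueError("contaminant_fraction must be in [0, 1)")
    rng = spec.rng() if rng is None else rng
    pairs = _normalize_composition(composition)
    w_anc = sum(f * (g.k - g.m) for g, f in pairs)
    w_evo = sum(f * g.m for g, f in pairs)
    w_tot = w_anc + w_evo
    if w_tot <= 0:
        raise ValueError("composition yields no template molecules")
    probs = np.array(
        [
            (1 - contaminant_fraction) * w_anc / w_tot,
            (1 - contaminant_fraction) * w_evo / w_tot,
            contaminant_fraction,
        ]
    )
    templates = [reference.sequence, reference.evolved_sequence(), reference.contaminant]
    if contaminant_fraction > 0 and not reference.contaminant:
        raise ValueError("contaminant_fraction > 0 but reference has no contaminant sequence")
    n_per = rng.multinomial(spec.n_reads, probs)

    chunks: list[np.ndarray] = []
    for template, n in zip(templates, n_per):
        if n == 0:
            continue
        t_arr = np.frombuffer(template.encode(), dtype=np.uint8)
        L = min(spec.read_length, len(t_arr))
        if L < len(t_arr):
            starts = rng.integers(0, len(t_arr) - L + 1, size=n)
            reads = np.stack([t_arr[s : s + L] for s in starts])
        else:
            reads = np.tile(t_arr, (n, 1))
        chunks.append(_mutate_reads(reads, spec.error_rate, rng))
    arr = np.concatenate(chunks, axis=0)
    order = rng.permutation(len(arr))
    arr = arr[order]
    flip = rng.random(len(arr)) < 0.5
    seqs = [row.tobytes().decode() for row in arr]
    seqs = [reverse_complement(s) if f else s for s, f in zip(seqs, flip)]
    truth = {
        "n_reads": spec.n_reads,
        "ancestral_templates": float(w_anc / w_tot),
        "evolved_templates": float(w_evo / w_tot),
        "contaminant_fraction": contaminant_fraction,
        "error_rate": spec.error_rate,
    }
    return seqs, truth


def gen_qpcr_run(
    true_copies: float,
    e_target: float,
    e_ref: float,
    spec: SynthSpec,
    rng: np.random.Generator | None = None,
    intercept_target: float = 20.0,
    intercept_ref: float = 18.0,
    n_replicates: int = 3,
    dilutions: Sequence[float] = (1.0, 0.1, 0.01, 0.001),
) -> tuple[QPCRRun, dict]:
    """Simulate a qPCR run measuring relative copy number of one sample.

    The target channel follows Cq = intercept - log_E(copies) + noise with
    the calibrator at one copy; the reference channel is copy-invariant.
    Each channel gets a dilution series (4 points by default) and
    ``n_replicates`` technical replicates, all with additive Gaussian Cq
    noise of sd ``cq_noise_sd``.
    """
    if true_copies < 1:
        raise ValueError("true_copies must be >= 1")
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.2:
            raise ValueError(f"efficiency must be in (1, 2.2], got {e}")
    rng = spec.rng() if rng is None else rng
    sd = spec.cq_noise_sd

    def noisy(mean: float, n: int) -> np.ndarray:
        return mean + sd * rng.standard_normal(n)

    cq_t_cal = intercept_target
    cq_t_sample = intercept_target - math.log(true_copies, e_target)
    cq_r = intercept_ref

    def series(e: float, intercept: float) -> tuple[np.ndarray, np.ndarray]:
        logd = np.repeat(np.log10(np.asarray(dilutions, dtype=float)), n_replicates)
        slope = -1.0 / math.log10(e)
        return logd, intercept + slope * logd + sd * rng.standard_normal(len(logd))

    run = QPCRRun(
        target_cq_sample=noisy(cq_t_sample, n_replicates),
        target_cq_calibrator=noisy(cq_t_cal, n_replicates),
        ref_cq_sample=noisy(cq_r, n_replicates),
        ref_cq_calibrator=noisy(cq_r, n_replicates),
        target_series=series(e_target, intercept_target),
        ref_series=series(e_ref, intercept_ref),
    )
    truth = {"copies": true_copies, "e_target": e_target, "e_ref": e_ref}
    return run, truth
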