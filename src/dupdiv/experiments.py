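"""Pre-assembled desk-scale experiments over the simulator and assays.

These functions bundle the package's headline computations — the regime
comparisons between demand levels and strains, the mean-field oracle check,
the pooled-amplicon divergence comparison and the duplication-rate
monotonicity scan — so that scripts and tests share one implementation.

All experiments run at a scaled-down carrying capacity (1e6 cells instead
of the experimental ~1e8) so a full regime comparison takes seconds on one
CPU.  The scaling preserves the ~10 generations/day regrowth regime but
reduces mutation supply proportionally, which matters for rare events (see
the package methods notes on point-mutant establishment).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.stats import fisher_exact

from .assays import count_motifs, divergence_fractions
from .classify import FractionLabel, classify_population
from .config import RunConfig, preset
from .evolve import SerialProtocol, Trajectory, deterministic_trajectory, run_replicate
from .model_core import Genotype, MutationRates
from .reporter import population_fluorescence
from .synthetic_data import SynthSpec, default_reference, gen_amplicon_reads

__all__ = [
    "generations_per_transfer",
    "scaled_config",
    "final_states",
    "regime_summary",
    "demand_regime_fisher",
    "oracle_max_deviation",
    "pooled_divergence",
    "divergence_batch_comparison",
    "amplified_count_by_mu_dup",
]

SCALED_CAPACITY = 1e6
COMBINATION_CUTOFF = 0.01  # frequency above which a replicate "has" combination mutants


def generations_per_transfer(dilution_factor: float = 820.0) -> int:
    """Generations of regrowth implied by the daily dilution: round(log2(d))."""
    return int(round(math.log2(dilution_factor)))


def scaled_config(demand: str, strain: str, carrying_capacity: float = SCALED_CAPACITY, **overrides) -> RunConfig:
    """A demand/strain preset with the desk-scale carrying capacity."""
    return preset(
        demand, strain, protocol=SerialProtocol(carrying_capacity=carrying_capacity), **overrides
    )


def final_states(config: RunConfig, seeds) -> list:
    """Day-12 (pre-dilution) population states for one replicate per seed."""
    return [run_replicate(config, int(s)).final() for s in seeds]


def regime_summary(config: RunConfig, seeds) -> dict:
    """Per-replicate endpoint summary of one condition.

    Returns counts of replicates whose combination-class frequency reaches
    COMBINATION_CUTOFF, the bulk fraction label of every replicate, and the
    tallies of amplified replicates with and without the mixed fraction
    (both tallies are reported because bulk fluorescence cannot tell a
    combination clone from a mixture of the two pure mutant types).
    """
    states = final_states(config, seeds)
    combo_flags = [st.combination_frequency() >= COMBINATION_CUTOFF for st in states]
    labels = []
    for st in states:
        yn, cn = population_fluorescence(st, config.alleles, config.reporter)
        labels.append(classify_population(yn, cn, config.thresholds))
    n = len(states)
    label_counts = {lab: sum(1 for x in labels if x is lab) for lab in FractionLabel}
    return {
        "n_replicates": n,
        "combination_replicates": int(sum(combo_flags)),
        "combination_free_fraction": 1.0 - sum(combo_flags) / n,
        "label_counts": label_counts,
        "amplified_replicates": label_counts[FractionLabel.YFP_CFP_PLUS],
        "amplified_incl_mixed": label_counts[FractionLabel.YFP_CFP_PLUS]
        + label_counts[FractionLabel.MIXED],
        "states": states,
    }


def demand_regime_fisher(low_combo: int, high_combo: int, n: int) -> float:
    """One-sided Fisher exact p for more combination replicates at high demand."""
    table = [[high_combo, n - high_combo], [low_combo, n - low_combo]]
    return float(fisher_exact(table, alternative="greater").pvalue)


def oracle_max_deviation(config: RunConfig, n_replicates: int, base_seed: int) -> float:
    """Max |mean stochastic - deterministic| class frequency over all days.

    The mean-field recursion is the correct limit only when every relevant
    mutation flow is a frequent event; with rare flows the deterministic
    recursion keeps fractional jackpot lineages that finite populations
    usually lose at the bottleneck, and the two sides genuinely diverge.
    """
    det = deterministic_trajectory(config)
    sums = None
    for i in range(n_replicates):
        traj = run_replicate(config, base_seed + i)
        freqs = np.array([st.frequencies() for st in traj.states])
        sums = freqs if sums is None else sums + freqs
    mean = sums / n_replicates
    det_freqs = np.array([st.frequencies() for st in det.states])
    return float(np.abs(mean - det_freqs).max())


def pooled_divergence(states, n_reads: int, seed: int, error_rate: float = 0.001,
                      contaminant_fraction: float = 0.02) -> float:
    """Total evolved/ancestral read fraction of a pool of populations.

    Pools the class abundances of all given states, simulates one amplicon
    library and sums the divergence fractions over all evolved motifs.
    """
    pooled = sum(st.counts for st in states)
    kmax = pooled.shape[0]
    comp = {
        Genotype(k, m): float(pooled[k - 1, m])
        for k in range(1, kmax + 1)
        for m in range(0, k + 1)
        if pooled[k - 1, m] > 0
    }
    ref = default_reference()
    spec = SynthSpec(n_reads=n_reads, error_rate=error_rate, seed=seed)
    seqs, _ = gen_amplicon_reads(comp, ref, spec, contaminant_fraction=contaminant_fraction)
    counts = count_motifs(seqs, ref.motif_set())
    return float(sum(divergence_fractions(counts).values()))


def divergence_batch_comparison(
    n_batches: int,
    reps_per_batch: int,
    n_reads: int,
    base_seed: int,
    demand: str = "low",
) -> dict:
    """Paired IS- vs IS+ pooled divergence over seed batches.

    For each batch, both strains evolve ``reps_per_batch`` replicates under
    the same demand; the pooled evolved/ancestral amplicon fraction is
    compared.  Frequent amplification is expected to suppress divergence,
    so the IS- pool should exceed the IS+ pool in nearly every batch.
    """
    wins = 0
    pairs = []
    for b in range(n_batches):
        seed0 = base_seed + b * 1000
        seeds = range(seed0, seed0 + reps_per_batch)
        f_minus = pooled_divergence(
            final_states(scaled_config(demand, "IS-"), seeds), n_reads, seed=seed0
        )
        f_plus = pooled_divergence(
            final_states(scaled_config(demand, "IS+"), seeds), n_reads, seed=seed0 + 500
        )
        pairs.append((f_minus, f_plus))
        wins += f_minus > f_plus
    return {"wins": wins, "n_batches": n_batches, "fraction": wins / n_batches, "pairs": pairs}


def amplified_count_by_mu_dup(
    mu_dups,
    n_replicates: int,
    base_seed: int,
    majority_cutoff: float = 0.5,
) -> list[int]:
    """Replicates with an amplified majority at day 12, per duplication rate.

    Holds everything at the low-demand IS+ preset except mu_dup; the count
    is expected to be non-decreasing in the duplication-formation rate.
    """
    counts = []
    for mu in mu_dups:
        cfg = scaled_config("low", "IS+")
        cfg = replace(cfg, rates=replace(cfg.rates, mu_dup=float(mu)))
        states = final_states(cfg, range(base_seed, base_seed + n_replicates))
        counts.append(sum(st.amplified_frequency() > majority_cutoff for st in states))
    return counts
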