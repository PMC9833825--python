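"""Stochastic simulator of a serial-dilution evolution experiment.

Each replicate population is a vector of abundances over genotype classes
``(k, m)`` (tandem copies, mutant copies).  A day consists of deterministic
exponential growth of every class up to a shared carrying capacity, with
Poisson tau-leaped mutation flows applied in sub-steps, followed by a
multinomial bottleneck (the daily 1:820 transfer, about 10 generations of
regrowth).  Population sizes around 1e8 make agent-based simulation
pointless; the bottleneck is the dominant source of stochasticity and is
modelled exactly.

A deterministic infinite-population recursion (`deterministic_trajectory`)
replaces Poisson draws by their means and the bottleneck by exact dilution;
it serves as the law-of-large-numbers oracle for the stochastic simulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .model_core import AlleleParams, Environment, MutationRates, growth_rate_grid

__all__ = [
    "SerialProtocol",
    "PopulationState",
    "Trajectory",
    "UnreachableCapacityError",
    "ExtinctPopulationError",
    "TauLeapError",
    "solve_day_duration",
    "mutation_flows",
    "grow_day",
    "bottleneck",
    "run_replicate",
    "run_experiment",
    "deterministic_trajectory",
]

LN2 = math.log(2.0)
T_MAX_HOURS = 1000.0


class UnreachableCapacityError(RuntimeError):
    """The population cannot regrow to carrying capacity within T_MAX_HOURS."""


class ExtinctPopulationError(RuntimeError):
    """The bottleneck would sample zero cells."""


class TauLeapError(RuntimeError):
    """A per-substep mutation probability reached 1; increase substeps_per_day."""


@dataclass(frozen=True)
class SerialProtocol:
    """The daily transfer regime.

    dilution_factor: daily dilution at transfer (1:820 by default, ~10
    generations of regrowth).  carrying_capacity: cells at the end of a
    day's growth (~1e8 CFU in the real protocol; scaled down in tests).
    n_days: length of the experiment.  substeps_per_day: tau-leap
    sub-intervals per day, chosen so per-substep mutation probabilities
    stay well below 1.
    """

    dilution_factor: float = 820.0
    carrying_capacity: float = 1e8
    n_days: int = 12
    substeps_per_day: int = 10

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.carrying_capacity / self.dilution_factor < 10:
            raise ValueError("carrying_capacity / dilution_factor must be >= 10")
        if self.n_days < 1 or self.substeps_per_day < 1:
            raise ValueError("n_days and substeps_per_day must be >= 1")

    @property
    def bottleneck_size(self) -> int:
        return int(round(self.carrying_capacity / self.dilution_factor))


@dataclass
class PopulationState:
    """Class abundances of one replicate on one day.

    ``counts`` is a (kmax, kmax+1) array indexed ``[k-1, m]``; entries with
    m > k are structurally zero.  Abundances are real during within-day
    growth and integer after a bottleneck.
    """

    counts: np.ndarray
    day: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.counts.shape[0] + 1:
            raise ValueError("counts must have shape (kmax, kmax+1)")
        if np.any(self.counts < 0):
            raise ValueError("abundances must be non-negative")

    @classmethod
    def ancestral(cls, n_cells: float, kmax: int, day: int = 0) -> "PopulationState":
        counts = np.zeros((kmax, kmax + 1))
        counts[0, 0] = n_cells
        return cls(counts, day=day)

    @property
    def kmax(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        tot = self.total
        if tot == 0:
            raise ExtinctPopulationError("population is empty")
        return self.counts / tot

    def amplified_frequency(self) -> float:
        """Frequency of all classes with k >= 2."""
        return float(self.counts[1:, :].sum() / self.total)

    def combination_frequency(self) -> float:
        """Frequency of combination classes (k >= 2 and m >= 1)."""
        return float(self.counts[1:, 1:].sum() / self.total)


@dataclass
class Trajectory:
    """Per-day snapshots of one replicate, taken pre-dilution.

    ``states[0]`` is the day-0 inoculum; ``states[d]`` for d >= 1 is the
    end-of-day state just before the bottleneck.  ``extinct_day`` is set if
    the replicate died out (simulation stops there, no resampling).
    """

    states: list[PopulationState]
    replicate: int = 0
    seed: int | None = None
    extinct_day: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return len(self.states) - 1

    def final(self) -> PopulationState:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: (replicate, day, k, m, count), nonzero rows only."""
        rows = []
        for st in self.states:
            ks, ms = np.nonzero(st.counts)
            for k_i, m_i in zip(ks, ms):
                rows.append((self.replicate, st.day, int(k_i) + 1, int(m_i), st.counts[k_i, m_i]))
        return pd.DataFrame(rows, columns=["replicate", "day", "k", "m", "count"])


def solve_day_duration(
    state: PopulationState,
    env: Environment,
    alleles: AlleleParams,
    protocol: SerialProtocol,
) -> float:
    """Hours of growth needed to reach carrying capacity.

    Solves sum_i n_i * exp(r_i * T) = K_cap for T by bracketed root finding
    (in log space, so large r*T cannot overflow), to relative tolerance
    1e-10.  Returns 0 if all growth rates are zero or the population already
    is at capacity; raises UnreachableCapacityError if capacity cannot be
    reached within T_MAX_HOURS.
    """
    n = state.counts
    total = n.sum()
    if total <= 0:
        raise ValueError("total abundance must be > 0")
    k_cap = protocol.carrying_capacity
    if total >= k_cap:
        return 0.0
    r = growth_rate_grid(state.kmax, env, alleles)
    occupied = n > 0
    if not np.any(r[occupied] > 0):
        return 0.0

    log_n = np.log(n[occupied])
    r_occ = r[occupied]
    log_cap = math.log(k_cap)

    def log_excess(t: float) -> float:
        return float(logsumexp(log_n + r_occ * t)) - log_cap

    if log_excess(T_MAX_HOURS) < 0:
        raise UnreachableCapacityError(
            f"population cannot reach capacity {k_cap:g} within {T_MAX_HOURS} h"
        )
    return float(brentq(log_excess, 0.0, T_MAX_HOURS, rtol=1e-12, xtol=1e-12))


def _draw(mean: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Poisson draw, or the mean itself in deterministic mode."""
    if rng is None:
        return mean
    return rng.poisson(mean).astype(float)


def _split(total: np.ndarray, p: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Binomial split of event counts, or exact fractions in deterministic mode."""
    if rng is None:
        return total * p
    return rng.binomial(total.astype(np.int64), p).astype(float)


def mutation_flows(
    state: PopulationState,
    rates: MutationRates,
    generations: float | np.ndarray,
    rng: np.random.Generator | None,
) -> PopulationState:
    """Apply one tau-leap of the three mutation processes.

    For each source class (k, m) with abundance n, event counts are Poisson
    with mean n * rate * generations (``generations`` may be a per-class
    array, since classes grow through different numbers of doublings):

    * duplication (k=1 only): (1, m) -> (2, 2m) at mu_dup — a tandem
      duplication copies the allele state of the existing copy;
    * amplification (2 <= k < kmax): (k, m) -> (k+1, m+1) with probability
      m/k else (k+1, m), at mu_step * (k-1) — unequal recombination adds a
      uniformly chosen existing copy;
    * deletion (k >= 2): (k, m) -> (k-1, m-1) with probability m/k else
      (k-1, m), at mu_step * (k-1) — a uniformly chosen copy is lost, which
      is how amplifications revert to single copy;
    * point mutation (m < k): (k, m) -> (k, m+1) at mu_pm * (k-m) — each
      ancestral copy is an independent target.

    Flows are capped at the source abundance (proportional rescaling) and
    the total abundance is conserved exactly.  Passing ``rng=None`` replaces
    every draw by its mean (the deterministic recursion).

    Raises TauLeapError if any per-class event probability reaches 1.
    """
    n = state.counts
    kmax = state.kmax
    g = np.broadcast_to(np.asarray(generations, dtype=float), n.shape)
    if np.any(g < 0):
        raise ValueError("generations must be >= 0")

    k = np.arange(1, kmax + 1)[:, None].astype(float)
    m = np.arange(0, kmax + 1)[None, :].astype(float)
    valid = m <= k

    # per-class event probabilities for the tau-leap validity check
    p_dup = np.where(k == 1, rates.mu_dup, 0.0) * g
    if kmax < 2:  # no room for a second copy in the state space
        p_dup = np.zeros_like(p_dup)
    p_step = np.where(k >= 2, rates.mu_step * (k - 1), 0.0) * g
    p_pm = np.where(valid, rates.mu_pm * np.maximum(k - m, 0.0), 0.0) * g
    occupied = n > 0
    for p in (p_dup, p_step, p_pm):
        if np.any(p[occupied] >= 1.0):
            raise TauLeapError(
                "per-substep mutation probability >= 1; increase substeps_per_day"
            )

    dup = _draw(n * p_dup, rng)  # nonzero only on row k=1
    amp_allowed = np.zeros_like(n)
    amp_allowed[1:-1, :] = 1.0  # 2 <= k < kmax; the top class cannot grow further
    amp = _draw(n * p_step * amp_allowed, rng)
    dele = _draw(n * p_step, rng)  # nonzero only for k >= 2 via p_step
    pm = _draw(n * p_pm, rng)

    # cap total outflow at source abundance
    out = dup + amp + dele + pm
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(out > n, n / np.where(out > 0, out, 1.0), 1.0)
    dup, amp, dele, pm = dup * scale, amp * scale, dele * scale, pm * scale
    out = dup + amp + dele + pm

    new = n - out

    # duplication: (1, m) -> (2, 2m); for k=1, m in {0, 1}
    if kmax >= 2:
        new[1, 0] += dup[0, 0]
        new[1, 2] += dup[0, 1]

    frac_m = np.where(valid, m / k, 0.0)
    # amplification: (k, m) -> (k+1, m+1) w.p. m/k else (k+1, m)
    amp_up = _split(amp, frac_m, rng)
    amp_same = amp - amp_up
    new[2:, 1:] += amp_up[1:-1, :-1]
    new[2:, :] += amp_same[1:-1, :]
    # deletion: (k, m) -> (k-1, m-1) w.p. m/k else (k-1, m)
    del_down = _split(dele, frac_m, rng)
    del_same = dele - del_down
    new[:-1, :-1] += del_down[1:, 1:]
    new[:-1, :] += del_same[1:, :]
    # point mutation: (k, m) -> (k, m+1)
    new[:, 1:] += pm[:, :-1]

    new = np.maximum(new, 0.0)  # guard float dust
    return PopulationState(new, day=state.day)


def grow_day(
    state: PopulationState,
    env: Environment,
    alleles: AlleleParams,
    rates: MutationRates,
    protocol: SerialProtocol,
    rng: np.random.Generator | None,
    duration: float | None = None,
) -> PopulationState:
    """One day: exponential growth to capacity with interleaved mutation.

    The solved day duration is split into ``substeps_per_day`` equal
    sub-intervals.  Within each, every class grows deterministically at its
    own rate, then `mutation_flows` is applied with per-class generation
    counts r_i * dt / ln 2.  ``duration`` overrides the solver (used when a
    day is truncated because capacity is unreachable).
    """
    t = solve_day_duration(state, env, alleles, protocol) if duration is None else duration
    r = growth_rate_grid(state.kmax, env, alleles)
    dt = t / protocol.substeps_per_day
    growth = np.exp(r * dt)
    gens = r * dt / LN2
    counts = state.counts
    cur = PopulationState(counts, day=state.day)
    for _ in range(protocol.substeps_per_day):
        cur = PopulationState(cur.counts * growth, day=cur.day)
        cur = mutation_flows(cur, rates, gens, rng)
    return cur


def bottleneck(
    state: PopulationState,
    protocol: SerialProtocol,
    rng: np.random.Generator | None,
) -> PopulationState:
    """The daily transfer: multinomial sampling of total/dilution_factor cells.

    Deterministic mode (rng=None) divides every class by the dilution factor
    exactly, keeping real-valued abundances.
    """
    total = state.total
    if total <= 0:
        raise ExtinctPopulationError("cannot bottleneck an empty population")
    if rng is None:
        return PopulationState(state.counts / protocol.dilution_factor, day=state.day)
    n_b = int(round(total / protocol.dilution_factor))
    if n_b == 0:
        raise ExtinctPopulationError("bottleneck would sample zero cells")
    p = (state.counts / total).ravel()
    sampled = rng.multinomial(n_b, p / p.sum()).reshape(state.counts.shape)
    return PopulationState(sampled.astype(float), day=state.day)


def _run(config, rng: np.random.Generator | None, replicate: int = 0, seed: int | None = None) -> Trajectory:
    protocol: SerialProtocol = config.protocol
    inoculum = PopulationState.ancestral(protocol.bottleneck_size, config.kmax, day=0)
    states = [inoculum]
    warns: list[str] = []
    extinct_day = None
    cur = inoculum
    for day in range(1, protocol.n_days + 1):
        try:
            grown = grow_day(cur, config.environment, config.alleles, config.rates, protocol, rng)
        except UnreachableCapacityError:
            warns.append(f"day {day}: capacity unreachable, day truncated at {T_MAX_HOURS} h")
            grown = grow_day(
                cur, config.environment, config.alleles, config.rates, protocol, rng,
                duration=T_MAX_HOURS,
            )
        grown.day = day
        states.append(grown)
        try:
            cur = bottleneck(grown, protocol, rng)
        except ExtinctPopulationError:
            extinct_day = day
            warns.append(f"day {day}: population extinct at bottleneck")
            break
    return Trajectory(states, replicate=replicate, seed=seed, extinct_day=extinct_day, warnings=warns)


def run_replicate(config, seed: int, replicate: int = 0) -> Trajectory:
    """Simulate one replicate population; reproducible given (config, seed)."""
    rng = np.random.default_rng(seed)
    return _run(config, rng, replicate=replicate, seed=seed)


def run_experiment(config, n_replicates: int, base_seed: int) -> list[Trajectory]:
    """Simulate n_replicates populations with seeds base_seed + i.

    The additive seed scheme means replicate i can be re-run in isolation
    with run_replicate(config, base_seed + i).
    """
    return [run_replicate(config, base_seed + i, replicate=i) for i in range(n_replicates)]


def deterministic_trajectory(config) -> Trajectory:
    """Infinite-population oracle: mean-field recursion, exact dilution.

    Identical to the stochastic recursion with Poisson flows replaced by
    their means and the multinomial bottleneck by exact division, so mean
    stochastic class frequencies converge to it as carrying capacity grows.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _run(config, rng=None)
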