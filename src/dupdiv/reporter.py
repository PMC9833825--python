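"""Virtual dual-fluorophore readout of genotype classes.

The reporter cassette couples two signals to the two mutation routes: YFP is
fused to the selected gene, so it tracks total expression E (and rises with
either promoter mutations or dosage); CFP is driven by an independent
constitutive promoter inside the same cassette, so it tracks copy number k
only.  A pure amplification moves a cell up the YFP = CFP diagonal; a pure
promoter mutation moves it along YFP at ancestral CFP; a combination mutant
sits above the diagonal.

Event tables are plain pandas DataFrames with columns (event, yfp, cfp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evolve import ExtinctPopulationError, PopulationState
from .model_core import AlleleParams, Genotype, expression_grid, expression_level

__all__ = [
    "ReporterParams",
    "EVENT_COLUMNS",
    "cell_fluorescence",
    "population_fluorescence",
    "sample_flow_events",
]

EVENT_COLUMNS = ["event", "yfp", "cfp"]


@dataclass(frozen=True)
class ReporterParams:
    """Gains, autofluorescence floors and per-cell noise of the two channels.

    yfp_gain: fluorescence units per expression unit.  cfp_per_copy:
    fluorescence units per gene copy.  noise_cv: coefficient of variation of
    the multiplicative lognormal per-cell noise (mean exactly 1).
    """

    yfp_gain: float = 1.0
    cfp_per_copy: float = 1.0
    yfp_background: float = 0.1
    cfp_background: float = 0.1
    noise_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.yfp_gain <= 0 or self.cfp_per_copy <= 0:
            raise ValueError("gains must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_mean1(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Lognormal multiplier with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _noiseless(g_k: np.ndarray, g_e: np.ndarray, p: ReporterParams):
    yfp = p.yfp_background + p.yfp_gain * g_e
    cfp = p.cfp_background + p.cfp_per_copy * g_k
    return yfp, cfp


def cell_fluorescence(
    g: Genotype,
    a: AlleleParams,
    p: ReporterParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Single-cell (yfp, cfp): noiseless signal times lognormal noise.

    yfp = (yfp_background + yfp_gain * E(g)) * eps_y,
    cfp = (cfp_background + cfp_per_copy * k) * eps_c,
    with eps lognormal, mean 1, CV = noise_cv, independent per channel.
    """
    e = expression_level(g, a)
    yfp0 = p.yfp_background + p.yfp_gain * e
    cfp0 = p.cfp_background + p.cfp_per_copy * g.k
    eps = _lognormal_mean1(p.noise_cv, 2, rng)
    return float(yfp0 * eps[0]), float(cfp0 * eps[1])


def ancestral_fluorescence(a: AlleleParams, p: ReporterParams) -> tuple[float, float]:
    """Noiseless (yfp, cfp) of the single-copy ancestral genotype."""
    return (p.yfp_background + p.yfp_gain * a.beta_anc, p.cfp_background + p.cfp_per_copy * 1.0)


def population_fluorescence(
    state: PopulationState,
    a: AlleleParams,
    p: ReporterParams,
) -> tuple[float, float]:
    """Bulk (yfp_norm, cfp_norm): abundance-weighted mean, ancestral-normalized.

    The abundance-weighted mean of the noiseless per-class signals, divided
    channel-wise by the ancestral single-copy value, so a pure ancestral
    population reads (1, 1) and normalized CFP is a direct copy-number proxy.
    """
    total = state.total
    if total <= 0:
        raise ExtinctPopulationError("empty population has no fluorescence")
    kmax = state.kmax
    e_grid = np.nan_to_num(expression_grid(kmax, a))
    k_grid = np.broadcast_to(np.arange(1, kmax + 1, dtype=float)[:, None], state.counts.shape)
    yfp_grid, cfp_grid = _noiseless(k_grid, e_grid, p)
    w = state.counts / total
    yfp = float((w * yfp_grid).sum())
    cfp = float((w * cfp_grid).sum())
    yfp_anc, cfp_anc = ancestral_fluorescence(a, p)
    return yfp / yfp_anc, cfp / cfp_anc


def sample_flow_events(
    state: PopulationState,
    a: AlleleParams,
    p: ReporterParams,
    n_events: int,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Draw a flow-cytometry-like event table from a population.

    Cells are drawn multinomially by class frequency and each is passed
    through the single-cell fluorescence model.  Returns a DataFrame with
    columns (event, yfp, cfp); ``df.attrs["sample_id"]`` carries the label.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    freqs = state.frequencies().ravel()
    class_counts = rng.multinomial(n_events, freqs / freqs.sum())
    kmax = state.kmax
    e_grid = np.nan_to_num(expression_grid(kmax, a)).ravel()
    k_grid = np.broadcast_to(
        np.arange(1, kmax + 1, dtype=float)[:, None], state.counts.shape
    ).ravel()

    yfp_parts, cfp_parts = [], []
    for idx in np.nonzero(class_counts)[0]:
        n_c = int(class_counts[idx])
        yfp0, cfp0 = _noiseless(k_grid[idx], e_grid[idx], p)
        yfp_parts.append(yfp0 * _lognormal_mean1(p.noise_cv, n_c, rng))
        cfp_parts.append(cfp0 * _lognormal_mean1(p.noise_cv, n_c, rng))
    yfp = np.concatenate(yfp_parts)
    cfp = np.concatenate(cfp_parts)
    df = pd.DataFrame({"event": np.arange(len(yfp)), "yfp": yfp, "cfp": cfp})
    df.attrs["sample_id"] = sample_id
    return df
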