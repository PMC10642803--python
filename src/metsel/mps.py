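"""Mean performance and stability (MPS) index.

Performance and stability are first rescaled to a common 0-100 scale,
with 100 always the desirable end (so lower-is-better traits such as
the plant-architecture score, and lower-is-better statistics such as
Sdi2 and RMSE, are order-reversed).  The MPS of genotype i is the
weighted convex combination

    MPS_i = (rY_i * w_perf + rE_i * w_stab) / (w_perf + w_stab)

with default weights 65 (performance) / 35 (stability).  A sweep over
weight pairs from 0/100 to 100/0 in 5-point steps gives 21 ranking
scenarios; the extremes are the pure-stability and pure-performance
rankings.  Genotypes are further classified in four quadrant groups by
comparing each axis to a threshold (the genotype mean of the axis by
default), and selection differentials are reported on the MPS scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stability import StabilityEstimates, STAT_HIGHER_IS_BETTER

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (65.0, 35.0)

GROUP_LABELS = {
    1: "productive and stable",
    2: "stable but low-productive",
    3: "productive but unstable",
    4: "low-productive and unstable",
}


def rescale(values: pd.Series, higher_is_better: bool = True,
            nmin: float = 0.0, nmax: float = 100.0) -> pd.Series:
    """Linear map of values onto [nmin, nmax], desirable end at nmax.

    The best value (largest when ``higher_is_better``, smallest
    otherwise) maps to 100 and the worst to 0.  A constant input is
    mapped to the neutral midpoint with a warning (the raw formula would
    divide by zero there).
    """
    if len(values) < 2:
        raise ValueError("need at least 2 values to rescale")
    v = values.astype(float)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        logger.warning("constant column rescaled to the neutral midpoint")
        return pd.Series((nmin + nmax) / 2.0, index=v.index)
    t = (v - vmin) / (vmax - vmin)
    if not higher_is_better:
        t = 1.0 - t
    return nmin + t * (nmax - nmin)


def mps(rY: pd.Series, rE: pd.Series, w_perf: float = DEFAULT_WEIGHTS[0],
        w_stab: float = DEFAULT_WEIGHTS[1]) -> pd.Series:
    """Weighted mean of rescaled performance and stability per genotype."""
    if w_perf < 0 or w_stab < 0 or (w_perf + w_stab) == 0:
        raise ValueError("weights must be >= 0 and not both zero")
    rY, rE = rY.align(rE, join="inner")
    return (rY * w_perf + rE * w_stab) / (w_perf + w_stab)


@dataclass
class MPSResult:
    """MPS values for one trait under one stability statistic."""

    trait: str
    stat: str
    rY: pd.Series
    rE: pd.Series
    mps: pd.Series
    weights: tuple[float, float]


def mps_for_trait(
    performance: pd.Series,
    stability: StabilityEstimates,
    stat: str,
    *,
    higher_is_better: bool = True,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    trait: str = "",
) -> MPSResult:
    """Build the MPS for one trait from genotype-level performance values
    (predicted genotypic means) and a fitted stability table."""
    if stat not in STAT_HIGHER_IS_BETTER:
        raise ValueError(f"stat must be one of {sorted(STAT_HIGHER_IS_BETTER)}")
    stat_vals = stability[stat]
    perf, stat_vals = performance.align(stat_vals, join="inner")
    rY = rescale(perf, higher_is_better)
    rE = rescale(stat_vals, STAT_HIGHER_IS_BETTER[stat])
    return MPSResult(
        trait=trait, stat=stat, rY=rY, rE=rE,
        mps=mps(rY, rE, *weights), weights=tuple(weights),
    )


@dataclass
class ScenarioGrid:
    """Genotype ranks across the performance/stability weight sweep."""

    mps_values: pd.DataFrame   # genotypes x scenarios, MPS values
    ranks: pd.DataFrame        # genotypes x scenarios, 1 = best, ties averaged
    weights: list[tuple[float, float]]

    @property
    def n_scenarios(self) -> int:
        return len(self.weights)


def scenario_sweep(rY: pd.Series, rE: pd.Series, step: float = 5.0) -> ScenarioGrid:
    """MPS rankings for weight pairs (w_perf, w_stab) from 0/100 to 100/0.

    ``step`` must divide 100; a 5-point step yields 21 scenarios.  Ranks
    are dense within a scenario with ties given their average rank.
    """
    if step <= 0 or (100.0 / step) % 1 != 0:
        raise ValueError("step must be a positive divisor of 100")
    weights = [(w, 100.0 - w) for w in np.arange(0.0, 100.0 + step, step)]
    cols = {}
    for w_perf, w_stab in weights:
        cols[f"{w_perf:g}/{w_stab:g}"] = mps(rY, rE, w_perf, w_stab)
    values = pd.DataFrame(cols)
    ranks = values.rank(ascending=False, method="average")
    return ScenarioGrid(mps_values=values, ranks=ranks, weights=weights)


def classify_groups(rY: pd.Series, rE: pd.Series,
                    threshold: str = "mean") -> pd.Series:
    """Quadrant classification of genotypes on the rescaled axes.

    Group 1: above-threshold performance and stability; Group 2: stable
    but low-productive; Group 3: productive but unstable; Group 4: low
    on both.  ``threshold`` is ``"mean"`` (default), ``"median"`` or
    ``"fixed50"``.
    """
    rY, rE = rY.align(rE, join="inner")
    if threshold == "mean":
        ty, te = float(rY.mean()), float(rE.mean())
    elif threshold == "median":
        ty, te = float(rY.median()), float(rE.median())
    elif threshold == "fixed50":
        ty = te = 50.0
    else:
        raise ValueError("threshold must be 'mean', 'median' or 'fixed50'")
    productive = rY >= ty
    stable = rE >= te
    group = pd.Series(4, index=rY.index, name="group")
    group[productive & stable] = 1
    group[~productive & stable] = 2
    group[productive & ~stable] = 3
    return group


@dataclass
class SelectionDifferential:
    Xo: float
    Xs: float
    SD: float
    SD_pct: float


def selection_differential(values: pd.Series, selected) -> SelectionDifferential:
    """Selection differential of a selected set on any genotype-level scale.

    Xo is the mean of all genotypes, Xs the mean of the selected ones,
    SD = Xs - Xo and SD% = 100 SD / Xo (missing when Xo = 0).
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected set is empty")
    xo = float(values.mean())
    xs = float(values.loc[selected].mean())
    sd = xs - xo
    sd_pct = 100.0 * sd / xo if xo != 0 else float("nan")
    return SelectionDifferential(Xo=xo, Xs=xs, SD=sd, SD_pct=sd_pct)


def differential_from_means(xo: float, xs: float) -> SelectionDifferential:
    """Selection differential straight from population and selected means."""
    sd = xs - xo
    return SelectionDifferential(
        Xo=xo, Xs=xs, SD=sd, SD_pct=100.0 * sd / xo if xo != 0 else float("nan")
    )


def select_top(values: pd.Series, intensity: float, *,
               higher_is_better: bool = True) -> list[str]:
    """Truncation selection of ceil(intensity * g) genotypes."""
    if not (0 < intensity <= 1):
        raise ValueError("intensity must be in (0, 1]")
    k = math.ceil(intensity * len(values))
    ordered = values.sort_values(ascending=not higher_is_better, kind="mergesort")
    return ordered.index[:k].tolist()
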