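"""Eberhart-Russell joint-regression stability analysis.

Each genotype's environment means are regressed on the coded
environmental index I_j (environment mean minus grand mean of the
environment means):

    y_ij = beta0_i + beta1_i * I_j + delta_ij

Three stability statistics feed the downstream selection indices:

* Sdi2 = SSE / (e_i - 2)  - variance of regression deviations (small =
  predictable genotype);
* R2   = 1 - SSE/SStot    - fraction of the genotype's environmental
  response captured by the linear term (large = responsive/adapted);
* RMSE = sqrt(SSE / e_i)  - root mean square error on the population
  denominator, so RMSE <= sqrt(Sdi2) always.

Sdi2 is the raw residual variance of the regression on cell means; no
pooled-error correction is subtracted (the analysis runs on genotype x
environment means, not plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EnvironmentalIndex:
    """Coded environmental index and the genotype counts behind it."""

    index: pd.Series          # I_j per environment
    n_genotypes: pd.Series    # genotypes contributing to each environment mean
    grand_mean: float


def environmental_index(cm: pd.DataFrame) -> EnvironmentalIndex:
    """Environmental index from a genotype x environment cell-mean matrix.

    Each environment mean uses the genotypes present there; the grand
    mean is the unweighted mean of the environment means, so the index
    sums to zero (exactly on balanced data, and by construction here).
    Environments with no data are excluded with a warning.
    """
    counts = cm.notna().sum(axis=0)
    empty = counts[counts == 0].index.tolist()
    if empty:
        logger.warning("environments with no data excluded from index: %s", empty)
        cm = cm.drop(columns=empty)
        counts = counts.drop(empty)
    if cm.shape[1] < 2:
        raise ValueError("need at least 2 environments with data")
    env_means = cm.mean(axis=0, skipna=True)
    grand = float(env_means.mean())
    return EnvironmentalIndex(index=env_means - grand, n_genotypes=counts,
                              grand_mean=grand)


@dataclass
class StabilityEstimates:
    """Per-genotype joint-regression results for one trait."""

    table: pd.DataFrame  # columns: beta0, beta1, Sdi2, R2, RMSE, SSE, e_i
    skipped: dict[str, str]

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def fit_er(cm: pd.DataFrame, index: EnvironmentalIndex | None = None,
           *, min_envs: int = 3) -> StabilityEstimates:
    """Joint regression of each genotype's means on the environmental index.

    ``cm`` is the genotype x environment cell-mean matrix.  Genotypes
    observed in fewer than ``min_envs`` environments are skipped with a
    logged reason.  A genotype whose means do not vary at all gets
    beta1 = 0 and R2 defined as 0.
    """
    if index is None:
        index = environmental_index(cm)
    I = index.index
    if float(np.nanvar(I.to_numpy())) == 0:
        raise ValueError("environmental index has zero variance")
    rows, skipped = {}, {}
    for genotype, means in cm.iterrows():
        mask = means.notna() & means.index.isin(I.index)
        e_i = int(mask.sum())
        if e_i < min_envs:
            skipped[genotype] = f"only {e_i} environments (< {min_envs})"
            logger.info("skipping %s for stability: %s", genotype, skipped[genotype])
            continue
        y = means[mask].to_numpy(float)
        x = I[means.index[mask]].to_numpy(float)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            skipped[genotype] = "zero index variance among its environments"
            continue
        beta1 = float(xc @ (y - y.mean())) / sxx
        beta0 = float(y.mean() - beta1 * x.mean())
        resid = y - (beta0 + beta1 * x)
        sse = float(resid @ resid)
        sstot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sstot if sstot > 0 else 0.0
        rows[genotype] = {
            "beta0": beta0,
            "beta1": beta1,
            "Sdi2": sse / (e_i - 2),
            "R2": r2,
            "RMSE": np.sqrt(sse / e_i),
            "SSE": sse,
            "e_i": e_i,
        }
    if not rows:
        raise ValueError("no genotype has enough environments for the regression")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return StabilityEstimates(table=table, skipped=skipped)


#: Orientation of each stability statistic: True where larger is better.
STAT_HIGHER_IS_BETTER = {"Sdi2": False, "R2": True, "RMSE": False}
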