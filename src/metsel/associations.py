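"""Trait-relationship layer: correlation network and path analysis.

Correlations are computed by default on the per-trait MPS values (one
column per trait, rows = genotypes), mirroring how breeders read the
trait network after the performance/stability weighting; raw genotype
means can be passed instead.  Path ("trail") analysis decomposes the
correlation between predictor traits and a response trait into direct
effects, the standardized partial regression coefficients

    b = Rxx^{-1} r_xy ,

with residual effect sqrt(1 - b' r_xy) and variance-inflation factors
from the diagonal of Rxx^{-1}.  VIF above 10 signals multicollinearity
and is reported as a warning, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    edges: pd.DataFrame     # trait_a, trait_b, r, p_value, significant
    graph: nx.Graph         # filtered network (alpha and |r| thresholds)
    alpha: float
    min_abs_r: float
    excluded: list[str]     # constant columns with undefined correlations


def correlation_network(
    values: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_r: float = 0.0,
    *,
    bonferroni: bool = False,
) -> CorrelationNetwork:
    """Pairwise Pearson correlation network among trait columns.

    Edges carry r and the two-sided t-test p-value; the graph keeps
    edges with p <= alpha (Bonferroni-adjusted if requested) and
    |r| >= min_abs_r.  Constant columns are excluded with a warning.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 rows for correlation tests")
    excluded = [c for c in values.columns if values[c].nunique() <= 1]
    if excluded:
        logger.warning("constant column(s) excluded from network: %s", excluded)
    cols = [c for c in values.columns if c not in excluded]
    pairs = list(combinations(cols, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        r, p = stats.pearsonr(values[a], values[b])
        p_eff = min(p * m, 1.0) if bonferroni else p
        rows.append({"trait_a": a, "trait_b": b, "r": float(r),
                     "p_value": float(p_eff),
                     "significant": bool(p_eff <= alpha and abs(r) >= min_abs_r)})
    edges = pd.DataFrame(rows)
    graph = nx.Graph()
    graph.add_nodes_from(cols)
    for row in rows:
        if row["significant"]:
            graph.add_edge(row["trait_a"], row["trait_b"],
                           r=row["r"], p_value=row["p_value"])
    return CorrelationNetwork(edges=edges, graph=graph, alpha=alpha,
                              min_abs_r=min_abs_r, excluded=excluded)


@dataclass
class PathAnalysis:
    response: str
    direct_effects: pd.Series   # standardized partial regression coefficients
    residual_effect: float
    r_squared: float
    vif: pd.Series
    correlations_with_response: pd.Series

    def high_vif(self, threshold: float = 10.0) -> list[str]:
        return self.vif.index[self.vif > threshold].tolist()


def path_analysis(predictors: pd.DataFrame, response: pd.Series,
                  *, vif_warn: float = 10.0) -> PathAnalysis:
    """Direct effects of predictor traits on a response, correlation scale."""
    X = predictors.astype(float)
    y = response.astype(float)
    Rxx = np.corrcoef(X.to_numpy(), rowvar=False)
    if X.shape[1] == 1:
        Rxx = np.atleast_2d(Rxx)
    rxy = np.array([stats.pearsonr(X[c], y)[0] for c in X.columns])
    try:
        Rinv = np.linalg.inv(Rxx)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular predictor correlation matrix (perfect collinearity)"
        ) from exc
    vif = pd.Series(np.diag(Rinv), index=X.columns, name="vif")
    if (vif > vif_warn).any():
        logger.warning("high multicollinearity: VIF > %s for %s",
                       vif_warn, vif.index[vif > vif_warn].tolist())
    b = Rinv @ rxy
    r2 = float(b @ rxy)
    residual = float(np.sqrt(max(1.0 - r2, 0.0)))
    return PathAnalysis(
        response=response.name or "response",
        direct_effects=pd.Series(b, index=X.columns, name="direct_effect"),
        residual_effect=residual,
        r_squared=r2,
        vif=vif,
        correlations_with_response=pd.Series(rxy, index=X.columns, name="r"),
    )
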