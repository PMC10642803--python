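"""Factor analysis of the MPS matrix and the MTMPS selection index.

The genotypes x traits matrix of MPS values (one column per trait, all
on the 0-100 scale with 100 desirable) is summarized by an exploratory
factor model X = mu + L f + eps fitted from the trait correlation
matrix R: factors with eigenvalue >= 1 are retained (Kaiser rule,
overridable), initial loadings eigvec * sqrt(lambda) are varimax-rotated
with Kaiser row normalization, and genotype scores use the
regression-type estimator

    F = Z (A' R^-1)'

with Z the column-standardized MPS matrix.  The ideotype is the
hypothetical genotype with MPS = 100 on every trait (trait directions
are already folded into the rescaling); it is standardized with the
genotype columns' means/sds and scored by the same estimator.  The
multi-trait index is the Euclidean genotype-ideotype distance over the
retained factor scores,

    MTMPS_i = sqrt( sum_j (F_ij - F_j)^2 ),

smaller meaning closer to the ideotype; selection keeps the
ceil(intensity * g) smallest at the default 30% intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors


@dataclass
class FactorModel:
    correlation: pd.DataFrame          # p x p trait correlations
    eigenvalues: pd.Series             # all p eigenvalues, descending
    n_factors: int
    loadings_unrotated: pd.DataFrame   # p x f
    loadings: pd.DataFrame             # p x f varimax-rotated
    communalities: pd.Series           # per trait, row sums of squared loadings
    explained_pct: pd.Series           # per retained factor
    cumulative_pct: pd.Series
    scores: pd.DataFrame               # q x f genotype factor scores
    means: pd.Series                   # column means used for standardization
    sds: pd.Series                     # column sds (ddof=1)

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    def trait_factor_map(self) -> pd.Series:
        """Factor of maximum absolute loading per trait (ties: lower index)."""
        return self.loadings.abs().idxmax(axis=1)


def explained_variance_pct(eigenvalues, p: int | None = None) -> np.ndarray:
    """Percent variance per factor, lambda / p * 100."""
    ev = np.asarray(eigenvalues, float)
    if p is None:
        p = len(ev)
    return ev / p * 100.0


def communalities_from_loadings(loadings: pd.DataFrame) -> pd.Series:
    """Row sums of squared loadings: variance shared with the factors."""
    return (loadings ** 2).sum(axis=1)


def varimax(loadings: np.ndarray, *, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation with Kaiser row normalization."""
    A = np.asarray(loadings, float)
    if A.shape[1] < 2:
        return A.copy()
    if normalize:
        h = np.sqrt((A ** 2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    L, _T = rotate_factors(A, "varimax", tol=tol, max_tries=max_iter)
    if normalize:
        L = L * h[:, None]
    return L


def _display_signs(L: np.ndarray) -> np.ndarray:
    """Per-factor sign flip making the largest-|loading| entry negative.

    Display convention only; every distance downstream is sign-invariant.
    """
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] > 0:
            signs[j] = -1.0
    return L * signs


def fit_factor_model(
    mps_matrix: pd.DataFrame,
    *,
    n_factors: int | None = None,
    ridge: float = 0.0,
) -> FactorModel:
    """Exploratory factor analysis of a genotypes x traits MPS matrix.

    Retains factors with eigenvalue >= 1 unless ``n_factors`` overrides.
    ``ridge`` adds a small diagonal to the correlation matrix if it is
    numerically singular.
    """
    X = mps_matrix.astype(float)
    q, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 traits")
    sds = X.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise ValueError(f"constant MPS column(s) {bad}: correlation undefined")
    means = X.mean()
    Z = (X - means) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    if ridge:
        R = R + ridge * np.eye(p)
        dscale = np.sqrt(np.diag(R))
        R = R / np.outer(dscale, dscale)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    f = int(np.sum(evals >= 1.0)) if n_factors is None else int(n_factors)
    f = max(1, min(f, p))
    L0 = evecs[:, :f] * np.sqrt(np.clip(evals[:f], 0.0, None))
    L = _display_signs(varimax(L0)) if f > 1 else _display_signs(L0.copy())

    factor_names = [f"FA{j+1}" for j in range(f)]
    # keep factor order by explained variance after rotation
    expl = (L ** 2).sum(axis=0)
    order_f = np.argsort(expl)[::-1]
    L, L0 = L[:, order_f], L0[:, order_f]
    expl = expl[order_f]

    loadings = pd.DataFrame(L, index=X.columns, columns=factor_names)
    loadings_unrot = pd.DataFrame(L0, index=X.columns, columns=factor_names)
    communal = communalities_from_loadings(loadings)
    expl_pct = pd.Series(expl / p * 100.0, index=factor_names)
    cum_pct = expl_pct.cumsum()

    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular correlation matrix; pass ridge=1e-8 or larger"
        ) from exc
    scores = pd.DataFrame(
        Z.to_numpy() @ Rinv @ L, index=X.index, columns=factor_names
    )
    return FactorModel(
        correlation=pd.DataFrame(R, index=X.columns, columns=X.columns),
        eigenvalues=pd.Series(evals, index=[f"PC{i+1}" for i in range(p)]),
        n_factors=f,
        loadings_unrotated=loadings_unrot,
        loadings=loadings,
        communalities=communal,
        explained_pct=expl_pct,
        cumulative_pct=cum_pct,
        scores=scores,
        means=means,
        sds=sds,
    )


def ideotype_scores(model: FactorModel, ideal_value: float = 100.0) -> pd.Series:
    """Factor scores of the ideotype (MPS = 100 on every trait).

    The ideotype row is standardized with the genotype columns' own
    means and sds, then pushed through the same score estimator.
    """
    z = (ideal_value - model.means) / model.sds
    Rinv = np.linalg.inv(model.correlation.to_numpy())
    f = z.to_numpy() @ Rinv @ model.loadings.to_numpy()
    return pd.Series(f, index=model.factor_names, name="ideotype")


@dataclass
class MTMPSResult:
    distances: pd.Series            # MTMPS per genotype, ascending = better
    ranking: pd.Series              # 1 = closest to the ideotype
    selected: list[str]
    intensity: float
    ideotype: pd.Series
    scores: pd.DataFrame
    contributions: pd.DataFrame     # per-genotype factor contribution shares
    uniform_contribution_flags: list[str]


def mtmps(model: FactorModel, *, intensity: float = 0.30,
          ideotype: pd.Series | None = None) -> MTMPSResult:
    """Genotype-ideotype distance index over the retained factors."""
    if not (0 < intensity <= 1):
        raise ValueError("intensity must be in (0, 1]")
    ideo = ideotype_scores(model) if ideotype is None else ideotype
    diff = model.scores - ideo
    dist = np.sqrt((diff ** 2).sum(axis=1))
    dist.name = "MTMPS"
    ranking = dist.rank(method="first").astype(int)
    k = math.ceil(intensity * len(dist))
    selected = dist.sort_values(kind="mergesort").index[:k].tolist()

    contributions = (diff ** 2).div(dist ** 2, axis=0)
    flags = dist.index[dist == 0].tolist()
    if flags:
        contributions.loc[flags] = 1.0 / model.n_factors
    return MTMPSResult(
        distances=dist, ranking=ranking, selected=selected,
        intensity=intensity, ideotype=ideo, scores=model.scores.copy(),
        contributions=contributions, uniform_contribution_flags=flags,
    )


def selection_gains(
    trait_means: pd.DataFrame,
    selected,
    directions: dict[str, str],
    factor_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-trait gain table for a selected genotype set.

    ``trait_means`` is genotypes x traits on the original scale
    (predicted genotypic means).  Per trait: Xo (all-genotype mean), Xs
    (selected mean), GS = Xs - Xo, SG% = 100 GS / Xo, the declared
    direction and whether the realized gain points the right way.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected set is empty")
    rows = []
    for trait in trait_means.columns:
        xo = float(trait_means[trait].mean())
        xs = float(trait_means.loc[selected, trait].mean())
        gs = xs - xo
        sg = 100.0 * gs / xo if xo != 0 else float("nan")
        direction = directions.get(trait, "higher")
        goal_met = gs >= 0 if direction == "higher" else gs <= 0
        rows.append({
            "trait": trait,
            "factor": factor_map.get(trait, "") if factor_map is not None else "",
            "Xo": xo, "Xs": xs, "GS": gs, "SG_pct": sg,
            "direction": "increase" if direction == "higher" else "decrease",
            "goal_met": bool(goal_met),
        })
    return pd.DataFrame(rows).set_index("trait")
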