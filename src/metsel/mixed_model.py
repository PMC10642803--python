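"""REML fitting of the MET random-effects model.

Model (one trait at a time):

    Y_ijk = mu + alpha_i + tau_j + (alpha tau)_ij + y_jk + eps_ijk

with genotype alpha_i ~ N(0, sigma_g^2), environment tau_j ~ N(0,
sigma_e^2) and their interaction ~ N(0, sigma_gxe^2) all random,
block-within-environment y_jk fixed, and eps ~ N(0, sigma_eps^2).

Blocks are coded as sum-to-zero contrasts *within* each environment plus
a global intercept.  With full block dummies the fixed space would
contain every environment indicator, and the environment variance would
vanish from all REML error contrasts, i.e. be non-identifiable; the
within-environment contrast coding keeps between-environment variation
in the random part, which is the only coherent reading of a model with
random environments and fixed blocks.

Two REML engines share one likelihood:

* ``method="profile"`` (default): Nelder-Mead over the log variance
  ratios gamma_i = sigma_i^2 / sigma_eps^2 with sigma_eps^2 profiled
  out.  The mixed-model equations are evaluated with the large
  interaction block absorbed (its coefficient block is diagonal), so
  each likelihood evaluation costs a Cholesky of a small dense matrix.
* ``method="em"``: the classical expectation-maximization REML
  iteration, kept as the transparent reference implementation; its
  restricted likelihood is non-decreasing across iterations.

BLUPs, prediction-error variances (PEV) and genotype BLUEs (from the
companion fixed-genotype model used for the Piepho heritability) are
recovered from the mixed-model equations at the converged components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .met_data import METDataset, GENOTYPE, ENVIRONMENT, BLOCK

_LOG2PI = np.log(2.0 * np.pi)
_RANDOM_TERMS = ("genotype", "environment", "gei")


class ConvergenceError(RuntimeError):
    """REML did not converge; carries the last iterate in ``last``."""

    def __init__(self, msg: str, last=None):
        super().__init__(msg)
        self.last = last


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_gxe: float
    sigma2_eps: float
    loglik: float
    converged: bool
    n_iter: int

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "sigma2_gxe": self.sigma2_gxe,
            "sigma2_eps": self.sigma2_eps,
        }


@dataclass
class ModelFit:
    """Converged random-model fit for one trait."""

    trait: str
    components: VarianceComponents
    mu: float
    blups_genotype: pd.Series
    pev_genotype: pd.Series
    pev_cov_genotype: pd.DataFrame    # g x g PEV covariance of genotype BLUPs
    blups_gei: pd.Series              # indexed by (genotype, environment)
    block_effects: pd.Series          # fixed block contrasts (within-env)
    blues_genotype: pd.Series | None = None
    blue_cov_genotype: pd.DataFrame | None = None
    n_obs: int = 0
    grand_mean_raw: float = 0.0

    @property
    def predicted_genotype_means(self) -> pd.Series:
        """mu + genotype BLUP: the predicted genotypic value per genotype."""
        return self.mu + self.blups_genotype


@dataclass
class LRTResult:
    term: str
    statistic: float
    df: int
    p_value: float
    kind: str = "lrt"  # "lrt" for random terms, "wald_f" for the block term


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

class _Design:
    """Pre-computed cross-products for one trait's mixed-model equations.

    W collects the dense part [X | Z_genotype | Z_environment]; the
    genotype-by-environment block Z_c is kept implicitly through its
    diagonal cross-product and coupling matrix B = W' Z_c.
    """

    def __init__(self, dataset: METDataset, trait: str,
                 random_terms: tuple[str, ...] = _RANDOM_TERMS,
                 fixed_genotype: bool = False):
        df = dataset.records[[GENOTYPE, ENVIRONMENT, BLOCK, trait]].dropna(subset=[trait])
        if df.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        y = df[trait].to_numpy(float)
        if np.allclose(y.var(), 0):
            raise ValueError(f"trait {trait!r} has zero variance")
        self.y = y
        self.n = len(y)
        self.trait = trait

        genos = sorted(df[GENOTYPE].unique())
        envs = sorted(df[ENVIRONMENT].unique())
        gi = pd.Categorical(df[GENOTYPE], categories=genos).codes
        ej = pd.Categorical(df[ENVIRONMENT], categories=envs).codes
        self.genotypes, self.environments = genos, envs
        self.g, self.e = len(genos), len(envs)

        # fixed part: intercept + sum-to-zero block contrasts within env
        cols = [np.ones(self.n)]
        self.block_labels: list[str] = []
        for j, env in enumerate(envs):
            in_env = ej == j
            blocks = sorted(df.loc[df[ENVIRONMENT].eq(env), BLOCK].unique())
            ref = blocks[-1]
            for b in blocks[:-1]:
                col = np.zeros(self.n)
                col[in_env & df[BLOCK].eq(b).to_numpy()] = 1.0
                col[in_env & df[BLOCK].eq(ref).to_numpy()] = -1.0
                cols.append(col)
                self.block_labels.append(f"{env}:{b}")
        X = np.column_stack(cols)
        if fixed_genotype:
            # cell-mean genotype coding replaces the intercept
            Xg = np.zeros((self.n, self.g))
            Xg[np.arange(self.n), gi] = 1.0
            X = np.column_stack([Xg, X[:, 1:]])
        self.p = X.shape[1]
        self.fixed_genotype = fixed_genotype

        # dense random blocks inside W
        blocks_W = [X]
        self.slices: dict[str, slice] = {}
        pos = self.p
        self.random_terms = tuple(random_terms)
        if "genotype" in random_terms and not fixed_genotype:
            Zg = np.zeros((self.n, self.g))
            Zg[np.arange(self.n), gi] = 1.0
            blocks_W.append(Zg)
            self.slices["genotype"] = slice(pos, pos + self.g)
            pos += self.g
        if "environment" in random_terms:
            Ze = np.zeros((self.n, self.e))
            Ze[np.arange(self.n), ej] = 1.0
            blocks_W.append(Ze)
            self.slices["environment"] = slice(pos, pos + self.e)
            pos += self.e
        W = np.column_stack(blocks_W)
        self.m = W.shape[1]

        # interaction block, absorbed: cells observed in the data
        self.has_gei = "gei" in random_terms
        if self.has_gei:
            cell_codes, cell_index = pd.factorize(
                pd.Series(list(zip(gi, ej))), sort=True
            )
            self.q_c = len(cell_index)
            self.cell_index = [(genos[a], envs[b]) for a, b in cell_index]
            Zc = np.zeros((self.n, self.q_c))
            Zc[np.arange(self.n), cell_codes] = 1.0
            self.d = np.bincount(cell_codes, minlength=self.q_c).astype(float)
            self.B = W.T @ Zc
            self.cy = Zc.T @ y
        else:
            self.q_c = 0
            self.cell_index = []
            self.d = np.zeros(0)
            self.B = np.zeros((self.m, 0))
            self.cy = np.zeros(0)

        self.M = W.T @ W
        self.Wy = W.T @ y
        self.yy = float(y @ y)
        self.q = {
            "genotype": self.g, "environment": self.e, "gei": self.q_c,
        }
        self.active = tuple(
            t for t in random_terms if t != "genotype" or not fixed_genotype
        )

    # -- likelihood machinery ------------------------------------------
    def _assemble(self, gammas: dict[str, float]):
        """Return (S, rhs, logdet_D, dfull) with the GEI block absorbed."""
        diag = np.zeros(self.m)
        for term, sl in self.slices.items():
            diag[sl] = 1.0 / gammas[term]
        A = self.M + np.diag(diag)
        if self.has_gei:
            dfull = self.d + 1.0 / gammas["gei"]
            Bd = self.B / dfull
            S = A - Bd @ self.B.T
            rhs = self.Wy - Bd @ self.cy
            return S, rhs, float(np.sum(np.log(dfull))), dfull
        return A, self.Wy, 0.0, None

    def neg2_reml(self, gammas: dict[str, float]) -> float:
        """-2 restricted log-likelihood with sigma_eps^2 profiled out."""
        S, rhs, logdet_D, dfull = self._assemble(gammas)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(L))))
        theta_w = _chol_solve(L, rhs)
        ypy = self.yy - float(theta_w @ self.Wy)
        if self.has_gei:
            theta_c = (self.cy - self.B.T @ theta_w) / dfull
            ypy -= float(theta_c @ self.cy)
        nu = self.n - self.p
        if ypy <= 0:
            return np.inf
        logdet_G = sum(self.q[t] * np.log(gammas[t]) for t in self.active)
        return (
            nu * np.log(ypy / nu) + logdet_G + logdet_S + logdet_D
            + nu * (1.0 + _LOG2PI)
        )

    def neg2_reml_sigmas(self, sigmas: dict[str, float], s2e: float) -> float:
        """-2 restricted log-likelihood at explicit variance components."""
        gammas = {t: max(sigmas[t], 1e-12) / s2e for t in self.active}
        S, rhs, logdet_D, dfull = self._assemble(gammas)
        L = np.linalg.cholesky(S)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(L))))
        theta_w = _chol_solve(L, rhs)
        ypy = self.yy - float(theta_w @ self.Wy)
        if self.has_gei:
            theta_c = (self.cy - self.B.T @ theta_w) / dfull
            ypy -= float(theta_c @ self.cy)
        nu = self.n - self.p
        logdet_G = sum(self.q[t] * np.log(gammas[t]) for t in self.active)
        return (
            nu * np.log(s2e) + logdet_G + logdet_S + logdet_D
            + ypy / s2e + nu * _LOG2PI
        )

    def solve(self, gammas: dict[str, float]):
        """Solutions, inverse blocks and profiled residual variance."""
        S, rhs, logdet_D, dfull = self._assemble(gammas)
        Sinv = np.linalg.inv(S)
        theta_w = Sinv @ rhs
        ypy = self.yy - float(theta_w @ self.Wy)
        theta_c = None
        if self.has_gei:
            theta_c = (self.cy - self.B.T @ theta_w) / dfull
            ypy -= float(theta_c @ self.cy)
        s2e = ypy / (self.n - self.p)
        return theta_w, theta_c, Sinv, dfull, s2e

    def cinv_diag_gei(self, Sinv: np.ndarray, dfull: np.ndarray) -> np.ndarray:
        """Diagonal of the absorbed GEI block of the MME inverse."""
        Bd = self.B / dfull
        return 1.0 / dfull + np.einsum("ij,ij->j", Bd, Sinv @ Bd)


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    return solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)


# ---------------------------------------------------------------------------
# ANOVA starting values (method of moments; exact oracle under balance)
# ---------------------------------------------------------------------------

def anova_components(dataset: METDataset, trait: str) -> dict[str, float]:
    """Method-of-moments variance components for a *balanced* design.

    Classical expected-mean-square solutions of the two-way model with
    blocks nested in environments; on balanced data these coincide with
    REML whenever all estimates are interior.
    """
    df = dataset.records.dropna(subset=[trait])
    g = df[GENOTYPE].nunique()
    e = df[ENVIRONMENT].nunique()
    b = df.groupby(ENVIRONMENT)[BLOCK].nunique()
    if b.nunique() != 1 or len(df) != g * e * b.iloc[0]:
        raise ValueError("anova_components requires a fully balanced dataset")
    b = int(b.iloc[0])
    y = df[trait]
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    gm = df.groupby(GENOTYPE)[trait].mean()
    em = df.groupby(ENVIRONMENT)[trait].mean()
    bm = df.groupby([ENVIRONMENT, BLOCK])[trait].mean()
    cm = df.groupby([GENOTYPE, ENVIRONMENT])[trait].mean()
    ss_g = e * b * ((gm - grand) ** 2).sum()
    ss_e = g * b * ((em - grand) ** 2).sum()
    ss_blk = g * ((bm - em.reindex(bm.index.get_level_values(0)).to_numpy()) ** 2).sum()
    cm_frame = cm.reset_index()
    cm_frame["resid"] = (
        cm_frame[trait]
        - gm.reindex(cm_frame[GENOTYPE]).to_numpy()
        - em.reindex(cm_frame[ENVIRONMENT]).to_numpy()
        + grand
    )
    ss_ge = b * (cm_frame["resid"] ** 2).sum()
    ss_err = ss_total - ss_g - ss_e - ss_blk - ss_ge
    ms_g = ss_g / (g - 1)
    ms_e = ss_e / (e - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_err = ss_err / (e * (g - 1) * (b - 1))
    return {
        "sigma2_eps": ms_err,
        "sigma2_gxe": max((ms_ge - ms_err) / b, 0.0),
        "sigma2_g": max((ms_g - ms_ge) / (e * b), 0.0),
        "sigma2_e": max((ms_e - ms_ge) / (g * b), 0.0),
    }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_KEY = {"genotype": "sigma2_g", "environment": "sigma2_e", "gei": "sigma2_gxe"}


def _optimize_profile(design: _Design, tol: float, max_iter: int):
    terms = design.active
    k = len(terms)

    def f(x):
        return design.neg2_reml(dict(zip(terms, np.exp(x))))

    x0 = np.zeros(k)
    res = optimize.minimize(
        f, x0, method="Nelder-Mead",
        bounds=[(-16.0, 16.0)] * k,
        options={"xatol": tol, "fatol": tol, "maxiter": max_iter, "maxfev": max_iter},
    )
    gammas = dict(zip(terms, np.exp(res.x)))
    return gammas, res


def fit_random_model(
    dataset: METDataset,
    trait: str,
    *,
    method: str = "profile",
    random_terms: tuple[str, ...] = _RANDOM_TERMS,
    tol: float = 1e-8,
    max_iter: int = 2000,
    with_blues: bool = True,
) -> ModelFit:
    """Fit the random genotype/environment/GEI model by REML for one trait.

    ``method="profile"`` (default) optimizes the profiled restricted
    likelihood; ``method="em"`` runs the reference EM iteration.  When
    ``with_blues`` the companion fixed-genotype model is also fitted so
    Piepho's heritability can be computed downstream.
    """
    design = _Design(dataset, trait, random_terms=random_terms)

    if method == "profile":
        gammas, res = _optimize_profile(design, tol=1e-10, max_iter=4000)
        n_iter = int(res.nit)
        converged = bool(res.success)
        if not converged:
            raise ConvergenceError(
                f"REML optimizer failed for {trait!r}: {res.message}", last=gammas
            )
    elif method == "em":
        gammas, n_iter, converged = _em_reml(design, tol=tol, max_iter=max_iter)
        if not converged:
            raise ConvergenceError(
                f"EM-REML did not converge within {max_iter} iterations for {trait!r}",
                last=gammas,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    theta_w, theta_c, Sinv, dfull, s2e = design.solve(gammas)
    comps = {"sigma2_eps": s2e}
    for term in design.active:
        comps[_KEY[term]] = gammas[term] * s2e
    # variance ratios driven to the lower bound are boundary estimates: report 0
    for term in design.active:
        if gammas[term] <= 2e-7:
            comps[_KEY[term]] = 0.0
    loglik = -0.5 * design.neg2_reml(gammas)

    vc = VarianceComponents(
        sigma2_g=comps.get("sigma2_g", 0.0),
        sigma2_e=comps.get("sigma2_e", 0.0),
        sigma2_gxe=comps.get("sigma2_gxe", 0.0),
        sigma2_eps=comps["sigma2_eps"],
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
    )

    sl_g = design.slices.get("genotype")
    mu = float(theta_w[0])
    blups_g = pd.Series(theta_w[sl_g], index=design.genotypes, name=trait)
    pev_cov = s2e * Sinv[sl_g, :][:, sl_g]
    pev_cov_df = pd.DataFrame(pev_cov, index=design.genotypes, columns=design.genotypes)
    pev = pd.Series(np.diag(pev_cov), index=design.genotypes, name="pev")

    if design.has_gei and theta_c is not None:
        gei_index = pd.MultiIndex.from_tuples(
            design.cell_index, names=[GENOTYPE, ENVIRONMENT]
        )
        blups_gei = pd.Series(theta_c, index=gei_index, name="gei_blup")
    else:
        blups_gei = pd.Series(dtype=float)
    block_eff = pd.Series(theta_w[1: design.p], index=design.block_labels)

    fit = ModelFit(
        trait=trait,
        components=vc,
        mu=mu,
        blups_genotype=blups_g,
        pev_genotype=pev,
        pev_cov_genotype=pev_cov_df,
        blups_gei=blups_gei,
        block_effects=block_eff,
        n_obs=design.n,
        grand_mean_raw=float(design.y.mean()),
    )
    if with_blues:
        blues, blue_cov = fit_genotype_blues(dataset, trait)
        fit.blues_genotype = blues
        fit.blue_cov_genotype = blue_cov
    return fit


def _em_reml(design: _Design, tol: float, max_iter: int):
    """Classical EM-REML iteration on the mixed-model equations.

    Updates sigma_i^2 <- (u_i'u_i + s2e * tr(Cinv_ii)) / q_i and the
    residual from y'Py; every update keeps components non-negative by
    construction.  Returns variance *ratios* for the shared machinery.
    """
    sigmas = {t: 1.0 for t in design.active}
    s2e = float(np.var(design.y))
    prev_m2 = np.inf
    for it in range(1, max_iter + 1):
        gammas = {t: sigmas[t] / s2e for t in design.active}
        theta_w, theta_c, Sinv, dfull, _ = design.solve(gammas)
        new = {}
        for term in design.active:
            if term == "gei":
                u = theta_c
                tr = float(np.sum(design.cinv_diag_gei(Sinv, dfull)))
            else:
                sl = design.slices[term]
                u = theta_w[sl]
                tr = float(np.trace(Sinv[sl, sl]))
            new[term] = (float(u @ u) + s2e * tr) / design.q[term]
        ypy = design.yy - float(theta_w @ design.Wy)
        if design.has_gei:
            ypy -= float(theta_c @ design.cy)
        s2e_new = ypy / (design.n - design.p)
        rel = max(
            abs(new[t] - sigmas[t]) / max(sigmas[t], 1e-12) for t in design.active
        )
        rel = max(rel, abs(s2e_new - s2e) / max(s2e, 1e-12))
        sigmas, s2e = new, s2e_new
        if rel < tol:
            return {t: sigmas[t] / s2e for t in design.active}, it, True
    return {t: sigmas[t] / s2e for t in design.active}, max_iter, False


def em_loglik_path(dataset: METDataset, trait: str, n_iter: int = 25) -> list[float]:
    """Restricted log-likelihood after each of the first EM iterations.

    Exposed so the EM monotonicity guarantee can be checked directly.
    """
    design = _Design(dataset, trait)
    sigmas = {t: 1.0 for t in design.active}
    s2e = float(np.var(design.y))
    path = []
    for _ in range(n_iter):
        gammas = {t: max(sigmas[t], 1e-12) / s2e for t in design.active}
        path.append(-0.5 * design.neg2_reml_sigmas(sigmas, s2e))
        theta_w, theta_c, Sinv, dfull, _ = design.solve(gammas)
        new = {}
        for term in design.active:
            if term == "gei":
                u = theta_c
                tr = float(np.sum(design.cinv_diag_gei(Sinv, dfull)))
            else:
                sl = design.slices[term]
                u = theta_w[sl]
                tr = float(np.trace(Sinv[sl, sl]))
            new[term] = (float(u @ u) + s2e * tr) / design.q[term]
        ypy = design.yy - float(theta_w @ design.Wy)
        if design.has_gei:
            ypy -= float(theta_c @ design.cy)
        s2e = ypy / (design.n - design.p)
        sigmas = new
    return path


def fit_genotype_blues(dataset: METDataset, trait: str):
    """Genotype BLUEs and their covariance from the fixed-genotype model.

    Companion model for Piepho's heritability: genotype and blocks
    fixed, environment and GEI random, components re-estimated by REML.
    """
    design = _Design(
        dataset, trait, random_terms=("environment", "gei"), fixed_genotype=True
    )
    gammas, res = _optimize_profile(design, tol=1e-10, max_iter=2000)
    theta_w, theta_c, Sinv, dfull, s2e = design.solve(gammas)
    blues = pd.Series(theta_w[: design.g], index=design.genotypes, name=trait)
    cov = pd.DataFrame(
        s2e * Sinv[: design.g, : design.g],
        index=design.genotypes, columns=design.genotypes,
    )
    return blues, cov


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def lrt(dataset: METDataset, trait: str, term: str,
        *, boundary_correction: bool = False) -> LRTResult:
    """Likelihood-ratio test for one random term (chi-square, 1 df).

    The statistic is (-2 logL_R of the model without the term) minus
    (-2 logL_R of the full model), floored at 0.  By default the p-value
    uses a plain chi-square(1) reference, which is conservative because
    the null value sits on the boundary of the parameter space;
    ``boundary_correction=True`` uses the calibrated 50:50 mixture of a
    point mass at 0 and chi-square(1).  The block term is fixed, so
    ``term="block"`` reports the Wald F analogue instead and is
    labelled as such.
    """
    if term == "block":
        return _block_wald_f(dataset, trait)
    if term not in _RANDOM_TERMS:
        raise ValueError(f"unknown term {term!r}")
    full = _Design(dataset, trait)
    g_full, _ = _optimize_profile(full, tol=1e-10, max_iter=4000)
    reduced_terms = tuple(t for t in _RANDOM_TERMS if t != term)
    red = _Design(dataset, trait, random_terms=reduced_terms)
    g_red, _ = _optimize_profile(red, tol=1e-10, max_iter=4000)
    stat = red.neg2_reml(g_red) - full.neg2_reml(g_full)
    stat = max(float(stat), 0.0)
    p = float(stats.chi2.sf(stat, 1))
    if boundary_correction:
        p = 0.5 * p if stat > 0 else 1.0
    return LRTResult(term=term, statistic=stat, df=1, p_value=p)


def _block_wald_f(dataset: METDataset, trait: str) -> LRTResult:
    design = _Design(dataset, trait)
    gammas, _ = _optimize_profile(design, tol=1e-10, max_iter=4000)
    theta_w, _, Sinv, _, s2e = design.solve(gammas)
    sl = slice(1, design.p)  # block contrast coefficients
    beta = theta_w[sl]
    cov = s2e * Sinv[sl, sl]
    q = len(beta)
    fstat = float(beta @ np.linalg.solve(cov, beta)) / q
    df2 = design.n - design.p
    return LRTResult(term="block", statistic=fstat, df=q,
                     p_value=float(stats.f.sf(fstat, q, df2)), kind="wald_f")


def selective_accuracy(fit: ModelFit) -> float:
    """Selective accuracy r_gg = sqrt(1 - mean(PEV)/sigma_g^2), in [0, 1].

    Undefined (NaN) when the genotypic variance is estimated at zero.
    """
    s2g = fit.components.sigma2_g
    if s2g <= 0:
        return float("nan")
    val = 1.0 - float(fit.pev_genotype.mean()) / s2g
    return float(np.sqrt(np.clip(val, 0.0, 1.0)))
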