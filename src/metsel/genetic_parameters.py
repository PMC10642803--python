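"""Derived genetic parameters from a REML mixed-model fit.

All quantities are functions of the variance components
(sigma_g^2, sigma_e^2, sigma_gxe^2, sigma_eps^2) and of the BLUP/BLUE
machinery of the fitted model:

* broad-sense heritability          H2  = s2g / (s2g + s2gxe + s2eps)
* genotype-mean heritability        h2mg = s2g / (s2g + s2gxe/e + s2eps/(e b))
* Cullis heritability               1 - vd(BLUP) / (2 s2g)
* Piepho heritability               s2g / (s2g + vbar/2)
* phenotypic variance (mean basis)  s2g + s2gxe/e + s2eps/(e b)
* CVg, CVr (%) and their ratio; GEI determination r2; GEI correlation rge

where vd(BLUP) is the mean variance of a difference of two genotype
BLUPs and vbar the mean variance of a difference of two genotype BLUEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import ModelFit, VarianceComponents


@dataclass
class GeneticParameters:
    trait: str
    H2: float
    h2_mg: float
    H2_cullis: float
    H2_cullis_se_reading: float   # alternative "mean squared SE of BLUPs" reading
    H2_piepho: float
    sigma2_p_mean_basis: float
    sigma2_p_plot_basis: float
    CVg: float
    CVr: float
    CV_ratio: float
    r2_gei: float
    r_ge: float
    grand_mean: float
    grand_mean_raw: float
    e: int
    b: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__).drop("trait")


def broad_sense_h2(components: VarianceComponents) -> float:
    """Plot-basis broad-sense heritability s2g/(s2g+s2gxe+s2eps)."""
    denom = components.sigma2_g + components.sigma2_gxe + components.sigma2_eps
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return components.sigma2_g / denom


def plot_mean_h2(components: VarianceComponents, e: int, b: int) -> float:
    """Genotype-mean heritability; increases with environments and blocks."""
    if e < 1 or b < 1:
        raise ValueError("need e, b >= 1")
    denom = (
        components.sigma2_g
        + components.sigma2_gxe / e
        + components.sigma2_eps / (e * b)
    )
    return components.sigma2_g / denom if denom > 0 else float("nan")


def mean_variance_of_difference(cov: pd.DataFrame) -> float:
    """Mean of var(x_i - x_j) over all unordered pairs from a covariance."""
    v = cov.to_numpy()
    g = v.shape[0]
    diag = np.diag(v)
    # sum over i<j of (v_ii + v_jj - 2 v_ij)
    total = (g - 1) * diag.sum() - (v.sum() - diag.sum())
    return float(total / (g * (g - 1) / 2.0))


def cullis_h2(fit: ModelFit) -> tuple[float, float]:
    """Cullis generalized heritability, both readings.

    Primary (standard) reading: 1 - vd(BLUP)/(2 s2g) with vd(BLUP) the
    mean variance of a difference of two genotype BLUPs.  The secondary
    reading replaces vd(BLUP) by the mean squared standard error of the
    BLUPs (mean PEV); both are returned, primary first.
    """
    s2g = fit.components.sigma2_g
    if s2g <= 0:
        return float("nan"), float("nan")
    vd = mean_variance_of_difference(fit.pev_cov_genotype)
    primary = float(np.clip(1.0 - vd / (2.0 * s2g), 0.0, 1.0))
    secondary = float(np.clip(1.0 - fit.pev_genotype.mean() / s2g, 0.0, 1.0))
    return primary, secondary


def piepho_h2(fit: ModelFit) -> float:
    """Piepho heritability s2g/(s2g + vbar/2) from the BLUE covariance."""
    if fit.blue_cov_genotype is None:
        raise ValueError(
            "genotype BLUEs missing: fit the fixed-genotype companion model "
            "(fit_random_model(..., with_blues=True))"
        )
    s2g = fit.components.sigma2_g
    vbar = mean_variance_of_difference(fit.blue_cov_genotype)
    return s2g / (s2g + vbar / 2.0) if s2g + vbar > 0 else float("nan")


def variation_coefficients(
    components: VarianceComponents, grand_mean: float
) -> tuple[float, float, float]:
    """(CVg%, CVr%, CVg/CVr) from components and the grand mean."""
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive for CVs")
    cvg = 100.0 * np.sqrt(components.sigma2_g) / grand_mean
    cvr = 100.0 * np.sqrt(components.sigma2_eps) / grand_mean
    ratio = cvg / cvr if cvr > 0 else float("inf")
    return float(cvg), float(cvr), float(ratio)


def gei_summary(
    components: VarianceComponents, e: int, b: int
) -> tuple[float, float, float]:
    """(r2 of GEI, rge correlation, phenotypic variance on the mean basis)."""
    plot_total = components.sigma2_g + components.sigma2_gxe + components.sigma2_eps
    if plot_total <= 0:
        raise ValueError("all variance components are zero")
    r2 = components.sigma2_gxe / plot_total
    ge_total = components.sigma2_g + components.sigma2_gxe
    rge = components.sigma2_g / ge_total if ge_total > 0 else float("nan")
    s2p = (
        components.sigma2_g
        + components.sigma2_gxe / e
        + components.sigma2_eps / (e * b)
    )
    return float(r2), float(rge), float(s2p)


def genetic_parameters(fit: ModelFit, e: int | None = None, b: int | None = None,
                       *, n_blocks: int | None = None) -> GeneticParameters:
    """All derived genetic parameters for one fitted trait.

    ``e`` and ``b`` default to the number of environments seen in the
    fit and the block count passed as ``n_blocks``; they are exposed
    because under unbalance the effective number of environments per
    genotype may be smaller than the environment total.
    """
    comp = fit.components
    if e is None:
        e = len(fit.blups_gei.index.get_level_values(1).unique()) \
            if len(fit.blups_gei) else 1
    if b is None:
        b = n_blocks if n_blocks is not None else 3
    h2 = broad_sense_h2(comp)
    h2mg = plot_mean_h2(comp, e, b)
    cullis, cullis_alt = cullis_h2(fit)
    piepho = piepho_h2(fit) if fit.blue_cov_genotype is not None else float("nan")
    cvg, cvr, ratio = variation_coefficients(comp, fit.mu)
    r2, rge, s2p_mean = gei_summary(comp, e, b)
    s2p_plot = comp.sigma2_g + comp.sigma2_gxe + comp.sigma2_eps
    return GeneticParameters(
        trait=fit.trait,
        H2=h2, h2_mg=h2mg,
        H2_cullis=cullis, H2_cullis_se_reading=cullis_alt,
        H2_piepho=piepho,
        sigma2_p_mean_basis=s2p_mean, sigma2_p_plot_basis=s2p_plot,
        CVg=cvg, CVr=cvr, CV_ratio=ratio,
        r2_gei=r2, r_ge=rge,
        grand_mean=fit.mu, grand_mean_raw=fit.grand_mean_raw,
        e=int(e), b=int(b),
    )
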