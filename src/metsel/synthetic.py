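"""Synthetic multi-environment-trial generator.

Simulates plot data from the additive random-effects model that the
analysis stages assume,

    Y_ijk = mu + g_i + e_j + (ge)_ij + b_jk + eps_ijk,

with independent normal genotype, environment and genotype-by-environment
(GEI) effects of stated variances, block offsets drawn once per
environment and treated as fixed by the analysis, and i.i.d. plot error.
The true effect draws are returned alongside the dataset so recovery
tests can compare estimates against the simulated truth.

Default trait settings emulate a late-stage cassava trial series:
22 genotypes x 47 environments x 3 blocks and seven traits (FRY, ShY,
DMC, DRY, PH, HI, PIA) with grand means and genotypic / GEI / residual
variances on the published scale of such trials.  The environment
variance and block spread are not published for that series; defaults
(sigma_e^2 = 2 sigma_g^2, block_sd = 0.5 sigma_eps) are this package's
documented choice (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .met_data import METDataset, TraitSpec, GENOTYPE, ENVIRONMENT, BLOCK


@dataclass(frozen=True)
class TraitSim:
    """Simulation settings for one trait."""

    name: str
    mean: float
    var_g: float
    var_e: float
    var_gxe: float
    var_eps: float
    direction: str = "higher"
    bounds: tuple[float, float] | None = None
    clip: bool = False  # clip to bounds (latent-normal then censor); off by default

    def __post_init__(self) -> None:
        for v in (self.var_g, self.var_e, self.var_gxe, self.var_eps):
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"trait {self.name!r}: variances must be >= 0")


def _cassava_trait(name, mean, cv_g, cv_r, var_gxe, direction="higher", bounds=None):
    var_g = (cv_g / 100.0 * mean) ** 2
    var_eps = (cv_r / 100.0 * mean) ** 2
    return TraitSim(
        name=name, mean=mean, var_g=var_g, var_e=2.0 * var_g,
        var_gxe=var_gxe, var_eps=var_eps, direction=direction, bounds=bounds,
    )


#: Trait settings shaped on a published cassava MET series: grand means,
#: genotypic/residual CVs and GEI variances per trait.
CASSAVA_TRAITS: tuple[TraitSim, ...] = (
    _cassava_trait("FRY", 24.22, 17.20, 16.70, 20.55),
    _cassava_trait("ShY", 20.94, 18.60, 19.00, 17.91),
    _cassava_trait("DMC", 35.58, 4.28, 2.77, 0.86),
    _cassava_trait("DRY", 7.64, 17.10, 17.20, 2.08),
    _cassava_trait("PH", 2.24, 9.37, 7.02, 0.02),
    _cassava_trait("HI", 54.04, 10.10, 8.13, 23.36),
    _cassava_trait("PIA", 2.44, 31.40, 28.20, 0.35, direction="lower", bounds=(1.0, 5.0)),
)


@dataclass
class SimulationSpec:
    """Design and variance settings for one simulated MET.

    ``block_sd_scale`` sets the block offset spread as a multiple of the
    residual standard deviation of each trait.
    """

    g: int = 22
    e: int = 47
    b: int = 3
    traits: tuple[TraitSim, ...] = CASSAVA_TRAITS
    block_sd_scale: float = 0.5
    missing_cell_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 2 or self.e < 2 or self.b < 1:
            raise ValueError("need g >= 2, e >= 2, b >= 1")
        if not (0 <= self.missing_cell_fraction < 1):
            raise ValueError("missing_cell_fraction must be in [0, 1)")

    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


@dataclass
class TrueEffects:
    """The effect draws behind one simulated trait, for recovery tests."""

    mean: float
    genotype: pd.Series       # length g
    environment: pd.Series    # length e
    gxe: pd.DataFrame         # g x e
    block: pd.DataFrame       # e x b block offsets (fixed by construction)
    var_g: float
    var_e: float
    var_gxe: float
    var_eps: float


def simulate_met(spec: SimulationSpec) -> tuple[METDataset, dict[str, TrueEffects]]:
    """Draw a complete balanced MET; returns (dataset, true effects per trait).

    Unbalance is applied separately with :func:`apply_unbalance` so the
    complete draws stay available.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genos = [f"G{i+1:02d}" for i in range(spec.g)]
    envs = [f"E{j+1:02d}" for j in range(spec.e)]
    blocks = [f"B{k+1}" for k in range(spec.b)]

    gi, ej, bk = np.meshgrid(
        np.arange(spec.g), np.arange(spec.e), np.arange(spec.b), indexing="ij"
    )
    gi, ej, bk = gi.ravel(), ej.ravel(), bk.ravel()
    df = pd.DataFrame(
        {
            GENOTYPE: np.array(genos)[gi],
            ENVIRONMENT: np.array(envs)[ej],
            BLOCK: np.array(blocks)[bk],
        }
    )

    effects: dict[str, TrueEffects] = {}
    for t in spec.traits:
        a = rng.normal(0.0, np.sqrt(t.var_g), spec.g)
        tau = rng.normal(0.0, np.sqrt(t.var_e), spec.e)
        ge = rng.normal(0.0, np.sqrt(t.var_gxe), (spec.g, spec.e))
        blk = rng.normal(0.0, spec.block_sd_scale * np.sqrt(t.var_eps), (spec.e, spec.b))
        eps = rng.normal(0.0, np.sqrt(t.var_eps), spec.g * spec.e * spec.b)
        y = t.mean + a[gi] + tau[ej] + ge[gi, ej] + blk[ej, bk] + eps
        if t.clip and t.bounds is not None:
            y = np.clip(y, *t.bounds)
        df[t.name] = y
        effects[t.name] = TrueEffects(
            mean=t.mean,
            genotype=pd.Series(a, index=genos),
            environment=pd.Series(tau, index=envs),
            gxe=pd.DataFrame(ge, index=genos, columns=envs),
            block=pd.DataFrame(blk, index=envs, columns=blocks),
            var_g=t.var_g, var_e=t.var_e, var_gxe=t.var_gxe, var_eps=t.var_eps,
        )

    traits = [
        TraitSpec(t.name, t.direction, bounds=t.bounds if t.clip else None)
        for t in spec.traits
    ]
    dataset = METDataset(df, traits)
    if spec.missing_cell_fraction > 0:
        dataset = apply_unbalance(dataset, spec.missing_cell_fraction, seed=spec.seed + 1)
    return dataset, effects


def apply_unbalance(
    dataset: METDataset,
    fraction: float,
    seed: int,
    *,
    min_envs_per_genotype: int = 3,
    min_genotypes_per_env: int = 2,
) -> METDataset:
    """Remove whole genotype x environment cells (all blocks) at random.

    Mirrors clones dropped from later trial years.  Exactly
    ``round(fraction * g * e)`` cells are removed, subject to every
    genotype keeping at least ``min_envs_per_genotype`` environments and
    every environment keeping at least ``min_genotypes_per_env``
    genotypes; an infeasible fraction raises.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return dataset
    rng = np.random.default_rng(seed)
    df = dataset.records
    cells = df[[GENOTYPE, ENVIRONMENT]].drop_duplicates().to_numpy().tolist()
    n_remove = round(fraction * dataset.n_genotypes * dataset.n_environments)
    if n_remove > len(cells):
        raise ValueError("fraction removes more cells than exist")

    env_per_geno = {g: set() for g in dataset.genotypes}
    geno_per_env = {e: set() for e in dataset.environments}
    for g, e in cells:
        env_per_geno[g].add(e)
        geno_per_env[e].add(g)

    order = rng.permutation(len(cells))
    removed: list[tuple[str, str]] = []
    for idx in order:
        if len(removed) == n_remove:
            break
        g, e = cells[idx]
        if (
            len(env_per_geno[g]) - 1 >= min_envs_per_genotype
            and len(geno_per_env[e]) - 1 >= min_genotypes_per_env
        ):
            env_per_geno[g].discard(e)
            geno_per_env[e].discard(g)
            removed.append((g, e))
    if len(removed) < n_remove:
        raise ValueError(
            f"infeasible unbalance fraction {fraction}: only {len(removed)} of "
            f"{n_remove} cells removable under the design constraints"
        )
    drop_keys = set(removed)
    keep = ~df.apply(lambda r: (r[GENOTYPE], r[ENVIRONMENT]) in drop_keys, axis=1)
    return METDataset(df.loc[keep].reset_index(drop=True), dataset.traits)
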