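"""End-to-end MET selection pipeline.

Chains the stages: (simulate or read) -> REML fits per trait -> genetic
parameters -> joint-regression stability -> MPS (chosen statistic and
weights) -> factor-analytic MTMPS selection -> trait associations, and
writes every table as delimited text plus a JSON manifest with content
hashes.  Outputs are a pure function of (input, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import met_data, synthetic, mixed_model
from . import stability as stab
from . import associations as assoc
from .genetic_parameters import genetic_parameters as _genetic_parameters
from .mps import MPSResult, mps_for_trait, classify_groups, scenario_sweep
from .mtmps import FactorModel, MTMPSResult, fit_factor_model
from .mtmps import mtmps as mtmps_index
from .mtmps import selection_gains

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str | None = None          # None -> simulate
    simulation: synthetic.SimulationSpec | None = None
    stat: str = "Sdi2"                     # Sdi2 | R2 | RMSE
    w_perf: float = 65.0
    w_stab: float = 35.0
    sweep_step: float = 5.0
    intensity: float = 0.30
    n_factors: int | None = None           # None -> Kaiser rule
    group_threshold: str = "mean"
    out_dir: str = "metsel_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_perf + self.w_stab <= 0:
            raise ValueError("weights must sum to > 0")
        if not (0 < self.intensity <= 1):
            raise ValueError("intensity must be in (0, 1]")
        if self.stat not in stab.STAT_HIGHER_IS_BETTER:
            raise ValueError(f"stat must be one of {sorted(stab.STAT_HIGHER_IS_BETTER)}")


@dataclass
class PipelineResult:
    dataset: met_data.METDataset
    fits: dict[str, mixed_model.ModelFit]
    parameters: pd.DataFrame
    stability: dict[str, stab.StabilityEstimates]
    mps_results: dict[str, MPSResult]
    mps_matrix: pd.DataFrame
    groups: pd.DataFrame
    factor_model: FactorModel
    mtmps_result: MTMPSResult
    gains: pd.DataFrame
    network: assoc.CorrelationNetwork
    manifest: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed: {exc}; rerun with "
                    f"`metsel run --seed <seed>` after fixing the input"
                ) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        dataset = met_data.read_met_table(config.input_path)
    else:
        spec = config.simulation or synthetic.SimulationSpec(seed=config.seed)
        dataset, _ = _stage("simulate")(synthetic.simulate_met)(spec)
    report = met_data.validate(dataset)

    traits = dataset.trait_names
    fits: dict[str, mixed_model.ModelFit] = {}
    params = {}
    for trait in traits:
        fit = _stage(f"fit:{trait}")(mixed_model.fit_random_model)(dataset, trait)
        fits[trait] = fit
        params[trait] = _genetic_parameters(
            fit, e=dataset.n_environments, b=dataset.n_blocks
        ).as_series()
    parameters = pd.DataFrame(params)

    stability: dict[str, stab.StabilityEstimates] = {}
    mps_results: dict[str, MPSResult] = {}
    groups = {}
    for trait in traits:
        cm = met_data.cell_means(dataset, trait)
        est = _stage(f"stability:{trait}")(stab.fit_er)(cm)
        stability[trait] = est
        perf = fits[trait].predicted_genotype_means
        res = mps_for_trait(
            perf, est, config.stat,
            higher_is_better=dataset.trait_spec(trait).higher_is_better,
            weights=(config.w_perf, config.w_stab), trait=trait,
        )
        mps_results[trait] = res
        groups[trait] = classify_groups(
            res.rY, res.rE, threshold=config.group_threshold
        )
    mps_matrix = pd.DataFrame({t: r.mps for t, r in mps_results.items()})
    groups = pd.DataFrame(groups)

    model = _stage("factor")(fit_factor_model)(
        mps_matrix, n_factors=config.n_factors
    )
    result = mtmps_index(model, intensity=config.intensity)
    trait_means = pd.DataFrame(
        {t: fits[t].predicted_genotype_means for t in traits}
    )
    directions = {t: dataset.trait_spec(t).direction for t in traits}
    gains = selection_gains(
        trait_means, result.selected, directions, model.trait_factor_map()
    )
    network = _stage("network")(assoc.correlation_network)(mps_matrix)

    manifest = _write_bundle(
        out, config, dataset, report, parameters, stability, mps_results,
        mps_matrix, groups, model, result, gains, network,
    )
    return PipelineResult(
        dataset=dataset, fits=fits, parameters=parameters, stability=stability,
        mps_results=mps_results, mps_matrix=mps_matrix, groups=groups,
        factor_model=model, mtmps_result=result, gains=gains, network=network,
        manifest=manifest,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bundle(out, config, dataset, report, parameters, stability,
                  mps_results, mps_matrix, groups, model, result, gains,
                  network) -> dict:
    files: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.round(6).to_csv(path)
        files.append(path)

    met_data.write_met_table(dataset, out / "dataset.csv")
    files.append(out / "dataset.csv")
    save(parameters, "genetic_parameters.csv")
    for trait, est in stability.items():
        save(est.table, f"stability_{trait}.csv")
    save(mps_matrix, "mps_matrix.csv")
    save(groups, "groups.csv")
    for trait, res in mps_results.items():
        grid = scenario_sweep(res.rY, res.rE, step=config.sweep_step)
        save(grid.ranks, f"scenario_ranks_{trait}.csv")
    save(model.loadings.assign(communality=model.communalities), "factor_loadings.csv")
    mt = pd.DataFrame({
        "MTMPS": result.distances, "rank": result.ranking,
        "selected": result.distances.index.isin(result.selected),
    })
    save(mt, "mtmps_ranking.csv")
    save(result.contributions, "factor_contributions.csv")
    save(gains, "selection_gains.csv")
    save(network.edges.set_index(["trait_a", "trait_b"]), "correlation_edges.csv")

    payload = {
        "validation": report.to_dict(),
        "design": dataset.design_summary(),
        "eigenvalues": model.eigenvalues.round(6).to_dict(),
        "explained_pct": model.explained_pct.round(4).to_dict(),
        "selected": result.selected,
        "ideotype_scores": result.ideotype.round(6).to_dict(),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    files.append(out / "report.json")

    cfg = asdict(config)
    if cfg.get("simulation") is not None:
        cfg["simulation"]["traits"] = [t["name"] for t in cfg["simulation"]["traits"]]
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "files": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
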