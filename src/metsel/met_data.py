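"""Data model and validation for multi-environment trial (MET) tables.

A MET dataset holds plot-level records from a randomized complete block
design replicated across environments (year x location combinations):
one row per (genotype, environment, block) with one column per measured
trait.  Blocks are nested within environments: block "1" in environment
E1 is a different physical block from block "1" in E2.

Missing data are first-class: a genotype may be absent from whole
environments (unbalance) and a plot may have some traits unrecorded.
Missing values are always represented as NaN, never sentinel numerics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names used internally for the design factors.
GENOTYPE, ENVIRONMENT, BLOCK = "genotype", "environment", "block"
_DESIGN_COLS = [GENOTYPE, ENVIRONMENT, BLOCK]


class METDataError(ValueError):
    """Raised when a MET table violates a structural invariant."""


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of one trait: its name, selection direction and units.

    ``direction`` is ``"higher"`` when larger values are agronomically
    desirable (yields, dry-matter content ...) and ``"lower"`` for traits
    such as the 1-5 plant-architecture score where compact plants score
    low and are preferred.
    """

    name: str
    direction: str = "higher"
    units: str = ""
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise METDataError(
                f"trait {self.name!r}: direction must be 'higher' or 'lower', "
                f"got {self.direction!r}"
            )

    @property
    def higher_is_better(self) -> bool:
        return self.direction == "higher"


@dataclass
class METDataset:
    """Validated long-format plot records plus trait declarations.

    ``records`` has the design columns ``genotype``, ``environment``,
    ``block`` (all treated as opaque strings) and one numeric column per
    trait.  The (genotype, environment, block) triple is unique.
    """

    records: pd.DataFrame
    traits: list[TraitSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _DESIGN_COLS if c not in df.columns]
        if missing:
            raise METDataError(f"records lack design column(s): {missing}")
        if not self.traits:
            self.traits = [
                TraitSpec(c) for c in df.columns if c not in _DESIGN_COLS
            ]
        for spec in self.traits:
            if spec.name not in df.columns:
                raise METDataError(f"declared trait {spec.name!r} has no column")
        df = df.copy()
        for c in _DESIGN_COLS:
            df[c] = df[c].astype(str)
        for spec in self.traits:
            df[spec.name] = pd.to_numeric(df[spec.name], errors="raise")
        dup = df.duplicated(subset=_DESIGN_COLS, keep=False)
        if dup.any():
            triple = tuple(df.loc[dup.idxmax(), _DESIGN_COLS])
            raise METDataError(f"duplicate (genotype, environment, block): {triple}")
        vals = df[self.trait_names].to_numpy(float)
        if np.isinf(vals).any():
            raise METDataError("non-finite trait value present")
        for spec in self.traits:
            if spec.bounds is not None:
                lo, hi = spec.bounds
                col = df[spec.name].dropna()
                if ((col < lo) | (col > hi)).any():
                    raise METDataError(
                        f"trait {spec.name!r} outside declared bounds {spec.bounds}"
                    )
        if self.n_genotypes < 2 or self.n_environments < 2:
            raise METDataError("need at least 2 genotypes and 2 environments")
        self.records = df.reset_index(drop=True)

    # -- design summary -------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records[GENOTYPE].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.records[ENVIRONMENT].unique())

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def n_genotypes(self) -> int:
        return self.records[GENOTYPE].nunique()

    @property
    def n_environments(self) -> int:
        return self.records[ENVIRONMENT].nunique()

    @property
    def n_blocks(self) -> int:
        """Maximum number of blocks in any environment."""
        return int(self.records.groupby(ENVIRONMENT)[BLOCK].nunique().max())

    def trait_spec(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(f"unknown trait {name!r}")

    def design_summary(self) -> dict:
        return {
            "g": self.n_genotypes,
            "e": self.n_environments,
            "b": self.n_blocks,
            "n_plots": len(self.records),
            "traits": self.trait_names,
        }


def read_met_table(
    source,
    *,
    genotype_col: str = GENOTYPE,
    environment_col: str = ENVIRONMENT,
    block_col: str = BLOCK,
    trait_cols: Sequence[str] | None = None,
    trait_directions: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> METDataset:
    """Read a delimited MET table into a validated :class:`METDataset`.

    ``source`` is a path or text stream.  Column names are remapped via
    the ``*_col`` arguments; every remaining numeric column is taken as a
    trait unless ``trait_cols`` narrows the set.  ``trait_directions``
    maps trait name -> ``"higher"``/``"lower"`` (default: higher).
    Rows where every trait is missing are dropped with a logged count.
    """
    if sep is None:
        sep = _sniff_sep(source)
    df = pd.read_csv(source, sep=sep)
    mapping = {genotype_col: GENOTYPE, environment_col: ENVIRONMENT, block_col: BLOCK}
    for src_name in mapping:
        if src_name not in df.columns:
            raise METDataError(f"column {src_name!r} not found in header {list(df.columns)}")
    df = df.rename(columns=mapping)
    if trait_cols is None:
        trait_cols = [c for c in df.columns if c not in _DESIGN_COLS]
    if not trait_cols:
        raise METDataError("no trait columns found")
    for c in trait_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            raise METDataError(
                f"unparseable numeric cell in trait {c!r} at row(s) {list(bad[:5])}"
            ) from exc
    all_missing = df[list(trait_cols)].isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d rows with all traits missing", int(all_missing.sum()))
        df = df.loc[~all_missing]
    directions = dict(trait_directions or {})
    traits = [TraitSpec(c, directions.get(c, "higher")) for c in trait_cols]
    return METDataset(df[_DESIGN_COLS + list(trait_cols)], traits)


def write_met_table(dataset: METDataset, target, *, sep: str = ",") -> None:
    """Write a dataset back to delimited text (inverse of read_met_table)."""
    dataset.records.to_csv(target, sep=sep, index=False)


def _sniff_sep(source) -> str:
    """Guess comma vs tab from the header line (path or seekable stream)."""
    if hasattr(source, "read"):
        if not source.seekable():
            return ","
        head = source.readline()
        source.seek(0)
        return "\t" if "\t" in head else ","
    with open(source) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def cell_means(dataset: METDataset, trait: str) -> pd.DataFrame:
    """Genotype x environment matrix of block-mean phenotypes.

    Entry (i, j) averages the available plots of genotype i in
    environment j; cells where the genotype was never planted are NaN,
    never 0.
    """
    if trait not in dataset.trait_names:
        raise KeyError(f"unknown trait {trait!r}")
    piv = dataset.records.pivot_table(
        index=GENOTYPE, columns=ENVIRONMENT, values=trait, aggfunc="mean"
    )
    return piv.reindex(index=dataset.genotypes, columns=dataset.environments)


@dataclass
class ValidationReport:
    environments_per_genotype: dict[str, int]
    insufficient_for_stability: list[str]
    constant_traits: list[str]
    unbalance_fraction: float
    n_plots: int

    def to_dict(self) -> dict:
        return {
            "environments_per_genotype": self.environments_per_genotype,
            "insufficient_for_stability": self.insufficient_for_stability,
            "constant_traits": self.constant_traits,
            "unbalance_fraction": self.unbalance_fraction,
            "n_plots": self.n_plots,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def validate(dataset: METDataset, *, min_envs_for_stability: int = 3) -> ValidationReport:
    """Screen a dataset for problems that break downstream stages.

    Flags genotypes observed in fewer than ``min_envs_for_stability``
    environments (unusable for joint-regression stability), traits that
    are constant over every plot, and reports the fraction of empty
    genotype x environment cells.
    """
    df = dataset.records
    env_counts = df.groupby(GENOTYPE)[ENVIRONMENT].nunique().to_dict()
    insufficient = sorted(
        g for g, n in env_counts.items() if n < min_envs_for_stability
    )
    constant = [
        t for t in dataset.trait_names
        if df[t].dropna().nunique() <= 1
    ]
    cells = df.groupby([GENOTYPE, ENVIRONMENT]).size()
    observed = len(cells)
    total = dataset.n_genotypes * dataset.n_environments
    return ValidationReport(
        environments_per_genotype=env_counts,
        insufficient_for_stability=insufficient,
        constant_traits=constant,
        unbalance_fraction=1.0 - observed / total,
        n_plots=len(df),
    )
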