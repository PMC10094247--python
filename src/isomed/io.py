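"""Readers and writers for the tabular formats the pipeline touches.

All expression-like matrices are oriented features x samples and serialized
as TSV with the feature identifier in the first column and sample identifiers
in the header.  Sample IDs are the join key across every file of a run.
Gene sets use GMT semantics (name, description, then members, tab-separated).
Run configuration is JSON with flat keys so that a resolved config can be
diffed between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class ConfigError(ValueError):
    """A run configuration value is out of range or inconsistent."""


# ---------------------------------------------------------------------------
# gene-set collection


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics.

    ``sets`` maps set name -> ordered, de-duplicated member list;
    ``descriptions`` carries the GMT description field per set.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Members are de-duplicated preserving first occurrence.  Lines with fewer
    than three fields, or duplicate set names, raise :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV into a float DataFrame.

    Rejects duplicate feature or sample identifiers (listing the duplicates),
    non-numeric cells (reporting row and column), and missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate feature IDs: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise FormatError(f"{path}: duplicate sample IDs: {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise FormatError(
            f"{path}: missing value at row {df.index[rows[0]]!r}, "
            f"column {df.columns[cols[0]]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


ANNOTATION_COLUMNS = ["iso1", "iso2", "group", "time", "event"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-sample annotation TSV (sample_id, iso1, iso2, group, time, event)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate sample IDs: {dups}")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns: {missing}")
    df.index = df.index.astype(str)
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``sims`` is the number of quasi-Bayesian parameter draws per mediation
    fit; ``alpha`` the per-run significance level used by the screen;
    ``ci_level`` the nominal coverage of reported intervals;
    ``minimum_group_fraction`` the per-side bound of the optimal-cutpoint
    scan.  Paths may be None when the corresponding stage is not run.
    """

    expression: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    treatment_feature: str = "iso2"
    candidate_genes: str | None = None
    candidate_pathways: str | None = None
    sims: int = 1000
    alpha: float = 0.05
    ci_level: float = 0.95
    seed: int = 0
    minimum_group_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.sims < 100:
            raise ConfigError(f"sims must be >= 100, got {self.sims}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if not 0.0 < self.minimum_group_fraction < 1.0:
            raise ConfigError(
                f"minimum_group_fraction must be in (0, 1), got {self.minimum_group_fraction}"
            )
        self.seed = int(self.seed)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text identifier list, one per line, blank lines skipped."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate identifiers: {dups}")
    return ids
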