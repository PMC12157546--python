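"""Readers and writers for the tab-separated interchange formats.

Expression matrices are TSV with a header row of sample IDs, a first column
of feature IDs and a numeric body; ``NA`` or empty cells are missing.
Metadata tables are TSV with a sample-ID first column and one declared type
(numeric | categorical) per variable column.  TSV is the canonical format for
inspectability; the parsers are line-based so format violations are reported
with their line number and the offending token.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ConfigError, ParseError
from .partitioning import (
    CATEGORICAL,
    MISSING_TOKENS,
    NUMERIC,
    FeatureVector,
    categorical_feature,
)

logger = logging.getLogger("cccoef")

_NA_TOKENS = set(MISSING_TOKENS)


@dataclass(frozen=True)
class FeatureMatrix:
    """An ordered feature collection plus the shared sample IDs."""

    features: list
    sample_ids: list

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for f in self.features:
            if f.n_samples != n:
                raise ParseError(f"feature {f.id!r} has {f.n_samples} values, expected {n}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def feature_ids(self) -> list:
        return [f.id for f in self.features]


@dataclass(frozen=True)
class MetadataTable:
    """Typed metadata variables aligned to sample IDs."""

    variables: list
    sample_ids: list

    @property
    def variable_ids(self) -> list:
        return [v.id for v in self.variables]


def read_expression_matrix(path) -> FeatureMatrix:
    """Read a feature-by-sample expression TSV.

    Rejects ragged rows, duplicate feature IDs and non-numeric cells, naming
    the line and offender.  Features preserve file order.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}: line 1: header needs a feature-ID column plus sample IDs")
        sample_ids = cols[1:]
        n = len(sample_ids)
        features = []
        seen = set()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n + 1:
                raise ParseError(f"{path}: line {lineno}: expected {n + 1} fields, got {len(parts)}")
            fid = parts[0]
            if fid in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            vals = np.empty(n)
            mask = np.zeros(n, dtype=bool)
            for c, cell in enumerate(parts[1:]):
                if cell in _NA_TOKENS:
                    vals[c] = np.nan
                    mask[c] = True
                else:
                    try:
                        vals[c] = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric value {cell!r} for feature {fid!r}"
                        ) from None
            features.append(FeatureVector(fid, vals, NUMERIC, mask))
    if not features:
        raise ParseError(f"{path}: no feature rows")
    return FeatureMatrix(features, sample_ids)


def write_expression_matrix(matrix: FeatureMatrix, path) -> None:
    """Write an expression TSV; missing cells become "NA", floats use
    shortest round-trip representation (write-then-read is lossless)."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for f in matrix.features:
            cells = [
                "NA" if m else repr(float(v))
                for v, m in zip(f.values, f.missing_mask)
            ]
            fh.write(f.id + "\t" + "\t".join(cells) + "\n")


def read_metadata(
    path,
    type_declarations: Dict[str, str],
    sample_ids: Optional[Sequence[str]] = None,
) -> MetadataTable:
    """Read a sample metadata TSV with declared per-variable types.

    Every variable column must appear in ``type_declarations`` (numeric |
    categorical).  When ``sample_ids`` is given, variables are aligned to that
    order: samples present only in the file are dropped with a warning and
    samples absent from the file become missing values (pairwise-complete
    handling happens downstream).
    """
    for name, t in type_declarations.items():
        if t not in (NUMERIC, CATEGORICAL):
            raise ConfigError(f"variable {name!r}: type must be 'numeric' or 'categorical', got {t!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: line 1: header needs a sample-ID column plus variables")
        var_names = header[1:]
        for name in var_names:
            if name not in type_declarations:
                raise ConfigError(f"{path}: column {name!r} has no declared type")
        file_ids = []
        rows = []
        seen = set()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}")
            sid = parts[0]
            if sid in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate sample ID {sid!r}")
            seen.add(sid)
            file_ids.append(sid)
            rows.append(parts[1:])
    if sample_ids is None:
        target_ids = file_ids
    else:
        target_ids = list(sample_ids)
        extra = [sid for sid in file_ids if sid not in set(target_ids)]
        if extra:
            logger.warning(
                "metadata: %d sample(s) absent from expression matrix dropped: %s",
                len(extra), extra[:10],
            )
    pos = {sid: r for r, sid in enumerate(file_ids)}
    variables = []
    for c, name in enumerate(var_names):
        cells = [rows[pos[sid]][c] if sid in pos else "NA" for sid in target_ids]
        if type_declarations[name] == NUMERIC:
            vals = np.empty(len(cells))
            mask = np.zeros(len(cells), dtype=bool)
            for r, cell in enumerate(cells):
                if cell in _NA_TOKENS:
                    vals[r] = np.nan
                    mask[r] = True
                else:
                    try:
                        vals[r] = float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric value {cell!r} in numeric variable {name!r}"
                        ) from None
            variables.append(FeatureVector(name, vals, NUMERIC, mask))
        else:
            variables.append(categorical_feature(name, cells))
    return MetadataTable(variables, target_ids)


def write_metadata(table: MetadataTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.variable_ids) + "\n")
        for r, sid in enumerate(table.sample_ids):
            cells = []
            for v in table.variables:
                if v.missing_mask[r]:
                    cells.append("NA")
                elif v.dtype == NUMERIC:
                    cells.append(repr(float(v.values[r])))
                else:
                    cells.append(str(v.values[r]))
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


@dataclass
class RunConfig:
    """Effective configuration of a CLI run; always written next to outputs."""

    command: str = ""
    input_paths: dict = field(default_factory=dict)
    output_dir: str = ""
    k_range: list = field(default_factory=lambda: list(range(2, 11)))
    min_pairwise_samples: int = 10
    backend: str = "parallel"
    chunk_size: int = 4096
    tier_mode: str = "percentile"
    high_pct: float = 0.30
    low_pct: float = 0.30
    n_perms: int = 500
    q: float = 0.99
    seed: int = 0
    top_k: int = 100
    absolute: bool = True
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
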