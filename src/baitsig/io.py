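"""Core data types and text-format readers/writers.

Expression matrices are genes x samples TSV (header row = sample ids, first
column = gene ids), gene sets are GMT, sample metadata is TSV with columns
``sample_id``, ``group`` and optionally ``is_tumor`` / ``hypoxia_label``.
Gene identifiers are opaque, case-sensitive strings; no symbol aliasing is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("baitsig")

VALID_SCALES = ("linear", "log2")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample numeric expression matrix with a declared scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (unique ids as index), samples in columns (unique ids).
        All entries must be finite; on the linear scale they must be >= 0.
    scale : {"linear", "log2"}
        Whether values are raw-linear or already log2-transformed.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        dup_g = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_g):
            raise ValidationError(f"duplicate gene ids: {sorted(map(str, dup_g))}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample ids: {sorted(map(str, dup_s))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if self.scale == "linear" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r} on declared linear scale"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def fingerprint(self) -> str:
        """Stable short digest of ids and values, for provenance blocks."""
        import hashlib

        h = hashlib.sha256()
        h.update("\x00".join(map(str, self.gene_ids)).encode())
        h.update("\x00".join(map(str, self.sample_ids)).encode())
        h.update(np.ascontiguousarray(self.values.to_numpy(dtype=float)).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample genotype-group / tissue labels.

    ``table`` is indexed by unique sample id and carries a categorical
    ``group`` column (e.g. SDH / VHL / EPAS1 / other / normal), a boolean
    ``is_tumor`` column, and optionally a boolean ``hypoxia_label`` column
    used only by the pan-cancer bait-consistency stage.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValidationError("sample annotation requires a 'group' column")
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate sample ids in annotation: {sorted(map(str, dup))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @property
    def hypoxia_label(self) -> pd.Series | None:
        if "hypoxia_label" in self.table.columns:
            return self.table["hypoxia_label"].astype(bool)
        return None


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and numerical options shared across the pipeline.

    Defaults encode the published procedure: genes co-expressed with a bait
    at Pearson R > 0.4 and p < 0.001 enter that bait's set; genes present in
    >= 5 of the bait sets form the signature and >= 9 the top-ranking subset.
    """

    r_threshold: float = 0.4
    p_threshold: float = 0.001
    min_overlap_k: int = 5
    top_overlap_k: int = 9
    direction: str = "positive_only"  # or "both"
    log_pseudocount: float = 1.0
    z_ddof: int = 1
    multiple_testing: str = "BH"  # or "none"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValidationError("r_threshold must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.min_overlap_k < 1:
            raise ValidationError("min_overlap_k must be >= 1")
        if self.top_overlap_k < self.min_overlap_k:
            raise ValidationError("top_overlap_k must be >= min_overlap_k")
        if self.direction not in ("positive_only", "both"):
            raise ValidationError("direction must be 'positive_only' or 'both'")
        if self.log_pseudocount <= 0:
            raise ValidationError("log_pseudocount must be positive")
        if self.multiple_testing not in ("none", "BH"):
            raise ValidationError("multiple_testing must be 'none' or 'BH'")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, scale_declared: str = "linear") -> ExpressionMatrix:
    """Read a genes-x-samples TSV into a validated :class:`ExpressionMatrix`.

    Duplicate gene rows are an error (never silently collapsed); non-numeric
    cells raise with their row/column location.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: header row with sample ids is missing or empty")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id(s): {sorted(map(str, dup))}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
            loc = f"gene {bad[0]!r}, sample {col!r}" if len(bad) else f"column {col!r}"
            raise ValidationError(f"{path}: non-numeric cell at {loc}")
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    return ExpressionMatrix(values=df.astype(float), scale=scale_declared)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: sample metadata needs a 'sample_id' column")
    df = df.set_index("sample_id")
    if "is_tumor" in df.columns:
        df["is_tumor"] = df["is_tumor"].astype(bool)
    if "hypoxia_label" in df.columns:
        df["hypoxia_label"] = df["hypoxia_label"].astype(bool)
    return SampleAnnotation(table=df)


def write_sample_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate members within a line are removed with a logged warning; a line
    with fewer than three fields is a parse error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name, desc, *members = fields
            members = [g for g in members if g]
            if len(set(members)) < len(members):
                dups = sorted({g for g in members if members.count(g) > 1})
                logger.warning("GMT set %r: duplicate member(s) %s removed", name, dups)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.sorted_members()]) + "\n")


def to_log_scale(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(value + pseudocount)`` with scale promoted to log2.

    Applying this to an already-log2 matrix is a contract error: the
    transform is not idempotent and double application silently corrupts
    downstream correlations.
    """
    if m.scale == "log2":
        raise ValidationError("matrix is already on log2 scale; refusing to log-transform again")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return ExpressionMatrix(values=np.log2(m.values + pseudocount), scale="log2")


def ensure_log2(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Log-transform linear matrices; pass log2 matrices through unchanged."""
    return m if m.scale == "log2" else to_log_scale(m, pseudocount)
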