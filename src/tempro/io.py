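"""Readers, writers and validated containers for all on-disk artifacts.

Every table is UTF-8 TSV. Expression matrices are features x samples with the
feature ID in the first column and sample IDs in the header row. Missing
protein intensities are written as ``NA`` (or left empty) and carried in
memory as NaN — never as zero, which in count data is a real observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_KINDS = ("mrna", "protein")
VALID_SUBSETS = ("CD4", "CD8")

METADATA_COLUMNS = ("sample_id", "subset", "timepoint_h", "replicate")
IDMAP_COLUMNS = ("protein_id", "gene_id")


class FormatError(ValueError):
    """A file violates the documented on-disk contract."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    counts = pd.Index(labels).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise FormatError(f"duplicate {what} ID(s): {', '.join(map(str, dups.index[:5]))}")


@dataclass
class ExpressionMatrix:
    """A features x samples abundance matrix for one omics layer.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, index = feature IDs, columns = sample IDs. For
        ``kind="protein"`` missing values are NaN; for ``kind="mrna"`` the
        matrix must be dense non-negative counts.
    kind : {"mrna", "protein"}
    feature_annot : pandas.DataFrame, optional
        Per-feature annotation aligned to ``values.index`` (e.g. the
        ``unique_razor_peptides`` and ``id_score`` columns of a protein table).
    """

    values: pd.DataFrame
    kind: str
    feature_annot: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise FormatError(f"unknown matrix kind {self.kind!r}; expected one of {VALID_KINDS}")
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if self.kind == "mrna" and np.isnan(vals).any():
            raise FormatError("mRNA count matrix contains missing values; zeros are the only "
                              "valid representation of non-detection for counts")
        present = vals[~np.isnan(vals)]
        if (present < 0).any():
            raise FormatError("negative abundance values are not allowed")
        if self.feature_annot is not None and not self.feature_annot.index.equals(self.values.index):
            raise FormatError("feature_annot index must match the matrix feature IDs")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a value is missing."""
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        annot = self.feature_annot.loc[ids] if self.feature_annot is not None else None
        return ExpressionMatrix(self.values.loc[ids], self.kind, annot)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member sets."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

ANNOT_COLUMNS = ("unique_razor_peptides", "id_score")


def read_expression_matrix(path, kind: str, zeros_are_missing: bool = False) -> ExpressionMatrix:
    """Read a features x samples TSV into a validated :class:`ExpressionMatrix`.

    Empty cells and ``NA`` denote missing protein intensities. Annotation
    columns (``unique_razor_peptides``, ``id_score``) are split off into
    ``feature_annot`` when present. ``zeros_are_missing`` converts legacy
    protein tables that encode non-detection as 0.
    """
    path = Path(path)
    df = _read_tsv_rectangular(path)
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    _check_unique(df.index, "feature")
    annot = None
    annot_cols = [c for c in ANNOT_COLUMNS if c in df.columns]
    if annot_cols:
        annot = df[annot_cols].astype(float)
        df = df.drop(columns=annot_cols)
    try:
        values = df.astype(float)  # exact strtod parsing for bit-safe round trips
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
    if kind == "protein" and zeros_are_missing:
        values = values.mask(values == 0)
    return ExpressionMatrix(values.astype(float), kind, annot)


def _read_tsv_rectangular(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != width:
                raise FormatError(f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {width})")
            rows.append(fields)
    df = pd.DataFrame(rows, columns=header)
    return df.replace({"": np.nan, "NA": np.nan})


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.feature_annot is not None:
        df = pd.concat([matrix.feature_annot, df], axis=1)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


# ---------------------------------------------------------------------------
# metadata / ID map
# ---------------------------------------------------------------------------

def read_metadata(path, timepoints: Iterable[float] | None = None) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, subset, timepoint_h, replicate)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subset": str, "replicate": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata is missing column(s): {sorted(missing)}")
    bad = set(meta["subset"]) - set(VALID_SUBSETS)
    if bad:
        raise FormatError(f"unknown subset token(s): {sorted(bad)}")
    meta["timepoint_h"] = pd.to_numeric(meta["timepoint_h"])
    if timepoints is not None:
        off_grid = set(meta["timepoint_h"]) - set(timepoints)
        if off_grid:
            raise FormatError(f"timepoint(s) outside the configured grid: {sorted(off_grid)}")
    _check_unique(meta["sample_id"], "sample")
    return meta


def cross_validate(meta: pd.DataFrame, matrix: ExpressionMatrix) -> list[str]:
    """Check metadata against a matrix; return warnings for single-replicate groups.

    Raises :class:`FormatError` if any matrix sample has no metadata row or
    vice versa. Groups (subset, timepoint) with fewer than 2 replicates cannot
    be tested and are reported as warnings rather than errors.
    """
    meta_ids = set(meta["sample_id"])
    mat_ids = set(matrix.sample_ids)
    if meta_ids != mat_ids:
        extra = sorted(mat_ids - meta_ids)[:5]
        absent = sorted(meta_ids - mat_ids)[:5]
        raise FormatError(f"metadata/matrix sample mismatch (matrix-only: {extra}, metadata-only: {absent})")
    warnings = []
    for (subset, tp), grp in meta.groupby(["subset", "timepoint_h"]):
        if len(grp) < 2:
            warnings.append(f"group ({subset}, {tp} h) has a single replicate and is untestable")
    return warnings


def read_id_map(path) -> pd.DataFrame:
    """Read the protein_id <-> gene_id mapping TSV."""
    idmap = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(IDMAP_COLUMNS) - set(idmap.columns)
    if missing:
        raise FormatError(f"ID map is missing column(s): {sorted(missing)}")
    if idmap.duplicated(subset=list(IDMAP_COLUMNS)).any():
        raise FormatError("ID map contains duplicated (protein_id, gene_id) pair(s)")
    return idmap[list(IDMAP_COLUMNS)]


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# result objects
# ---------------------------------------------------------------------------

def write_json(obj: Mapping, path) -> None:
    """Canonical JSON writer: sorted keys, no timestamps, trailing newline."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
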