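"""Quality filters and normalization to analysis-ready log2 abundance matrices.

mRNA counts are normalized to log2 counts-per-million on TMM-adjusted
effective library sizes; protein intensities (already library-normalized
upstream, maxLFQ-style) are log2-transformed and filtered on peptide support,
identification score, and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class QCParams:
    """Protein QC thresholds: keep features with >= 2 unique/razor peptides,
    identification score >= 5, and missing fraction < 20% across all samples."""

    min_unique_razor_peptides: int = 2
    min_id_score: float = 5.0
    max_missing_fraction: float = 0.20
    cpm_prior: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise PreprocessError("max_missing_fraction must lie in [0, 1]")
        if self.cpm_prior <= 0:
            raise PreprocessError("cpm_prior must be > 0")


@dataclass
class NormalizedMatrix:
    """Log2-scale abundance matrix plus the per-sample scaling applied."""

    values: pd.DataFrame            # features x samples, log2 scale, NaN = missing
    kind: str
    scale_factors: pd.Series        # per-sample factor (TMM for mRNA, 1.0 for protein)
    transform: str                  # "log2cpm" | "log2intensity"

    def __post_init__(self) -> None:
        if (self.scale_factors <= 0).any():
            raise PreprocessError("scale factors must be > 0")
        if len(self.scale_factors) != self.values.shape[1]:
            raise PreprocessError("one scale factor per sample required")


class FilterResult(NamedTuple):
    matrix: ExpressionMatrix
    report: pd.DataFrame  # dropped features with their exclusion reasons


def filter_proteins(matrix: ExpressionMatrix, qc: QCParams = QCParams()) -> FilterResult:
    """Apply the protein QC filters; idempotent.

    A feature is retained iff peptides >= ``min_unique_razor_peptides`` AND
    score >= ``min_id_score`` AND missing fraction < ``max_missing_fraction``.
    The report lists every dropped feature with all reasons that applied.
    """
    if matrix.kind != "protein":
        raise PreprocessError("filter_proteins expects a protein matrix")
    annot = matrix.feature_annot
    if annot is None or not {"unique_razor_peptides", "id_score"} <= set(annot.columns):
        raise PreprocessError("protein matrix lacks 'unique_razor_peptides'/'id_score' annotation")
    peptides = annot["unique_razor_peptides"]
    scores = annot["id_score"]
    miss_frac = matrix.missing_mask.mean(axis=1)

    low_pep = peptides < qc.min_unique_razor_peptides
    low_score = scores < qc.min_id_score
    high_miss = miss_frac >= qc.max_missing_fraction
    drop = low_pep | low_score | high_miss

    reasons = []
    for fid in matrix.values.index[drop]:
        why = []
        if low_pep[fid]:
            why.append(f"unique_razor_peptides={peptides[fid]}<{qc.min_unique_razor_peptides}")
        if low_score[fid]:
            why.append(f"id_score={scores[fid]}<{qc.min_id_score}")
        if high_miss[fid]:
            why.append(f"missing_fraction={miss_frac[fid]:.3f}>={qc.max_missing_fraction}")
        reasons.append((fid, "; ".join(why)))
    report = pd.DataFrame(reasons, columns=["feature_id", "reason"]).set_index("feature_id")
    kept = matrix.subset_features(matrix.values.index[~drop])
    return FilterResult(kept, report)


# ---------------------------------------------------------------------------
# TMM (trimmed mean of M-values) scaling factors
# ---------------------------------------------------------------------------

def _choose_reference(counts: np.ndarray) -> int:
    """Column whose upper-quartile CPM is closest to the mean upper quartile."""
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (edgeR's doubly trimmed,
    precision-weighted mean of gene-wise log ratios)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise PreprocessError("sample shares no positively expressed gene with the reference")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or np.sum(w[keep]) == 0:
        return 1.0
    return float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_factors(matrix: ExpressionMatrix | pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    counts = values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = values.columns[lib <= 0][0]
        raise PreprocessError(f"sample {bad!r} has zero library size")
    ref = _choose_reference(counts)
    factors = np.array([
        1.0 if j == ref else _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref], trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


def cpm(matrix: ExpressionMatrix, log: bool = True, prior: float = 1.0,
        norm_factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts per million on effective library sizes (raw column sum x TMM factor)."""
    if matrix.kind != "mrna":
        raise PreprocessError("cpm expects an mRNA count matrix")
    counts = matrix.values
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise PreprocessError(f"sample {bad!r} has zero library size")
    factors = pd.Series(1.0, index=counts.columns) if norm_factors is None \
        else norm_factors.reindex(counts.columns)
    eff = lib * factors
    vals = counts / eff * 1e6
    if log:
        vals = np.log2(vals + prior)
    return NormalizedMatrix(vals, "mrna", factors, "log2cpm" if log else "cpm")


def log2_intensities(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Elementwise log2 of protein intensities; missing values stay missing."""
    if matrix.kind != "protein":
        raise PreprocessError("log2_intensities expects a protein matrix")
    vals = matrix.values
    present = vals.to_numpy()[~np.isnan(vals.to_numpy())]
    if (present <= 0).any():
        raise PreprocessError("non-positive protein intensity present; cannot log-transform")
    return NormalizedMatrix(np.log2(vals), "protein",
                            pd.Series(1.0, index=vals.columns), "log2intensity")


def compute_log2fc(norm: NormalizedMatrix, samples_a, samples_b) -> pd.Series:
    """Per-feature log2 fold change = mean(log2 A) - mean(log2 B).

    Missing values are omitted from each group mean; a feature with no present
    value in a group gets NaN.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise PreprocessError("both groups must contain at least one sample")
    a = norm.values[samples_a].mean(axis=1, skipna=True)
    b = norm.values[samples_b].mean(axis=1, skipna=True)
    fc = a - b
    fc.name = "log2fc"
    return fc


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: raw counts -> log2 CPM on TMM effective sizes.

    Follows the sklearn convention X = (n_samples, n_features), i.e. libraries
    are rows. ``fit`` learns per-library TMM factors against a reference
    library chosen by the upper-quartile rule; ``transform`` returns
    log2(CPM + prior) using the factors learned on the same libraries.

    Attributes
    ----------
    norm_factors_ : ndarray of shape (n_samples,)
    lib_sizes_ : ndarray of shape (n_samples,)
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05,
                 log: bool = True, prior: float = 1.0):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.log = log
        self.prior = prior

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        df = pd.DataFrame(X.T)  # features x samples for the functional core
        self.norm_factors_ = tmm_factors(df, self.trim_m, self.trim_a).to_numpy()
        self.lib_sizes_ = X.sum(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "norm_factors_")
        X = np.asarray(X, dtype=float)
        eff = X.sum(axis=1) * self.norm_factors_[: X.shape[0]] \
            if X.shape[0] == len(self.norm_factors_) else X.sum(axis=1)
        vals = X / eff[:, None] * 1e6
        return np.log2(vals + self.prior) if self.log else vals
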