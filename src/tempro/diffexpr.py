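"""Per-timepoint differential expression with two-stage adaptive FDR.

Each stimulation timepoint is compared against the 0 h baseline (and CD4
against CD8 within a timepoint) by row-wise two-sample t-tests on log2
abundances, followed by the two-stage linear step-up FDR procedure of
Benjamini, Krieger & Yekutieli (BKY). DE calls combine a fold-change
threshold with the adjusted significance: strict inequalities for mRNA
(|log2fc| > 1.5, q < 0.01), inclusive for protein (|log2fc| >= 1.0,
q <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix, compute_log2fc


class DiffExprError(ValueError):
    pass


@dataclass(frozen=True)
class DEThresholds:
    """Layer-specific DE thresholds. mRNA bounds are strict, protein inclusive."""

    mrna_lfc: float = 1.5
    mrna_alpha: float = 0.01
    prot_lfc: float = 1.0
    prot_alpha: float = 0.05

    def __post_init__(self) -> None:
        for v in (self.mrna_lfc, self.prot_lfc):
            if v <= 0:
                raise DiffExprError("fold-change thresholds must be > 0")
        for a in (self.mrna_alpha, self.prot_alpha):
            if not (0.0 < a < 1.0):
                raise DiffExprError("alpha levels must lie in (0, 1)")


# ---------------------------------------------------------------------------
# row-wise t-tests
# ---------------------------------------------------------------------------

def row_ttests(values_a: np.ndarray, values_b: np.ndarray, paired: bool = False):
    """Vectorized two-sided t-tests over rows with missing-value handling.

    Parameters
    ----------
    values_a, values_b : 2-D arrays (features x replicates), NaN = missing.
    paired : pair columns by position (replicate label order) and test the
        mean difference; unpaired uses the pooled equal-variance statistic.

    Returns
    -------
    (p, t, tested) — tested is False for rows with < 2 present values in
    either group (p is NaN there). Degenerate rows (zero variance): p = 1
    when the group means coincide, p = 0 when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise DiffExprError("inputs must be 2-D with matching row counts")

    if paired:
        if a.shape[1] != b.shape[1]:
            raise DiffExprError("paired mode requires equal replicate counts")
        n, mean, var = _row_stats(a - b)  # NaN wherever either member is missing
        tested = n >= 2
        df = n - 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(var / np.maximum(n, 1))
    else:
        na, ma, va = _row_stats(a)
        nb, mb, vb = _row_stats(b)
        tested = (na >= 2) & (nb >= 2)
        df = na + nb - 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = ((na - 1) * va + (nb - 1) * vb) / df
            se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        mean = ma - mb

    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    with np.errstate(invalid="ignore"):
        zero_se = tested & ~(se > 0)
        shifted = np.abs(mean) > 1e-12
        p = np.where(zero_se & ~shifted, 1.0, p)
        p = np.where(zero_se & shifted, 0.0, p)
        t = np.where(zero_se, np.where(shifted, np.inf * np.sign(np.where(zero_se, mean, 1.0)), 0.0), t)
    p = np.where(tested, p, np.nan)
    return p, t, tested


def _row_stats(x: np.ndarray):
    """Per-row (n present, mean, unbiased variance) ignoring NaN, warning-free."""
    mask = np.isfinite(x)
    n = mask.sum(axis=1)
    filled = np.where(mask, x, 0.0)
    mean = np.where(n > 0, filled.sum(axis=1) / np.maximum(n, 1), np.nan)
    centered = np.where(mask, x - mean[:, None], 0.0)
    var = np.where(n >= 2, (centered ** 2).sum(axis=1) / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


# ---------------------------------------------------------------------------
# BKY two-stage linear step-up FDR
# ---------------------------------------------------------------------------

def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Classical BH adjusted p-values (monotone step-up transform)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bky_reject(p_raw: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Rejection mask of the two-stage BKY procedure at nominal level q.

    Stage 1: BH at q' = q/(1+q) giving r1 rejections. r1 = 0 -> reject none;
    r1 = m -> reject all; otherwise stage 2 is BH at q' * m / (m - r1).
    """
    p = _validated_p(p_raw)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    q1 = q / (1.0 + q)
    padj = _bh_adjusted(p)
    r1 = int(np.sum(padj <= q1))
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return padj <= q1 * m / (m - r1)


def bky_adjust(p_raw: np.ndarray, q: float = 0.05):
    """Two-stage BKY q-values and the rejection set at level ``q``.

    The reported q_adj of a feature is the smallest nominal q at which the
    two-stage procedure would reject it, computed exactly by scanning the
    intervals of q on which the stage-1 rejection count is constant. By
    construction ``{q_adj <= q}`` equals :func:`bky_reject` at any level
    (features never rejected below q = 1 report q_adj = 1).
    """
    p = _validated_p(p_raw)
    m = len(p)
    if m == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    padj = _bh_adjusted(p)

    # stage-1 count r1(q) = #{padj <= q/(1+q)} is a step function of q with
    # breakpoints where q/(1+q) crosses a distinct padj value
    u = np.unique(padj)                      # ascending distinct BH-adjusted values
    counts = np.searchsorted(np.sort(padj), u, side="right")
    qprime_min = np.full(m, np.inf)
    for k, (u_k, c_k) in enumerate(zip(u, counts)):
        hi = u[k + 1] if k + 1 < len(u) else np.inf  # interval [u_k, hi) of q'
        if u_k >= 0.5:
            break  # q' = q/(1+q) < 0.5 for any q < 1
        if c_k == m:
            cand = np.full(m, u_k)           # everything rejected on entry
        else:
            cand = np.maximum(u_k, padj * (m - c_k) / m)
        feasible = cand < hi
        qprime_min = np.where(feasible, np.minimum(qprime_min, cand), qprime_min)

    with np.errstate(divide="ignore", invalid="ignore"):
        q_adj = np.where(np.isfinite(qprime_min) & (qprime_min < 0.5),
                         qprime_min / (1.0 - qprime_min), 1.0)
    q_adj = np.minimum(q_adj, 1.0)
    return q_adj, q_adj <= q


def _validated_p(p_raw) -> np.ndarray:
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("p-values must be a 1-D vector")
    if len(p) and (not np.isfinite(p).all() or p.min() < 0 or p.max() > 1):
        raise DiffExprError("p-values must be finite and within [0, 1]")
    return p


# ---------------------------------------------------------------------------
# DE calls and summaries
# ---------------------------------------------------------------------------

def call_de(log2fc: pd.Series, q_adj: pd.Series, kind: str,
            thr: DEThresholds = DEThresholds()) -> pd.Series:
    """Direction calls {up, down, ns} from aligned fold changes and q-values."""
    if kind == "mrna":
        up = (log2fc > thr.mrna_lfc) & (q_adj < thr.mrna_alpha)
        down = (log2fc < -thr.mrna_lfc) & (q_adj < thr.mrna_alpha)
    elif kind == "protein":
        up = (log2fc >= thr.prot_lfc) & (q_adj <= thr.prot_alpha)
        down = (log2fc <= -thr.prot_lfc) & (q_adj <= thr.prot_alpha)
    else:
        raise DiffExprError(f"unknown omics kind {kind!r}")
    out = pd.Series("ns", index=log2fc.index, name="direction")
    out[up.fillna(False)] = "up"
    out[down.fillna(False)] = "down"
    return out


def percent_de(n_de: int, n_quantified: int) -> float:
    """Percentage of quantified features called DE: 100 * n_de / n_quantified."""
    if n_quantified == 0:
        raise DiffExprError("n_quantified must be > 0")
    if n_de > n_quantified:
        raise DiffExprError("n_de cannot exceed n_quantified")
    return 100.0 * n_de / n_quantified


def de_contrast(norm: NormalizedMatrix, meta: pd.DataFrame, samples_a, samples_b,
                label: str, thr: DEThresholds = DEThresholds(),
                paired: bool = False) -> pd.DataFrame:
    """Full DE table for one contrast (group A vs group B).

    Columns: log2fc, p_raw, q_adj, direction, tested. Untested features
    (fewer than 2 present values in a group) carry NaN statistics and ns.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise DiffExprError(f"contrast {label!r}: empty group")
    a = norm.values[samples_a].to_numpy(dtype=float)
    b = norm.values[samples_b].to_numpy(dtype=float)
    p, t, tested = row_ttests(a, b, paired=paired)
    lfc = compute_log2fc(norm, samples_a, samples_b)

    q = np.full(len(p), np.nan)
    if tested.any():
        alpha = thr.mrna_alpha if norm.kind == "mrna" else thr.prot_alpha
        q[tested], _ = bky_adjust(p[tested], q=alpha)
    table = pd.DataFrame({
        "log2fc": lfc,
        "p_raw": p,
        "q_adj": q,
        "tested": tested,
    }, index=norm.values.index)
    direction = call_de(table["log2fc"], table["q_adj"], norm.kind, thr)
    direction[~table["tested"]] = "ns"
    table["direction"] = direction
    table.attrs["contrast"] = label
    return table


def timecourse_de(norm: NormalizedMatrix, meta: pd.DataFrame, subset: str,
                  thr: DEThresholds = DEThresholds(), paired: bool = False,
                  baseline: float = 0.0) -> dict[float, pd.DataFrame]:
    """DE tables for every timepoint vs the 0 h baseline within one subset."""
    sub = meta[meta["subset"] == subset]
    base = sub.loc[sub["timepoint_h"] == baseline, "sample_id"].tolist()
    if not base:
        raise DiffExprError(f"no baseline ({baseline} h) samples for subset {subset!r}")
    out = {}
    for tp in sorted(set(sub["timepoint_h"]) - {baseline}):
        grp = sub.loc[sub["timepoint_h"] == tp, "sample_id"].tolist()
        out[tp] = de_contrast(norm, meta, grp, base, f"{subset}:{tp}h_vs_0h",
                              thr=thr, paired=paired)
    return out


def subset_contrast(norm: NormalizedMatrix, meta: pd.DataFrame, timepoint: float,
                    thr: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """CD4 vs CD8 DE at one timepoint; positive log2fc = higher in CD4."""
    cd4 = meta.loc[(meta["subset"] == "CD4") & (meta["timepoint_h"] == timepoint), "sample_id"]
    cd8 = meta.loc[(meta["subset"] == "CD8") & (meta["timepoint_h"] == timepoint), "sample_id"]
    if cd4.empty or cd8.empty:
        raise DiffExprError(f"both subsets required at {timepoint} h")
    return de_contrast(norm, meta, cd4.tolist(), cd8.tolist(),
                       f"CD4_vs_CD8:{timepoint}h", thr=thr)


def percent_de_table(de_tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Percent-DE kinetics: one row per contrast timepoint."""
    rows = []
    for tp, tab in sorted(de_tables.items()):
        n_quant = int(tab["tested"].sum())
        n_de = int((tab["direction"] != "ns").sum())
        rows.append((tp, n_de, n_quant, percent_de(n_de, n_quant)))
    return pd.DataFrame(rows, columns=["timepoint_h", "n_de", "n_quantified", "percent"])
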