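"""Cross-omics matching and mRNA-protein coupling kinetics.

Matched gene-protein pairs carry per-timepoint log2 fold changes on both
layers. Coupling is summarized as (i) Pearson correlation of the paired fold
changes per timepoint with the conventional strength bands, (ii) quadrant
concordance of fold-change signs, and (iii) a translation-lag track: how many
proteins whose transcript was DE at the anchor timepoint (6 h) become DE at
each later timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class CouplingError(ValueError):
    pass


QUADRANTS = ("up_up", "up_down", "down_up", "down_down")  # (mRNA, protein) sign


@dataclass
class MatchedPairs:
    """Matched gene-protein pairs with per-timepoint fold changes and DE flags.

    ``table`` has one row per (gene_id, protein_id) pair and column blocks
    ``mrna_lfc_<t>``, ``prot_lfc_<t>``, ``mrna_de_<t>``, ``prot_de_<t>``.
    """

    table: pd.DataFrame
    timepoints: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.table)


def match_features(mrna_ids, protein_ids, idmap: pd.DataFrame,
                   best_single: bool = False) -> pd.DataFrame:
    """Pairs (protein_id, gene_id) quantified on both layers.

    One-to-many mappings contribute one pair per mapping by default
    (multiplicity flagged in the ``n_mappings`` column); ``best_single`` keeps
    only the first mapping per protein in ID-map order.
    """
    mrna_ids = set(mrna_ids)
    protein_ids = set(protein_ids)
    pairs = idmap[idmap["protein_id"].isin(protein_ids) & idmap["gene_id"].isin(mrna_ids)].copy()
    if pairs.empty:
        return pd.DataFrame(columns=["protein_id", "gene_id", "n_mappings"])
    pairs["n_mappings"] = pairs.groupby("protein_id")["gene_id"].transform("size")
    if best_single:
        pairs = pairs.drop_duplicates(subset="protein_id", keep="first")
    return pairs.reset_index(drop=True)


def build_matched_pairs(pairs: pd.DataFrame,
                        mrna_de: dict[float, pd.DataFrame],
                        prot_de: dict[float, pd.DataFrame]) -> MatchedPairs:
    """Assemble the per-timepoint fold-change/DE table for matched pairs."""
    tps = tuple(sorted(mrna_de))
    if tuple(sorted(prot_de)) != tps:
        raise CouplingError("mRNA and protein DE results cover different timepoint grids")
    rows = pairs[["gene_id", "protein_id"]].copy()
    for tp in tps:
        mt, pt = mrna_de[tp], prot_de[tp]
        rows[f"mrna_lfc_{tp:g}"] = mt["log2fc"].reindex(rows["gene_id"]).to_numpy()
        rows[f"prot_lfc_{tp:g}"] = pt["log2fc"].reindex(rows["protein_id"]).to_numpy()
        rows[f"mrna_de_{tp:g}"] = (mt["direction"].reindex(rows["gene_id"]) != "ns").to_numpy()
        rows[f"prot_de_{tp:g}"] = (pt["direction"].reindex(rows["protein_id"]) != "ns").to_numpy()
    return MatchedPairs(rows, tps)


def classify_strength(r: float) -> str:
    """Conventional Pearson-correlation strength bands on |r|.

    strong >= 0.70 > moderate >= 0.40 > weak >= 0.10 > negligible.
    """
    if not (-1.0 <= r <= 1.0):
        raise CouplingError(f"correlation {r} outside [-1, 1]")
    a = abs(r)
    if a >= 0.70:
        return "strong"
    if a >= 0.40:
        return "moderate"
    if a >= 0.10:
        return "weak"
    return "negligible"


def correlation_kinetics(pairs: MatchedPairs, selection: str = "mrna_de") -> pd.DataFrame:
    """Pearson r of (mRNA log2fc, protein log2fc) per timepoint.

    ``selection`` chooses the pairs entering each timepoint's correlation:
    "mrna_de" (default) gates on the transcript being DE at that timepoint,
    "mrna_de_any" on DE at any timepoint, "all" uses every pair. Pairs with a
    missing fold change on either layer are dropped; r is reported missing
    with fewer than 3 pairs.
    """
    rows = []
    tab = pairs.table
    any_de = None
    if selection == "mrna_de_any":
        any_de = np.column_stack([tab[f"mrna_de_{tp:g}"] for tp in pairs.timepoints]).any(axis=1)
    for tp in pairs.timepoints:
        x = tab[f"mrna_lfc_{tp:g}"].to_numpy(dtype=float)
        y = tab[f"prot_lfc_{tp:g}"].to_numpy(dtype=float)
        if selection == "mrna_de":
            sel = tab[f"mrna_de_{tp:g}"].to_numpy(dtype=bool)
        elif selection == "mrna_de_any":
            sel = any_de
        elif selection == "all":
            sel = np.ones(len(tab), dtype=bool)
        else:
            raise CouplingError(f"unknown selection rule {selection!r}")
        sel = sel & np.isfinite(x) & np.isfinite(y)
        n = int(sel.sum())
        if n < 3:
            rows.append((tp, np.nan, n, "na"))
            continue
        r = pearson(x[sel], y[sel])
        rows.append((tp, r, n, classify_strength(r)))
    return pd.DataFrame(rows, columns=["timepoint_h", "r", "n_pairs", "strength"])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form Pearson correlation (covariance over the SD product)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def quadrant_summary(pairs: MatchedPairs, timepoint: float,
                     de_gated: bool = True) -> pd.DataFrame:
    """Fractions of pairs per fold-change sign quadrant at one timepoint.

    Pairs with exactly zero fold change on either axis are excluded (tie
    rule) so the four fractions sum to 1 over counted pairs. ``de_gated``
    restricts to pairs whose transcript is DE at the timepoint.
    """
    tab = pairs.table
    x = tab[f"mrna_lfc_{timepoint:g}"].to_numpy(dtype=float)
    y = tab[f"prot_lfc_{timepoint:g}"].to_numpy(dtype=float)
    sel = np.isfinite(x) & np.isfinite(y) & (x != 0) & (y != 0)
    if de_gated:
        sel &= tab[f"mrna_de_{timepoint:g}"].to_numpy(dtype=bool)
    n = int(sel.sum())
    fracs = {}
    for name, (sx, sy) in zip(QUADRANTS, ((1, 1), (1, -1), (-1, 1), (-1, -1))):
        k = int(np.sum(sel & (np.sign(x) == sx) & (np.sign(y) == sy)))
        fracs[name] = k / n if n else np.nan
    out = pd.DataFrame([{"timepoint_h": timepoint, "n_pairs": n, **fracs}])
    return out


def lag_track(pairs: MatchedPairs, anchor_timepoint: float = 6.0) -> pd.DataFrame:
    """Protein DE counts among pairs whose transcript was DE at the anchor.

    For each timepoint: counts of anchored proteins called DE up / down, and
    the cumulative count DE at >= 1 timepoint up to and including it.
    """
    tab = pairs.table
    key = f"mrna_de_{anchor_timepoint:g}"
    if key not in tab:
        raise CouplingError(f"anchor timepoint {anchor_timepoint} not in the DE grid")
    anchored = tab[tab[key].astype(bool)]
    rows = []
    ever = np.zeros(len(anchored), dtype=bool)
    for tp in pairs.timepoints:
        de = anchored[f"prot_de_{tp:g}"].to_numpy(dtype=bool)
        lfc = anchored[f"prot_lfc_{tp:g}"].to_numpy(dtype=float)
        ever |= de
        rows.append((tp, int(np.sum(de & (lfc > 0))), int(np.sum(de & (lfc < 0))),
                     int(de.sum()), int(ever.sum())))
    out = pd.DataFrame(rows, columns=["timepoint_h", "n_up", "n_down", "n_de", "n_cumulative"])
    out.attrs["n_anchored"] = len(anchored)
    return out


def set_overlap(set_a, set_b) -> dict:
    """Exact set arithmetic: intersection, asymmetric differences, Jaccard."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    union = len(a | b)
    return {
        "intersection": inter,
        "only_a": len(a - b),
        "only_b": len(b - a),
        "jaccard": inter / union if union else 1.0,
    }
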