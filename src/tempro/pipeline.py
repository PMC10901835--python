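"""End-to-end orchestration: simulate/load -> preprocess -> DE -> coupling ->
clustering -> enrichment, with a machine-readable run report.

A single global seed fans out to per-stage seeds by fixed offsets so stages
are independently reproducible; identical config + seed gives byte-identical
reports (no timestamps in any canonical output).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (build_profiles, cluster_counts, core_members,
                      fuzzy_cmeans, standardize)
from .coupling import (build_matched_pairs, correlation_kinetics, lag_track,
                       match_features, quadrant_summary, set_overlap)
from .diffexpr import DEThresholds, percent_de_table, subset_contrast, timecourse_de
from .enrich import enrich_sets
from .io import (cross_validate, read_expression_matrix, read_gmt,
                 read_id_map, read_metadata, write_json)
from .preprocess import QCParams, cpm, filter_proteins, log2_intensities, tmm_factors
from .simulate import (SimConfig, gene_sets_from_truth, simulate_dataset,
                       write_dataset)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the global seed
SEED_OFFSET_SIM = 0
SEED_OFFSET_CLUSTER = 1009
SEED_OFFSET_GENESETS = 2003


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (one of synthetic / real input mode)."""

    seed: int = 0
    synthetic: SimConfig | None = None
    inputs: dict | None = None          # paths: mrna, protein, metadata, id_map[, gene_sets]
    qc: QCParams = field(default_factory=QCParams)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    n_clusters: int = 12
    core_threshold: float = 0.5
    enrich_alpha: float = 0.05
    paired: bool = False
    log_level: str = "INFO"


_SECTION_KEYS = {"mode", "seed", "synthetic", "inputs", "qc", "thresholds",
                 "clustering", "enrichment", "paired", "log_level"}


def validate_config(raw: dict, base_dir: Path | None = None) -> RunConfig:
    """Fill defaults, run cross-field checks, reject unknown keys."""
    unknown = set(raw) - _SECTION_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "real"):
        raise ConfigError(f"mode must be 'synthetic' or 'real', got {mode!r}")
    seed = int(raw.get("seed", 0))

    synthetic = None
    inputs = None
    if mode == "synthetic":
        if raw.get("inputs"):
            raise ConfigError("synthetic mode must not declare real input paths")
        sim_raw = dict(raw.get("synthetic") or {})
        sim_raw.setdefault("seed", seed + SEED_OFFSET_SIM)
        valid = {f.name for f in fields(SimConfig)}
        unknown = set(sim_raw) - valid
        if unknown:
            raise ConfigError(f"unknown synthetic key(s): {sorted(unknown)}")
        if "timepoints" in sim_raw:
            sim_raw["timepoints"] = tuple(float(t) for t in sim_raw["timepoints"])
        synthetic = SimConfig(**sim_raw)
    else:
        if raw.get("synthetic"):
            raise ConfigError("real mode must not declare a synthetic block")
        inputs = dict(raw.get("inputs") or {})
        required = {"mrna", "protein", "metadata", "id_map"}
        missing = required - set(inputs)
        if missing:
            raise ConfigError(f"real mode requires input path(s): {sorted(missing)}")
        for key, path in inputs.items():
            p = Path(path)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise ConfigError(f"input file for {key!r} not found: {p}")
            inputs[key] = str(p)

    def build(section, cls):
        kwargs = dict(raw.get(section) or {})
        valid = {f.name for f in fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ConfigError(f"unknown {section} key(s): {sorted(unknown)}")
        try:
            return cls(**kwargs)
        except ValueError as exc:
            raise ConfigError(f"invalid {section} parameter: {exc}") from exc

    clustering = dict(raw.get("clustering") or {})
    unknown = set(clustering) - {"c", "core_threshold"}
    if unknown:
        raise ConfigError(f"unknown clustering key(s): {sorted(unknown)}")
    enrichment = dict(raw.get("enrichment") or {})
    unknown = set(enrichment) - {"alpha"}
    if unknown:
        raise ConfigError(f"unknown enrichment key(s): {sorted(unknown)}")

    return RunConfig(
        seed=seed,
        synthetic=synthetic,
        inputs=inputs,
        qc=build("qc", QCParams),
        thresholds=build("thresholds", DEThresholds),
        n_clusters=int(clustering.get("c", 12)),
        core_threshold=float(clustering.get("core_threshold", 0.5)),
        enrich_alpha=float(enrichment.get("alpha", 0.05)),
        paired=bool(raw.get("paired", False)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return validate_config(raw, base_dir=path.parent)


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    blob = json.dumps(asdict(cfg), sort_keys=True, default=enc).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages in order, writing every intermediate to ``outdir``.

    Returns the run report (also written as ``run_report.json``). A stage
    failure aborts with :class:`StageError` naming the stage; downstream
    stages are not run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seeds": {"global": cfg.seed,
                  "simulate": (cfg.synthetic.seed if cfg.synthetic else None),
                  "cluster": cfg.seed + SEED_OFFSET_CLUSTER},
        "stages": {},
    }

    # ---- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if cfg.synthetic is not None:
            ds = simulate_dataset(cfg.synthetic)
            write_dataset(ds, outdir / "simulated")
            mrna, protein, meta, idmap = ds.mrna, ds.protein, ds.metadata, ds.id_map
            gmt = gene_sets_from_truth(ds.truth, seed=cfg.seed + SEED_OFFSET_GENESETS)
            truth = ds.truth
        else:
            mrna = read_expression_matrix(cfg.inputs["mrna"], "mrna")
            protein = read_expression_matrix(cfg.inputs["protein"], "protein")
            meta = read_metadata(cfg.inputs["metadata"])
            idmap = read_id_map(cfg.inputs["id_map"])
            gmt = read_gmt(cfg.inputs["gene_sets"]) if "gene_sets" in cfg.inputs else None
            truth = None
        for w in cross_validate(meta, mrna) + cross_validate(meta, protein):
            logger.warning(w)
        timepoints = sorted(set(meta["timepoint_h"]))
        subsets = sorted(set(meta["subset"]))
        report["stages"]["inputs"] = {
            "n_genes_quantified": mrna.shape[0],
            "n_proteins_quantified": protein.shape[0],
            "n_samples": mrna.shape[1],
            "timepoints_h": timepoints,
            "subsets": subsets,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ---- stage: preprocess -------------------------------------------------
    stage = "preprocess"
    try:
        prot_kept, qc_report = filter_proteins(protein, cfg.qc)
        qc_report.to_csv(outdir / "protein_qc_exclusions.tsv", sep="\t")
        factors = tmm_factors(mrna)
        factors.to_csv(outdir / "tmm_factors.tsv", sep="\t")
        mrna_norm = cpm(mrna, log=True, prior=cfg.qc.cpm_prior, norm_factors=factors)
        prot_norm = log2_intensities(prot_kept)
        report["stages"]["preprocess"] = {
            "n_proteins_post_qc": prot_kept.shape[0],
            "n_proteins_excluded": int(len(qc_report)),
            "tmm_factor_range": [float(factors.min()), float(factors.max())],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: diffexpr ---------------------------------------------------
    stage = "diffexpr"
    try:
        mrna_de: dict[str, dict[float, pd.DataFrame]] = {}
        prot_de: dict[str, dict[float, pd.DataFrame]] = {}
        de_counts: dict[str, dict] = {}
        for subset in subsets:
            mrna_de[subset] = timecourse_de(mrna_norm, meta, subset, thr=cfg.thresholds,
                                            paired=cfg.paired)
            prot_de[subset] = timecourse_de(prot_norm, meta, subset, thr=cfg.thresholds,
                                            paired=cfg.paired)
            for layer, tabs in (("mrna", mrna_de[subset]), ("protein", prot_de[subset])):
                pct = percent_de_table(tabs)
                pct.to_csv(outdir / f"percent_de_{layer}_{subset}.tsv", sep="\t", index=False)
                de_counts[f"{layer}_{subset}"] = {
                    f"{tp:g}": {"n_de": int(r.n_de), "n_quantified": int(r.n_quantified),
                                "percent": round(float(r.percent), 4)}
                    for tp, r in zip(pct["timepoint_h"], pct.itertuples(index=False))
                }
                for tp, tab in tabs.items():
                    tab.to_csv(outdir / f"de_{layer}_{subset}_{tp:g}h.tsv", sep="\t")
        between = {}
        if len(subsets) == 2:
            for tp in timepoints:
                tab = subset_contrast(mrna_norm, meta, tp, thr=cfg.thresholds)
                between[f"{tp:g}"] = int((tab["direction"] != "ns").sum())
        report["stages"]["diffexpr"] = {"percent_de": de_counts,
                                        "n_between_subset_de_mrna": between}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: coupling ---------------------------------------------------
    stage = "coupling"
    try:
        pairs_df = match_features(mrna.feature_ids, prot_kept.feature_ids, idmap)
        coupling_report = {"n_pairs": int(len(pairs_df)),
                           "shared_quantification": set_overlap(
                               mrna.feature_ids,
                               idmap.loc[idmap["protein_id"].isin(prot_kept.feature_ids),
                                         "gene_id"])}
        corr_tables = {}
        for subset in subsets:
            mp = build_matched_pairs(pairs_df, mrna_de[subset], prot_de[subset])
            corr = correlation_kinetics(mp)
            corr.to_csv(outdir / f"coupling_r_{subset}.tsv", sep="\t", index=False)
            quad = pd.concat([quadrant_summary(mp, tp) for tp in mp.timepoints],
                             ignore_index=True)
            quad.to_csv(outdir / f"coupling_quadrants_{subset}.tsv", sep="\t", index=False)
            anchor = 6.0 if 6.0 in mp.timepoints else mp.timepoints[0]
            track = lag_track(mp, anchor_timepoint=anchor)
            track.to_csv(outdir / f"lag_track_{subset}.tsv", sep="\t", index=False)
            corr_tables[subset] = {
                "r": {f"{tp:g}": (None if not np.isfinite(r) else round(float(r), 6))
                      for tp, r in zip(corr["timepoint_h"], corr["r"])},
                "strength": dict(zip([f"{t:g}" for t in corr["timepoint_h"]], corr["strength"])),
                "lag_cumulative": dict(zip([f"{t:g}" for t in track["timepoint_h"]],
                                           [int(v) for v in track["n_cumulative"]])),
                "n_anchored": int(track.attrs["n_anchored"]),
            }
        coupling_report["per_subset"] = corr_tables
        report["stages"]["coupling"] = coupling_report
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: clustering -------------------------------------------------
    stage = "clustering"
    try:
        clust_report = {}
        cluster_sets: dict[str, dict[int, set]] = {}
        for subset in subsets:
            prof = build_profiles(mrna_de[subset])
            z = standardize(prof)
            c = cfg.n_clusters if len(z) >= cfg.n_clusters else max(2, len(z) // 2)
            if len(z) < 4:
                clust_report[subset] = {"skipped": True, "n_profiles": int(len(z))}
                continue
            model = fuzzy_cmeans(z, c=c, seed=cfg.seed + SEED_OFFSET_CLUSTER)
            assign = core_members(model, z.index, threshold=cfg.core_threshold)
            assign.to_csv(outdir / f"cluster_assignments_{subset}.tsv", sep="\t")
            pd.DataFrame(model.cluster_centers_, columns=z.columns).to_csv(
                outdir / f"cluster_centroids_{subset}.tsv", sep="\t")
            counts = cluster_counts(assign, c)
            cluster_sets[subset] = {
                int(k): set(assign.index[(assign["cluster"] == k) & assign["core"]])
                for k in range(c)}
            clust_report[subset] = {
                "n_profiles": int(len(z)),
                "c": int(c),
                "fuzzifier": round(float(model.fuzzifier_), 6),
                "n_core": int(assign["core"].sum()),
                "core_per_cluster": [int(v) for v in counts],
                "objective_final": round(float(model.objective_trace_[-1]), 6),
            }
        if len(cluster_sets) == 2:
            s4, s8 = (cluster_sets[s] for s in subsets)
            all4 = set().union(*s4.values()) if s4 else set()
            all8 = set().union(*s8.values()) if s8 else set()
            clust_report["subset_core_overlap"] = set_overlap(all4, all8)
        report["stages"]["clustering"] = clust_report
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: enrichment -------------------------------------------------
    stage = "enrichment"
    try:
        enr_report = {}
        if gmt is not None and subsets:
            subset = subsets[0]
            background = set(mrna.feature_ids)
            de_any = build_profiles(mrna_de[subset]).index
            if len(de_any):
                table = enrich_sets(set(de_any), background, gmt, alpha=cfg.enrich_alpha)
                table.to_csv(outdir / f"enrichment_{subset}.tsv", sep="\t", index=False)
                enr_report = {
                    "n_sets_tested": int(len(table)),
                    "n_significant": int(table["significant"].sum()) if len(table) else 0,
                    "top_set": (str(table.iloc[0]["set_name"]) if len(table) else None),
                }
        report["stages"]["enrichment"] = enr_report
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    _check_report_consistency(report)
    write_json(report, outdir / "run_report.json")
    return report


def _check_report_consistency(report: dict) -> None:
    """Internal count constraints asserted on every run."""
    inputs = report["stages"]["inputs"]
    pre = report["stages"]["preprocess"]
    assert pre["n_proteins_post_qc"] + pre["n_proteins_excluded"] == inputs["n_proteins_quantified"]
    for key, per_tp in report["stages"]["diffexpr"]["percent_de"].items():
        for tp, rec in per_tp.items():
            assert 0 <= rec["n_de"] <= rec["n_quantified"], (key, tp)
            limit = inputs["n_genes_quantified"] if key.startswith("mrna") \
                else pre["n_proteins_post_qc"]
            assert rec["n_quantified"] <= limit, (key, tp)
    for subset, rec in report["stages"]["coupling"]["per_subset"].items():
        lag = list(rec["lag_cumulative"].values())
        assert all(b >= a for a, b in zip(lag, lag[1:])), subset
        assert (lag[-1] if lag else 0) <= rec["n_anchored"]
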