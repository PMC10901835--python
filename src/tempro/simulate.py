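"""Coupled mRNA/protein time-course simulator with ground truth.

The generator emulates a stimulation time course measured in parallel by
RNA-seq and label-free proteomics: two cell subsets, six timepoints, three
replicates. Transcript induction follows a saturating exponential; protein
follows first-order synthesis/degradation kinetics driven by the transcript,
which produces the translation lag the downstream coupling analysis is built
to detect. Counts are negative-binomial with library-size variation; protein
intensities are log-normal with mixed MCAR/MNAR missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, GeneSetCollection, write_expression_matrix

DEFAULT_TIMEPOINTS = (0.0, 6.0, 12.0, 24.0, 72.0, 168.0)


class ParameterError(ValueError):
    """A kinetic or simulation parameter violates its constraints."""


@dataclass(frozen=True)
class KineticParams:
    """First-order induction/translation kinetics for one gene-protein pair.

    ``fold_response`` is the plateau multiplicative change of the transcript
    (1 = non-responsive null, <1 = down-regulated); ``t_on`` the onset time in
    hours; ``tau_m`` the transcript response time constant; ``k_s`` the
    translation rate (protein units per mRNA unit per hour); ``k_d`` the
    protein degradation rate per hour.
    """

    baseline_mrna: float
    fold_response: float = 1.0
    t_on: float = 0.0
    tau_m: float = 12.0
    k_s: float = 0.1
    k_d: float = 0.01

    def __post_init__(self) -> None:
        if self.baseline_mrna <= 0:
            raise ParameterError("baseline_mrna must be > 0")
        if self.fold_response <= 0:
            raise ParameterError("fold_response must be > 0")
        if not (0.0 <= self.t_on <= 168.0):
            raise ParameterError("t_on must lie in [0, 168] hours")
        if self.tau_m <= 0:
            raise ParameterError("tau_m must be > 0")
        if self.k_s <= 0 or self.k_d <= 0:
            raise ParameterError("k_s and k_d must be > 0")


def mrna_profile(params: KineticParams, t):
    """Expected transcript abundance M(t).

    M(t) = baseline * (1 + (fold_response - 1) * s(t)) with
    s(t) = 1 - exp(-max(0, t - t_on) / tau_m): continuous, flat before onset,
    saturating at baseline * fold_response.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    s = -np.expm1(-np.maximum(0.0, t - params.t_on) / params.tau_m)
    return params.baseline_mrna * (1.0 + (params.fold_response - 1.0) * s)


def protein_profile(params: KineticParams, t):
    """Expected protein abundance P(t) under dP/dt = k_s M(t) - k_d P.

    Initialized at the pre-stimulation steady state P(0) = k_s M(0) / k_d and
    evaluated with the piecewise closed form of the linear ODE (stable in the
    k_d -> 1/tau_m degenerate limit via the expm1 formulation).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    B, F = params.baseline_mrna, params.fold_response
    k_s, k_d, a = params.k_s, params.k_d, 1.0 / params.tau_m
    p0 = k_s * B / k_d
    tau = np.maximum(0.0, t - params.t_on)
    # convolution of e^{-a s} with the k_d filter: (e^{-a tau}-e^{-k_d tau})/(k_d-a)
    d = (k_d - a) * tau
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(np.abs(d) < 1e-12, 1.0, np.expm1(d) / np.where(d == 0, 1.0, d))
    h = np.exp(-k_d * tau) * tau * ratio
    forced = k_s * (B * F * -np.expm1(-k_d * tau) / k_d - B * (F - 1.0) * h)
    return p0 * np.exp(-k_d * tau) + forced


def _half_rise(fun, t0: float, plateau: float, start: float) -> float:
    target = 0.5 * (start + plateau)
    lo, hi = t0, t0 + 1.0
    while abs(fun(hi) - target) > 0 and (fun(hi) - target) * (fun(lo) - target) > 0:
        hi = t0 + 2 * (hi - t0)
        if hi > 1e7:
            raise RuntimeError("half-rise bracket not found")
    return brentq(lambda t: fun(t) - target, lo, hi)


def mrna_half_rise(params: KineticParams) -> float:
    """Time at which M(t) covers half its total change (hours)."""
    if params.fold_response == 1.0:
        raise ParameterError("null feature has no rise")
    plateau = params.baseline_mrna * params.fold_response
    return _half_rise(lambda t: float(mrna_profile(params, t)), params.t_on,
                      plateau, params.baseline_mrna)


def protein_half_rise(params: KineticParams) -> float:
    """Time at which P(t) covers half its total change (hours)."""
    if params.fold_response == 1.0:
        raise ParameterError("null feature has no rise")
    p0 = params.k_s * params.baseline_mrna / params.k_d
    plateau = p0 * params.fold_response
    return _half_rise(lambda t: float(protein_profile(params, t)), params.t_on, plateau, p0)


# ---------------------------------------------------------------------------
# dataset-level simulation
# ---------------------------------------------------------------------------

#: kinetic archetypes planted as soft-clustering ground truth:
#: (onset t_on [h], time constant tau_m [h], direction)
ARCHETYPES = (
    (0.0, 4.0, +1),
    (12.0, 12.0, +1),
    (48.0, 36.0, +1),
    (0.0, 4.0, -1),
    (12.0, 12.0, -1),
    (48.0, 36.0, -1),
)

#: archetype prevalence among responders: the immediate-early wave dominates
#: a receptor-stimulation time course
ARCHETYPE_WEIGHTS = (0.3, 0.1, 0.1, 0.3, 0.1, 0.1)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults mirror the emulated design: 2 subsets x 6 timepoints x 3
    replicates, ~20% of transcripts quantified at the protein level, 10%
    responders with strong induction, <20% protein missingness.
    """

    n_genes: int = 2000
    protein_fraction: float = 0.2
    de_fraction: float = 0.10
    subset_de_fraction: float = 0.025
    n_subsets: int = 2
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    nb_dispersion: float = 0.02
    library_size_mean: float = 1e6
    library_size_cv: float = 0.15
    intensity_cv: float = 0.25
    missing_rate: float = 0.10
    missing_mnar_weight: float = 0.5
    qc_fail_peptide_fraction: float = 0.05
    qc_fail_score_fraction: float = 0.05
    qc_fail_missing_fraction: float = 0.05
    lfc_up_range: tuple[float, float] = (2.5, 5.0)
    k_s_range: tuple[float, float] = (0.05, 0.5)
    k_d_range: tuple[float, float] = (0.002, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if tps != tuple(sorted(tps)) or (self.n_genes and 0.0 not in tps):
            raise ParameterError("timepoints must be sorted ascending and include 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must lie in [0, 1)")
        if self.n_replicates < 2:
            raise ParameterError("n_replicates must be >= 2")
        if not (0.0 <= self.protein_fraction <= 1.0):
            raise ParameterError("protein_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")


@dataclass
class SynthTruth:
    """Generative ground truth: per-feature parameters and expected effects."""

    params: pd.DataFrame            # per gene: kinetics, labels, protein_id
    id_map: pd.DataFrame            # protein_id, gene_id
    mrna_lfc: pd.DataFrame          # genes x timepoints, expected log2fc vs 0 h
    protein_lfc: pd.DataFrame       # proteins x timepoints, expected log2fc vs 0 h
    timepoints: tuple[float, ...]

    @property
    def responder_genes(self) -> list[str]:
        return list(self.params.index[self.params["is_responder"]])

    @property
    def cluster_labels(self) -> pd.Series:
        return self.params["cluster_label"]

    def mrna_de_genes(self, timepoint: float, lfc_threshold: float = 1.5) -> list[str]:
        lfc = self.mrna_lfc[timepoint]
        return list(lfc.index[lfc.abs() > lfc_threshold])


@dataclass
class SimulatedDataset:
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    metadata: pd.DataFrame
    truth: SynthTruth

    @property
    def id_map(self) -> pd.DataFrame:
        return self.truth.id_map


def _empty_dataset(cfg: SimConfig) -> SimulatedDataset:
    empty = pd.DataFrame(index=pd.Index([], name="feature_id"))
    truth = SynthTruth(
        params=pd.DataFrame(index=pd.Index([], name="gene_id")),
        id_map=pd.DataFrame(columns=["protein_id", "gene_id"]),
        mrna_lfc=pd.DataFrame(), protein_lfc=pd.DataFrame(),
        timepoints=tuple(cfg.timepoints),
    )
    meta = pd.DataFrame(columns=["sample_id", "subset", "timepoint_h", "replicate"])
    return SimulatedDataset(ExpressionMatrix(empty.copy(), "mrna"),
                            ExpressionMatrix(empty.copy(), "protein"), meta, truth)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate one coupled mRNA/protein dataset plus its ground truth.

    Deterministic for a fixed config: the same ``cfg.seed`` reproduces the
    matrices bit-exactly.
    """
    if cfg.n_genes == 0:
        return _empty_dataset(cfg)
    rng = np.random.default_rng(cfg.seed)
    tps = np.asarray(cfg.timepoints, dtype=float)
    subsets = ["CD4", "CD8"][: cfg.n_subsets]

    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    n_resp = int(round(cfg.de_fraction * cfg.n_genes))
    n_subset_de = int(round(cfg.subset_de_fraction * cfg.n_genes))

    # relative baselines, rescaled so the expected 0 h library totals library_size_mean
    baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=cfg.n_genes))
    baseline *= cfg.library_size_mean / baseline.sum()

    order = rng.permutation(cfg.n_genes)
    resp_idx = order[:n_resp]
    subset_idx = order[n_resp:n_resp + n_subset_de]

    fold = np.ones(cfg.n_genes)
    t_on = np.zeros(cfg.n_genes)
    tau_m = np.full(cfg.n_genes, 12.0)
    cluster = np.full(cfg.n_genes, -1, dtype=int)
    arche = rng.choice(len(ARCHETYPES), size=n_resp, p=ARCHETYPE_WEIGHTS)
    mag = rng.uniform(*cfg.lfc_up_range, size=n_resp)
    for j, g in enumerate(resp_idx):
        on, tau, sign = ARCHETYPES[arche[j]]
        jitter = rng.uniform(0.8, 1.2, size=2)
        t_on[g] = on * jitter[0]
        tau_m[g] = tau * jitter[1]
        fold[g] = 2.0 ** (sign * mag[j])
        cluster[g] = arche[j]

    subset_effect = np.zeros(cfg.n_genes)  # log2, + = higher in CD4
    if len(subsets) > 1:
        signs = np.where(np.arange(n_subset_de) % 2 == 0, 1.0, -1.0)
        subset_effect[subset_idx] = signs * rng.uniform(2.5, 4.5, size=n_subset_de)

    k_s = np.exp(rng.uniform(*np.log(cfg.k_s_range), size=cfg.n_genes))
    k_d = np.exp(rng.uniform(*np.log(cfg.k_d_range), size=cfg.n_genes))

    # expected profiles on the grid (shared across subsets up to the constant
    # subset multiplier, which cancels in log2fc vs 0 h)
    M = np.empty((cfg.n_genes, len(tps)))
    P = np.empty((cfg.n_genes, len(tps)))
    for g in range(cfg.n_genes):
        p = KineticParams(baseline[g], fold[g], t_on[g], tau_m[g], k_s[g], k_d[g])
        M[g] = mrna_profile(p, tps)
        P[g] = protein_profile(p, tps)

    # proteins: random subset of genes
    n_prot = int(round(cfg.protein_fraction * cfg.n_genes))
    prot_gene_idx = np.sort(rng.choice(cfg.n_genes, size=n_prot, replace=False))
    protein_ids = np.array([f"P{i:05d}" for i in range(n_prot)])

    meta_rows = []
    for subset in subsets:
        for tp in tps:
            for rep in range(1, cfg.n_replicates + 1):
                meta_rows.append((f"{subset}_t{int(tp):03d}_r{rep}", subset, tp, f"r{rep}"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "subset", "timepoint_h", "replicate"])
    n_samples = len(meta)

    subset_mult = 2.0 ** subset_effect  # applied to CD4; CD8 keeps 1
    lib_sigma = np.sqrt(np.log1p(cfg.library_size_cv ** 2))
    lib_factor = rng.lognormal(-0.5 * lib_sigma ** 2, lib_sigma, size=n_samples)

    counts = np.empty((cfg.n_genes, n_samples))
    inv_disp = 1.0 / cfg.nb_dispersion
    for j, row in enumerate(meta.itertuples(index=False)):
        ti = int(np.searchsorted(tps, row.timepoint_h))
        mu = M[:, ti] * lib_factor[j]
        if row.subset == "CD4":
            mu = mu * subset_mult
        mu = np.maximum(mu, 1e-8)
        counts[:, j] = rng.negative_binomial(inv_disp, inv_disp / (inv_disp + mu))

    sigma = np.sqrt(np.log1p(cfg.intensity_cv ** 2))
    intens = np.empty((n_prot, n_samples))
    for j, row in enumerate(meta.itertuples(index=False)):
        ti = int(np.searchsorted(tps, row.timepoint_h))
        mu = P[prot_gene_idx, ti]
        if row.subset == "CD4":
            mu = mu * subset_mult[prot_gene_idx]
        intens[:, j] = rng.lognormal(np.log(mu) - 0.5 * sigma ** 2, sigma)

    # missingness: uniform MCAR share + MNAR share concentrated in the lowest
    # intensity tercile of the dataset; planted QC failures for each filter
    n_fail_pep = int(round(cfg.qc_fail_peptide_fraction * n_prot))
    n_fail_score = int(round(cfg.qc_fail_score_fraction * n_prot))
    n_fail_miss = int(round(cfg.qc_fail_missing_fraction * n_prot))
    prot_order = rng.permutation(n_prot)
    fail_pep = prot_order[:n_fail_pep]
    fail_score = prot_order[n_fail_pep:n_fail_pep + n_fail_score]
    fail_miss = prot_order[n_fail_pep + n_fail_score:n_fail_pep + n_fail_score + n_fail_miss]

    p_miss = np.full(intens.shape, cfg.missing_rate * (1.0 - cfg.missing_mnar_weight))
    if intens.size:
        tercile = np.quantile(intens, 1.0 / 3.0)
        p_miss[intens <= tercile] += 3.0 * cfg.missing_rate * cfg.missing_mnar_weight
    p_miss[fail_miss, :] = 0.35
    missing = rng.random(intens.shape) < p_miss
    intens_obs = np.where(missing, np.nan, intens)

    peptides = 2 + rng.poisson(7.0, size=n_prot)
    peptides[fail_pep] = 1
    scores = rng.uniform(5.0, 20.0, size=n_prot)
    scores[fail_score] = rng.uniform(0.0, 5.0, size=n_fail_score)

    mrna = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature_id"),
                     columns=meta["sample_id"].to_numpy()), "mrna")
    annot = pd.DataFrame(
        {"unique_razor_peptides": peptides, "id_score": np.round(scores, 3)},
        index=pd.Index(protein_ids, name="feature_id"))
    protein = ExpressionMatrix(
        pd.DataFrame(intens_obs, index=pd.Index(protein_ids, name="feature_id"),
                     columns=meta["sample_id"].to_numpy()), "protein", annot)

    protein_of_gene = pd.Series(index=gene_ids, dtype=object)
    protein_of_gene.iloc[prot_gene_idx] = protein_ids
    params = pd.DataFrame({
        "baseline_mrna": baseline, "fold_response": fold, "t_on": t_on,
        "tau_m": tau_m, "k_s": k_s, "k_d": k_d,
        "is_responder": np.isin(np.arange(cfg.n_genes), resp_idx),
        "direction": np.sign(np.log2(fold)).astype(int),
        "cluster_label": cluster,
        "subset_effect_log2": subset_effect,
        "protein_id": protein_of_gene.to_numpy(),
    }, index=pd.Index(gene_ids, name="gene_id"))

    with np.errstate(divide="ignore"):
        mrna_lfc = pd.DataFrame(np.log2(M / M[:, [0]]), index=params.index, columns=tps)
        protein_lfc = pd.DataFrame(np.log2(P[prot_gene_idx] / P[prot_gene_idx][:, [0]]),
                                   index=pd.Index(protein_ids, name="protein_id"), columns=tps)
    id_map = pd.DataFrame({"protein_id": protein_ids, "gene_id": gene_ids[prot_gene_idx]})
    truth = SynthTruth(params, id_map, mrna_lfc, protein_lfc, tuple(tps))
    return SimulatedDataset(mrna, protein, meta, truth)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write the simulated dataset as the pipeline's on-disk input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna_counts.tsv",
        "protein": outdir / "protein_intensities.tsv",
        "metadata": outdir / "metadata.tsv",
        "id_map": outdir / "id_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_matrix(ds.mrna, paths["mrna"])
    write_expression_matrix(ds.protein, paths["protein"])
    ds.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    ds.id_map.to_csv(paths["id_map"], sep="\t", index=False)
    ds.truth.params.to_csv(paths["truth"], sep="\t", na_rep="NA")
    return paths


def gene_sets_from_truth(truth: SynthTruth, n_random: int = 20,
                         random_set_size: int = 50, seed: int = 0) -> GeneSetCollection:
    """Gene sets for exercising enrichment end-to-end: one set per planted
    kinetic archetype plus random decoy sets drawn from all genes."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.params.index)
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for k in sorted(set(truth.cluster_labels) - {-1}):
        members = set(truth.params.index[truth.cluster_labels == k])
        if members:
            sets[f"archetype_{k}"] = members
            desc[f"archetype_{k}"] = f"planted kinetic archetype {k}"
    for i in range(n_random):
        size = min(random_set_size, len(genes))
        sets[f"random_{i}"] = set(rng.choice(genes, size=size, replace=False))
        desc[f"random_{i}"] = "random decoy set"
    return GeneSetCollection(sets, desc)


#: distinct six-point kinetic shapes for planted-recovery tests: sustained
#: immediate, gradual late, and transient responses, up and down
PROFILE_TEMPLATES = np.array([
    [0.0, 1.0, 1.0, 1.0, 1.0, 1.0],     # immediate up, sustained
    [0.0, 0.0, 0.1, 0.3, 0.7, 1.0],     # gradual up, late
    [0.0, 1.0, 0.8, 0.4, 0.1, 0.0],     # transient up
    [0.0, -1.0, -1.0, -1.0, -1.0, -1.0],
    [0.0, 0.0, -0.1, -0.3, -0.7, -1.0],
    [0.0, -1.0, -0.8, -0.4, -0.1, 0.0],
])


def make_archetype_profiles(n_archetypes: int = 6, n_per: int = 100,
                            noise_sd: float = 0.3, scale: float = 3.0,
                            seed: int = 0):
    """Profile matrix with planted kinetic archetypes, for clustering tests.

    Returns ``(X, labels, centers)``: X is (n_archetypes*n_per) x 6 with rows
    = scale * template + N(0, noise_sd) noise, left unstandardized (the
    clustering pipeline standardizes); labels are the planted archetype index.
    """
    if n_archetypes > len(PROFILE_TEMPLATES):
        raise ParameterError(f"at most {len(PROFILE_TEMPLATES)} archetypes available")
    rng = np.random.default_rng(seed)
    centers = scale * PROFILE_TEMPLATES[:n_archetypes]
    X = np.repeat(centers, n_per, axis=0) \
        + rng.normal(0.0, noise_sd, size=(n_archetypes * n_per, centers.shape[1]))
    labels = np.repeat(np.arange(n_archetypes), n_per)
    return X, labels, centers
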