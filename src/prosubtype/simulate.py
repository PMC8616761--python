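"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* single-cell counts for five prostate epithelial lineages (luminal,
  basal, club-like, hillock-like, neuroendocrine) plus stromal
  populations, with planted marker genes;
* sorted-bulk profiles (per-population means with multiplicative
  log-normal noise);
* cluster-level reference profiles and bulk mixtures with known
  Dirichlet mixing proportions;
* per-sample tumor-purity scores;
* an mCRPC-like cohort with serum PSA/PAP values and group-dependent
  progression hazards.

Single-cell counts are negative-binomial (dispersion 0.5 by default,
i.e. var = mu + 0.5 mu^2) with optional dropout zeros; noise on bulk
profiles is multiplicative log-normal parameterized by its coefficient
of variation, which preserves non-negativity.  Every generator is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SignatureMatrix, ValidationError

logger = logging.getLogger("prosubtype")

__all__ = [
    "CellTypeSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "EPITHELIAL_TYPES",
    "STROMAL_TYPES",
    "simulate_reference",
    "simulate_cluster_profiles",
    "simulate_bulk_mixtures",
    "simulate_purity",
    "simulate_planted_clusters",
    "simulate_cohort",
    "simulate_pap_calibration",
    "DEFAULT_COHORT",
]

EPITHELIAL_TYPES = ("luminal", "basal", "club", "hillock", "neuroendocrine")
STROMAL_TYPES = ("fibroblast", "immune")


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell population: marker-gene count and linear fold-change."""

    name: str
    n_markers: int = 20
    fold_change: float = 10.0
    epithelial: bool = True

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValidationError("marker fold-change must be >= 1")
        if self.n_markers < 0:
            raise ValidationError("marker count must be non-negative")


def _default_cell_types() -> list[CellTypeSpec]:
    return [CellTypeSpec(t, epithelial=True) for t in EPITHELIAL_TYPES] + [
        CellTypeSpec(t, epithelial=False) for t in STROMAL_TYPES
    ]


@dataclass
class SimulationConfig:
    """Knobs for the reference / mixture generators.

    Defaults describe the study conditions the pipeline is exercised
    under: 1000 genes, five epithelial and two stromal populations with
    20 planted 10x markers each (plus a shared pan-epithelial block),
    four tumor clusters and 200 bulk mixtures.
    """

    n_genes: int = 1000
    cell_types: list[CellTypeSpec] = field(default_factory=_default_cell_types)
    n_shared_epithelial_markers: int = 30
    n_cells_per_type: int = 150
    n_bulk_reps: int = 3
    n_bulk_samples: int = 200
    n_clusters: int = 4
    mixing_alpha: tuple[float, ...] | None = None  # default: all-ones
    noise_cv: float = 0.1
    dropout_rate: float = 0.2
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total_markers = (
            sum(ct.n_markers for ct in self.cell_types) + self.n_shared_epithelial_markers
        )
        if total_markers > self.n_genes:
            raise ValidationError(
                f"marker genes ({total_markers}) exceed n_genes ({self.n_genes})"
            )
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.mixing_alpha is not None and any(a <= 0 for a in self.mixing_alpha):
            raise ValidationError("mixing_alpha must be strictly positive")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for downstream scoring."""

    true_proportions: pd.DataFrame | None = None  # samples x clusters
    true_labels: pd.Series | None = None  # sample -> subtype label (PEmax rule)
    marker_assignment: dict[str, str] | None = None  # gene -> population
    survival_params: dict | None = None

    def __post_init__(self) -> None:
        if self.true_proportions is not None:
            w = self.true_proportions.to_numpy()
            if (w < 0).any() or np.abs(w.sum(axis=1) - 1).max() > 1e-9:
                raise ValidationError("true proportions must be non-negative and sum to 1")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _lognormal_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Multiplicative log-normal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, ExpressionMatrix, pd.Series, SyntheticTruth]:
    """Generate labeled single-cell counts and sorted-bulk profiles.

    Returns ``(single_cell, cell_labels, sorted_bulk, bulk_labels,
    truth)``.  Marker genes are multiplied by their population's
    fold-change in that population's mean (shared epithelial markers in
    every epithelial population); single-cell counts are
    negative-binomial draws around the type means with dropout zeros,
    and sorted-bulk columns are the type means with log-normal noise.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    types = config.cell_types
    base = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)

    # disjoint marker blocks: shared pan-epithelial block first, then per type
    marker_assignment: dict[str, str] = {}
    cursor = 0
    shared = genes[cursor : cursor + config.n_shared_epithelial_markers]
    cursor += config.n_shared_epithelial_markers
    for g in shared:
        marker_assignment[g] = "all_epithelia"
    per_type: dict[str, list[str]] = {}
    for ct in types:
        block = genes[cursor : cursor + ct.n_markers]
        cursor += ct.n_markers
        per_type[ct.name] = block
        for g in block:
            marker_assignment[g] = ct.name

    # per-type mean profiles
    means = {}
    shared_fold = max((ct.fold_change for ct in types if ct.epithelial), default=1.0)
    for ct in types:
        mu = base.copy()
        idx = [genes.index(g) for g in per_type[ct.name]]
        mu[idx] *= ct.fold_change
        if ct.epithelial and shared:
            sidx = [genes.index(g) for g in shared]
            mu[sidx] *= shared_fold
        means[ct.name] = mu

    # single-cell counts
    sc_cols, sc_labels = [], []
    for ct in types:
        mu = means[ct.name]
        counts = _nb_counts(rng, np.tile(mu[:, None], (1, config.n_cells_per_type)), config.nb_dispersion)
        if config.dropout_rate > 0:
            keep = rng.random(counts.shape) >= config.dropout_rate
            counts = counts * keep
        sc_cols.append(counts)
        sc_labels.extend([ct.name] * config.n_cells_per_type)
    sc_ids = [f"cell{i:05d}" for i in range(len(sc_labels))]
    sc = ExpressionMatrix(
        pd.DataFrame(np.hstack(sc_cols).astype(float), index=genes, columns=sc_ids)
    )
    cell_labels = pd.Series(sc_labels, index=sc_ids, name="cell_type")

    # sorted-bulk profiles: per-type means with log-normal noise
    bulk_cols, bulk_labels, bulk_ids = [], [], []
    for ct in types:
        for r in range(config.n_bulk_reps):
            noise = _lognormal_noise(rng, config.n_genes, config.noise_cv)
            bulk_cols.append(means[ct.name] * noise)
            bulk_labels.append(ct.name)
            bulk_ids.append(f"{ct.name}_rep{r}")
    bulk = ExpressionMatrix(pd.DataFrame(np.column_stack(bulk_cols), index=genes, columns=bulk_ids))
    bulk_labels = pd.Series(bulk_labels, index=bulk_ids, name="group")

    truth = SyntheticTruth(marker_assignment=marker_assignment)
    return sc, cell_labels, bulk, bulk_labels, truth


def simulate_cluster_profiles(
    n_genes: int = 300,
    n_clusters: int = 4,
    markers_per_cluster: int = 30,
    fold_change: float = 8.0,
    seed: int = 0,
) -> SignatureMatrix:
    """Generate tumor-cluster mean profiles usable as a deconvolution design.

    Clusters share a common log-normal baseline; each has a disjoint
    block of ``markers_per_cluster`` genes elevated ``fold_change``-fold.
    Cluster names are letters A, B, C, ...
    """
    if markers_per_cluster * n_clusters > n_genes:
        raise ValidationError("marker genes exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    names = [chr(ord("A") + i) for i in range(n_clusters)]
    cols = {}
    for i, name in enumerate(names):
        mu = base * _lognormal_noise(rng, n_genes, 0.2)
        idx = slice(i * markers_per_cluster, (i + 1) * markers_per_cluster)
        mu[idx] = mu[idx] * fold_change
        cols[name] = mu
    return SignatureMatrix(pd.DataFrame(cols, index=genes))


def simulate_bulk_mixtures(
    signature: SignatureMatrix,
    config: SimulationConfig,
    weights: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Mix signature columns with Dirichlet weights and log-normal noise.

    Each bulk sample is ``signature @ w`` with ``w ~
    Dirichlet(mixing_alpha)`` (or the explicitly supplied ``weights``,
    one row per sample), then multiplied by gene-wise log-normal noise
    with CV ``noise_cv``.  The truth records the weights and the
    PEmax-rule label (argmax cluster if wmax > 0.5, else "mixed").
    """
    rng = np.random.default_rng(config.seed)
    clusters = signature.cluster_names
    alpha = config.mixing_alpha or tuple(1.0 for _ in clusters)
    if len(alpha) != len(clusters):
        raise ValidationError("mixing_alpha length must match cluster count")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(clusters):
            raise ValidationError("weights must be (n_samples, n_clusters)")
        if (w < 0).any() or np.abs(w.sum(axis=1) - 1).max() > 1e-9:
            raise ValidationError("weights rows must be non-negative and sum to 1")
        n = w.shape[0]
    else:
        n = config.n_bulk_samples
        w = rng.dirichlet(alpha, size=n)
    S = signature.data.to_numpy()
    mixed = S @ w.T
    mixed = mixed * _lognormal_noise(rng, mixed.shape, config.noise_cv)
    ids = [f"bulk{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(mixed, index=signature.gene_ids, columns=ids))
    props = pd.DataFrame(w, index=ids, columns=clusters)
    labels = pd.Series(
        np.where(w.max(axis=1) > 0.5, props.idxmax(axis=1), "mixed"), index=ids
    )
    truth = SyntheticTruth(true_proportions=props, true_labels=labels)
    return expr, truth


def simulate_purity(
    sample_ids,
    pure_fraction: float = 0.5,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Four purity scores per sample (dna_1, dna_2, rna_1, rna_2).

    A ``pure_fraction`` of samples draw all scores from U(0.6, 0.95)
    (passing the >0.5 gate), the rest include at least one score below
    0.5; each score is independently missing with ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    cols = ["dna_1", "dna_2", "rna_1", "rna_2"]
    pure = rng.random(n) < pure_fraction
    vals = rng.uniform(0.6, 0.95, size=(n, 4))
    low = rng.uniform(0.1, 0.5, size=(n, 4))
    which_low = rng.integers(0, 4, size=n)
    for i in range(n):
        if not pure[i]:
            vals[i, which_low[i]] = low[i, which_low[i]]
    miss = rng.random((n, 4)) < missing_rate
    vals[miss] = np.nan
    return pd.DataFrame(vals, index=list(sample_ids), columns=cols)


def simulate_planted_clusters(
    n_samples: int = 40,
    n_genes: int = 50,
    k: int = 4,
    separation_sd: float = 5.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Gaussian blobs with centers ``separation_sd`` noise-SDs apart.

    Separation is measured against the norm of the isotropic unit noise
    (sqrt(n_genes)), i.e. the minimum pairwise center distance equals
    ``separation_sd`` times the SD of a point's Euclidean deviation from
    its center, so blob distance dominates noise at separation >= ~3.
    Emits a log2-scale matrix (values may be negative) with balanced
    cluster sizes, for planted-partition recovery tests of the
    consensus-clustering stage.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(k, n_genes))
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    min_d = d[np.triu_indices(k, 1)].min()
    centers *= separation_sd * np.sqrt(n_genes) / min_d
    labels = np.repeat(np.arange(k), int(np.ceil(n_samples / k)))[:n_samples]
    X = centers[labels] + rng.normal(size=(n_samples, n_genes))
    ids = [f"s{i:03d}" for i in range(n_samples)]
    expr = ExpressionMatrix(
        pd.DataFrame(X.T, index=_gene_ids(n_genes), columns=ids), scale="log2"
    )
    return expr, pd.Series(labels, index=ids, name="true_cluster")


# mCRPC-like docetaxel cohort: two serum phenotypes (PSA-high vs PAP-high),
# group sizes and survival medians matching a 30-patient docetaxel cohort
# split 11/19 at PSA/PAP ratio 20.  Serum values in ng/mL.
DEFAULT_COHORT = {
    "group_fracs": {"psa_high": 11 / 30, "pap_high": 19 / 30},
    "survival_params": {"psa_high": {"median_days": 91.0}, "pap_high": {"median_days": 210.0}},
    "os_params": {"psa_high": {"median_days": 309.0}, "pap_high": {"median_days": 551.0}},
    "serum_params": {
        "psa_high": {"psa_median": 120.0, "pap_median": 1.5, "sigma": 0.3},
        "pap_high": {"psa_median": 20.0, "pap_median": 5.0, "sigma": 0.3},
    },
}


def simulate_cohort(
    n_patients: int,
    group_fracs: dict[str, float],
    survival_params: dict[str, dict],
    serum_params: dict[str, dict],
    seed: int = 0,
    censor_rate: float = 0.1,
) -> pd.DataFrame:
    """Simulate a serum-marker survival cohort.

    Event times are exponential with group rate ln2 / median_days.  A
    ``censor_rate`` fraction of patients (Bernoulli) are censored at a
    uniform fraction of their event time.  PSA and PAP are log-normal
    per group (log-scale SD ``sigma``) so the PSA/PAP ratio separates
    the groups.  Group sizes are deterministic (largest remainder), so
    a cohort of 30 with fractions 11/30 and 19/30 always splits 11/19.
    """
    if abs(sum(group_fracs.values()) - 1.0) > 1e-9:
        raise ValidationError("group fractions must sum to 1")
    if not (0.0 <= censor_rate <= 1.0):
        raise ValidationError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(group_fracs)
    # largest-remainder apportionment of group sizes
    quotas = {g: group_fracs[g] * n_patients for g in names}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    rem = n_patients - sum(counts.values())
    for g in sorted(names, key=lambda g: quotas[g] - counts[g], reverse=True)[:rem]:
        counts[g] += 1

    rows = []
    pid = 0
    for g in names:
        rate = np.log(2) / survival_params[g]["median_days"]
        sp = serum_params[g]
        for _ in range(counts[g]):
            t_event = rng.exponential(1.0 / rate)
            censored = rng.random() < censor_rate
            time = t_event * rng.random() if censored else t_event
            psa = np.exp(np.log(sp["psa_median"]) + sp["sigma"] * rng.standard_normal())
            pap = np.exp(np.log(sp["pap_median"]) + sp["sigma"] * rng.standard_normal())
            rows.append(
                {
                    "patient_id": f"P{pid:05d}",
                    "group": g,
                    "psa": psa,
                    "pap": pap,
                    "pap_assay": "immulite_ngml",
                    "time_days": time,
                    "event": not censored,
                }
            )
            pid += 1
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def simulate_pap_calibration(
    n_pairs: int = 975,
    slope: float = 0.35,
    intercept: float = 0.2,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired PAP measurements (U/L vs ng/mL) on a noisy linear relation."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(1.0, 60.0, size=n_pairs)  # U/L
    y = np.clip(slope * x + intercept + rng.normal(0, noise_sd, size=n_pairs), 0, None)
    return pd.DataFrame({"pap_UL": x, "pap_ngml": y})
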