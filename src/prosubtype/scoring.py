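"""Single-sample gene-set enrichment and drug-sensitivity scores.

The ssGSEA score ranks a sample's genes by decreasing expression and
integrates a weighted running sum: in-set genes step up by their rank
statistic raised to the weighting exponent (normalized over in-set
genes), out-of-set genes step down by 1/(N - m).  The score is the sum
of the running-sum values over all positions, scaled by 1/N.  At weight
0 the score depends only on ranks, so any strictly monotone transform
of expression leaves it unchanged, and a set and its complement score
to exactly opposite values.

The docetaxel responder score subtracts the ssGSEA score of the
under-expressed responder gene set from that of the over-expressed set,
then z-normalizes the difference across samples.  A correlation-derived
set (Pearson r strictly above a threshold against a drug-sensitivity
vector) supports the paclitaxel-style construction.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    GeneSet,
    ScorePanel,
    SubtypeCall,
    ValidationError,
)

logger = logging.getLogger("prosubtype")

__all__ = [
    "ssgsea",
    "ssgsea_panel",
    "z_normalize",
    "docetaxel_score",
    "build_correlation_set",
    "score_pe_correlation",
    "groupwise_score_test",
]

DEFAULT_WEIGHT = 0.75


def ssgsea(sample_values: pd.Series, gene_set: GeneSet, weight: float = DEFAULT_WEIGHT) -> float:
    """Weighted running-sum enrichment of one gene set in one sample.

    Genes are ordered by decreasing expression (ties broken by gene ID
    for determinism); the rank statistic of the gene at position j
    (1-based) is N - j + 1.
    """
    values = sample_values.dropna()
    N = len(values)
    in_set = values.index.isin(gene_set.genes)
    m = int(in_set.sum())
    if m == 0:
        raise ValidationError(f"no gene of set {gene_set.name!r} present in sample")
    if m == N:
        raise ValidationError(f"set {gene_set.name!r} covers the whole gene universe")

    # stable decreasing sort; equal values keep gene-ID order
    values = values.sort_index()
    order = values.sort_values(ascending=False, kind="mergesort")
    in_set = order.index.isin(gene_set.genes)

    rank_stat = np.arange(N, 0, -1, dtype=float)
    w = np.abs(rank_stat) ** weight
    steps = np.where(in_set, w / w[in_set].sum(), -1.0 / (N - m))
    running = np.cumsum(steps)
    return float(running.sum() / N)


def ssgsea_panel(
    expr: ExpressionMatrix, gene_sets: Sequence[GeneSet], weight: float = DEFAULT_WEIGHT
) -> ScorePanel:
    """ssGSEA of every set in every sample, z-normalized across samples."""
    raw = pd.DataFrame(
        {
            gs.name: [ssgsea(expr.data[s], gs, weight) for s in expr.sample_ids]
            for gs in gene_sets
        },
        index=expr.sample_ids,
    )
    return ScorePanel(raw_scores=raw, scores=z_normalize(raw))


def z_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (sample SD, ddof=1); constant columns -> NaN."""
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        logger.warning("z-normalization: %d constant score column(s)", int(const.sum()))
    return (df - mu) / sd.replace(0, np.nan)


def docetaxel_score(
    expr: ExpressionMatrix,
    up_set: GeneSet,
    down_set: GeneSet,
    weight: float = DEFAULT_WEIGHT,
) -> ScorePanel:
    """Responder score: ssGSEA(up) - ssGSEA(down), z-normalized across samples."""
    if up_set.genes & down_set.genes:
        raise ValidationError("up and down gene sets must be disjoint")
    raw = pd.Series(
        [
            ssgsea(expr.data[s], up_set, weight) - ssgsea(expr.data[s], down_set, weight)
            for s in expr.sample_ids
        ],
        index=expr.sample_ids,
    )
    raw_df = raw.to_frame("docetaxel_responder")
    return ScorePanel(raw_scores=raw_df, scores=z_normalize(raw_df))


def build_correlation_set(
    expr: ExpressionMatrix,
    sensitivity: pd.Series,
    r_threshold: float = 0.3,
    name: str = "drug_sensitivity_corr",
) -> GeneSet:
    """Genes whose expression correlates with drug sensitivity (Pearson r
    strictly above ``r_threshold``); zero-variance genes are skipped."""
    sens = sensitivity.reindex(expr.sample_ids)
    if sens.isna().any() or not np.isfinite(sens).all():
        raise ValidationError("sensitivity must be finite for every sample")
    if expr.n_samples < 3:
        raise ValidationError("need >=3 samples for correlations")
    X = expr.data.to_numpy(dtype=float)
    s = sens.to_numpy(dtype=float)
    s_c = s - s.mean()
    s_norm = np.sqrt((s_c**2).sum())
    X_c = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((X_c**2).sum(axis=1))
    skip = (x_norm == 0) | (s_norm == 0)
    if skip.any():
        logger.warning("skipping %d zero-variance genes in correlation set", int(skip.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X_c @ s_c) / (x_norm * s_norm)
    genes = [g for g, ri, sk in zip(expr.gene_ids, r, skip) if not sk and ri > r_threshold]
    if not genes:
        raise ValidationError(f"no gene passed r > {r_threshold}")
    return GeneSet(name=name, genes=frozenset(genes), direction="up")


def score_pe_correlation(
    panel: ScorePanel, calls: Sequence[SubtypeCall]
) -> pd.DataFrame:
    """Spearman correlation of each score against each cluster's PE.

    Returns a table (score, cluster, spearman_r, p_two_tailed) over the
    samples shared between the panel and the calls (>= 5 required).
    Constant scores give missing correlations with a warning.
    """
    pe = pd.DataFrame({c.sample_id: c.pe for c in calls}).T
    shared = [s for s in panel.scores.index if s in pe.index]
    if len(shared) < 5:
        raise ValidationError(f"only {len(shared)} shared samples, need >=5")
    rows = []
    for score in panel.scores.columns:
        x = panel.scores.loc[shared, score]
        for cluster in pe.columns:
            y = pe.loc[shared, cluster]
            if x.nunique() <= 1 or y.nunique() <= 1:
                logger.warning("constant values for %s vs %s; correlation undefined", score, cluster)
                r, p = np.nan, np.nan
            else:
                res = stats.spearmanr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            rows.append({"score": score, "cluster": cluster, "spearman_r": r, "p_two_tailed": p})
    return pd.DataFrame(rows)


def groupwise_score_test(scores: pd.Series, labels: pd.Series) -> dict:
    """Kruskal-Wallis omnibus plus Dunn's pairwise z-tests (Bonferroni).

    Returns ``{"kruskal_p": float, "pairwise": DataFrame}`` with columns
    group_a, group_b, z, p_raw, p_adj.  All-identical data gives p = 1
    by convention.
    """
    labels = labels.reindex(scores.index).dropna()
    scores = scores.loc[labels.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("need >=2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} has <2 samples")
    parts = [scores[labels == g].to_numpy() for g in groups]
    if scores.nunique() == 1:
        kw_p = 1.0
    else:
        kw_p = float(stats.kruskal(*parts).pvalue)

    # Dunn's test on pooled mid-ranks with tie correction
    pooled = scores.to_numpy(dtype=float)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    rank_means = {g: ranks[(labels == g).to_numpy()].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        se2 = var_base * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se2 <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (rank_means[a] - rank_means[b]) / np.sqrt(se2)
            p_raw = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * len(pairs)),
            }
        )
    return {"kruskal_p": kw_p, "pairwise": pd.DataFrame(rows)}
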