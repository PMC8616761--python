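"""Prostate epithelial-expressed marker-gene selection.

Two complementary routes feed the marker list:

* labeled single-cell data — per-population overexpression calls by
  two-sided Wilcoxon rank-sum (population vs. all remaining cells) with
  Benjamini-Hochberg adjustment and a linear fold-change threshold;
* sorted-bulk data — a strict greater-than-5-fold mean-ratio rule,
  either all epithelial groups vs. stroma ("all_epithelia") or one
  epithelial group vs. the remaining epithelial groups.

The two lists are merged by gene-ID union, optionally mapped through a
user-supplied symbol-to-ID map (unmapped genes dropped with a logged
count).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MarkerResult, ValidationError

logger = logging.getLogger("prosubtype")

__all__ = ["sc_overexpressed", "bulk_fold_rule", "merge_marker_lists"]

#: pseudocount (FPKM-like units) added to group means before ratios, so
#: zero-expression genes yield bounded fold changes
DEFAULT_PSEUDOCOUNT = 0.01


def sc_overexpressed(
    sc: ExpressionMatrix,
    labels: pd.Series,
    target_populations: Sequence[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MarkerResult]:
    """Per-population overexpressed genes from labeled single-cell data.

    For each target population, a gene is called when the two-sided
    rank-sum test (population vs. all remaining cells) passes BH-adjusted
    p < ``alpha``, the linear mean fold-change exceeds ``fc_threshold``,
    and the population mean exceeds the rest mean.
    """
    labels = labels.reindex(sc.sample_ids)
    if labels.isna().any():
        raise ValidationError("every cell must be labeled")
    results: list[MarkerResult] = []
    X = sc.data.to_numpy(dtype=float)
    for pop in target_populations:
        mask = (labels == pop).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"population {pop!r} absent from labels")
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValidationError(f"population {pop!r} needs >=2 cells on each side")
        in_pop = X[:, mask]
        out_pop = X[:, ~mask]
        res = stats.mannwhitneyu(in_pop, out_pop, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals = np.nan_to_num(pvals, nan=1.0)  # constant genes: no evidence
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        mean_in = in_pop.mean(axis=1)
        mean_out = out_pop.mean(axis=1)
        fc = (mean_in + pseudocount) / (mean_out + pseudocount)
        sel = (p_adj < alpha) & (fc > fc_threshold) & (mean_in > mean_out)
        for i in np.flatnonzero(sel):
            results.append(
                MarkerResult(
                    gene_id=sc.gene_ids[i],
                    source="single_cell",
                    population=pop,
                    fold_change=float(fc[i]),
                    p_adj=float(p_adj[i]),
                )
            )
    return results


def bulk_fold_rule(
    bulk: ExpressionMatrix,
    group_labels: pd.Series,
    epithelial_groups: Sequence[str],
    stromal_groups: Sequence[str],
    fold: float = 5.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MarkerResult]:
    """Strictly-more-than-``fold`` mean-ratio rule on sorted-bulk data.

    A gene is selected when mean(all epithelia) / mean(stroma) > fold
    (tagged "all_epithelia"), or when mean(one epithelial group) /
    mean(remaining epithelial groups) > fold (tagged with that group).
    Ratios use linear-scale means with a pseudocount; exact equality
    with ``fold`` is excluded.
    """
    group_labels = group_labels.reindex(bulk.sample_ids)
    if group_labels.isna().any():
        raise ValidationError("every bulk sample must have a group label")
    if not epithelial_groups or not stromal_groups:
        raise ValidationError("need >=1 epithelial and >=1 stromal group")
    for g in list(epithelial_groups) + list(stromal_groups):
        if g not in set(group_labels):
            raise ValidationError(f"group {g!r} absent from labels")

    X = bulk.data
    epi_mask = group_labels.isin(epithelial_groups).to_numpy()
    stroma_mask = group_labels.isin(stromal_groups).to_numpy()
    mean_epi = X.to_numpy()[:, epi_mask].mean(axis=1)
    mean_stroma = X.to_numpy()[:, stroma_mask].mean(axis=1)

    results: list[MarkerResult] = []
    ratio_all = (mean_epi + pseudocount) / (mean_stroma + pseudocount)
    for i in np.flatnonzero(ratio_all > fold):
        results.append(
            MarkerResult(
                gene_id=bulk.gene_ids[i],
                source="bulk",
                population="all_epithelia",
                fold_change=float(ratio_all[i]),
            )
        )
    for g in epithelial_groups:
        own = (group_labels == g).to_numpy()
        rest = epi_mask & ~own
        if rest.sum() == 0:
            continue
        m_own = X.to_numpy()[:, own].mean(axis=1)
        m_rest = X.to_numpy()[:, rest].mean(axis=1)
        ratio = (m_own + pseudocount) / (m_rest + pseudocount)
        for i in np.flatnonzero(ratio > fold):
            results.append(
                MarkerResult(
                    gene_id=bulk.gene_ids[i],
                    source="bulk",
                    population=g,
                    fold_change=float(ratio[i]),
                )
            )
    return results


def merge_marker_lists(
    a: Iterable[MarkerResult],
    b: Iterable[MarkerResult],
    id_map: Mapping[str, str] | None = None,
) -> list[MarkerResult]:
    """Union the two marker lists at the gene level.

    Genes present in both lists are tagged ``source='both'`` (keeping
    the first list's population and statistics).  With an ``id_map``,
    gene symbols are translated and unmapped genes are dropped with a
    logged count.  Returns one entry per gene, ordered by first
    appearance.
    """
    a, b = list(a), list(b)
    if not a and not b:
        logger.warning("both marker lists are empty")
        return []

    def _mapped(res: MarkerResult) -> MarkerResult | None:
        if id_map is None:
            return res
        gid = id_map.get(res.gene_id)
        if gid is None:
            return None
        return MarkerResult(gid, res.source, res.population, res.fold_change, res.p_adj)

    merged: dict[str, MarkerResult] = {}
    dropped = 0
    genes_a, genes_b = set(), set()
    for source, items in (("a", a), ("b", b)):
        for res in items:
            m = _mapped(res)
            if m is None:
                dropped += 1
                continue
            (genes_a if source == "a" else genes_b).add(m.gene_id)
            if m.gene_id not in merged:
                merged[m.gene_id] = m
    if dropped:
        logger.warning("dropped %d marker genes absent from the ID map", dropped)
    out = []
    for gid, res in merged.items():
        if gid in genes_a and gid in genes_b:
            res = MarkerResult(gid, "both", res.population, res.fold_change, res.p_adj)
        out.append(res)
    return out
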