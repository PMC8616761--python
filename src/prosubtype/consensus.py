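"""Purity gating and resampling consensus clustering with PAC model selection.

Samples first pass a tumor-purity gate: a sample is kept only when at
least one DNA-based and one RNA-based purity score are available and
every available score exceeds the threshold (default 0.5, strict).

Consensus clustering follows the subsampling scheme of Monti et al.:
genes are row-standardized once, then for each candidate k the samples
are repeatedly subsampled (80% without replacement) and partitioned by
the base clusterer; the consensus matrix is the fraction of subsamples
in which two samples co-cluster, among those where both were drawn.
The number of clusters is chosen by the minimal proportion of
ambiguously clustered pairs (PAC: consensus values strictly inside an
intermediate band, default (0.1, 0.9)); ties go to the smaller k.  The
final assignment cuts an average-linkage tree on 1 - consensus at the
chosen k.

The default base clusterer is k-means with a single k-means++
initialization per subsample (so resampling variability, not restarts,
drives the consensus signal); a one-dimensional self-organizing map is
available as an alternative.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .containers import ConsensusResult, ExpressionMatrix, ValidationError

logger = logging.getLogger("prosubtype")

__all__ = ["purity_gate", "consensus_cluster", "pac"]

_DNA_COLS = ("dna_1", "dna_2")
_RNA_COLS = ("rna_1", "rna_2")


def purity_gate(
    samples: Sequence[str], purity: pd.DataFrame, threshold: float = 0.5
) -> list[str]:
    """Keep samples whose every available purity score is > threshold.

    ``purity`` is indexed by sample with columns among dna_1, dna_2,
    rna_1, rna_2 (NaN = missing).  A sample must have at least one DNA
    and one RNA score available; samples missing from the table are
    dropped.  Order of the input is preserved.
    """
    kept = []
    for s in samples:
        if s not in purity.index:
            continue
        row = purity.loc[s]
        dna = row[[c for c in _DNA_COLS if c in purity.columns]].dropna()
        rna = row[[c for c in _RNA_COLS if c in purity.columns]].dropna()
        if len(dna) == 0 or len(rna) == 0:
            continue
        avail = pd.concat([dna, rna])
        if (avail > threshold).all():
            kept.append(s)
    return kept


def pac(consensus_matrix: np.ndarray | pd.DataFrame, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs.

    The fraction of off-diagonal upper-triangle consensus entries
    strictly between ``u1`` and ``u2``.
    """
    M = np.asarray(consensus_matrix, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValidationError("PAC needs >=2 samples")
    vals = M[np.triu_indices(n, k=1)]
    return float(np.mean((vals > u1) & (vals < u2)))


def _som_labels(points: np.ndarray, k: int, rng: np.random.Generator, iters: int = 2000) -> np.ndarray:
    """1 x k self-organizing map with Gaussian neighborhood, then nearest-node labels."""
    n = len(points)
    codes = points[rng.choice(n, size=k, replace=False)].astype(float).copy()
    grid = np.arange(k)
    sigma0, sigma1 = max(k / 2.0, 1.0), 0.5
    lr0, lr1 = 0.5, 0.01
    for t in range(iters):
        frac = t / max(iters - 1, 1)
        lr = lr0 * (lr1 / lr0) ** frac
        sigma = sigma0 * (sigma1 / sigma0) ** frac
        x = points[rng.integers(n)]
        bmu = int(np.argmin(((codes - x) ** 2).sum(axis=1)))
        infl = np.exp(-((grid - bmu) ** 2) / (2 * sigma**2))
        codes += lr * infl[:, None] * (x - codes)
    d = ((points[:, None, :] - codes[None, :, :]) ** 2).sum(axis=-1)
    return d.argmin(axis=1)


def _cluster_letters(raw: np.ndarray) -> list[str]:
    order: dict[int, str] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = chr(ord("A") + len(order))
    return [order[lab] for lab in raw]


def consensus_cluster(
    expr: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    kmax: int = 15,
    iterations: int = 20,
    subsample: float = 0.80,
    seed: int = 0,
    base: str = "kmeans",
    u1: float = 0.1,
    u2: float = 0.9,
) -> ConsensusResult:
    """Resampling consensus clustering over k = 2..kmax.

    Rows (genes) are standardized to mean 0 / SD 1 once, before any
    resampling; zero-variance genes are excluded with a warning.
    Sample pairs never drawn together get consensus 0 with a warning.
    """
    if genes is None:
        genes = expr.gene_ids
    X = expr.data.loc[list(genes)]
    n = X.shape[1]
    if n < kmax + 1:
        raise ValidationError(f"need >= kmax+1 = {kmax + 1} samples, got {n}")

    sd = X.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("excluding %d zero-variance genes from standardization", int(zero_var.sum()))
        X = X.loc[~zero_var]
        sd = sd[~zero_var]
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    points = Z.to_numpy().T  # samples x genes

    sub_n = int(np.floor(subsample * n))
    sample_ids = list(X.columns)
    k_range = list(range(2, kmax + 1))
    consensus: dict[int, pd.DataFrame] = {}
    cosample: dict[int, np.ndarray] = {}
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    pac_by_k: dict[int, float] = {}

    for k in k_range:
        co = np.zeros((n, n))
        drawn = np.zeros((n, n))
        for it in range(iterations):
            ss = np.random.SeedSequence([seed, k, it])
            rng = np.random.default_rng(ss)
            idx = rng.choice(n, size=sub_n, replace=False)
            sub = points[idx]
            if base == "kmeans":
                km = KMeans(
                    n_clusters=k,
                    n_init=1,
                    init="k-means++",
                    random_state=int(rng.integers(2**31)),
                )
                labels = km.fit_predict(sub)
            elif base == "som":
                labels = _som_labels(sub, k, rng)
            else:
                raise ValueError(f"unknown base clusterer {base!r}")
            same = labels[:, None] == labels[None, :]
            co[np.ix_(idx, idx)] += same
            drawn[np.ix_(idx, idx)] += 1
        never = drawn == 0
        np.fill_diagonal(never, False)
        if never.any():
            logger.warning(
                "k=%d: %d sample pairs never co-sampled; consensus set to 0",
                k,
                int(never.sum() // 2),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(drawn > 0, co / np.maximum(drawn, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        consensus[k] = pd.DataFrame(M, index=sample_ids, columns=sample_ids)
        cosample[k] = drawn
        vals = np.sort(M[np.triu_indices(n, k=1)])
        grid = np.concatenate([[0.0], vals, [1.0]])
        ecdf = np.searchsorted(vals, grid, side="right") / len(vals)
        cdf[k] = (grid, ecdf)
        pac_by_k[k] = pac(M, u1=u1, u2=u2)

    chosen_k = min(k_range, key=lambda k: (pac_by_k[k], k))

    D = 1.0 - consensus[chosen_k].to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    tree = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(tree, t=chosen_k, criterion="maxclust")
    if len(np.unique(raw)) < chosen_k:
        logger.warning(
            "average-linkage cut produced %d < chosen_k=%d clusters (degenerate consensus)",
            len(np.unique(raw)),
            chosen_k,
        )
    assignment = pd.Series(_cluster_letters(raw), index=sample_ids, name="cluster")

    return ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        cosample_counts=cosample,
        cdf=cdf,
        pac=pac_by_k,
        chosen_k=chosen_k,
        assignment=assignment,
    )
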