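"""Signature-matrix construction and nu-SVR proportion-estimate deconvolution.

The signature matrix holds, per reference cluster, the mean linear-scale
expression of the cluster-discriminating genes (Kruskal-Wallis q < 0.05
across clusters, restricted to the epithelial marker universe).  Each
bulk sample is then regressed on the signature columns with linear-kernel
nu-support-vector regression over a small nu grid, the best nu chosen by
root-mean-square fit error; negative coefficients are clipped at zero
and the remainder renormalized into a proportion-estimate (PE) vector.
Significance comes from a gene-permutation null on the fit correlation.

The subtype call applies the PEmax rule: a significant sample is labeled
with its argmax cluster when PEmax > 0.5, "mixed" when PEmax <= 0.5, and
"unclassified" when the permutation p-value is not significant.

A non-negative least-squares backend (`nnls_proportions`) is provided as
an independent cross-check for the SVR route.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from sklearn.svm import NuSVR
from statsmodels.stats.multitest import multipletests

from .containers import (
    ExpressionMatrix,
    SignatureMatrix,
    SubtypeCall,
    ValidationError,
)

logger = logging.getLogger("prosubtype")

__all__ = [
    "select_cluster_degs",
    "build_signature",
    "classify_pe",
    "deconvolve_sample",
    "deconvolve_matrix",
    "nnls_proportions",
]

NU_GRID = (0.25, 0.5, 0.75)


def select_cluster_degs(
    expr: ExpressionMatrix,
    assignment: pd.Series,
    genes: Sequence[str] | None = None,
    q_threshold: float = 0.05,
) -> list[str]:
    """Genes differing across clusters (Kruskal-Wallis, BH q < threshold).

    ``genes`` restricts the tested universe (e.g. the epithelial marker
    list); every cluster needs >= 2 samples.
    """
    assignment = assignment.reindex(expr.sample_ids).dropna()
    clusters = assignment.unique()
    if len(clusters) < 2:
        raise ValidationError("need >=2 clusters")
    for c in clusters:
        if (assignment == c).sum() < 2:
            raise ValidationError(f"cluster {c!r} has <2 samples")
    universe = list(genes) if genes is not None else expr.gene_ids
    X = expr.data.loc[universe, assignment.index]
    groups = [(assignment == c).to_numpy() for c in clusters]
    pvals = np.ones(len(universe))
    for i, row in enumerate(X.to_numpy()):
        parts = [row[g] for g in groups]
        try:
            pvals[i] = stats.kruskal(*parts).pvalue
        except ValueError:  # all values identical
            pvals[i] = 1.0
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return [g for g, qv in zip(universe, q) if qv < q_threshold]


def build_signature(
    expr: ExpressionMatrix, assignment: pd.Series, genes: Sequence[str]
) -> SignatureMatrix:
    """Per-cluster arithmetic mean expression over the given genes.

    All-zero gene rows are dropped with a warning; an empty cluster is
    an error.  Cluster column order follows sorted cluster names.
    """
    assignment = assignment.reindex(expr.sample_ids)
    if assignment.isna().any():
        raise ValidationError("every sample must be assigned to a cluster")
    X = expr.data.loc[list(genes)]
    cols = {}
    for c in sorted(assignment.unique()):
        members = assignment.index[assignment == c]
        if len(members) == 0:
            raise ValidationError(f"cluster {c!r} is empty")
        cols[c] = X[members].mean(axis=1)
    sig = pd.DataFrame(cols)
    zero = sig.sum(axis=1) == 0
    if zero.any():
        logger.warning("dropping %d all-zero gene rows from signature", int(zero.sum()))
        sig = sig.loc[~zero]
    return SignatureMatrix(sig)


def classify_pe(pe: pd.Series, p_value: float, alpha: float = 0.05) -> str:
    """The PEmax subtype rule: pure cluster iff PEmax > 0.5 (strict)."""
    if p_value >= alpha:
        return "unclassified"
    if float(pe.max()) > 0.5:
        return str(pe.idxmax())
    return "mixed"


def _standardize(v: np.ndarray) -> np.ndarray:
    # whole-array z-score: preserves relative column scales of the
    # signature, which the proportion interpretation relies on
    return (v - v.mean()) / v.std()


def deconvolve_sample(
    mixture: pd.Series,
    signature: SignatureMatrix,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> SubtypeCall:
    """Proportion estimates for one bulk sample.

    Genes are intersected pairwise (>= 50% of signature genes must be
    present), mixture and signature are z-scored as whole arrays, and a
    linear nu-SVR is fit for nu in {0.25, 0.5, 0.75}; the best nu by
    RMSE provides the coefficients.  The p-value is the fraction of
    ``n_perm`` gene-permuted mixtures whose fit correlation reaches the
    observed one.
    """
    sig_genes = signature.gene_ids
    present = mixture.dropna()
    common = [g for g in sig_genes if g in present.index]
    if len(common) < 0.5 * len(sig_genes):
        raise ValidationError(
            f"only {len(common)}/{len(sig_genes)} signature genes present in mixture"
        )
    S = signature.data.loc[common].to_numpy(dtype=float)
    y = present.loc[common].to_numpy(dtype=float)
    if S.shape[1] < 2:
        raise ValidationError("need >=2 signature clusters")
    if not y.any():
        raise ValidationError("all-zero mixture")

    Sz = _standardize(S)
    yz = _standardize(y)

    best = None
    for nu in NU_GRID:
        model = NuSVR(nu=nu, kernel="linear", C=1.0)
        model.fit(Sz, yz)
        pred = model.predict(Sz)
        rmse = float(np.sqrt(np.mean((pred - yz) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, nu, model.coef_.ravel().copy(), pred)
    _, best_nu, coef, pred = best

    r_obs = stats.pearsonr(pred, yz).statistic

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(yz)
        m = NuSVR(nu=best_nu, kernel="linear", C=1.0)
        m.fit(Sz, yp)
        r_p = stats.pearsonr(m.predict(Sz), yp).statistic
        if r_p >= r_obs:
            exceed += 1
    p_value = exceed / n_perm

    w = np.clip(coef, 0.0, None)
    if w.sum() == 0:
        logger.warning("sample %s: all SVR coefficients non-positive", mixture.name)
        pe = pd.Series(1.0 / S.shape[1], index=signature.cluster_names)
        return SubtypeCall(str(mixture.name), pe, 1.0, "unclassified")
    pe = pd.Series(w / w.sum(), index=signature.cluster_names)
    label = classify_pe(pe, p_value, alpha=alpha)
    return SubtypeCall(str(mixture.name), pe, p_value, label)


def deconvolve_matrix(
    expr: ExpressionMatrix,
    signature: SignatureMatrix,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[SubtypeCall]:
    """Deconvolve every sample column; per-sample failures are logged."""
    calls: list[SubtypeCall] = []
    base = np.random.SeedSequence(seed)
    children = base.spawn(expr.n_samples)
    for child, sid in zip(children, expr.sample_ids):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            calls.append(
                deconvolve_sample(
                    expr.data[sid], signature, n_perm=n_perm, seed=sub_seed, alpha=alpha
                )
            )
        except ValidationError as exc:
            logger.warning("sample %s failed deconvolution: %s", sid, exc)
    return calls


def nnls_proportions(mixture: pd.Series, signature: SignatureMatrix) -> pd.Series:
    """Non-negative least-squares proportions (independent of the SVR route).

    Uses the same gene intersection and whole-array standardization,
    then solves min ||Sz w - yz|| subject to w >= 0 and renormalizes.
    """
    common = [g for g in signature.gene_ids if g in mixture.dropna().index]
    if len(common) < 0.5 * len(signature.gene_ids):
        raise ValidationError("too few signature genes present in mixture")
    S = signature.data.loc[common].to_numpy(dtype=float)
    y = mixture.loc[common].to_numpy(dtype=float)
    w, _ = nnls(_standardize(S), _standardize(y))
    if w.sum() == 0:
        return pd.Series(1.0 / S.shape[1], index=signature.cluster_names)
    return pd.Series(w / w.sum(), index=signature.cluster_names)
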