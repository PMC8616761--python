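# prosubtype

Molecular subtyping of prostate adenocarcinoma from bulk RNA-seq, built
around the cell-of-origin idea: tumor transcriptomes are interpreted
through genes expressed by normal prostate **epithelial** lineages
(luminal, basal, club-like, hillock-like, neuroendocrine), so that
stromal and immune contamination does not drive the classification.
The package is aimed at computational oncologists who want a tested,
reusable implementation of this style of analysis, exercised end-to-end
on synthetic data with known ground truth.

## What it does

1. **Marker selection** — epithelial-expressed genes from two sources:
   per-population Wilcoxon rank-sum calls (BH-adjusted p < 0.05, linear
   fold change > 2) on labeled single-cell data, and a strict
   greater-than-5-fold mean-ratio rule on sorted-bulk profiles
   (all epithelia vs. stroma, or one epithelial population vs. the
   rest); the lists are merged by gene-ID union.
2. **Subtype discovery** — samples pass a tumor-purity gate (every
   available DNA and RNA purity score strictly above 0.5), then
   resampling consensus clustering over the marker genes
   (row-standardized, 80% sample subsampling, Euclidean k-means or
   1-D SOM base clusterer, average-linkage merge).  The cluster number
   k minimizes the **PAC** — the proportion of consensus values
   strictly inside (0.1, 0.9).
3. **Deconvolution** — the signature matrix S (genes × clusters) holds
   mean cluster expression of cluster-discriminating genes
   (Kruskal–Wallis BH q < 0.05).  Each sample's expression m is fit by
   linear-kernel ν-SVR over ν ∈ {0.25, 0.5, 0.75} (best RMSE);
   clipped, renormalized coefficients are the **proportion estimates**
   (PE), with a gene-permutation p-value on the fit correlation.
   The subtype call is **PEmax > 0.5 → that cluster ("pure")**,
   **PEmax ≤ 0.5 → "mixed"**, non-significant → "unclassified".
4. **Drug-sensitivity scoring** — single-sample GSEA: genes ranked by
   decreasing expression; in-set genes step the running sum up by
   rank^0.75 (normalized), out-of-set genes step down by 1/(N−m); the
   score integrates the running sum.  The docetaxel responder score is
   ssGSEA(up-set) − ssGSEA(down-set), z-normalized across samples;
   correlation-derived sets use Pearson r strictly above 0.3.
5. **Serum-marker survival analysis** — PAP calibrated across assays
   (U/L → ng/mL) by OLS; the PSA/PAP ratio (PPR) dichotomized at 20
   (strictly above → "high"); Kaplan–Meier curves, log-rank test, and
   the stratified Mantel–Haenszel hazard ratio
   HR = Σ(d_A·n_B/n) / Σ(d_B·n_A/n) with a Peto-style CI.  Also: the
   KLK3−ACP3 log2 expression ratio, the AVPC molecular-signature flag
   (≥2 of PTEN/TP53/RB1 altered), and chi-square enrichment scans with
   Benjamini–Hochberg correction.
6. **Synthetic data** — negative-binomial single-cell counts with
   planted markers, sorted-bulk profiles, Dirichlet bulk mixtures with
   log-normal noise, purity scores, and an mCRPC-like serum/survival
   cohort, all with recorded ground truth.

## Worked example

```python
import pandas as pd
import prosubtype as ps

# four tumor-cluster reference profiles and five noisy bulk mixtures
sig = ps.simulate_cluster_profiles(n_genes=300, n_clusters=4, seed=7)
cfg = ps.SimulationConfig(seed=7, n_genes=300, n_bulk_samples=5, noise_cv=0.1)
mix, truth = ps.simulate_bulk_mixtures(sig, cfg)

for c in ps.deconvolve_matrix(mix, sig, n_perm=100, seed=7):
    pes = "  ".join(f"{k}={v:.3f}" for k, v in c.pe.items())
    print(f"{c.sample_id}: {pes}  p={c.p_value:.2f}  label={c.label}")
```

```
bulk0000: A=0.223  B=0.322  C=0.177  D=0.277  p=0.00  label=mixed
bulk0001: A=0.029  B=0.525  C=0.004  D=0.442  p=0.00  label=B
bulk0002: A=0.331  B=0.182  C=0.309  D=0.178  p=0.00  label=mixed
bulk0003: A=0.210  B=0.270  C=0.462  D=0.058  p=0.00  label=mixed
bulk0004: A=0.622  B=0.146  C=0.065  D=0.167  p=0.00  label=A
```

Each line is one tumor: the PE vector sums to 1, the permutation
p-value says the fit beats gene-shuffled noise, and the label applies
the PEmax rule — `bulk0004` is a pure cluster-A tumor (PE 0.62 > 0.5),
`bulk0001` is pure B at the margin, the rest are mixed.  All five match
the generating truth.

The serum-ratio survival analysis on a simulated 30-patient mCRPC
docetaxel cohort (11 PSA-high vs 19 PAP-high patients):

```python
cohort = ps.simulate_cohort(
    30, **{k: ps.DEFAULT_COHORT[k]
           for k in ("group_fracs", "survival_params", "serum_params")}, seed=8)
groups = pd.Series(ps.dichotomize(cohort["psa"] / cohort["pap"]), index=cohort.index)
hi, lo = cohort[groups == "high"], cohort[groups == "low"]
chi2, p = ps.logrank_test((hi["time_days"], hi["event"]), (lo["time_days"], lo["event"]))
hr, l, h = ps.mh_hazard_ratio((hi["time_days"], hi["event"]), (lo["time_days"], lo["event"]))
```

```
PPR>20: n=11, median rPFS 71 d; PPR<=20: n=19, median 200 d
log-rank chi2=5.48 p=0.0193; MH HR=2.67 (95% CI 1.05-6.79)
```

Patients with a high PSA/PAP ratio progress markedly faster on
docetaxel than those with a low ratio — the pattern the ratio cutoff
is designed to expose (at n = 30 the medians and HR carry substantial
sampling noise around the generating values of 91 and 210 days).

There is also a CLI mirroring the stages:

```bash
prosubtype simulate --seed 1 --out sim/
prosubtype markers --sc-expr sim/single_cell.tsv --sc-labels sim/cell_labels.csv \
    --bulk-expr sim/sorted_bulk.tsv --bulk-labels sim/bulk_labels.csv --out markers/
prosubtype deconvolve --expr sim/mixtures.tsv --signature sim/cluster_profiles.tsv --out calls/
prosubtype survival --clinical sim/cohort.csv --out surv/
```

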