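"""Serum-marker computations, survival analysis, and enrichment scans.

Serum PAP values measured in U/L (colorimetric assay) are calibrated to
ng/mL (immunoassay) by ordinary least squares on paired measurements,
after which the PSA/PAP ratio (PPR) is the linear serum PSA divided by
PAP in ng/mL.  Patients are dichotomized at PPR 20 (strictly greater
than 20 is "high").  Transcript-level analogues use the KLK3 minus ACP3
difference of log2 expression.

Survival machinery: Kaplan-Meier product-limit curves (median = smallest
time with S(t) <= 0.5), the one-degree-of-freedom log-rank test, and the
Mantel-Haenszel hazard ratio (O_A/E_A)/(O_B/E_B) with a Peto-style
log-scale confidence interval from the log-rank variance.  Censored
observations tied with an event time remain at risk at that time.

The AVPC molecular signature flag is true when at least two of PTEN,
TP53, RB1 carry a mutation or deletion (each gene counts once).
Categorical enrichment scans use chi-square tests of independence with
Benjamini-Hochberg adjustment across features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ProsubtypeError, ValidationError

logger = logging.getLogger("prosubtype")

__all__ = [
    "calibrate_pap",
    "psa_pap_ratio",
    "klk3_acp3_log_ratio",
    "dichotomize",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "mh_hazard_ratio",
    "avpc_ms",
    "enrichment_scan",
    "AVPC_GENES",
]

AVPC_GENES = ("PTEN", "TP53", "RB1")
_ALTERED = {"mutated", "deleted", "mutated_and_deleted"}


def calibrate_pap(
    paired: Sequence[tuple[float, float]], to_convert: Sequence[float]
) -> tuple[float, float, list[float]]:
    """OLS calibration of U/L PAP values onto the ng/mL scale.

    Fits y = a*x + b on ``paired`` (x in U/L, y in ng/mL) and converts
    ``to_convert``; negative conversions are floored at 0 with a warning.
    Returns (slope, intercept, converted).
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValidationError("need >=3 calibration pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValidationError("degenerate calibration: all x values equal")
    fit = stats.linregress(x, y)
    converted = fit.slope * np.asarray(to_convert, dtype=float) + fit.intercept
    if (converted < 0).any():
        logger.warning("flooring %d negative PAP conversions at 0", int((converted < 0).sum()))
        converted = np.clip(converted, 0.0, None)
    return float(fit.slope), float(fit.intercept), converted.tolist()


def psa_pap_ratio(psa: float, pap_ngml: float) -> float:
    """Serum PSA/PAP ratio on the linear scale (undefined at PAP = 0)."""
    if pap_ngml <= 0:
        raise ValidationError("PSA/PAP ratio undefined for PAP <= 0")
    if psa < 0:
        raise ValidationError("PSA must be non-negative")
    return psa / pap_ngml


def klk3_acp3_log_ratio(klk3_log2: float, acp3_log2: float) -> float:
    """Transcript-level ratio: KLK3 minus ACP3 log2 expression."""
    return klk3_log2 - acp3_log2


def dichotomize(ppr: Sequence[float], cutoff: float = 20.0) -> list[str]:
    """Label "high" iff the ratio is strictly above the cutoff, else "low"."""
    return ["high" if v > cutoff else "low" for v in ppr]


@dataclass
class KMCurve:
    """A Kaplan-Meier step function with its median."""

    times: np.ndarray  # event/censor time grid (starts at 0)
    survival: np.ndarray  # S(t) at each grid time, starts at 1
    median: float  # NaN when S never falls to 0.5

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit survival estimate.

    Median is the smallest observed time with S(t) <= 0.5, NaN when the
    curve never reaches 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t < 0).any():
        raise ValidationError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = float(med) if np.isfinite(med) else float("nan")
    return KMCurve(times=grid, survival=surv, median=median)


def _logrank_tables(
    times_a, events_a, times_b, events_b
) -> tuple[float, float, float, float, float, float, float]:
    """Risk-table sums over pooled distinct event times.

    Returns (O_A, E_A, O_B, E_B, V, mh_num, mh_den): observed/expected
    event counts, the hypergeometric log-rank variance, and the
    Mantel-Haenszel sums sum(d_A * n_B / n) and sum(d_B * n_A / n).
    Censored observations at t remain at risk at t.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O_A = float(ea.sum())
    O_B = float(eb.sum())
    E_A = E_B = V = mh_num = mh_den = 0.0
    for t in event_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        d_a = float(((ta == t) & ea).sum())
        d_b = float(((tb == t) & eb).sum())
        d = d_a + d_b
        if n == 0:
            continue
        E_A += d * n_a / n
        E_B += d * n_b / n
        mh_num += d_a * n_b / n
        mh_den += d_b * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return O_A, E_A, O_B, E_B, V, mh_num, mh_den


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank (Mantel-Cox) test.

    Returns (chi2, p).  Identical groups give chi2 = 0, p = 1; zero
    total events is an error.
    """
    ta, ea = group_a
    tb, eb = group_b
    if len(ta) == 0 or len(tb) == 0:
        raise ValidationError("both groups must be non-empty")
    O_A, E_A, O_B, E_B, V, _, _ = _logrank_tables(ta, ea, tb, eb)
    if O_A + O_B == 0:
        raise ValidationError("log-rank needs >=1 event")
    if V == 0:
        return 0.0, 1.0
    chi2 = (O_A - E_A) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def mh_hazard_ratio(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
    conf_level: float = 0.95,
) -> tuple[float, float, float]:
    """Mantel-Haenszel hazard ratio (A vs B) with log-scale CI.

    Point estimate: the classical stratified Mantel-Haenszel ratio
    sum(d_A * n_B / n) / sum(d_B * n_A / n) over the per-event-time
    risk tables, which is consistent for the hazard ratio under
    proportional hazards.  The confidence interval uses the Peto-style
    standard error 1/sqrt(V) around log HR, V being the log-rank
    hypergeometric variance.
    """
    ta, ea = group_a
    tb, eb = group_b
    O_A, E_A, O_B, E_B, V, mh_num, mh_den = _logrank_tables(ta, ea, tb, eb)
    if O_A == 0 or O_B == 0:
        raise ValidationError("Mantel-Haenszel HR needs >=1 event in each group")
    if E_A == 0 or E_B == 0 or mh_den == 0:
        raise ValidationError("zero expected event count")
    hr = mh_num / mh_den
    if V == 0:
        raise ValidationError("zero log-rank variance")
    z = stats.norm.ppf(0.5 + conf_level / 2)
    se = 1.0 / np.sqrt(V)
    return float(hr), float(hr * np.exp(-z * se)), float(hr * np.exp(z * se))


def avpc_ms(profile: Mapping[str, str]) -> bool:
    """AVPC molecular signature: >=2 of PTEN/TP53/RB1 mutated or deleted."""
    altered = 0
    for gene in AVPC_GENES:
        if gene not in profile:
            raise ValidationError(f"missing alteration status for {gene}")
        status = profile[gene]
        if status not in _ALTERED and status != "wildtype":
            raise ValidationError(f"unknown status {status!r} for {gene}")
        altered += status in _ALTERED
    return altered >= 2


def enrichment_scan(
    labels: pd.Series, features: pd.DataFrame, correction: bool = False
) -> pd.DataFrame:
    """Chi-square enrichment of each categorical feature across groups.

    Per feature, a test of independence between the group label and the
    feature categories; Benjamini-Hochberg adjustment across all tested
    features.  Constant features are skipped with a note.  Returns a
    table (feature, chi2, chi2_p, bh_q).
    """
    labels = labels.reindex(features.index).dropna()
    if labels.nunique() < 2:
        raise ValidationError("need >=2 groups")
    feats = features.loc[labels.index]
    rows = []
    for col in feats.columns:
        vals = feats[col].dropna()
        if vals.nunique() < 2:
            logger.info("feature %r constant across samples; skipped", col)
            continue
        tab = pd.crosstab(labels.loc[vals.index], vals)
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=correction)
        rows.append({"feature": col, "chi2": float(chi2), "chi2_p": float(p)})
    if not rows:
        return pd.DataFrame(columns=["feature", "chi2", "chi2_p", "bh_q"])
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["chi2_p"].to_numpy(), method="fdr_bh")
    out["bh_q"] = q
    return out
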