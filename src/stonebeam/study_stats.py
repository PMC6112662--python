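"""Cohort summaries, paired comparisons with Bonferroni correction, and the
study report tables (method-vs-baseline deltas for contrast/CNR/SNR, sizing
errors vs the reference size, and shadow-contrast deltas).

Conventions: sample standard deviations use the n-1 denominator, paired
Student t-tests are two-sided, and the family-wise error rate is controlled
by dividing the family alpha by the number of comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidParameterError

__all__ = [
    "pilot_cohort",
    "cohort_summary",
    "paired_t",
    "sign_flip_permutation_p",
    "bonferroni_alpha",
    "ComparisonResult",
    "build_report",
]


def pilot_cohort() -> pd.DataFrame:
    """Bundled example cohort: five human stone formers, six stones, with
    CT skin-to-stone distance (cm), BMI (kg/m^2) and CT-measured size (mm)."""
    rows = [
        (1, 60, "M", "left", 12.1, 36.9, 5.9),
        (2, 65, "F", "right", 16.3, 42.3, 6.3),
        (3, 74, "F", "right", 10.0, 24.4, 2.9),
        (4, 58, "M", "right", 5.4, 22.6, 4.2),
        (5, 51, "F", "right", 10.0, 25.5, 12.2),
        (5, 51, "F", "left", 7.5, 25.5, 4.7),
    ]
    return pd.DataFrame(rows, columns=["subject", "age", "sex", "laterality",
                                       "skin_to_stone_cm", "bmi", "ct_size_mm"])


def cohort_summary(rows: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Mean, sample SD, min and max per numeric column.

    Full precision is kept in the returned frame; the ``display`` attribute
    holds the one-decimal rounded view used in report tables.  With a single
    row the SD is reported as missing.
    """
    num = rows.select_dtypes(include=[np.number])
    if num.shape[0] < 1:
        raise InvalidParameterError("cohort must contain at least one row")
    out = pd.DataFrame({
        "mean": num.mean(),
        "sd": num.std(ddof=1) if num.shape[0] >= 2 else pd.Series(math.nan, index=num.columns),
        "min": num.min(),
        "max": num.max(),
    })
    out.attrs["display"] = out.round(decimals)
    return out


def paired_t(deltas) -> tuple:
    """Two-sided paired Student t-test on per-subject differences.

    Returns (t, p) with t = mean(d) / (sd(d)/sqrt(n)) and p from the
    t-distribution with n-1 degrees of freedom.  All-zero deltas give
    (0, 1); zero variance with a nonzero mean gives the p = 0 sentinel.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise InvalidParameterError("need at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise InvalidParameterError("deltas must be finite")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        import warnings

        warnings.warn("zero-variance deltas with nonzero mean: p=0 sentinel",
                      RuntimeWarning, stacklevel=2)
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def sign_flip_permutation_p(deltas, n_perm: int = 10_000, seed: int = 0,
                            exact_max_n: int = 20) -> float:
    """Two-sided p from the paired sign-flip permutation null of the t
    statistic; exact enumeration when 2^n <= 2^exact_max_n is feasible."""
    d = np.asarray(deltas, dtype=float)
    n = d.size
    t_obs, _ = paired_t(d)

    def t_stat(x):
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0 if x.mean() == 0 else math.inf
        return x.mean() / (sd / math.sqrt(n))

    if n <= exact_max_n and 2 ** n <= n_perm:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        ts = np.array([t_stat(d * s) for s in signs])
        return float(np.mean(np.abs(ts) >= abs(t_obs) - 1e-12))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        s = rng.integers(0, 2, size=n) * 2 - 1
        if abs(t_stat(d * s)) >= abs(t_obs) - 1e-12:
            count += 1
    return count / n_perm


def bonferroni_alpha(family_alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance threshold family_alpha / n_comparisons."""
    if not (0.0 < family_alpha < 1.0):
        raise InvalidParameterError("family_alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise InvalidParameterError("n_comparisons must be >= 1")
    return family_alpha / n_comparisons


@dataclass(frozen=True)
class ComparisonResult:
    """One method-vs-reference paired comparison."""

    method: str
    delta_mean: float
    delta_sd: float
    t_statistic: float
    p_value: float
    alpha_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def _delta_table(records: pd.DataFrame, metric: str, baseline: str,
                 alpha: float) -> pd.DataFrame:
    methods = [m for m in records["method"].unique() if m != baseline]
    base = records[records["method"] == baseline].set_index("phantom_id")[metric]
    rows = []
    n_comp = len(methods)
    a_adj = bonferroni_alpha(alpha, n_comp) if n_comp else alpha
    for m in methods:
        cur = records[records["method"] == m].set_index("phantom_id")[metric]
        joined = pd.concat([cur, base], axis=1, keys=["m", "b"]).dropna()
        d = (joined["m"] - joined["b"]).to_numpy()
        if d.size >= 2:
            t, p = paired_t(d)
        else:
            t, p = math.nan, math.nan
        rows.append({"method": m, "delta_mean": d.mean() if d.size else math.nan,
                     "delta_sd": d.std(ddof=1) if d.size >= 2 else math.nan,
                     "n": d.size, "t": t, "p": p, "alpha_adjusted": a_adj,
                     "significant": bool(p < a_adj) if np.isfinite(p) else False})
    return pd.DataFrame(rows)


def build_report(records: pd.DataFrame, shadow: pd.DataFrame | None = None,
                 baseline: str = "bmode", family_alpha: float = 0.05) -> dict:
    """Study tables from per-phantom MeasurementRecord rows.

    records needs columns phantom_id, method, contrast_dB, cnr_dB, snr,
    measured_size_mm, reference_size_mm (and optionally sizing_error_mm);
    shadow needs phantom_id, method, shadow_contrast_dB, shadow_width_mm,
    shadow_detected.  Returns dict with 'stone' (contrast/CNR/SNR deltas vs
    baseline), 'sizing' (error vs reference per method, tested against zero),
    and, when shadow data is given, 'shadow' (contrast deltas vs baseline,
    with methods lacking any detected shadow reported as n/a).
    """
    if baseline not in set(records["method"]):
        raise InvalidParameterError(f"baseline method '{baseline}' missing from records")
    rec = records.copy()
    if "sizing_error_mm" not in rec.columns:
        rec["sizing_error_mm"] = rec["measured_size_mm"] - rec["reference_size_mm"]

    stone = {metric: _delta_table(rec, metric, baseline, family_alpha)
             for metric in ("contrast_dB", "cnr_dB", "snr")}

    methods = list(dict.fromkeys(rec["method"]))
    a_size = bonferroni_alpha(family_alpha, len(methods))
    size_rows = []
    for m in methods:
        err = rec.loc[rec["method"] == m, "sizing_error_mm"].dropna().to_numpy()
        t, p = paired_t(err) if err.size >= 2 else (math.nan, math.nan)
        size_rows.append({"method": m, "error_mean_mm": err.mean() if err.size else math.nan,
                          "error_sd_mm": err.std(ddof=1) if err.size >= 2 else math.nan,
                          "n": err.size, "t": t, "p": p, "alpha_adjusted": a_size,
                          "significant": bool(p < a_size) if np.isfinite(p) else False})
    tables = {"stone": stone, "sizing": pd.DataFrame(size_rows)}

    if shadow is not None:
        sh = shadow.copy()
        sh.loc[~sh["shadow_detected"].astype(bool), "shadow_contrast_dB"] = math.nan
        tab = _delta_table(sh, "shadow_contrast_dB", baseline, family_alpha)
        n_missing = (sh.groupby("method")["shadow_contrast_dB"]
                     .apply(lambda s: s.isna().all()))
        tab["status"] = ["n/a" if n_missing.get(m, False) else "ok" for m in tab["method"]]
        tab.loc[tab["status"] == "n/a", ["delta_mean", "delta_sd", "t", "p"]] = math.nan
        tab.loc[tab["status"] == "n/a", "significant"] = False
        tables["shadow"] = tab
    return tables
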