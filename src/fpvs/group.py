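"""Population-level statistics: proportions, contingency tests, bootstrap
and t-test comparisons of latencies and amplitudes."""
from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidParameterError

__all__ = ["percent", "chi2_2x2", "bootstrap_diff", "t_test", "cohort_summary"]


def percent(numerator: int, denominator: int) -> float:
    """100*n/d rounded half-up to one decimal (the convention of the report tables)."""
    if denominator <= 0:
        raise InvalidParameterError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise InvalidParameterError("numerator must lie in [0, denominator]")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def chi2_2x2(table, continuity_correction: bool = True) -> Tuple[float, float]:
    """Pearson chi-square test of homogeneity on a 2x2 table (1 d.f.).

    Yates continuity correction is applied by default; disable with
    ``continuity_correction=False``.  Returns ``(statistic, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InvalidParameterError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidParameterError("both margins must be positive for the test to be defined")
    res = sps.chi2_contingency(t, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def bootstrap_diff(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_boot: int = 10000,
    seed: Optional[int] = None,
) -> float:
    """Two-tailed percentile-bootstrap p for a difference in group means.

    Each group is resampled with replacement ``n_boot`` times;
    ``p = 2 * min(P(diff* <= 0), P(diff* >= 0))`` clipped to 1.  The two
    resampling streams are assigned after putting the groups in a canonical
    order, so the p-value is exactly invariant to swapping the group labels
    under the same seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if n_boot < 1000:
        raise InvalidParameterError("n_boot must be >= 1000")
    if a.size == 1 or b.size == 1:
        warnings.warn("a group of size 1 gives very wide bootstrap intervals")
    # canonical order -> label-swap invariance (p is symmetric in the sign of diff)
    if (a.size, tuple(a)) > (b.size, tuple(b)):
        a, b = b, a
    rng = np.random.default_rng(seed)
    means_a = a[rng.integers(0, a.size, (n_boot, a.size))].mean(axis=1)
    means_b = b[rng.integers(0, b.size, (n_boot, b.size))].mean(axis=1)
    diff = means_a - means_b
    p = 2.0 * min(np.mean(diff <= 0), np.mean(diff >= 0))
    return float(min(p, 1.0))


def t_test(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-tailed.

    Two constant groups with equal means return ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def cohort_summary(
    classification: pd.DataFrame,
    group_col: str = "participant",
    n_boot: int = 10000,
    seed: Optional[int] = None,
) -> dict:
    """Results-style summary of a classified cohort.

    Expects one row per unit with columns ``visually_responsive``,
    ``face_selective_p05``, ``face_selective_p01``, ``response_sign``,
    ``face_exclusive`` and optionally ``latency_ms`` / ``amplitude_hz``,
    plus a grouping column (participant).  Returns a nested dict of counts,
    percentages, chi-square p-values between the two groups, and the
    latency (bootstrap) and amplitude (Welch t) comparisons between
    increase- and decrease-type units.
    """
    df = classification
    out: dict = {"groups": {}}
    for g, sub in df.groupby(group_col):
        n = len(sub)
        n_resp = int(sub["visually_responsive"].sum())
        resp = sub[sub["visually_responsive"]]
        n_p05 = int(resp["face_selective_p05"].sum())
        n_p01 = int(resp["face_selective_p01"].sum())
        sel = sub[sub["face_selective_p01"]]
        n_inc = int((sel["response_sign"] == "increase").sum())
        n_dec = int((sel["response_sign"] == "decrease").sum())
        entry = {
            "n_units": n,
            "n_visually_responsive": n_resp,
            "pct_unresponsive": percent(n - n_resp, n),
            "n_face_selective_p05": n_p05,
            "pct_face_selective_p05": percent(n_p05, len(resp)) if len(resp) else np.nan,
            "n_face_selective_p01": n_p01,
            "pct_face_selective_p01": percent(n_p01, len(resp)) if len(resp) else np.nan,
            "n_increase": n_inc,
            "n_decrease": n_dec,
            "n_face_exclusive": int(sub["face_exclusive"].sum()),
        }
        out["groups"][str(g)] = entry

    groups = list(out["groups"].values())
    if len(groups) == 2:
        g1, g2 = groups
        t_resp = [
            [g1["n_units"] - g1["n_visually_responsive"], g1["n_visually_responsive"]],
            [g2["n_units"] - g2["n_visually_responsive"], g2["n_visually_responsive"]],
        ]
        t_sel = [
            [g1["n_face_selective_p01"], g1["n_visually_responsive"] - g1["n_face_selective_p01"]],
            [g2["n_face_selective_p01"], g2["n_visually_responsive"] - g2["n_face_selective_p01"]],
        ]
        for key, table in (("chi2_p_unresponsive", t_resp), ("chi2_p_face_selective_p01", t_sel)):
            try:
                out[key] = chi2_2x2(table)[1]
            except InvalidParameterError:
                out[key] = np.nan  # a zero margin leaves the test undefined

    if "latency_ms" in df.columns and "response_sign" in df.columns:
        sel = df[df["face_selective_p01"]] if "face_selective_p01" in df.columns else df
        inc = sel[sel["response_sign"] == "increase"]
        dec = sel[sel["response_sign"] == "decrease"]
        lat_inc = inc["latency_ms"].dropna().to_numpy()
        lat_dec = dec["latency_ms"].dropna().to_numpy()
        if lat_inc.size and lat_dec.size:
            out["latency_ms_increase_mean"] = float(lat_inc.mean())
            out["latency_ms_decrease_mean"] = float(lat_dec.mean())
            out["latency_bootstrap_p"] = bootstrap_diff(lat_inc, lat_dec, n_boot=n_boot, seed=seed)
        if "amplitude_hz" in df.columns:
            amp_inc = inc["amplitude_hz"].dropna().to_numpy()
            amp_dec = dec["amplitude_hz"].dropna().to_numpy()
            if amp_inc.size >= 2 and amp_dec.size >= 2:
                out["amplitude_hz_increase_mean"] = float(amp_inc.mean())
                out["amplitude_hz_decrease_mean"] = float(amp_dec.mean())
                out["amplitude_welch_p"] = t_test(np.abs(amp_inc), np.abs(amp_dec))[1]
    return out
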