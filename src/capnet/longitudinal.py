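"""Longitudinal conservation of Ca2+ activity across revisits.

The same cells are revisited days to weeks apart (cell correspondence is an
input, from landmark-based revisiting).  Conservation of activity status is
tested with a two-category chi-squared goodness of fit against the study's
"random activity" null: the expected proportion of cells maintaining their
status equals the Day-0 active proportion p0 (58% for 24-hour revisits, 54%
for 14-day revisits, 74% for the Cx43cKO 14-day revisits).  That null is
implemented verbatim as the default; the statistically standard
independence null, P(maintain) = p0^2 + (1-p0)^2, is computed alongside and
labeled, since the two differ.

Treatment effects are summarized as the percent change of per-mouse means
(frequency, average duration, active proportion, persistent cluster size)
between pre- and post-treatment recordings, compared between conditions by
an unpaired two-tailed t test (equal variances assumed, matching the
study's test; Welch available as a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConservationResult",
    "conservation_stats",
    "chi_square_conservation",
    "dynamics_retention",
    "treatment_percent_change",
    "compare_percent_change",
]


@dataclass
class ConservationResult:
    n: int
    observed_maintained: int
    observed_proportion: float
    expected_proportion: float
    chi2: float
    df: int
    p_value: float
    # same statistic under the independence null P = p0^2 + (1-p0)^2
    independence_expected_proportion: float
    independence_chi2: float
    independence_p_value: float


def conservation_stats(pair: pd.DataFrame) -> dict:
    """Proportion of cells maintaining activity status, plus class retention.

    ``pair`` needs ``status_day0``/``status_dayN``; class retention is
    reported for any of ``high_frequency``, ``high_avg_duration`` and
    ``persistent`` present as ``<name>_day0``/``<name>_dayN`` boolean
    columns (see :func:`dynamics_retention` for the Venn counts).
    """
    if len(pair) == 0:
        raise ValueError("empty revisit pair")
    maintained = (pair["status_day0"] == pair["status_dayN"]).sum()
    out = {
        "n": len(pair),
        "maintained": int(maintained),
        "maintained_proportion": maintained / len(pair),
    }
    for cls in ("high_frequency", "high_avg_duration", "persistent"):
        c0, cn = f"{cls}_day0", f"{cls}_dayN"
        if c0 in pair.columns and cn in pair.columns:
            day0 = pair[c0].astype(bool)
            if day0.sum() == 0:
                out[f"{cls}_retention"] = np.nan
            else:
                out[f"{cls}_retention"] = float(
                    (day0 & pair[cn].astype(bool)).sum() / day0.sum()
                )
    return out


def chi_square_conservation(pair: pd.DataFrame, expected_p0: float) -> ConservationResult:
    """Two-category goodness of fit of observed status maintenance.

    Observed counts: maintained vs not-maintained.  Expected counts under
    the study null: ``p0 * n`` and ``(1 - p0) * n`` where p0 is the Day-0
    active proportion; chi2 = sum (obs - exp)^2 / exp with df = 1 and an
    upper-tail p-value.  The independence-null variant replaces p0 with
    p0^2 + (1-p0)^2.
    """
    if not (0.0 < expected_p0 < 1.0):
        raise ValueError("expected_p0 must be in (0, 1)")
    n = len(pair)
    if n < 1:
        raise ValueError("empty revisit pair")
    obs_m = int((pair["status_day0"] == pair["status_dayN"]).sum())

    def gof(p: float) -> tuple[float, float]:
        exp = np.array([p * n, (1.0 - p) * n])
        if exp.min() < 1:
            warnings.warn("expected count < 1; chi-squared approximation is unreliable",
                          stacklevel=3)
        obs = np.array([obs_m, n - obs_m])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return chi2, float(stats.chi2.sf(chi2, df=1))

    chi2, p = gof(expected_p0)
    p_ind = expected_p0**2 + (1.0 - expected_p0) ** 2
    chi2_i, p_i = gof(p_ind)
    return ConservationResult(
        n=n,
        observed_maintained=obs_m,
        observed_proportion=obs_m / n,
        expected_proportion=expected_p0,
        chi2=chi2,
        df=1,
        p_value=p,
        independence_expected_proportion=p_ind,
        independence_chi2=chi2_i,
        independence_p_value=p_i,
    )


def dynamics_retention(pair: pd.DataFrame,
                       classes=("high_frequency", "high_avg_duration")) -> dict:
    """Retention of >1SD dynamics classes across the revisit.

    For each class, retention = |day0 members also in class on day N| /
    |day0 members| (classes must have been assigned with Day-0 or control
    reference thresholds on both days).  Also emits the Venn counts
    (day0_only, dayN_only, both) behind the retention maps.  Classes empty
    on day 0 report retention as NaN.
    """
    out = {}
    for cls in classes:
        d0 = pair[f"{cls}_day0"].astype(bool)
        dn = pair[f"{cls}_dayN"].astype(bool)
        both = int((d0 & dn).sum())
        venn = {
            "day0_only": int((d0 & ~dn).sum()),
            "dayN_only": int((~d0 & dn).sum()),
            "both": both,
        }
        retention = both / d0.sum() if d0.sum() else np.nan
        out[cls] = {"retention": retention, "venn": venn, "n_day0": int(d0.sum())}
    return out


def treatment_percent_change(
    pre: pd.DataFrame, post: pd.DataFrame, metrics=None
) -> pd.DataFrame:
    """Percent change of per-mouse mean metrics between paired recordings.

    ``pre``/``post`` are indexed (or keyed by a ``mouse`` column) per-mouse
    summary tables with one column per metric.  percent change =
    100 * (post - pre) / pre, per mouse per metric.  Mice with a zero
    pre-treatment mean are excluded for that metric with a warning.
    """
    def keyed(df):
        return df.set_index("mouse") if "mouse" in df.columns else df

    pre, post = keyed(pre), keyed(post)
    if metrics is None:
        metrics = [c for c in pre.columns if c in post.columns]
    common = pre.index.intersection(post.index)
    if len(common) == 0:
        raise ValueError("no matched mice between pre and post tables")
    rows = {}
    for m in metrics:
        p0 = pre.loc[common, m].astype(float)
        p1 = post.loc[common, m].astype(float)
        zero = p0 == 0
        if zero.any():
            warnings.warn(
                f"metric {m}: pre-treatment mean is 0 for {list(common[zero])}; excluded",
                stacklevel=2,
            )
        rows[m] = 100.0 * (p1 - p0) / p0.where(~zero)
    return pd.DataFrame(rows, index=common)


def compare_percent_change(
    group_a: pd.Series | np.ndarray,
    group_b: pd.Series | np.ndarray,
    welch: bool = False,
) -> dict:
    """Unpaired two-tailed t test on per-mouse percent changes."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {"t": float(t), "p_value": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n_a": int(a.size), "n_b": int(b.size)}
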