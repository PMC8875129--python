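"""Inhibitor and co-administration effect analysis.

Quantifies how a treatment (an efflux inhibitor such as verapamil or
cyclosporin, or a co-administered compound) shifts the transport metrics
of a baseline condition: signed percent changes in Papp (both
directions) and in the efflux ratio, plus a two-sample Welch test on
per-well Papp values. Welch's t is the default because group variances
in small transport experiments are rarely equal; the choice is
configurable. No multiple-testing correction is applied by default (a
bidirectional study makes only a handful of contrasts); Holm adjustment
is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transport import GroupSummary

__all__ = [
    "percent_change",
    "describe_change",
    "contrast_groups",
    "effect_report",
    "holm_adjust",
    "build_report",
    "ContrastResult",
    "EffectReport",
]


def percent_change(baseline: float, treated: float) -> float:
    """Signed percent change, ``(treated - baseline) / baseline * 100``.

    Negative values are decreases; :func:`describe_change` renders the
    conventional "decrease of X%" phrasing.
    """
    if baseline == 0 or not math.isfinite(baseline):
        raise ValueError("percent_change: baseline must be nonzero and finite")
    return (treated - baseline) / baseline * 100.0


def describe_change(pct: float, ndigits: int = 2) -> str:
    """Render a signed percent change as 'a decrease/increase of X%'."""
    if math.isnan(pct):
        return "no data"
    word = "decrease" if pct < 0 else "increase" if pct > 0 else "change"
    return f"{word} of {abs(round(pct, ndigits)):.{ndigits}f}%"


@dataclass(frozen=True)
class ContrastResult:
    """Two-sample test on per-well Papp values."""

    statistic: float
    pvalue: float
    direction: str          # "increase", "decrease" or "none" (treated vs baseline)
    significant: bool
    alpha: float
    test: str = "welch"

    @property
    def verdict(self) -> str:
        return ("significant difference" if self.significant
                else "no significant difference")


def contrast_groups(baseline, treated, alpha: float = 0.05,
                    test: str = "welch") -> ContrastResult:
    """Welch (default) or Student two-sample t-test on per-well values.

    Needs >= 2 wells per group. When both groups are degenerate (zero
    variance) and have equal means, p = 1 by convention — identical
    groups can never be called different.
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("contrast_groups: need >= 2 wells per group")
    diff = float(np.mean(b) - np.mean(a))
    direction = "increase" if diff > 0 else "decrease" if diff < 0 else "none"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.mean(a) == np.mean(b):
            return ContrastResult(0.0, 1.0, "none", False, alpha, test)
        return ContrastResult(math.inf, 0.0, direction, True, alpha, test)
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    p = float(res.pvalue)
    return ContrastResult(float(res.statistic), p, direction, p < alpha, alpha, test)


@dataclass
class EffectReport:
    """Baseline-vs-treated comparison across the three transport metrics.

    ``rows`` holds one record per metric (Papp(AP->BL), Papp(BL->AP),
    ER) with baseline value, treated value, signed percent change and —
    where per-well values exist for a Papp metric — the two-sample test
    p-value.
    """

    baseline: str
    treated: str
    rows: pd.DataFrame = field(repr=False, default=None)

    def frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(0, "treated", self.treated)
        out.insert(0, "baseline", self.baseline)
        return out


_METRIC_ATTRS = {
    "papp_ab": ("papp_ab_mean_e6", "papp_ab"),
    "papp_ba": ("papp_ba_mean_e6", "papp_ba"),
}


def effect_report(baseline: GroupSummary, treated: GroupSummary,
                  alpha: float = 0.05, test: str = "welch") -> EffectReport:
    """Build the per-metric effect table for one baseline/treated pair.

    Papp values are compared on the 1e-6 cm/s reporting scale; ER on its
    natural scale. Percent changes are signed. Tests run only where both
    groups have >= 2 wells in that direction; otherwise the p-value is
    NaN (descriptive only). A missing BL->AP arm leaves that metric and
    the ER row NaN rather than imputing anything.
    """
    rows = []
    for metric, (mean_attr, wells_attr) in _METRIC_ATTRS.items():
        base = getattr(baseline, mean_attr)
        trt = getattr(treated, mean_attr)
        pct = percent_change(base, trt) if _ok(base) and _ok(trt) else float("nan")
        pval = float("nan")
        wb = getattr(baseline, wells_attr)
        wt = getattr(treated, wells_attr)
        if wb.size >= 2 and wt.size >= 2:
            pval = contrast_groups(wb * 1e6, wt * 1e6, alpha, test).pvalue
        rows.append({"metric": metric, "base_value": base, "treated_value": trt,
                     "pct_change": pct, "p_value": pval})
    base_er, trt_er = baseline.er, treated.er
    pct = percent_change(base_er, trt_er) if _ok(base_er) and _ok(trt_er) else float("nan")
    rows.append({"metric": "er", "base_value": base_er, "treated_value": trt_er,
                 "pct_change": pct, "p_value": float("nan")})
    return EffectReport(baseline=baseline.condition, treated=treated.condition,
                        rows=pd.DataFrame(rows))


def _ok(x: float) -> bool:
    return x is not None and math.isfinite(x)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def build_report(summaries: list[GroupSummary],
                 effects: list[EffectReport] | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the condition table and the pairwise effect table.

    The condition table mirrors a bidirectional-assay report: n per
    direction, mean +/- SD Papp in units of 1e-6 cm/s, ratio-of-means
    ER, and the mechanism label. Missing arms stay NaN in memory and are
    rendered as an em dash by the CSV writer. Output is deterministic:
    identical inputs give identical frames (and bytes, once written).
    """
    labels = [s.condition for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels in report")
    cond = pd.DataFrame([{
        "condition": s.condition,
        "n_ab": s.n_ab, "n_ba": s.n_ba,
        "papp_ab_e6_mean": s.papp_ab_mean_e6, "papp_ab_e6_sd": s.papp_ab_sd * 1e6,
        "papp_ba_e6_mean": s.papp_ba_mean_e6, "papp_ba_e6_sd": s.papp_ba_sd * 1e6,
        "er": s.er,
        "er_well_mean": s.er_well_mean, "er_well_sd": s.er_well_sd,
        "classification": s.classification,
    } for s in summaries])
    if effects:
        eff = pd.concat([e.frame() for e in effects], ignore_index=True)
    else:
        eff = pd.DataFrame(columns=["baseline", "treated", "metric",
                                    "base_value", "treated_value",
                                    "pct_change", "p_value"])
    return cond, eff
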