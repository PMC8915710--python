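"""Bland–Altman agreement analysis and the model-comparison report.

The report table mirrors the published layout: one row per analysis case
(regression, classification at the >15 mmHg cutoff, classification at
the >10 mmHg sensitivity cutoff), listing the selected terms and the full
metric suite for the waveform model next to the dummy and BNP-only
comparators.  Values are re-serializations of the modeling outputs — the
report recomputes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import UsageError
from .modeling import ClassifierMetrics, RegressionFit

__all__ = [
    "BlandAltman",
    "bland_altman",
    "bland_altman_frame",
    "build_report",
    "plot_regression_scatter",
    "plot_bland_altman",
]

log = logging.getLogger(__name__)

_LOA_MULTIPLIER = 1.96  # standard normal 95% limits of agreement


@dataclass
class BlandAltman:
    """Agreement between predicted and invasively measured pressure."""

    mean: np.ndarray  # per-subject mean of (predicted, actual), mmHg
    diff: np.ndarray  # predicted - actual, mmHg
    bias: float
    loa_low: float
    loa_high: float
    slope: float  # proportional-bias check: diff regressed on mean
    slope_p: float


def bland_altman(pred, actual) -> BlandAltman:
    """Bias and 1.96-SD limits of agreement for paired measurements."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise UsageError("pred and actual must be equal-length 1-d arrays")
    if len(pred) < 3:
        raise UsageError("Bland–Altman needs at least 3 pairs")
    diff = pred - actual
    mean = (pred + actual) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) > 0:
        fit = linregress(mean, diff)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    else:  # all pair means identical; no proportional trend estimable
        slope, slope_p = 0.0, 1.0
    return BlandAltman(
        mean=mean,
        diff=diff,
        bias=bias,
        loa_low=bias - _LOA_MULTIPLIER * sd,
        loa_high=bias + _LOA_MULTIPLIER * sd,
        slope=slope,
        slope_p=slope_p,
    )


def bland_altman_frame(ba: BlandAltman) -> pd.DataFrame:
    """Per-subject table plus summary columns, ready for CSV export."""
    df = pd.DataFrame({"mean_mmHg": ba.mean, "diff_mmHg": ba.diff})
    df["bias"] = ba.bias
    df["loa_low"] = ba.loa_low
    df["loa_high"] = ba.loa_high
    df["slope"] = ba.slope
    df["slope_p"] = ba.slope_p
    return df


_CLS_METRICS = ("accuracy", "precision", "recall", "f1", "auroc", "specificity")


def _regression_cells(prefix: str, fit: Optional[RegressionFit]) -> dict:
    if fit is None:
        return {}
    return {
        f"{prefix}_r2": fit.r2,
        f"{prefix}_adj_r2": fit.adj_r2,
        f"{prefix}_p": fit.f_pvalue,
        f"{prefix}_cv_r2": fit.cv_r2,
    }


def _classifier_cells(prefix: str, m: Optional[ClassifierMetrics]) -> dict:
    if m is None:
        return {}
    return {f"{prefix}_{k}": getattr(m, k) for k in _CLS_METRICS}


def build_report(case_results: dict[str, dict]) -> pd.DataFrame:
    """Assemble the comparison table from :func:`modeling.evaluate_case`
    outputs keyed by case name; cases without results are omitted with a
    logged notice."""
    rows = []
    for case in ("regression", "classify_10", "classify_15"):
        res = case_results.get(case)
        if not res:
            log.info("case %s has no results; omitted from report", case)
            continue
        row: dict = {"case": case, "terms": "; ".join(res.get("features", []))}
        if case == "regression":
            row.update(_regression_cells("model", res.get("fit")))
            row.update(_regression_cells("bnp", res.get("bnp")))
        else:
            row.update(_classifier_cells("model", res.get("metrics")))
            row.update(_classifier_cells("dummy", res.get("dummy")))
            row.update(_classifier_cells("bnp", res.get("bnp")))
        rows.append(row)
    if not rows:
        raise UsageError("no fitted case to report")
    return pd.DataFrame(rows)


def plot_regression_scatter(pred, actual, path) -> None:
    """Predicted vs measured filling pressure with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(actual, pred, s=18, alpha=0.7)
    lims = [min(actual.min(), pred.min()) - 1, max(actual.max(), pred.max()) + 1]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("Measured filling pressure (mmHg)")
    ax.set_ylabel("Predicted filling pressure (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(ba: BlandAltman, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.mean, ba.diff, s=18, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("Mean of predicted and measured (mmHg)")
    ax.set_ylabel("Predicted − measured (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
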