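"""Method-comparison statistics: paired t-test, Pearson r, intensity labels.

Two administrations of the DEM test (e.g., printed card vs. VR headset) are
compared subject by subject with a paired t-test and with Pearson
correlation, the correlation strength being reported on a conventional
seven-level scale from "strongly negative" through "negligible" to
"strongly positive".  A Wilcoxon signed-rank alternative to the t-test is
available behind a flag for data that defy normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "pearson",
    "classify_intensity",
    "compare_methods",
    "INTENSITY_BINS",
]

ALPHA = 0.05

#: (|r| lower bound, label stem).  Bins are closed on the boundary nearer
#: zero and open on the boundary nearer +-1 (so r = 0.3 is already
#: "distinct", r = 0.7 already "strong"); the outermost bin includes +-1.
#: The sign of r picks the (+)/(-) variant; |r| < 0.1 is "negligible".
INTENSITY_BINS = (
    (0.7, "strongly"),
    (0.3, "distinctly"),
    (0.1, "weakly"),
)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    intensity: str


def _paired_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed")
    return x, y


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t-test on the differences ``x - y``.

    Identical pairs (zero-variance, zero-mean differences) are the
    no-evidence case and return t = 0, p = 1; zero-variance differences
    with a non-zero mean have no finite t statistic and raise.
    """
    x, y = _paired_arrays(x, y)
    n = x.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got n = {n}")
    d = x - y
    mean = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        raise ValueError("all differences identical and non-zero: t undefined")
    res = sps.ttest_rel(x, y)
    return PairedTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue), mean_diff=mean
    )


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Wilcoxon signed-rank alternative; statistic reported in ``t``."""
    x, y = _paired_arrays(x, y)
    n = x.size
    d = x - y
    if not np.any(d != 0):
        return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
    res = sps.wilcoxon(x, y)
    return PairedTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue),
        mean_diff=float(d.mean()),
    )


def classify_intensity(r: float) -> str:
    """Seven-level label for the strength of a linear relationship."""
    if not -1.0 <= r <= 1.0 or not np.isfinite(r):
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    mag = abs(r)
    for lo, stem in INTENSITY_BINS:
        if mag >= lo:
            sign = "positive" if r > 0 else "negative"
            return f"{stem} {sign}"
    return "negligible"


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p and an intensity label."""
    x, y = _paired_arrays(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"correlation needs n >= 3, got n = {n}")
    if float(x.std()) == 0.0 or float(y.std()) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(r=r, p=float(res.pvalue), n=n,
                             intensity=classify_intensity(r))


def compare_methods(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    *,
    method_names: tuple[str, str] = ("method_a", "method_b"),
    nonparametric: bool = False,
) -> pd.DataFrame:
    """Per-metric comparison of two methods over the same subjects.

    ``results_a`` and ``results_b`` are subject-by-metric tables with
    identical indices and columns (one row per subject).  The report holds
    one row per metric: mean and SD under each method, the paired test
    (t by default, Wilcoxon when ``nonparametric``), the Pearson r between
    methods with its intensity label, and a significance mark at p < 0.05.
    """
    if not results_a.index.equals(results_b.index):
        raise ValueError("subject sets (indices) differ between methods")
    if list(results_a.columns) != list(results_b.columns):
        raise ValueError("metric columns differ between methods")
    test = wilcoxon_signed_rank if nonparametric else paired_t
    na, nb = method_names
    rows = []
    for metric in results_a.columns:
        a = results_a[metric].to_numpy(dtype=float)
        b = results_b[metric].to_numpy(dtype=float)
        tt = test(a, b)
        if np.array_equal(a, b):
            corr_r, corr_p, intensity = 1.0, 0.0, classify_intensity(1.0)
        else:
            corr = pearson(a, b)
            corr_r, corr_p, intensity = corr.r, corr.p, corr.intensity
        rows.append({
            "metric": metric,
            f"mean_{na}": a.mean(), f"sd_{na}": a.std(ddof=1),
            f"mean_{nb}": b.mean(), f"sd_{nb}": b.std(ddof=1),
            "t": tt.t, "df": tt.df, "p": tt.p,
            "significant": tt.p < ALPHA,
            "r": corr_r, "r_p": corr_p, "intensity": intensity,
        })
    return pd.DataFrame(rows).set_index("metric")
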