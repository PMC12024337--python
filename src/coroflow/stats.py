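"""Paired pre/post statistics and agreement analysis.

Every index is compared pre vs post valve replacement with a paired test
whose form is gated on the distribution of the paired differences
(Shapiro–Wilk at alpha = 0.05: normal → paired t, otherwise Wilcoxon
signed-rank).  Agreement between modelled and invasively measured FFR is
summarized by a Bland–Altman analysis on percentage differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PairedTestResult:
    variable: str
    n: int
    mean_pre: float
    mean_post: float
    median_pre: float
    median_post: float
    delta_mean: float
    test_used: str          # {"paired_t", "wilcoxon"}
    statistic: float
    p_value: float

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class BlandAltmanResult:
    bias: float          # mean difference (percent by default)
    sd: float            # sample SD (n−1) of the differences
    loa_low: float
    loa_high: float
    pct_within_loa: float
    differences: np.ndarray = field(repr=False, default=None)
    means: np.ndarray = field(repr=False, default=None)


class DegenerateDataError(ValueError):
    """Constant non-zero paired differences: no admissible paired test."""


def paired_compare(x_pre, x_post, alpha: float = 0.05,
                   variable: str = "", force_test: str | None = None) -> PairedTestResult:
    """Distribution-gated paired comparison of two matched samples.

    All-zero differences return p = 1 under the sign-symmetry convention;
    constant non-zero differences raise :class:`DegenerateDataError`.
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape or x_pre.ndim != 1:
        raise ValueError("samples must be matching 1-D arrays")
    n = x_pre.size
    if n < 3:
        raise ValueError("paired comparison needs n >= 3")
    d = x_post - x_pre
    base = dict(variable=variable, n=n,
                mean_pre=float(x_pre.mean()), mean_post=float(x_post.mean()),
                median_pre=float(np.median(x_pre)), median_post=float(np.median(x_post)),
                delta_mean=float(d.mean()))
    if np.all(d == 0):
        return PairedTestResult(**base, test_used="none", statistic=0.0, p_value=1.0)
    if np.ptp(d) == 0:
        raise DegenerateDataError("paired differences are a non-zero constant")
    if force_test is None:
        normal = sps.shapiro(d).pvalue > alpha
        test = "paired_t" if normal else "wilcoxon"
    else:
        test = force_test
    if test == "paired_t":
        res = sps.ttest_rel(x_post, x_pre)
        return PairedTestResult(**base, test_used="paired_t",
                                statistic=float(res.statistic), p_value=float(res.pvalue))
    res = sps.wilcoxon(x_post, x_pre, zero_method="wilcox", method="auto")
    return PairedTestResult(**base, test_used="wilcoxon",
                            statistic=float(res.statistic), p_value=float(res.pvalue))


def wilcoxon_exact(differences) -> float:
    """Exact two-sided signed-rank p-value by full enumeration of the 2^n
    sign assignments (zero differences excluded first; ties get midranks).

    Exponential in n; intended as the small-sample oracle (n ≤ ~12).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n > 20:
        raise ValueError("enumeration limited to n <= 20")
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = 0
    le = 0
    ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        total += 1
        le += w <= w_obs
        ge += w >= w_obs
    p = 2.0 * min(le, ge) / total
    return float(min(p, 1.0))


def bland_altman(reference, test_values, mode: str = "percent") -> BlandAltmanResult:
    """Bland–Altman agreement of ``test_values`` against ``reference``.

    ``mode='percent'`` (default) analyses 100·(test − reference)/pair-mean;
    ``mode='absolute'`` analyses raw differences.  Limits of agreement are
    bias ± 1.96 × sample SD.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test_values, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1 or ref.size < 2:
        raise ValueError("need two matching 1-D arrays of length >= 2")
    means = (ref + tst) / 2.0
    if mode == "percent":
        if np.any(means == 0):
            raise ZeroDivisionError("pair mean of zero; percentage difference undefined")
        diffs = 100.0 * (tst - ref) / means
    elif mode == "absolute":
        diffs = tst - ref
    else:
        raise ValueError("mode must be 'percent' or 'absolute'")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi)))
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=lo, loa_high=hi,
                             pct_within_loa=within, differences=diffs, means=means)


#: variables reported in the paired pre/post tables, with printing precision
PAIRED_VARIABLES = [
    ("ffr", 3), ("ifr", 3), ("pd_pa_rest", 3), ("cfr", 3),
    ("q_rest", 2), ("q_hyper", 2), ("pa_mean", 1), ("pd_mean", 1),
    ("tawss_mean", 2), ("tawss_median", 2), ("osi_mean", 4), ("high_frac", 3),
]


def paired_table(cohort_df: pd.DataFrame, variables=None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Paired-comparison table over a tidy cohort frame.

    ``cohort_df`` must contain columns ``patient``, ``state`` ∈ {pre, post},
    and one column per variable.
    """
    variables = variables or [v for v, _ in PAIRED_VARIABLES
                              if v in cohort_df.columns]
    wide = cohort_df.pivot(index="patient", columns="state")
    rows = []
    for var in variables:
        pre = wide[(var, "pre")].to_numpy()
        post = wide[(var, "post")].to_numpy()
        ok = np.isfinite(pre) & np.isfinite(post)
        try:
            r = paired_compare(pre[ok], post[ok], alpha=alpha, variable=var)
        except DegenerateDataError:
            continue
        rows.append(dict(variable=var, n=r.n, mean_pre=r.mean_pre,
                         mean_post=r.mean_post, median_pre=r.median_pre,
                         median_post=r.median_post, delta_mean=r.delta_mean,
                         test=r.test_used, statistic=r.statistic,
                         p_value=r.p_value))
    return pd.DataFrame(rows)


def bland_altman_plot(result: BlandAltmanResult, path, title: str = "") -> None:
    """Write a Bland–Altman scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, color="#1f4e79")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="tab:blue", ls=":", lw=1.0)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (%)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
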