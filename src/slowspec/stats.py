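"""Paired tests, effect sizes, Holm-Bonferroni correction, and the
regression battery relating band power and clinical outcome to spectral
features.

Conventions throughout:

* differences are pre minus post, so treatment-related increases give
  negative deltas and negative t statistics;
* normality of the paired differences is gated by Shapiro-Wilk at 0.05 —
  normal data get a paired t test with Cohen's d_z, otherwise a Wilcoxon
  signed-rank test with Cliff's delta;
* the Wilcoxon statistic W is the smaller of the two signed rank sums,
  zero differences dropped; p is exact (tie-aware, computed from the
  full null distribution of W+) for n <= 25 and a continuity-corrected
  normal approximation above;
* Holm-Bonferroni ranks the family's p-values ascending and compares the
  k-th to alpha / (m - k + 1), rejecting step-down.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "HolmResult",
    "RegressionResult",
    "shapiro_gate",
    "paired_test",
    "cohens_dz",
    "cliffs_delta",
    "wilcoxon_signed_rank",
    "holm_bonferroni",
    "normalize_hamd",
    "remission_rate",
    "hc3_ols",
    "band_power_regression",
    "exhaustive_outcome_search",
    "electrode_topography_tests",
    "HAMD_MAX",
]

HAMD_MAX = {17: 52, 24: 76}

OUTCOME_CANDIDATES = [
    "exponent_pre",
    "delta_abundance_pre",
    "theta_abundance_pre",
    "exponent_diff",
    "delta_abundance_diff",
    "theta_abundance_diff",
    "n_treatments",
]


# --------------------------------------------------------------------------
# paired comparisons


@dataclass
class TestResult:
    name: str
    test: str                 # "paired_t" | "wilcoxon"
    statistic: float          # t or W
    n: int                    # pairs entering the test (nonzero for W)
    p: float
    effect_type: str          # "cohens_dz" | "cliffs_delta"
    effect: float
    descriptives: dict = field(default_factory=dict)


def shapiro_gate(diffs: np.ndarray, alpha: float = 0.05) -> str:
    """Choose the paired test from Shapiro-Wilk normality of differences."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 3:
        raise ValueError(f"need at least 3 paired differences, got {diffs.size}")
    if np.ptp(diffs) == 0:
        warnings.warn("constant differences; falling back to wilcoxon")
        return "wilcoxon"
    _w, p = sps.shapiro(diffs)
    return "paired_t" if p >= alpha else "wilcoxon"


def cohens_dz(diffs: np.ndarray) -> float:
    """Paired effect size: mean of differences over their SD (ddof=1)."""
    diffs = np.asarray(diffs, dtype=float)
    sd = np.std(diffs, ddof=1)
    if sd == 0:
        return 0.0 if np.mean(diffs) == 0 else np.inf * np.sign(np.mean(diffs))
    return float(np.mean(diffs) / sd)


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Dominance statistic over all cross pairs: in [-1, 1], positive when
    x tends to exceed y. Conventions: 0.147 small, 0.33 medium, 0.47 large."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float((np.sign(x - y)).mean())


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of |d| (average ties) and signs, zero differences dropped."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    return ranks, np.sign(d)


def _wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of W+ = sum of ranks with positive sign.

    Ranks are doubled so midranks from ties become integers; the pmf is
    built by the usual generating-polynomial recursion, valid with ties.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        pmf[r:] += pmf[: total + 1 - r]
    pmf /= pmf.sum()
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns (W, p, n_nonzero) where W = min(W+, W-). Exact tie-aware p
    for n <= 25; otherwise normal approximation with continuity and tie
    correction.
    """
    ranks, signs = _signed_ranks(diffs)
    n = ranks.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    w_plus = float(ranks[signs > 0].sum())
    total = float(ranks.sum())
    w = min(w_plus, total - w_plus)
    if n <= 25:
        support, pmf = _wplus_distribution(ranks)
        # W+ is symmetric about total/2 under H0, so double the small tail
        p = float(min(1.0, 2.0 * pmf[support <= w + 1e-9].sum()))
    else:
        mean = total / 2.0
        var = float((ranks**2).sum()) / 4.0
        z = (w - mean + 0.5) / np.sqrt(var)  # continuity toward the mean
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return w, p, n


def paired_test(
    pre: np.ndarray,
    post: np.ndarray,
    choice: str | None = None,
    name: str = "",
) -> TestResult:
    """Paired pre/post comparison on pre-minus-post differences.

    ``choice`` overrides the Shapiro-Wilk gate ("paired_t"/"wilcoxon").
    The t branch reports mean +/- sd and Cohen's d_z; the Wilcoxon branch
    reports median (IQR) and Cliff's delta over all cross pairs.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = pre - post
    if choice is None:
        choice = shapiro_gate(diffs)
    if choice == "paired_t":
        if np.ptp(diffs) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_rel(pre, post)
        return TestResult(
            name, "paired_t", float(stat), pre.size, float(p),
            "cohens_dz", cohens_dz(diffs),
            {
                "pre_mean": float(np.mean(pre)), "pre_sd": float(np.std(pre, ddof=1)),
                "post_mean": float(np.mean(post)), "post_sd": float(np.std(post, ddof=1)),
            },
        )
    if choice != "wilcoxon":
        raise ValueError(f"unknown test choice {choice!r}")
    if np.ptp(diffs) == 0 and diffs[0] == 0:
        warnings.warn("all differences zero; degenerate wilcoxon")
        w, p, n = 0.0, 1.0, 0
    else:
        w, p, n = wilcoxon_signed_rank(diffs)
    q = lambda a: tuple(float(v) for v in np.percentile(a, [50, 25, 75]))
    pre_md, pre_lo, pre_hi = q(pre)
    post_md, post_lo, post_hi = q(post)
    return TestResult(
        name, "wilcoxon", float(w), int(n), float(p),
        "cliffs_delta", cliffs_delta(pre, post),
        {
            "pre_median": pre_md, "pre_iqr": (pre_lo, pre_hi),
            "post_median": post_md, "post_iqr": (post_lo, post_hi),
        },
    )


# --------------------------------------------------------------------------
# multiple comparisons


@dataclass
class HolmResult:
    """Step-down Holm-Bonferroni decisions for one family of tests.

    ``table`` rows are in ascending-p order (ties keep the declared label
    order) with the rank-k threshold alpha / (m - k + 1); rejection stops
    at the first p exceeding its threshold. ``below_threshold`` is the
    per-rank comparison without the step-down stopping rule.
    """

    table: pd.DataFrame
    alpha: float

    def threshold(self, label: str) -> float:
        return float(self.table.set_index("label").loc[label, "threshold"])

    def rejected(self, label: str) -> bool:
        return bool(self.table.set_index("label").loc[label, "reject"])


def holm_bonferroni(
    pvals, labels: list[str] | None = None, alpha: float = 0.05
) -> HolmResult:
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if labels is None:
        labels = [f"test{i}" for i in range(pvals.size)]
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranks = np.arange(1, m + 1)
    thresholds = alpha / (m - ranks + 1)
    sorted_p = pvals[order]
    below = sorted_p <= thresholds
    reject = np.zeros(m, dtype=bool)
    for k in range(m):
        if not below[k]:
            break
        reject[k] = True
    table = pd.DataFrame(
        {
            "label": [labels[i] for i in order],
            "p": sorted_p,
            "rank": ranks,
            "threshold": thresholds,
            "reject": reject,
            "below_threshold": below,
        }
    )
    return HolmResult(table, alpha)


# --------------------------------------------------------------------------
# clinical scores


def normalize_hamd(raw: float, version: int) -> float:
    """Map a HAM-D score onto [0, 1]: (raw - 0) / (scale max - 0), with
    maxima 52 (17-item) and 76 (24-item)."""
    if version not in HAMD_MAX:
        raise ValueError(f"hamd version must be 17 or 24, got {version}")
    top = HAMD_MAX[version]
    if not 0 <= raw <= top:
        raise ValueError(f"HAMD-{version} score {raw} outside [0, {top}]")
    return float(raw) / top


def remission_rate(pre_scores, post_scores) -> float:
    """Percent of patients with >= 50% symptom decrease (pre > 0 required;
    zero-baseline patients are excluded with a warning)."""
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired scores required")
    ok = pre > 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} patient(s) with baseline 0")
    pre, post = pre[ok], post[ok]
    if pre.size == 0:
        raise ValueError("no patients with positive baseline")
    return float(100.0 * np.mean((pre - post) / pre >= 0.5))


# --------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series             # standard errors under cov_type
    conf_int: pd.DataFrame     # columns: lower, upper
    pvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    cov_type: str
    n: int


def _wrap(res, cov_type: str) -> RegressionResult:
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return RegressionResult(
        params=res.params,
        bse=pd.Series(np.asarray(res.bse), index=res.params.index),
        conf_int=ci,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        cov_type=cov_type,
        n=int(res.nobs),
    )


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    if np.any(np.diag(hat) > 1 - 1e-10):
        raise ValueError("leverage of 1 encountered; HC3 weights undefined")


def hc3_ols(y, X: pd.DataFrame, cov_type: str = "HC3") -> RegressionResult:
    """OLS with (by default) HC3 heteroskedasticity-consistent covariance.

    HC3 weights squared residuals by (1 - h_ii)^-2, the small-sample
    (n < 250) recommendation. A constant is added; the design must be
    full rank with all leverages < 1.
    """
    X = sm.add_constant(pd.DataFrame(X), has_constant="add")
    y = np.asarray(y, dtype=float)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    _check_design(X.to_numpy())
    model = sm.OLS(y, X)
    if cov_type == "standard":
        res = model.fit()
    else:  # inference on t with n - p dof
        res = model.fit(cov_type=cov_type, use_t=True)
    return _wrap(res, cov_type)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - np.mean(x)) / np.std(x, ddof=1)


def band_power_regression(
    features: pd.DataFrame, band: str, alpha: float = 0.05
) -> tuple[RegressionResult, HolmResult]:
    """Regress the band-power change on the exponent, abundance, and
    oscillation-power changes (all pre minus post, all z-scored).

    Only patients with the band's oscillation power defined at both
    timepoints (hence a finite delta) enter. The three main-effect
    p-values get Holm thresholds within the family (lowest 0.0167).
    """
    cols = [
        f"{band}_power_diff",
        "exponent_diff",
        f"{band}_abundance_diff",
        f"{band}_osc_diff",
    ]
    sub = features[cols].dropna()
    if len(sub) <= 5:
        raise ValueError(
            f"only {len(sub)} complete cases for the {band} regression; need > 5"
        )
    y = _zscore(sub[cols[0]].to_numpy())
    X = pd.DataFrame(
        {c: _zscore(sub[c].to_numpy()) for c in cols[1:]}, index=sub.index
    )
    _check_design(sm.add_constant(X, has_constant="add").to_numpy())
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    reg = _wrap(res, "standard")
    holm = holm_bonferroni(
        [reg.pvalues[c] for c in cols[1:]], cols[1:], alpha
    )
    return reg, holm


def exhaustive_outcome_search(
    features: pd.DataFrame,
    candidates: list[str] = OUTCOME_CANDIDATES,
    max_features: int | None = 1,
) -> tuple[tuple[str, ...], RegressionResult]:
    """Exhaustive feature search for the treatment-outcome model.

    Normalized post-treatment HAM-D is predicted from two fixed effects —
    normalized pre-treatment HAM-D and treatment type (ECT=0, MST=1) —
    plus subsets of ``candidates`` up to ``max_features`` (default 1
    added main effect, the form of the published outcome model; pass
    None to enumerate all non-empty subsets). The subset maximizing
    adjusted R^2 wins and is re-fit with HC3 covariance. Continuous
    variables are z-scored; the treatment indicator stays 0/1.

    ``features`` needs columns norm_hamd_pre, norm_hamd_post,
    treatment_code, and the candidates; incomplete rows are dropped.
    """
    needed = ["norm_hamd_post", "norm_hamd_pre", "treatment_code"] + list(candidates)
    sub = features[needed].dropna()
    y = _zscore(sub["norm_hamd_post"].to_numpy())
    fixed = pd.DataFrame(
        {
            "norm_hamd_pre": _zscore(sub["norm_hamd_pre"].to_numpy()),
            "treatment_code": sub["treatment_code"].to_numpy(dtype=float),
        },
        index=sub.index,
    )
    zcand = {
        c: (
            _zscore(sub[c].to_numpy())
            if sub[c].nunique() > 2
            else sub[c].to_numpy(dtype=float)
        )
        for c in candidates
    }
    best_subset, best_r2adj = None, -np.inf
    max_k = max_features or len(candidates)
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(candidates, k):
            X = fixed.assign(**{c: zcand[c] for c in subset})
            if len(sub) <= X.shape[1] + 1:
                continue  # more parameters than the data can support
            try:
                res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
            except Exception:
                continue
            if res.rsquared_adj > best_r2adj:
                best_r2adj, best_subset = float(res.rsquared_adj), subset
    if best_subset is None:
        raise ValueError("no candidate subset could be fit")
    X = fixed.assign(**{c: zcand[c] for c in best_subset})
    return best_subset, hc3_ols(y, X)


# --------------------------------------------------------------------------
# electrode-wise topography


def electrode_topography_tests(
    pre: pd.DataFrame, post: pd.DataFrame, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Per-electrode paired tests across patients (uncorrected p).

    ``pre``/``post``: patients x electrodes, NaN where an electrode was
    excluded for a patient. Electrodes missing in more than half the
    patients are flagged and skipped. Returns median pre-minus-post
    change, test used, statistic, p per electrode.
    """
    if list(pre.columns) != list(post.columns) or len(pre) != len(post):
        raise ValueError("pre and post must share patients and electrodes")
    if len(pre) < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for ch in pre.columns:
        pair = pd.concat([pre[ch], post[ch]], axis=1, keys=["pre", "post"]).dropna()
        if len(pair) < max(3, int(np.ceil(min_fraction * len(pre)))):
            rows.append(
                {"electrode": ch, "n": len(pair), "flagged": True,
                 "median_diff": np.nan, "test": "", "statistic": np.nan, "p": np.nan}
            )
            continue
        res = paired_test(pair["pre"].to_numpy(), pair["post"].to_numpy(), name=ch)
        rows.append(
            {
                "electrode": ch, "n": len(pair), "flagged": False,
                "median_diff": float(np.median(pair["pre"] - pair["post"])),
                "test": res.test, "statistic": res.statistic, "p": res.p,
            }
        )
    return pd.DataFrame(rows)
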