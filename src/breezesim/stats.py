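"""Nonparametric within-subject statistics for the three-condition study.

The analysis plan: per measure, descriptive summaries by condition
(mean/SD/median/IQR), a Friedman omnibus test across BASELINE / CIRCLE /
BREEZE, and — for measures whose omnibus p falls below alpha — the three
pairwise Wilcoxon signed-rank comparisons with rank-biserial correlation as
the effect size.  No multiple-testing correction is applied by default; a
Holm adjustment is available via a flag.  Cohen's kappa quantifies
inter-coder agreement on the qualitative feedback codes.

Signed-rank conventions: zero differences are excluded before ranking,
mid-ranks break ties in |d|, the reported W is min(W+, W-), p-values are
exact (full sign enumeration) for tie-free samples up to n = 20 and a
tie-corrected normal approximation without continuity correction otherwise,
and the rank-biserial correlation is (W+ - W-) / (W+ + W-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "ConditionSummary",
    "FriedmanResult",
    "WilcoxonResult",
    "AgreementResult",
    "AnalysisReport",
    "summarize_conditions",
    "friedman_test",
    "wilcoxon_signed_rank",
    "cohen_kappa",
    "run_analysis",
    "EXACT_N_MAX",
]


#: Largest tie-free sample for which the exact signed-rank null is enumerated.
EXACT_N_MAX = 20


@dataclass(frozen=True)
class ConditionSummary:
    """Descriptives for one measure in one condition."""

    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class FriedmanResult:
    q: float
    df: int
    p: float


@dataclass(frozen=True)
class WilcoxonResult:
    w: float
    p: float
    method: str  # "exact" | "normal_approx"
    rbc: float
    median_diff: float
    iqr_diff_low: float
    iqr_diff_high: float
    n_effective: int


@dataclass(frozen=True)
class AgreementResult:
    p_o: float
    kappa: float


def summarize_conditions(values: "pd.Series | np.ndarray") -> ConditionSummary:
    """Mean, sample SD, median and quartiles (linear interpolation).

    With a single observation the SD is undefined and reported as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else math.nan
    return ConditionSummary(
        mean=float(np.mean(x)), sd=sd,
        median=float(med), iqr_low=float(q1), iqr_high=float(q3),
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(x, method="average")


def friedman_test(data: np.ndarray) -> FriedmanResult:
    """Friedman omnibus test on an (n subjects x k conditions) array.

    Uses within-subject mid-ranks and the tie-corrected statistic

        Q = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    which reduces to the classical 12/(nk(k+1)) * sum R_j^2 - 3n(k+1) form
    when there are no ties; p comes from the chi-square with k - 1 df.
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("data must be 2-D with at least 2 conditions")
    n, k = a.shape
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    ranks = np.apply_along_axis(_midranks, 1, a)
    col_sums = ranks.sum(axis=0)
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if denom <= 0:  # every subject's row fully tied
        return FriedmanResult(q=0.0, df=k - 1, p=1.0)
    q = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom
    p = float(sp_stats.chi2.sf(q, k - 1))
    return FriedmanResult(q=q, df=k - 1, p=p)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by counting every sign assignment of the ranks.

    The null distribution of W+ is built by dynamic-programming convolution
    over the 2^n equally likely sign vectors (equivalent to full
    enumeration); p = 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    int_ranks = np.rint(ranks).astype(int)  # tie-free mid-ranks are integers
    total = int(int_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in int_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    continuity_correction: bool = False,
) -> WilcoxonResult:
    """Paired signed-rank test of x against y with effect size.

    See the module docstring for the zero-handling, tie, exactness and
    effect-size conventions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D samples (n >= 2)")
    d = x - y
    q1, med, q3 = np.percentile(d, [25, 50, 75])

    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    absd = np.abs(d)
    ranks = _midranks(absd)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    s = n * (n + 1) / 2.0
    w = min(w_plus, w_minus)
    rbc = (w_plus - w_minus) / s

    has_ties = len(np.unique(absd)) < n
    if not has_ties and n <= EXACT_N_MAX:
        method = "exact"
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        method = "normal_approx"
        mean_w = n * (n + 1) / 4.0
        _, tie_counts = np.unique(absd, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var_w <= 0:
            p = 1.0
        else:
            num = w_plus - mean_w
            if continuity_correction:
                num -= 0.5 * np.sign(num)
            z = num / math.sqrt(var_w)
            p = float(2.0 * sp_stats.norm.sf(abs(z)))
    return WilcoxonResult(
        w=w, p=min(p, 1.0), method=method, rbc=float(rbc),
        median_diff=float(med), iqr_diff_low=float(q1), iqr_diff_high=float(q3),
        n_effective=n,
    )


def cohen_kappa(codes_a, codes_b) -> AgreementResult:
    """Raw agreement and chance-corrected (Cohen) kappa of two coders.

    p_e is the product-of-marginals chance agreement; kappa is undefined
    (NaN) in the degenerate case p_e = 1.
    """
    a = list(codes_a)
    b = list(codes_b)
    if len(a) != len(b) or not a:
        raise ValueError("code sequences must be nonempty and equal length")
    n = len(a)
    p_o = sum(u == v for u, v in zip(a, b)) / n
    labels = sorted(set(a) | set(b), key=str)
    counts_a = {lab: a.count(lab) for lab in labels}
    counts_b = {lab: b.count(lab) for lab in labels}
    p_e = sum(counts_a[lab] * counts_b[lab] for lab in labels) / n**2
    kappa = math.nan if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(p_o=p_o, kappa=kappa)


# Pairwise comparisons in reporting order: (condition, reference).
PAIRWISE_ORDER = (("CIRCLE", "BASELINE"), ("BREEZE", "BASELINE"),
                  ("BREEZE", "CIRCLE"))


@dataclass(frozen=True)
class AnalysisReport:
    """Summaries, omnibus tests and (where warranted) pairwise comparisons."""

    summaries: pd.DataFrame     # measure x condition descriptives
    omnibus: pd.DataFrame       # measure -> Q, df, p
    pairwise: pd.DataFrame      # only measures with omnibus p < alpha
    alpha: float


def _holm(pvals: list[float]) -> list[float]:
    idx_valid = [i for i, p in enumerate(pvals) if not math.isnan(p)]
    m = len(idx_valid)
    order = sorted(idx_valid, key=lambda i: pvals[i])
    adj = [math.nan] * len(pvals)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def run_analysis(
    data: pd.DataFrame,
    alpha: float = 0.05,
    conditions: tuple[str, ...] = ("BASELINE", "CIRCLE", "BREEZE"),
    holm: bool = False,
) -> AnalysisReport:
    """Run the full statistical plan on a tidy measurement table.

    Parameters
    ----------
    data
        Tidy frame with columns ``measure``, ``subject``, ``condition``,
        ``value`` and no missing cells.
    alpha
        Omnibus significance level gating the pairwise comparisons.
    holm
        Apply a Holm step-down adjustment within each measure's three
        pairwise p-values (off by default).
    """
    required = {"measure", "subject", "condition", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")

    sum_rows, omni_rows, pair_rows = [], [], []
    for measure, grp in data.groupby("measure", sort=False):
        wide = grp.pivot(index="subject", columns="condition", values="value")
        missing = [c for c in conditions if c not in wide.columns]
        if missing or wide[list(conditions)].isna().any().any():
            raise ValueError(
                f"incomplete design for measure {measure!r}: "
                f"missing {missing or 'cells'}"
            )
        wide = wide[list(conditions)]

        for cond in conditions:
            s = summarize_conditions(wide[cond].to_numpy())
            sum_rows.append({"measure": measure, "condition": cond, **vars(s)})

        fr = friedman_test(wide.to_numpy())
        omni_rows.append(
            {"measure": measure, "q": fr.q, "df": fr.df, "p": fr.p,
             "significant": fr.p < alpha}
        )

        if fr.p < alpha:
            results = []
            for cond, ref in PAIRWISE_ORDER:
                a, b = wide[cond].to_numpy(), wide[ref].to_numpy()
                try:
                    wr = wilcoxon_signed_rank(a, b)
                except ValueError:
                    # all paired differences zero: nothing to rank
                    wr = WilcoxonResult(
                        w=math.nan, p=math.nan, method="degenerate",
                        rbc=math.nan, median_diff=0.0, iqr_diff_low=0.0,
                        iqr_diff_high=0.0, n_effective=0,
                    )
                results.append((cond, ref, wr))
            pvals = [wr.p for _, _, wr in results]
            adj = _holm(pvals) if holm else pvals
            for (cond, ref, wr), p_adj in zip(results, adj):
                pair_rows.append(
                    {
                        "measure": measure, "condition": cond,
                        "reference": ref,
                        "median_diff": wr.median_diff,
                        "iqr_diff_low": wr.iqr_diff_low,
                        "iqr_diff_high": wr.iqr_diff_high,
                        "w": wr.w, "p": p_adj, "method": wr.method,
                        "rbc": wr.rbc, "n_effective": wr.n_effective,
                    }
                )

    pairwise_cols = ["measure", "condition", "reference", "median_diff",
                     "iqr_diff_low", "iqr_diff_high", "w", "p", "method",
                     "rbc", "n_effective"]
    return AnalysisReport(
        summaries=pd.DataFrame(sum_rows),
        omnibus=pd.DataFrame(omni_rows),
        pairwise=pd.DataFrame(pair_rows, columns=pairwise_cols),
        alpha=alpha,
    )
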