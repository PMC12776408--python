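"""Nonparametric statistical framework and dataset/group accounting.

Rank tests (Kruskal–Wallis, Wilcoxon signed-rank, Mann–Whitney U) delegate
to scipy with the tie policies fixed here (mid-ranks everywhere, zero
differences dropped); Dunn's post-hoc test with Bonferroni correction is
implemented directly from pooled ranks.  Exact small-sample p-values are
used below the stated switchover sizes (Wilcoxon n <= 12, Mann–Whitney
min(n) <= 8 without ties), normal approximations above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .core import SpatiodynError

WILCOXON_EXACT_MAX_N = 12
MWU_EXACT_MAX_N = 8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    adjusted: bool = False
    p_raw: float | None = None
    defined: bool = True
    comparison: tuple[int, int] | None = None   # group indices, for post-hoc


def _undefined(method: str, n: tuple[int, ...]) -> TestResult:
    return TestResult(statistic=math.nan, p_value=math.nan, method=method,
                      n=n, defined=False)


def kruskal_wallis(groups: list) -> TestResult:
    """Rank-based H test with tie correction, chi-square p at k−1 df.

    All-identical pooled data (H degenerate through the tie correction)
    returns H = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise SpatiodynError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise SpatiodynError("empty group")
    ns = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis",
                          n=ns)
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p),
                      method="kruskal-wallis", n=ns)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired signed-rank test; zero differences dropped; exact two-sided p
    for n <= 12 non-zero pairs, normal approximation above.

    All-zero differences yield an undefined-result marker (defined=False).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) == 0:
        raise SpatiodynError("paired samples must have equal nonzero length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    n = len(nonzero)
    if n == 0:
        return _undefined("wilcoxon-signed-rank", (len(x),))
    method = "exact" if n <= WILCOXON_EXACT_MAX_N else "approx"
    stat, p = sps.wilcoxon(nonzero, zero_method="wilcox",
                           alternative="two-sided", method=method)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method=f"wilcoxon-signed-rank-{method}", n=(n,))


def mann_whitney(x, y) -> TestResult:
    """Two-sample U test; exact p for min(n) <= 8 on tie-free data,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise SpatiodynError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(x), len(y)) <= MWU_EXACT_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method=f"mann-whitney-{method}", n=(len(x), len(y)))


def dunn_bonferroni(groups: list) -> list[TestResult]:
    """Dunn's post-hoc z tests on pooled mid-ranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))
    with T = Σ(t³ − t) over tie groups; adjusted p = min(1, m · p_raw) with
    m = k(k−1)/2 comparisons.  ``p_value`` is the adjusted p; the raw p is
    kept in ``p_raw``.
    """
    k = len(groups)
    if k < 3:
        raise SpatiodynError(
            "Dunn's test is a post-hoc for >= 3 groups; use mann_whitney"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise SpatiodynError("empty group")
    ns = [len(a) for a in arrays]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)   # mid-ranks
    mean_ranks = []
    offset = 0
    for n in ns:
        mean_ranks.append(ranks[offset:offset + n].mean())
        offset += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    m = k * (k - 1) // 2
    results: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            se_sq = base_var * (1.0 / ns[i] + 1.0 / ns[j])
            if se_sq <= 0:        # fully tied data: no evidence of difference
                z, p_raw = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se_sq)
                p_raw = 2.0 * sps.norm.sf(abs(z))
            results.append(TestResult(
                statistic=float(z), p_value=min(1.0, m * p_raw),
                method="dunn-bonferroni", n=(ns[i], ns[j]),
                adjusted=True, p_raw=float(p_raw), comparison=(i, j),
            ))
    return results


@dataclass
class GroupDelineation:
    """Accounting for one dataset's division into independent groups."""

    dataset_name: str
    n_groups: int
    subjects_per_group: int
    scans_per_group: int
    tr: float                       # seconds
    timepoints_per_scan: int
    total_scans: int
    scan_time_per_group: float      # hours, 2 decimals
    total_timepoints: int
    total_hours: float              # hours, 2 decimals
    resampled_trs: list[float]


def _hours(n_samples: int, tr: float) -> float:
    """Exact-decimal hour conversion rounded half-up to 2 decimals."""
    seconds = Decimal(n_samples) * Decimal(str(tr))
    hours = seconds / Decimal(3600)
    return float(hours.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def delineate_groups(dataset_name: str, n_groups: int, subjects_per_group: int,
                     scans_per_group: int, tr: float, timepoints_per_scan: int,
                     total_scans: int | None = None,
                     k_max: int = 5) -> GroupDelineation:
    """Compute per-group and total scan-time accounting plus the resampled
    TR ladder {k·tr : k = 2..k_max}.

    ``total_scans`` defaults to n_groups × scans_per_group but can differ
    when the delineation uses only a subset of the available scans.
    """
    if min(n_groups, subjects_per_group, scans_per_group,
           timepoints_per_scan) <= 0 or tr <= 0:
        raise SpatiodynError("all delineation inputs must be positive")
    if total_scans is None:
        total_scans = n_groups * scans_per_group
    if total_scans <= 0:
        raise SpatiodynError("total_scans must be positive")
    total_timepoints = total_scans * timepoints_per_scan
    return GroupDelineation(
        dataset_name=dataset_name,
        n_groups=n_groups,
        subjects_per_group=subjects_per_group,
        scans_per_group=scans_per_group,
        tr=tr,
        timepoints_per_scan=timepoints_per_scan,
        total_scans=total_scans,
        scan_time_per_group=_hours(scans_per_group * timepoints_per_scan, tr),
        total_timepoints=total_timepoints,
        total_hours=_hours(total_timepoints, tr),
        resampled_trs=[round(k * tr, 10) for k in range(2, k_max + 1)],
    )
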