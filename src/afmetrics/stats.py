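"""Group-level statistics: rank tests, medians, taxon heat maps.

Comparisons between species groups (e.g. ORC6-positive vs ORC6-negative)
use the two-tailed Mann-Whitney U test, exact for small samples and via
the tie-corrected normal approximation otherwise, with p values reported
to four decimal places. Missing values — a species whose interface pAE
could not be calculated because no interface formed — are dropped
listwise, never imputed.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from afmetrics.types import InterfaceScore

__all__ = [
    "mann_whitney",
    "group_medians",
    "taxon_heatmap",
    "classification_report",
    "EXACT_MAX_N",
]

#: exact enumeration is used when the smaller group has at most this many values
EXACT_MAX_N = 8


def _exact_two_tailed_p(doubled_ranks: list[int], n1: int, u2_obs: int) -> float:
    """Exact two-tailed p over all equally likely group-a assignments.

    Dynamic programme over the doubled midranks (doubling makes tied
    midranks integral): counts, for every achievable doubled rank sum, the
    number of n1-subsets attaining it, giving the exact permutation
    distribution of U under the null.
    """
    max_sum = sum(doubled_ranks)
    # dp[j] maps doubled rank sum -> count of j-subsets
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in doubled_ranks:
        for j in range(min(n1, len(dp)) - 1, -1, -1):
            if not dp[j]:
                continue
            target = dp[j + 1]
            for s, c in dp[j].items():
                target[s + r] = target.get(s + r, 0) + c
    dist = dp[n1]
    total = sum(dist.values())
    offset = n1 * (n1 + 1)  # doubled n1(n1+1)/2
    le = sum(c for s, c in dist.items() if s - offset <= u2_obs)
    ge = sum(c for s, c in dist.items() if s - offset >= u2_obs)
    return min(1.0, 2.0 * min(le, ge) / total)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic for ``group_a`` (number of
    (a, b) pairs with a ranked above b, ties counted half) and p is the
    two-tailed p value rounded to four decimal places. Ties get midranks.
    The exact permutation distribution is enumerated when the smaller
    group has at most 8 values; larger samples use the normal
    approximation with tie and continuity corrections.
    """
    a = [float(x) for x in group_a if not math.isnan(float(x))]
    b = [float(x) for x in group_b if not math.isnan(float(x))]
    if not a or not b:
        raise ValueError("both groups must contain at least one value")
    n1, n2 = len(a), len(b)
    combined = a + b
    ranks = rankdata(combined)  # midranks
    r_a = float(np.sum(ranks[:n1]))
    u_a = r_a - n1 * (n1 + 1) / 2.0

    if min(n1, n2) <= EXACT_MAX_N:
        doubled = [int(round(2 * r)) for r in ranks]
        p = _exact_two_tailed_p(doubled, n1, int(round(2 * r_a)) - n1 * (n1 + 1))
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_counts = Counter(combined).values()
        tie_term = sum(t**3 - t for t in tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * float(norm.sf(z)))
    return u_a, round(p, 4)


def group_medians(
    values: Mapping[str, Optional[float]], grouping: Mapping[str, str]
) -> dict[str, tuple[Optional[float], int]]:
    """Per-group median and n over non-missing values.

    ``values`` maps species to a metric value or None/NaN (missing);
    ``grouping`` maps species to a group label. A group whose values are
    all missing reports ``(None, 0)``.
    """
    pools: dict[str, list[float]] = defaultdict(list)
    for species, group in grouping.items():
        v = values.get(species)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        pools[group].append(float(v))
    out: dict[str, tuple[Optional[float], int]] = {}
    for group in set(grouping.values()):
        pool = pools.get(group, [])
        out[group] = (float(np.median(pool)) if pool else None, len(pool))
    return out


def taxon_heatmap(
    calls: Mapping[str, Optional[str]],
    taxon_of: Mapping[str, str],
    categories: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-taxon-group percentage of species in each category.

    Returns a DataFrame indexed by taxon group with one percentage column
    per category plus an ``n`` column, and the list of groups with no
    data (``n.d.``), which are omitted from the frame. Rows sum to 100
    within rounding. Species with a missing call do not count toward
    their group.
    """
    if categories is None:
        categories = sorted({c for c in calls.values() if c is not None})
    counts: dict[str, Counter] = defaultdict(Counter)
    for species, group in taxon_of.items():
        call = calls.get(species)
        if call is None:
            continue
        counts[group][call] += 1
    rows = []
    nd_groups = []
    for group in sorted(set(taxon_of.values())):
        n = sum(counts[group].values())
        if n == 0:
            nd_groups.append(group)
            continue
        row = {"taxon_group": group, "n": n}
        for cat in categories:
            row[cat] = round(100.0 * counts[group][cat] / n, 1)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["taxon_group", "n", *categories])
    if not df.empty:
        df = df.set_index("taxon_group")
    return df, nd_groups


def classification_report(
    scores: Iterable[InterfaceScore], truth: Mapping[str, bool]
) -> dict[str, int]:
    """Confusion counts of confident calls against fixture ground truth.

    ``truth`` maps target_id to whether a real (consistent, confident)
    interface was generated for that target.
    """
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for score in scores:
        actual = truth[score.target_id]
        if score.confident and actual:
            counts["tp"] += 1
        elif score.confident and not actual:
            counts["fp"] += 1
        elif not score.confident and actual:
            counts["fn"] += 1
        else:
            counts["tn"] += 1
    return counts
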