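"""Explicit statistical primitives: Fisher z comparison of two correlations,
misincorporation log-odds with chi-square/FDR, and rank-sum tests.

The rank tests enumerate the exact null distribution for small pooled sample
sizes (n1 + n2 ≤ 12) and otherwise use the normal approximation with tie and
continuity corrections, so results are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 12


@dataclass(frozen=True)
class CorrelationComparison:
    """Independent-samples comparison of two Pearson correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p_two_sided: float


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher z test for the difference of two independent correlations.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)), two-sided normal p.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError(f"|r| must be < 1 (got {r})")
    for n in (n1, n2):
        if n < 4:
            raise ValueError(f"sample size must be ≥ 4 (got {n})")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return CorrelationComparison(r1, n1, r2, n2, z, min(p, 1.0))


@dataclass(frozen=True)
class ModificationComparisonRow:
    """Misincorporation odds between two conditions at one tRNA site."""

    log_odds: float
    chi2_p: float


def modification_log_odds(a: int, c: int, b: int, d: int) -> ModificationComparisonRow:
    """Natural-log odds ratio of misincorporation proportions between conditions.

    ``a``/``c`` are misincorporation count and coverage in condition 1,
    ``b``/``d`` in condition 2.  The 2×2 table contrasts misincorporated vs
    read-through events; zero cells get the Haldane–Anscombe 0.5 correction.
    The p-value is a chi-square test with Yates continuity correction.
    """
    if not (0 <= a <= c and 0 <= b <= d):
        raise ValueError("misincorporation counts must not exceed coverage")
    if c <= 0 or d <= 0:
        raise ValueError("coverage must be positive")
    cells = [a, c - a, b, d - b]
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    a1, a2, b1, b2 = cells
    log_odds = math.log((a1 / a2) / (b1 / b2))
    table = np.array([[a, c - a], [b, d - b]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        p = 1.0  # degenerate margin: no information against equality
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=True)
    return ModificationComparisonRow(log_odds, p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values (monotone, ≤ 1; equals p when m = 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def modification_comparison(
    sites: pd.DataFrame,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Log odds, chi-square p, BH q and significance flag per modified site.

    ``sites`` needs columns transcript, position, misinc_1, coverage_1,
    misinc_2, coverage_2; a site is significant at q ≤ ``q_threshold``.
    """
    required = {"transcript", "position", "misinc_1", "coverage_1", "misinc_2", "coverage_2"}
    if not required.issubset(sites.columns):
        raise ValueError(f"sites table needs columns {sorted(required)}")
    rows = [
        modification_log_odds(int(r.misinc_1), int(r.coverage_1),
                              int(r.misinc_2), int(r.coverage_2))
        for r in sites.itertuples(index=False)
    ]
    out = sites.copy()
    out["log_odds"] = [r.log_odds for r in rows]
    out["p"] = [r.chi2_p for r in rows]
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] <= q_threshold
    return out


def read_modification_tsv(path, condition_1: str, condition_2: str) -> pd.DataFrame:
    """Read a long-format site table (transcript, position, misinc, coverage,
    condition) and pivot it to the wide layout ``modification_comparison`` uses."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript", "position", "misinc", "coverage", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"modification TSV needs columns {sorted(required)}")
    wide = None
    for i, cond in enumerate((condition_1, condition_2), start=1):
        sub = df[df["condition"] == cond].rename(
            columns={"misinc": f"misinc_{i}", "coverage": f"coverage_{i}"}
        )[["transcript", "position", f"misinc_{i}", f"coverage_{i}"]]
        wide = sub if wide is None else wide.merge(sub, on=["transcript", "position"])
    if wide is None or wide.empty:
        raise ValueError("no sites shared between the two conditions")
    return wide


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U1 = #{(i,j): x_i > y_j} + 0.5·#{ties}, the standard Mann–Whitney form."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all pooled-group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        us.append(_mann_whitney_u(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    total = len(us)
    lower = np.sum(us <= u_obs + 1e-12) / total
    upper = np.sum(us >= u_obs - 1e-12) / total
    return min(1.0, 2 * min(lower, upper))


def rank_tests(
    x: Sequence[float],
    y: Sequence[float],
    kind: str = "mann_whitney",
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U / Wilcoxon rank-sum test.

    Exact enumeration over all C(n1+n2, n1) group assignments when
    n1 + n2 ≤ 12; otherwise normal approximation with midrank tie correction
    and 0.5 continuity correction.  Returns (statistic, p): the U statistic
    of ``x`` for ``kind='mann_whitney'`` or the rank sum of ``x`` for
    ``kind='wilcoxon_ranksum'`` (the p-value is identical).
    """
    if kind not in ("mann_whitney", "wilcoxon_ranksum"):
        raise ValueError(f"unknown test kind {kind!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xa.size, ya.size
    u = _mann_whitney_u(xa, ya)
    # W = rank sum of x; U1 = W − n1(n1+1)/2 with midranks
    w = u + n1 * (n1 + 1) / 2

    if n1 + n2 <= EXACT_LIMIT:
        p = _exact_two_sided_p(xa, ya, u)
    else:
        pooled = np.concatenate([xa, ya])
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts)
        mu = n1 * n2 / 2
        var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0  # all observations identical
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2 * sps.norm.sf(z))

    stat = u if kind == "mann_whitney" else w
    return float(stat), float(p)
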