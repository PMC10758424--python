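"""Edge-wise group comparison of causal connectomes and power analysis.

Given subject-level CFC graphs from two or more clinical groups, each
detected edge's weight distributions are compared with Welch's t-test (a
subject lacking the edge contributes weight 0), edges are ranked by
one-sided p-value, and the lowest-p edges reported.  No multiple-testing
correction is applied to the ranking — it is an exploratory screen; the
Bonferroni correction enters only the companion power/sample-size
computation, which asks how many subjects per group a confirmatory study
would need to detect a small standardised effect on every tested edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDataError
from .graphs import RolledCFC

__all__ = [
    "SubjectCFCSet",
    "PowerResult",
    "edge_density",
    "collect_edge_weights",
    "welch_t_test",
    "edgewise_comparison",
    "top_k_edges",
    "required_sample_size",
]

#: Column order of an edge-statistics table.
EDGE_STATS_COLUMNS = (
    "source",
    "target",
    "mean_g1",
    "mean_g2",
    "t",
    "df",
    "p",
    "n_g1_present",
    "n_g2_present",
)


@dataclass(frozen=True)
class SubjectCFCSet:
    """Subject-level CFC graphs with group labels, on a common region set."""

    entries: tuple[tuple[str, str, RolledCFC], ...]  # (subject id, group, cfc)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("at least one subject is required")
        labels = {cfc.region_labels for _, _, cfc in self.entries}
        if len(labels) > 1:
            raise ValueError("all CFCs must share the same region labels/order")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def region_labels(self) -> tuple[str, ...]:
        return self.entries[0][2].region_labels

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, g, _ in self.entries:
            seen.setdefault(g)
        return tuple(seen)

    def in_group(self, group: str) -> list[tuple[str, RolledCFC]]:
        out = [(sid, cfc) for sid, g, cfc in self.entries if g == group]
        if not out:
            raise KeyError(f"unknown group {group!r}")
        return out


def edge_density(graph: RolledCFC, include_self_loops: bool = True) -> float:
    """Edges as a fraction of the fully connected directed graph.

    The denominator is ``N**2`` when self-loops count (the default — rolled
    CFCs contain self-loops) and ``N * (N - 1)`` otherwise; an empty graph
    has density 0, a fully connected one density 1.
    """
    n = graph.n_regions
    if n < 1:
        raise ValueError("graph must have at least one region")
    denom = n * n if include_self_loops else n * (n - 1)
    edges = graph.edge_set()
    if not include_self_loops:
        edges = {e for e in edges if e[0] != e[1]}
    if denom == 0:
        return 0.0
    return len(edges) / denom


def collect_edge_weights(
    cfcs: SubjectCFCSet,
    edge: tuple[str, str],
    groups: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject weight vectors for one edge in two groups.

    Subjects lacking the edge contribute weight 0 (absence is a zero-strength
    connection, not missing data); order is stable by subject id.
    """
    src, tgt = edge
    labels = cfcs.region_labels
    if src not in labels or tgt not in labels:
        raise KeyError(f"unknown region in edge {edge!r}")
    out = []
    for g in groups:
        members = sorted(cfcs.in_group(g), key=lambda e: e[0])
        out.append(np.array([cfc.weight(src, tgt) for _, cfc in members]))
    return out[0], out[1]


def welch_t_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, p)``.

    ``alternative="greater"`` tests mean(x) > mean(y).  Both samples
    constant and equal is degenerate (no test possible); both constant but
    unequal yields ``t = +/-inf, p -> 0 or 1`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            raise DegenerateDataError(
                "both samples constant and equal; Welch test undefined"
            )
        t = math.inf if x.mean() > y.mean() else -math.inf
        df = float(x.size + y.size - 2)
        if alternative == "two-sided":
            p = 0.0
        elif alternative == "greater":
            p = 0.0 if t > 0 else 1.0
        else:
            p = 0.0 if t < 0 else 1.0
        return t, df, p
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    se2 = vx / x.size + vy / y.size
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def edgewise_comparison(
    cfcs: SubjectCFCSet,
    g1: str,
    g2: str,
    direction: str = "g1>g2",
) -> pd.DataFrame:
    """Welch t-test per detected edge, ranked by ascending one-sided p.

    Iterates over the union of edges detected in at least one subject of the
    two groups; ``direction="g1>g2"`` tests greater mean weight in ``g1``.
    Ties in p are broken lexicographically by (source, target).  Edges whose
    weight vectors are constant and equal in both groups carry no
    comparative information and are omitted.
    """
    if direction not in ("g1>g2", "g2>g1"):
        raise ValueError("direction must be 'g1>g2' or 'g2>g1'")
    m1, m2 = cfcs.in_group(g1), cfcs.in_group(g2)
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError("need at least 2 subjects per group")
    edges: set[tuple[str, str]] = set()
    for _, cfc in m1 + m2:
        edges |= cfc.edge_set()
    rows = []
    for src, tgt in sorted(edges):
        x, y = collect_edge_weights(cfcs, (src, tgt), (g1, g2))
        alt_x, alt_y = (x, y) if direction == "g1>g2" else (y, x)
        try:
            t, df, p = welch_t_test(alt_x, alt_y, alternative="greater")
        except DegenerateDataError:
            continue
        rows.append(
            {
                "source": src,
                "target": tgt,
                "mean_g1": float(x.mean()),
                "mean_g2": float(y.mean()),
                "t": t,
                "df": df,
                "p": p,
                "n_g1_present": int(np.count_nonzero(x)),
                "n_g2_present": int(np.count_nonzero(y)),
            }
        )
    table = pd.DataFrame(rows, columns=list(EDGE_STATS_COLUMNS))
    table = table.sort_values(
        ["p", "source", "target"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def top_k_edges(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """First ``k`` rows of a (sorted) edge-statistics table."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return table.head(k).reset_index(drop=True)


@dataclass(frozen=True)
class PowerResult:
    """Sample-size requirement for a Bonferroni-corrected edge-wise family.

    ``n_exact`` is the fractional per-group size solving the power equation;
    ``n_per_group`` and ``n_total`` are its whole-subject reports (nearest
    integer; ``n_total`` rounds ``n_groups * n_exact``).
    """

    n_per_group: int
    n_total: int
    n_exact: float
    alpha_per_test: float
    power_per_test: float
    n_groups: int


def _power_two_sample(n: float, d: float, alpha: float, df: float) -> float:
    """Two-sided two-sample t-test power at per-group size n (noncentral t)."""
    if df <= 1:
        return 0.0
    q = stats.t.isf(alpha / 2, df)
    ncp = d * math.sqrt(n / 2.0)
    upper = stats.nct.sf(q, df, ncp)
    lower = stats.nct.cdf(-q, df, ncp)  # wrong-tail rejections, ~0
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        raise ValueError(f"power evaluation failed at n={n}")
    return float(upper + lower)


def required_sample_size(
    cohens_d: float,
    n_tests: int,
    fwer: float = 0.05,
    family_power: float = 0.95,
    n_groups: int = 2,
) -> PowerResult:
    """Per-group sample size for family-wise power over ``n_tests`` edges.

    Both error rates are budgeted by union (Bonferroni-type) bounds: the
    per-test significance is ``fwer / n_tests`` (two-sided) and the per-test
    type-II error is ``(1 - family_power) / n_tests``, which guarantees the
    family-wise power without an independence assumption.  Power is
    evaluated with the noncentral-t distribution for a two-sample comparison
    at effect size ``cohens_d``, with residual degrees of freedom pooled
    over all groups in the design, ``df = n_groups * (n - 1)``.
    """
    if not 0 < fwer < 1 or not 0 < family_power < 1:
        raise ValueError("fwer and family_power must be in (0, 1)")
    if cohens_d <= 0:
        raise ValueError("cohens_d must be positive")
    if n_tests < 1 or n_groups < 2:
        raise ValueError("n_tests must be >= 1 and n_groups >= 2")
    alpha = fwer / n_tests
    power = 1.0 - (1.0 - family_power) / n_tests
    if power <= alpha:
        raise ValueError("requested power not above per-test significance")

    def gap(n: float) -> float:
        return _power_two_sample(n, cohens_d, alpha, n_groups * (n - 1)) - power

    lo, hi = 2.0, 16.0
    if gap(lo) >= 0:  # already powered at the minimum viable group size
        return PowerResult(2, 2 * n_groups, 2.0, alpha, power, n_groups)
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e8:
            raise ValueError("no feasible sample size below 1e8")
    n_exact = float(optimize.brentq(gap, lo, hi, xtol=1e-6))
    return PowerResult(
        n_per_group=int(round(n_exact)),
        n_total=int(round(n_groups * n_exact)),
        n_exact=n_exact,
        alpha_per_test=alpha,
        power_per_test=power,
        n_groups=n_groups,
    )
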