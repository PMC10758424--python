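"""Time-aware PC: causal discovery on multivariate time series.

The method lifts a stationary multi-region series into *sequential samples*
over lagged copies of each region (offsets ``0..tau``), runs the PC
algorithm (stable variant) with Fisher-z partial-correlation tests to
estimate an *unrolled* DAG over ``(region, offset)`` nodes, orients edges
using temporal background knowledge (time precedes effect) plus v-structure
detection and Meek rules, attaches signed regression weights, and finally
*rolls* the DAG into a region-level directed graph — the subject's causal
functional connectome.  Contemporaneous (same-offset) causal edges are
first-class citizens: at fMRI sampling rates much slower than neural
causation, true causal effects often appear within a single sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import CollinearityError, DegenerateDataError, OrientationError
from .graphs import RolledCFC
from .timeseries import ROITimeSeries

__all__ = [
    "TPCParams",
    "SequentialSamples",
    "UnrolledDAG",
    "build_sequential_samples",
    "FisherZ",
    "ci_test_fisher_z",
    "pc_skeleton",
    "orient_unrolled",
    "estimate_edge_weights",
    "roll_cfc",
    "run_tpc",
]

Variable = tuple[str, int]  # (region label, time offset)
CITest = Callable[..., tuple[bool, float]]

UNDIRECTED_POLICIES = ("both-directions", "drop")


@dataclass(frozen=True)
class TPCParams:
    """Tuning knobs of the time-aware PC procedure.

    tau
        Maximum time delay of interaction, in samples (``tau = 1`` at a 3 s
        TR allows causal delays up to 3 s; ``tau = 0`` reduces to static PC).
    alpha_ci
        Significance level of the conditional-independence tests.  Smaller
        values give sparser graphs; for series of ~1000 samples 0.01 is a
        good operating point, the default 0.05 is more liberal.
    max_cond_size
        Optional cap on the conditioning-set size of the skeleton search.
    undirected_policy
        What to do with contemporaneous edges the orientation rules leave
        undirected: ``"both-directions"`` keeps both orientations in the
        rolled graph (agnostic), ``"drop"`` discards them (conservative).
    """

    tau: int = 1
    alpha_ci: float = 0.05
    max_cond_size: int | None = None
    undirected_policy: str = "both-directions"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 < self.alpha_ci < 1:
            raise ValueError("alpha_ci must be in (0, 1)")
        if self.undirected_policy not in UNDIRECTED_POLICIES:
            raise ValueError(
                f"undirected_policy must be one of {UNDIRECTED_POLICIES}"
            )


@dataclass(frozen=True)
class SequentialSamples:
    """Lagged design matrix: one row per time window, one column per
    (region, offset) variable."""

    variables: tuple[Variable, ...]
    data: np.ndarray
    region_labels: tuple[str, ...]
    tau: int

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def index(self, var: Variable) -> int:
        try:
            return self.variables.index(var)
        except ValueError:
            raise KeyError(f"unknown variable {var!r}") from None


@dataclass(frozen=True)
class UnrolledDAG:
    """Spatio-temporal causal structure over (region, offset) nodes.

    The *directed* part is acyclic and never points backward in time.
    Contemporaneous edges the orientation rules could not direct are kept in
    ``undirected`` and expanded only when rolling, according to the
    configured policy, so the DAG invariants stay intact.
    """

    nodes: tuple[Variable, ...]
    directed: frozenset[tuple[Variable, Variable]]
    undirected: frozenset[frozenset]
    sepsets: Mapping[frozenset, frozenset] = field(default_factory=dict)
    weights: Mapping[tuple[Variable, Variable], float] = field(default_factory=dict)
    undirected_policy: str = "both-directions"

    def __post_init__(self) -> None:
        for u, v in self.directed:
            if u[1] > v[1]:
                raise OrientationError(f"backward-in-time edge {u} -> {v}")
        g = nx.DiGraph(list(self.directed))
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OrientationError(f"directed part contains a cycle: {cycle}")

    def parents(self, node: Variable) -> list[Variable]:
        ps = [u for (u, v) in self.directed if v == node]
        if self.undirected_policy == "both-directions":
            ps += [
                next(iter(pair - {node}))
                for pair in self.undirected
                if node in pair
            ]
        return sorted(ps, key=lambda x: (x[1], x[0]))


# ---------------------------------------------------------------------------
# sequential samples


def build_sequential_samples(ts: ROITimeSeries, tau: int = 1) -> SequentialSamples:
    """Lift a length-T series into T - tau overlapping windows.

    Sample ``i`` assigns variable ``(v, s)`` the value of region ``v`` at
    time ``i + s`` (stride 1).  Variables are ordered offset-major:
    all regions at offset 0, then offset 1, ...
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    T = ts.n_timepoints
    if T < tau + 2:
        raise ValueError(f"series of length {T} too short for tau={tau}")
    n = ts.n_regions
    blocks = [ts.values[s : T - tau + s, :] for s in range(tau + 1)]
    data = np.hstack(blocks)
    variables = tuple(
        (lab, s) for s in range(tau + 1) for lab in ts.region_labels
    )
    return SequentialSamples(variables, data, ts.region_labels, tau)


# ---------------------------------------------------------------------------
# conditional-independence testing


class FisherZ:
    """Fisher-z partial-correlation CI test over a fixed sample matrix.

    The full correlation matrix is computed once; each query inverts only
    the submatrix of the tested variables, so repeated PC queries are cheap.
    """

    def __init__(self, data: np.ndarray, alpha: float):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D")
        self.n = data.shape[0]
        self.alpha = alpha
        sd = data.std(axis=0)
        self._constant = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self.corr = np.corrcoef(data, rowvar=False)

    def __call__(
        self, i: int, j: int, cond: Sequence[int] = ()
    ) -> tuple[bool, float]:
        independent, p, _ = self.test(i, j, cond)
        return independent, p

    def test(
        self, i: int, j: int, cond: Sequence[int] = ()
    ) -> tuple[bool, float, float]:
        """Return (independent, p, partial r) for x_i vs x_j given x_cond."""
        cond = tuple(cond)
        if i == j or i in cond or j in cond:
            raise ValueError("i, j and cond must be distinct")
        for k in (i, j, *cond):
            if self._constant[k]:
                raise DegenerateDataError(f"variable {k} has zero variance")
        if self.n <= len(cond) + 3:
            raise DegenerateDataError(
                f"need more than |cond|+3 = {len(cond) + 3} samples, have {self.n}"
            )
        idx = [i, j, *cond]
        sub = self.corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            raise DegenerateDataError(
                f"singular conditioning covariance for ({i}, {j} | {cond})"
            ) from None
        denom = prec[0, 0] * prec[1, 1]
        if denom <= 0 or not np.isfinite(denom):
            raise DegenerateDataError(
                f"degenerate precision for ({i}, {j} | {cond})"
            )
        r = float(np.clip(-prec[0, 1] / np.sqrt(denom), -1 + 1e-12, 1 - 1e-12))
        z = 0.5 * np.log((1 + r) / (1 - r))
        stat = np.sqrt(self.n - len(cond) - 3) * abs(z)
        p = float(2 * stats.norm.sf(stat))
        return p > self.alpha, p, r


def ci_test_fisher_z(
    samples: SequentialSamples,
    i: Variable | int,
    j: Variable | int,
    cond: Iterable[Variable | int] = (),
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Fisher-z conditional-independence test between two sample variables.

    ``i``, ``j`` and the conditioning set may be given as (region, offset)
    tuples or as column indices.  Returns ``(independent, p)`` where
    independence is declared iff ``p > alpha``.
    """

    def _idx(v):
        return v if isinstance(v, (int, np.integer)) else samples.index(v)

    tester = FisherZ(samples.data, alpha)
    return tester(_idx(i), _idx(j), tuple(_idx(c) for c in cond))


# ---------------------------------------------------------------------------
# PC skeleton search (stable variant)


def pc_skeleton(
    samples: SequentialSamples | None = None,
    params: TPCParams | None = None,
    *,
    ci_test: Callable[[int, int, tuple], tuple[bool, float]] | None = None,
    variables: Sequence[Variable] | None = None,
) -> tuple[set[frozenset], dict[frozenset, frozenset]]:
    """Order-independent (stable) PC adjacency search.

    Starting from the complete undirected graph, level ``l = 0, 1, 2, ...``
    removes edge ``(i, j)`` as soon as some size-``l`` subset of ``i``'s or
    ``j``'s *level-start* neighbourhood renders the pair independent; the
    separating set is recorded.  Neighbourhoods are snapshot per level, so
    the result does not depend on variable order.

    ``ci_test`` may be injected (e.g. an exact d-separation oracle); it is
    called with integer variable indices and a tuple conditioning set and
    must return ``(independent, p)``.  By default a Fisher-z tester over
    ``samples`` at ``params.alpha_ci`` is used.

    Returns the skeleton as a set of frozen pairs of variables, plus the
    separating sets keyed by frozen pair.
    """
    params = params or TPCParams()
    if ci_test is None:
        if samples is None:
            raise ValueError("either samples or ci_test must be provided")
        ci_test = FisherZ(samples.data, params.alpha_ci)
    if variables is None:
        if samples is None:
            raise ValueError("either samples or variables must be provided")
        variables = samples.variables
    variables = tuple(variables)
    nvar = len(variables)

    adj: dict[int, set[int]] = {i: set(range(nvar)) - {i} for i in range(nvar)}
    sepsets: dict[frozenset, frozenset] = {}
    max_level = params.max_cond_size if params.max_cond_size is not None else nvar - 2

    level = 0
    while level <= max_level:
        snapshot = {i: frozenset(adj[i]) for i in range(nvar)}
        if all(len(snapshot[i]) - 1 < level for i in range(nvar)):
            break
        for i in range(nvar):
            for j in sorted(snapshot[i]):
                if i > j or j not in adj[i]:
                    continue
                removed = False
                for base in (i, j):
                    pool = snapshot[base] - {i, j}
                    if len(pool) < level:
                        continue
                    for cond in itertools.combinations(sorted(pool), level):
                        independent, _ = ci_test(i, j, cond)
                        if independent:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepsets[frozenset((variables[i], variables[j]))] = frozenset(
                                variables[c] for c in cond
                            )
                            removed = True
                            break
                    if removed:
                        break
        level += 1

    skeleton = {
        frozenset((variables[i], variables[j]))
        for i in range(nvar)
        for j in adj[i]
        if i < j
    }
    return skeleton, sepsets


# ---------------------------------------------------------------------------
# orientation


def orient_unrolled(
    skeleton: set[frozenset],
    sepsets: Mapping[frozenset, frozenset],
    params: TPCParams | None = None,
    variables: Sequence[Variable] | None = None,
) -> UnrolledDAG:
    """Orient a skeleton over (region, offset) variables into an unrolled DAG.

    Order of precedence: (1) temporal background knowledge — every edge
    between different offsets points from the smaller to the larger offset;
    (2) v-structure (collider) detection from the separating sets, applied
    only to still-undirected contemporaneous edges (a conflict with the
    temporal rule is resolved in favour of time); (3) Meek rules R1-R3 to a
    fixpoint.  Whatever remains undirected is kept aside for the
    undirected-edge policy at rolling time.
    """
    params = params or TPCParams()
    if variables is None:
        variables = sorted({v for pair in skeleton for v in pair})
    nodes = tuple(variables)

    neighbors: dict[Variable, set[Variable]] = {v: set() for v in nodes}
    for pair in skeleton:
        a, b = tuple(pair)
        neighbors[a].add(b)
        neighbors[b].add(a)

    directed: set[tuple[Variable, Variable]] = set()
    undirected: set[frozenset] = set()
    for pair in skeleton:
        a, b = tuple(pair)
        if a[1] == b[1]:
            undirected.add(pair)
        else:
            lo, hi = (a, b) if a[1] < b[1] else (b, a)
            directed.add((lo, hi))

    def orient(x: Variable, y: Variable) -> None:
        pair = frozenset((x, y))
        if pair in undirected and (y, x) not in directed:
            undirected.discard(pair)
            directed.add((x, y))

    # v-structures: x - z - y with x, y nonadjacent and z outside sepset(x, y)
    for z in nodes:
        for x, y in itertools.combinations(sorted(neighbors[z]), 2):
            if y in neighbors[x]:
                continue
            sep = sepsets.get(frozenset((x, y)))
            if sep is None or z in sep:
                continue
            orient(x, z)
            orient(y, z)

    _apply_meek(nodes, neighbors, directed, undirected)

    # Stationarity: the contemporaneous mechanism u -> v is the same at every
    # offset, so an orientation found for one offset copy transfers to the
    # still-undirected copies of the same region pair (conflicting copies are
    # left untouched).
    changed = True
    while changed:
        changed = False
        contemp_dirs = {
            (u[0], v[0]) for (u, v) in directed if u[1] == v[1]
        }
        for pair in list(undirected):
            a, b = tuple(pair)
            ab, ba = (a[0], b[0]) in contemp_dirs, (b[0], a[0]) in contemp_dirs
            if ab == ba:
                continue  # no information, or conflicting copies
            x, y = (a, b) if ab else (b, a)
            if (y, x) not in directed:
                undirected.discard(pair)
                directed.add((x, y))
                changed = True
        if changed:
            _apply_meek(nodes, neighbors, directed, undirected)

    dag = UnrolledDAG(
        nodes=nodes,
        directed=frozenset(directed),
        undirected=frozenset(undirected),
        sepsets=dict(sepsets),
        undirected_policy=params.undirected_policy,
    )
    return dag


def _apply_meek(
    nodes: Sequence[Variable],
    neighbors: Mapping[Variable, set],
    directed: set,
    undirected: set,
) -> None:
    """Meek rules R1-R3, iterated to a fixpoint, in place."""

    def orient(x, y) -> bool:
        pair = frozenset((x, y))
        if pair in undirected and (y, x) not in directed:
            undirected.discard(pair)
            directed.add((x, y))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for pair in list(undirected):
            b, c = tuple(pair)
            for x, y in ((b, c), (c, b)):
                # R1: a -> x, x - y, a and y nonadjacent  =>  x -> y
                if any(
                    (a, x) in directed and y not in neighbors[a] and a != y
                    for a in neighbors[x]
                ):
                    if orient(x, y):
                        changed = True
                        break
                # R2: x -> w -> y and x - y  =>  x -> y
                if any(
                    (x, w) in directed and (w, y) in directed
                    for w in neighbors[x] & neighbors[y]
                ):
                    if orient(x, y):
                        changed = True
                        break
                # R3: x - z1, x - z2, z1 -> y, z2 -> y, z1 and z2 nonadjacent
                cands = [
                    z
                    for z in neighbors[x] & neighbors[y]
                    if frozenset((x, z)) in undirected and (z, y) in directed
                ]
                if any(
                    z2 not in neighbors[z1]
                    for z1, z2 in itertools.combinations(cands, 2)
                ):
                    if orient(x, y):
                        changed = True
                        break
            if changed:
                break


# ---------------------------------------------------------------------------
# weights and rolling


def estimate_edge_weights(
    dag: UnrolledDAG, samples: SequentialSamples
) -> UnrolledDAG:
    """Attach signed strengths: per node, OLS on its DAG parents.

    Each variable is regressed (with intercept) on all its parents in the
    unrolled DAG; the coefficient on a parent becomes the weight of that
    incoming edge.  Under the ``both-directions`` policy an undirected
    contemporaneous neighbour is treated as a parent on both sides, giving
    each direction its own regression coefficient.
    """
    weights: dict[tuple[Variable, Variable], float] = {}
    col = {v: k for k, v in enumerate(samples.variables)}
    for node in dag.nodes:
        parents = dag.parents(node)
        if not parents:
            continue
        X = np.column_stack(
            [np.ones(samples.n_samples)]
            + [samples.data[:, col[p]] for p in parents]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CollinearityError(
                f"collinear parents {parents} for node {node}"
            )
        y = samples.data[:, col[node]]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        for p, b in zip(parents, beta[1:]):
            weights[(p, node)] = float(b)
    return replace(dag, weights=weights)


def roll_cfc(
    dag: UnrolledDAG, region_labels: Sequence[str] | None = None
) -> RolledCFC:
    """Collapse an unrolled DAG into the region-level causal graph.

    An unrolled edge ``(u, s1) -> (v, s2)`` (necessarily ``s1 <= s2``)
    contributes to rolled edge ``u -> v``; ``u = v`` with ``s1 < s2`` yields
    a self-loop.  Multiple contributing unrolled edges collapse into one
    rolled edge whose weight is the sum of their weights (no multigraph).
    Residual undirected contemporaneous edges are expanded according to the
    DAG's undirected policy: ``both-directions`` contributes both
    orientations, ``drop`` contributes nothing.  Unweighted DAGs roll with
    unit weights.
    """
    if region_labels is None:
        seen: dict[str, None] = {}
        for lab, _ in dag.nodes:
            seen.setdefault(lab)
        region_labels = tuple(seen)

    def w(u: Variable, v: Variable) -> float:
        return dag.weights.get((u, v), 1.0) if dag.weights else 1.0

    rolled: dict[tuple[str, str], float] = {}

    def add(u: Variable, v: Variable) -> None:
        key = (u[0], v[0])
        rolled[key] = rolled.get(key, 0.0) + w(u, v)

    for u, v in dag.directed:
        add(u, v)
    if dag.undirected_policy == "both-directions":
        for pair in dag.undirected:
            a, b = tuple(pair)
            add(a, b)
            add(b, a)
    return RolledCFC(tuple(region_labels), rolled)


def run_tpc(ts: ROITimeSeries, params: TPCParams | None = None) -> RolledCFC:
    """Full time-aware PC pipeline on one preprocessed subject series.

    Composition of :func:`build_sequential_samples`, :func:`pc_skeleton`,
    :func:`orient_unrolled`, :func:`estimate_edge_weights` and
    :func:`roll_cfc`; deterministic given input and parameters.
    """
    params = params or TPCParams()
    samples = build_sequential_samples(ts, params.tau)
    skeleton, sepsets = pc_skeleton(samples, params)
    dag = orient_unrolled(skeleton, sepsets, params, variables=samples.variables)
    dag = estimate_edge_weights(dag, samples)
    return roll_cfc(dag, region_labels=ts.region_labels)
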