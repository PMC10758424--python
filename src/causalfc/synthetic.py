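"""Ground-truth structural-VAR models and synthetic multi-group cohorts.

The generator emulates the statistical structure the downstream causal
inference assumes: several brain regions evolving as a sparse structural
vector autoregression with both lag-1 and contemporaneous (same-sample)
causal edges, signed excitatory/inhibitory weights, Gaussian innovations,
and two or more subject groups that differ only in the weights of a small
designated set of edges.

Coefficient convention (package-wide): entry ``(i, j)`` of a coefficient
matrix is the effect of region ``i`` on region ``j`` — ``lag_coeffs[i, j]``
multiplies region ``i`` at time ``t-1`` in region ``j``'s equation at time
``t``; ``contemp_coeffs[i, j]`` multiplies region ``i`` at time ``t``
itself.  The contemporaneous graph must be acyclic so the structural
equations are solvable in a topological order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import StabilityError
from .graphs import RolledCFC
from .timeseries import ROITimeSeries, write_roi_timeseries

__all__ = [
    "GroundTruthModel",
    "Cohort",
    "make_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "structure_recovery_metrics",
    "true_cfc",
    "write_cohort",
]

#: Transient steps discarded before a simulated series is kept.
BURN_IN = 100

#: Delta triple: (source label index or label, target, additive weight change).
#: A 4th element selects the lag (0 = contemporaneous, 1 = lagged; default 1).
DeltaTriple = tuple


def _default_labels(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n)))
    return tuple(f"R{i + 1:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class GroundTruthModel:
    """Sparse structural VAR specification with group-level weight deltas.

    ``group_deltas`` maps a group label to a tuple of delta triples; groups
    absent from the mapping use the base coefficients unchanged (reference
    groups).
    """

    n_regions: int
    lag_coeffs: np.ndarray
    contemp_coeffs: np.ndarray
    noise_sd: float = 1.0
    group_deltas: Mapping[str, tuple[DeltaTriple, ...]] = field(default_factory=dict)
    seed: int = 0
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = self.n_regions
        lag = np.array(self.lag_coeffs, dtype=float)
        con = np.array(self.contemp_coeffs, dtype=float)
        if lag.shape != (n, n) or con.shape != (n, n):
            raise ValueError("coefficient matrices must be n_regions x n_regions")
        if np.any(np.diag(con) != 0):
            raise ValueError("contemporaneous self-effects are not allowed")
        labels = self.region_labels or _default_labels(n)
        if len(labels) != n:
            raise ValueError("region_labels length must equal n_regions")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "lag_coeffs", lag)
        object.__setattr__(self, "contemp_coeffs", con)
        object.__setattr__(self, "region_labels", tuple(labels))
        object.__setattr__(
            self,
            "group_deltas",
            {g: tuple(tuple(d) for d in ds) for g, ds in dict(self.group_deltas).items()},
        )
        if not self.contemp_is_acyclic():
            raise ValueError("contemporaneous coefficient graph must be acyclic")

    # -- structure -------------------------------------------------------
    def contemp_is_acyclic(self) -> bool:
        g = nx.from_numpy_array(
            (self.contemp_coeffs != 0).astype(int), create_using=nx.DiGraph
        )
        return nx.is_directed_acyclic_graph(g)

    def companion_spectral_radius(self, group: str | None = None) -> float:
        """Spectral radius of the reduced-form VAR(1) transition matrix.

        With structural form ``x_t = A0' x_t + A1' x_{t-1} + e_t`` the
        reduced form is ``x_t = (I - A0')^{-1} A1' x_{t-1} + ...``; for a
        single lag the companion matrix is that transition matrix, and the
        process is stationary iff its spectral radius is < 1.
        """
        con, lag = self.coeffs_for(group) if group else (self.contemp_coeffs, self.lag_coeffs)
        n = self.n_regions
        trans = np.linalg.solve(np.eye(n) - con.T, lag.T)
        return float(np.max(np.abs(np.linalg.eigvals(trans))))

    def coeffs_for(self, group: str | None) -> tuple[np.ndarray, np.ndarray]:
        """(contemp, lag) coefficient matrices with the group's deltas applied."""
        con = self.contemp_coeffs.copy()
        lag = self.lag_coeffs.copy()
        idx = {lab: i for i, lab in enumerate(self.region_labels)}

        def _loc(x):
            return idx[x] if isinstance(x, str) else int(x)

        for d in self.group_deltas.get(group, ()):  # type: ignore[arg-type]
            if len(d) == 3:
                src, tgt, delta = d
                lag_sel = 1
            else:
                src, tgt, lag_sel, delta = d
            i, j = _loc(src), _loc(tgt)
            if lag_sel == 1:
                lag[i, j] += delta
            elif lag_sel == 0:
                if i == j:
                    raise ValueError("contemporaneous self-delta is not allowed")
                con[i, j] += delta
            else:
                raise ValueError(f"delta lag must be 0 or 1, got {lag_sel}")
        return con, lag

    def validate(self, groups: Iterable[str | None] = (None,)) -> None:
        for g in groups:
            rho = self.companion_spectral_radius(g)
            if not rho < 1:
                raise StabilityError(
                    f"companion spectral radius {rho:.4f} >= 1 for group {g!r}"
                )


@dataclass(frozen=True)
class Cohort:
    """A simulated multi-group study: subjects plus the generating model."""

    subjects: tuple[tuple[str, str, ROITimeSeries], ...]
    model: GroundTruthModel
    true_cfc: Mapping[str, RolledCFC]

    def __post_init__(self) -> None:
        labels = {s[2].region_labels for s in self.subjects}
        lengths = {s[2].n_timepoints for s in self.subjects}
        if len(labels) > 1 or len(lengths) > 1:
            raise ValueError("all subjects must share region labels and length")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, g, _ in self.subjects:
            seen.setdefault(g)
        return tuple(seen)

    def subjects_in(self, group: str) -> list[tuple[str, ROITimeSeries]]:
        return [(sid, ts) for sid, g, ts in self.subjects if g == group]


# ---------------------------------------------------------------------------
# model construction


def make_ground_truth(
    n_regions: int,
    edge_density: float,
    contemp_fraction: float = 0.0,
    weight_range: tuple[float, float] = (0.2, 0.8),
    inhibitory_fraction: float = 0.2,
    seed: int = 0,
    noise_sd: float = 1.0,
    group_deltas: Mapping[str, Sequence[DeltaTriple]] | None = None,
    max_rescale: int = 60,
) -> GroundTruthModel:
    """Draw a random sparse, stable, signed structural-VAR model.

    Roughly ``edge_density * n_regions**2`` causal edges are placed, a
    fraction ``contemp_fraction`` of them contemporaneous (drawn consistent
    with a random topological order so the same-time structure is acyclic;
    self-loops are lagged-only), and a fraction ``inhibitory_fraction``
    negative-signed.  Edge magnitudes are uniform over ``weight_range``.
    Stability is enforced by shrinking both coefficient matrices by 0.9
    until the companion spectral radius is <= 0.95 (for every group,
    deltas applied); :class:`~causalfc.errors.StabilityError` is raised if
    ``max_rescale`` shrinks do not suffice.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not 0 <= edge_density < 1:
        raise ValueError("edge_density must be in [0, 1)")
    if not 0 <= contemp_fraction <= 1:
        raise ValueError("contemp_fraction must be in [0, 1]")
    lo, hi = weight_range
    if not 0 < lo <= hi:
        raise ValueError("weight_range must be positive with low <= high")

    rng = np.random.default_rng(seed)
    n = n_regions
    n_edges = int(round(edge_density * n * n))
    n_contemp = int(round(contemp_fraction * n_edges))
    max_contemp = n * (n - 1) // 2
    if n_contemp > max_contemp:
        raise ValueError(
            f"{n_contemp} contemporaneous edges requested but only "
            f"{max_contemp} fit under acyclicity for {n} regions"
        )
    n_lag = n_edges - n_contemp

    order = rng.permutation(n)  # topological order for the contemporaneous DAG
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    contemp_pairs = [(i, j) for i in range(n) for j in range(n) if rank[i] < rank[j]]
    lag_pairs = [(i, j) for i in range(n) for j in range(n)]  # self-loops allowed

    con = np.zeros((n, n))
    lag = np.zeros((n, n))
    if n_contemp:
        pick = rng.choice(len(contemp_pairs), size=n_contemp, replace=False)
        for k in pick:
            con[contemp_pairs[k]] = _draw_weight(rng, lo, hi, inhibitory_fraction)
    if n_lag:
        pick = rng.choice(len(lag_pairs), size=min(n_lag, len(lag_pairs)), replace=False)
        for k in pick:
            lag[lag_pairs[k]] = _draw_weight(rng, lo, hi, inhibitory_fraction)

    deltas = {g: tuple(tuple(d) for d in ds) for g, ds in (group_deltas or {}).items()}
    for attempt in range(max_rescale + 1):
        model = GroundTruthModel(
            n_regions=n,
            lag_coeffs=lag,
            contemp_coeffs=con,
            noise_sd=noise_sd,
            group_deltas=deltas,
            seed=seed,
        )
        radii = [model.companion_spectral_radius(g) for g in (None, *deltas)]
        if max(radii) <= 0.95:
            return model
        lag = lag * 0.9
        con = con * 0.9
    raise StabilityError(
        f"no stable coefficient draw within {max_rescale} rescaling attempts "
        f"(spectral radius {max(radii):.3f})"
    )


def _draw_weight(rng: np.random.Generator, lo: float, hi: float, inhib: float) -> float:
    w = rng.uniform(lo, hi)
    return -w if rng.random() < inhib else w


# ---------------------------------------------------------------------------
# simulation


def simulate_subject(
    model: GroundTruthModel,
    group: str | None,
    n_timepoints: int,
    seed: int,
    sampling_interval: float = 3.0,
    burn_in: int = BURN_IN,
) -> ROITimeSeries:
    """Simulate one subject's series from the structural VAR.

    The contemporaneous equations are solved exactly (equivalent to
    substitution in topological order), lag terms and i.i.d. Gaussian
    innovations added, and ``burn_in`` initial steps discarded so the kept
    segment is approximately stationary.  Identical ``(model, group, seed)``
    give identical output.
    """
    if n_timepoints <= 2:
        raise ValueError("n_timepoints must exceed 2")
    con, lag = model.coeffs_for(group)
    n = model.n_regions
    solve = np.linalg.inv(np.eye(n) - con.T)
    trans = solve @ lag.T
    rng = np.random.default_rng(seed)
    eps = rng.normal(scale=model.noise_sd, size=(burn_in + n_timepoints, n))
    x = np.zeros((burn_in + n_timepoints, n))
    x[0] = solve @ eps[0]
    for t in range(1, burn_in + n_timepoints):
        x[t] = trans @ x[t - 1] + solve @ eps[t]
    out = x[burn_in:]
    if not np.all(np.isfinite(out)):
        raise StabilityError(
            f"simulation diverged for group {group!r} (non-finite values); "
            "check the model's spectral radius"
        )
    return ROITimeSeries(out, model.region_labels, sampling_interval)


def simulate_cohort(
    model: GroundTruthModel,
    n_per_group: Mapping[str, int],
    n_timepoints: int = 140,
    seed: int = 0,
    sampling_interval: float = 3.0,
) -> Cohort:
    """Simulate a multi-group cohort with independent per-subject noise.

    Per-subject seeds are spawned deterministically from the master seed via
    ``numpy.random.SeedSequence``, so the cohort is a pure function of its
    arguments.  Default series length of 140 samples mirrors a typical
    resting-state acquisition.
    """
    if len(n_per_group) < 2:
        raise ValueError("a cohort needs at least two groups")
    for g, n in n_per_group.items():
        if not isinstance(g, str) or not g:
            raise ValueError(f"invalid group label {g!r}")
        if n < 1:
            raise ValueError(f"group {g!r} needs at least one subject")
    total = sum(n_per_group.values())
    children = np.random.SeedSequence(seed).spawn(total)
    subjects = []
    k = 0
    for g in n_per_group:
        for s in range(n_per_group[g]):
            sid = f"{g}{s + 1:03d}"
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            ts = simulate_subject(
                model, g, n_timepoints, sub_seed, sampling_interval=sampling_interval
            )
            subjects.append((sid, g, ts))
            k += 1
    cfc = {g: true_cfc(model, g) for g in n_per_group}
    return Cohort(tuple(subjects), model, cfc)


def true_cfc(model: GroundTruthModel, group: str | None = None) -> RolledCFC:
    """Region-level ground-truth causal graph implied by the coefficients.

    The edge set is the union of nonzero lagged and contemporaneous
    coefficients (deltas applied) mapped region -> region; when both a lagged
    and a contemporaneous coefficient link the same ordered pair, the rolled
    weight is their sum, mirroring how estimated unrolled edges aggregate.
    """
    con, lag = model.coeffs_for(group)
    labels = model.region_labels
    weights: dict[tuple[str, str], float] = {}
    for mat in (lag, con):
        for i, j in zip(*np.nonzero(mat)):
            key = (labels[i], labels[j])
            weights[key] = weights.get(key, 0.0) + float(mat[i, j])
    weights = {k: w for k, w in weights.items() if w != 0.0}
    return RolledCFC(labels, weights)


# ---------------------------------------------------------------------------
# evaluation & export


def structure_recovery_metrics(
    true_graph: RolledCFC, estimated_graph: RolledCFC
) -> tuple[float, float, float]:
    """Directed-edge precision, recall and F1 (self-loops included).

    Conventions for empty sets: both empty -> (1, 1, 1); a vanishing
    denominator with non-identical edge sets contributes 0.
    """
    if set(true_graph.region_labels) != set(estimated_graph.region_labels):
        raise ValueError("region label sets differ between graphs")
    t = true_graph.edge_set()
    e = estimated_graph.edge_set()
    if not t and not e:
        return 1.0, 1.0, 1.0
    tp = len(t & e)
    precision = tp / len(e) if e else 0.0
    recall = tp / len(t) if t else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def write_cohort(cohort: Cohort, out_dir: str | Path, delimiter: str = ",") -> Path:
    """Write one series file per subject, a manifest and a ground-truth edge list.

    Layout: ``<out_dir>/series/<subject_id>.csv``, ``<out_dir>/manifest.csv``
    (subject_id, group, path) and ``<out_dir>/ground_truth.tsv`` (source,
    target, lag in {0,1}, weight) for the reference (delta-free) model.
    """
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, group, ts in cohort.subjects:
        rel = Path("series") / f"{sid}.csv"
        write_roi_timeseries(ts, out_dir / rel, delimiter=delimiter)
        rows.append({"subject_id": sid, "group": group, "path": str(rel)})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)

    labels = cohort.model.region_labels
    edges = []
    for lag_sel, mat in ((1, cohort.model.lag_coeffs), (0, cohort.model.contemp_coeffs)):
        for i, j in zip(*np.nonzero(mat)):
            edges.append(
                {
                    "source": labels[i],
                    "target": labels[j],
                    "lag": lag_sel,
                    "weight": float(mat[i, j]),
                }
            )
    pd.DataFrame(edges, columns=["source", "target", "lag", "weight"]).to_csv(
        out_dir / "ground_truth.tsv", sep="\t", index=False
    )
    return out_dir
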