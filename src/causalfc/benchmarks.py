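"""Seeded benchmark harnesses: calibration, recovery and power studies.

Each function runs a self-contained study on synthetic data with known
ground truth and returns summary numbers.  They are used by the acceptance
machinery and are handy for judging how the methods behave at a given
series length or test level before touching real data.

Problem sizes follow the package's reference study conditions: 10-region
sparse structural-VAR models (edge density 0.05, 30 % contemporaneous
edges), series lengths in the hundreds-to-thousands range, and two-group
cohorts of 30 subjects with 140-sample series.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .baselines import gc_statistics, threshold_gc
from .groups import (
    SubjectCFCSet,
    collect_edge_weights,
    edgewise_comparison,
    top_k_edges,
    welch_t_test,
)
from .synthetic import (
    Cohort,
    GroundTruthModel,
    make_ground_truth,
    simulate_cohort,
    simulate_subject,
    structure_recovery_metrics,
    true_cfc,
)
from .tpc import (
    FisherZ,
    TPCParams,
    build_sequential_samples,
    estimate_edge_weights,
    pc_skeleton,
    roll_cfc,
    run_tpc,
)
from .validation import dag_skeleton, dsep_ci_oracle, enumerate_dags, oracle_unrolled_dag

__all__ = [
    "tpc_recovery_f1",
    "fisher_z_null_rejection_rate",
    "pc_oracle_exhaustive",
    "gc_recovery_f1",
    "welch_null_rejection_rate",
    "injected_effect_rank_study",
    "regression_readout_cfcs",
]

#: Reference recovery conditions: sparse 10-region models.
RECOVERY_MODEL = dict(n_regions=10, edge_density=0.05, contemp_fraction=0.3)

#: Operating alpha for structure recovery at T ~ 1000: with ~190 variable
#: pairs at tau = 1, a per-pair level of ~1/n_pairs keeps the expected
#: number of spurious adjacencies per subject well below one.
RECOVERY_ALPHA = 0.001


def tpc_recovery_f1(
    n_seeds: int = 20,
    n_timepoints: int = 1000,
    alpha_ci: float = RECOVERY_ALPHA,
    seed: int = 0,
    contemp_fraction: float = 0.3,
) -> dict:
    """Directed-edge recovery of TPC on known sparse SVAR models.

    Returns mean precision/recall/F1 over ``n_seeds`` independently drawn
    model + subject pairs.
    """
    params = TPCParams(tau=1, alpha_ci=alpha_ci)
    rows = []
    for k in range(n_seeds):
        model = make_ground_truth(
            10, 0.05, contemp_fraction=contemp_fraction, seed=seed + k
        )
        ts = simulate_subject(model, None, n_timepoints, seed=seed + 10_000 + k)
        est = run_tpc(ts, params)
        rows.append(structure_recovery_metrics(true_cfc(model), est))
    prec, rec, f1 = np.mean(rows, axis=0)
    return {
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "n_seeds": n_seeds,
        "n_timepoints": n_timepoints,
    }


def fisher_z_null_rejection_rate(
    n_replicates: int = 2000, n_samples: int = 200, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the Fisher-z test on truly independent Gaussians."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.normal(size=(n_samples, 2))
        independent, _ = FisherZ(x, alpha)(0, 1)
        rejections += not independent
    return rejections / n_replicates


def pc_oracle_exhaustive(max_nodes: int = 4) -> dict:
    """PC with a perfect d-separation oracle vs every DAG on <= max_nodes.

    For each labelled DAG the skeleton search runs with exact CI answers
    and is compared with the DAG's true adjacency; returns the counts.
    """
    n_dags = 0
    n_correct = 0
    for n_nodes in range(2, max_nodes + 1):
        variables = [(str(i), 0) for i in range(n_nodes)]
        for edges in enumerate_dags(n_nodes):
            ci = dsep_ci_oracle(edges, n_nodes)
            skeleton, _ = pc_skeleton(ci_test=ci, variables=variables)
            got = {frozenset(int(v[0]) for v in pair) for pair in skeleton}
            n_dags += 1
            n_correct += got == dag_skeleton(edges)
    return {"n_dags": n_dags, "n_correct": n_correct}


def gc_recovery_f1(
    n_seeds: int = 20, n_timepoints: int = 2000, percentile: float = 95.0, seed: int = 0
) -> dict:
    """Granger recovery of lag-only ground truth (self-loops excluded:
    GC scores ordered pairs of distinct regions only)."""
    f1s = []
    for k in range(n_seeds):
        model = make_ground_truth(10, 0.05, contemp_fraction=0.0, seed=seed + k)
        ts = simulate_subject(model, None, n_timepoints, seed=seed + 20_000 + k)
        res = threshold_gc(gc_statistics(ts, 1), percentile, ts.region_labels)
        truth = {e for e in true_cfc(model).edge_set() if e[0] != e[1]}
        est = res.graph.edge_set()
        tp = len(truth & est)
        p = tp / len(est) if est else 0.0
        r = tp / len(truth) if truth else 1.0
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return {"f1": float(np.mean(f1s)), "n_seeds": n_seeds}


def welch_null_rejection_rate(
    n_edges: int = 5000, n_per_group: int = 30, alpha: float = 0.05, seed: int = 0
) -> float:
    """One-sided Welch type-I error across many null replicate edges."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_edges):
        x = rng.normal(size=n_per_group)
        y = rng.normal(size=n_per_group)
        rejections += welch_t_test(x, y, "greater")[2] < alpha
    return rejections / n_edges


def regression_readout_cfcs(cohort: Cohort, tau: int = 1) -> SubjectCFCSet:
    """Subject CFCs with the *true* structure and per-subject OLS weights.

    Bypasses structure search: each subject's edge weights are read out by
    regressing every region on its ground-truth parents in the oracle
    unrolled DAG.  Isolates the group-comparison machinery from structure
    estimation noise.
    """
    entries = []
    for sid, group, ts in cohort.subjects:
        dag = oracle_unrolled_dag(cohort.model, group, tau=tau)
        samples = build_sequential_samples(ts, tau)
        dag = estimate_edge_weights(dag, samples)
        entries.append((sid, group, roll_cfc(dag, region_labels=ts.region_labels)))
    return SubjectCFCSet(tuple(entries))


def _ranking_base_model() -> tuple[np.ndarray, tuple[int, int]]:
    n = 10
    lag = np.zeros((n, n))
    for i, j, w in [(0, 1, 0.5), (2, 3, -0.4), (4, 5, 0.45), (6, 7, 0.5),
                    (8, 9, -0.35), (1, 2, 0.3)]:
        lag[i, j] = w
    return lag, (0, 1)


def injected_effect_rank_study(
    n_cohorts: int = 10,
    n_per_group: int = 30,
    n_timepoints: int = 140,
    effect_sd_multiple: float = 1.5,
    top_k: int = 10,
    seed: int = 0,
) -> dict:
    """Does a single boosted edge rank first in the top-k table?

    The injected group difference is calibrated in units of the within-group
    standard deviation of that edge's estimated weight, measured on a null
    cohort generated by the same procedure.  Returns the fraction of seeded
    cohorts in which the boosted edge tops the ranking.
    """
    lag, (ti, tj) = _ranking_base_model()
    n = lag.shape[0]
    null_model = GroundTruthModel(n, lag, np.zeros((n, n)))
    null_cohort = simulate_cohort(
        null_model, {"g1": n_per_group, "g2": n_per_group}, n_timepoints,
        seed=seed + 90_000,
    )
    cfcs0 = regression_readout_cfcs(null_cohort)
    labels = null_model.region_labels
    x, y = collect_edge_weights(cfcs0, (labels[ti], labels[tj]), ("g1", "g2"))
    weight_sd = float(np.concatenate([x, y]).std(ddof=1))
    delta = effect_sd_multiple * weight_sd

    model = GroundTruthModel(
        n, lag, np.zeros((n, n)), group_deltas={"g2": ((ti, tj, delta),)}
    )
    wins = 0
    for k in range(n_cohorts):
        cohort = simulate_cohort(
            model, {"g1": n_per_group, "g2": n_per_group}, n_timepoints,
            seed=seed + k,
        )
        table = edgewise_comparison(
            regression_readout_cfcs(cohort), "g1", "g2", direction="g2>g1"
        )
        top = top_k_edges(table, top_k)
        if len(top) and (top.iloc[0]["source"], top.iloc[0]["target"]) == (
            labels[ti],
            labels[tj],
        ):
            wins += 1
    return {
        "rank1_rate": wins / n_cohorts,
        "n_cohorts": n_cohorts,
        "weight_sd": weight_sd,
        "delta": delta,
    }
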