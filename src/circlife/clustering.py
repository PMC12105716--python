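"""Fold-change trajectory clustering.

Trajectories are per-circRNA fold changes relative to the first age point
(baseline column identically 1).  Clustering operates on the log2
trajectories: consensus k-means aggregates many randomly initialized
k-means runs into a co-assignment frequency matrix, and the final
partition is obtained by average-linkage hierarchical clustering of
(1 - consensus) cut at k.  The number of clusters is chosen where the
cross-sex Rand index shows its greatest increase, with WSS-elbow and
silhouette diagnostics reported as advisory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "TrajectoryMatrix",
    "ConsensusClustering",
    "build_trajectories",
    "consensus_kmeans",
    "rand_index",
    "adjusted_rand_index",
    "cross_sex_diagnostics",
    "select_k",
    "cluster_summaries",
]


@dataclass
class TrajectoryMatrix:
    """circRNA x age matrix of fold changes to the first time point.

    ``values`` is on the linear scale with the baseline column equal to 1;
    ``log2`` provides the log2 view used for clustering.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("trajectory fold changes must be positive")

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    @property
    def circ_ids(self) -> list[str]:
        return list(self.values.index)


def build_trajectories(
    fold_changes: dict[int, pd.DataFrame],
    baseline_age: int = 0,
) -> TrajectoryMatrix:
    """Assemble a trajectory matrix from per-age fold-change results.

    ``fold_changes`` maps each non-baseline age to a frame with a
    ``log2fc`` column (fold change of that age versus the baseline age).
    Features missing a finite value at any age are dropped with a warning.
    """
    ages = sorted(fold_changes)
    cols = {baseline_age: None}
    frame = pd.DataFrame(
        {age: fold_changes[age]["log2fc"] for age in ages}
    )
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} features with missing fold changes")
    out = np.power(2.0, complete)
    out.insert(0, baseline_age, 1.0)
    out.index.name = "circ_id"
    return TrajectoryMatrix(out)


@dataclass
class ConsensusClustering:
    """Result of consensus k-means at a fixed k."""

    assignments: pd.Series              # circ_id -> 1..k
    consensus: pd.DataFrame             # co-assignment frequencies
    k: int
    n_repetitions: int
    seed: int
    diagnostics: dict = field(default_factory=dict)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map labels to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def consensus_kmeans(
    traj: TrajectoryMatrix,
    k: int,
    n_rep: int = 500,
    seed: int = 0,
    use_log: bool = True,
    final: str = "hierarchical",
) -> ConsensusClustering:
    """Consensus k-means on (log2) trajectories.

    Runs ``n_rep`` k-means clusterings with independent random
    initializations; consensus(i, j) is the fraction of runs co-assigning
    features i and j.  The final partition cuts an average-linkage tree of
    (1 - consensus) at k (``final="hierarchical"``); ``final="best_run"``
    instead returns the run with the lowest within-cluster sum of squares,
    for the reading in which the consensus matrix is display-only.
    """
    from sklearn.cluster import KMeans

    X = (traj.log2 if use_log else traj.values).to_numpy(dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of features ({n})")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    consensus = np.zeros((n, n))
    best_labels, best_inertia = None, np.inf
    for _ in range(n_rep):
        rs = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(X)
        labels = km.labels_
        consensus += labels[:, None] == labels[None, :]
        if km.inertia_ < best_inertia:
            best_inertia, best_labels = km.inertia_, labels
    consensus /= n_rep
    np.fill_diagonal(consensus, 1.0)

    if final == "best_run" or n_rep == 1:
        labels = _relabel_contiguous(best_labels)
    elif final == "hierarchical":
        dist = squareform(1.0 - consensus, checks=False)
        tree = linkage(dist, method="average")
        labels = _relabel_contiguous(fcluster(tree, t=k, criterion="maxclust"))
    else:
        raise ValueError(f"unknown consolidation {final!r}")

    assignments = pd.Series(labels, index=traj.circ_ids, name="cluster")
    cons = pd.DataFrame(consensus, index=traj.circ_ids, columns=traj.circ_ids)
    diag = {
        "wss": _wss(X, labels),
        "silhouette": _silhouette(X, labels),
        "best_run_inertia": float(best_inertia),
    }
    return ConsensusClustering(
        assignments=assignments, consensus=cons, k=k,
        n_repetitions=n_rep, seed=seed, diagnostics=diag,
    )


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def _silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(silhouette_score(X, labels))


# ---------------------------------------------------------------------------
# Rand index
# ---------------------------------------------------------------------------


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def rand_index(a: pd.Series, b: pd.Series, intersect: bool = False) -> float:
    """Plain (unadjusted) Rand index between two partitions.

    The fraction of item pairs treated concordantly: together in both
    partitions or apart in both.  Item sets must match unless
    ``intersect=True``, which restricts to the shared items.
    """
    a, b = pd.Series(a), pd.Series(b)
    if intersect:
        shared = a.index.intersection(b.index)
        a, b = a.loc[shared], b.loc[shared]
    elif set(a.index) != set(b.index):
        raise ValueError("partitions cover different item sets (use intersect=True)")
    else:
        b = b.reindex(a.index)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    ct = pd.crosstab(a.to_numpy(), b.to_numpy()).to_numpy(dtype=float)
    total_pairs = n * (n - 1) / 2.0
    same_both = _comb2(ct).sum()
    same_a = _comb2(ct.sum(axis=1)).sum()
    same_b = _comb2(ct.sum(axis=0)).sum()
    disagreements = same_a + same_b - 2.0 * same_both
    return float((total_pairs - disagreements) / total_pairs)


def adjusted_rand_index(a: pd.Series, b: pd.Series) -> float:
    """Chance-corrected Rand index (secondary diagnostic)."""
    from sklearn.metrics import adjusted_rand_score

    b = pd.Series(b).reindex(pd.Series(a).index)
    return float(adjusted_rand_score(pd.Series(a).to_numpy(), b.to_numpy()))


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------


def cross_sex_diagnostics(
    traj_by_sex: dict[str, TrajectoryMatrix],
    k_range: range = range(2, 11),
    n_rep: int = 500,
    seed: int = 0,
    final: str = "hierarchical",
) -> pd.DataFrame:
    """Per-k diagnostics: cross-sex Rand index plus mean WSS/silhouette.

    Each sex is clustered independently at every k; the Rand index is
    computed on the circRNAs present in both sexes.
    """
    if len(traj_by_sex) != 2:
        raise ValueError("expected trajectories for exactly two sexes")
    (sex_a, traj_a), (sex_b, traj_b) = sorted(traj_by_sex.items())
    rows = []
    for i, k in enumerate(k_range):
        cc_a = consensus_kmeans(traj_a, k, n_rep=n_rep, seed=seed + 2 * i, final=final)
        cc_b = consensus_kmeans(traj_b, k, n_rep=n_rep, seed=seed + 2 * i + 1, final=final)
        rows.append(
            {
                "k": k,
                "rand": rand_index(cc_a.assignments, cc_b.assignments, intersect=True),
                "adjusted_rand": adjusted_rand_index(
                    cc_a.assignments.loc[
                        cc_a.assignments.index.intersection(cc_b.assignments.index)
                    ],
                    cc_b.assignments,
                ),
                "wss": (cc_a.diagnostics["wss"] + cc_b.diagnostics["wss"]) / 2.0,
                "silhouette": (
                    cc_a.diagnostics["silhouette"] + cc_b.diagnostics["silhouette"]
                ) / 2.0,
            }
        )
    return pd.DataFrame(rows).set_index("k")


def select_k(diagnostics: pd.DataFrame) -> tuple[int, dict]:
    """Choose k at the greatest increase of the cross-sex Rand index.

    ``diagnostics`` is indexed by consecutive k with a ``rand`` column.
    When the Rand index never increases, the smallest k attaining the
    maximum is returned, flagged as weak evidence.  Silhouette maximum and
    the WSS elbow are reported alongside as advisory.
    """
    if len(diagnostics) < 2:
        raise ValueError("need diagnostics for at least 2 values of k")
    ks = list(diagnostics.index)
    rand = diagnostics["rand"]
    increases = rand.diff().dropna()
    report: dict = {"rand": dict(rand), "flags": []}
    if (increases <= 0).all():
        chosen = int(rand.index[np.argmax(rand.to_numpy())])
        report["flags"].append("weak evidence: Rand index never increases")
    else:
        chosen = int(increases.idxmax())
        report["rand_increase"] = float(increases.max())
    if "silhouette" in diagnostics:
        report["silhouette_argmax"] = int(diagnostics["silhouette"].idxmax())
    if "wss" in diagnostics and len(diagnostics) >= 3:
        # elbow: largest drop in the decrease of WSS
        w = diagnostics["wss"]
        second_diff = w.diff().diff().dropna()
        if len(second_diff):
            report["wss_elbow"] = int(second_diff.idxmax())
    report["chosen_k"] = chosen
    return chosen, report


# ---------------------------------------------------------------------------
# cluster summaries
# ---------------------------------------------------------------------------


def cluster_summaries(
    traj: TrajectoryMatrix,
    assignments: pd.Series,
    linear_traj: TrajectoryMatrix | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cluster, per-age mean +/- SEM fold-change traces.

    Optionally adds traces for the host mRNA trajectories (matched by
    circ_id) and per-age mean log10 expression levels.  Clusters with
    fewer than 2 members report SEM = NA.
    """
    missing = traj.values.index.difference(assignments.index)
    if len(missing):
        raise ValueError(f"assignments missing for {len(missing)} trajectory rows")
    rows = []
    for cluster, ids in assignments.groupby(assignments).groups.items():
        ids = traj.values.index.intersection(ids)
        sub = traj.values.loc[ids]
        n = len(ids)
        for age in traj.values.columns:
            row = {
                "cluster": cluster,
                "age": age,
                "n": n,
                "circ_fc_mean": float(sub[age].mean()),
                "circ_fc_sem": float(sub[age].sem()) if n >= 2 else np.nan,
            }
            if linear_traj is not None:
                lin_ids = linear_traj.values.index.intersection(ids)
                lin = linear_traj.values.loc[lin_ids, age]
                row["host_fc_mean"] = float(lin.mean()) if len(lin) else np.nan
                row["host_fc_sem"] = float(lin.sem()) if len(lin) >= 2 else np.nan
            if expression is not None and age in expression.columns:
                expr = np.log10(expression.loc[expression.index.intersection(ids), age] + 1.0)
                row["log10_expr_mean"] = float(expr.mean()) if len(expr) else np.nan
                row["log10_expr_sem"] = float(expr.sem()) if len(expr) >= 2 else np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["cluster", "age"])
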