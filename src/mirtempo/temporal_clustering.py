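"""Temporal trajectories and fuzzy c-means soft clustering.

Pathway-level trajectories count, per time point, how many significant
genes a pathway contains; standardized trajectories are soft-clustered so
each pathway receives a membership ("fitness") score in [0, 1] for every
cluster, rows summing to one.  For whole-course (nonpairwise) DE the same
machinery clusters gene-level trajectories and enriches each temporal
cluster separately.

Fuzzy c-means here uses the classical alternating updates: membership
u_ic = 1 / sum_c' (d_ic/d_ic')^(2/(m-1)) with Euclidean distances d to the
centers, centers v_c = sum_i u_ic^m x_i / sum_i u_ic^m, iterated from a
seeded draw of c distinct rows as initial centers until the maximum center
change drops below tol.  A row coinciding with a center receives membership
one there.  The fuzzifier m (default 2) controls sharpness: m -> 1+
approaches hard k-means assignments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_ingest import COMBINED, GENE_TYPES, SignificantSets, IDMap
from .enrichment import enrich_per_context
from .pathway_resources import PathwaySet

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Rows (pathways or genes) x ordered time points.

    When ``standardized`` every retained row has mean 0 and population
    standard deviation 1; rows with zero variance were dropped and are
    listed in ``dropped``.
    """

    values: pd.DataFrame  # index: row ids, columns: time points in order
    standardized: bool = False
    dropped: tuple[str, ...] = ()

    @property
    def time_points(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def row_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, standardized: bool = False) -> "TrajectoryMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(df, standardized=standardized)


@dataclass(frozen=True)
class SoftClustering:
    """Fuzzy c-means result: centers, membership in [0,1], convergence info."""

    centers: pd.DataFrame  # c x T
    membership: pd.DataFrame  # rows x c, each row sums to 1
    m: float
    seed: int
    iterations: int
    converged: bool
    objective: tuple[float, ...]  # per-iteration objective values

    @property
    def c(self) -> int:
        return self.centers.shape[0]

    def membership_to_tsv(self, path) -> None:
        self.membership.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def build_pathway_trajectories(
    sig: SignificantSets,
    pathways: PathwaySet,
    ids: IDMap | None = None,
    normalize_by_size: bool = False,
):
    """Count significant pathway genes per time point.

    value[p, t] = |significant set at t (mapped to the pathway namespace)
    intersected with members(p)|.  Combined mode returns one
    TrajectoryMatrix; separate mode returns {gene_type: TrajectoryMatrix}.
    With ``normalize_by_size`` counts are divided by pathway size.
    """
    if len(sig.time_points) < 2:
        raise ClusteringError("at least 2 time points required for trajectories")

    def mapped(labels):
        if ids is None:
            return set(labels)
        return set(ids.to_namespace(labels, pathways.namespace).values())

    def one_matrix(key_of):
        data = {}
        for p in pathways:
            row = []
            for tp in sig.time_points:
                genes = mapped(sig.sets.get(key_of(tp), frozenset()))
                count = len(genes & p.members)
                row.append(count / len(p.members) if normalize_by_size else count)
            data[p.pathway_id] = row
        df = pd.DataFrame.from_dict(data, orient="index", columns=list(sig.time_points))
        if (df.to_numpy() == 0).all():
            return None
        return TrajectoryMatrix(df.astype(float))

    if sig.mode == COMBINED:
        mat = one_matrix(lambda tp: tp)
        if mat is None:
            raise ClusteringError("no pathway overlaps any significant set at any time point")
        return mat
    result = {}
    for gt in GENE_TYPES:
        mat = one_matrix(lambda tp, gt=gt: (tp, gt))
        if mat is None:
            logger.warning("gene type %s overlaps no pathway; omitted from trajectories", gt)
        else:
            result[gt] = mat
    if not result:
        raise ClusteringError("no pathway overlaps any significant set at any time point")
    return result


def standardize(traj: TrajectoryMatrix) -> TrajectoryMatrix:
    """Row-standardize to mean 0 / population sd 1; drop zero-variance rows."""
    X = traj.values.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (n-denominator) convention
    keep = sd[:, 0] > 0
    dropped = tuple(np.asarray(traj.values.index)[~keep])
    if dropped:
        logger.info("dropping %d zero-variance rows: %s", len(dropped), list(dropped))
    if not keep.any():
        raise ClusteringError("every row has zero variance; nothing to standardize")
    Z = (X[keep] - mean[keep]) / sd[keep]
    df = pd.DataFrame(Z, index=traj.values.index[keep], columns=traj.values.columns)
    return TrajectoryMatrix(df, standardized=True, dropped=traj.dropped + dropped)


def membership_matrix(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy membership update: u_ic = 1 / sum_c' (d_ic/d_ic')^(2/(m-1)).

    A row at zero distance from a center receives membership 1 there
    (split equally if coincident with several centers).  Rows sum to 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n_rows, c = X.shape[0], centers.shape[0]
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    U = np.zeros((n_rows, c))
    zero = d <= 0
    any_zero = zero.any(axis=1)
    if any_zero.any():
        Z = zero[any_zero]
        U[any_zero] = Z / Z.sum(axis=1, keepdims=True)
    finite = ~any_zero
    if finite.any():
        ratio = (d[finite, :, None] / d[finite, None, :]) ** (2.0 / (m - 1.0))
        U[finite] = 1.0 / ratio.sum(axis=2)
    return U


def fuzzy_cmeans(
    traj: TrajectoryMatrix,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> SoftClustering:
    """Soft-cluster standardized trajectories into ``c`` clusters."""
    if not traj.standardized:
        raise ClusteringError("fuzzy_cmeans requires a standardized TrajectoryMatrix")
    X = traj.values.to_numpy(dtype=float)
    n_rows = X.shape[0]
    if not (2 <= c < n_rows):
        raise ClusteringError(f"need 2 <= c < rows ({n_rows}), got c={c}")
    if m <= 1:
        raise ClusteringError(f"fuzzifier m must be > 1, got {m}")

    # seeded init: first c rows of a random permutation with pairwise
    # distinct value vectors (duplicated rows must not collapse two centers)
    rng = np.random.default_rng(seed)
    centers_list: list[np.ndarray] = []
    for idx in rng.permutation(n_rows):
        row = X[idx]
        if all(not np.array_equal(row, cc) for cc in centers_list):
            centers_list.append(row)
        if len(centers_list) == c:
            break
    if len(centers_list) < c:
        raise ClusteringError(
            f"only {len(centers_list)} distinct rows available for c={c} initial centers"
        )
    centers = np.array(centers_list)

    objective = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = membership_matrix(X, centers, m)
        d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
        objective.append(float(((U**m) * d**2).sum()))
        W = U**m
        new_centers = (W.T @ X) / W.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("fuzzy c-means did not converge in %d iterations", max_iter)

    U = membership_matrix(X, centers, m)  # final membership vs converged centers

    cluster_ids = [f"C{i+1}" for i in range(c)]
    return SoftClustering(
        centers=pd.DataFrame(centers, index=cluster_ids, columns=traj.values.columns),
        membership=pd.DataFrame(U, index=traj.values.index, columns=cluster_ids),
        m=m,
        seed=seed,
        iterations=it,
        converged=converged,
        objective=tuple(objective),
    )


def filter_by_membership(
    clust: SoftClustering, cluster_id: str, min_membership: float
) -> list[str]:
    """Rows with membership >= threshold in a cluster, sorted descending.

    Ties break lexicographically by row id.
    """
    if not (0 <= min_membership <= 1):
        raise ClusteringError(f"min_membership must be in [0, 1], got {min_membership}")
    if cluster_id not in clust.membership.columns:
        raise ClusteringError(f"unknown cluster {cluster_id!r}")
    col = clust.membership[cluster_id]
    hits = col[col >= min_membership]
    order = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return [rid for rid, _ in order]


def hard_assign(clust: SoftClustering) -> dict[str, str]:
    """Max-membership cluster per row; ties go to the lower-indexed cluster."""
    out = {}
    cols = list(clust.membership.columns)
    for rid, row in clust.membership.iterrows():
        best = row.max()
        winners = [c for c in cols if row[c] == best]
        if len(winners) > 1:
            logger.info("row %s tied between clusters %s; assigning %s", rid, winners, winners[0])
        out[rid] = winners[0]
    return out


def cluster_genes_then_enrich(
    gene_traj: TrajectoryMatrix,
    pathways: PathwaySet,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    universe="auto",
    ids: IDMap | None = None,
) -> pd.DataFrame:
    """Gene-level temporal clustering followed by per-cluster enrichment.

    For whole-course DE: cluster significantly-changing genes by trajectory
    shape, hard-assign each gene to its max-membership cluster, then run
    overrepresentation with the clusters as contexts.
    """
    traj = gene_traj if gene_traj.standardized else standardize(gene_traj)
    clust = fuzzy_cmeans(traj, c=c, m=m, seed=seed)
    assign = hard_assign(clust)
    sets = {}
    for cid in clust.membership.columns:
        sets[cid] = frozenset(g for g, a in assign.items() if a == cid)
    all_genes = {"mRNA": frozenset(gene_traj.row_ids), "miRNA": frozenset()}
    sig = SignificantSets(
        sets, mode="combined", alpha=float("nan"),
        time_points=gene_traj.time_points, all_genes=all_genes,
    )
    return enrich_per_context(sig, pathways, universe=universe, ids=ids)


def best_label_agreement(assign: dict[str, str], truth: dict[str, str]) -> float:
    """Fraction of rows whose cluster matches planted truth under the best
    label permutation (cluster names are arbitrary)."""
    rows = sorted(set(assign) & set(truth))
    if not rows:
        return 0.0
    a_labels = sorted({assign[r] for r in rows})
    t_labels = sorted({truth[r] for r in rows})
    best = 0
    for perm in itertools.permutations(t_labels, len(a_labels)):
        mapping = dict(zip(a_labels, perm))
        best = max(best, sum(mapping[assign[r]] == truth[r] for r in rows))
    return best / len(rows)
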