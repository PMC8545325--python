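"""miRNA-mRNA interaction matrix, filtering and network assembly.

Given a signaling pathway of interest, every input mRNA found in the
pathway is treated as a potential target of every candidate miRNA.  The
resulting all-pairs matrix carries (i) the correlation of the two genes'
trajectories over time (Pearson by default; Spearman or Kendall tau-b
optional) and (ii) one 0/1 presence flag per target database, summed into a
vote count over the user-selected databases.  Pairs are kept when
corr <= max_corr (default -0.5, inclusive: miRNAs repress their targets,
so strongly negative correlation is the interesting sign) AND
votes >= min_dbs (default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

DEFAULT_MAX_CORR = -0.5
DEFAULT_MIN_DBS = 1
CORR_METHODS = ("pearson", "spearman", "kendall")


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionMatrix:
    """All-pairs miRNA x mRNA grid of correlations, flags and votes.

    ``corr`` is mirnas x mrnas (NaN where a trajectory had zero variance —
    such pairs can never pass the filter); ``flags`` maps database name to
    a 0/1 matrix; ``votes`` sums flags over ``selected`` databases.
    """

    corr: pd.DataFrame
    method: str
    flags: dict = field(default_factory=dict)
    votes: pd.DataFrame | None = None
    selected: tuple[str, ...] = ()

    @property
    def mirnas(self) -> list[str]:
        return list(self.corr.index)

    @property
    def mrnas(self) -> list[str]:
        return list(self.corr.columns)


@dataclass(frozen=True)
class InteractionNetwork:
    """Bipartite miRNA/mRNA graph; every edge passed the active filter."""

    graph: nx.Graph

    @property
    def mirnas(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == "miRNA")

    @property
    def mrnas(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == "mRNA")

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            if self.graph.nodes[u]["type"] == "miRNA":
                out.append((u, v, d))
            else:
                out.append((v, u, d))
        return sorted(out, key=lambda e: (e[0], e[1]))

    def edge_set(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.edges}


def pathway_mrnas(pathway_id, pathways, de, ids) -> list[str]:
    """Input mRNA labels whose mapped ID belongs to the pathway, sorted.

    Labels mapping to the same pathway member are de-duplicated (first
    label lexicographically wins, logged).
    """
    try:
        pathway = pathways.get(pathway_id)
    except KeyError:
        raise InteractionError(f"unknown pathway {pathway_id!r}") from None
    labels = sorted(de.genes("mRNA"))
    mapped = ids.to_namespace(labels, pathways.namespace)
    by_member: dict[str, str] = {}
    for lab in labels:  # lexicographic order -> first label kept per member
        mid = mapped.get(lab)
        if mid is None or mid not in pathway.members:
            continue
        if mid in by_member:
            logger.warning(
                "labels %r and %r both map to pathway member %s; keeping %r",
                by_member[mid], lab, mid, by_member[mid],
            )
            continue
        by_member[mid] = lab
    result = sorted(by_member.values())
    if not result:
        raise InteractionError(
            f"no input mRNA maps into pathway {pathway_id}; select another pathway"
        )
    return result


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y)[0])
    if method == "spearman":
        return float(stats.spearmanr(x, y)[0])
    if method == "kendall":
        return float(stats.kendalltau(x, y)[0])  # tau-b, tie-corrected
    raise InteractionError(f"unknown correlation method {method!r}")


def pair_correlations(
    de,
    mirnas,
    mrnas,
    value: str = "log2fc",
    method: str = "pearson",
    expression: pd.DataFrame | None = None,
) -> InteractionMatrix:
    """Correlate each miRNA trajectory with each mRNA trajectory.

    ``value`` selects log2fc from the DE data or avg_expression, in which
    case ``expression`` must be a genes x time-points matrix of per-time-
    point mean expression supplied by the caller.  Zero-variance
    trajectories yield NaN (pair marked unavailable) with a warning.
    """
    if method not in CORR_METHODS:
        raise InteractionError(f"method must be one of {CORR_METHODS}")
    T = len(de.time_points)
    if T < 3:
        raise InteractionError(f"need at least 3 time points for correlations, got {T}")

    def traj(gene, gene_type):
        if value == "log2fc":
            return de.trajectory(gene, gene_type, "log2fc")
        if value == "avg_expression":
            if expression is None or gene not in expression.index:
                raise InteractionError(f"no expression trajectory for {gene!r}")
            return expression.loc[gene, list(de.time_points)].to_numpy(dtype=float)
        raise InteractionError(f"unknown value source {value!r}")

    mirna_traj = {m: traj(m, "miRNA") for m in mirnas}
    mrna_traj = {g: traj(g, "mRNA") for g in mrnas}
    corr = pd.DataFrame(index=list(mirnas), columns=list(mrnas), dtype=float)
    for m, x in mirna_traj.items():
        for g, y in mrna_traj.items():
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 2 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                logger.warning("pair (%s, %s): degenerate trajectory, correlation unavailable", m, g)
                corr.loc[m, g] = np.nan
            else:
                corr.loc[m, g] = _corr(x[ok], y[ok], method)
    return InteractionMatrix(corr=corr, method=method)


def apply_db_flags(mat: InteractionMatrix, dbs, selected=None) -> InteractionMatrix:
    """Annotate each pair with per-database 0/1 flags and the vote count.

    ``selected`` restricts which databases contribute to the vote
    (default: all supplied); flags are still recorded for every database.
    """
    by_name = {db.name: db for db in dbs}
    if selected is None:
        selected = tuple(by_name)
    missing = set(selected) - set(by_name)
    if missing:
        raise InteractionError(f"selected databases not loaded: {sorted(missing)}")
    flags = {}
    for name, db in by_name.items():
        f = pd.DataFrame(0, index=mat.corr.index, columns=mat.corr.columns, dtype=int)
        for m in mat.mirnas:
            for g in mat.mrnas:
                if (m, g) in db.pairs:
                    f.loc[m, g] = 1
        flags[name] = f
    votes = sum(flags[name] for name in selected)
    if not isinstance(votes, pd.DataFrame):  # selected empty
        votes = pd.DataFrame(0, index=mat.corr.index, columns=mat.corr.columns, dtype=int)
    return InteractionMatrix(
        corr=mat.corr, method=mat.method, flags=flags, votes=votes, selected=tuple(selected)
    )


def filter_interactions(
    mat: InteractionMatrix,
    max_corr: float = DEFAULT_MAX_CORR,
    min_dbs: int = DEFAULT_MIN_DBS,
) -> InteractionNetwork:
    """Keep pairs with corr <= max_corr and votes >= min_dbs; build the network.

    Both boundaries are inclusive.  Pairs whose correlation is unavailable
    (NaN) never pass.  Isolated nodes are excluded; an empty network is
    allowed (warning).
    """
    if mat.votes is None:
        raise InteractionError("database flags not applied; call apply_db_flags first")
    g = nx.Graph()
    n_kept = 0
    for m in mat.mirnas:
        for t in mat.mrnas:
            c = mat.corr.loc[m, t]
            v = int(mat.votes.loc[m, t])
            if pd.isna(c) or not (c <= max_corr and v >= min_dbs):
                continue
            g.add_node(m, type="miRNA")
            g.add_node(t, type="mRNA")
            attrs = {"corr": float(c), "votes": v}
            for name, f in mat.flags.items():
                attrs[f"in_{name}"] = int(f.loc[m, t])
            g.add_edge(m, t, **attrs)
            n_kept += 1
    if n_kept == 0:
        logger.warning("no interaction passed corr <= %g and votes >= %d", max_corr, min_dbs)
    return InteractionNetwork(g)


def gene_trends(
    de,
    network: InteractionNetwork,
    highlight_threshold: float = 1.5,
    value: str = "log2fc",
    out=None,
) -> pd.DataFrame:
    """Trajectories of the network's genes with a highlight flag.

    A gene is highlighted when any of its values exceeds the (signed)
    threshold, mirroring an over-the-line rule on the time-course plot.
    """
    if not np.isfinite(highlight_threshold):
        raise InteractionError("highlight threshold must be finite")
    rows = []
    nodes = [(n, network.graph.nodes[n]["type"]) for n in sorted(network.graph.nodes)]
    if not nodes:
        logger.warning("empty network; no gene trends to compute")
    for gene, gtype in nodes:
        vec = de.trajectory(gene, gtype, value)
        rows.append(
            {
                "gene": gene,
                "gene_type": gtype,
                **{tp: v for tp, v in zip(de.time_points, vec)},
                "highlighted": bool(np.any(vec > highlight_threshold)),
            }
        )
    tab = pd.DataFrame(rows)
    if out is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        xs = np.arange(len(de.time_points))
        for _, r in tab.iterrows():
            ys = [r[tp] for tp in de.time_points]
            ax.plot(xs, ys, color="#d65f5f" if r["highlighted"] else "#888888",
                    lw=1.8 if r["highlighted"] else 0.8)
        ax.axhline(highlight_threshold, ls="--", color="black", lw=0.8)
        ax.set_xticks(xs, de.time_points)
        ax.set_ylabel(value)
        fig.tight_layout()
        fig.savefig(out, dpi=100)
        plt.close(fig)
    return tab


def cluster_network_genes(
    de,
    network: InteractionNetwork,
    k: int,
    linkage: str = "average",
    value: str = "log2fc",
    out_prefix=None,
) -> dict:
    """Hierarchically cluster network-gene trajectories; cut into k clusters.

    Standardized trajectories, Euclidean distance, average linkage by
    default.  Returns the dendrogram leaf order (shared with the heatmap
    rows), cluster labels, per-cluster mean trajectories with a smoothing-
    spline overlay, and the standardized matrix for heatmap rendering.
    """
    nodes = [(n, network.graph.nodes[n]["type"]) for n in sorted(network.graph.nodes)]
    if len(nodes) < 2:
        raise InteractionError("need at least 2 genes in the network to cluster")
    if k > len(nodes):
        raise InteractionError(f"k={k} exceeds number of network genes ({len(nodes)})")
    X = np.array([de.trajectory(g, t, value) for g, t in nodes], dtype=float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    link = hierarchy.linkage(Z, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    leaf_order = list(hierarchy.leaves_list(link))
    names = [n for n, _ in nodes]
    tps = np.arange(len(de.time_points))
    cluster_means = {}
    for cid in sorted(set(labels)):
        members = Z[labels == cid]
        mean = members.mean(axis=0)
        if len(tps) >= 4:
            spline = CubicSpline(tps, mean, bc_type="natural")
            smooth = spline(np.linspace(tps[0], tps[-1], 100))
        else:
            smooth = mean
        cluster_means[int(cid)] = {"mean": mean, "smooth": smooth}
    result = {
        "leaf_order": [names[i] for i in leaf_order],
        "labels": {names[i]: int(labels[i]) for i in range(len(names))},
        "linkage": link,
        "heatmap": pd.DataFrame(Z, index=names, columns=list(de.time_points)).iloc[leaf_order],
        "cluster_means": cluster_means,
    }
    if out_prefix is not None:
        fig, axes = plt.subplots(1, max(len(cluster_means), 1), figsize=(4 * len(cluster_means), 3))
        axes = np.atleast_1d(axes)
        for ax, (cid, cm) in zip(axes, sorted(cluster_means.items())):
            members = Z[labels == cid]
            for row in members:
                ax.plot(tps, row, color="#aaaaaa", lw=0.7)
            ax.plot(np.linspace(tps[0], tps[-1], len(cm["smooth"])), cm["smooth"],
                    color="#d62728", lw=2)
            ax.set_title(f"cluster {cid} (n={members.shape[0]})")
            ax.set_xticks(tps, de.time_points)
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_clusters.png", dpi=100)
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(5, 0.3 * len(names) + 1.5))
        hm = result["heatmap"]
        im = ax.imshow(hm.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(len(hm.index)), hm.index, fontsize=6)
        ax.set_xticks(range(len(hm.columns)), hm.columns)
        fig.colorbar(im, ax=ax, label="standardized " + value)
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_heatmap.png", dpi=100)
        plt.close(fig)
    return result
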