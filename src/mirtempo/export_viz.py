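"""Exports: PathVisio-importable data files, filtered-miRNA list, Cytoscape
network files (GraphML, SIF + edge attributes) and an in-package network
rendering.

All writers are deterministic: rows are sorted on stable keys and floats
are formatted with 10 significant digits, so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .data_ingest import IDMap, TimeCourseDE
from .interaction import InteractionNetwork

logger = logging.getLogger(__name__)

# PathVisio/BridgeDb system codes
SYSTEM_CODES = {"entrez": "L", "ensembl": "En"}


class ExportError(ValueError):
    pass


def _fmt(v: float) -> str:
    return "%.10g" % v


def write_pathvisio_data(
    de: TimeCourseDE,
    ids: IDMap,
    result: str = "log2fc",
    namespace: str = "entrez",
    out=None,
) -> dict:
    """Write the per-gene, per-time-point data file PathVisio imports.

    Columns: mapped gene ID, system code ("L" entrez / "En" ensembl), one
    ``<result>_<tp>`` column per time point in course order.  Genes without
    an ID in the chosen namespace are omitted and counted in the returned
    summary.
    """
    if result not in ("log2fc", "padj"):
        raise ExportError(f"result must be 'log2fc' or 'padj', got {result!r}")
    code = SYSTEM_CODES.get(namespace)
    if code is None:
        raise ExportError(f"unknown namespace {namespace!r}")
    labels = sorted({(g, t) for g, t in de.table[["gene", "gene_type"]].itertuples(index=False)})
    mapped = ids.to_namespace([g for g, _ in labels], namespace)
    omitted = 0
    rows = []
    seen_ids = set()
    for gene, gtype in labels:
        gid = mapped.get(gene)
        if gid is None:
            omitted += 1
            continue
        if gid in seen_ids:  # one row per mapped gene ID
            continue
        seen_ids.add(gid)
        vec = de.trajectory(gene, gtype, result)
        rows.append([gid, code] + [("NA" if not np.isfinite(v) else _fmt(v)) for v in vec])
    if not rows:
        raise ExportError(f"no gene has a {namespace} ID; nothing to export")
    rows.sort(key=lambda r: r[0])
    header = ["GeneID", "SystemCode"] + [f"{result}_{tp}" for tp in de.time_points]
    with open(out, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return {"written": len(rows), "omitted": omitted, "path": str(out)}


def read_pathvisio_data(path) -> pd.DataFrame:
    """Re-parse a PathVisio data file (round-trip check helper)."""
    df = pd.read_csv(path, sep="\t", dtype={"GeneID": str, "SystemCode": str})
    for col in df.columns[2:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_filtered_mirnas(network: InteractionNetwork, ids: IDMap, out, namespace: str = "entrez") -> int:
    """Write the network's miRNA nodes for PathVisio/MAPPbuilder upload.

    Three tab-separated columns: adjusted label, mapped ID (or the label if
    unmapped), system code.  Lexicographic order; -3p/-5p arms sharing one
    mapped ID stay distinct rows via their adjusted labels.
    """
    code = SYSTEM_CODES.get(namespace)
    if code is None:
        raise ExportError(f"unknown namespace {namespace!r}")
    mirnas = network.mirnas
    if not mirnas:
        logger.warning("empty network; writing empty filtered-miRNA file")
    mapped = ids.to_namespace(mirnas, namespace)
    with open(out, "w") as fh:
        fh.write("adjusted_label\tmapped_id\tsystem_code\n")
        for m in sorted(ids.adjusted(m) for m in mirnas):
            fh.write(f"{m}\t{mapped.get(m, m)}\t{code}\n")
    return len(mirnas)


def write_network(network: InteractionNetwork, fmt: str, out) -> list[str]:
    """Serialize the filtered network for Cytoscape import.

    ``fmt`` 'graphml': one GraphML file with node attribute "type" and edge
    attributes corr (full precision), votes and per-database 0/1 flags.
    ``fmt`` 'sif': edge list ``mirna<TAB>targets<TAB>mrna`` plus a sidecar
    ``<out>.attrs.tsv`` of edge attributes.  Returns written paths.
    """
    out = str(out)
    if fmt == "graphml":
        g = nx.Graph()
        for n in sorted(network.graph.nodes):
            g.add_node(n, type=network.graph.nodes[n]["type"])
        for m, t, d in network.edges:
            g.add_edge(m, t, **{k: d[k] for k in sorted(d)})
        nx.write_graphml(g, out)
        return [out]
    if fmt == "sif":
        edges = network.edges
        attr_names = sorted({k for _, _, d in edges for k in d})
        attrs_path = out + ".attrs.tsv"
        with open(out, "w") as fh:
            for m, t, _ in edges:
                fh.write(f"{m}\ttargets\t{t}\n")
        with open(attrs_path, "w") as fh:
            fh.write("source\ttarget\t" + "\t".join(attr_names) + "\n")
            for m, t, d in edges:
                vals = [_fmt(d[k]) if isinstance(d[k], float) else str(d[k]) for k in attr_names]
                fh.write(f"{m}\t{t}\t" + "\t".join(vals) + "\n")
        return [out, attrs_path]
    raise ExportError(f"unknown network format {fmt!r}")


def read_sif(path) -> list[tuple[str, str, str]]:
    """Parse a SIF file into (source, relation, target) triples."""
    triples = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                s, rel, t = line.split("\t")
                triples.append((s, rel, t))
    return triples


def render_network(network: InteractionNetwork, out=None, seed: int = 0) -> pd.DataFrame:
    """Draw the bipartite graph: miRNAs pink, mRNAs blue, edges colored by
    correlation (most negative maps to the colormap's low end).

    Returns the node position/color table so the mapping is testable
    without image inspection.  Empty network: warning, no file.
    """
    if network.graph.number_of_nodes() == 0:
        logger.warning("empty network; nothing to render")
        return pd.DataFrame(columns=["node", "type", "x", "y", "color_class"])
    pos = nx.spring_layout(network.graph, seed=seed)
    rows = []
    for n in sorted(network.graph.nodes):
        ntype = network.graph.nodes[n]["type"]
        rows.append(
            {
                "node": n,
                "type": ntype,
                "x": float(pos[n][0]),
                "y": float(pos[n][1]),
                "color_class": "pink" if ntype == "miRNA" else "blue",
            }
        )
    table = pd.DataFrame(rows)
    if out is not None:
        corrs = [d["corr"] for _, _, d in network.edges]
        cmap = plt.get_cmap("coolwarm")
        lo, hi = min(corrs), max(corrs)
        span = (hi - lo) or 1.0
        fig, ax = plt.subplots(figsize=(6, 6))
        node_colors = ["#f2a5c0" if network.graph.nodes[n]["type"] == "miRNA" else "#7aa6d9"
                       for n in network.graph.nodes]
        edge_colors = [cmap((d["corr"] - lo) / span) for _, _, d in network.graph.edges(data=True)]
        nx.draw_networkx(network.graph, pos=pos, ax=ax, node_color=node_colors,
                         edge_color=edge_colors, font_size=6, node_size=300)
        ax.set_axis_off()
        fig.tight_layout()
        fig.savefig(out, dpi=100)
        plt.close(fig)
    return table
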