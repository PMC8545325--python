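"""Per-context pathway overrepresentation analysis (hypergeometric tail).

For each context (a time point, a (time point, gene type) pair in separate
mode, or a temporal cluster) the overlap between the significant gene set
and each pathway is scored with the one-sided upper hypergeometric tail
P(X >= k), the standard ORA convention, and Benjamini-Hochberg adjusted
within the context.  The background universe defaults to all genes present
in the input DE data ("auto") and can be replaced by the user (e.g. the
probes of an array platform).
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import comb
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_ingest import IDMap, SignificantSets
from .pathway_resources import PathwaySet

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed with exact integer binomial coefficients (so it is correct to
    full float precision on gene-set-sized inputs), where N is the universe
    size, K the pathway size, n the drawn (significant) set size and k the
    observed overlap.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v != int(v) or v < 0:
            raise EnrichmentError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N or k > min(n, K):
        raise EnrichmentError(f"invalid bounds: k={k}, K={K}, n={n}, N={N}")
    total = comb(N, n)
    acc = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return float(Fraction(acc, total))


def benjamini_hochberg(p_raw: Iterable[float]) -> np.ndarray:
    """BH step-up adjusted p-values (FDR), order-preserving."""
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _map_set(labels: Iterable[str], ids: IDMap | None, namespace: str) -> set[str]:
    if ids is None:
        return set(labels)
    return set(ids.to_namespace(labels, namespace).values())


def enrich_per_context(
    sig: SignificantSets,
    pathways: PathwaySet,
    universe: Iterable[str] | str = "auto",
    ids: IDMap | None = None,
    keep_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Overrepresentation table: one row per (context, pathway).

    Significant sets and pathway members are intersected with the universe
    before counting.  When an ID map is given, gene labels are translated to
    the pathway namespace (unmapped labels drop out; shared mapped IDs are
    de-duplicated).  BH adjustment runs within each context across its
    pathways.  Rows with zero overlap are dropped by default (they carry
    p_raw near 1 and no signal).

    Columns: context, pathway_id, pathway_name, k, n, K, N, p_raw, p_adj.
    """
    ns = pathways.namespace
    if isinstance(universe, str) and universe == "auto":
        all_labels = set().union(*sig.all_genes.values()) if sig.all_genes else set()
        uni = _map_set(all_labels, ids, ns)
    else:
        uni = set(universe)
    if not uni:
        raise EnrichmentError("universe is empty")

    rows = []
    for context, labels in sig.sets.items():
        gene_set = _map_set(labels, ids, ns) & uni
        n = len(gene_set)
        for p in pathways:
            members = p.members & uni
            K = len(members)
            if K == 0:
                continue
            k = len(gene_set & members)
            rows.append(
                {
                    "context": context,
                    "pathway_id": p.pathway_id,
                    "pathway_name": p.name,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": len(uni),
                    "p_raw": hypergeom_tail(k, K, n, len(uni)),
                }
            )
    tab = pd.DataFrame(rows, columns=["context", "pathway_id", "pathway_name", "k", "n", "K", "N", "p_raw"])
    if tab.empty:
        tab["p_adj"] = pd.Series(dtype=float)
        return tab
    tab["p_adj"] = np.nan
    for _, idx in tab.groupby("context", sort=False).groups.items():
        tab.loc[idx, "p_adj"] = benjamini_hochberg(tab.loc[idx, "p_raw"])
    if not keep_zero_overlap:
        tab = tab[tab["k"] > 0].reset_index(drop=True)
    return tab


def rank_and_barplot(
    tab: pd.DataFrame,
    context,
    top: int = 10,
    out=None,
) -> list[tuple[str, float]]:
    """Top pathways for a context ordered by adjusted p (most significant first).

    Writes a horizontal bar plot of -log10(p_adj) when ``out`` is given and
    returns the plotted (pathway_id, p_adj) list so ordering is testable
    without reading the image.
    """
    contexts = set(tab["context"]) if not tab.empty else set()
    if context not in contexts:
        raise EnrichmentError(f"unknown context {context!r}")
    sub = tab[tab["context"] == context].sort_values(
        ["p_adj", "pathway_id"], kind="mergesort"
    )
    sub = sub.head(top)
    pairs = list(zip(sub["pathway_id"], sub["p_adj"]))
    if not pairs:
        logger.warning("context %r has no pathways with non-zero overlap", context)
    if out is not None:
        fig, ax = plt.subplots(figsize=(6, max(1.5, 0.4 * max(len(pairs), 1))))
        if pairs:
            names = [p for p, _ in pairs][::-1]
            vals = [-np.log10(max(q, 1e-300)) for _, q in pairs][::-1]
            ax.barh(names, vals, color="#4878d0")
        ax.set_xlabel("-log10 adjusted p")
        ax.set_title(str(context))
        fig.tight_layout()
        fig.savefig(out, dpi=100)
        plt.close(fig)
    return pairs
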