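"""Synthetic fixture generator with planted, recorded ground truth.

Every input the pipeline consumes — per-time-point DE tables for miRNAs
and mRNAs, a GMT pathway file, three target-database tables (one with
miRTarBase-style evidence strings including some "Weak" labels), and an ID
map — is generated at toy scale from a seeded spec, with the planted
structure written to a machine-readable truth file:

* planted *enriched* pathways are stuffed with genes that are significant
  at their planted time points;
* planted *cluster* pathways get disjoint member sets whose per-time-point
  significant counts follow a named shape (monotone-up, monotone-down,
  pulse);
* planted *interactions* get anticorrelated log2fc trajectories
  (mRNA = -a * miRNA + Gaussian noise) and configurable database flags,
  so with noise_sd = 0 each planted pair has Pearson correlation exactly -1.

The defaults mirror a five-time-point post-baseline injury time course
(days 1, 2, 3, 7, 14) at a scale that runs in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pathway_resources import ALL_DBS

DEFAULT_TIME_POINTS = ("D1", "D2", "D3", "D7", "D14")

# significant-count templates per shape, scaled to pathway size
CLUSTER_SHAPES = {
    "monotone-up": (0.1, 0.3, 0.5, 0.75, 1.0),
    "monotone-down": (1.0, 0.75, 0.5, 0.3, 0.1),
    "pulse": (0.1, 0.6, 1.0, 0.6, 0.1),
}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedInteraction:
    mirna: str
    mrna: str
    slope: float  # a > 0 in mRNA = -a * miRNA + noise
    dbs: tuple[str, ...]  # databases listing the pair


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded description of one synthetic dataset and its planted truth."""

    seed: int = 0
    n_mirna: int = 30
    n_mrna: int = 60
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_pathways: int = 10
    pathway_size: int = 12
    noise_sd: float = 0.0
    n_planted_interactions: int = 6
    planted_enriched_time_point: str = "D1"
    planted_cluster_shapes: tuple[str, ...] = ("monotone-up", "pulse")
    alpha: float = 0.05
    interaction_dbs: tuple[tuple[str, ...], ...] = field(
        default=(("targetscan", "mirtarbase"),)
    )

    def validate(self) -> None:
        if min(self.n_mirna, self.n_mrna, self.n_pathways, self.pathway_size) < 1:
            raise FixtureError("all counts must be >= 1")
        if len(self.time_points) != len(set(self.time_points)):
            raise FixtureError("time points must be unique")
        if self.planted_enriched_time_point not in self.time_points:
            raise FixtureError("planted enriched time point not in time_points")
        for shape in self.planted_cluster_shapes:
            if shape not in CLUSTER_SHAPES:
                raise FixtureError(f"unknown cluster shape {shape!r}")
            if len(self.time_points) != len(CLUSTER_SHAPES[shape]):
                raise FixtureError("cluster shapes are defined for 5 time points")
        if self.n_planted_interactions > min(self.n_mirna, self.n_mrna):
            raise FixtureError("more planted interactions than genes")
        if self.noise_sd < 0:
            raise FixtureError("noise_sd must be >= 0")
        for combo in self.interaction_dbs:
            for db in combo:
                if db not in ALL_DBS:
                    raise FixtureError(f"unknown database {db!r}")


def make_shape_trajectories(
    seed: int = 0,
    shapes: tuple[str, ...] = ("monotone-up", "pulse"),
    n_per_shape: int = 6,
    noise_sd: float = 0.0,
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS,
):
    """Trajectory matrix with planted shapes, for clustering benchmarks.

    Returns (TrajectoryMatrix, truth) where truth maps row id -> shape.
    With noise_sd = 0 all rows of one shape are identical.
    """
    from .temporal_clustering import TrajectoryMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows, truth = {}, {}
    for shape in shapes:
        if shape not in CLUSTER_SHAPES:
            raise FixtureError(f"unknown cluster shape {shape!r}")
        template = 4.0 * np.asarray(CLUSTER_SHAPES[shape])
        for i in range(n_per_shape):
            rid = f"{shape}-{i}"
            rows[rid] = template + rng.normal(0, noise_sd, len(time_points))
            truth[rid] = shape
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(time_points))
    return TrajectoryMatrix(df), truth


def _sig_padj(rng) -> float:
    return float(rng.uniform(1e-4, 0.01))


def _nonsig_padj(rng) -> float:
    return float(rng.uniform(0.2, 0.9))


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Generate the full fixture file set plus its truth record.

    Writes mirna_de.tsv, mrna_de.tsv, pathways.gmt, targetscan.tsv,
    mirdb.tsv, mirtarbase.tsv, idmap.tsv and truth.json under ``out_dir``
    and returns the truth record.  Regeneration from the same spec is
    byte-identical.
    """
    spec.validate()
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    T = len(spec.time_points)

    mirnas = [f"mmu-miR-{100 + i}-5p" for i in range(spec.n_mirna)]
    mrnas = [f"Gene{i:03d}" for i in range(spec.n_mrna)]

    # --- trajectories & significance -------------------------------------
    mirna_fc = {m: rng.normal(0, 1, T) for m in mirnas}
    mrna_fc = {g: rng.normal(0, 1, T) for g in mrnas}
    mirna_padj = {m: np.array([_nonsig_padj(rng) for _ in range(T)]) for m in mirnas}
    mrna_padj = {g: np.array([_nonsig_padj(rng) for _ in range(T)]) for g in mrnas}

    # planted interactions: first k miRNAs paired with first k mRNAs,
    # anticorrelated trajectories, significant everywhere so they survive
    # the significance filter
    planted_interactions = []
    db_combos = spec.interaction_dbs
    for i in range(spec.n_planted_interactions):
        m, g = mirnas[i], mrnas[i]
        slope = float(rng.uniform(0.5, 2.0))
        base = rng.normal(0, 1, T)
        while np.std(base) == 0:  # pragma: no cover - measure-zero event
            base = rng.normal(0, 1, T)
        mirna_fc[m] = base
        mrna_fc[g] = -slope * base + rng.normal(0, spec.noise_sd, T)
        mirna_padj[m] = np.array([_sig_padj(rng) for _ in range(T)])
        mrna_padj[g] = np.array([_sig_padj(rng) for _ in range(T)])
        combo = db_combos[i % len(db_combos)]
        planted_interactions.append(PlantedInteraction(m, g, slope, tuple(combo)))

    # decoy interactions: listed in every database but with exactly
    # orthogonal trajectories (Pearson 0), so they can never pass the
    # correlation filter regardless of the vote count
    decoy_pairs = []
    k = spec.n_planted_interactions
    for i in range(k, min(k + 4, spec.n_mirna, spec.n_mrna)):
        m, g = mirnas[i], mrnas[i]
        x = mirna_fc[m] - mirna_fc[m].mean()
        y = mrna_fc[g] - mrna_fc[g].mean()
        y = y - (y @ x) / (x @ x) * x  # residualize: corr(x, y) == 0
        mrna_fc[g] = y
        decoy_pairs.append((m, g))

    # --- pathways ---------------------------------------------------------
    # reserve disjoint blocks of non-interaction mRNAs for planted pathways
    pool = [g for g in mrnas if g not in {p.mrna for p in planted_interactions}]
    cursor = 0

    def take(n):
        nonlocal cursor
        if cursor + n > len(pool):
            raise FixtureError("n_mrna too small for the planted pathway structure")
        block = pool[cursor : cursor + n]
        cursor += n
        return block

    pathways = {}
    truth_clusters = {}

    # planted-enriched pathway: members significant at the planted time point
    enriched_id = "WP_ENR"
    tp_idx = spec.time_points.index(spec.planted_enriched_time_point)
    enr_members = take(spec.pathway_size)
    for g in enr_members:
        mrna_padj[g][tp_idx] = _sig_padj(rng)
    pathways[enriched_id] = ("Planted enriched pathway", enr_members)

    # planted cluster-shape pathways: per-time-point significant counts
    # follow the shape template
    for si, shape in enumerate(spec.planted_cluster_shapes):
        pid = f"WP_CL{si + 1}"
        members = take(spec.pathway_size)
        counts = [max(1, round(f * spec.pathway_size)) for f in CLUSTER_SHAPES[shape]]
        for t, cnt in enumerate(counts):
            for g in members[:cnt]:
                mrna_padj[g][t] = _sig_padj(rng)
            for g in members[cnt:]:
                mrna_padj[g][t] = _nonsig_padj(rng)
        pathways[pid] = (f"Planted {shape} pathway", members)
        truth_clusters[pid] = {"shape": shape, "counts": counts}

    # interaction pathway: exactly the planted-interaction mRNAs
    interaction_pid = "WP_INT"
    pathways[interaction_pid] = (
        "Planted interaction pathway",
        [p.mrna for p in planted_interactions],
    )

    # decoy pathways: random members from the remaining pool
    n_decoys = max(0, spec.n_pathways - len(pathways))
    for d in range(n_decoys):
        members = sorted(rng.choice(pool, size=min(spec.pathway_size, len(pool)), replace=False))
        pathways[f"WP_DEC{d + 1}"] = (f"Decoy pathway {d + 1}", list(members))

    # --- ID map -----------------------------------------------------------
    # entrez IDs: sequential; both arms of the first miRNA pair share one
    # entrez ID to exercise the adjusted-label rule
    id_rows = []
    entrez_of = {}
    for i, g in enumerate(mrnas):
        entrez_of[g] = str(10000 + i)
        id_rows.append((g, entrez_of[g], f"ENSMUSG{10000 + i:011d}"))
    shared_arm = None
    for i, m in enumerate(mirnas):
        entrez_of[m] = str(20000 + i)
        id_rows.append((m, entrez_of[m], f"ENSMUSG{20000 + i:011d}"))
    if spec.n_mirna >= 1:
        # add a -3p arm sharing the -5p arm's entrez ID
        arm5 = mirnas[0]
        shared_arm = arm5.replace("-5p", "-3p")
        id_rows.append((shared_arm, entrez_of[arm5], f"ENSMUSG{20000:011d}"))

    # --- write files ------------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)

    def write_de(path, genes, fc, padj):
        with open(path, "w") as fh:
            cols = ["gene"]
            for tp in spec.time_points:
                cols += [f"log2fc_{tp}", f"padj_{tp}"]
            fh.write("\t".join(cols) + "\n")
            for g in genes:
                vals = []
                for t in range(T):
                    vals += ["%.10g" % fc[g][t], "%.10g" % padj[g][t]]
                fh.write(g + "\t" + "\t".join(vals) + "\n")

    write_de(out_dir / "mirna_de.tsv", mirnas, mirna_fc, mirna_padj)
    write_de(out_dir / "mrna_de.tsv", mrnas, mrna_fc, mrna_padj)

    with open(out_dir / "pathways.gmt", "w") as fh:
        for pid, (name, members) in pathways.items():
            ids = sorted(entrez_of[g] for g in members)
            fh.write("\t".join([name, pid, *ids]) + "\n")

    with open(out_dir / "idmap.tsv", "w") as fh:
        fh.write("input_label\tentrez\tensembl\n")
        for label, entrez, ensembl in id_rows:
            fh.write(f"{label}\t{entrez}\t{ensembl}\n")

    # target databases: planted pairs per their combos, decoys in all three
    db_pairs: dict[str, list[tuple[str, str]]] = {db: [] for db in ALL_DBS}
    for p in planted_interactions:
        for db in p.dbs:
            db_pairs[db].append((p.mirna, entrez_of[p.mrna]))
    for m, g in decoy_pairs:
        for db in ALL_DBS:
            db_pairs[db].append((m, entrez_of[g]))
    # weak-evidence rows exercised in mirtarbase: pad with weak entries
    weak_rows = [
        (mirnas[-1], entrez_of[mrnas[-1]], "Functional MTI (Weak)"),
        (mirnas[-2], entrez_of[mrnas[-2]], "Functional MTI (Weak)"),
    ]
    for db in ("targetscan", "mirdb"):
        with open(out_dir / f"{db}.tsv", "w") as fh:
            fh.write("mirna\ttarget\n")
            for m, t in sorted(db_pairs[db]):
                fh.write(f"{m}\t{t}\n")
    with open(out_dir / "mirtarbase.tsv", "w") as fh:
        fh.write("mirna\ttarget\tevidence\n")
        rows = [(m, t, "Functional MTI") for m, t in db_pairs["mirtarbase"]] + weak_rows
        for m, t, ev in sorted(rows):
            fh.write(f"{m}\t{t}\t{ev}\n")

    # --- truth record -----------------------------------------------------
    sig_mrnas = {
        tp: sorted(g for g in mrnas if mrna_padj[g][t] <= spec.alpha)
        for t, tp in enumerate(spec.time_points)
    }
    sig_mirnas = {
        tp: sorted(m for m in mirnas if mirna_padj[m][t] <= spec.alpha)
        for t, tp in enumerate(spec.time_points)
    }
    truth = {
        "seed": spec.seed,
        "time_points": list(spec.time_points),
        "alpha": spec.alpha,
        "noise_sd": spec.noise_sd,
        "planted_interactions": [
            {"mirna": p.mirna, "mrna": p.mrna, "slope": p.slope, "dbs": list(p.dbs)}
            for p in planted_interactions
        ],
        "decoy_db_pairs": [[m, g] for m, g in decoy_pairs],
        "interaction_pathway": interaction_pid,
        "enriched_pathway": enriched_id,
        "enriched_time_point": spec.planted_enriched_time_point,
        "enriched_overlap": len(enr_members),
        "cluster_pathways": truth_clusters,
        "significant_mrnas": sig_mrnas,
        "significant_mirnas": sig_mirnas,
        "shared_entrez_arms": [mirnas[0], shared_arm] if shared_arm else [],
        "entrez_of": entrez_of,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def truth_check(
    network_edges: set[tuple[str, str]],
    truth: dict,
    enrichment_rank: int | None = None,
    cluster_assignment: dict | None = None,
    min_dbs: int = 1,
) -> dict:
    """Compare pipeline outputs with planted truth.

    ``network_edges`` are (miRNA label, mRNA label) pairs from the filtered
    network.  Planted pairs only count as expected when they carry at least
    ``min_dbs`` database flags.  Returns recall/precision of the planted
    interactions, the planted pathway's enrichment rank if given, and
    permutation-invariant cluster agreement if given.
    """
    for key in ("planted_interactions", "enriched_pathway"):
        if key not in truth:
            raise FixtureError(f"truth record missing field {key!r}")
    expected = {
        (p["mirna"], p["mrna"])
        for p in truth["planted_interactions"]
        if len(p["dbs"]) >= min_dbs
    }
    tp = len(network_edges & expected)
    recall = tp / len(expected) if expected else 1.0
    precision = tp / len(network_edges) if network_edges else 1.0
    report = {
        "n_expected": len(expected),
        "n_found": len(network_edges),
        "recall": recall,
        "precision": precision,
    }
    if enrichment_rank is not None:
        report["enriched_pathway_rank"] = enrichment_rank
    if cluster_assignment is not None:
        from .temporal_clustering import best_label_agreement

        truth_assign = {
            pid: rec["shape"] for pid, rec in truth.get("cluster_pathways", {}).items()
        }
        report["cluster_agreement"] = best_label_agreement(
            {k: v for k, v in cluster_assignment.items() if k in truth_assign},
            truth_assign,
        )
    return report
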