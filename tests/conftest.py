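"""Shared fixtures: a seeded synthetic dataset with planted truth, loaded
into the pipeline's in-memory objects once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from mirtempo.data_ingest import filter_significant, map_ids, read_de_table
from mirtempo.pathway_resources import ALL_DBS, read_gmt, read_target_db
from mirtempo.simulate import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    truth = make_fixture(FixtureSpec(seed=7), d)
    return d, truth


@pytest.fixture(scope="session")
def loaded(fixture_dir):
    d, truth = fixture_dir
    tps = truth["time_points"]
    mirna = read_de_table(d / "mirna_de.tsv", "miRNA", tps)
    mrna = read_de_table(d / "mrna_de.tsv", "mRNA", tps)
    de = mirna.concat(mrna)
    ids = map_ids(de, d / "idmap.tsv")
    sig = filter_significant(de, mode="combined", alpha=truth["alpha"])
    pathways = read_gmt(d / "pathways.gmt", "entrez")
    dbs = {name: read_target_db(d / f"{name}.tsv", name) for name in ALL_DBS}
    return {
        "dir": d,
        "truth": truth,
        "de": de,
        "mirna": mirna,
        "mrna": mrna,
        "ids": ids,
        "sig": sig,
        "pathways": pathways,
        "dbs": dbs,
    }


@pytest.fixture()
def tiny_de():
    """3 genes x 2 time points, hand-written values."""
    table = pd.DataFrame(
        {
            "gene": ["G1", "G1", "G2", "G2", "miR-a", "miR-a"],
            "gene_type": ["mRNA", "mRNA", "mRNA", "mRNA", "miRNA", "miRNA"],
            "time_point": ["D1", "D2"] * 3,
            "log2fc": [1.0, 2.0, -0.5, 0.5, 0.3, -0.3],
            "padj": [0.04, 0.2, 0.01, 0.01, 0.04, 0.5],
        }
    )
    from mirtempo.data_ingest import TimeCourseDE

    return TimeCourseDE(table, ("D1", "D2"))
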