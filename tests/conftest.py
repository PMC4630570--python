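from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ccanet import simulate

DATA_DIR = Path(__file__).parent / "data"

# per-family TF lists read off the published regulator-intersection figure:
# TFs correlated with pathway metabolites vs with biosynthetic genes
FIG5B_METABOLITE_TFS = {
    "AP2": ["Ii076", "Ii080", "Ii065", "Ii064", "Ii077"],
    "DREB": ["Ii100", "Ii059", "Ii074", "Ii007", "Ii073"],
    "ERF": ["Ii103", "Ii102", "Ii075", "Ii006", "Ii085"],
    "RAV": ["Ii052", "Ii053"],
    "Soloist": ["Ii049", "Ii050"],
}
FIG5B_GENE_TFS = {
    "AP2": ["Ii080", "Ii083", "Ii062", "Ii039", "Ii016"],
    "DREB": ["Ii098", "Ii007", "Ii034", "Ii014", "Ii028"],
    "ERF": ["Ii019", "Ii099", "Ii096", "Ii094", "Ii060"],
    "RAV": [],
    "Soloist": ["Ii049", "Ii050"],
}

# printed per-pair variable correlation coefficients for the Ii4CL transcript
II4CL_SCORES = {
    "coniferin": -0.23,
    "lariciresinol": 0.75,
    "secoisolariciresinol": 0.41,
    "pinoresinol": 0.60,
}


@pytest.fixture(scope="session")
def table2_pairs() -> pd.DataFrame:
    df = pd.read_csv(DATA_DIR / "table2_duplicate_pairs.tsv", sep="\t")
    return df.rename(columns={"ID1": "id1", "ID2": "id2", "Identity (%)": "identity_pct"})


@pytest.fixture(scope="session")
def noise_free_expression() -> pd.DataFrame:
    cfg = simulate.default_induction_config(noise_cv=0.0, seed=11)
    return simulate.gen_timecourse_expression(cfg)


@pytest.fixture(scope="session")
def default_config() -> simulate.InductionConfig:
    return simulate.default_induction_config(noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def protein_set():
    spec = simulate.ProteinSetSpec(
        n_decoys=6,
        duplicate_pairs=(("Ii001", "Ii001dup", 0.96), ("Ii005", "Ii005dup", 0.90)),
        seed=42,
    )
    return simulate.gen_protein_set(spec), spec


def fig5b_networks():
    """Encode the published per-family TF lists as two bipartite networks."""
    from ccanet.cca import BipartiteNetwork

    def as_network(per_family: dict, right: str) -> BipartiteNetwork:
        tfs = sorted({t for ts in per_family.values() for t in ts})
        edges = tuple((t, right, 0.6, 1) for t in tfs)
        return BipartiteNetwork(
            left_nodes=tuple(tfs), right_nodes=(right,), edges=edges, cutoff=0.5
        )

    labels = {}
    for fam, ts in FIG5B_METABOLITE_TFS.items():
        labels.update({t: fam for t in ts})
    for fam, ts in FIG5B_GENE_TFS.items():
        labels.update({t: fam for t in ts})
    return (
        as_network(FIG5B_METABOLITE_TFS, "lignans"),
        as_network(FIG5B_GENE_TFS, "pathway"),
        labels,
    )
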