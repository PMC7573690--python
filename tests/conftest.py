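import networkx as nx
import pytest

from oligodist.io import ProteinRecord


@pytest.fixture
def ten_records():
    """k-multiset {1 x4, 2 x3, 4 x2, 6 x1} of known homo-oligomers."""
    ks = [1, 1, 1, 1, 2, 2, 2, 4, 4, 6]
    return [
        ProteinRecord(protein_id=f"P{i}", length_aa=300, oligomer_k=k, is_homo=True)
        for i, k in enumerate(ks)
    ]


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")])
    return g


@pytest.fixture
def proteome_tsv(tmp_path):
    path = tmp_path / "proteome.tsv"
    path.write_text(
        "protein_id\torganism\tlength_aa\tsubunit_annotation\tgo_terms\tabundance\n"
        "P1\teco\t300\tHomotetramer.\tcatalytic\t12.5\n"
        "P2\teco\t250\tHomodimer; can also form homotetramers.\ttransport\t\n"
        "P3\teco\t400\tHeterodimer of subunits A and B.\t\t3.0\n"
    )
    return path


@pytest.fixture
def string_tsv(tmp_path):
    path = tmp_path / "interactions.tsv"
    header = (
        "ecoli_interaction_id_a\tecoli_interaction_id_b\tecoli_interaction_mode"
        "\tecoli_interaction_action\ta_is_acting\tscore\n"
    )
    rows = [
        "A\tB\tbinding\t\tf\t900",
        "B\tA\tbinding\t\tf\t900",
        "A\tA\tbinding\t\tf\t900",
        "B\tC\tbinding\t\tf\t150",
        "C\tD\tbinding\t\tf\t700",
    ]
    path.write_text(header + "\n".join(rows) + "\n")
    return path
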