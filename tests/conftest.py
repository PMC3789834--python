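import networkx as nx
import pytest

from motifnet import CoexpressionNetwork, PromoterSet


def make_fasta(path, records):
    """Write a dict of {header: sequence} as FASTA."""
    with open(path, "w") as fh:
        for header, seq in records.items():
            fh.write(f">{header}\n{seq}\n")
    return path


def make_network(edges, threshold=0.05):
    """Build a CoexpressionNetwork from (a, b, pcor) triples."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, pcor=w)
    return CoexpressionNetwork(graph=g, pcor_threshold=threshold)


@pytest.fixture
def star_promoters():
    """Hub + 5 leaves; the motif CACGTG sits in 4 of the 6 promoters."""
    pad = "A" * 200
    records = {}
    for i, gene in enumerate(["HUB", "N1", "N2", "N3", "N4", "N5"]):
        if i < 4:
            # motif abuts the TSS: strongly position-biased
            records[gene] = pad[: 200 - 16] + "CACGTG" + pad[:10]
        else:
            records[gene] = pad
    return PromoterSet(records=records, nominal_length=200)


@pytest.fixture
def star_network():
    return make_network([("HUB", n, 0.2) for n in ["N1", "N2", "N3", "N4", "N5"]])
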