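"""Bundled benchmark data."""

from importlib import resources

from .graph import WeightedNetwork
from .io import read_edgelist


def karate_club(weighted: bool = False) -> WeightedNetwork:
    """Zachary's Karate Club (34 nodes, 78 edges).

    The standard unweighted graph by default; ``weighted=True`` returns
    Zachary's original interaction counts as edge weights.
    """
    name = "karate_club_weighted.tsv" if weighted else "karate_club.tsv"
    path = resources.files("nqmod.data") / name
    with resources.as_file(path) as p:
        return read_edgelist(p, node_labels=[str(i) for i in range(34)])
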