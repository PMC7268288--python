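"""Packaged literature fixtures: the curated RPL differentially-expressed miRNA
table and the narrated TF-miRNA loop network.

The miRNA table is kept verbatim as curated (35 records, including one
duplicated hsa-miR-30d-5p entry and negative log-scale fold values for four
down-regulated miRNAs; ``<0.001`` p-values are retained as text).  The loop
network encodes, edge by edge, the regulatory relationships narrated for
recurrent pregnancy loss: six miRNAs targeting NFKB1, the NFKB1-centered
feedback loops (the NFKB1/hsa-miR-21-5p pair forming a double-negative
switch), the STAT3/STAT5/E2F1/REL/ESR1 regulations of hsa-miR-21-5p and
hsa-miR-17-5p, their downstream targets, and the direct ESR1->NFKB1 edge that
closes the ESR1/hsa-miR-21-5p/NFKB1 incoherent feedforward loop.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .netmodel import (
    RegulatoryNetwork,
    assemble_network,
    read_edge_table,
    read_node_table,
)


def _data_path(name: str):
    return resources.files("regnet.data").joinpath(name)


def dem_mirna_table() -> pd.DataFrame:
    """The curated differentially-expressed miRNA attribute table, verbatim."""
    with resources.as_file(_data_path("rpl_dem_mirnas.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)


def rpl_fixture() -> tuple[RegulatoryNetwork, pd.DataFrame]:
    """The narrated RPL loop network plus the miRNA attribute table."""
    with resources.as_file(_data_path("rpl_loop_nodes.tsv")) as p:
        nodes = read_node_table(str(p))
    with resources.as_file(_data_path("rpl_loop_edges.tsv")) as p:
        edges = read_edge_table(str(p))
    net = assemble_network(nodes, edges, prune=False)
    return net, dem_mirna_table()
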