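"""Small packaged worked-example tables for the colorectal-cancer network study.

Two published summary tables ship with the package so the replay stages and
the worked examples run without the (non-redistributable) full interaction
network: the top-10 hub/bottleneck ranking of the CRC protein-protein
interaction network, and the bottleneck-hub x subnetwork interaction-strength
matrix.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_top10_table", "load_strength_table"]


def _path(name: str):
    return resources.files("ppinet.data").joinpath(name)


def load_top10_table() -> pd.DataFrame:
    """Top-10 hubs (degree) and bottlenecks (betweenness) of the CRC PPI network."""
    with resources.as_file(_path("crc_top10_hubs_bottlenecks.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_strength_table() -> pd.DataFrame:
    """Bottleneck-hub x subnetwork interaction-strength cells (no totals)."""
    with resources.as_file(_path("crc_bnh_subnetwork_strengths.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="bnh")
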