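"""A-priori networks on the AAL-116 parcellation.

The default mode (DMN), central executive (CEN) and salience (SAL) networks
are each represented by 10 distinct AAL nodes. The bundled node table maps
the classical region-family descriptions of these networks onto lateralized
AAL labels; it is a documented choice and can be replaced by any YAML file
mapping network names to lists of AAL labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import edges

NETWORK_SIZE = 10


def aal116_labels() -> pd.DataFrame:
    """The bundled AAL-116 label table (columns: index, label)."""
    with resources.files("connectoscramble.data").joinpath("aal116.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class NetworkDefinition:
    """A named brain subnetwork as a set of parcel indices."""

    name: str
    nodes: tuple[int, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"network {self.name!r} has duplicate nodes")
        for v in self.nodes:
            if not 0 <= v < edges.N_NODES:
                raise ValueError(
                    f"network {self.name!r}: node {v} outside [0, {edges.N_NODES})"
                )

    @property
    def inner_edges(self) -> np.ndarray:
        """Edges with both endpoints in the network (45 for 10 nodes)."""
        return edges.inner_edges(self.nodes)

    @property
    def connecting_edges(self) -> np.ndarray:
        """Edges with >=1 endpoint in the network (1105 for 10 nodes in 116)."""
        return edges.connecting_edges(self.nodes)

    def edge_set(self, mode: str) -> np.ndarray:
        if mode == "inner":
            return self.inner_edges
        if mode == "connecting":
            return self.connecting_edges
        raise ValueError(f"unknown edge mode {mode!r} (inner|connecting)")


def load_networks(path: str | Path | None = None) -> dict[str, NetworkDefinition]:
    """Load network definitions from YAML (bundled defaults when path is None).

    The YAML maps network name -> list of AAL labels; labels are resolved
    against the bundled AAL-116 table.
    """
    if path is None:
        with resources.files("connectoscramble.data").joinpath(
            "networks.yaml"
        ).open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    table = aal116_labels()
    lookup = dict(zip(table["label"], table["index"]))
    out = {}
    for name, labels in raw.items():
        missing = [lab for lab in labels if lab not in lookup]
        if missing:
            raise ValueError(f"network {name!r}: unknown AAL labels {missing}")
        out[name] = NetworkDefinition(
            name=name,
            nodes=tuple(int(lookup[lab]) for lab in labels),
            labels=tuple(labels),
        )
    return out
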