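"""Colony-level trait assembly: one network in, one trait-table row out."""

from __future__ import annotations

import pandas as pd

from .core import MycelialNetwork
from .morphology import morphological_traits
from .network_traits import network_traits
from .robustness import robustness_traits

#: trait-table column order (morphology, network, robustness)
TRAIT_COLUMNS = [
    "mean_edge_length", "mean_tip_width", "mean_main_width",
    "mean_branch_angle", "length_density",
    "meshedness", "R_eff", "RT_eff", "G_eff", "G_eff_MST", "volume_MST",
    "R_eff_area", "RT_eff_area",
    "rob_random_single", "rob_random_chunk", "rob_asc_width",
    "rob_desc_width", "rob_desc_length",
]


def phenotype(net: MycelialNetwork, seed: int = 0, replicates: int = 100,
              chunk_k: int | None = None) -> dict[str, float | None]:
    """All measured traits of one colony as a flat dict.

    ``seed``/``replicates`` control the stochastic attack schemes; the
    other traits are deterministic.
    """
    row: dict[str, float | None] = {}
    row.update(morphological_traits(net).as_dict())
    row.update(network_traits(net).as_dict())
    row.update(robustness_traits(net, seed=seed, replicates=replicates,
                                 chunk_k=chunk_k))
    return row


def phenotype_table(nets, species=None, phylum=None, seed: int = 0,
                    replicates: int = 100, chunk_k: int | None = None) -> pd.DataFrame:
    """Trait table for a list of colonies (rows) with optional factor columns."""
    rows = []
    for i, net in enumerate(nets):
        row = phenotype(net, seed=seed + i, replicates=replicates, chunk_k=chunk_k)
        if species is not None:
            row["species"] = species[i]
        if phylum is not None:
            row["phylum"] = phylum[i]
        rows.append(row)
    cols = TRAIT_COLUMNS + [c for c in ("species", "phylum") if rows and c in rows[0]]
    return pd.DataFrame(rows, columns=cols)
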