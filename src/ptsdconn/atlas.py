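"""Parcellation atlases and the shared edge-indexing convention.

An atlas is a table of brain nodes (parcels), each carrying an
intrinsic-network label.  All connectivity matrices in this package are
indexed by atlas node order, and edge vectors use the upper triangle in
row-major order (``numpy.triu_indices(n, k=1)``) with 1-based node ids in
the on-disk formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

#: Intrinsic-network labels used by the default cortical parcellation.
DEFAULT_NETWORKS = (
    "default_mode",
    "frontoparietal",
    "cingulo_opercular",
    "salience",
    "dorsal_attention",
    "ventral_attention",
    "auditory",
    "visual",
    "somatomotor_hand",
    "somatomotor_mouth",
    "retrosplenial_temporal",
    "none",
)

SUBCORTICAL_LABEL = "subcortical"


@dataclass(frozen=True)
class ParcelAtlas:
    """A labelled brain parcellation.

    Parameters
    ----------
    table
        One row per node with columns ``node_id`` (consecutive integers
        from 1), ``node_name``, ``network`` and ``hemisphere``
        (``L``/``R``/``subcortical-neutral``); optional ``mni_x/y/z``.
    atlas_id
        Short identifier recorded in connectome sidecars.
    """

    table: pd.DataFrame
    atlas_id: str = "atlas"
    _net_codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"node_id", "node_name", "network"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"atlas table missing columns: {sorted(missing)}")
        ids = t["node_id"].to_numpy()
        if len(ids) == 0:
            raise FormatError("atlas table is empty")
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            bad = int(np.flatnonzero(ids != np.arange(1, len(ids) + 1))[0])
            raise FormatError(
                f"node_ids must be consecutive from 1; first violation at row {bad + 1}"
            )
        if t["node_name"].duplicated().any():
            dup = t.loc[t["node_name"].duplicated(), "node_name"].iloc[0]
            raise FormatError(f"duplicate node name: {dup!r}")
        if t["network"].isna().any():
            raise FormatError("every node needs a network label")
        object.__setattr__(self, "_net_codes", t["network"].to_numpy())

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def networks(self) -> np.ndarray:
        """Per-node network label, in node order."""
        return self._net_codes

    @property
    def network_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for lbl in self._net_codes:
            seen.setdefault(lbl)
        return list(seen)

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based (i, j) arrays for the upper-triangle edge order."""
        return np.triu_indices(self.n_nodes, k=1)

    def edge_networks(self) -> list[tuple[str, str]]:
        """Sorted unordered network-pair label per edge, in edge order."""
        iu, ju = self.edge_index()
        nets = self._net_codes
        return [tuple(sorted((nets[i], nets[j]))) for i, j in zip(iu, ju)]


def edges_to_flat(edges: set[tuple[int, int]], n_nodes: int) -> np.ndarray:
    """Map unordered 0-based node pairs to upper-triangle flat edge indices."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    out = []
    for a, b in edges:
        i, j = (a, b) if a < b else (b, a)
        if (i, j) not in lookup:
            raise FormatError(f"edge ({a}, {b}) not valid for {n_nodes} nodes")
        out.append(lookup[(i, j)])
    return np.asarray(sorted(out), dtype=np.intp)


def flat_to_edges(flat: np.ndarray, n_nodes: int) -> set[tuple[int, int]]:
    """Inverse of :func:`edges_to_flat`."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return {(int(iu[k]), int(ju[k])) for k in np.asarray(flat, dtype=np.intp)}


def make_atlas(
    n_cortical: int,
    subcortical_names: list[str],
    network_names: list[str] | tuple[str, ...] = DEFAULT_NETWORKS,
    seed: int = 0,
) -> ParcelAtlas:
    """Build a labelled parcellation with ``n_cortical`` cortical nodes.

    Cortical nodes are partitioned into contiguous blocks, one per network,
    with block sizes drawn (reproducibly from ``seed``) around equality so
    every network receives at least one node.  Subcortical nodes are
    appended with the ``subcortical`` label.  The default configuration
    (333 cortical nodes over 12 networks plus 10 subcortical regions)
    mirrors a high-resolution cortical template combined with subcortical
    regions, 343 nodes in total.
    """
    network_names = list(network_names)
    if n_cortical < len(network_names):
        raise FormatError("need at least one cortical node per network")
    if len(set(subcortical_names)) != len(subcortical_names):
        raise FormatError("subcortical names must be unique")
    if len(set(network_names)) != len(network_names):
        raise FormatError("network names must be unique")

    rng = np.random.default_rng(seed)
    k = len(network_names)
    # near-equal blocks; the remainder goes to seed-chosen networks
    sizes = np.full(k, n_cortical // k)
    extra = rng.choice(k, size=n_cortical % k, replace=False)
    sizes[extra] += 1

    rows = []
    nid = 1
    for net, size in zip(network_names, sizes):
        for _ in range(int(size)):
            hemi = "L" if nid % 2 else "R"
            rows.append((nid, f"ctx_{hemi}_{nid:03d}", net, hemi))
            nid += 1
    for name in subcortical_names:
        rows.append((nid, name, SUBCORTICAL_LABEL, "subcortical-neutral"))
        nid += 1

    table = pd.DataFrame(rows, columns=["node_id", "node_name", "network", "hemisphere"])
    return ParcelAtlas(table=table, atlas_id=f"synthetic_{len(table)}")
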