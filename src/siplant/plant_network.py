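"""The plant as a hydraulic-node network.

The whole plant is discretised into hydraulic nodes where a xylem and a
phloem resistor network meet; water moves along potential gradients
(circuit analogy), silicon rides the xylem stream, sucrose and the
root-bound signal ride the phloem stream.  This module holds the graph
data structures, the builder for the standard simplified rice plant
(one root segment, five stem junctions, five sheath+leaf pairs) and the
structural validator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import networkx as nx
import pandas as pd

from .config import PlantConfig


class Tissue(str, Enum):
    ROOT = "root"
    INTERNODE = "internode"
    JUNCTION = "junction"
    SHEATH = "sheath"
    LEAF = "leaf"


class Pathway(str, Enum):
    XYLEM = "xylem"
    PHLOEM = "phloem"


class BranchClass(str, Enum):
    NONE = "none"
    EVB = "EVB"  # enlarged vascular bundle: feeds the leaf attached at this stem node
    DVB = "DVB"  # diffuse vascular bundle: feeds the younger tissue above (Si-enriched)


@dataclass
class HydraulicNode:
    id: int
    tissue: Tissue
    v_st: float   # sieve-tube tissue volume, ml
    v_con: float  # conduit tissue volume, ml
    v_cyt: float  # cytoplasm volume of tissue cells, ml
    temperature: float  # K
    is_top_leaf: bool = False
    is_root: bool = False


@dataclass
class Edge:
    i: int
    j: int
    pathway: Pathway
    r: float  # flow resistance, MPa h ml^-1
    branch_class: BranchClass = BranchClass.NONE


@dataclass
class JunctionParams:
    node: int
    rho: float  # DVB enrichment factor, >= 1


@dataclass
class RootParams:
    tr_exo: float      # exodermal transport capability at max expression, ml h^-1
    tr_end: float      # endodermal transport capability, ml h^-1
    p_cm: float        # membrane permeability, ml h^-1
    v_cor: float       # cortex tissue volume, ml
    r_lat_root: float  # soil-to-root-xylem radial resistance, MPa h ml^-1
    psi_soil: float    # soil water potential boundary, MPa


@dataclass
class PlantGraph:
    nodes: list[HydraulicNode]
    edges: list[Edge]
    junctions: list[JunctionParams]
    root: RootParams
    r_lat: dict[int, float]  # per-node xylem<->phloem lateral resistance

    # -- convenience views ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root_index(self) -> int:
        return next(n.id for n in self.nodes if n.is_root)

    @property
    def leaf_indices(self) -> list[int]:
        return [n.id for n in self.nodes if n.tissue == Tissue.LEAF]

    @property
    def top_leaf_index(self) -> int:
        return next(n.id for n in self.nodes if n.is_top_leaf)

    @property
    def junction_indices(self) -> list[int]:
        return [n.id for n in self.nodes if n.tissue == Tissue.JUNCTION]

    def edges_of(self, pathway: Pathway) -> list[Edge]:
        return [e for e in self.edges if e.pathway == pathway]

    def rho_of(self, node: int) -> float:
        for jp in self.junctions:
            if jp.node == node:
                return jp.rho
        return 1.0

    def to_edge_csv(self, path) -> None:
        """Export the edge list (i, j, pathway, r, branch_class) for inspection."""
        df = pd.DataFrame(
            [(e.i, e.j, e.pathway.value, e.r, e.branch_class.value) for e in self.edges],
            columns=["i", "j", "pathway", "r", "branch_class"],
        )
        df.to_csv(path, index=False)


def build_standard_plant(config: Optional[PlantConfig] = None) -> PlantGraph:
    """Build the standard simplified rice plant.

    One root segment, ``n_leaves`` stem junctions chained by identical
    internodes, one sheath node per leaf, and both vascular networks wired
    in parallel.  The top (youngest) leaf is fed by the DVB branch of the
    highest junction; every lower leaf by the EVB branch of its junction,
    with the DVB branch continuing up the stem.

    Node ids: 0 = root, 1..L = junctions (bottom to top),
    L+1..2L = sheaths, 2L+1..3L = leaves.
    """
    cfg = config or PlantConfig()
    st, res, vol = cfg.structure, cfg.resistances, cfg.volumes
    L = st.n_leaves
    if L < 1:
        raise ValueError("need at least one leaf")
    for name in ("r_x_internode", "r_x_sheath", "r_x_leaf",
                 "r_p_internode", "r_p_sheath", "r_p_leaf", "r_lat"):
        if getattr(res, name) <= 0:
            raise ValueError(f"resistance {name} must be positive")
    for f in vol.__dataclass_fields__:
        if getattr(vol, f) <= 0:
            raise ValueError(f"volume {f} must be positive")
    if cfg.junctions.rho < 1.0:
        raise ValueError("DVB enrichment factor rho must be >= 1")
    if min(cfg.root.tr_exo, cfg.root.tr_end, cfg.root.p_cm) < 0:
        raise ValueError("root transport parameters must be non-negative")
    if cfg.root.v_cor <= 0 or cfg.root.r_lat_root <= 0:
        raise ValueError("root volume and radial resistance must be positive")

    T = st.temperature_K
    nodes: list[HydraulicNode] = []
    nodes.append(HydraulicNode(0, Tissue.ROOT, vol.v_st_root, vol.v_con_root,
                               vol.v_cyt_root, T, is_root=True))
    for k in range(1, L + 1):
        nodes.append(HydraulicNode(k, Tissue.JUNCTION, vol.v_st_junction,
                                   vol.v_con_junction, vol.v_cyt_junction, T))
    for k in range(1, L + 1):
        nodes.append(HydraulicNode(L + k, Tissue.SHEATH, vol.v_st_sheath,
                                   vol.v_con_sheath, vol.v_cyt_sheath, T))
    for k in range(1, L + 1):
        nodes.append(HydraulicNode(2 * L + k, Tissue.LEAF, vol.v_st_leaf,
                                   vol.v_con_leaf, vol.v_cyt_leaf, T,
                                   is_top_leaf=(k == L)))

    edges: list[Edge] = []

    def both(i, j, r_x, r_p, bc=BranchClass.NONE):
        edges.append(Edge(i, j, Pathway.XYLEM, r_x, bc))
        edges.append(Edge(i, j, Pathway.PHLOEM, r_p))

    # stem: root -> J1 -> ... -> JL
    both(0, 1, res.r_x_internode, res.r_p_internode)
    for k in range(1, L):
        both(k, k + 1, res.r_x_internode, res.r_p_internode, bc=BranchClass.DVB)
    # junction -> sheath -> leaf; top junction feeds its (top) leaf via DVB
    for k in range(1, L + 1):
        bc = BranchClass.DVB if k == L else BranchClass.EVB
        both(k, L + k, res.r_x_sheath, res.r_p_sheath, bc=bc)
        both(L + k, 2 * L + k, res.r_x_leaf, res.r_p_leaf)

    junctions = [JunctionParams(k, cfg.junctions.rho) for k in range(1, L + 1)]
    root = RootParams(cfg.root.tr_exo, cfg.root.tr_end, cfg.root.p_cm,
                      cfg.root.v_cor, cfg.root.r_lat_root, cfg.root.psi_soil)
    r_lat = {n.id: res.r_lat for n in nodes}
    return PlantGraph(nodes, edges, junctions, root, r_lat)


def validate_graph(g: PlantGraph) -> list[str]:
    """Check all structural invariants; returns a list of human-readable
    violations (empty iff the graph is valid).  Never raises."""
    violations: list[str] = []
    ids = {n.id for n in g.nodes}
    for n in g.nodes:
        for attr in ("v_st", "v_con", "v_cyt"):
            if getattr(n, attr) <= 0:
                violations.append(f"node {n.id}: {attr} must be > 0")
    roots = [n.id for n in g.nodes if n.is_root]
    if len(roots) != 1:
        violations.append(f"expected exactly one root node, found {roots}")
    tops = [n.id for n in g.nodes if n.is_top_leaf]
    if len(tops) != 1:
        violations.append(f"expected exactly one top leaf, found {tops}")
    node_by_id = {n.id: n for n in g.nodes}
    for e in g.edges:
        if e.r <= 0:
            violations.append(f"edge ({e.i},{e.j},{e.pathway.value}): resistance must be > 0")
        if e.i not in ids or e.j not in ids:
            violations.append(f"edge ({e.i},{e.j}): unknown endpoint")
            continue
        if (e.branch_class != BranchClass.NONE
                and node_by_id[e.i].tissue != Tissue.JUNCTION):
            violations.append(
                f"edge ({e.i},{e.j},{e.pathway.value}): branch class "
                f"{e.branch_class.value} on a non-junction tail node")
    for jp in g.junctions:
        if jp.rho < 1.0:
            violations.append(f"junction {jp.node}: rho must be >= 1")
    for i in ids:
        if g.r_lat.get(i, 0.0) <= 0:
            violations.append(f"node {i}: lateral resistance must be > 0")

    if roots:
        root_id = roots[0]
        for pathway in Pathway:
            sub = nx.Graph()
            sub.add_nodes_from(ids)
            sub.add_edges_from((e.i, e.j) for e in g.edges if e.pathway == pathway)
            if not nx.is_connected(sub):
                comps = [c for c in nx.connected_components(sub) if root_id not in c]
                stranded = sorted(set().union(*comps)) if comps else []
                violations.append(
                    f"{pathway.value} network is disconnected; nodes without a "
                    f"path to the root: {stranded}")
    return violations
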