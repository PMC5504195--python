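"""Shared fixtures: the standard plant, cached 4-day runs per control mode,
and a minimal hand-built two-node plant for closed-form oracles."""

from __future__ import annotations

import numpy as np
import pytest

from siplant import (ControlConfig, PlantGraph, build_standard_plant,
                     default_config, run_standard)
from siplant.plant_network import (BranchClass, Edge, HydraulicNode, Pathway,
                                   RootParams, Tissue)


@pytest.fixture()
def config():
    return default_config()


@pytest.fixture()
def plant(config):
    return build_standard_plant(config)


def make_two_node_plant(*, r_x=0.1, r_p=1.0, r_lat=2.0, v_st=0.1, v_con=0.1,
                        v_cyt=1.0, temperature=298.0) -> PlantGraph:
    """Root plus one leaf: the smallest valid plant, used to check the
    transport kernels against hand-assembled balances."""
    nodes = [
        HydraulicNode(0, Tissue.ROOT, v_st, v_con, v_cyt, temperature,
                      is_root=True),
        HydraulicNode(1, Tissue.LEAF, v_st, v_con, v_cyt, temperature,
                      is_top_leaf=True),
    ]
    edges = [Edge(0, 1, Pathway.XYLEM, r_x), Edge(0, 1, Pathway.PHLOEM, r_p)]
    root = RootParams(tr_exo=0.5, tr_end=1.0, p_cm=0.05, v_cor=1.0,
                      r_lat_root=0.05, psi_soil=0.0)
    return PlantGraph(nodes, edges, [], root, {0: r_lat, 1: r_lat})


def make_chain_plant(n: int, *, v_con=0.1, **kw) -> PlantGraph:
    """Root -> n-1 junctions -> leaf chain (single unbranched xylem path)
    for 1-D advection oracles."""
    nodes = [HydraulicNode(0, Tissue.ROOT, 0.1, v_con, 1.0, 298.0, is_root=True)]
    for i in range(1, n - 1):
        nodes.append(HydraulicNode(i, Tissue.INTERNODE, 0.1, v_con, 1.0, 298.0))
    nodes.append(HydraulicNode(n - 1, Tissue.LEAF, 0.1, v_con, 1.0, 298.0,
                               is_top_leaf=True))
    edges = []
    for i in range(n - 1):
        edges.append(Edge(i, i + 1, Pathway.XYLEM, 0.1))
        edges.append(Edge(i, i + 1, Pathway.PHLOEM, 1.0))
    root = RootParams(0.5, 1.0, 0.05, 1.0, 0.05, 0.0)
    return PlantGraph(nodes, edges, [], root, {i: 2.0 for i in range(n)})


@pytest.fixture(scope="session")
def constant_run():
    return run_standard(ControlConfig.for_mode("constant", 0.0, 0.0))


@pytest.fixture(scope="session")
def accumulation_run():
    return run_standard(ControlConfig.for_mode("accumulation", 0.02, 0.2))


@pytest.fixture(scope="session")
def shortage_run():
    return run_standard(ControlConfig.for_mode("shortage", 0.02, 0.2))


@pytest.fixture(scope="session")
def water_stress_run():
    cfg = default_config()
    ctrl = ControlConfig.for_mode(
        "water_stress", 0.2, 0.2,
        trans_signal_scale=cfg.signaling.trans_signal_scale)
    return run_standard(ctrl, cfg)


@pytest.fixture(scope="session")
def efficiency_table():
    from siplant import efficiency_experiment
    return efficiency_experiment()


def day_slice(traj, day: int):
    """Boolean mask for simulation day ``day`` (1-based)."""
    return (traj.t >= (day - 1) * 24.0) & (traj.t < day * 24.0)


def hours_into_day(traj, mask=None):
    t = traj.t if mask is None else traj.t[mask]
    return t % 24.0
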