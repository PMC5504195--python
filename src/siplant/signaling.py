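"""Shoot-to-root signaling and transporter expression control.

A signaling substance of unspecified identity (units arbitrary) is
generated in the leaves under one of three hypotheses -- in proportion to
leaf-cell Si (accumulation control), to the shortfall of leaf-cell Si
below a reference (shortage control), or to leaf transpiration (water
stress control) -- rides the phloem stream toward the root, and decays
first-order at rate dec.  The root transporter expression factor alpha
responds to the root signal concentration, with a delay chi for the
water-stress pathway:

    accumulation / water stress:  alpha = max(0, 1 - C_R(root, t - chi))
    shortage:                     alpha = min(1, C_R(root, t - chi))

Signal pools are tracked in (signal units) x ml with V_st mixing volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .hydraulics import WaterState
from .plant_network import PlantGraph, Pathway


class ControlMode(str, Enum):
    ACCUMULATION = "accumulation"
    SHORTAGE = "shortage"
    WATER_STRESS = "water_stress"
    CONSTANT = "constant"


@dataclass
class ControlConfig:
    mode: ControlMode = ControlMode.CONSTANT
    slp: float = 0.0          # generation-rate parameter (slp_c | slp_r | slp_J)
    dec: float = 0.0          # signal decay rate, h^-1
    chi: float = 0.0          # response delay, h (5 for water stress)
    shortage_ref: float = 1.0  # reference leaf-cell Si (mM) for the shortage drive
    trans_signal_scale: float = 1.0  # scale on per-leaf transpiration in the
    #                                  water-stress drive (signal units are arbitrary)

    def __post_init__(self):
        self.mode = ControlMode(self.mode)
        if self.slp < 0 or self.dec < 0 or self.chi < 0:
            raise ValueError("slp, dec and chi must be non-negative")

    @classmethod
    def for_mode(cls, mode, slp, dec, *, chi=None, **kw) -> "ControlConfig":
        """Build a config with the mode's conventional delay (chi = 5 h for
        water stress, 0 otherwise) unless overridden."""
        mode = ControlMode(mode)
        if chi is None:
            chi = 5.0 if mode == ControlMode.WATER_STRESS else 0.0
        return cls(mode=mode, slp=slp, dec=dec, chi=chi, **kw)


@dataclass
class SignalState:
    c_r: np.ndarray                       # per-node signal concentration
    history_t: list[float] = field(default_factory=list)   # root-signal record
    history_c: list[float] = field(default_factory=list)

    @classmethod
    def zeros(cls, g: PlantGraph) -> "SignalState":
        return cls(np.zeros(g.n_nodes))

    def record_root(self, t: float, c_root: float) -> None:
        self.history_t.append(t)
        self.history_c.append(c_root)


def generation_rate(mode: ControlMode, slp: float, c_m_cyt: float,
                    trans: float) -> float:
    """Signal generation rate in one leaf (dC_R/dt contribution).

    ``c_m_cyt`` must already be on the relative (reference-normalised)
    scale for shortage control; ``trans`` is the (scaled) leaf
    transpiration for water-stress control.
    """
    if c_m_cyt < 0 or trans < 0 or slp < 0:
        raise ValueError("generation inputs must be non-negative")
    mode = ControlMode(mode)
    if mode == ControlMode.ACCUMULATION:
        return slp * c_m_cyt
    if mode == ControlMode.SHORTAGE:
        return slp * max(0.0, 1.0 - c_m_cyt)
    if mode == ControlMode.WATER_STRESS:
        return slp * trans
    return 0.0  # constant control: no signal needed


class SignalStepper:
    """Precomputed kernel advancing the signal field one step."""

    def __init__(self, g: PlantGraph):
        self.g = g
        self.v_st = np.array([nd.v_st for nd in g.nodes])
        self.leaves = np.array(g.leaf_indices)
        self.nr = g.root_index
        pe = g.edges_of(Pathway.PHLOEM)
        self.pi_ = np.array([e.i for e in pe])
        self.pj_ = np.array([e.j for e in pe])

    def step(self, sig: SignalState, water: WaterState, ctrl: ControlConfig,
             gr_per_leaf: np.ndarray, dt: float, t: float) -> SignalState:
        """dC_R/dt = -dec*C_R + GR (leaves only) plus upwind phloem
        advection; records the root concentration at t + dt."""
        c = sig.c_r
        pools = c * self.v_st
        jw = water.j_w_p
        up_c = np.where(jw > 0, c[self.pi_], np.where(jw < 0, c[self.pj_], 0.0))
        flux = jw * up_c
        np.add.at(pools, self.pi_, -flux * dt)
        np.add.at(pools, self.pj_, flux * dt)
        pools[self.leaves] += np.asarray(gr_per_leaf, float) * self.v_st[self.leaves] * dt
        pools -= ctrl.dec * c * self.v_st * dt
        if np.any(pools < -1e-12):
            pools = np.maximum(pools, 0.0)
        new = SignalState(pools / self.v_st,
                          sig.history_t, sig.history_c)
        new.record_root(t + dt, float(new.c_r[self.nr]))
        return new


def step_signal(g: PlantGraph, sig: SignalState, water: WaterState,
                ctrl: ControlConfig, gr_per_leaf: np.ndarray, dt: float,
                t: float = 0.0) -> SignalState:
    """One-shot signal step (builds the kernel; use SignalStepper in loops)."""
    return SignalStepper(g).step(sig, water, ctrl, gr_per_leaf, dt, t)


def root_signal_at(sig: SignalState, t: float) -> float:
    """Root signal concentration at time t from the recorded history,
    linearly interpolated; times before the record equal the earliest
    recorded value (initial condition)."""
    if not sig.history_t:
        return 0.0
    return float(np.interp(t, sig.history_t, sig.history_c))


def expression_factor(ctrl: ControlConfig, sig: SignalState, t: float) -> float:
    """Transporter expression factor alpha from the (delayed) root signal."""
    if ctrl.mode == ControlMode.CONSTANT:
        return 1.0
    c_root = root_signal_at(sig, t - ctrl.chi)
    if ctrl.mode == ControlMode.SHORTAGE:
        return float(min(1.0, c_root))
    return float(max(0.0, 1.0 - c_root))
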