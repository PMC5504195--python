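"""Silicon uptake, xylem transport, node partitioning and unloading.

The root is a two-compartment model (cortex, stele) separated from the
soil and from each other by Casparian strips, so Si crosses by transporter
activity (tr_exo, tr_end, both scaled by the expression factor alpha) plus
a passive membrane leak (p_cm).  From the root stele, Si rides the xylem
transpiration stream (advection only, never against the flow).  At each
stem junction the stream splits between the diffuse vascular bundle (DVB,
serving younger tissue above) and the enlarged vascular bundle (EVB,
serving the leaf at that node); transporters enrich the DVB branch by the
factor rho while conserving Si mass.  Along the way Si is unloaded
first-order into the tissue cells, a terminal sink.

Si pools are tracked in umol (mM x ml); concentrations are mM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hydraulics import WaterState
from .plant_network import BranchClass, PlantGraph, Pathway, RootParams


@dataclass
class SiParams:
    k_m_unload: float = 0.1      # unloading rate constant, h^-1
    c_m_cor_init: float = 0.0    # initial cortex concentration, mM
    root_si_volume: str = "st"   # mixing volume of the root stele pool: "st"|"con"
    conserve_mass: bool = True   # junction partition: mass-conserving form (see junction_partition)


@dataclass
class SiState:
    c_m_out: float               # external (soil) Si concentration, mM
    c_m_cor: float               # root cortex concentration, mM
    c_m: np.ndarray              # per-node xylem concentration, mM
    c_m_cyt: np.ndarray          # per-node tissue-cell concentration, mM
    alpha: float = 1.0           # transporter expression factor, [0, 1]

    @classmethod
    def initial(cls, g: PlantGraph, c_m_out: float, params: SiParams) -> "SiState":
        return cls(c_m_out, params.c_m_cor_init,
                   np.zeros(g.n_nodes), np.zeros(g.n_nodes))


@dataclass
class SiStepDiagnostics:
    """Per-step fluxes for ledgers and the efficiency analysis (all umol h^-1)."""

    j_m_oc: float                # soil -> cortex
    j_m_cs: float                # cortex -> stele
    j_m_up: float                # stele -> first node above the root
    j_unload: np.ndarray         # per-node xylem -> cell unloading


def root_uptake_fluxes(s: SiState, root: RootParams, nr: int = 0) -> tuple[float, float]:
    """Transporter + leak fluxes across the exodermis and endodermis.

    J_oc = alpha*tr_exo*C_out - p_cm*(C_cor - C_out)
    J_cs = alpha*tr_end*C_cor - p_cm*(C_stele - C_cor)
    """
    if not 0.0 <= s.alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    j_oc = s.alpha * root.tr_exo * s.c_m_out - root.p_cm * (s.c_m_cor - s.c_m_out)
    j_cs = s.alpha * root.tr_end * s.c_m_cor - root.p_cm * (s.c_m[nr] - s.c_m_cor)
    return float(j_oc), float(j_cs)


def axial_si_flux(c_m_i: float, j_w_x: float) -> float:
    """Advective Si flux along a xylem edge; zero against the flow
    (only the transpiration stream carries Si upward)."""
    return c_m_i * j_w_x if j_w_x > 0 else 0.0


def junction_partition(c_m_i: float, j_w_dvb: float, j_w_evb: float,
                       rho: float, conserve_mass: bool = True
                       ) -> tuple[float, float]:
    """Split the junction xylem stream into DVB/EVB branch concentrations.

    The DVB branch is enriched rho-fold over the EVB branch; the branch
    concentrations satisfy J_dvb*C_dvb + J_evb*C_evb = (J_dvb+J_evb)*C_i
    so no Si is created or destroyed at the junction (``conserve_mass=True``,
    the default, puts rho on the DVB flow in the denominator; the
    alternative form with rho on the EVB flow is retained for comparison
    but does not balance mass).  Returns (C_dvb, C_evb).
    """
    if rho < 1.0:
        raise ValueError("rho must be >= 1")
    if j_w_dvb < 0 or j_w_evb < 0:
        raise ValueError("branch flows must be non-negative")
    total = j_w_dvb + j_w_evb
    if total == 0.0:
        warnings.warn("junction partition with zero branch flow; returning "
                      "unpartitioned concentration", stacklevel=2)
        return c_m_i, c_m_i
    denom = (rho * j_w_dvb + j_w_evb) if conserve_mass else (rho * j_w_evb + j_w_dvb)
    c_evb = total * c_m_i / denom
    return rho * c_evb, c_evb


def unload_flux(c_m_i: float, v_con_i: float, k_m_unload: float) -> float:
    """First-order unloading from the xylem into the tissue cells,
    J = k * C * V_con (umol h^-1)."""
    if min(c_m_i, v_con_i, k_m_unload) < 0:
        raise ValueError("unload inputs must be non-negative")
    return k_m_unload * c_m_i * v_con_i


def mixing_volumes(g: PlantGraph, params: SiParams) -> np.ndarray:
    """Per-node xylem mixing volume: V_con everywhere, except the root
    stele which uses V_st as printed in the root balance (configurable)."""
    v = np.array([nd.v_con for nd in g.nodes])
    if params.root_si_volume == "st":
        v[g.root_index] = g.nodes[g.root_index].v_st
    return v


def step_root(s: SiState, root: RootParams, j_m_up: float, dt: float,
              v_mix_root: float) -> SiState:
    """Advance the root cortex and stele pools one Euler step (used on its
    own by the calibration forward model; step_silicon inlines the same
    update for the whole plant)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    j_oc, j_cs = root_uptake_fluxes(s, root)
    c_cor = s.c_m_cor + dt * (j_oc - j_cs) / root.v_cor
    c_m = s.c_m.copy()
    c_m[0] += dt * (j_cs - j_m_up) / v_mix_root
    if c_cor < -0.01 * max(s.c_m_cor, 1e-12) or c_m[0] < -0.01 * max(s.c_m[0], 1e-12):
        raise RuntimeError("root Si pool overshot zero by more than 1%; reduce dt")
    if c_cor < 0 or c_m[0] < 0:
        warnings.warn("negative root Si pool clipped to zero", stacklevel=2)
        c_cor = max(c_cor, 0.0)
        c_m[0] = max(c_m[0], 0.0)
    return SiState(s.c_m_out, c_cor, c_m, s.c_m_cyt.copy(), s.alpha)


class SiliconStepper:
    """Precomputed kernel advancing the whole-plant Si state one step."""

    def __init__(self, g: PlantGraph, params: SiParams):
        self.g = g
        self.params = params
        self.v_mix = mixing_volumes(g, params)
        self.v_con = np.array([nd.v_con for nd in g.nodes])
        self.v_cyt = np.array([nd.v_cyt for nd in g.nodes])
        self.nr = g.root_index
        xe = g.edges_of(Pathway.XYLEM)
        self.xi = np.array([e.i for e in xe])
        self.xj = np.array([e.j for e in xe])
        self.branch = [e.branch_class for e in xe]
        # per junction: indices into the xylem edge list of its out-branches
        self.junction_branches: dict[int, dict[str, int]] = {}
        for idx, e in enumerate(xe):
            if e.branch_class != BranchClass.NONE:
                self.junction_branches.setdefault(e.i, {})[e.branch_class.value] = idx
        self.rho = {n: g.rho_of(n) for n in g.junction_indices}

    def step(self, s: SiState, water: WaterState, dt: float
             ) -> tuple[SiState, SiStepDiagnostics]:
        g, p = self.g, self.params
        c = s.c_m
        jw = water.j_w_x
        # effective advected concentration per edge: upstream node value,
        # replaced by the branch concentration at junction out-edges
        c_edge = np.where(jw > 0, c[self.xi], 0.0)
        for node, branches in self.junction_branches.items():
            i_dvb = branches.get("DVB")
            i_evb = branches.get("EVB")
            j_d = max(jw[i_dvb], 0.0) if i_dvb is not None else 0.0
            j_e = max(jw[i_evb], 0.0) if i_evb is not None else 0.0
            if j_d + j_e == 0.0 or c[node] == 0.0:
                continue
            c_dvb, c_evb = junction_partition(c[node], j_d, j_e,
                                              self.rho[node], p.conserve_mass)
            if i_dvb is not None and jw[i_dvb] > 0:
                c_edge[i_dvb] = c_dvb
            if i_evb is not None and jw[i_evb] > 0:
                c_edge[i_evb] = c_evb
        flux = np.where(jw > 0, jw * c_edge, 0.0)  # umol h^-1, oriented i->j

        pools = c * self.v_mix
        np.add.at(pools, self.xi, -flux * dt)
        np.add.at(pools, self.xj, flux * dt)

        j_unl = p.k_m_unload * c * self.v_con
        pools -= j_unl * dt
        c_cyt = s.c_m_cyt + j_unl * dt / self.v_cyt

        j_oc, j_cs = root_uptake_fluxes(s, g.root)
        c_cor = s.c_m_cor + dt * (j_oc - j_cs) / g.root.v_cor
        pools[self.nr] += j_cs * dt
        j_up = float(flux[(self.xi == self.nr)].sum())

        if np.any(pools < -0.01 * np.maximum(c * self.v_mix, 1e-12)) or \
                c_cor < -0.01 * max(s.c_m_cor, 1e-12):
            raise RuntimeError("Si pool overshot zero by more than 1%; reduce dt")
        if np.any(pools < 0) or c_cor < 0:
            warnings.warn("negative Si pool clipped to zero", stacklevel=2)
            pools = np.maximum(pools, 0.0)
            c_cor = max(c_cor, 0.0)
        new = SiState(s.c_m_out, c_cor, pools / self.v_mix, c_cyt, s.alpha)
        return new, SiStepDiagnostics(j_oc, j_cs, j_up, j_unl)

    def total_si(self, s: SiState) -> float:
        """Total Si in the plant (umol): cortex + xylem pools + cell pools."""
        return (s.c_m_cor * self.g.root.v_cor
                + float(np.sum(s.c_m * self.v_mix))
                + float(np.sum(s.c_m_cyt * self.v_cyt)))


def step_silicon(g: PlantGraph, s: SiState, water: WaterState,
                 params: SiParams, dt: float) -> tuple[SiState, SiStepDiagnostics]:
    """One-shot whole-plant Si step (builds the kernel; use SiliconStepper
    in loops)."""
    return SiliconStepper(g, params).step(s, water, dt)
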