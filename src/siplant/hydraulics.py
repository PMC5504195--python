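"""Coupled xylem/phloem water flow and sucrose/starch carbon dynamics.

Water: the two vascular networks are resistor circuits.  Axial xylem flow
follows the xylem water-potential gradient, axial phloem flow follows the
hydraulic (turgor) pressure gradient P = Psi_P - Pi, and the two circuits
exchange water laterally at every node through r_lat.  Because the osmotic
potential Pi = -R T C_S is fixed by the instantaneous sucrose state, the
node balance (sum of flows = 0 at every node) is a linear system in the
potentials and is re-solved quasi-statically every step.  Boundary
conditions: prescribed transpiration flux out of every leaf xylem node and
a fixed soil water potential behind the root radial resistance.

Carbon: photosynthesis builds a leaf starch pool; starch converts to
sucrose at rate k4 and is loaded into the leaf phloem; sucrose advects
with phloem water (upwind) and is respired everywhere at rate k1.  This
Munch loop is what couples sugar status to phloem flow: starch depletion
by dawn collapses the leaf osmotic drive and with it the downward phloem
stream.

Sucrose pools are tracked in umol; concentrations C_S = pool / V_st are in
mol m^-3 (umol / ml == mol m^-3, ml == 1e-6 m^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .plant_network import PlantGraph, Pathway

R_GAS = 8.314  # J mol^-1 K^-1


def osmotic_potential(c_s: float | np.ndarray, temperature: float | np.ndarray):
    """Osmotic potential Pi = -R*T*C_S in MPa (van 't Hoff).

    c_s in mol m^-3, temperature in K.  Always <= 0.
    """
    c_s = np.asarray(c_s, dtype=float)
    if np.any(c_s < 0):
        raise ValueError("sucrose concentration must be non-negative")
    if np.any(np.asarray(temperature) <= 0):
        raise ValueError("temperature must be positive")
    out = -R_GAS * np.asarray(temperature, dtype=float) * c_s * 1e-6
    return out if out.ndim else float(out)


def sucrose_axial_flow(j_w_p: float, c_s_i: float, c_s_j: float) -> float:
    """Upwind axial phloem solute flow: the flow carries the upstream
    concentration (umol h^-1 for flow in ml h^-1, C in mol m^-3)."""
    if j_w_p > 0:
        return j_w_p * c_s_i
    if j_w_p < 0:
        return j_w_p * c_s_j
    return 0.0


@dataclass
class WaterState:
    """Solved potentials and flows for one time step.

    Edge flows are oriented with the stored edge (positive i -> j, i.e.
    rootward node to shootward node); ``j_w_lat`` is positive for
    xylem -> phloem transfer.
    """

    psi_x: np.ndarray   # xylem water potential per node, MPa
    psi_p: np.ndarray   # phloem water potential per node, MPa
    p_p: np.ndarray     # phloem hydraulic pressure per node, MPa
    pi: np.ndarray      # osmotic potential per node, MPa
    j_w_x: np.ndarray   # per xylem edge, ml h^-1
    j_w_p: np.ndarray   # per phloem edge, ml h^-1
    j_w_lat: np.ndarray  # per node, ml h^-1
    soil_inflow: float   # ml h^-1 into the root xylem
    transpiration: np.ndarray  # per-leaf boundary outflow, ml h^-1


class WaterSolver:
    """Pre-factorised linear solver for the node water balance.

    The system matrix depends only on the network resistances, so it is
    LU-factorised once; per step only the right-hand side (osmotic terms
    and boundary fluxes) changes.
    """

    def __init__(self, g: PlantGraph):
        self.g = g
        self.n = g.n_nodes
        self.xedges = g.edges_of(Pathway.XYLEM)
        self.pedges = g.edges_of(Pathway.PHLOEM)
        self.xi = np.array([e.i for e in self.xedges])
        self.xj = np.array([e.j for e in self.xedges])
        self.gx = np.array([1.0 / e.r for e in self.xedges])
        self.pi_ = np.array([e.i for e in self.pedges])
        self.pj_ = np.array([e.j for e in self.pedges])
        self.gp = np.array([1.0 / e.r for e in self.pedges])
        self.g_lat = np.array([1.0 / g.r_lat[i] for i in range(self.n)])
        self.root = g.root_index
        self.leaves = np.array(g.leaf_indices)
        self.g_root = 1.0 / g.root.r_lat_root
        self.temperature = np.array([nd.temperature for nd in g.nodes])

        n = self.n
        M = np.zeros((2 * n, 2 * n))
        # xylem rows (0..n-1): sum_j gx*(PsiX_i - PsiX_j) + g_lat*(PsiX_i - PsiP_i)
        for a, b, gv in zip(self.xi, self.xj, self.gx):
            M[a, a] += gv
            M[a, b] -= gv
            M[b, b] += gv
            M[b, a] -= gv
        M[np.arange(n), np.arange(n)] += self.g_lat
        M[np.arange(n), n + np.arange(n)] -= self.g_lat
        M[self.root, self.root] += self.g_root
        # phloem rows (n..2n-1): sum gp*(PsiP_i - PsiP_j) + g_lat*(PsiP_i - PsiX_i)
        for a, b, gv in zip(self.pi_, self.pj_, self.gp):
            M[n + a, n + a] += gv
            M[n + a, n + b] -= gv
            M[n + b, n + b] += gv
            M[n + b, n + a] -= gv
        M[n + np.arange(n), n + np.arange(n)] += self.g_lat
        M[n + np.arange(n), np.arange(n)] -= self.g_lat
        self.matrix = M
        try:
            self.lu = lu_factor(M)
        except Exception as exc:  # pragma: no cover - guarded by validate_graph
            raise RuntimeError(f"singular water-balance system: {exc}") from exc

    def solve(self, c_s: np.ndarray, transpiration_per_leaf: np.ndarray) -> WaterState:
        """Solve for all potentials given sucrose state and leaf transpiration.

        ``c_s``: per-node phloem sucrose concentration (mol m^-3);
        ``transpiration_per_leaf``: boundary outflow per leaf node (ml h^-1),
        ordered as ``g.leaf_indices``.
        """
        n = self.n
        pi = np.asarray(osmotic_potential(c_s, self.temperature))
        rhs = np.zeros(2 * n)
        rhs[self.leaves] -= transpiration_per_leaf
        rhs[self.root] += self.g_root * self.g.root.psi_soil
        # phloem rows: the osmotic part of P = Psi_P - Pi moved to the RHS
        np.add.at(rhs, n + self.pi_, self.gp * (pi[self.pi_] - pi[self.pj_]))
        np.add.at(rhs, n + self.pj_, self.gp * (pi[self.pj_] - pi[self.pi_]))
        u = lu_solve(self.lu, rhs)
        psi_x, psi_p = u[:n], u[n:]
        p_p = psi_p - pi
        j_w_x = (psi_x[self.xi] - psi_x[self.xj]) * self.gx
        j_w_p = (p_p[self.pi_] - p_p[self.pj_]) * self.gp
        j_w_lat = (psi_x - psi_p) * self.g_lat
        soil_inflow = (self.g.root.psi_soil - psi_x[self.root]) * self.g_root
        return WaterState(psi_x, psi_p, p_p, pi, j_w_x, j_w_p, j_w_lat,
                          float(soil_inflow), np.asarray(transpiration_per_leaf, float))

    def residuals(self, w: WaterState) -> np.ndarray:
        """Node-wise |sum of flows| for both circuits (conservation audit)."""
        n = self.n
        res = np.zeros(2 * n)
        np.add.at(res, self.xi, w.j_w_x)
        np.add.at(res, self.xj, -w.j_w_x)
        res[:n] += w.j_w_lat
        res[self.leaves] += w.transpiration
        res[self.root] -= w.soil_inflow
        np.add.at(res, n + self.pi_, w.j_w_p)
        np.add.at(res, n + self.pj_, -w.j_w_p)
        res[n:] -= w.j_w_lat
        return np.abs(res)


def solve_water(g: PlantGraph, c_s: np.ndarray,
                transpiration_per_leaf: np.ndarray) -> WaterState:
    """One-shot water solve (builds the solver; use WaterSolver in loops)."""
    return WaterSolver(g).solve(np.asarray(c_s, float),
                                np.asarray(transpiration_per_leaf, float))


# --------------------------------------------------------------------------
# carbon
# --------------------------------------------------------------------------

@dataclass
class CarbonParams:
    """Respiration (k1), starch conversion (k4) and loading constants."""

    k1: float = 8.0e-5
    k4: float = 0.1
    k1_time_factor: float = 3600.0
    loading_frac: float = 1.0

    @property
    def k1_per_h(self) -> float:
        return self.k1 * self.k1_time_factor


@dataclass
class CarbonState:
    """Starch per leaf (umol sucrose-equivalent) and per-node phloem
    sucrose pools (umol); ``c_s`` is the derived concentration."""

    starch: np.ndarray   # per leaf, umol
    sucrose: np.ndarray  # per node pool, umol

    @classmethod
    def zeros(cls, g: PlantGraph) -> "CarbonState":
        return cls(np.zeros(len(g.leaf_indices)), np.zeros(g.n_nodes))

    def c_s(self, v_st: np.ndarray) -> np.ndarray:
        return self.sucrose / v_st


def step_carbon(state: CarbonState, params: CarbonParams,
                photosynthesis_per_leaf: np.ndarray, water: WaterState,
                g: PlantGraph, dt: float, *,
                _pedge_idx=None) -> CarbonState:
    """Advance starch and sucrose one explicit-Euler step.

    ``photosynthesis_per_leaf``: umol sucrose-equivalent h^-1 entering each
    leaf starch pool.  Starch converts to sucrose at k4 and is loaded into
    the leaf phloem pool; sucrose advects upwind along phloem flows and is
    respired everywhere at k1 (converted to h^-1).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_st = np.array([nd.v_st for nd in g.nodes])
    leaves = np.array(g.leaf_indices)
    starch = state.starch + (np.asarray(photosynthesis_per_leaf, float)
                             - params.k4 * state.starch) * dt
    pool = state.sucrose.copy()
    pool[leaves] += params.loading_frac * params.k4 * state.starch * dt

    c = state.sucrose / v_st
    if _pedge_idx is None:
        pe = g.edges_of(Pathway.PHLOEM)
        pi_ = np.array([e.i for e in pe])
        pj_ = np.array([e.j for e in pe])
    else:
        pi_, pj_ = _pedge_idx
    jw = water.j_w_p
    up_c = np.where(jw > 0, c[pi_], np.where(jw < 0, c[pj_], 0.0))
    j_s = jw * up_c
    np.add.at(pool, pi_, -j_s * dt)
    np.add.at(pool, pj_, j_s * dt)

    pool -= params.k1_per_h * state.sucrose * dt

    ref = np.maximum(state.sucrose, 1e-12)
    if np.any(pool < -0.01 * ref) or np.any(starch < -0.01 * np.maximum(state.starch, 1e-12)):
        raise RuntimeError(
            "carbon pool overshot zero by more than 1%: time step too large, "
            "reduce dt")
    if np.any(pool < 0) or np.any(starch < 0):
        warnings.warn("negative carbon pool clipped to zero", stacklevel=2)
        pool = np.maximum(pool, 0.0)
        starch = np.maximum(starch, 0.0)
    return CarbonState(starch, pool)
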