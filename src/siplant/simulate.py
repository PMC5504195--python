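"""Boundary forcing, the 4-day simulation driver, and the analyses.

The standard artificial forcing is a repeating 24-h cycle: 14 h of light
and 10 h of darkness, transpiration and photosynthesis shaped as a
trapezoid rising linearly from lights-on to a 2-h flat peak centred on
midday and falling back by lights-off; night transpiration is held at 10%
of the standard rate (0.4 ml cm^-2 day^-1) and night photosynthesis is
zero.  A reader for field forcing (eddy-covariance latent heat flux LE and
net ecosystem exchange NEE) converts measured fluxes to the same model
units.

The driver composes, per explicit-Euler step: water solve -> carbon step
-> silicon step -> signal generation/transport -> expression factor.

Analyses: investment efficiency IE = (top-leaf Si unloaded) / (integral
of alpha) over a time window, the water-stress sensitivity experiment
(constant vs low/intermediate/high sensitivity), and the sucrose
cyclic-stability scan over the (k1, k4) grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PlantConfig, default_config
from .hydraulics import CarbonParams, CarbonState, WaterSolver
from .plant_network import PlantGraph, Pathway, build_standard_plant, validate_graph
from .signaling import (ControlConfig, ControlMode, SignalState, SignalStepper,
                        expression_factor, generation_rate)
from .silicon import SiliconStepper, SiParams, SiState

STANDARD_TRANSPIRATION = 0.4    # ml cm^-2 day^-1
STANDARD_PHOTOSYNTHESIS = 0.0015  # model photosynthesis units (treated as given)
NIGHT_TRANSPIRATION_FRACTION = 0.10
DAY_HOURS = 14.0
NIGHT_HOURS = 10.0
PEAK_HOURS = 2.0
LATENT_HEAT_VAPORIZATION = 2.45e6  # J kg^-1


@dataclass
class Forcing:
    """Boundary time series on an hourly-unit grid.

    ``transpiration`` and ``photosynthesis`` are in forcing units
    (ml cm^-2 day^-1 and model photosynthesis units); the driver scales
    them by leaf area to per-leaf flows.
    """

    t: np.ndarray               # h
    transpiration: np.ndarray
    photosynthesis: np.ndarray
    temperature: np.ndarray     # K
    day_mask: np.ndarray        # True in the light period

    def to_csv(self, path) -> None:
        # 17 significant digits so float64 values survive the round trip
        pd.DataFrame({
            "time_h": self.t,
            "transpiration": self.transpiration,
            "photosynthesis": self.photosynthesis,
            "temperature": self.temperature,
            "day": self.day_mask.astype(int),
        }).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Forcing":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"time_h", "transpiration", "photosynthesis", "temperature"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"forcing CSV missing columns: {sorted(missing)}")
        t = df["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("forcing time grid must be strictly increasing")
        day = (df["day"].to_numpy(int).astype(bool) if "day" in df.columns
               else df["photosynthesis"].to_numpy(float) > 0)
        return cls(t, df["transpiration"].to_numpy(float),
                   df["photosynthesis"].to_numpy(float),
                   df["temperature"].to_numpy(float), day)

    def interp(self, tq: np.ndarray) -> "Forcing":
        """Resample onto a new grid (nearest-sample day mask)."""
        idx = np.clip(np.searchsorted(self.t, tq, side="right") - 1, 0, len(self.t) - 1)
        return Forcing(np.asarray(tq, float),
                       np.interp(tq, self.t, self.transpiration),
                       np.interp(tq, self.t, self.photosynthesis),
                       np.interp(tq, self.t, self.temperature),
                       self.day_mask[idx])


def _trapezoid_shape(tod: np.ndarray) -> np.ndarray:
    """Daily waveform on [0, 24): 0 at lights-on, linear rise to a 2-h flat
    peak (value 1) centred on midday, linear fall to lights-off, 0 at night."""
    midday = DAY_HOURS / 2.0
    rise = midday - PEAK_HOURS / 2.0            # 6 h
    fall_start = midday + PEAK_HOURS / 2.0      # 8 h
    s = np.zeros_like(tod)
    m = (tod >= 0) & (tod < rise)
    s[m] = tod[m] / rise
    m = (tod >= rise) & (tod < fall_start)
    s[m] = 1.0
    m = (tod >= fall_start) & (tod < DAY_HOURS)
    s[m] = (DAY_HOURS - tod[m]) / (DAY_HOURS - fall_start)
    return s


def generate_standard_forcing(days: int = 4, dt: float = 0.05,
                              temperature: float = 298.0) -> Forcing:
    """The artificial diurnal boundary condition (see module docstring)."""
    if days < 1:
        raise ValueError("days must be >= 1")
    n_per_day = 24.0 / dt
    if abs(n_per_day - round(n_per_day)) > 1e-9:
        dt = 24.0 / round(n_per_day)
        warnings.warn(f"dt does not divide the 24-h photoperiod; snapped to {dt}",
                      stacklevel=2)
    n = int(round(days * 24.0 / dt))
    t = np.arange(n) * dt
    tod = t % 24.0
    shape = _trapezoid_shape(tod)
    day_mask = tod < DAY_HOURS
    floor = NIGHT_TRANSPIRATION_FRACTION * STANDARD_TRANSPIRATION
    trans = floor + (STANDARD_TRANSPIRATION - floor) * shape
    trans[~day_mask] = floor
    phot = STANDARD_PHOTOSYNTHESIS * shape
    phot[~day_mask] = 0.0
    temp = np.full(n, float(temperature))
    return Forcing(t, trans, phot, temp, day_mask)


def read_field_forcing(path, *, latent_heat: float = LATENT_HEAT_VAPORIZATION,
                       nee_scale: float = 1.0,
                       default_temperature: float = 298.0) -> Forcing:
    """Convert eddy-covariance field measurements to model forcing.

    Expects columns ``time`` (h), ``LE`` (W m^-2), ``NEE`` and optionally
    ``temperature`` (K).  Transpiration = LE / latent heat of vaporization,
    converted to ml cm^-2 day^-1 (1 kg m^-2 = 1 mm = 0.1 ml cm^-2);
    photosynthesis = -NEE clipped at zero, scaled by ``nee_scale`` into
    model photosynthesis units.  Gaps (NaN) are linearly interpolated.
    """
    df = pd.read_csv(path)
    for col in ("time", "LE", "NEE"):
        if col not in df.columns:
            raise ValueError(f"field forcing CSV missing required column {col!r}")
    t = df["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("field forcing time grid must be strictly increasing")

    def fill(x):
        x = np.asarray(x, float)
        if np.isnan(x).any():
            warnings.warn("field forcing gaps linearly interpolated", stacklevel=2)
            ok = ~np.isnan(x)
            x = np.interp(t, t[ok], x[ok])
        return x

    le = fill(df["LE"])
    nee = fill(df["NEE"])
    # W m^-2 -> kg m^-2 s^-1 -> mm day^-1 -> ml cm^-2 day^-1
    trans = np.clip(le, 0.0, None) / latent_heat * 86400.0 * 0.1
    phot = np.clip(-nee, 0.0, None) * nee_scale
    temp = (fill(df["temperature"]) if "temperature" in df.columns
            else np.full_like(t, default_temperature))
    return Forcing(t, trans, phot, temp, phot > 0)


# --------------------------------------------------------------------------
# trajectory and driver
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded state snapshots over the simulation."""

    t: np.ndarray
    day_mask: np.ndarray
    alpha: np.ndarray
    psi_x: np.ndarray        # (n_rec, n_nodes)
    psi_p: np.ndarray
    c_s: np.ndarray          # sucrose concentration, mol m^-3
    starch: np.ndarray       # (n_rec, n_leaves), umol
    c_m: np.ndarray          # xylem Si, mM
    c_m_cyt: np.ndarray      # tissue-cell Si, mM
    c_m_cor: np.ndarray
    c_r: np.ndarray          # signal concentration
    j_unload: np.ndarray     # per-node unloading flux, umol h^-1
    j_w_p_root_edge: np.ndarray  # phloem flow on the root-to-first-junction edge
    cumulative_uptake: np.ndarray   # integral of soil->cortex flux, umol
    total_si: np.ndarray     # plant Si inventory, umol
    top_leaf: int
    leaf_indices: list[int]
    root_index: int
    max_water_residual: float = 0.0

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format (time_h, node_id, variable, value)."""
        frames = []
        per_node = {"psi_x": self.psi_x, "psi_p": self.psi_p, "c_s": self.c_s,
                    "c_m": self.c_m, "c_m_cyt": self.c_m_cyt, "c_r": self.c_r,
                    "j_unload": self.j_unload}
        n = self.psi_x.shape[1]
        for name, arr in per_node.items():
            df = pd.DataFrame(arr, columns=range(n))
            df["time_h"] = self.t
            long = df.melt(id_vars="time_h", var_name="node_id", value_name="value")
            long["variable"] = name
            frames.append(long)
        scalars = pd.DataFrame({"time_h": self.t, "node_id": -1,
                                "value": self.alpha, "variable": "alpha"})
        frames.append(scalars)
        return pd.concat(frames, ignore_index=True)[
            ["time_h", "node_id", "variable", "value"]]


def run_simulation(g: PlantGraph, forcing: Forcing, ctrl: ControlConfig,
                   config: Optional[PlantConfig] = None, *,
                   days: Optional[float] = None, dt: Optional[float] = None,
                   record_stride: Optional[int] = None,
                   components: Sequence[str] = ("carbon", "silicon", "signal"),
                   ) -> Trajectory:
    """Run the whole-plant simulation (default: the 4-day standard run).

    Deterministic: the model has no random element.  ``components`` can
    drop "silicon"/"signal" for carbon-only scans.
    """
    cfg = config or default_config()
    days = days if days is not None else cfg.simulation.days
    dt = dt if dt is not None else cfg.simulation.dt
    stride = record_stride if record_stride is not None else cfg.simulation.record_stride
    problems = validate_graph(g)
    if problems:
        raise ValueError("invalid plant graph: " + "; ".join(problems))

    n_steps = int(round(days * 24.0 / dt))
    tgrid = np.arange(n_steps) * dt
    if forcing.t[-1] < tgrid[-1] - 1e-9:
        raise ValueError("forcing does not cover the simulation span")
    fr = forcing.interp(tgrid)

    leaf_area = cfg.structure.leaf_area_cm2
    leaves = g.leaf_indices
    nl = len(leaves)
    top = g.top_leaf_index
    top_pos = leaves.index(top)
    # forcing units -> per-leaf flows
    trans_per_leaf = fr.transpiration * leaf_area / 24.0           # ml h^-1
    phot_per_leaf = fr.photosynthesis * leaf_area * cfg.carbon.assimilation_scale

    solver = WaterSolver(g)
    cparams = CarbonParams(cfg.carbon.k1, cfg.carbon.k4,
                           cfg.carbon.k1_time_factor, cfg.carbon.loading_frac)
    sparams = SiParams(cfg.silicon.k_m_unload, root_si_volume=cfg.silicon.root_si_volume)
    si_step = SiliconStepper(g, sparams)
    sig_step = SignalStepper(g)
    pe = g.edges_of(Pathway.PHLOEM)
    pedge_idx = (np.array([e.i for e in pe]), np.array([e.j for e in pe]))
    root_pedge = next(k for k, e in enumerate(pe) if e.i == g.root_index
                      or e.j == g.root_index)

    carbon = CarbonState.zeros(g)
    si = SiState.initial(g, cfg.silicon.c_m_out, sparams)
    sig = SignalState.zeros(g)
    sig.record_root(0.0, 0.0)
    alpha = 1.0 if ctrl.mode != ControlMode.SHORTAGE else expression_factor(ctrl, sig, 0.0)
    v_st = np.array([nd.v_st for nd in g.nodes])

    do_carbon = "carbon" in components
    do_si = "silicon" in components
    do_sig = "signal" in components and ctrl.mode != ControlMode.CONSTANT

    rec_idx = list(range(0, n_steps, stride))
    nrec = len(rec_idx)
    nn = g.n_nodes
    out = Trajectory(
        t=tgrid[rec_idx], day_mask=fr.day_mask[rec_idx],
        alpha=np.zeros(nrec), psi_x=np.zeros((nrec, nn)), psi_p=np.zeros((nrec, nn)),
        c_s=np.zeros((nrec, nn)), starch=np.zeros((nrec, nl)),
        c_m=np.zeros((nrec, nn)), c_m_cyt=np.zeros((nrec, nn)),
        c_m_cor=np.zeros(nrec), c_r=np.zeros((nrec, nn)),
        j_unload=np.zeros((nrec, nn)), j_w_p_root_edge=np.zeros(nrec),
        cumulative_uptake=np.zeros(nrec), total_si=np.zeros(nrec),
        top_leaf=top, leaf_indices=leaves, root_index=g.root_index)

    cum_uptake = 0.0
    max_resid = 0.0
    rec_ptr = 0
    from .hydraulics import step_carbon
    for k in range(n_steps):
        t = tgrid[k]
        si.alpha = alpha
        water = solver.solve(carbon.sucrose / v_st, np.full(nl, trans_per_leaf[k]))
        resid = solver.residuals(water).max()
        scale = water.transpiration.sum() + abs(water.soil_inflow) + 1e-12
        max_resid = max(max_resid, resid / scale)

        if rec_ptr < nrec and rec_idx[rec_ptr] == k:
            junl = sparams.k_m_unload * si.c_m * si_step.v_con
            out.alpha[rec_ptr] = alpha
            out.psi_x[rec_ptr] = water.psi_x
            out.psi_p[rec_ptr] = water.psi_p
            out.c_s[rec_ptr] = carbon.sucrose / v_st
            out.starch[rec_ptr] = carbon.starch
            out.c_m[rec_ptr] = si.c_m
            out.c_m_cyt[rec_ptr] = si.c_m_cyt
            out.c_m_cor[rec_ptr] = si.c_m_cor
            out.c_r[rec_ptr] = sig.c_r
            out.j_unload[rec_ptr] = junl
            out.j_w_p_root_edge[rec_ptr] = water.j_w_p[root_pedge]
            out.cumulative_uptake[rec_ptr] = cum_uptake
            out.total_si[rec_ptr] = si_step.total_si(si)
            rec_ptr += 1

        try:
            if do_carbon:
                carbon = step_carbon(carbon, cparams, phot_per_leaf[k], water,
                                     g, dt, _pedge_idx=pedge_idx)
            if do_si:
                si, diag = si_step.step(si, water, dt)
                cum_uptake += diag.j_m_oc * dt
            if do_sig:
                trans_scaled = trans_per_leaf[k] * ctrl.trans_signal_scale
                gr = np.array([
                    generation_rate(ctrl.mode, ctrl.slp,
                                    (si.c_m_cyt[i] / ctrl.shortage_ref
                                     if ctrl.mode == ControlMode.SHORTAGE
                                     else si.c_m_cyt[i]),
                                    trans_scaled)
                    for i in leaves])
                sig = sig_step.step(sig, water, ctrl, gr, dt, t)
                alpha = expression_factor(ctrl, sig, t + dt)
            else:
                alpha = 1.0
        except RuntimeError as exc:
            raise RuntimeError(f"simulation failed at t = {t:.2f} h: {exc}") from exc

    out.max_water_residual = max_resid
    return out


def run_standard(ctrl: ControlConfig, config: Optional[PlantConfig] = None,
                 **kwargs) -> Trajectory:
    """Convenience wrapper: standard plant + standard forcing, 4 days."""
    cfg = config or default_config()
    g = build_standard_plant(cfg)
    days = kwargs.pop("days", cfg.simulation.days)
    dt = kwargs.pop("dt", cfg.simulation.dt)
    forcing = generate_standard_forcing(int(np.ceil(days)), dt,
                                        cfg.structure.temperature_K)
    return run_simulation(g, forcing, ctrl, cfg, days=days, dt=dt, **kwargs)


# --------------------------------------------------------------------------
# investment efficiency
# --------------------------------------------------------------------------

@dataclass
class EfficiencyReport:
    label: str
    ie: float                 # top-leaf Si per unit integrated expression, umol h^-1
    investment_day: float     # integral of alpha over light hours
    investment_night: float
    ie_change_vs_constant: float = float("nan")  # percent

    @property
    def night_day_ratio(self) -> float:
        return self.investment_night / self.investment_day


def investment_efficiency(traj: Trajectory, stri: Optional[float] = None,
                          endi: Optional[float] = None,
                          label: str = "") -> EfficiencyReport:
    """IE = integral of top-leaf unloading flux / integral of alpha over
    [stri, endi] (trapezoidal quadrature on the recorded grid), with the
    alpha integral split into light/dark investment."""
    t = traj.t
    stri = t[0] if stri is None else stri
    endi = t[-1] if endi is None else endi
    m = (t >= stri - 1e-9) & (t <= endi + 1e-9)
    if m.sum() < 2:
        raise ValueError("integration window does not cover the trajectory")
    tt = t[m]
    alpha = traj.alpha[m]
    junl_top = traj.j_unload[m, traj.top_leaf]
    total_alpha = float(np.trapezoid(alpha, tt))
    if total_alpha <= 0:
        raise ZeroDivisionError("integrated expression is zero; IE undefined")
    si_top = float(np.trapezoid(junl_top, tt))
    day = traj.day_mask[m]
    wa = alpha.copy()
    inv_day = float(np.trapezoid(np.where(day, alpha, 0.0), tt))
    inv_night = float(np.trapezoid(np.where(day, 0.0, wa), tt))
    return EfficiencyReport(label, si_top / total_alpha, inv_day, inv_night)


DEFAULT_SENSITIVITIES = (("low", 0.2, 0.05), ("intermediate", 0.2, 0.1),
                         ("high", 0.2, 0.2))


def efficiency_experiment(config: Optional[PlantConfig] = None,
                          sensitivities=DEFAULT_SENSITIVITIES,
                          forcing: Optional[Forcing] = None,
                          **run_kwargs) -> pd.DataFrame:
    """Water-stress-control investment-efficiency experiment.

    Runs a constant-expression reference plus the given (label, dec, slp_J)
    settings on identical forcing and reports each setting's IE, its
    percent change versus the constant run, and the night/day investment
    split.
    """
    cfg = config or default_config()

    def run_one(ctrl):
        if forcing is not None:
            g = build_standard_plant(cfg)
            return run_simulation(g, forcing, ctrl, cfg, **run_kwargs)
        return run_standard(ctrl, cfg, **run_kwargs)

    reports = []
    const = investment_efficiency(
        run_one(ControlConfig.for_mode("constant", 0.0, 0.0)), label="constant")
    const.ie_change_vs_constant = 0.0
    reports.append(const)
    for label, dec, slp in sensitivities:
        ctrl = ControlConfig.for_mode(
            "water_stress", slp, dec,
            trans_signal_scale=cfg.signaling.trans_signal_scale)
        rep = investment_efficiency(run_one(ctrl), label=label)
        rep.ie_change_vs_constant = 100.0 * (rep.ie - const.ie) / const.ie
        reports.append(rep)
    return pd.DataFrame([{
        "label": r.label, "IE": r.ie,
        "IE_change_vs_constant_pct": r.ie_change_vs_constant,
        "investment_day": r.investment_day,
        "investment_night": r.investment_night,
        "night_day_ratio": r.night_day_ratio,
    } for r in reports])


# --------------------------------------------------------------------------
# sucrose cyclic stability
# --------------------------------------------------------------------------

class Stability(str, Enum):
    CYCLIC_STABLE = "cyclic_stable"
    DRIFTING = "drifting"
    DECAYING = "decaying"


def detect_cyclic_stability(series: np.ndarray, samples_per_day: int,
                            tolerance: float = 0.02,
                            amplitude_floor: float = 1e-3) -> Stability:
    """Classify a daily-forced time series.

    ``cyclic_stable`` iff the last two full daily cycles agree within
    ``tolerance`` (relative L-infinity) and the final cycle's amplitude is
    non-degenerate; ``decaying`` if the amplitude has shrunk below the
    floor (relative to the series maximum); otherwise ``drifting``.
    """
    series = np.asarray(series, float)
    n_days = len(series) // samples_per_day
    if n_days < 3:
        raise ValueError("need at least 3 full days to classify")
    days = series[:n_days * samples_per_day].reshape(n_days, samples_per_day)
    last, prev = days[-1], days[-2]
    scale = np.max(np.abs(last)) + 1e-30
    amp_last = last.max() - last.min()
    overall = np.max(np.abs(series)) + 1e-30
    if amp_last < amplitude_floor * overall:
        return Stability.DECAYING
    if np.max(np.abs(last - prev)) / scale <= tolerance:
        return Stability.CYCLIC_STABLE
    return Stability.DRIFTING


K1_GRID = tuple(x * 1e-5 for x in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0,
                                   16.0, 18.0, 20.0))
K4_GRID = (0.1, 0.15, 0.2)


def carbon_stability_scan(config: Optional[PlantConfig] = None,
                          k1_grid=K1_GRID, k4_grid=K4_GRID,
                          tolerance: float = 0.02, **run_kwargs) -> pd.DataFrame:
    """Classify top-leaf sucrose dynamics over the (k1, k4) grid using
    carbon-only 4-day standard runs.

    The scan steps at dt = 0.02 h by default: the slow-respiration corner
    of the grid accumulates enough sucrose to need a finer step than the
    standard run.
    """
    import copy
    cfg = config or default_config()
    run_kwargs.setdefault("dt", 0.02)
    rows = []
    for k4 in k4_grid:
        for k1 in k1_grid:
            c = copy.deepcopy(cfg)
            c.carbon.k1 = k1
            c.carbon.k4 = k4
            traj = run_standard(ControlConfig.for_mode("constant", 0.0, 0.0),
                                c, components=("carbon",), **run_kwargs)
            spd = int(round(24.0 / (traj.t[1] - traj.t[0])))
            cls = detect_cyclic_stability(traj.c_s[:, traj.top_leaf], spd,
                                          tolerance)
            rows.append({"k1": k1, "k4": k4, "classification": cls.value})
    return pd.DataFrame(rows)
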