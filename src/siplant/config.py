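"""Configuration schema for the whole-plant silicon model.

Every tunable constant of the model lives here, grouped into the keyed
sections of the plant configuration file (structure, resistances, volumes,
root, junctions, carbon, silicon, signaling, simulation).  Values whose
docstring comment says "package default" are choices of this package, made
once to keep the model in a realistic physiological regime; they are not
measured quantities.

Internal unit system: MPa (water potential / pressure), ml (volume),
h (time), mM (silicon concentration), mol m^-3 (sucrose concentration).
All config inputs are expected in these units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class StructureConfig:
    """Plant architecture of the standard simplified rice plant."""

    n_leaves: int = 5            # five leaves, one per stem node
    leaf_area_cm2: float = 20.0  # per-leaf area used to scale boundary fluxes; package default
    temperature_K: float = 298.0


@dataclass
class ResistanceConfig:
    """Flow resistances, MPa h ml^-1.  All package defaults."""

    r_x_internode: float = 0.02  # xylem, junction-to-junction (and root-to-first-junction)
    r_x_sheath: float = 0.04     # xylem, junction-to-sheath
    r_x_leaf: float = 0.04       # xylem, sheath-to-leaf
    r_p_internode: float = 0.5   # phloem counterparts
    r_p_sheath: float = 0.5
    r_p_leaf: float = 0.5
    r_lat: float = 2.0           # xylem<->phloem lateral resistance, per node


@dataclass
class VolumeConfig:
    """Tissue volumes per node class, ml.  All package defaults."""

    v_st_root: float = 0.40      # sieve-tube volume
    v_st_junction: float = 0.02
    v_st_sheath: float = 0.02
    v_st_leaf: float = 0.30
    v_con_root: float = 0.30     # conduit (xylem) volume
    v_con_junction: float = 0.15
    v_con_sheath: float = 0.05
    v_con_leaf: float = 0.05
    v_cyt_root: float = 2.0      # cytoplasm volume of tissue cells
    v_cyt_junction: float = 1.0
    v_cyt_sheath: float = 1.0
    v_cyt_leaf: float = 2.0


@dataclass
class RootConfig:
    """Root transport and boundary parameters."""

    tr_exo: float = 0.5       # exodermal transport capability at max expression, ml h^-1
    tr_end: float = 1.0       # endodermal transport capability, ml h^-1
    p_cm: float = 0.05        # membrane permeability, ml h^-1
    v_cor: float = 1.0        # cortex tissue volume, ml (1 ml for simplicity)
    r_lat_root: float = 0.05  # radial soil-to-root-xylem resistance, MPa h ml^-1; package default
    psi_soil: float = 0.0     # soil water potential boundary, MPa (well-watered paddy)


@dataclass
class JunctionConfig:
    """Stem-node silicon partitioning."""

    rho: float = 1.5  # DVB enrichment factor (>= 1) applied at every junction; package default


@dataclass
class CarbonConfig:
    """Starch/sucrose dynamics.

    k1 and k4 are the respiration and starch-to-sucrose rate constants.
    The k1 grid values are interpreted as s^-1 and converted internally
    with ``k1_time_factor`` (h per model hour / s) so that the respiration
    time constant (1.4-14 h across the grid) permits a stable daily sucrose
    cycle within a 4-day run.
    """

    k1: float = 8.0e-5            # respiration rate constant (s^-1 scale)
    k4: float = 0.1               # starch -> sucrose conversion, h^-1
    k1_time_factor: float = 3600.0
    loading_frac: float = 1.0     # fraction of converted starch loaded into the leaf phloem
    assimilation_scale: float = 2000.0
    # ^ umol sucrose-equivalent h^-1 per (photosynthesis forcing unit x cm^2 leaf);
    #   package default chosen so midday phloem osmotic potentials reach ~-0.5 MPa.


@dataclass
class SiliconConfig:
    """Silicon transport constants."""

    c_m_out: float = 1.0        # external (soil) Si concentration, mM
    k_m_unload: float = 0.1     # xylem-to-cell unloading rate constant, h^-1; package default
    root_si_volume: str = "st"  # mixing volume for the root stele Si pool: "st" or "con"


@dataclass
class SignalingConfig:
    """Signal generation/response defaults (per-run mode settings override)."""

    mode: str = "constant"      # constant | accumulation | shortage | water_stress
    slp: float = 0.0            # generation-rate parameter for the selected mode
    dec: float = 0.0            # signal decay rate, h^-1
    chi_water_stress: float = 5.0  # response delay for water-stress control, h
    trans_signal_scale: float = 12.0
    # ^ multiplier turning per-leaf transpiration (ml h^-1) into the water-stress
    #   generation drive; free scale (signal units are arbitrary), tuned once.
    shortage_ref: float = 1.0
    # ^ reference leaf-cell Si concentration (mM) normalising the shortage drive;
    #   1.0 mM puts the drive on the natural concentration scale of the model.


@dataclass
class SimulationConfig:
    days: int = 4
    dt: float = 0.05          # explicit-Euler step, h
    record_stride: int = 1


@dataclass
class PlantConfig:
    """Full model configuration; round-trips losslessly through YAML."""

    structure: StructureConfig = field(default_factory=StructureConfig)
    resistances: ResistanceConfig = field(default_factory=ResistanceConfig)
    volumes: VolumeConfig = field(default_factory=VolumeConfig)
    root: RootConfig = field(default_factory=RootConfig)
    junctions: JunctionConfig = field(default_factory=JunctionConfig)
    carbon: CarbonConfig = field(default_factory=CarbonConfig)
    silicon: SiliconConfig = field(default_factory=SiliconConfig)
    signaling: SignalingConfig = field(default_factory=SignalingConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PlantConfig":
        sections = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for name, fobj in zip(sections, dataclasses.fields(cls)):
            sect_cls = fobj.default_factory  # type: ignore[misc]
            data = d.get(name, {})
            kwargs[name] = sect_cls(**data)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlantConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config() -> PlantConfig:
    """The standard configuration used throughout the package."""
    return PlantConfig()
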