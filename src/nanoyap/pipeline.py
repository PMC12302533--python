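"""Reproducible in-silico experiment sweeps.

Three canonical experiments: a geometry sweep over nanopillar substrates
(flat vs pitch/radius variants), an indentation sweep over nuclear
indentation depths and NPC stretch sensitivities, and a rupture sweep over
pore sizes, rupture transport coefficients and nuclear retention ratios.
Each returns a tidy table with one row per sweep point and provenance
(config hash, package version) for byte-reproducible reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

from dataclasses import replace as dc_replace

import pandas as pd

from . import __version__
from .geometry import SubstrateSpec, build_cell_geometry
from .nucleus import IndentationSpec, NEPatch, build_nucleus, indent_nucleus
from .params import MechanoParams, load_params
from .signaling import (ModelState, assemble_rhs, initial_state, phi_free,
                        readouts, simulate)
from .transport import RuptureSpec, wellmixed_nc_with_rupture

log = logging.getLogger("nanoyap.pipeline")

SNAPSHOT_T = 3600.0  # s; early snapshot emitted alongside the steady state

# default substrate geometries; contact radii encode the reduced spreading
# measured on denser nanopillar arrays
DEFAULT_SUBSTRATES = {
    "flat": dict(r_np_um=0.1, h_np_um=0.0, p_np_um=2.5, r_tip_um=0.0,
                 e_mod_kpa=1.0e5, contact_radius_um=15.0),
    "pillars_p2.5": dict(r_np_um=0.1, h_np_um=1.0, p_np_um=2.5, r_tip_um=0.1,
                         e_mod_kpa=1.0e5, contact_radius_um=11.0),
    "pillars_p5.0": dict(r_np_um=0.1, h_np_um=1.0, p_np_um=5.0, r_tip_um=0.1,
                         e_mod_kpa=1.0e5, contact_radius_um=13.0),
}

# tall-pillar substrate used for nuclear indentation experiments
INDENT_SUBSTRATE = dict(r_np_um=0.5, h_np_um=3.0, p_np_um=3.5, r_tip_um=0.2,
                        e_mod_kpa=1.0e5, contact_radius_um=11.0)


def substrate_from_config(block: dict) -> SubstrateSpec:
    return SubstrateSpec(
        r_np=block["r_np_um"], h_np=block["h_np_um"], p_np=block["p_np_um"],
        r_tip=block["r_tip_um"], e_mod=block["e_mod_kpa"],
        contact_radius=block["contact_radius_um"],
    )


@dataclass
class ExperimentConfig:
    """One experiment: substrates, indentation, rupture and sweep axes."""

    experiment: str
    substrates: dict = field(default_factory=lambda: dict(DEFAULT_SUBSTRATES))
    indent_substrate: dict = field(default_factory=lambda: dict(INDENT_SUBSTRATE))
    depths_um: list = field(default_factory=lambda: [0.0, 1.0, 1.8, 2.8])
    alpha_0_values: list = field(default_factory=lambda: [5.0])
    sigma_ner_um: list = field(default_factory=lambda: [0.1, 0.2])
    k_rupture: list = field(default_factory=lambda: [1.0e4, 3.0e4, 1.0e5])
    upsilon_values: list = field(default_factory=lambda: [1.0, 5.0])
    param_file: str | None = None
    indent_grid_um: float = 0.05
    pm_offset_um: float = 0.05
    fillet_radius_um: float = 0.2
    ne_pillar_gap_um: float = 0.2
    seed: int = 0

    def params(self) -> MechanoParams:
        return load_params(self.param_file)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class SweepResult:
    """Tidy sweep table plus provenance."""

    table: pd.DataFrame
    provenance: dict

    def save(self, csv_path: str) -> None:
        self.table.to_csv(csv_path, index=False)
        with open(str(csv_path) + ".provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _provenance(config: ExperimentConfig) -> dict:
    return {"config_hash": config.config_hash(), "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}


def _row_from_state(state: ModelState, params: MechanoParams,
                    geometry) -> dict:
    ro = readouts(state, params)
    rhoa = state["rhoa_gtp"]
    return {
        "nc_ratio": ro.nc_ratio,
        "pfak_uM": state["pfak"],
        "rhoa_pm_per_um2": rhoa,
        "rhoa_pm_molecules": rhoa * geometry.total_pm_area,
        "e_cyto": ro.e_cyto,
        "sf": ro.sf,
        "phi_free": phi_free(state),
    }


def _simulate_case(geometry, ne_patches, params, rupture=None, state0=None):
    rhs = assemble_rhs(geometry, ne_patches, params, rupture=rupture)
    s0 = initial_state(params) if state0 is None else state0
    return simulate(rhs, s0, params=params)


def undeformed_ne_patches(params: MechanoParams) -> list[NEPatch]:
    """Single undeformed NE patch for cells without nuclear indentation."""
    nuc = build_nucleus(params.v_nuc, aspect_ratio=params.nuclear_aspect_ratio)
    return [NEPatch("undeformed", nuc.surface_area(), 1.0, 0.0)]


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def run_geometry_sweep(config: ExperimentConfig,
                       params: MechanoParams | None = None) -> SweepResult:
    """Steady-state readouts across nanopillar substrates."""
    params = params or config.params()
    ne = undeformed_ne_patches(params)
    rows = []
    for name, block in config.substrates.items():
        t0 = time.perf_counter()
        spec = substrate_from_config(block)
        geom = build_cell_geometry(spec, params.v_cyto, params.v_nuc,
                                   config.pm_offset_um, config.fillet_radius_um)
        traj = _simulate_case(geom, ne, params)
        for label, t in (("t3600", SNAPSHOT_T), ("steady", traj.times[-1])):
            row = {"substrate": name, "snapshot": label,
                   "contact_area_um2": geom.substrate_contact_area,
                   "n_pillars": geom.n_pillars_under_cell,
                   "alpha_tot": 1.0, "sa_def_um2": 0.0}
            row.update(_row_from_state(traj.state_at(t), params, geom))
            rows.append(row)
        log.info(json.dumps({"stage": "geometry", "case": name,
                             "elapsed_s": round(time.perf_counter() - t0, 3)}))
    return SweepResult(pd.DataFrame(rows), _provenance(config))


def run_indentation_sweep(config: ExperimentConfig,
                          params: MechanoParams | None = None) -> SweepResult:
    """Steady N/C across nuclear indentation depths and alpha_0 values."""
    params = params or config.params()
    spec = substrate_from_config(config.indent_substrate)
    geom = build_cell_geometry(spec, params.v_cyto, params.v_nuc,
                               config.pm_offset_um, config.fillet_radius_um)
    nuc = build_nucleus(params.v_nuc, aspect_ratio=params.nuclear_aspect_ratio)
    rows = []
    for depth in config.depths_um:
        ind = indent_nucleus(nuc, spec, IndentationSpec(
            depth=depth, ne_pillar_gap=config.ne_pillar_gap_um,
            grid_um=config.indent_grid_um))
        patches = ind.patches()
        for a0 in config.alpha_0_values:
            t0 = time.perf_counter()
            p = params.replace(transport=dc_replace(params.transport,
                                                    alpha_0=a0))
            traj = _simulate_case(geom, patches, p)
            for label, t in (("t3600", SNAPSHOT_T), ("steady", traj.times[-1])):
                row = {"depth_um": depth, "alpha_0": a0, "snapshot": label,
                       "alpha_tot": ind.alpha_tot, "sa_def_um2": ind.sa_def}
                row.update(_row_from_state(traj.state_at(t), p, geom))
                rows.append(row)
            log.info(json.dumps({"stage": "indent", "depth": depth,
                                 "alpha_0": a0,
                                 "elapsed_s": round(time.perf_counter() - t0, 3)}))
    return SweepResult(pd.DataFrame(rows), _provenance(config))


def run_rupture_sweep(config: ExperimentConfig,
                      params: MechanoParams | None = None,
                      depth_um: float = 2.8) -> SweepResult:
    """Steady N/C across pore size, rupture coefficient and retention ratio.

    The baseline (no rupture) steady state is computed once per
    configuration; each rupture case restarts from it with the pore open.
    """
    params = params or config.params()
    spec = substrate_from_config(config.indent_substrate)
    geom = build_cell_geometry(spec, params.v_cyto, params.v_nuc,
                               config.pm_offset_um, config.fillet_radius_um)
    nuc = build_nucleus(params.v_nuc, aspect_ratio=params.nuclear_aspect_ratio)
    ind = indent_nucleus(nuc, spec, IndentationSpec(
        depth=depth_um, ne_pillar_gap=config.ne_pillar_gap_um,
        grid_um=config.indent_grid_um))
    patches = ind.patches()

    rows = []
    for ups in config.upsilon_values:
        p = params.replace(transport=params.transport.with_upsilon(ups))
        base = _simulate_case(geom, patches, p)
        base_nc = float(base.nc_ratio()[-1])
        for sigma in config.sigma_ner_um:
            for k_rup in config.k_rupture:
                rup = RuptureSpec(sigma_ner=sigma, k_rupture=k_rup,
                                  z_ne=ind.z_ne)
                traj = _simulate_case(geom, patches, p, rupture=rup,
                                      state0=base.steady.vector())
                closed = wellmixed_nc_with_rupture(
                    phi_free(traj.steady), patches,
                    traj.steady["npc_a"], traj.steady["npc_a"],
                    ind.alpha_tot, p.transport, rup)
                for label, t in (("t3600", SNAPSHOT_T),
                                 ("steady", traj.times[-1])):
                    row = {"upsilon": ups, "sigma_ner_um": sigma,
                           "k_rupture": k_rup,
                           "ner_transport_rate": k_rup * rup.sa_ner,
                           "snapshot": label, "nc_baseline": base_nc,
                           "nc_closed_form": closed["nc_ratio"],
                           "alpha_tot": ind.alpha_tot,
                           "sa_def_um2": ind.sa_def}
                    row.update(_row_from_state(traj.state_at(t), p, geom))
                    rows.append(row)
    return SweepResult(pd.DataFrame(rows), _provenance(config))
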