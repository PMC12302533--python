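"""Model parameter table: loading, validation, defaults.

Parameters ship as a versioned YAML table (``data/params_v1.yaml``) with
units annotated per key.  The loader validates the file against a
required-key manifest and raises a :class:`ParameterError` naming the first
missing key, so an incomplete transcription fails loudly rather than
silently falling back.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml


class ParameterError(KeyError):
    """A required model parameter is missing or invalid."""


REQUIRED_KEYS: dict[str, tuple[str, ...]] = {
    "cell": ("v_cyto_um3", "v_nuc_um3", "nuclear_aspect_ratio",
             "apical_clearance_um"),
    "pm_curvature": ("rho_i_max_per_um2", "h0_per_um", "k_f_per_s",
                     "k_sf_per_s", "c_kpa", "k_df_per_s", "ell_pm_um"),
    "nwasp": ("k_nwasp_um_per_s", "h_nwasp_per_um"),
    "network": (
        "fak_tot_uM", "rhoa_tot_per_um2", "k_fkrho_per_s", "gamma_per_uM5",
        "k_drho_per_s", "rock_tot_uM", "k_rock_um_per_s", "k_drock_per_s",
        "mdia_tot_uM", "k_mdia_um_per_s", "k_dmdia_per_s", "myo_tot_uM",
        "k_myo0_per_s", "k_myo_per_uM_s", "k_dmyo_per_s", "limk_tot_uM",
        "k_limk_per_uM_s", "k_dlimk_per_s", "cof_tot_uM", "k_turn_per_s",
        "k_cat_per_uM_s", "k_mcof_uM", "actin_tot_uM", "k_ra_per_s",
        "alpha_mdia", "k_dep_per_s", "alpha_cof", "lam_tot_per_um2",
        "k_flam_per_s", "k_lam_e_kpa", "k_dlam_per_s", "npc_tot_per_um2",
        "k_fnpc", "k_rnpc_per_s", "k_cn_per_uM2_s", "k_nc_per_s",
    ),
    "transport": ("k_inb_um_per_s", "k_in_um3_per_s", "k_out_npc_um_per_s",
                  "alpha_0", "k_bind_per_s", "k_unbind_per_s"),
    "readouts": ("c_e_kpa", "stiffness_exponent", "c_sf"),
    "initial_state": (
        "pfak_uM", "rhoa_gtp_per_um2", "rock_a_uM", "mdia_a_uM", "myo_a_uM",
        "limk_a_uM", "cofilin_np_uM", "factin_uM", "lamin_a_per_um2",
        "npc_a_per_um2", "yap_p_uM", "yap_cyto_uM", "yap_nuc_uM"),
}


@dataclass(frozen=True)
class TransportParams:
    """Nucleocytoplasmic transport constants (stretch-gated NPC + binding).

    ``upsilon = 1 + k_bind/k_unbind`` is the nuclear retention ratio, the
    ratio of total to freely diffusing YAP/TAZ in the nucleus.
    """

    k_inb: float
    k_in: float
    k_out_npc: float
    alpha_0: float
    k_bind: float
    k_unbind: float
    phi_free_override: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_0 <= 0:
            raise ParameterError("alpha_0 must be positive")
        if self.k_unbind <= 0 or self.k_bind < 0:
            raise ParameterError("binding rates must be k_unbind>0, k_bind>=0")
        if self.phi_free_override is not None and not (
                0.0 <= self.phi_free_override <= 1.0):
            raise ParameterError("phi_free must lie in [0, 1]")

    @property
    def upsilon(self) -> float:
        return 1.0 + self.k_bind / self.k_unbind

    def with_upsilon(self, upsilon: float) -> "TransportParams":
        if upsilon < 1:
            raise ParameterError("upsilon must be >= 1")
        return replace(self, k_bind=(upsilon - 1.0) * self.k_unbind)


@dataclass(frozen=True)
class MechanoParams:
    """Every rate constant of the curvature-coupled network.

    The curvature-law constants are first-class attributes; the remaining
    prior-network constants ride in ``network`` keyed by name and are
    validated against the manifest at load time.
    """

    rho_i_max: float
    h0: float
    k_f: float
    k_sf: float
    c_kpa: float
    k_df: float
    ell_pm: float
    k_nwasp: float
    h_nwasp: float
    c_e: float
    stiffness_exponent: float
    c_sf: float
    v_cyto: float
    v_nuc: float
    nuclear_aspect_ratio: float
    apical_clearance: float
    network: dict = field(default_factory=dict)
    transport: TransportParams = None
    initial_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rho_i_max", "h0", "h_nwasp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("k_f", "k_sf", "k_df", "k_nwasp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")

    def replace(self, **kw) -> "MechanoParams":
        return replace(self, **kw)


def _validate(table: dict) -> None:
    for section, keys in REQUIRED_KEYS.items():
        if section not in table:
            raise ParameterError(f"missing parameter section {section!r}")
        for key in keys:
            if key not in table[section]:
                raise ParameterError(
                    f"missing parameter {section}.{key} in parameter table")


def load_raw_params(path: str | None = None) -> dict:
    """Load and validate the raw YAML parameter table."""
    if path is None:
        src = importlib.resources.files("nanoyap.data") / "params_v1.yaml"
        table = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            table = yaml.safe_load(fh)
    _validate(table)
    return table


def load_params(path: str | None = None, **overrides) -> MechanoParams:
    """Build :class:`MechanoParams` from the default or a user table.

    Keyword overrides patch top-level attributes after loading, e.g.
    ``load_params(h0=10.0)``.
    """
    t = load_raw_params(path)
    pc, nw, ro, ce = (t["pm_curvature"], t["nwasp"], t["readouts"], t["cell"])
    tr = t["transport"]
    params = MechanoParams(
        rho_i_max=pc["rho_i_max_per_um2"],
        h0=pc["h0_per_um"],
        k_f=pc["k_f_per_s"],
        k_sf=pc["k_sf_per_s"],
        c_kpa=pc["c_kpa"],
        k_df=pc["k_df_per_s"],
        ell_pm=pc["ell_pm_um"],
        k_nwasp=nw["k_nwasp_um_per_s"],
        h_nwasp=nw["h_nwasp_per_um"],
        c_e=ro["c_e_kpa"],
        stiffness_exponent=ro["stiffness_exponent"],
        c_sf=ro["c_sf"],
        v_cyto=ce["v_cyto_um3"],
        v_nuc=ce["v_nuc_um3"],
        nuclear_aspect_ratio=ce["nuclear_aspect_ratio"],
        apical_clearance=ce["apical_clearance_um"],
        network=dict(t["network"]),
        transport=TransportParams(
            k_inb=tr["k_inb_um_per_s"],
            k_in=tr["k_in_um3_per_s"],
            k_out_npc=tr["k_out_npc_um_per_s"],
            alpha_0=tr["alpha_0"],
            k_bind=tr["k_bind_per_s"],
            k_unbind=tr["k_unbind_per_s"],
        ),
        initial_state=dict(t["initial_state"]),
    )
    if overrides:
        params = params.replace(**overrides)
    return params
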