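"""Curvature-dependent mechanotransduction network and its time integration.

The 15 species of the YAP/TAZ mechanotransduction network live in four
compartments: the plasma membrane (PM, surface densities), the cytosol
(µM), the nuclear envelope (NE, surface densities) and the nucleoplasm
(µM).  Activation/inactivation pairs share conserved totals, so the state
vector carries the active member of each pair:

    PM        RhoA-GTP (µm⁻²)             [RhoA-GDP = total - active]
    cytosol   pFAK, ROCK_A, mDia_A, Myo_A, LIMK_A, cofilin (active),
              F-actin, YAP/TAZ_p, YAP/TAZ_cyto (all µM)
              [FAK, inactive enzymes, G-actin derived from totals]
    NE        dephosphorylated lamin A, activated NPC (µm⁻²)
    nucleus   YAP/TAZ_nuc (µM)

Surface reactions on a patch of area A contribute to a volume species at
rate (A / V_compartment) x (per-area rate law), which is what couples the
signaling state to substrate geometry: bound-integrin density falls
exponentially with PM mean curvature (curvature-sensitive endocytosis),
FAK phosphorylation scales with bound integrins and substrate stiffness,
and N-WASP-driven actin polymerization grows exponentially with PM
curvature.  Downstream, cytosolic stiffness (prop. to [F-actin]^2.6) drives
lamin A dephosphorylation, and lamin A together with stress fibers
([F-actin][Myo_A]) potentiates NPC opening; stretch-gated nuclear import and
rupture fluxes are supplied by :mod:`nanoyap.transport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import CellGeometry
from .nucleus import NEPatch
from .params import MechanoParams

STATE_NAMES = (
    "pfak", "rhoa_gtp", "rock_a", "mdia_a", "myo_a", "limk_a",
    "cofilin_np", "factin", "lamin_a", "npc_a", "yap_p", "yap_cyto",
    "yap_nuc",
)

STEADY_STATE_T = 10_000.0  # s; steady state assessed here by convention


class SimulationError(RuntimeError):
    """The stiff integrator failed; carries the last good state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# curvature-dependent rate laws
# ---------------------------------------------------------------------------

def integrin_density(h_pm, params: MechanoParams):
    """Bound-integrin density (µm⁻²) vs PM mean curvature (µm⁻¹).

    Curvature-sensitive endocytosis depletes integrins where the membrane
    bends inward:  rho_max * exp(-H/H0) for H >= 0, rho_max for H < 0.
    Continuous at H = 0 and bounded by rho_max.
    """
    h = np.asarray(h_pm, dtype=float)
    rho = params.rho_i_max * np.where(h >= 0, np.exp(-h / params.h0), 1.0)
    return rho if rho.ndim else float(rho)


def fak_rate(rho_i_bound, e_mod: float, params: MechanoParams):
    """Total FAK phosphorylation rate (s⁻¹) on a substrate-contact patch.

    (rho/rho_max) * (k_f + k_sf * E/(C+E)): integrin occupancy gates both
    the stiffness-independent and the saturating stiffness-dependent term.
    """
    rho = np.asarray(rho_i_bound, dtype=float)
    if e_mod < 0:
        raise ValueError("substrate stiffness must be >= 0")
    if np.any(rho > params.rho_i_max * (1 + 1e-12)):
        raise ValueError("bound-integrin density exceeds rho_i_max")
    k = (rho / params.rho_i_max) * (
        params.k_f + params.k_sf * e_mod / (params.c_kpa + e_mod))
    return k if k.ndim else float(k)


def nwasp_rate(h_pm, params: MechanoParams):
    """Curvature-enhanced N-WASP actin polymerization velocity (µm s⁻¹).

    k_NWASP * exp(H/H_NWASP) on substrate-contact membrane; the curvature
    scale is fixed at 2 µm⁻¹ (mean curvature of the curved sides of 500-nm
    nanobars, where N-WASP activation is observed to onset).
    """
    h = np.asarray(h_pm, dtype=float)
    k = params.k_nwasp * np.exp(h / params.h_nwasp)
    return k if k.ndim else float(k)


# ---------------------------------------------------------------------------
# state and readouts
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Named view over the concentration vector at one time point."""

    time: float
    values: dict

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray) -> "ModelState":
        return cls(time=t, values=dict(zip(STATE_NAMES, y)))

    def vector(self) -> np.ndarray:
        return np.array([self.values[k] for k in STATE_NAMES])


@dataclass(frozen=True)
class Readouts:
    """Whole-cell readouts derived from a state."""

    e_cyto: float   # cytosolic stiffness, c_E * [F-actin]^2.6 (kPa-scale)
    sf: float       # stress-fiber abundance, c_SF * [F-actin][Myo_A]
    nc_ratio: float  # nuclear-to-cytosolic YAP/TAZ, Y_nuc/(Y_p + Y_cyto)


def readouts(state: ModelState, params: MechanoParams) -> Readouts:
    f = state["factin"]
    myo = state["myo_a"]
    if f < 0 or myo < 0 or state["yap_nuc"] < 0:
        raise ValueError("negative concentration in readout computation")
    cyto = state["yap_p"] + state["yap_cyto"]
    return Readouts(
        e_cyto=params.c_e * f ** params.stiffness_exponent,
        sf=params.c_sf * f * myo,
        nc_ratio=state["yap_nuc"] / cyto if cyto > 0 else math.inf,
    )


def phi_free(state: ModelState) -> float:
    """Fraction of cytosolic YAP/TAZ that is dephosphorylated (import-competent)."""
    tot = state["yap_p"] + state["yap_cyto"]
    return state["yap_cyto"] / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# right-hand side assembly
# ---------------------------------------------------------------------------

def assemble_rhs(
    geometry: CellGeometry,
    ne_patches: list[NEPatch],
    params: MechanoParams,
    rupture=None,
    freeze_cytoskeleton: bool = False,
):
    """Build the ODE right-hand side f(t, y) for the full network.

    ``ne_patches`` supplies the NE decomposition (areas and stretch ratios)
    used by the stretch-gated import law; ``rupture`` is an optional
    :class:`nanoyap.transport.RuptureSpec` adding the rupture exchange flux;
    ``freeze_cytoskeleton`` zeroes every non-YAP/TAZ derivative (used to
    compare dynamic and closed-form nucleocytoplasmic transport).
    """
    net = params.network
    tp = params.transport
    v_cyto, v_nuc = geometry.v_cyto, geometry.v_nuc
    e_mod = geometry.substrate.e_mod

    # precompute geometric couplings
    sub = geometry.substrate_patches
    areas = np.array([p.area for p in sub])
    curvs = np.array([p.h_pm for p in sub])
    rho_b = integrin_density(curvs, params)
    # FAK drive: sum_i A_i * ell_PM * k_FAK(H_i) / V_cyto  (s^-1)
    j_fak = float(np.sum(areas * params.ell_pm * fak_rate(rho_b, e_mod, params))
                  ) / v_cyto
    # N-WASP drive: sum_i A_i * k_poly(H_i) / V_cyto  (s^-1)
    j_wasp = float(np.sum(areas * nwasp_rate(curvs, params))) / v_cyto
    s_pm = geometry.total_pm_area * params.ell_pm / v_cyto  # dimensionless

    ne_areas = np.array([p.area for p in ne_patches])
    ne_alpha = np.array([p.alpha for p in ne_patches])
    sa_nuc = float(ne_areas.sum())
    if sa_nuc <= 0:
        raise ValueError("NE patch set has zero total area")

    if rupture is not None:
        from .transport import ner_permeability
        sa_ner = rupture.sa_ner
        cx, cy = rupture.center_xy

    manifest = ("fak_tot_uM", "rhoa_tot_per_um2", "k_fkrho_per_s",
                "gamma_per_uM5", "k_drho_per_s")
    for key in manifest:
        if key not in net:
            raise KeyError(f"missing network parameter {key!r}")

    def rhs(t, y):
        (pfak, rhoa, rock, mdia, myo, limk, cof, fact, lam, npc,
         yp, ycyt, ynuc) = y

        d = np.zeros_like(y)

        if not freeze_cytoskeleton:
            # FAK phosphorylation at substrate-contact PM
            d[0] = j_fak * (net["fak_tot_uM"] - pfak) - params.k_df * pfak

            # RhoA activation at the PM (surface density balance)
            act = net["k_fkrho_per_s"] * (
                1.0 + net["gamma_per_uM5"] * max(pfak, 0.0) ** 5)
            d[1] = act * (net["rhoa_tot_per_um2"] - rhoa) \
                - net["k_drho_per_s"] * rhoa

            u_rho = rhoa / net["rhoa_tot_per_um2"]

            # ROCK and mDia activation by RhoA-GTP over the whole PM
            d[2] = net["k_rock_um_per_s"] / params.ell_pm * s_pm * u_rho \
                * (net["rock_tot_uM"] - rock) - net["k_drock_per_s"] * rock
            d[3] = net["k_mdia_um_per_s"] / params.ell_pm * s_pm * u_rho \
                * (net["mdia_tot_uM"] - mdia) - net["k_dmdia_per_s"] * mdia

            # myosin and LIMK downstream of ROCK
            d[4] = (net["k_myo0_per_s"] + net["k_myo_per_uM_s"] * rock) \
                * (net["myo_tot_uM"] - myo) - net["k_dmyo_per_s"] * myo
            d[5] = net["k_limk_per_uM_s"] * rock \
                * (net["limk_tot_uM"] - limk) - net["k_dlimk_per_s"] * limk

            # cofilin: LIMK phosphorylates (inactivates), constant turnover back
            d[6] = net["k_turn_per_s"] * (net["cof_tot_uM"] - cof) \
                - net["k_cat_per_uM_s"] * limk * cof / (net["k_mcof_uM"] + cof)

            # actin: mDia- and N-WASP-assisted polymerization vs
            # cofilin-assisted depolymerization
            g_actin = net["actin_tot_uM"] - fact
            k_on = net["k_ra_per_s"] * (
                1.0 + net["alpha_mdia"] * mdia / net["mdia_tot_uM"]) + j_wasp
            k_off = net["k_dep_per_s"] * (
                1.0 + net["alpha_cof"] * cof / net["cof_tot_uM"])
            d[7] = k_on * g_actin - k_off * fact

            # lamin A dephosphorylation driven by cytosolic stiffness
            e_cyto = params.c_e * max(fact, 0.0) ** params.stiffness_exponent
            d[8] = net["k_flam_per_s"] * e_cyto / (net["k_lam_e_kpa"] + e_cyto) \
                * (net["lam_tot_per_um2"] - lam) - net["k_dlam_per_s"] * lam

            # NPC opening: lamin A in cooperation with stress fibers
            d[9] = net["k_fnpc"] * lam * fact * myo \
                * (net["npc_tot_per_um2"] - npc) - net["k_rnpc_per_s"] * npc

        # --- YAP/TAZ ------------------------------------------------------
        sf = fact * myo
        dephos = net["k_cn_per_uM2_s"] * sf * yp       # stress-fiber driven
        rephos = net["k_nc_per_s"] * ycyt

        # stretch-gated NPC import over NE patches; export of total nuclear
        kin = tp.k_inb + tp.k_in * npc * np.exp((ne_alpha - 1.0) / tp.alpha_0)
        j_in = float(np.sum(ne_areas * kin)) * ycyt    # µm³ µM / s
        j_out = tp.k_out_npc * sa_nuc * ynuc

        j_rup = 0.0
        if rupture is not None:
            p = ner_permeability(cx, cy, rupture.z_ne, t, rupture)
            j_rup = rupture.k_rupture * p * sa_ner * (ycyt - ynuc / tp.upsilon)

        d[10] = rephos - dephos
        d[11] = dephos - rephos - (j_in - j_out + j_rup) / v_cyto
        d[12] = (j_in - j_out + j_rup) / v_nuc
        return d

    return rhs


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Integrated trajectory with readouts and the steady-state snapshot."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    params: MechanoParams
    steady: ModelState = field(init=False)

    def __post_init__(self):
        self.steady = ModelState.from_vector(self.times[-1], self.states[-1])

    def state_at(self, t: float) -> ModelState:
        i = int(np.argmin(np.abs(self.times - t)))
        return ModelState.from_vector(self.times[i], self.states[i])

    def nc_ratio(self) -> np.ndarray:
        yp = self.states[:, STATE_NAMES.index("yap_p")]
        yc = self.states[:, STATE_NAMES.index("yap_cyto")]
        yn = self.states[:, STATE_NAMES.index("yap_nuc")]
        return yn / (yp + yc)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_s", self.times)
        df["nc_ratio"] = self.nc_ratio()
        return df


def initial_state(params: MechanoParams) -> np.ndarray:
    """Resting state: minimal cytoskeletal activation, nuclear N/C < 1."""
    ini = params.initial_state
    order = ("pfak_uM", "rhoa_gtp_per_um2", "rock_a_uM", "mdia_a_uM",
             "myo_a_uM", "limk_a_uM", "cofilin_np_uM", "factin_uM",
             "lamin_a_per_um2", "npc_a_per_um2", "yap_p_uM", "yap_cyto_uM",
             "yap_nuc_uM")
    return np.array([ini[k] for k in order], dtype=float)


def simulate(
    rhs,
    state0: np.ndarray,
    t_end: float = STEADY_STATE_T,
    params: MechanoParams | None = None,
    n_out: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    steady_tol: float = 1e-8,
) -> Trajectory:
    """Integrate the stiff network to ``t_end`` (default 10,000 s).

    BDF with adaptive stepping (initial step 0.01 s); integration stops
    early once the relative rate of change of every species falls below
    ``steady_tol`` (s⁻¹).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    def steady_event(t, y):
        dy = rhs(t, y)
        scale = np.abs(y) + 1e-6
        return float(np.max(np.abs(dy) / scale)) - steady_tol

    steady_event.terminal = True
    steady_event.direction = -1

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        rhs, (0.0, t_end), np.asarray(state0, dtype=float),
        method="BDF", t_eval=t_eval, rtol=rtol, atol=atol,
        first_step=0.01, events=steady_event, dense_output=False,
    )
    if not sol.success and sol.status != 1:
        raise SimulationError(
            f"integrator failed at t={sol.t[-1] if len(sol.t) else 0}: "
            f"{sol.message}",
            last_state=sol.y[:, -1] if sol.y.size else None,
        )
    times, states = sol.t, sol.y.T
    if sol.status == 1 and len(sol.t_events[0]):
        # converged early: extend the record to t_end with the settled state
        t_hit = sol.t_events[0][0]
        tail = t_eval[t_eval > t_hit]
        if tail.size:
            times = np.concatenate([times, tail])
            states = np.concatenate(
                [states, np.repeat(sol.y_events[0], tail.size, axis=0)])
    return Trajectory(times=times, states=states,
                      params=params)
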