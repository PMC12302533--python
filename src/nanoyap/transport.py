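"""Stretch-gated NPC transport and nuclear-envelope-rupture fluxes.

Nuclear import through NPCs is gated by the local lamina stretch ratio
alpha:

    k_in,NPC([NPC_A], alpha) = k_inb + k_in [NPC_A] exp((alpha - 1)/alpha_0)

so entry is enhanced where the NE is stretched (alpha > 1) and reduced
under surface compression (alpha < 1).  In the well-mixed limit the steady
nuclear-to-cytosolic ratio splits into a stretch-enhanced term over the
deformed NE and a baseline term over the undeformed NE:

    N/C = phi_free / (k_out SA_nuc)
          * [ k_in,NPC(def, alpha_tot) SA_def + k_in,NPC(undef, 1) SA_undef ]

Rupture opens a pore of Gaussian spatial footprint (size sigma_NER) whose
relative permeability approaches 1 with time constant t_0; YAP/TAZ crosses
it diffusively, with the nuclear side discounted by the retention ratio
upsilon = 1 + k_bind/k_unbind (free nuclear fraction 1/upsilon).  With the
pore aggregated to an NE patch of area SA_NER = pi sigma_NER^2:

    N/C = phi_free (k_in,def + k_in,undef + k_rup SA_NER)
          / (k_out SA_nuc + (k_rup/upsilon) SA_NER)

which reduces to the no-rupture form at SA_NER = 0 and approaches upsilon
when rupture transport dominates and phi_free -> 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nucleus import NEPatch
from .params import MechanoParams, TransportParams


class TransportError(ValueError):
    """Invalid transport configuration or state."""


@dataclass(frozen=True)
class RuptureSpec:
    """A rupture-induced pore in the lower NE above the central nanopillar."""

    sigma_ner: float          # pore size scale (µm)
    k_rupture: float          # transport coefficient (µm⁻² s⁻¹ µM⁻¹ aggregate)
    z_ne: float               # height of the lower NE at the pore center (µm)
    t_0: float = 1.0          # pore-opening time constant (s)
    center_xy: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sigma_ner <= 0:
            raise TransportError("sigma_NER must be positive")
        if self.t_0 <= 0 or self.k_rupture < 0:
            raise TransportError("t_0 must be > 0 and k_rupture >= 0")

    @property
    def sa_ner(self) -> float:
        """Effective pore area, SA_NER = pi sigma_NER^2."""
        return math.pi * self.sigma_ner**2


# ---------------------------------------------------------------------------
# elementary laws
# ---------------------------------------------------------------------------

def npc_import_rate(npc_a_density, alpha, params: TransportParams):
    """Stretch-gated NPC import velocity (µm s⁻¹), increasing in alpha."""
    a = np.asarray(alpha, dtype=float)
    n = np.asarray(npc_a_density, dtype=float)
    if np.any(a <= 0):
        raise TransportError("stretch ratio alpha must be positive")
    if np.any(n < 0):
        raise TransportError("NPC density must be nonnegative")
    k = params.k_inb + params.k_in * n * np.exp((a - 1.0) / params.alpha_0)
    return k if k.ndim else float(k)


def free_nuclear_fraction(upsilon: float) -> float:
    """Fraction of nuclear YAP/TAZ free to diffuse: 1/upsilon."""
    if upsilon < 1:
        raise TransportError("upsilon must be >= 1")
    return 1.0 / upsilon


def ner_permeability(x, y, z, t, spec: RuptureSpec):
    """Relative NE permeability of the rupture pore, in [0, 1].

    Separable in space and time: a Gaussian footprint of scale sigma_NER
    around the pore center at (center_xy, z_NE), opening as 1 - exp(-t/t_0).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise TransportError("time must be >= 0")
    cx, cy = spec.center_xy
    r2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 \
        + (np.asarray(z) - spec.z_ne) ** 2
    p = (1.0 - np.exp(-t_arr / spec.t_0)) * np.exp(-r2 / spec.sigma_ner**2)
    return p if np.ndim(p) else float(p)


def rupture_flux(y_cyto_free, y_nuc, p_ner, params: TransportParams,
                 k_rupture: float):
    """Diffusive per-area rupture flux, positive into the nucleus.

    k_rupture * p_NER * (Y_cyto,free - Y_nuc/upsilon); the nuclear term is
    the free nuclear concentration Y_nuc/upsilon (rapid-binding limit).
    """
    if params.upsilon < 1:
        raise TransportError("upsilon must be >= 1")
    y_c = np.asarray(y_cyto_free, dtype=float)
    y_n = np.asarray(y_nuc, dtype=float)
    if np.any(y_c < 0) or np.any(y_n < 0):
        raise TransportError("concentrations must be nonnegative")
    j = k_rupture * np.asarray(p_ner) * (y_c - y_n / params.upsilon)
    return j if np.ndim(j) else float(j)


# ---------------------------------------------------------------------------
# well-mixed steady-state closed forms
# ---------------------------------------------------------------------------

def _split_ne(ne_patches: list[NEPatch]):
    sa_def = sum(p.area for p in ne_patches if p.label == "deformed")
    sa_undef = sum(p.area for p in ne_patches if p.label == "undeformed")
    return sa_def, sa_undef


def wellmixed_nc(
    phi_free: float,
    ne_patches: list[NEPatch],
    npc_a_def: float,
    npc_a_undef: float,
    alpha_tot: float,
    params: TransportParams,
) -> dict:
    """Steady-state N/C in the well-mixed limit (no rupture).

    Returns the ratio together with the stretch-enhanced and baseline
    import terms (k_in,NPC,def and k_in,NPC,undef, units µm³ s⁻¹).
    """
    sa_def, sa_undef = _split_ne(ne_patches)
    sa_nuc = sa_def + sa_undef
    if sa_nuc <= 0:
        raise TransportError("total NE area must be positive")
    k_def = npc_import_rate(npc_a_def, alpha_tot, params) * sa_def
    k_undef = npc_import_rate(npc_a_undef, 1.0, params) * sa_undef
    nc = phi_free * (k_def + k_undef) / (params.k_out_npc * sa_nuc)
    return {"nc_ratio": nc, "k_in_npc_def": k_def, "k_in_npc_undef": k_undef,
            "sa_nuc": sa_nuc}


def wellmixed_nc_with_rupture(
    phi_free: float,
    ne_patches: list[NEPatch],
    npc_a_def: float,
    npc_a_undef: float,
    alpha_tot: float,
    params: TransportParams,
    rupture: RuptureSpec,
    p_ner: float = 1.0,
) -> dict:
    """Steady-state N/C with the rupture pore included.

    The pore enters as an extra exchange pathway of strength
    ``k_rupture * p_NER * SA_NER``; at SA_NER = 0 the expression reduces
    exactly to :func:`wellmixed_nc`.
    """
    base = wellmixed_nc(phi_free, ne_patches, npc_a_def, npc_a_undef,
                        alpha_tot, params)
    s = rupture.k_rupture * p_ner * rupture.sa_ner
    nc = phi_free * (base["k_in_npc_def"] + base["k_in_npc_undef"] + s) / (
        params.k_out_npc * base["sa_nuc"] + s / params.upsilon)
    out = dict(base)
    out["nc_ratio"] = nc
    out["nc_ratio_no_rupture"] = base["nc_ratio"]
    out["ner_transport_rate"] = rupture.k_rupture * rupture.sa_ner
    return out


# ---------------------------------------------------------------------------
# dynamic rupture time course
# ---------------------------------------------------------------------------

def dynamic_rupture_course(
    geometry,
    ne_patches: list[NEPatch],
    params: MechanoParams,
    rupture: RuptureSpec,
    state0=None,
    t_end: float = 10_000.0,
    freeze_cytoskeleton: bool = False,
    n_out: int = 201,
):
    """Integrate the full network with the rupture flux switched on at t=0.

    ``state0`` should normally be the converged pre-rupture steady state
    (computed here if omitted).  Returns the trajectory; N/C dynamics are
    available via ``Trajectory.nc_ratio()``.
    """
    from .signaling import assemble_rhs, initial_state, simulate

    if state0 is None:
        rhs0 = assemble_rhs(geometry, ne_patches, params)
        state0 = simulate(rhs0, initial_state(params), params=params).steady.vector()
    rhs = assemble_rhs(geometry, ne_patches, params, rupture=rupture,
                       freeze_cytoskeleton=freeze_cytoskeleton)
    return simulate(rhs, state0, t_end=t_end, params=params, n_out=n_out)
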