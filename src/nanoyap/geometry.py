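"""Nanopillar substrate and plasma-membrane geometry.

The substrate is a square lattice of vertical nanopillars (radius ``r_np``,
height ``h_np``, center-to-center pitch ``p_np``) on a flat floor, with one
pillar on the axis of the circular cell-substrate contact region.  The plasma
membrane (PM) conforms to the substrate at a fixed offset (50 nm by default)
and meets the floor through a smooth fillet of characteristic radius 200 nm.

All geometric quantities used downstream (patch areas and mean curvatures)
are closed-form, so the PM is represented as a small set of analytic patches
rather than a triangulated mesh.  Mean curvature is signed positive when the
membrane bends toward the cytosol (pillar-induced, inward curvature); the
base fillet therefore carries a negative tube curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """A geometric precondition is violated."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or incomplete."""


# ---------------------------------------------------------------------------
# curvature primitives
# ---------------------------------------------------------------------------

def mean_curvature_cylinder(r: float) -> float:
    """Mean curvature of a cylindrical membrane of radius ``r`` (µm).

    The two principal curvatures of a cylinder are ``1/r`` (circumferential)
    and ``0`` (axial), so ``H = 1/(2 r)``; positive for a membrane wrapping
    a pillar (bending toward the cytosol).
    """
    if not (r > 0):
        raise GeometryError(f"cylinder radius must be positive, got {r}")
    return 1.0 / (2.0 * r)


def mean_curvature_sphere(r: float) -> float:
    """Mean curvature ``1/r`` of a spherical cap of radius ``r`` (µm)."""
    if not (r > 0):
        raise GeometryError(f"sphere radius must be positive, got {r}")
    return 1.0 / r


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

PM_LABELS = (
    "flat_substrate",
    "pillar_sidewall",
    "pillar_tip",
    "base_fillet",
    "free_apical",
    "free_lateral",
)


@dataclass(frozen=True)
class SubstrateSpec:
    """Nanopillar array and stiffness parameters defining the ECM surface.

    Lengths in µm, stiffness in kPa.  ``r_tip`` is the rounding radius of the
    pillar top edge; ``r_tip == r_np`` gives a hemispherical tip and
    ``r_tip == 0`` a sharp-edged cylinder.  A flat substrate is encoded with
    ``h_np == 0`` (see :meth:`flat`).
    """

    r_np: float
    h_np: float
    p_np: float
    r_tip: float
    e_mod: float
    contact_radius: float

    def __post_init__(self) -> None:
        if self.h_np > 0:
            if self.r_np <= 0 or self.p_np <= 0:
                raise GeometryError("pillar radius and pitch must be positive")
            if self.p_np <= 2 * self.r_np:
                raise GeometryError(
                    f"pitch {self.p_np} must exceed pillar diameter "
                    f"{2 * self.r_np} (pillars overlap)"
                )
            if not (0 <= self.r_tip <= self.r_np):
                raise GeometryError("tip radius must satisfy 0 <= r_tip <= r_np")
        if self.h_np < 0:
            raise GeometryError("pillar height must be nonnegative")
        if self.e_mod <= 0 or self.contact_radius <= 0:
            raise GeometryError("stiffness and contact radius must be positive")

    @property
    def is_flat(self) -> bool:
        return self.h_np == 0

    @classmethod
    def flat(cls, e_mod: float, contact_radius: float) -> "SubstrateSpec":
        """A flat substrate of the given stiffness and contact radius."""
        return cls(r_np=0.1, h_np=0.0, p_np=1.0, r_tip=0.0,
                   e_mod=e_mod, contact_radius=contact_radius)


@dataclass(frozen=True)
class PMPatch:
    """One analytic PM patch: label, total area (µm²) and mean curvature (µm⁻¹).

    ``area`` aggregates all copies of the patch (e.g. the sidewalls of every
    pillar under the cell); ``h_pm`` is the area-weighted mean curvature of
    the underlying parametric surface, exact for cylinders/spheres/planes and
    a closed-form area-weighted average for torus segments.
    """

    label: str
    area: float
    h_pm: float

    def __post_init__(self) -> None:
        if self.label not in PM_LABELS:
            raise ConfigurationError(f"unknown PM patch label {self.label!r}")
        if not (self.area > 0):
            raise GeometryError(f"patch area must be positive, got {self.area}")
        if not math.isfinite(self.h_pm):
            raise GeometryError("patch mean curvature must be finite")

    @property
    def on_substrate(self) -> bool:
        return self.label in ("flat_substrate", "pillar_sidewall",
                              "pillar_tip", "base_fillet")


@dataclass
class CellGeometry:
    """Substrate spec plus the PM patch decomposition and cell volumes."""

    substrate: SubstrateSpec
    pm_patches: list[PMPatch]
    v_cyto: float
    v_nuc: float
    pm_offset: float = 0.05
    fillet_radius: float = 0.2
    n_pillars_under_cell: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def substrate_contact_area(self) -> float:
        return sum(p.area for p in self.pm_patches if p.on_substrate)

    @property
    def total_pm_area(self) -> float:
        return sum(p.area for p in self.pm_patches)

    @property
    def substrate_patches(self) -> list[PMPatch]:
        return [p for p in self.pm_patches if p.on_substrate]


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

def count_pillars_under_cell(spec: SubstrateSpec) -> int:
    """Number of square-lattice pillar axes within the contact radius.

    The lattice has a pillar at the contact-region center; points
    ``(i p, j p)`` with distance <= contact_radius are counted.
    """
    if spec.contact_radius <= 0:
        raise GeometryError("contact radius must be positive")
    if spec.is_flat:
        return 0
    nmax = int(math.floor(spec.contact_radius / spec.p_np))
    r2 = (spec.contact_radius / spec.p_np) ** 2
    count = 0
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            if i * i + j * j <= r2:
                count += 1
    return count


def pillar_centers(spec: SubstrateSpec, radius: float | None = None) -> np.ndarray:
    """(n, 2) array of pillar axis positions within ``radius`` of the origin."""
    if spec.is_flat:
        return np.zeros((0, 2))
    rad = spec.contact_radius if radius is None else radius
    nmax = int(math.floor(rad / spec.p_np))
    pts = []
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            if (i * i + j * j) * spec.p_np**2 <= rad**2:
                pts.append((i * spec.p_np, j * spec.p_np))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# torus segment closed forms
# ---------------------------------------------------------------------------

def _rim_torus_patch(rc: float, rho: float) -> tuple[float, float]:
    """Area and area-weighted mean curvature of an outer quarter-torus rim.

    The rim wraps a pillar's top edge: tube radius ``rho``, centerline radius
    ``rc`` (``rc = 0`` degenerates to a hemispherical cap).  Parametrized by
    the tube angle ``phi`` in [0, pi/2] from the horizontal top, the surface
    point sits at cylindrical radius ``r = rc + rho sin(phi)`` with principal
    curvatures ``1/rho`` (tube) and ``sin(phi)/r`` (azimuthal), both positive
    (membrane bends toward the cytosol).  Closed forms:

        A        = 2 pi rho (rc pi/2 + rho)
        int H dA = pi (rc pi/2 + 2 rho)
    """
    area = 2.0 * math.pi * rho * (rc * math.pi / 2.0 + rho)
    h_int = math.pi * (rc * math.pi / 2.0 + 2.0 * rho)
    return area, h_int / area


def _fillet_torus_patch(r_side: float, rho: float) -> tuple[float, float]:
    """Area and mean curvature of the inner quarter-torus base fillet.

    The fillet joins the vertical sidewall (cylindrical radius ``r_side``) to
    the flat floor with tube radius ``rho``; its tube curvature is negative
    (the membrane bends away from the cytosol in the valley) while the
    azimuthal curvature stays positive.  With centerline radius
    ``rc = r_side + rho``:

        A        = 2 pi rho (rc pi/2 - rho)
        int H dA = pi (2 rho - rc pi/2)
    """
    rc = r_side + rho
    area = 2.0 * math.pi * rho * (rc * math.pi / 2.0 - rho)
    # int H dA = pi * integral of (-r/rho + cos t) * rho dt over [0, pi/2]
    h_int = math.pi * (2.0 * rho - rc * math.pi / 2.0)
    return area, h_int / area


# ---------------------------------------------------------------------------
# PM surface construction
# ---------------------------------------------------------------------------

def build_pm_surface(
    spec: SubstrateSpec,
    pm_offset: float = 0.05,
    fillet_radius: float = 0.2,
) -> list[PMPatch]:
    """Decompose the substrate-contact PM into analytic patches.

    Returns patches for the flat floor annulus, the per-pillar sidewall
    cylinders (radius ``r_np + pm_offset``), the tip rim/cap tori (tube
    radius ``r_tip + pm_offset``) and the base fillet tori, with areas from
    closed-form surface formulas and the sign convention described in the
    module docstring.  Pillar multiplicities are folded into patch areas.
    """
    if pm_offset < 0 or fillet_radius < 0:
        raise ConfigurationError("pm_offset and fillet_radius must be >= 0")
    contact_area = math.pi * spec.contact_radius**2

    if spec.is_flat:
        return [PMPatch("flat_substrate", contact_area, 0.0)]

    n = count_pillars_under_cell(spec)
    r_side = spec.r_np + pm_offset          # sidewall cylinder radius
    rho_tip = spec.r_tip + pm_offset        # tip rim tube radius
    rc_tip = spec.r_np - spec.r_tip         # tip rim centerline radius
    foot_radius = r_side + fillet_radius    # floor footprint radius per pillar
    if 2.0 * foot_radius > spec.p_np:
        raise ConfigurationError(
            f"fillet footprint diameter {2 * foot_radius:.3f} exceeds pitch "
            f"{spec.p_np}: fillets of neighboring pillars overlap"
        )

    patches: list[PMPatch] = []

    flat_area = contact_area - n * math.pi * foot_radius**2
    if flat_area <= 0:
        raise ConfigurationError("pillar footprints exceed the contact area")
    patches.append(PMPatch("flat_substrate", flat_area, 0.0))

    # sidewall: cylinder from fillet top to tip-rim base
    h_eff = max(spec.h_np - spec.r_tip - fillet_radius, 0.0)
    if h_eff > 0:
        patches.append(PMPatch(
            "pillar_sidewall",
            2.0 * math.pi * r_side * h_eff * n,
            mean_curvature_cylinder(r_side),
        ))

    # tip: flat top disk (if the edge is rounded with r_tip < r_np) plus the
    # rim torus; rc_tip == 0 reduces the rim to a hemispherical cap.
    tip_area, tip_h = _rim_torus_patch(rc_tip, rho_tip)
    if rc_tip > 0:
        top_disk = math.pi * rc_tip**2
        tip_area_tot = tip_area + top_disk
        tip_h = tip_h * tip_area / tip_area_tot  # flat part has H = 0
        tip_area = tip_area_tot
    patches.append(PMPatch("pillar_tip", tip_area * n, tip_h))

    if fillet_radius > 0:
        f_area, f_h = _fillet_torus_patch(r_side, fillet_radius)
        patches.append(PMPatch("base_fillet", f_area * n, f_h))

    return patches


def build_cell_geometry(
    spec: SubstrateSpec,
    v_cyto: float,
    v_nuc: float,
    pm_offset: float = 0.05,
    fillet_radius: float = 0.2,
) -> CellGeometry:
    """Full PM decomposition including the free (non-contact) membrane.

    The free PM closes the cell surface over the circular contact region:
    the cell is modeled as a squat cylinder of volume ``v_cyto + v_nuc``
    over the contact disk, giving an apical disk and a lateral band, both
    carried flat (H = 0) for reaction purposes.
    """
    if v_cyto <= 0 or v_nuc <= 0:
        raise GeometryError("cell volumes must be positive")
    patches = build_pm_surface(spec, pm_offset, fillet_radius)
    r_c = spec.contact_radius
    # pillar volume steals negligible space; ignore it in the envelope height
    h_cell = (v_cyto + v_nuc) / (math.pi * r_c**2)
    patches.append(PMPatch("free_apical", math.pi * r_c**2, 0.0))
    patches.append(PMPatch("free_lateral", 2.0 * math.pi * r_c * h_cell, 0.0))
    return CellGeometry(
        substrate=spec,
        pm_patches=patches,
        v_cyto=v_cyto,
        v_nuc=v_nuc,
        pm_offset=pm_offset,
        fillet_radius=fillet_radius,
        n_pillars_under_cell=count_pillars_under_cell(spec),
        extras={"cell_height": h_cell},
    )


# ---------------------------------------------------------------------------
# numeric curvature oracle (second fundamental form on a sampled surface)
# ---------------------------------------------------------------------------

def numeric_mean_curvature_revolution(
    r_of_t, z_of_t, t: float, dt: float = 1e-5, inward_positive: bool = True
) -> float:
    """Mean curvature of a surface of revolution at parameter ``t``.

    Central-difference evaluation of the meridian curvature plus the
    azimuthal normal curvature for the profile ``(r(t), z(t))`` revolved
    about the z-axis.  Used as an independent check of the closed-form patch
    curvatures; sign follows the inward-positive convention when the normal
    points away from the axis of revolution.
    """
    r0, z0 = r_of_t(t), z_of_t(t)
    rp = (r_of_t(t + dt) - r_of_t(t - dt)) / (2 * dt)
    zp = (z_of_t(t + dt) - z_of_t(t - dt)) / (2 * dt)
    rpp = (r_of_t(t + dt) - 2 * r0 + r_of_t(t - dt)) / dt**2
    zpp = (z_of_t(t + dt) - 2 * z0 + z_of_t(t - dt)) / dt**2
    speed = math.hypot(rp, zp)
    # meridian (profile) curvature, signed for normal n = (z', -r')/speed
    k_meridian = (rp * zpp - zp * rpp) / speed**3
    # azimuthal normal curvature
    k_azimuthal = zp / (r0 * speed)
    h = 0.5 * (k_meridian + k_azimuthal)
    return h if inward_positive else -h


# ---------------------------------------------------------------------------
# optional triangulated export
# ---------------------------------------------------------------------------

def export_surface(spec: SubstrateSpec, path: str,
                   pm_offset: float = 0.05, sections: int = 48) -> None:
    """Write a triangulated rendering of the substrate-side PM to STL/PLY.

    Convenience output only; all computations use the analytic patches.
    """
    import trimesh

    meshes = []
    disk = trimesh.creation.cylinder(
        radius=spec.contact_radius, height=0.01, sections=4 * sections)
    disk.apply_translation([0, 0, -0.005])
    meshes.append(disk)
    if not spec.is_flat:
        for cx, cy in pillar_centers(spec):
            cyl = trimesh.creation.capsule(
                radius=spec.r_np + pm_offset,
                height=max(spec.h_np - spec.r_np, 1e-3),
                count=[sections // 4, sections // 4],
            )
            cyl.apply_translation(
                [cx, cy, max(spec.h_np - spec.r_np, 1e-3) / 2.0])
            meshes.append(cyl)
    trimesh.util.concatenate(meshes).export(path)
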