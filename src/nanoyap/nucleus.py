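"""Nuclear shape, nanopillar indentation, NE stretch and curvature.

The nucleus is an oblate spheroid (equatorial semi-axis ``a``, vertical
semi-axis ``b``, target aspect ratio ``a/b = 2.21``) whose lower envelope is
represented as a height field ``z(x, y)`` on a regular grid.  Nanopillar
indentation displaces material points of the lower nuclear envelope (NE)
purely vertically: wherever a pillar's offset surface (pillar plus an
NE-pillar standoff, 0.2 µm by default) would penetrate the reference
surface, the deformed surface conforms to it; a steep conical skirt of
lateral width ``transition_width`` carries the NE back down around each
pillar, and the conforming/free pieces are blended with a smooth-max, so the
deformed surface is smooth and never penetrates a pillar.

The area stretch ratio follows from the vertical-displacement kinematics,

    alpha = sqrt(1 + |grad z|^2) / sqrt(1 + |grad z0|^2),

the pointwise ratio of deformed to reference area elements; it equals 1
wherever the surface slope is unchanged (in particular under rigid vertical
translation, e.g. directly over a flat pillar top).  Stretch is interpreted
as elastic stretching of the nuclear lamina, not areal dilation of the lipid
bilayer, so no upper cap is imposed.

Nuclear volume is conserved under indentation by widening the equatorial
semi-axis (1-D bisection); the indented nucleus is wider than the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, SubstrateSpec, pillar_centers

DEFAULT_ASPECT_RATIO = 2.21


# ---------------------------------------------------------------------------
# nucleus shape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusShape:
    """Oblate spheroid nucleus: x²/a² + y²/a² + (z - z_c)²/b² = 1."""

    a_radial: float
    b_vertical: float
    center_z: float
    v_nuc: float

    @property
    def aspect_ratio(self) -> float:
        return self.a_radial / self.b_vertical

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.a_radial**2 * self.b_vertical

    def surface_area(self) -> float:
        """Closed-form oblate spheroid surface area."""
        a, b = self.a_radial, self.b_vertical
        if a <= b:  # sphere or prolate degenerate; handle sphere exactly
            if math.isclose(a, b):
                return 4.0 * math.pi * a * a
            raise GeometryError("expected an oblate spheroid (a >= b)")
        e = math.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * math.pi * a * a * (1.0 + (1.0 - e * e) / e * math.atanh(e))


def build_nucleus(
    v_nuc: float,
    max_vertical_extent: float | None = None,
    aspect_ratio: float = DEFAULT_ASPECT_RATIO,
    bottom_z: float = 0.0,
) -> NucleusShape:
    """Construct the reference nucleus of volume ``v_nuc`` (µm³).

    The aspect ratio is honored when the nucleus fits within
    ``max_vertical_extent``; otherwise the vertical semi-axis is reduced to
    fit and the equatorial semi-axis recomputed so the volume is conserved.
    ``bottom_z`` positions the lowest point of the spheroid.
    """
    if not (v_nuc > 0):
        raise GeometryError(f"nuclear volume must be positive, got {v_nuc}")
    if aspect_ratio < 1:
        raise GeometryError("aspect ratio a/b must be >= 1 (oblate)")
    b = (3.0 * v_nuc / (4.0 * math.pi * aspect_ratio**2)) ** (1.0 / 3.0)
    if max_vertical_extent is not None:
        if max_vertical_extent <= 0:
            raise GeometryError("vertical envelope leaves no room for the nucleus")
        b = min(b, max_vertical_extent / 2.0)
    a = math.sqrt(3.0 * v_nuc / (4.0 * math.pi * b))
    if a < b:
        raise GeometryError("envelope too tall/narrow for an oblate nucleus")
    return NucleusShape(a_radial=a, b_vertical=b, center_z=bottom_z + b,
                        v_nuc=v_nuc)


# ---------------------------------------------------------------------------
# indentation spec and NE patches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndentationSpec:
    """Vertical nanopillar indentation of the lower NE.

    ``depth`` is how far the central pillar's offset surface protrudes above
    the reference lower NE at the pillar axis; ``ne_pillar_gap`` the NE-pillar
    standoff; ``transition_width`` the lateral width of the conical skirt
    carrying the NE down around each pillar (default: the pillar tip radius).
    """

    depth: float
    ne_pillar_gap: float = 0.2
    transition_width: float | None = None
    grid_um: float = 0.02

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise GeometryError("indentation depth must be >= 0")
        if self.ne_pillar_gap <= 0:
            raise GeometryError("NE-pillar gap must be positive")
        if self.grid_um <= 0:
            raise GeometryError("grid resolution must be positive")


@dataclass(frozen=True)
class NEPatch:
    """Aggregated NE patch: deformed-configuration area, stretch, curvature."""

    label: str  # "deformed" | "undeformed"
    area: float
    alpha: float
    h_ne: float
    z_ne: float = float("nan")

    def __post_init__(self) -> None:
        if self.label not in ("deformed", "undeformed"):
            raise GeometryError(f"unknown NE patch label {self.label!r}")
        if not (self.area >= 0 and self.alpha > 0):
            raise GeometryError("NE patch needs area >= 0 and alpha > 0")


# ---------------------------------------------------------------------------
# height-field differential geometry
# ---------------------------------------------------------------------------

def area_stretch(z0: np.ndarray, z: np.ndarray, grid_um: float) -> np.ndarray:
    """Pointwise area stretch ratio between two height fields.

    Under purely vertical displacement the deformed area element is
    ``sqrt(1+|grad z|^2) dx dy``, so alpha is the ratio of the two area
    elements on the shared parametric (x, y) domain.
    """
    gx0, gy0 = np.gradient(z0, grid_um)
    gx, gy = np.gradient(z, grid_um)
    w0 = np.sqrt(1.0 + gx0**2 + gy0**2)
    w = np.sqrt(1.0 + gx**2 + gy**2)
    alpha = w / w0
    if not np.all(np.isfinite(alpha)):
        raise GeometryError("non-finite gradients in stretch computation")
    return alpha


def ne_mean_curvature(z: np.ndarray, grid_um: float) -> np.ndarray:
    """Mean curvature field of a lower-NE height field.

    Half the divergence of the unit normal of the graph surface, signed
    positive where the surface bends toward the nucleoplasm (which lies
    above the lower NE), so an upward indentation bump is positive:

        H = -1/2 div( grad z / sqrt(1 + |grad z|^2) )
    """
    gx, gy = np.gradient(z, grid_um)
    w = np.sqrt(1.0 + gx**2 + gy**2)
    div = np.gradient(gx / w, grid_um, axis=0) + np.gradient(gy / w, grid_um, axis=1)
    h = -0.5 * div
    if not np.all(np.isfinite(h)):
        raise GeometryError("non-finite second derivatives in curvature field")
    return h


def area_weighted_mean(field: np.ndarray, weights: np.ndarray,
                       mask: np.ndarray) -> float:
    """Average ``field`` over ``mask`` weighted by the local area elements."""
    w = np.where(mask, weights, 0.0)
    tot = w.sum()
    if tot <= 0:
        raise GeometryError("empty region in area-weighted average")
    return float((field * w).sum() / tot)


# ---------------------------------------------------------------------------
# pillar obstacle profile (NE side)
# ---------------------------------------------------------------------------

def _pillar_obstacle_profile(d: np.ndarray, substrate: SubstrateSpec,
                             gap: float, skirt_width: float) -> np.ndarray:
    """Upper envelope the NE must clear, vs radial distance from one pillar.

    Piecewise: flat offset top (radius ``r_np - r_tip``), rim torus of tube
    radius ``r_tip + gap``, then a steep conical skirt dropping the envelope
    to the floor over lateral width ``skirt_width``.
    """
    rho = substrate.r_tip + gap
    rc = substrate.r_np - substrate.r_tip
    z_rim_base = substrate.h_np - substrate.r_tip  # rim tube center height
    out = np.full_like(d, -np.inf, dtype=float)

    top = d <= rc
    out[top] = substrate.h_np + gap

    rim = (d > rc) & (d <= rc + rho)
    dd = d[rim] - rc
    out[rim] = z_rim_base + np.sqrt(np.maximum(rho**2 - dd**2, 0.0))

    slope = max(z_rim_base, 1e-6) / max(skirt_width, 1e-6)
    skirt = d > rc + rho
    out[skirt] = z_rim_base - (d[skirt] - (rc + rho)) * slope
    return out


def _smooth_max(a: np.ndarray, b: np.ndarray, beta: float) -> np.ndarray:
    """C-infinity upper bound of two fields: beta*log(exp(a/b)+exp(b/b)).

    Always >= max(a, b), so the blended NE never penetrates an obstacle;
    corners are rounded over a vertical scale ``beta``.
    """
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    return hi + beta * np.log1p(np.exp(np.clip((lo - hi) / beta, -60.0, 0.0)))


# ---------------------------------------------------------------------------
# indentation
# ---------------------------------------------------------------------------

@dataclass
class IndentedNucleus:
    """Deformed lower NE on a grid, with aggregate patch bookkeeping.

    ``z0``/``z`` are reference/deformed height fields on the grid ``x, y``
    (restricted to the equatorial footprint mask), ``alpha`` the stretch
    field, ``h`` the mean-curvature field and ``w`` the deformed area-element
    weights (times the grid cell area).
    """

    nucleus: NucleusShape
    substrate: SubstrateSpec
    spec: IndentationSpec
    x: np.ndarray
    y: np.ndarray
    z0: np.ndarray
    z: np.ndarray
    alpha: np.ndarray
    h: np.ndarray
    w: np.ndarray          # deformed area element per grid cell (µm²)
    footprint: np.ndarray  # valid-domain mask
    deformed: np.ndarray   # alpha-based deformation mask
    contact: np.ndarray    # conforming-to-pillar mask
    belt_area: float       # analytic equatorial-belt area outside the grid
    upper_area: float      # analytic upper-half spheroid area
    extras: dict = field(default_factory=dict)

    # -- aggregates -------------------------------------------------------
    @property
    def sa_def(self) -> float:
        return float(self.w[self.deformed & self.footprint].sum())

    @property
    def sa_undef(self) -> float:
        lower_undef = float(self.w[~self.deformed & self.footprint].sum())
        return lower_undef + self.belt_area + self.upper_area

    @property
    def sa_nuc(self) -> float:
        return self.sa_def + self.sa_undef

    @property
    def alpha_tot(self) -> float:
        """Area-weighted mean stretch over the deformed region (>= 1)."""
        mask = self.deformed & self.footprint
        if not mask.any():
            return 1.0
        return area_weighted_mean(self.alpha, self.w, mask)

    @property
    def z_ne(self) -> float:
        """Height of the lower NE at the central pillar axis (µm)."""
        i = np.argmin(np.abs(self.x))
        j = np.argmin(np.abs(self.y))
        return float(self.z[i, j])

    def patches(self) -> list[NEPatch]:
        """Two-patch aggregation used by the well-mixed transport forms."""
        out = []
        mask_d = self.deformed & self.footprint
        if mask_d.any():
            out.append(NEPatch(
                "deformed", self.sa_def,
                area_weighted_mean(self.alpha, self.w, mask_d),
                area_weighted_mean(self.h, self.w, mask_d),
                z_ne=self.z_ne,
            ))
        out.append(NEPatch("undeformed", self.sa_undef, 1.0, 0.0))
        return out

    def patch_table(self):
        """NE patch table as a pandas DataFrame (CSV-exportable)."""
        import pandas as pd

        return pd.DataFrame(
            [{"label": p.label, "area_um2": p.area, "alpha": p.alpha,
              "H_per_um": p.h_ne} for p in self.patches()]
        )

    def central_indent_mean_curvature(self) -> float:
        """Area-weighted NE bending curvature over the membrane indented by
        the central pillar.

        Averages the total bending curvature kappa_1 + kappa_2 (the membrane-
        mechanics curvature sum, i.e. twice the mean-curvature field) over
        the NE conforming to the central pillar's offset surface.  The sum
        convention matches how indentation curvature is read off confocal
        reslices with a tangent circle at the pit apex, where the surface is
        locally spherical.
        """
        rr = np.hypot(self.x[:, None], self.y[None, :])
        central = self.contact & (rr <= self.substrate.p_np / 2.0)
        return 2.0 * area_weighted_mean(self.h, self.w, central)


def indent_nucleus(
    nucleus: NucleusShape,
    substrate: SubstrateSpec,
    spec: IndentationSpec,
    conserve_volume: bool = True,
    alpha_deformed_tol: float = 1e-3,
) -> IndentedNucleus:
    """Indent the lower NE on the pillar lattice by ``spec.depth``.

    The reference spheroid is positioned so the central pillar's offset
    surface protrudes ``depth`` above the reference lower NE at the axis;
    the deformed surface is the smooth-max of the reference against every
    pillar's obstacle profile.  With ``conserve_volume`` the equatorial
    semi-axis is rescaled (bisection, relative tolerance 1e-6) so the
    enclosed volume matches the reference nucleus.
    """
    if substrate.is_flat and spec.depth > 0:
        raise GeometryError("cannot indent on a flat substrate")
    if spec.depth > substrate.h_np + spec.ne_pillar_gap:
        raise GeometryError(
            f"depth {spec.depth} exceeds pillar height + standoff")

    w_t = spec.transition_width
    if w_t is None:
        w_t = substrate.r_tip if substrate.r_tip > 0 else 0.2
    beta = max(w_t / 2.0, 2.0 * spec.grid_um)

    obstacle_top = substrate.h_np + spec.ne_pillar_gap
    # position the nucleus so the central obstacle pokes `depth` into it
    bottom_z = obstacle_top - spec.depth

    def make_fields(a_scale: float):
        nuc = NucleusShape(
            a_radial=nucleus.a_radial * a_scale,
            b_vertical=nucleus.b_vertical,
            center_z=bottom_z + nucleus.b_vertical,
            v_nuc=nucleus.v_nuc,
        )
        a, b, zc = nuc.a_radial, nuc.b_vertical, nuc.center_z
        # grid over the equatorial footprint, trimmed of the near-vertical rim
        r_dom = 0.98 * a
        n = max(int(math.ceil(2 * r_dom / spec.grid_um)) + 1, 41)
        x = np.linspace(-r_dom, r_dom, n)
        y = np.linspace(-r_dom, r_dom, n)
        rr2 = (x[:, None] ** 2 + y[None, :] ** 2) / a**2
        footprint = rr2 <= (r_dom / a) ** 2
        safe = np.clip(1.0 - rr2, 0.0, None)
        z0 = zc - b * np.sqrt(safe)
        z_up = zc + b * np.sqrt(safe)

        if spec.depth == 0 or substrate.is_flat:
            z = z0.copy()
        else:
            rad = r_dom + substrate.p_np
            obst = np.full_like(z0, -np.inf)
            for cx, cy in pillar_centers(substrate, radius=rad):
                d = np.hypot(x[:, None] - cx, y[None, :] - cy)
                prof = _pillar_obstacle_profile(d, substrate,
                                                spec.ne_pillar_gap, w_t)
                np.maximum(obst, prof, out=obst)
            z = _smooth_max(z0, obst, beta)
        return nuc, x, y, z0, z, z_up, footprint

    def grid_volume(x, y, z, z_up, footprint):
        dxdy = (x[1] - x[0]) * (y[1] - y[0])
        col = np.where(footprint, np.maximum(z_up - z, 0.0), 0.0)
        return float(col.sum() * dxdy)

    # reference volume measured with the same quadrature, so bisection
    # compares like with like
    _, x, y, z0r, _, z_upr, fpr = make_fields(1.0)
    v_target = grid_volume(x, y, z0r, z_upr, fpr)

    a_scale = 1.0
    if conserve_volume and spec.depth > 0 and not substrate.is_flat:
        lo, hi = 1.0, 1.5
        nuc, x, y, z0, z, z_up, fp = make_fields(hi)
        while grid_volume(x, y, z, z_up, fp) < v_target:
            hi *= 1.2
            nuc, x, y, z0, z, z_up, fp = make_fields(hi)
            if hi > 4:
                raise GeometryError("volume conservation failed to bracket")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            nuc, x, y, z0, z, z_up, fp = make_fields(mid)
            v = grid_volume(x, y, z, z_up, fp)
            if abs(v - v_target) / v_target < 1e-6:
                break
            if v < v_target:
                lo = mid
            else:
                hi = mid
        a_scale = 0.5 * (lo + hi)

    nuc, x, y, z0, z, z_up, footprint = make_fields(a_scale)

    alpha = area_stretch(z0, z, spec.grid_um)
    h = ne_mean_curvature(z, spec.grid_um)
    gx, gy = np.gradient(z, spec.grid_um)
    dxdy = (x[1] - x[0]) * (y[1] - y[0])
    w = np.sqrt(1.0 + gx**2 + gy**2) * dxdy

    deformed = np.abs(alpha - 1.0) > alpha_deformed_tol

    # contact: where the deformed NE sits on a pillar's core offset surface
    contact = np.zeros_like(deformed)
    if spec.depth > 0 and not substrate.is_flat:
        tol = max(2.0 * spec.grid_um, beta * math.log(2.0))
        for cx, cy in pillar_centers(substrate, radius=0.98 * nuc.a_radial
                                     + substrate.p_np):
            d = np.hypot(x[:, None] - cx, y[None, :] - cy)
            core = d <= (substrate.r_np + spec.ne_pillar_gap)
            prof = _pillar_obstacle_profile(d, substrate, spec.ne_pillar_gap,
                                            w_t)
            contact |= core & (np.abs(z - prof) <= tol) & (prof > z0)
    contact &= footprint

    # analytic area accounting for the trimmed equatorial belt and upper half
    a, b = nuc.a_radial, nuc.b_vertical
    half_area = 0.5 * nuc.surface_area()
    belt_area = half_area - _lower_cap_area(a, b, 0.98)

    return IndentedNucleus(
        nucleus=nuc, substrate=substrate, spec=spec,
        x=x, y=y, z0=z0, z=z, alpha=alpha, h=h, w=w,
        footprint=footprint, deformed=deformed, contact=contact,
        belt_area=belt_area, upper_area=half_area,
        extras={"a_scale": a_scale, "transition_width": w_t, "beta": beta,
                "v_target": v_target,
                "v_deformed": grid_volume(x, y, z, z_up, footprint)},
    )


def _lower_cap_area(a: float, b: float, frac: float) -> float:
    """Area of the lower spheroid cap with cylindrical radius <= frac*a.

    Numeric 1-D quadrature of the surface-of-revolution area for the lower
    sheet of the oblate spheroid, used to account for the near-vertical
    equatorial belt excluded from the height-field grid.
    """
    t = np.linspace(0.0, math.asin(frac), 20001)  # r = a sin t, z = -b cos t
    r = a * np.sin(t)
    dr = a * np.cos(t)
    dz = b * np.sin(t)
    integrand = 2.0 * math.pi * r * np.hypot(dr, dz)
    return float(np.trapezoid(integrand, t))
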