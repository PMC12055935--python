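"""Parametric stenosed-artery geometry with calcified arcs and lithotripsy defects.

The idealized lesion is a straight two-layer artery (media+intima fused,
adventitia) carrying a concentric soft-plaque stenosis and a circumferential
calcium arc of angular extent ``theta_c``.  Lithotripsy-induced defects are
carved from the calcium as angular sectors (default) or prismatic boxes,
parametrized by the nondimensional width ``w`` (subtended angle over arc
angle) and length ``l`` (axial fraction of the lesion).

Angle convention: degrees everywhere in the public API, the arc bisector
points at 12 o'clock (+y), the artery axis is z with z=0 at the proximal end,
and u = z / artery_length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

__all__ = [
    "LesionConfig",
    "DefectSpec",
    "StudyModelSpec",
    "AnnularSector",
    "CrossSection",
    "LesionSolid",
    "chord_angle",
    "normalized_width",
    "chord_from_w",
    "normalized_length",
    "build_cross_section",
    "build_solid",
    "carve_defect",
    "enumerate_study_models",
    "MATERIAL_IDS",
]

#: integer material labels used by the mesh exporters and point classifier
MATERIAL_IDS = {
    "lumen": 1,
    "lipidic": 2,
    "calcium": 3,
    "media-intima": 4,
    "adventitia": 5,
}
_ID_TO_MATERIAL = {v: k for k, v in MATERIAL_IDS.items()}

SubModel = Literal["sided", "centered", "through"]


# ---------------------------------------------------------------------------
# nondimensional defect parametrization
# ---------------------------------------------------------------------------

def chord_angle(chord_width: float, r_c: float) -> float:
    """Central angle (degrees) subtended at radius ``r_c`` by a chord.

    Uses ``arccos(1 - w~^2 / (2 r_c^2))``, which equals the chord law
    ``2 arcsin(w~ / (2 r_c))``.

    Parameters
    ----------
    chord_width : float
        Chord length ``w~`` in mm, ``0 <= w~ <= 2 r_c``.
    r_c : float
        Radius (mm) at which the chord is measured, typically the calcium
        mid-surface radius.
    """
    if r_c <= 0:
        raise ValueError(f"r_c must be positive, got {r_c}")
    if chord_width < 0:
        raise ValueError(f"chord width must be nonnegative, got {chord_width}")
    if chord_width > 2.0 * r_c:
        raise ValueError(
            f"chord width {chord_width} exceeds the diameter 2*r_c = {2 * r_c}"
        )
    c = 1.0 - chord_width**2 / (2.0 * r_c**2)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def normalized_width(chord_width: float, r_c: float, theta_c: float) -> float:
    """Nondimensional defect width: subtended angle over the arc angle."""
    if theta_c <= 0:
        raise ValueError(f"theta_c must be positive, got {theta_c}")
    return chord_angle(chord_width, r_c) / theta_c


def chord_from_w(w: float, theta_c: float, r_c: float) -> float:
    """Chord length (mm) whose subtended angle is ``w * theta_c`` at ``r_c``.

    Inverse of :func:`normalized_width`.  Only defined while the subtended
    angle stays within a half-circle.
    """
    if w < 0:
        raise ValueError(f"w must be nonnegative, got {w}")
    ang = w * theta_c
    if ang > 180.0 + 1e-12:
        raise ValueError(
            f"w*theta_c = {ang:.6g} deg exceeds 180 deg; a chord at fixed "
            "radius cannot subtend more than a half-circle"
        )
    return r_c * math.sqrt(max(0.0, 2.0 * (1.0 - math.cos(math.radians(ang)))))


def normalized_length(axial_length: float, lesion_length: float) -> float:
    """Nondimensional defect length: axial extent over the lesion length."""
    if axial_length < 0:
        raise ValueError(f"axial length must be nonnegative, got {axial_length}")
    if axial_length > lesion_length:
        raise ValueError(
            f"axial length {axial_length} exceeds lesion length {lesion_length}"
        )
    return axial_length / lesion_length


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionConfig:
    """Dimensional parameters of the idealized calcified lesion (mm, degrees)."""

    artery_length: float = 40.0
    healthy_lumen_radius: float = 1.5
    media_thickness: float = 0.32
    adventitia_thickness: float = 0.34
    lesion_length: float = 10.0
    calcium_thickness: float = 1.1
    calcium_arc_angle: float = 270.0
    area_stenosis_fraction: float = 0.70
    transition_length: float = 2.0
    #: soft-plaque rim between the stenotic lumen and the calcium inner face
    soft_rim_thickness: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "artery_length",
            "healthy_lumen_radius",
            "media_thickness",
            "adventitia_thickness",
            "lesion_length",
            "calcium_thickness",
            "transition_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.area_stenosis_fraction < 1.0:
            raise ValueError("area_stenosis_fraction must lie in (0, 1)")
        if not 0.0 < self.calcium_arc_angle <= 360.0:
            raise ValueError("calcium_arc_angle must lie in (0, 360]")
        if self.lesion_length > self.artery_length:
            raise ValueError("lesion cannot be longer than the artery")

    # --- derived radii -----------------------------------------------------
    @property
    def stenotic_lumen_radius(self) -> float:
        """Lumen radius at full stenosis: r * sqrt(1 - area fraction)."""
        return self.healthy_lumen_radius * math.sqrt(1.0 - self.area_stenosis_fraction)

    @property
    def calcium_inner_radius(self) -> float:
        return self.stenotic_lumen_radius + self.soft_rim_thickness

    @property
    def calcium_outer_radius(self) -> float:
        return self.calcium_inner_radius + self.calcium_thickness

    @property
    def calcium_mid_radius(self) -> float:
        """Radial position r_c of the calcium mid-surface."""
        return self.calcium_inner_radius + 0.5 * self.calcium_thickness

    @property
    def lesion_center(self) -> float:
        return 0.5 * self.artery_length

    @property
    def lesion_z_window(self) -> tuple[float, float]:
        half = 0.5 * self.lesion_length
        return (self.lesion_center - half, self.lesion_center + half)

    @property
    def lesion_u_window(self) -> tuple[float, float]:
        z0, z1 = self.lesion_z_window
        return (z0 / self.artery_length, z1 / self.artery_length)

    # --- arc angular interval (degrees, bisector at 90) --------------------
    @property
    def arc_interval(self) -> tuple[float, float]:
        half = 0.5 * self.calcium_arc_angle
        return (90.0 - half, 90.0 + half)

    def lumen_radius(self, z: float | np.ndarray) -> float | np.ndarray:
        """Lumen radius at axial position z, with a cosine taper of
        ``transition_length`` just outside the lesion window."""
        z = np.asarray(z, dtype=float)
        z0, z1 = self.lesion_z_window
        rh, rs, lt = self.healthy_lumen_radius, self.stenotic_lumen_radius, self.transition_length
        d = np.maximum(np.maximum(z0 - z, z - z1), 0.0)  # distance outside lesion
        frac = np.clip(d / lt, 0.0, 1.0)
        # cosine blend: 0 -> stenotic, 1 -> healthy
        s = 0.5 * (1.0 - np.cos(np.pi * frac))
        r = rs + (rh - rs) * s
        return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class DefectSpec:
    """A lithotripsy-induced defect in nondimensional (w, l) coordinates.

    ``w`` is the defect's subtended angle at the calcium mid-surface divided
    by the arc angle; ``l`` is the axial extent divided by the lesion length.
    Through defects span the full lesion length (l = 1) and split the arc.
    """

    sub_model: SubModel
    w: float
    l: float

    def __post_init__(self) -> None:
        if self.sub_model not in ("sided", "centered", "through"):
            raise ValueError(f"unknown sub-model {self.sub_model!r}")
        if not 0.0 < self.w <= 1.0:
            raise ValueError(f"w must lie in (0, 1], got {self.w}")
        if not 0.0 < self.l <= 1.0:
            raise ValueError(f"l must lie in (0, 1], got {self.l}")
        if self.sub_model == "through" and self.l != 1.0:
            raise ValueError("through defects span the full lesion (l = 1)")
        if self.sub_model in ("sided", "centered") and self.w >= 1.0:
            raise ValueError("sided/centered defects must leave calcium (w < 1)")

    # --- dimensional realizations at a given configuration -----------------
    def subtended_angle(self, config: LesionConfig) -> float:
        """Angular width of the defect in degrees: w * theta_c."""
        return self.w * config.calcium_arc_angle

    def chord_width(self, config: LesionConfig) -> float:
        """Defect chord width w~ (mm) at the calcium mid-surface radius."""
        return chord_from_w(self.w, config.calcium_arc_angle, config.calcium_mid_radius)

    def axial_length(self, config: LesionConfig) -> float:
        """Defect axial extent l~ (mm)."""
        return self.l * config.lesion_length

    def angular_interval(self, config: LesionConfig) -> tuple[float, float]:
        """Absolute angular interval carved from the arc (degrees)."""
        a0, a1 = config.arc_interval
        width = self.subtended_angle(config)
        if self.sub_model == "sided":
            return (a0, a0 + width)
        # centered and through bisect the arc
        return (90.0 - 0.5 * width, 90.0 + 0.5 * width)

    def z_window(self, config: LesionConfig) -> tuple[float, float]:
        """Axial window of the defect (mm); axially centered in the lesion."""
        half = 0.5 * self.axial_length(config)
        return (config.lesion_center - half, config.lesion_center + half)


@dataclass(frozen=True)
class StudyModelSpec:
    """One member of the factorial study design: arc angle + defect (or intact)."""

    arc_angle: float
    defect: DefectSpec | None
    identifier: str

    @property
    def is_intact(self) -> bool:
        return self.defect is None


def _frac_label(x: float) -> str:
    for num, den in ((1, 3), (2, 3), (1, 1), (1, 2)):
        if abs(x - num / den) < 1e-9:
            return f"{num}" if den == 1 else f"{num}-{den}"
    return f"{x:.3f}".replace(".", "p")


def enumerate_study_models(base: LesionConfig | None = None) -> list[StudyModelSpec]:
    """Enumerate the full factorial study design.

    For each arc angle in {90, 270}: one intact baseline, four sided and four
    centered defects (l, w each in {1/3, 2/3}), and two through defects
    (l = 1, w in {1/3, 2/3}) — 11 per arc, 22 in total.  Ordering and
    identifiers are deterministic.
    """
    levels = (1.0 / 3.0, 2.0 / 3.0)
    specs: list[StudyModelSpec] = []
    for arc in (90.0, 270.0):
        specs.append(StudyModelSpec(arc, None, f"arc{int(arc):03d}_intact"))
        for sub in ("sided", "centered"):
            for l, w in product(levels, levels):
                ident = f"arc{int(arc):03d}_{sub}_l{_frac_label(l)}_w{_frac_label(w)}"
                specs.append(StudyModelSpec(arc, DefectSpec(sub, w, l), ident))
        for w in levels:
            ident = f"arc{int(arc):03d}_through_l1_w{_frac_label(w)}"
            specs.append(StudyModelSpec(arc, DefectSpec("through", w, 1.0), ident))
    return specs


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnularSector:
    """An annular sector region: radial interval x angular interval (degrees)."""

    label: str
    r_in: float
    r_out: float
    theta0: float
    theta1: float

    @property
    def area(self) -> float:
        dth = math.radians(self.theta1 - self.theta0)
        return 0.5 * dth * (self.r_out**2 - self.r_in**2)

    def polygon(self, deg_step: float = 1.0) -> Polygon:
        n = max(2, int(math.ceil((self.theta1 - self.theta0) / deg_step)) + 1)
        th = np.radians(np.linspace(self.theta0, self.theta1, n))
        outer = np.column_stack([self.r_out * np.cos(th), self.r_out * np.sin(th)])
        if self.r_in > 0:
            inner = np.column_stack([self.r_in * np.cos(th[::-1]), self.r_in * np.sin(th[::-1])])
            pts = np.vstack([outer, inner])
        else:
            pts = outer if self.theta1 - self.theta0 >= 360.0 else np.vstack([outer, [[0.0, 0.0]]])
        return Polygon(pts)


@dataclass
class CrossSection:
    """Labeled partition of one artery cross-section into annular sectors.

    Areas are exact closed forms of the defining radii and angles; polygons
    are discretizations for meshing and plotting only.
    """

    z: float
    regions: list[AnnularSector] = field(default_factory=list)

    def area(self, label: str) -> float:
        return sum(r.area for r in self.regions if r.label == label)

    @property
    def labels(self) -> set[str]:
        return {r.label for r in self.regions}

    @property
    def total_area(self) -> float:
        return sum(r.area for r in self.regions)

    def outer_area(self) -> float:
        """Area enclosed by the outer boundary, integrated per angular piece.

        Equals the sum of all region areas when the regions partition the
        section (conservation check).
        """
        # group by angular interval (mod 360): outermost radius per piece
        edges = sorted(
            {r.theta0 % 360.0 for r in self.regions}
            | {r.theta1 % 360.0 for r in self.regions}
            | {0.0, 360.0}
        )
        total = 0.0
        for t0, t1 in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (t0 + t1)
            rmax = max(
                (
                    r.r_out
                    for r in self.regions
                    if (mid - r.theta0) % 360.0 <= (r.theta1 - r.theta0) + 1e-12
                    or r.theta1 - r.theta0 >= 360.0
                ),
                default=0.0,
            )
            total += 0.5 * math.radians(t1 - t0) * rmax**2
        return total

    def polygons(self, label: str, deg_step: float = 1.0) -> list[Polygon]:
        return [r.polygon(deg_step) for r in self.regions if r.label == label]


def _wall_pieces(
    config: LesionConfig,
    z: float,
    defect: DefectSpec | None,
) -> list[tuple[float, float, bool, bool]]:
    """Angular pieces at axial position z inside the lesion.

    Returns (theta0, theta1, in_arc, in_defect) covering a full turn.
    """
    a0, a1 = config.arc_interval
    pieces: list[tuple[float, float, bool, bool]] = []
    carved = None
    if defect is not None:
        dz0, dz1 = defect.z_window(config)
        if dz0 - 1e-12 <= z <= dz1 + 1e-12:
            carved = defect.angular_interval(config)
    if carved is None:
        pieces.append((a0, a1, True, False))
    else:
        d0, d1 = carved
        if d0 > a0 + 1e-12:
            pieces.append((a0, d0, True, False))
        pieces.append((d0, d1, True, True))
        if d1 < a1 - 1e-12:
            pieces.append((d1, a1, True, False))
    if config.calcium_arc_angle < 360.0:
        pieces.append((a1, a0 + 360.0, False, False))
    return pieces


def build_cross_section(
    config: LesionConfig,
    z: float,
    defect: DefectSpec | None = None,
) -> CrossSection:
    """Labeled cross-section of the (possibly carved) lesion at axial z.

    Outside the lesion and its taper only lumen, media and adventitia exist;
    inside, soft plaque fills the annulus between the tapered lumen and the
    healthy wall, and the calcium arc (thickness t, angular extent theta_c)
    locally pushes media and adventitia outward.
    """
    if not 0.0 <= z <= config.artery_length:
        raise ValueError(
            f"z = {z} outside the artery [0, {config.artery_length}]"
        )
    rl = float(config.lumen_radius(z))
    rh = config.healthy_lumen_radius
    tm, ta = config.media_thickness, config.adventitia_thickness
    cs = CrossSection(z=z)
    z0, z1 = config.lesion_z_window
    in_lesion = z0 - 1e-12 <= z <= z1 + 1e-12

    cs.regions.append(AnnularSector("lumen", 0.0, rl, 0.0, 360.0))
    if not in_lesion:
        if rl < rh - 1e-12:  # taper band: soft plaque fills up to the healthy wall
            cs.regions.append(AnnularSector("lipidic", rl, rh, 0.0, 360.0))
        cs.regions.append(AnnularSector("media-intima", rh, rh + tm, 0.0, 360.0))
        cs.regions.append(AnnularSector("adventitia", rh + tm, rh + tm + ta, 0.0, 360.0))
        return cs

    rci, rco = config.calcium_inner_radius, config.calcium_outer_radius
    for t0, t1, in_arc, in_defect in _wall_pieces(config, z, defect):
        if in_arc and not in_defect:
            cs.regions.append(AnnularSector("lipidic", rl, rci, t0, t1))
            cs.regions.append(AnnularSector("calcium", rci, rco, t0, t1))
            wall = rco
        elif in_arc:  # carved defect: soft tissue fills the crack
            cs.regions.append(AnnularSector("lipidic", rl, rco, t0, t1))
            wall = rco
        else:
            cs.regions.append(AnnularSector("lipidic", rl, rh, t0, t1))
            wall = rh
        cs.regions.append(AnnularSector("media-intima", wall, wall + tm, t0, t1))
        cs.regions.append(AnnularSector("adventitia", wall + tm, wall + tm + ta, t0, t1))
    return cs


# ---------------------------------------------------------------------------
# the swept solid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSolid:
    """Semi-analytic 3D lesion model: configuration + optional carved defect.

    Cross-sections, volumes and point classification are evaluated on demand
    from the parametric description; meshes are tessellated separately.
    """

    config: LesionConfig
    defect: DefectSpec | None = None
    carve_mode: Literal["sector", "box"] = "sector"

    def cross_section(self, z: float) -> CrossSection:
        return build_cross_section(self.config, z, self.defect)

    # --- volumes -----------------------------------------------------------
    def intact_calcium_volume(self) -> float:
        c = self.config
        dth = math.radians(c.calcium_arc_angle)
        ring = 0.5 * dth * (c.calcium_outer_radius**2 - c.calcium_inner_radius**2)
        return ring * c.lesion_length

    def calcium_volume(self) -> float:
        """Remaining calcium volume (mm^3), exact for the sector carve."""
        v = self.intact_calcium_volume()
        if self.defect is None:
            return v
        c = self.config
        if self.carve_mode == "sector":
            dth = math.radians(self.defect.subtended_angle(c))
            carved_ring = 0.5 * dth * (c.calcium_outer_radius**2 - c.calcium_inner_radius**2)
            return v - carved_ring * self.defect.axial_length(c)
        # box mode: carved section area from the planar boolean
        full = self._arc_polygon()
        carved = full.difference(self._box_strip())
        per_z = full.area - carved.area
        return v - per_z * self.defect.axial_length(c)

    def carved_volume(self) -> float:
        return self.intact_calcium_volume() - self.calcium_volume()

    def _arc_polygon(self, deg_step: float = 0.25) -> Polygon:
        c = self.config
        a0, a1 = c.arc_interval
        return AnnularSector("calcium", c.calcium_inner_radius, c.calcium_outer_radius, a0, a1).polygon(deg_step)

    def _box_strip(self) -> Polygon:
        """Half-strip of width w~ along the defect bisector (box carve)."""
        c = self.config
        assert self.defect is not None
        d0, d1 = self.defect.angular_interval(c)
        phi = math.radians(0.5 * (d0 + d1))
        w = self.defect.chord_width(c)
        ex, ey = math.cos(phi), math.sin(phi)
        nx, ny = -ey, ex
        big = 2.0 * c.calcium_outer_radius + 1.0
        h = 0.5 * w
        # rectangle from the origin outward only (never carve the far side)
        corners = [
            (-h * nx, -h * ny),
            (big * ex - h * nx, big * ey - h * ny),
            (big * ex + h * nx, big * ey + h * ny),
            (h * nx, h * ny),
        ]
        return Polygon(corners)

    # --- point classification (vectorized; used by voxelizers) -------------
    def material_at(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Integer material id at each (x, y, z) point; 0 = outside/void."""
        c = self.config
        x, y, z = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float))
        out = np.zeros(x.shape, dtype=np.int8)
        inside_z = (z >= 0.0) & (z <= c.artery_length)
        r = np.hypot(x, y)
        theta = np.degrees(np.arctan2(y, x))
        rl = np.asarray(c.lumen_radius(z))
        rh, tm, ta = c.healthy_lumen_radius, c.media_thickness, c.adventitia_thickness
        z0, z1 = c.lesion_z_window
        in_lesion = (z >= z0) & (z <= z1)
        a0, _ = c.arc_interval
        in_arc = ((theta - a0) % 360.0) <= c.calcium_arc_angle

        in_defect = np.zeros(x.shape, dtype=bool)
        if self.defect is not None:
            dz0, dz1 = self.defect.z_window(c)
            dz = (z >= dz0) & (z <= dz1)
            if self.carve_mode == "sector":
                d0, d1 = self.defect.angular_interval(c)
                ang = ((theta - d0) % 360.0) <= (d1 - d0)
                in_defect = dz & ang
            else:
                d0, d1 = self.defect.angular_interval(c)
                phi = math.radians(0.5 * (d0 + d1))
                ex, ey = math.cos(phi), math.sin(phi)
                perp = np.abs(-ey * x + ex * y)
                fwd = (ex * x + ey * y) > 0
                in_defect = dz & (perp <= 0.5 * self.defect.chord_width(c)) & fwd

        rci, rco = c.calcium_inner_radius, c.calcium_outer_radius
        # wall reference radius: pushed out over the arc inside the lesion
        wall = np.where(in_lesion & in_arc, rco, rh)
        lumen = r <= rl
        out[inside_z & lumen] = MATERIAL_IDS["lumen"]
        calc = inside_z & in_lesion & in_arc & ~in_defect & (r > rci) & (r <= rco)
        out[calc] = MATERIAL_IDS["calcium"]
        soft = (
            inside_z & ~lumen & (r <= wall)
            & ~calc
            & (in_lesion | (rl < rh - 1e-12))
        )
        # inside the lesion arc, soft plaque only below the calcium inner face
        soft &= ~(in_lesion & in_arc & ~in_defect & (r > rco))
        out[soft] = MATERIAL_IDS["lipidic"]
        media = inside_z & (r > wall) & (r <= wall + tm)
        out[media] = MATERIAL_IDS["media-intima"]
        adv = inside_z & (r > wall + tm) & (r <= wall + tm + ta)
        out[adv] = MATERIAL_IDS["adventitia"]
        return out

    # --- calcium connectivity ----------------------------------------------
    def calcium_component_count(self, n_theta: int = 361, n_z: int = 201) -> int:
        """Number of connected calcium pieces, from occupancy at the
        mid-surface radius on a (theta, z) raster of the lesion window."""
        c = self.config
        a0, a1 = c.arc_interval
        z0, z1 = c.lesion_z_window
        th = np.linspace(a0 + 1e-6, a1 - 1e-6, n_theta)
        zz = np.linspace(z0 + 1e-6, z1 - 1e-6, n_z)
        T, Z = np.meshgrid(th, zz, indexing="ij")
        r = np.full(T.shape, c.calcium_mid_radius)
        mat = self.material_at(r * np.cos(np.radians(T)), r * np.sin(np.radians(T)), Z)
        occ = mat == MATERIAL_IDS["calcium"]
        _, n = ndimage.label(occ)
        return int(n)


def build_solid(
    config: LesionConfig,
    defect: DefectSpec | None = None,
    carve_mode: Literal["sector", "box"] = "sector",
) -> LesionSolid:
    """Construct the (intact or carved) lesion solid."""
    return LesionSolid(config=config, defect=defect, carve_mode=carve_mode)


def carve_defect(solid: LesionSolid, defect: DefectSpec) -> LesionSolid:
    """Carve a lithotripsy defect from the solid's calcium arc.

    Idempotent for identical specs; re-carving with a different spec replaces
    the defect (a solid carries at most one defect, matching the study design).
    """
    if defect.w > 1.0:
        raise ValueError("defect wider than the calcium arc (w > 1)")
    return replace(solid, defect=defect)


def solid_for_model(spec: StudyModelSpec, base: LesionConfig | None = None) -> LesionSolid:
    """Realize a study-design member as a solid with the arc angle applied."""
    base = base or LesionConfig()
    config = replace(base, calcium_arc_angle=spec.arc_angle)
    return build_solid(config, spec.defect)
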