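"""Synthetic CBCT impression phantom.

A prepared-tooth die (tapered abutment with a rounded chamfer margin and a
domed occlusal table) stands in for the patient's dentition. Its
elastomeric impression is emulated as the material complement of the die
inside a tray region, voxelized with sub-voxel (partial-volume) occupancy
fractions, and rendered into CBCT-like grayscale with two Gaussian
intensity classes plus additive noise.

The geometry parametrization is a stand-in: no real prepared-tooth shape
is modelled, only the features the conversion pipeline has to cope with
(a curved margin, a tapered wall, a smooth occlusal dome and optional
neighbouring teeth). Defaults follow common crown-preparation guidance:
1.5 / 1.0 mm functional / non-functional occlusal reduction, a chamfer
finish line, and 100 um isotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh

from .volume import GrayVolume

__all__ = [
    "PrepSpec",
    "IntensityModel",
    "make_prep_mesh",
    "voxelize_impression",
    "render_intensities",
    "make_phantom",
]


@dataclass
class PrepSpec:
    """Geometry of the synthetic prepared-tooth die (all lengths mm)."""

    abutment_height: float = 4.0
    total_convergence_angle: float = 12.0  # degrees, full taper
    margin_radius: float = 4.0  # radius of the chamfer margin centerline
    chamfer_depth: float = 0.5
    occlusal_reduction_functional: float = 1.5
    occlusal_reduction_nonfunctional: float = 1.0
    include_adjacent_teeth: bool = False
    adjacent_gap: float = 2.0

    def __post_init__(self) -> None:
        lengths = {
            "abutment_height": self.abutment_height,
            "margin_radius": self.margin_radius,
            "chamfer_depth": self.chamfer_depth,
            "occlusal_reduction_functional": self.occlusal_reduction_functional,
            "occlusal_reduction_nonfunctional": self.occlusal_reduction_nonfunctional,
            "adjacent_gap": self.adjacent_gap,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 0 <= self.total_convergence_angle < 90:
            raise ValueError(
                "total_convergence_angle must be in [0, 90) degrees, "
                f"got {self.total_convergence_angle}"
            )
        if self.chamfer_depth >= self.margin_radius:
            raise ValueError(
                "degenerate geometry: chamfer_depth "
                f"({self.chamfer_depth}) must be smaller than margin_radius "
                f"({self.margin_radius})"
            )

    @property
    def dome_height(self) -> float:
        """Height of the occlusal dome above the axial-wall top."""
        return max(
            self.occlusal_reduction_functional
            - self.occlusal_reduction_nonfunctional,
            1e-3,
        )

    @property
    def wall_top_radius(self) -> float:
        half = np.deg2rad(self.total_convergence_angle) / 2
        return (
            self.margin_radius
            - self.chamfer_depth
            - self.abutment_height * np.tan(half)
        )


@dataclass
class IntensityModel:
    """Two-class CBCT grayscale model (arbitrary intensity units).

    Voxel value is the occupancy-weighted blend of the air and PVS class
    means, with Gaussian noise whose standard deviation is blended the
    same way. ``supersample_factor`` controls the sub-voxel sampling used
    by :func:`voxelize_impression` to emulate partial-volume blur.
    """

    mean_air: float = 0.0
    sd_air: float = 40.0
    mean_pvs: float = 700.0
    sd_pvs: float = 40.0
    mean_tray: float | None = None
    sd_tray: float | None = None
    supersample_factor: int = 2
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_air <= 0 or self.sd_pvs <= 0:
            raise ValueError("intensity standard deviations must be > 0")
        if self.mean_pvs == self.mean_air:
            raise ValueError("mean_pvs must differ from mean_air")
        if self.supersample_factor not in (1, 2, 3, 4):
            raise ValueError(
                f"supersample_factor must be in {{1,2,3,4}}, "
                f"got {self.supersample_factor}"
            )
        if (self.sd_tray is not None) and self.sd_tray <= 0:
            raise ValueError("sd_tray must be > 0")


def _profile_points(spec: PrepSpec, step: float) -> np.ndarray:
    """(r, z) polyline of the die's solid-of-revolution profile.

    Runs from the axis at the base, out to the margin, up the chamfer
    arc and the tapered wall, over the occlusal dome back to the axis.
    """
    r0 = spec.margin_radius
    c = spec.chamfer_depth
    r1 = r0 - c
    r_top = spec.wall_top_radius
    if r_top <= 0:
        raise ValueError(
            "degenerate geometry: taper consumes the abutment "
            f"(wall top radius {r_top:.3f} mm <= 0)"
        )
    pts: list[tuple[float, float]] = [(0.0, 0.0), (r0, 0.0)]

    # concave chamfer arc: quarter circle of radius c centered at (r0, c)
    n_arc = max(4, int(np.ceil((np.pi / 2) * c / step)))
    phi = np.linspace(0.0, np.pi / 2, n_arc + 1)[1:]
    pts.extend(zip(r0 - c * np.sin(phi), c - c * np.cos(phi)))

    # tapered axial wall
    z_wall_top = c + spec.abutment_height
    pts.append((r_top, z_wall_top))

    # occlusal spherical cap from (r_top, z_wall_top) to the apex
    hd = spec.dome_height
    rho = (r_top**2 + hd**2) / (2 * hd)  # sphere radius
    zc = z_wall_top + hd - rho  # sphere center height
    phi_start = np.arcsin(min(1.0, r_top / rho))
    n_dome = max(4, int(np.ceil(phi_start * rho / step)))
    phi_d = np.linspace(phi_start, 0.0, n_dome + 1)[1:]
    pts.extend(zip(rho * np.sin(phi_d), zc + rho * np.cos(phi_d)))
    if pts[-1][0] != 0.0:
        pts.append((0.0, z_wall_top + hd))
    return np.array(pts)


def _adjacent_tooth_mesh(spec: PrepSpec, step: float, sections: int) -> trimesh.Trimesh:
    """Simple unprepared-neighbour solid: cylinder with a domed top."""
    r = spec.margin_radius
    h = spec.chamfer_depth + spec.abutment_height + spec.occlusal_reduction_functional
    hd = 0.3 * r
    rho = (r**2 + hd**2) / (2 * hd)
    zc = h + hd - rho
    phi_start = np.arcsin(min(1.0, r / rho))
    phi_d = np.linspace(phi_start, 0.0, max(4, int(np.ceil(phi_start * rho / step))) + 1)[1:]
    pts = [(0.0, 0.0), (r, 0.0), (r, h)]
    pts.extend(zip(rho * np.sin(phi_d), zc + rho * np.cos(phi_d)))
    if pts[-1][0] != 0.0:
        pts.append((0.0, h + hd))
    return trimesh.creation.revolve(np.array(pts), sections=sections)


def make_prep_mesh(
    spec: PrepSpec | None = None,
    *,
    sections: int = 96,
    profile_step: float = 0.1,
) -> trimesh.Trimesh:
    """Build the watertight ground-truth die mesh (mm).

    Parameters
    ----------
    spec : PrepSpec
        Geometry parameters; defaults used when omitted.
    sections : int
        Angular resolution of the surface of revolution.
    profile_step : float
        Approximate arc-length step (mm) when sampling curved profile
        segments.
    """
    if spec is None:
        spec = PrepSpec()
    profile = _profile_points(spec, profile_step)
    mesh = trimesh.creation.revolve(profile, sections=sections)
    if spec.include_adjacent_teeth:
        offset = 2 * spec.margin_radius + spec.adjacent_gap
        left = _adjacent_tooth_mesh(spec, profile_step, sections)
        right = left.copy()
        left.apply_translation([-offset, 0.0, 0.0])
        right.apply_translation([offset, 0.0, 0.0])
        mesh = trimesh.util.concatenate([mesh, left, right])
    if not mesh.is_watertight:
        raise ValueError(
            "non-manifold phantom mesh produced; geometry parameters are "
            "degenerate"
        )
    if mesh.volume <= 0:
        mesh.invert()
    return mesh


def _plane_coords(path2d, xf: np.ndarray, yf: np.ndarray, z: float):
    """Map world (x, y, z) sample grid into the section's 2-D plane frame."""
    to_3d = np.asarray(path2d.metadata["to_3D"])
    inv = np.linalg.inv(to_3d)
    # plane coords p2 = inv @ [x, y, z, 1]
    u = inv[0, 0] * xf[:, None] + inv[0, 1] * yf[None, :] + inv[0, 2] * z + inv[0, 3]
    v = inv[1, 0] * xf[:, None] + inv[1, 1] * yf[None, :] + inv[1, 2] * z + inv[1, 3]
    return u, v


def voxelize_impression(
    model: trimesh.Trimesh,
    bbox_margin: float = 1.0,
    spacing: float = 0.1,
    supersample_factor: int = 1,
) -> GrayVolume:
    """Voxelize the impression (tray region minus the model solid).

    The tray region is the model's axis-aligned bounding box dilated by
    ``bbox_margin``; the returned grid tiles it exactly (per-axis spacing
    is snapped to the nearest value that divides the tray extent, always
    within half a voxel of the request). Each voxel holds the fraction of
    ``supersample_factor**3`` regularly spaced sample points that fall in
    impression material, so boundary voxels carry partial-volume
    fractions in ``(0, 1)``.

    Inside/outside testing is done per z-slab: the mesh is cross-sectioned
    with parallel planes and samples are tested against the resulting
    planar polygons, which requires a watertight model.
    """
    if not model.is_watertight:
        raise ValueError("model mesh must be watertight (inside test undefined)")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if bbox_margin < 0:
        raise ValueError("bbox_margin must be >= 0")
    s = int(supersample_factor)
    if s < 1 or s > 4:
        raise ValueError("supersample_factor must be in {1,2,3,4}")

    lo = model.bounds[0] - bbox_margin
    hi = model.bounds[1] + bbox_margin
    extent = hi - lo
    n = np.maximum(2, np.round(extent / spacing).astype(int))
    sp = extent / n
    origin = lo + sp / 2

    # sub-voxel sample offsets, centered in the voxel
    off = (np.arange(s) + 0.5) / s - 0.5
    xf = (origin[0] + np.arange(n[0])[:, None] * sp[0] + off[None, :] * sp[0]).ravel()
    yf = (origin[1] + np.arange(n[1])[:, None] * sp[1] + off[None, :] * sp[1]).ravel()
    z_planes = (
        origin[2] + np.arange(n[2])[:, None] * sp[2] + off[None, :] * sp[2]
    ).ravel()
    # nudge planes off exact vertex rings of revolved solids
    z_planes = z_planes + 2.5e-4 * sp[2]

    base = np.array([0.0, 0.0, z_planes[0]])
    heights = z_planes - z_planes[0]
    paths = model.section_multiplane(
        plane_origin=base, plane_normal=[0.0, 0.0, 1.0], heights=heights
    )

    inside = np.zeros((n[0], n[1], n[2]), dtype=np.uint16)
    for plane_idx, path in enumerate(paths):
        if path is None or len(path.entities) == 0:
            continue
        iz = plane_idx // s
        mask = np.zeros((xf.size, yf.size), dtype=bool)
        u, v = _plane_coords(path, xf, yf, z_planes[plane_idx])
        for poly in path.polygons_full:
            mask |= shapely.contains_xy(poly, u, v)
        inside[:, :, iz] += (
            mask.reshape(n[0], s, n[1], s).sum(axis=(1, 3)).astype(np.uint16)
        )

    occupancy = 1.0 - inside.astype(float) / s**3
    return GrayVolume(occupancy, spacing=sp, origin=origin)


def render_intensities(
    occupancy: GrayVolume, model: IntensityModel | None = None
) -> GrayVolume:
    """Render a PVS-occupancy volume into CBCT-like grayscale.

    ``value = occ * mean_pvs + (1 - occ) * mean_air + N(0, sd)`` with the
    noise standard deviation blended the same way; deterministic under a
    fixed ``noise_seed``.
    """
    if model is None:
        model = IntensityModel()
    occ = occupancy.voxels
    if occ.min() < 0 or occ.max() > 1:
        raise ValueError("occupancy values must lie in [0, 1]")
    mean = occ * model.mean_pvs + (1.0 - occ) * model.mean_air
    sd = occ * model.sd_pvs + (1.0 - occ) * model.sd_air
    rng = np.random.default_rng(model.noise_seed)
    voxels = mean + rng.standard_normal(occ.shape) * sd
    return GrayVolume(voxels, spacing=occupancy.spacing, origin=occupancy.origin)


def make_phantom(
    spec: PrepSpec | None = None,
    intensity: IntensityModel | None = None,
    *,
    bbox_margin: float = 1.0,
    spacing: float = 0.1,
    sections: int = 96,
) -> tuple[trimesh.Trimesh, GrayVolume, GrayVolume]:
    """Convenience wrapper: die mesh, occupancy volume and gray volume."""
    if spec is None:
        spec = PrepSpec()
    if intensity is None:
        intensity = IntensityModel()
    mesh = make_prep_mesh(spec, sections=sections)
    occ = voxelize_impression(
        mesh,
        bbox_margin=bbox_margin,
        spacing=spacing,
        supersample_factor=intensity.supersample_factor,
    )
    gray = render_intensities(occ, intensity)
    return mesh, occ, gray
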