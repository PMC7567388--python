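"""End-to-end conversion: gray volume in, positive model mesh out.

Steps: intensity histogram -> EM Gaussian mixture -> valley ->
calibrated threshold -> binary mask -> area-of-conversion crop ->
marching-cubes iso-surface on the cropped grayscale -> Taubin smoothing
-> winding flip to the positive model -> cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass

import trimesh

from . import segmentation as seg
from . import surface as surf
from .volume import GrayVolume

__all__ = ["ConversionReport", "convert_impression"]


@dataclass
class ConversionReport:
    """What the converter decided and produced."""

    threshold: seg.ThresholdResult
    gmm: seg.GaussianMixtureModel
    n_vertices: int
    n_faces: int
    watertight: bool

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold.threshold,
            "valley": self.threshold.valley,
            "calibration_offset": self.threshold.calibration_offset,
            "em": {
                "k": self.gmm.k,
                "weights": self.gmm.weights.tolist(),
                "means": self.gmm.means.tolist(),
                "variances": self.gmm.variances.tolist(),
                "log_likelihood": self.gmm.log_likelihood,
                "n_iterations": self.gmm.n_iterations,
                "converged": self.gmm.converged,
            },
            "mesh": {
                "n_vertices": self.n_vertices,
                "n_faces": self.n_faces,
                "watertight": self.watertight,
            },
        }


def convert_impression(
    volume: GrayVolume,
    k: int = 2,
    n_bins: int = 256,
    calibration: seg.CalibrationRecord | None = None,
    smoothing: surf.SmoothingParams | None = None,
    positive: bool = True,
) -> tuple[trimesh.Trimesh, ConversionReport]:
    """Convert a CBCT impression volume into a (positive) surface model.

    Returns the mesh (mm, STL-ready) and a report with the EM fit, the
    threshold and mesh statistics. With ``positive=False`` the negative
    (impression-material) surface is returned instead.
    """
    if smoothing is None:
        smoothing = surf.SmoothingParams()
    threshold, gmm = seg.auto_threshold(
        volume, k=k, n_bins=n_bins, calibration=calibration
    )
    mask = seg.segment(volume, threshold.threshold, threshold.material_is_high)
    _mask_crop, offset = seg.area_of_conversion(mask)
    shape = _mask_crop.shape
    sub = GrayVolume(
        volume.voxels[
            offset[0] : offset[0] + shape[0],
            offset[1] : offset[1] + shape[1],
            offset[2] : offset[2] + shape[2],
        ],
        spacing=volume.spacing,
        origin=volume.origin + offset * volume.spacing,
    )
    mesh = surf.extract_isosurface(sub, threshold.threshold)
    mesh = surf.taubin_smooth(mesh, smoothing)
    if positive:
        mesh = surf.to_positive_model(mesh)
    mesh = surf.clean_mesh(mesh)
    report = ConversionReport(
        threshold=threshold,
        gmm=gmm,
        n_vertices=len(mesh.vertices),
        n_faces=len(mesh.faces),
        watertight=bool(mesh.is_watertight),
    )
    return mesh, report
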