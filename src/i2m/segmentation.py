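"""Auto-thresholding of the impression material.

A Gaussian mixture is fitted to the volume's intensity histogram by
expectation-maximization (run on bin centers weighted by counts, so each
iteration is O(n_bins)), the valley between the background and material
classes is located as the interior minimizer of the mixture density, and
an additive material-calibration offset turns the valley into the final
segmentation threshold. The binary mask is then restricted to the
largest connected component (the "area of conversion").

The EM initialization is quantile-based and fully deterministic: no
random restarts, so identical inputs always give identical thresholds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .volume import GrayVolume

__all__ = [
    "Histogram",
    "GaussianMixtureModel",
    "ThresholdResult",
    "CalibrationRecord",
    "compute_histogram",
    "fit_gmm_em",
    "estimate_valley",
    "calibrate_threshold",
    "fit_calibration",
    "segment",
    "area_of_conversion",
]


@dataclass
class Histogram:
    """Intensity histogram: ``n + 1`` monotone bin edges, ``n`` counts."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need n+1 edges for n counts")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("total count must be > 0")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.bin_edges)))


@dataclass
class GaussianMixtureModel:
    """EM fit to an intensity histogram, stored with ascending means."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.ll_history = np.asarray(self.ll_history, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be non-negative")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not np.all(np.diff(self.means) >= 0):
            raise ValueError("means must be stored in ascending order")

    @property
    def k(self) -> int:
        return self.weights.size

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Mixture probability density at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = (
            self.weights
            / np.sqrt(2 * np.pi * self.variances)
            * np.exp(-((x[:, None] - self.means) ** 2) / (2 * self.variances))
        )
        return comp.sum(axis=1)


@dataclass
class ThresholdResult:
    """Valley + calibration offset -> segmentation threshold."""

    valley: float
    calibration_offset: float
    threshold: float
    background_index: int
    material_index: int
    material_is_high: bool


@dataclass
class CalibrationRecord:
    """Additive intensity offset for one impression-material preset.

    The device-specific grayscale of the scanner is unknown a priori, so
    the package ships ``offset = 0`` and :func:`fit_calibration` to fit a
    material's offset from a reference scan with known true surface.
    """

    material: str = "medium-body PVS"
    offset: float = 0.0
    fitted_on: str | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "material": self.material,
                    "offset": self.offset,
                    "fitted_on": self.fitted_on,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationRecord":
        data = json.loads(Path(path).read_text())
        return cls(
            material=data["material"],
            offset=float(data["offset"]),
            fitted_on=data.get("fitted_on"),
        )


def compute_histogram(volume: GrayVolume | np.ndarray, n_bins: int = 256) -> Histogram:
    """Histogram of all voxel intensities spanning [min, max]."""
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    data = volume.voxels if isinstance(volume, GrayVolume) else np.asarray(volume)
    data = data.ravel()
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise ValueError("constant volume has no histogram structure")
    counts, edges = np.histogram(data, bins=n_bins, range=(vmin, vmax))
    return Histogram(edges, counts.astype(float))


def _quantile_init(hist: Histogram, k: int, var_floor: float):
    """Split bins at the k-1 weighted quantiles; deterministic."""
    x, w = hist.centers, hist.counts
    cum = np.cumsum(w) / w.sum()
    qs = np.arange(1, k) / k
    cut_idx = np.searchsorted(cum, qs)
    bounds = np.concatenate([[0], cut_idx, [x.size]])
    weights, means, variances = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_w = w[a:b]
        seg_x = x[a:b]
        tot = seg_w.sum()
        if tot <= 0:  # empty quantile segment: seed from the global stats
            m = float(np.average(x, weights=w))
            v = float(np.average((x - m) ** 2, weights=w))
            weights.append(1.0 / k)
            means.append(m)
            variances.append(max(v, var_floor))
            continue
        m = float(np.average(seg_x, weights=seg_w))
        v = float(np.average((seg_x - m) ** 2, weights=seg_w))
        weights.append(tot / w.sum())
        means.append(m)
        variances.append(max(v, var_floor))
    weights = np.array(weights)
    return weights / weights.sum(), np.array(means), np.array(variances)


def fit_gmm_em(
    hist: Histogram,
    k: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GaussianMixtureModel:
    """Fit a k-component Gaussian mixture to a histogram by EM.

    The E/M updates use bin centers weighted by counts. Stops when the
    relative log-likelihood gain drops below ``tol``; the log-likelihood
    is non-decreasing across iterations (EM guarantee). A variance floor
    of ``(bin width)^2 / 4`` prevents component collapse.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, w = hist.centers, hist.counts
    nonempty = int(np.count_nonzero(w))
    if k > nonempty:
        raise ValueError(f"k={k} exceeds the {nonempty} nonempty histogram bins")
    var_floor = hist.bin_width**2 / 4.0
    pi, mu, var = _quantile_init(hist, k, var_floor)
    total_w = w.sum()

    ll_prev = -np.inf
    history = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step (log domain)
        log_comp = (
            np.log(np.maximum(pi, 1e-300))
            - 0.5 * np.log(2 * np.pi * var)
            - ((x[:, None] - mu) ** 2) / (2 * var)
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(np.dot(w, log_norm))
        history.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])

        # M step (weighted by counts)
        wr = w[:, None] * resp
        nk = wr.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pi = nk / total_w
        mu = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)

        if np.isfinite(ll_prev) and (ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll

    order = np.argsort(mu)
    return GaussianMixtureModel(
        weights=pi[order],
        means=mu[order],
        variances=var[order],
        log_likelihood=history[-1],
        n_iterations=n_iter,
        converged=converged,
        ll_history=np.array(history),
    )


def dominant_components(gmm: GaussianMixtureModel) -> tuple[int, int]:
    """Indices (low-mean, high-mean) of the two highest-weight components."""
    if gmm.k < 2:
        raise ValueError("valley estimation requires at least 2 components")
    top2 = np.argsort(gmm.weights)[-2:]
    lo, hi = sorted(top2, key=lambda i: gmm.means[i])
    if gmm.means[lo] == gmm.means[hi]:
        raise ValueError("dominant components have identical means")
    return int(lo), int(hi)


def estimate_valley(gmm: GaussianMixtureModel, n_grid: int = 4096) -> float:
    """Minimizer of the mixture density between the two dominant means.

    For exactly two components this coincides with the point where the
    two weighted Gaussian densities intersect. Raises if the density has
    no interior minimum (classes not separable); falls back to the
    midpoint of the dominant means only if the numeric refinement fails.
    """
    lo_i, hi_i = dominant_components(gmm)
    lo, hi = gmm.means[lo_i], gmm.means[hi_i]
    grid = np.linspace(lo, hi, n_grid + 1)
    dens = gmm.pdf(grid)
    idx = int(np.argmin(dens[1:-1])) + 1
    if idx <= 1 or idx >= n_grid - 1:
        raise ValueError("classes not separable: no interior density minimum")
    try:
        res = minimize_scalar(
            lambda t: float(gmm.pdf(np.array([t]))[0]),
            bounds=(grid[idx - 1], grid[idx + 1]),
            method="bounded",
            options={"xatol": (hi - lo) * 1e-12},
        )
        return float(res.x)
    except Exception:  # pragma: no cover - numeric fallback
        warnings.warn("valley refinement failed; using midpoint of dominant means")
        return float((lo + hi) / 2)


def calibrate_threshold(
    valley: float,
    calibration: CalibrationRecord | None,
    gmm: GaussianMixtureModel,
) -> ThresholdResult:
    """Apply the material-calibration offset: threshold = valley + offset.

    The threshold must stay between the background and material means,
    otherwise the calibration is implausible for this scan.
    """
    if calibration is None:
        calibration = CalibrationRecord()
    bg_i, mat_i = dominant_components(gmm)
    material_is_high = True  # PVS is the bright class against air
    m_lo, m_hi = gmm.means[bg_i], gmm.means[mat_i]
    if not (m_lo < valley < m_hi):
        raise ValueError(
            f"valley {valley:.3f} outside the component means ({m_lo:.3f}, {m_hi:.3f})"
        )
    threshold = valley + calibration.offset
    if not (m_lo <= threshold <= m_hi):
        raise ValueError(
            f"calibration implausible: threshold {threshold:.3f} outside "
            f"[{m_lo:.3f}, {m_hi:.3f}]"
        )
    return ThresholdResult(
        valley=float(valley),
        calibration_offset=float(calibration.offset),
        threshold=float(threshold),
        background_index=bg_i,
        material_index=mat_i,
        material_is_high=material_is_high,
    )


def auto_threshold(
    volume: GrayVolume,
    k: int = 2,
    n_bins: int = 256,
    calibration: CalibrationRecord | None = None,
) -> tuple[ThresholdResult, GaussianMixtureModel]:
    """Histogram -> EM -> valley -> calibrated threshold, in one call."""
    hist = compute_histogram(volume, n_bins=n_bins)
    gmm = fit_gmm_em(hist, k=k)
    valley = estimate_valley(gmm)
    return calibrate_threshold(valley, calibration, gmm), gmm


def fit_calibration(
    reference_volume: GrayVolume,
    reference_mesh,
    material: str = "medium-body PVS",
    k: int = 2,
    n_bins: int = 256,
    n_coarse: int = 13,
    span: float = 0.45,
    max_vertices: int = 2000,
) -> CalibrationRecord:
    """Fit the additive offset from a reference scan with known surface.

    A 1-D search chooses the offset that minimizes the mean unsigned
    distance between the iso-surface extracted at ``valley + offset`` and
    the reference mesh: a coarse deterministic grid over
    ``[-span*(valley-m_bg), +span*(m_mat-valley)]`` followed by a
    parabolic refinement around the best grid point.
    """
    from .deviation import unsigned_distances  # local import, avoids cycle
    from .surface import extract_isosurface

    hist = compute_histogram(reference_volume, n_bins=n_bins)
    gmm = fit_gmm_em(hist, k=k)
    valley = estimate_valley(gmm)
    bg_i, mat_i = dominant_components(gmm)
    lo_span = span * (valley - gmm.means[bg_i])
    hi_span = span * (gmm.means[mat_i] - valley)
    offsets = np.linspace(-lo_span, hi_span, n_coarse)

    def objective(offset: float) -> float:
        mesh = extract_isosurface(reference_volume, valley + offset)
        verts = mesh.vertices
        if len(verts) > max_vertices:
            stride = int(np.ceil(len(verts) / max_vertices))
            verts = verts[::stride]
        return float(np.mean(unsigned_distances(verts, reference_mesh)))

    errors = np.array([objective(o) for o in offsets])
    best = int(np.argmin(errors))
    if best in (0, n_coarse - 1):
        raise ValueError(
            "calibration search interval exhausted without an interior minimum"
        )
    # parabolic refinement through the bracketing triple
    o1, o2, o3 = offsets[best - 1 : best + 2]
    e1, e2, e3 = errors[best - 1 : best + 2]
    denom = (o1 - o2) * (o1 - o3) * (o2 - o3)
    if denom != 0:
        a = (o3 * (e2 - e1) + o2 * (e1 - e3) + o1 * (e3 - e2)) / denom
        b = (o3**2 * (e1 - e2) + o2**2 * (e3 - e1) + o1**2 * (e2 - e3)) / denom
        if a > 0:
            cand = -b / (2 * a)
            if o1 < cand < o3 and objective(cand) < e2:
                return CalibrationRecord(material, float(cand), fitted_on="reference scan")
    return CalibrationRecord(material, float(offsets[best]), fitted_on="reference scan")


def segment(
    volume: GrayVolume, threshold: float, material_is_high: bool = True
) -> np.ndarray:
    """Binary material mask at the given threshold (same grid as input)."""
    if material_is_high:
        return volume.voxels >= threshold
    return volume.voxels <= threshold


def area_of_conversion(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a mask to its largest 26-connected component.

    Returns the component mask cropped to its bounding box padded by two
    voxels, together with the crop offset (voxel index of the cropped
    array's origin in the input grid).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to convert")
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_labels = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(np.argmax(sizes))
    component = labels == largest
    sl = ndimage.find_objects(component.astype(np.int8))[0]
    pad = 2
    starts = np.array([max(s.start - pad, 0) for s in sl])
    stops = np.array(
        [min(s.stop + pad, dim) for s, dim in zip(sl, mask.shape)]
    )
    cropped = component[
        starts[0] : stops[0], starts[1] : stops[1], starts[2] : stops[2]
    ]
    return cropped, starts
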