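"""Optical-flow silhouette descriptor for grayscale video.

For each interior frame of a clip the chain computes: Horn-Schunck optical
flow against both temporal neighbours, 5x5 median filtering of the flow
components, binarization of the flow magnitude at a threshold T, a moving-
silhouette mask combining the two binarized fields (holes filled), a ~4 px
inner contour band, and finally a normalized 8-bin histogram of flow
directions over the band.  Concatenating the per-frame histograms in time
order yields the video feature vector.

Angle convention: image x rightward, y downward; angles are measured
counter-clockwise from +x in *display* space (so (u, v) = (0, -1), upward
on screen, is 90 deg).  Bin B1 is centered on 0 deg and covers
[337.5, 360) u [0, 22.5); B2..B8 follow counter-clockwise in 45-deg steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateVectorError, HarkitError
from .biosignal import unit_interval_normalize

N_BINS = 8
BIN_WIDTH_DEG = 45.0


@dataclass
class FlowParams:
    """Horn-Schunck and descriptor settings.

    ``alpha`` is the flow-smoothness weight, ``n_iter`` the Jacobi
    iteration count, ``T`` the motion-magnitude binarization threshold in
    px/frame (one constant for all subjects), ``median_size`` the flow
    median-filter window.  ``combine`` selects how the two neighbouring
    flow masks form the moving silhouette; ``weighting`` selects magnitude-
    or count-weighted histogram accumulation.
    """

    alpha: float = 1.0
    n_iter: int = 100
    T: float = 0.5
    median_size: int = 5
    combine: str = "union"
    weighting: str = "magnitude"
    contour_width: int = 4
    backend: str = "numba"

    def __post_init__(self):
        if self.alpha <= 0:
            raise HarkitError("alpha must be positive")
        if self.n_iter < 1:
            raise HarkitError("n_iter must be >= 1")
        if self.T <= 0:
            raise HarkitError("threshold T must be positive")
        if self.combine not in ("union", "intersection"):
            raise HarkitError("combine must be 'union' or 'intersection'")
        if self.weighting not in ("magnitude", "count"):
            raise HarkitError("weighting must be 'magnitude' or 'count'")
        if self.backend not in ("numba", "numpy"):
            raise HarkitError("backend must be 'numba' or 'numpy'")


_REC601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Luminance of a 1- or 3-channel frame (ITU-R 601 weights)."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 1:
        return frame[..., 0]
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame @ _REC601
    raise HarkitError(f"unsupported frame shape {frame.shape}")


def _derivatives(a: np.ndarray, b: np.ndarray):
    """Horn-Schunck gradient estimates over the 2x2x2 cube (edges replicated)."""
    ap = np.pad(a, ((0, 1), (0, 1)), mode="edge")
    bp = np.pad(b, ((0, 1), (0, 1)), mode="edge")
    ex = 0.25 * ((ap[:-1, 1:] - ap[:-1, :-1]) + (ap[1:, 1:] - ap[1:, :-1])
                 + (bp[:-1, 1:] - bp[:-1, :-1]) + (bp[1:, 1:] - bp[1:, :-1]))
    ey = 0.25 * ((ap[1:, :-1] - ap[:-1, :-1]) + (ap[1:, 1:] - ap[:-1, 1:])
                 + (bp[1:, :-1] - bp[:-1, :-1]) + (bp[1:, 1:] - bp[:-1, 1:]))
    d = bp - ap
    et = 0.25 * (d[:-1, :-1] + d[:-1, 1:] + d[1:, :-1] + d[1:, 1:])
    return ex, ey, et


def _local_average(u: np.ndarray) -> np.ndarray:
    p = np.pad(u, 1, mode="edge")
    return ((p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]) / 6.0
            + (p[:-2, :-2] + p[:-2, 2:] + p[2:, :-2] + p[2:, 2:]) / 12.0)


def _hs_numpy(ex, ey, et, alpha2, n_iter, record_residuals=False):
    u = np.zeros_like(ex)
    v = np.zeros_like(ex)
    residuals = []
    for _ in range(n_iter):
        ubar = _local_average(u)
        vbar = _local_average(v)
        t = (ex * ubar + ey * vbar + et) / (alpha2 + ex ** 2 + ey ** 2)
        u = ubar - ex * t
        v = vbar - ey * t
        if record_residuals:
            residuals.append(float(np.mean((ex * u + ey * v + et) ** 2)))
    if record_residuals:
        return u, v, residuals
    return u, v


def horn_schunck(frame_a: np.ndarray, frame_b: np.ndarray,
                 params: FlowParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Optical flow (u, v) between two same-shape grayscale frames.

    Minimizes brightness-constancy error plus ``alpha**2`` times flow
    roughness via the classical Jacobi update, ``n_iter`` sweeps from a
    zero initialization.  u is the horizontal (x) and v the vertical
    (y, downward-positive) component in pixels/frame.
    """
    params = params or FlowParams()
    a = to_grayscale(frame_a)
    b = to_grayscale(frame_b)
    if a.shape != b.shape:
        raise HarkitError(f"frame shapes differ: {a.shape} vs {b.shape}")
    ex, ey, et = _derivatives(a, b)
    alpha2 = params.alpha ** 2
    if params.backend == "numba":
        from ._kernels import hs_jacobi
        return hs_jacobi(ex, ey, et, alpha2, params.n_iter)
    return _hs_numpy(ex, ey, et, alpha2, params.n_iter)


def hs_residual_history(frame_a, frame_b, alpha: float = 1.0, n_iter: int = 10
                        ) -> list[float]:
    """Mean squared brightness-constancy residual after each Jacobi sweep."""
    a = to_grayscale(frame_a)
    b = to_grayscale(frame_b)
    ex, ey, et = _derivatives(a, b)
    _, _, res = _hs_numpy(ex, ey, et, alpha ** 2, n_iter, record_residuals=True)
    return res


def median_filter_components(u: np.ndarray, v: np.ndarray, size: int = 5,
                             backend: str = "numba") -> tuple[np.ndarray, np.ndarray]:
    """Per-component median filter; borders use shrunken neighbourhoods."""
    if backend == "numba":
        from ._kernels import median_shrink
        return median_shrink(np.ascontiguousarray(u), size), \
            median_shrink(np.ascontiguousarray(v), size)
    return _median_shrink_numpy(u, size), _median_shrink_numpy(v, size)


def _median_shrink_numpy(a: np.ndarray, size: int) -> np.ndarray:
    h, w = a.shape
    r = size // 2
    out = np.empty_like(a)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(a[max(i - r, 0):i + r + 1, max(j - r, 0):j + r + 1])
    return out


def motion_mask(u: np.ndarray, v: np.ndarray, T: float) -> np.ndarray:
    """Moving pixels: flow magnitude strictly above the threshold T."""
    if T <= 0:
        raise HarkitError("threshold T must be positive")
    return np.hypot(u, v) > T


def moving_silhouette(mask_prev: np.ndarray, mask_next: np.ndarray,
                      combine: str = "union") -> np.ndarray:
    """Moving-silhouette mask S_{n-1} from the two neighbouring flow masks.

    The masks (from the backward and forward flow fields of frame n-1) are
    combined — union by default, intersection by configuration — and
    enclosed holes (background regions not connected to the border) are
    filled.
    """
    if mask_prev.shape != mask_next.shape:
        raise HarkitError("mask shapes differ")
    if combine == "union":
        joint = mask_prev | mask_next
    elif combine == "intersection":
        joint = mask_prev & mask_next
    else:
        raise HarkitError("combine must be 'union' or 'intersection'")
    return ndimage.binary_fill_holes(joint)


def thicken_contour(mask: np.ndarray, width: int = 4) -> np.ndarray:
    """Inner contour band: the mask minus its erosion by ``width`` pixels.

    Erosion uses the full 3x3 structuring element iterated ``width`` times
    (a Chebyshev ball of radius ``width``), so a solid region keeps a band
    of roughly ``width`` pixels along its inside boundary; regions thinner
    than 2*width survive whole.  An empty mask yields an empty band.
    """
    mask = mask.astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), iterations=width)
    return mask & ~eroded


def direction_angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Display-space CCW angle of each flow vector, degrees in [0, 360)."""
    return np.rad2deg(np.arctan2(-v, u)) % 360.0


def direction_histogram(u: np.ndarray, v: np.ndarray, band: np.ndarray,
                        weighting: str = "magnitude") -> np.ndarray:
    """Normalized 8-direction histogram of the flow over the contour band.

    Each band pixel with nonzero motion contributes its magnitude (or a
    unit count) to the 45-deg bin containing its direction; the histogram
    is divided by its sum.  If no band pixel moves, the all-zero sentinel
    is returned.
    """
    mag = np.hypot(u, v)
    sel = band.astype(bool) & (mag > 0)
    hist = np.zeros(N_BINS)
    if not sel.any():
        return hist
    theta = direction_angles_deg(u[sel], v[sel])
    bins = (np.floor((theta + BIN_WIDTH_DEG / 2) / BIN_WIDTH_DEG).astype(int)) % N_BINS
    weights = mag[sel] if weighting == "magnitude" else np.ones(bins.size)
    np.add.at(hist, bins, weights)
    total = hist.sum()
    return hist / total if total > 0 else hist


def build_video_feature(frames: np.ndarray, params: FlowParams | None = None
                        ) -> np.ndarray:
    """Video feature vector of an N-frame clip: (N-2) x 8 histogram values.

    Only frames with both neighbouring flow fields contribute (indices
    1..N-2 of 0-based frames), so a 40-frame clip yields a 304-dimensional
    vector.  The concatenation is unit-interval normalized; a motionless
    clip therefore surfaces a :class:`DegenerateVectorError`.
    """
    params = params or FlowParams()
    n = frames.shape[0]
    if n < 3:
        raise HarkitError(f"video clips need at least 3 frames, got {n}")
    gray = [to_grayscale(frames[k]) for k in range(n)]
    flows = []
    masks = []
    for k in range(1, n):
        u, v = horn_schunck(gray[k - 1], gray[k], params)
        u, v = median_filter_components(u, v, params.median_size, params.backend)
        flows.append((u, v))
        masks.append(motion_mask(u, v, params.T))
    hists = []
    for f in range(1, n - 1):
        sil = moving_silhouette(masks[f - 1], masks[f], params.combine)
        band = thicken_contour(sil, params.contour_width)
        u, v = flows[f]
        hists.append(direction_histogram(u, v, band, params.weighting))
    vec = np.concatenate(hists)
    try:
        return unit_interval_normalize(vec)
    except DegenerateVectorError as err:
        raise DegenerateVectorError(
            "clip contains no detected motion (all histograms zero)") from err
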