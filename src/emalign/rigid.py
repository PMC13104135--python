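"""Sequential rigid alignment of a slice stack.

Each adjacent slice pair goes through a feature pipeline — keypoint
detection, edge-mask filtering, bidirectional (mutual nearest-neighbor)
descriptor matching, locality-preserving match filtering — and the
surviving correspondences feed a closed-form least-squares rigid fit
(centered Kabsch/SVD with reflection correction).  Transforms are
propagated sequentially: slice 0 is the fixed reference, slice ``t`` is
estimated against the already-aligned slice ``t-1``, and the *original*
slice ``t`` is resampled exactly once under its cumulative transform so
interpolation blur never compounds.

The keypoint detector is pluggable.  The default is a classical
multi-scale corner detector with non-max suppression and an
orientation-normalized intensity-patch descriptor (mean-subtracted,
unit-norm), which makes matching robust to the rotation range seen in
serial-section jitter without any trained weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import corner_shi_tomasi, peak_local_max
from skimage.filters import apply_hysteresis_threshold
from skimage.registration import phase_cross_correlation
from skimage.morphology import dilation, disk

from .stack import SliceStack, as_stack_array

logger = logging.getLogger("emalign.rigid")

__all__ = [
    "Keypoint",
    "MatchSet",
    "RigidTransform",
    "RigidParams",
    "ClassicalDetector",
    "detect_keypoints",
    "edge_mask",
    "filter_edge_keypoints",
    "match_bidirectional",
    "lpm_filter",
    "estimate_rigid",
    "apply_rigid",
    "align_stack_rigid",
]


@dataclass(frozen=True)
class Keypoint:
    """Detected feature: subpixel (row, col) position, detector response,
    and a fixed-length unit-norm descriptor."""

    position: tuple
    score: float
    descriptor: np.ndarray


@dataclass
class MatchSet:
    """Accepted correspondences between two keypoint lists.

    ``pairs[k] = (i, j)`` links source keypoint ``i`` to target keypoint
    ``j``; ``distances[k]`` is their descriptor distance.  Mutual-NN
    acceptance guarantees each index appears at most once per side.
    """

    pairs: np.ndarray
    distances: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RigidTransform:
    """2D rotation + translation about a pivot, in (row, col) coordinates.

    The transform maps a point ``y`` of the moving image to
    ``x = R (y - center) + center + t`` where ``R`` rotates by
    ``theta_deg`` degrees.
    """

    theta_deg: float
    t: tuple
    center: tuple = (0.0, 0.0)

    @property
    def R(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "RigidTransform":
        return cls(0.0, (0.0, 0.0), tuple(map(float, center)))

    @classmethod
    def from_matrix(cls, A: np.ndarray, b: np.ndarray, center=(0.0, 0.0)) -> "RigidTransform":
        """Build from the origin form ``x = A y + b``, re-expressed about ``center``."""
        A = np.asarray(A, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        theta = math.degrees(math.atan2(A[1, 0], A[0, 0]))
        c = np.asarray(center, dtype=np.float64)
        t = b - c + A @ c
        return cls(theta, (float(t[0]), float(t[1])), (float(c[0]), float(c[1])))

    def as_matrix(self) -> tuple:
        """Origin form ``(A, b)`` with ``x = A y + b``."""
        c = np.asarray(self.center, dtype=np.float64)
        t = np.asarray(self.t, dtype=np.float64)
        A = self.R
        b = c + t - A @ c
        return A, b

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        A, b = self.as_matrix()
        return np.asarray(pts, dtype=np.float64) @ A.T + b

    def inverse(self) -> "RigidTransform":
        A, b = self.as_matrix()
        Ai = A.T
        return RigidTransform.from_matrix(Ai, -Ai @ b, self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        A1, b1 = self.as_matrix()
        A2, b2 = other.as_matrix()
        return RigidTransform.from_matrix(A1 @ A2, A1 @ b2 + b1, self.center)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


@dataclass
class RigidParams:
    """Parameters of the rigid-alignment pipeline (all config-exposed)."""

    max_keypoints: int = 800
    nms_radius: int = 8
    edge_low: float | None = None    # default: 0.1 * max gradient magnitude
    edge_high: float | None = None   # default: 0.2 * max gradient magnitude
    edge_dilate_r: int = 2
    lpm_k: int = 6
    lpm_tau: float = 0.5
    lpm_passes: int = 2
    min_matches: int = 8
    residual_trim_px: float = 3.0    # trim matches beyond this residual, then refit
    refine_iters: int = 1            # re-match against the warped slice and compose
    refine_translation: bool = True  # subpixel phase-correlation polish
    refine_upsample: int = 50
    detector: object | None = None


class ClassicalDetector:
    """Multi-scale corner detector with orientation-normalized patch descriptors.

    Corner response is the Shi–Tomasi minimum eigenvalue taken at two
    Gaussian integration scales; peaks are non-max suppressed with radius
    ``nms_radius`` and refined to subpixel by a parabolic fit.  Each
    keypoint gets a dominant orientation from the locally averaged image
    gradient, and its descriptor is a ``patch_size x patch_size`` intensity
    patch sampled along the rotated axes, mean-subtracted and
    unit-normalized — translation- and rotation-covariant by construction.
    """

    def __init__(self, nms_radius: int = 8, patch_size: int = 16,
                 patch_spacing: float = 2.0, smooth_sigma: float = 1.0,
                 desc_sigma: float = 2.0, orient_radius: int = 12,
                 response_sigmas=(1.5, 3.0), threshold_rel: float = 0.005):
        self.nms_radius = nms_radius
        self.patch_size = patch_size
        self.patch_spacing = patch_spacing
        self.smooth_sigma = smooth_sigma
        self.desc_sigma = desc_sigma
        self.orient_radius = orient_radius
        self.response_sigmas = tuple(response_sigmas)
        self.threshold_rel = threshold_rel

    def __call__(self, image: np.ndarray, max_n: int) -> list:
        image = np.asarray(image, dtype=np.float64)
        img = ndimage.gaussian_filter(image, self.smooth_sigma)

        resp = np.zeros_like(img)
        for s in self.response_sigmas:
            r = corner_shi_tomasi(img, sigma=s)
            m = r.max()
            if m > 0:
                resp = np.maximum(resp, r / m)
        if resp.max() <= 0:
            return []

        # Keep patches (rotated: half-diagonal) inside the image.
        border = int(math.ceil(
            self.patch_size / 2 * math.sqrt(2) * self.patch_spacing)) + 1
        coords = peak_local_max(
            resp, min_distance=self.nms_radius, threshold_rel=self.threshold_rel,
            exclude_border=border, num_peaks=max_n,
        )
        if coords.size == 0:
            return []

        pos = coords.astype(np.float64)
        scores = resp[coords[:, 0], coords[:, 1]]
        pos += _parabolic_offsets(resp, coords)

        kp_idx, theta = _dominant_orientations(img, coords, self.orient_radius)
        pos = pos[kp_idx]
        scores = scores[kp_idx]

        # Descriptors come from a more smoothed copy so they encode
        # medium-scale structure rather than slice-decorrelated grain.
        desc_img = ndimage.gaussian_filter(image, self.desc_sigma)
        desc = _sample_rotated_patches(desc_img, pos, theta, self.patch_size,
                                       self.patch_spacing)
        desc -= desc.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(desc, axis=1)
        ok = norms > 1e-9
        desc[ok] /= norms[ok, None]

        kps = [
            Keypoint((float(p[0]), float(p[1])), float(s), d)
            for p, s, d, good in zip(pos, scores, desc, ok) if good
        ]
        return kps


def _parabolic_offsets(resp: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Subpixel peak refinement: 1D parabola per axis, clipped to +-0.5 px."""
    offsets = np.zeros(coords.shape, dtype=np.float64)
    r, c = coords[:, 0], coords[:, 1]
    inside_r = (r > 0) & (r < resp.shape[0] - 1)
    inside_c = (c > 0) & (c < resp.shape[1] - 1)
    for axis, inside in ((0, inside_r), (1, inside_c)):
        rr, cc = r[inside], c[inside]
        if axis == 0:
            fm, f0, fp = resp[rr - 1, cc], resp[rr, cc], resp[rr + 1, cc]
        else:
            fm, f0, fp = resp[rr, cc - 1], resp[rr, cc], resp[rr, cc + 1]
        denom = fm - 2 * f0 + fp
        off = np.zeros_like(f0)
        nz = np.abs(denom) > 1e-12
        off[nz] = 0.5 * (fm[nz] - fp[nz]) / denom[nz]
        offsets[inside, axis] = np.clip(off, -0.5, 0.5)
    return offsets


def _dominant_orientations(img: np.ndarray, coords: np.ndarray,
                           radius: int, n_bins: int = 36,
                           peak_frac: float = 0.8) -> tuple:
    """Dominant gradient orientations per keypoint.

    Gradient angles in a Gaussian-weighted window are histogrammed with
    magnitude weights, the histogram is smoothed circularly, and every
    local peak within ``peak_frac`` of the maximum spawns its own
    orientation (parabolic subbin refinement).  Emitting all near-equal
    peaks matters on membrane-like structures, where the two gradient
    directions across a dark line are equally strong and a single winner
    would flip arbitrarily between slices.  Returns ``(keypoint_index,
    theta)`` arrays, one entry per (keypoint, orientation) pair.
    """
    gr, gc = np.gradient(img)
    mag = np.hypot(gr, gc)
    ang = np.arctan2(gr, gc)

    offs = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    win = np.exp(-(dr ** 2 + dc ** 2) / (2.0 * (radius / 2.0) ** 2)).ravel()
    dr, dc = dr.ravel(), dc.ravel()

    rows = np.clip(coords[:, 0][:, None] + dr[None, :], 0, img.shape[0] - 1)
    cols = np.clip(coords[:, 1][:, None] + dc[None, :], 0, img.shape[1] - 1)
    w = mag[rows, cols] * win[None, :]
    bins = ((ang[rows, cols] + np.pi) / (2 * np.pi) * n_bins).astype(np.intp) % n_bins

    n = len(coords)
    hist = np.zeros((n, n_bins))
    kp_idx = np.repeat(np.arange(n), bins.shape[1])
    np.add.at(hist, (kp_idx, bins.ravel()), w.ravel())

    # Circular smoothing, then one orientation per near-maximal local peak.
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    sm = np.zeros_like(hist)
    for k, kv in zip(range(-2, 3), kernel):
        sm += kv * np.roll(hist, k, axis=1)
    prev = np.roll(sm, 1, axis=1)
    nxt = np.roll(sm, -1, axis=1)
    is_peak = (sm > prev) & (sm >= nxt) & (sm >= peak_frac * sm.max(axis=1, keepdims=True))
    kp_idx, peak = np.nonzero(is_peak)
    f0 = sm[kp_idx, peak]
    fm = prev[kp_idx, peak]
    fp = nxt[kp_idx, peak]
    denom = fm - 2 * f0 + fp
    off = np.where(np.abs(denom) > 1e-12, 0.5 * (fm - fp) / denom, 0.0)
    off = np.clip(off, -0.5, 0.5)
    theta = (peak + off + 0.5) / n_bins * 2 * np.pi - np.pi
    if len(kp_idx) == 0:   # flat histograms (e.g. noise-free constant region)
        kp_idx = np.arange(n)
        theta = np.zeros(n)
    return kp_idx, theta


def _sample_rotated_patches(img: np.ndarray, pos: np.ndarray, theta: np.ndarray,
                            patch_size: int, spacing: float = 1.0) -> np.ndarray:
    """Bilinear sampling of patches along each keypoint's rotated axes."""
    half = (patch_size - 1) / 2.0
    grid = (np.arange(patch_size, dtype=np.float64) - half) * spacing
    dr, dc = np.meshgrid(grid, grid, indexing="ij")
    base = np.stack([dr.ravel(), dc.ravel()])              # (2, P)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # Rotate the sampling grid into each keypoint's orientation frame.
    # Gradient angles measured as atan2(d/drow, d/dcol) decrease when the
    # content rotates under the (row, col) rotation matrix used throughout,
    # so covariant sampling uses the transposed rotation (-theta).
    rows = (cos_t[:, None] * base[0] + sin_t[:, None] * base[1]) + pos[:, 0:1]
    cols = (-sin_t[:, None] * base[0] + cos_t[:, None] * base[1]) + pos[:, 1:2]
    samples = ndimage.map_coordinates(
        img, np.stack([rows.ravel(), cols.ravel()]), order=1, mode="nearest"
    )
    return samples.reshape(len(pos), patch_size * patch_size)


def detect_keypoints(image: np.ndarray, max_n: int = 800, detector=None) -> list:
    """Detect up to ``max_n`` keypoints, sorted by descending score.

    A constant image yields an empty list (not an error); images smaller
    than 32x32 raise.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 32:
        raise ValueError("image must be 2D grayscale, at least 32x32")
    det = detector if detector is not None else ClassicalDetector()
    kps = det(image, max_n)
    return sorted(kps, key=lambda k: -k.score)[:max_n]


def edge_mask(image: np.ndarray, low: float | None = None,
              high: float | None = None, dilate_r: int = 2) -> np.ndarray:
    """Hysteresis-thresholded gradient-magnitude edges, dilated by ``dilate_r``.

    Defaults: ``low = 0.1 * max``, ``high = 0.2 * max`` of the gradient
    magnitude.
    """
    image = np.asarray(image, dtype=np.float64)
    gr = ndimage.sobel(image, axis=0)
    gc = ndimage.sobel(image, axis=1)
    mag = np.hypot(gr, gc)
    gmax = mag.max()
    if gmax == 0:
        return np.zeros(image.shape, dtype=bool)
    if low is None:
        low = 0.1 * gmax
    if high is None:
        high = 0.2 * gmax
    if not 0 <= low < high:
        raise ValueError("edge thresholds must satisfy 0 <= low < high")
    mask = apply_hysteresis_threshold(mag, low, high)
    if dilate_r > 0:
        mask = dilation(mask, disk(dilate_r))
    return mask


def filter_edge_keypoints(kps: list, mask: np.ndarray) -> list:
    """Keep keypoints whose rounded position lies on a true mask pixel."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    for kp in kps:
        r = int(round(kp.position[0]))
        c = int(round(kp.position[1]))
        r = min(max(r, 0), mask.shape[0] - 1)
        c = min(max(c, 0), mask.shape[1] - 1)
        if mask[r, c]:
            out.append(kp)
    return out


def _descriptor_matrix(kps: list) -> np.ndarray:
    return np.stack([kp.descriptor for kp in kps])


def match_bidirectional(src_kps: list, tgt_kps: list) -> MatchSet:
    """Mutual nearest-neighbor descriptor matching.

    A pair (i, j) is accepted iff j is the Euclidean nearest neighbor of i
    among targets AND i is the nearest neighbor of j among sources.  Exact
    distance ties break to the smallest index.
    """
    if not src_kps or not tgt_kps:
        logger.warning("empty keypoint list: no matches")
        return MatchSet(np.empty((0, 2), dtype=np.intp), np.empty(0))
    A = _descriptor_matrix(src_kps)
    B = _descriptor_matrix(tgt_kps)
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    fwd = np.argmin(d2, axis=1)   # argmin takes the first (smallest index) on ties
    bwd = np.argmin(d2, axis=0)
    src_idx = np.arange(len(src_kps))
    mutual = bwd[fwd] == src_idx
    pairs = np.stack([src_idx[mutual], fwd[mutual]], axis=1)
    dist = np.sqrt(np.maximum(d2[pairs[:, 0], pairs[:, 1]], 0.0))
    return MatchSet(pairs.astype(np.intp), dist)


def lpm_filter(src_kps: list, tgt_kps: list, matches: MatchSet,
               K: int = 6, tau: float = 0.5, passes: int = 2) -> MatchSet:
    """Locality-preserving match filtering.

    For each match, the fraction of its K nearest matched neighbors (by
    source position) whose counterparts also lie within the K-neighborhood
    of its counterpart (by target position) must reach ``tau``; filtering
    is repeated for ``passes`` rounds, recomputing neighborhoods on
    survivors.
    """
    pairs = matches.pairs
    dist = matches.distances
    for _ in range(passes):
        m = len(pairs)
        if m <= K:
            logger.warning("lpm_filter: %d matches <= K=%d, returning unchanged", m, K)
            return MatchSet(pairs, dist)
        ps = np.array([src_kps[i].position for i in pairs[:, 0]])
        pt = np.array([tgt_kps[j].position for j in pairs[:, 1]])
        keep = _lpm_keep(ps, pt, K, tau)
        if keep.all():
            break
        pairs = pairs[keep]
        dist = dist[keep]
    return MatchSet(pairs, dist)


def _lpm_keep(ps: np.ndarray, pt: np.ndarray, K: int, tau: float) -> np.ndarray:
    m = len(ps)

    def knn_indicator(p):
        d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        nn = np.argpartition(d2, K - 1, axis=1)[:, :K]
        ind = np.zeros((m, m), dtype=bool)
        rows = np.repeat(np.arange(m), K)
        ind[rows, nn.ravel()] = True
        return ind

    frac = (knn_indicator(ps) & knn_indicator(pt)).sum(axis=1) / K
    return frac >= tau


def estimate_rigid(X: np.ndarray, Y: np.ndarray, center=(0.0, 0.0)):
    """Closed-form least-squares rigid transform mapping points Y onto X.

    Centered Kabsch/SVD: with centroids u, v and centered sets X̃, Ỹ, the
    cross-covariance S = X̃ᵀỸ is decomposed by SVD and the rotation is
    reflection-corrected via a determinant guard; translation is
    ``t = u - R v``.  Returns ``(RigidTransform, residual_rms)``.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X and Y must be matching (n, 2) point arrays")
    if len(X) < 2:
        raise ValueError("degenerate input: at least 2 point pairs required")
    u = X.mean(axis=0)
    v = Y.mean(axis=0)
    Xc = X - u
    Yc = Y - v
    if np.allclose(Xc, 0) or np.allclose(Yc, 0):
        raise ValueError("degenerate input: zero-variance point set")
    S = Xc.T @ Yc
    U, _, Vt = np.linalg.svd(S)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    b = u - R @ v
    resid = X - (Y @ R.T + b)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform.from_matrix(R, b, center), rms


def apply_rigid(image: np.ndarray, T: RigidTransform) -> np.ndarray:
    """Resample ``image`` under ``T`` (inverse mapping, bilinear, edge clamp)."""
    image = np.asarray(image, dtype=np.float64)
    A, b = T.as_matrix()
    Ai = A.T  # rotation inverse
    offset = -Ai @ b
    return ndimage.affine_transform(image, Ai, offset=offset, order=1, mode="nearest")


def _fit_keypoints(fixed: np.ndarray, moving: np.ndarray, params: RigidParams):
    """One keypoint-pipeline rigid fit of ``moving`` onto ``fixed``.

    Returns ``(transform or None, surviving match count)``.
    """
    kp_f = detect_keypoints(fixed, params.max_keypoints, params.detector)
    kp_m = detect_keypoints(moving, params.max_keypoints, params.detector)
    kp_f = filter_edge_keypoints(
        kp_f, edge_mask(fixed, params.edge_low, params.edge_high, params.edge_dilate_r))
    kp_m = filter_edge_keypoints(
        kp_m, edge_mask(moving, params.edge_low, params.edge_high, params.edge_dilate_r))
    matches = match_bidirectional(kp_f, kp_m)
    matches = lpm_filter(kp_f, kp_m, matches,
                         params.lpm_k, params.lpm_tau, params.lpm_passes)
    if len(matches) < params.min_matches:
        return None, len(matches)
    X = np.array([kp_f[i].position for i in matches.pairs[:, 0]])
    Y = np.array([kp_m[j].position for j in matches.pairs[:, 1]])
    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    T, rms = estimate_rigid(X, Y, center)
    # Residual-trim refinement: drop gross outliers and refit.
    if params.residual_trim_px is not None:
        for _ in range(2):
            if len(X) <= params.min_matches:
                break
            resid = np.linalg.norm(X - T.apply_points(Y), axis=1)
            keep = resid <= max(params.residual_trim_px, 3.0 * np.median(resid))
            if keep.sum() < params.min_matches or keep.all():
                break
            X, Y = X[keep], Y[keep]
            T, rms = estimate_rigid(X, Y, center)
    logger.debug("pair fit: %d matches, residual %.3f px", len(X), rms)
    return T, len(matches)


def _estimate_pair(fixed: np.ndarray, moving: np.ndarray, params: RigidParams):
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    After the initial keypoint fit the residual transform between the
    fixed slice and the already-warped moving slice is re-estimated and
    composed (matching without any rotation offset is far less ambiguous,
    which pins down the rotation), and the residual translation is
    polished by subpixel phase correlation — this suppresses the small
    systematic keypoint-localization bias that would otherwise accumulate
    as drift along long stacks.  Returns None when fewer than
    ``min_matches`` correspondences survive.
    """
    T, n_matches = _fit_keypoints(fixed, moving, params)
    if T is None:
        return None, n_matches
    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    for _ in range(params.refine_iters):
        warped = apply_rigid(moving, T)
        residual, _ = _fit_keypoints(fixed, warped, params)
        if residual is not None:
            T = residual.compose(T)
    if params.refine_translation:
        moved = apply_rigid(moving, T)
        shift, _, _ = phase_cross_correlation(
            fixed, moved, upsample_factor=params.refine_upsample,
            normalization=None)
        T = RigidTransform(0.0, (float(shift[0]), float(shift[1])),
                           center).compose(T)
    return T, n_matches


def align_stack_rigid(stack, params: RigidParams | None = None):
    """Sequentially rigid-align a stack; slice 0 is the fixed reference.

    For each slice t >= 1 the pairwise transform is estimated against the
    already-aligned slice t-1 (so the estimate lands directly in the
    global frame) and the original slice t is resampled exactly once under
    its cumulative transform.  Pairs with too few surviving matches fall
    back to the previous cumulative transform with a warning.

    Returns ``(aligned_stack, transforms)`` where ``transforms`` is the
    list of cumulative :class:`RigidTransform` per slice.
    """
    params = params or RigidParams()
    data = as_stack_array(stack)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 slices to align")
    center = ((data.shape[1] - 1) / 2.0, (data.shape[2] - 1) / 2.0)
    aligned = np.empty_like(data)
    aligned[0] = data[0]
    transforms = [RigidTransform.identity(center)]
    for t in range(1, data.shape[0]):
        T, n_matches = _estimate_pair(aligned[t - 1], data[t], params)
        if T is None:
            logger.warning(
                "slice %d: only %d matches (< %d); falling back to previous transform",
                t, n_matches, params.min_matches)
            T = transforms[t - 1]
        transforms.append(T)
        aligned[t] = apply_rigid(data[t], T)
        logger.info("slice %d: theta=%.3f deg, t=(%.2f, %.2f), matches=%d",
                    t, T.theta_deg, T.t[0], T.t[1], n_matches)
    if isinstance(stack, SliceStack):
        return stack.with_data(aligned), transforms
    return aligned, transforms
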