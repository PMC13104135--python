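"""Registration quality metrics.

Two families:

* A ground-truth-free multi-scale difference-filtering score for real
  stacks.  For each adjacent slice pair the signed difference image is
  Laplacian-filtered to amplify residual misalignment noise; noise is
  quantified by the 256-bin Shannon entropy and by an SNR that splits the
  Laplacian response into structure and noise via bilateral filtering;
  structure preservation is quantified by GLCM contrast computed on each
  layer of a difference-of-Gaussians pyramid.  Well-registered pairs show
  lower entropy, higher SNR and higher multi-scale contrast than
  misaligned ones.

* Conventional full-reference metrics against a ground-truth stack or
  labels: SSIM, NCC, mutual information, Dice and symmetric Hausdorff
  distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from skimage.metrics import structural_similarity
from skimage.restoration import denoise_bilateral

from .stack import as_stack_array

__all__ = [
    "EvalParams",
    "EvaluationReport",
    "difference_image",
    "laplacian_filter",
    "entropy",
    "saturating_quantize",
    "snr",
    "dog_pyramid",
    "glcm_contrast",
    "evaluate_stack",
    "reference_metrics",
    "ssim",
    "ncc",
    "mutual_information",
    "dice",
    "hausdorff",
]

#: Half-octave DoG pyramid scales (sigma_i = 2^{i/2}).
DEFAULT_DOG_SIGMAS = tuple(2.0 ** (i / 2.0) for i in range(5))

#: Distance-1 co-occurrence offsets at 0, 45, 90 and 135 degrees.
DEFAULT_GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class EvalParams:
    dog_sigmas: tuple = DEFAULT_DOG_SIGMAS
    glcm_levels: int = 256
    glcm_offsets: tuple = DEFAULT_GLCM_OFFSETS
    entropy_levels: int = 256
    #: Saturation half-range used to quantize the Laplacian difference to
    #: 256 levels before the entropy histogram.  A fixed scale (rather than
    #: per-image min-max) keeps entropies comparable across pairs: well
    #: registered pairs concentrate near zero (low entropy) while
    #: misaligned pairs spread over the range.
    entropy_clip: float = 1.0
    bilateral_win: int = 7
    bilateral_sigma_spatial: float = 2.0
    bilateral_sigma_range: float = 0.1


@dataclass
class EvaluationReport:
    """Per-pair and stack-aggregated quality numbers.

    ``per_pair`` has one row per adjacent pair with columns
    ``entropy, snr, con_0..con_3``; ``summary`` aggregates means (SNR mean
    over finite values) and ``entropy_hist`` is a (counts, bin_edges)
    histogram of the per-pair entropies.
    """

    per_pair: pd.DataFrame
    summary: dict
    entropy_hist: tuple = dataclass_field(default=None)

    def to_csv(self, path) -> None:
        self.per_pair.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "summary": {k: float(v) for k, v in self.summary.items()},
            "per_pair": self.per_pair.to_dict(orient="list"),
            "entropy_hist": {
                "counts": [int(c) for c in self.entropy_hist[0]],
                "bin_edges": [float(e) for e in self.entropy_hist[1]],
            },
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def difference_image(I_i: np.ndarray, I_next: np.ndarray) -> np.ndarray:
    """Signed difference D = I_next - I_i."""
    a = np.asarray(I_i, dtype=np.float64)
    b = np.asarray(I_next, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("slices must share one shape")
    return b - a


def laplacian_filter(D: np.ndarray) -> np.ndarray:
    """Discrete 4-neighbor Laplacian, edge-clamped borders."""
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2:
        raise ValueError("input must be 2D")
    kernel = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    return ndimage.convolve(D, kernel, mode="nearest")


def _quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max rescale of a (signed) image to 0..levels-1 integers.

    Constant images map to level 0 (entropy 0, contrast 0 by convention).
    """
    image = np.asarray(image, dtype=np.float64)
    mn, mx = image.min(), image.max()
    if mx == mn:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.round((image - mn) / (mx - mn) * (levels - 1))
    return q.astype(np.intp)


def entropy(image: np.ndarray, levels: int = 256) -> float:
    """Shannon entropy (bits) of the image's ``levels``-bin histogram.

    Integer-valued images already in ``0..levels-1`` are binned directly;
    float images are min-max quantized first.  Empty bins contribute zero.
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() >= levels:
            raise ValueError(f"integer image values outside 0..{levels - 1}")
        q = image.astype(np.intp)
    else:
        q = _quantize(image, levels)
    counts = np.bincount(q.ravel(), minlength=levels)
    p = counts[counts > 0] / q.size
    return float(-(p * np.log2(p)).sum())


def saturating_quantize(image: np.ndarray, clip: float, levels: int = 256) -> np.ndarray:
    """Quantize a signed image to ``0..levels-1`` on the fixed scale
    ``[-clip, clip]`` (values beyond the range saturate).

    Unlike per-image min-max scaling, this keeps the quantization scale
    common across images, which is what makes histogram statistics
    (entropy in particular) comparable between slice pairs.
    """
    if clip <= 0:
        raise ValueError("clip must be > 0")
    image = np.asarray(image, dtype=np.float64)
    q = np.round((image + clip) / (2 * clip) * (levels - 1))
    return np.clip(q, 0, levels - 1).astype(np.intp)


def snr(lap: np.ndarray, params: EvalParams | None = None) -> float:
    """Structure-to-noise variance ratio of a Laplacian-filtered difference.

    Bilateral filtering splits the input into a structural component I_f
    and residual noise I_n = input - I_f (conservation is exact by
    construction); the score is Var(I_f) / Var(I_n), +inf when the noise
    variance vanishes.
    """
    params = params or EvalParams()
    lap = np.asarray(lap, dtype=np.float64)
    if not np.all(np.isfinite(lap)):
        raise ValueError("input must be finite")
    i_f = bilateral_split(lap, params)
    i_n = lap - i_f
    var_n = i_n.var()
    if var_n == 0:
        return float("inf")
    return float(i_f.var() / var_n)


def bilateral_split(lap: np.ndarray, params: EvalParams | None = None) -> np.ndarray:
    """Structural component of ``lap`` via bilateral filtering.

    The filter operates on a [0, 1] min-max rescale of the input (the
    range sigma is expressed on that scale) and the result is mapped back,
    so ``lap - bilateral_split(lap)`` is the exact noise residual.
    """
    params = params or EvalParams()
    lap = np.asarray(lap, dtype=np.float64)
    mn, mx = lap.min(), lap.max()
    if mx == mn:
        return lap.copy()
    scaled = (lap - mn) / (mx - mn)
    filt = denoise_bilateral(
        scaled,
        win_size=params.bilateral_win,
        sigma_color=params.bilateral_sigma_range,
        sigma_spatial=params.bilateral_sigma_spatial,
    )
    return filt * (mx - mn) + mn


def dog_pyramid(lap: np.ndarray, sigmas=DEFAULT_DOG_SIGMAS) -> list:
    """Difference-of-Gaussians layers DoG_i = lap*G_i - lap*G_{i+1}.

    ``sigmas`` must be strictly increasing; len(sigmas)-1 full-resolution
    layers are returned (4 with the default half-octave scales).
    """
    lap = np.asarray(lap, dtype=np.float64)
    sigmas = tuple(float(s) for s in sigmas)
    if len(sigmas) < 2 or any(b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("sigmas must be strictly increasing, length >= 2")
    blurred = [ndimage.gaussian_filter(lap, s) for s in sigmas]
    return [blurred[i] - blurred[i + 1] for i in range(len(sigmas) - 1)]


def glcm_contrast(image: np.ndarray, levels: int = 256,
                  offsets=DEFAULT_GLCM_OFFSETS) -> float:
    """Mean GLCM contrast sum_{k,j} (k-j)^2 P(k,j) over the given offsets.

    The input is min-max quantized to ``levels`` gray levels; each offset's
    co-occurrence matrix is symmetric and normalized.  Counting is done
    with explicit (drow, dcol) offsets so the direction convention is
    unambiguous; pass a single offset for single-direction contrast.
    """
    q = _quantize(image, levels)
    cons = []
    k = np.arange(levels, dtype=np.float64)
    sq = (k[:, None] - k[None, :]) ** 2
    for dr, dc in offsets:
        a, b = _offset_pairs(q, dr, dc)
        if a.size == 0:
            raise ValueError(f"offset {(dr, dc)} leaves no pixel pairs")
        idx = a * levels + b
        counts = np.bincount(idx, minlength=levels * levels).astype(np.float64)
        glcm = counts.reshape(levels, levels)
        glcm = glcm + glcm.T          # symmetric
        glcm /= glcm.sum()            # normalized
        cons.append(float((sq * glcm).sum()))
    return float(np.mean(cons))


def _offset_pairs(q: np.ndarray, dr: int, dc: int) -> tuple:
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a.ravel(), b.ravel()


def evaluate_stack(stack, params: EvalParams | None = None) -> EvaluationReport:
    """Ground-truth-free quality report over all adjacent slice pairs.

    For each pair: difference image -> Laplacian -> entropy, SNR and the
    GLCM contrast of every DoG layer.
    """
    params = params or EvalParams()
    data = as_stack_array(stack)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 slices to evaluate")
    n_layers = len(params.dog_sigmas) - 1
    rows = []
    for i in range(data.shape[0] - 1):
        lap = laplacian_filter(difference_image(data[i], data[i + 1]))
        lap8 = saturating_quantize(lap, params.entropy_clip, params.entropy_levels)
        row = {
            "pair": i,
            "entropy": entropy(lap8, params.entropy_levels),
            "snr": snr(lap, params),
        }
        for k, layer in enumerate(dog_pyramid(lap, params.dog_sigmas)):
            row[f"con_{k}"] = glcm_contrast(layer, params.glcm_levels,
                                            params.glcm_offsets)
        rows.append(row)
    per_pair = pd.DataFrame(rows)
    finite_snr = per_pair["snr"][np.isfinite(per_pair["snr"])]
    summary = {
        "mean_entropy": float(per_pair["entropy"].mean()),
        "mean_snr": float(finite_snr.mean()) if len(finite_snr) else float("inf"),
    }
    for k in range(n_layers):
        summary[f"mean_con_{k}"] = float(per_pair[f"con_{k}"].mean())
    hist = np.histogram(per_pair["entropy"].to_numpy(), bins=16)
    return EvaluationReport(per_pair=per_pair, summary=summary, entropy_hist=hist)


# ---------------------------------------------------------------------------
# Full-reference metrics (require ground truth)

def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """SSIM with a 7x7 uniform window, K1=0.01, K2=0.03, data range 1."""
    return float(structural_similarity(
        np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64),
        win_size=7, K1=0.01, K2=0.03, data_range=1.0))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean, unit-variance normalized cross-correlation."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    """Mutual information (nats) over a ``bins``-square joint histogram."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (pa @ pb)[nz])).sum())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1 if both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    na, nb = a.sum(), b.sum()
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / (na + nb))


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance (px) between two binary masks.

    NaN sentinel when either mask is empty.
    """
    pa = np.argwhere(np.asarray(a).astype(bool))
    pb = np.argwhere(np.asarray(b).astype(bool))
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))


def reference_metrics(result_stack=None, gt_stack=None,
                      result_labels=None, gt_labels=None) -> pd.DataFrame:
    """Per-slice full-reference metrics against ground truth.

    Image stacks yield SSIM / NCC / MI columns; label stacks (binary or
    integer maps, compared as foreground masks) yield Dice / Hausdorff.
    """
    rows: dict = {}
    if result_stack is not None:
        res = as_stack_array(result_stack)
        gt = as_stack_array(gt_stack)
        if res.shape != gt.shape:
            raise ValueError("result and ground-truth stacks must share one shape")
        rows["ssim"] = [ssim(r, g) for r, g in zip(res, gt)]
        rows["ncc"] = [ncc(r, g) for r, g in zip(res, gt)]
        rows["mi"] = [mutual_information(r, g) for r, g in zip(res, gt)]
    if result_labels is not None:
        rl = np.asarray(result_labels)
        gl = np.asarray(gt_labels)
        if rl.shape != gl.shape:
            raise ValueError("label stacks must share one shape")
        rows["dice"] = [dice(r, g) for r, g in zip(rl, gl)]
        rows["hausdorff"] = [hausdorff(r, g) for r, g in zip(rl, gl)]
    if not rows:
        raise ValueError("give an image stack pair and/or a label stack pair")
    return pd.DataFrame(rows)
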