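"""Engineered features per segmented sub-image.

Five families are computed for each of the four quadrant sub-images and
concatenated in a fixed, named order (21 values per quadrant, 84 total):

* gradient block (7) — statistics of the Sobel gradient-magnitude histogram:
  spacing between its two highest modes, the probability mass within +-2 bins
  of each mode, the bimodality coefficient (g1^2 + 1) / b2 (g1 skewness, b2
  excess-free kurtosis), the raw skewness and kurtosis, and the mode-height
  ratio normalised by the mode spacing;
* spectral flatness (1) — geometric over arithmetic mean of the non-DC
  Fourier magnitudes of the zero-mean masked crop: 1 for a flat (noise-like)
  spectrum, toward 0 for tonal/smooth content;
* profile block (4) — statistics of vertical intensity profiles through the
  gradient image: rib-cross score (fraction of profiles with a peak above
  mean + 2 std), max/min peak ratio, the first-difference min/max slope
  ratio, and mean |second difference| (slope smoothness);
* on-rib block (7) — distance from the candidate nodule centroid to the
  nearest near-horizontal long edge chain ("rib"), the median inter-rib
  spacing, the on-rib flag (centroid closer to a rib than ribs are to each
  other), the nearest rib chain's length/slope/eccentricity, and the
  equivalent radius of the candidate nodule blob;
* on-vessel block (2) — product of the two longest thin-chain lengths over
  the sub-image area, and the inverse distance from the nearest chain to the
  sub-image center.

Every degenerate case (no edges, no modes, empty masks) maps to a finite
documented default — the feature vector never contains NaN or infinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from scipy.stats import kurtosis as sp_kurtosis
from scipy.stats import skew as sp_skew
from skimage.feature import canny
from skimage.filters import sobel
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage import morphology

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSegment",
    "FeatureConfig",
    "FeatureVector",
    "gradient_features",
    "spectral_flatness",
    "profile_stats",
    "profile_features",
    "detect_edges",
    "on_rib_features",
    "on_vessel_features",
    "nodule_candidate",
    "extract_features",
    "feature_names",
]

GRADIENT_KEYS = (
    "mode_spacing",
    "area_mode1",
    "area_mode2",
    "bimodality",
    "skewness",
    "kurtosis",
    "mode_ratio_norm",
)
PROFILE_KEYS = ("rib_cross_score", "peak_ratio", "slope_ratio", "slope_smoothness")
ORIB_KEYS = (
    "min_centroid_segment_dist",
    "inter_rib_dist",
    "on_rib_flag",
    "seg_length",
    "seg_slope",
    "seg_eccentricity",
    "nodule_blob_radius",
)
VESSEL_KEYS = ("vessel1", "vessel2")
BLOCK_KEYS = GRADIENT_KEYS + ("spectral_flatness",) + PROFILE_KEYS + ORIB_KEYS + VESSEL_KEYS
QUADRANT_TAGS = ("q0", "q1", "q2", "q3")  # TL, TR, BL, BR


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature extractors (defaults documented in methods)."""

    n_bins: int = 64  # gradient histogram bins
    n_profiles: int = 16
    profile_smooth_sigma: float = 1.0
    canny_sigma: float = 1.0
    l_rib: float = 15.0  # min chain length (px) for a rib candidate
    s_max: float = 0.5  # max |slope| for a rib candidate
    distance_cap: float = 1e4  # finite stand-in for "no chain anywhere"
    d_floor: float = 0.5  # px; caps the inverse center distance
    nodule_pct: float = 92.0  # brightness percentile for the nodule blob
    max_blob_ecc: float = 0.95  # compactness gate for lesion candidates


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order named feature values for one image (length 84)."""

    values: np.ndarray
    names: tuple[str, ...] = field(default_factory=lambda: tuple(feature_names()))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} values, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector must be finite")
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def feature_names() -> list[str]:
    """Canonical 84-name feature order: per quadrant, all block keys."""
    return [f"{q}_{k}" for q in QUADRANT_TAGS for k in BLOCK_KEYS]


# ------------------------------------------------------------- gradient


def _histogram_modes(counts: np.ndarray) -> list[int]:
    """Indices of local maxima of a histogram, tallest first."""
    idx = []
    for i, c in enumerate(counts):
        if c <= 0:
            continue
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[i + 1] if i < len(counts) - 1 else -np.inf
        if c >= left and c >= right and (c > left or c > right or len(counts) == 1):
            idx.append(i)
    # plateau handling: collapse runs of equal neighbouring maxima
    idx = [i for j, i in enumerate(idx) if j == 0 or i - idx[j - 1] > 1 or counts[i] != counts[idx[j - 1]]]
    return sorted(idx, key=lambda i: (-counts[i], i))


def gradient_features(sub_image: np.ndarray, mask: np.ndarray,
                      config: FeatureConfig | None = None) -> dict[str, float]:
    """Gradient-magnitude histogram statistics over the masked pixels.

    A constant sub-image (gradient identically 0) maps to the degenerate
    contract: skewness and kurtosis 0, bimodality 0, mode spacing clamped to
    one bin, both mode areas the full mass.
    """
    config = config or FeatureConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    grad = sobel(np.asarray(sub_image, dtype=float))
    sample = grad[mask]

    if np.ptp(sample) == 0:
        return {
            "mode_spacing": 1.0,
            "area_mode1": 1.0,
            "area_mode2": 1.0,
            "bimodality": 0.0,
            "skewness": 0.0,
            "kurtosis": 0.0,
            "mode_ratio_norm": 1.0,
        }

    counts, _ = np.histogram(sample, bins=config.n_bins)
    modes = _histogram_modes(counts)
    m1 = modes[0]
    if len(modes) >= 2:
        m2 = modes[1]
        spacing = float(abs(m1 - m2))
    else:
        logger.debug("single-mode gradient histogram; clamping spacing to 1 bin")
        m2 = m1
        spacing = 1.0
    spacing = max(spacing, 1.0)

    total = counts.sum()

    def mode_area(m: int) -> float:
        lo, hi = max(m - 2, 0), min(m + 3, len(counts))
        return float(counts[lo:hi].sum() / total)

    g1 = float(sp_skew(sample))
    b2 = float(sp_kurtosis(sample, fisher=False))
    bimodality = (g1 * g1 + 1.0) / b2 if b2 > 0 else 0.0
    h1, h2 = counts[m1], max(counts[m2], 1)
    return {
        "mode_spacing": spacing,
        "area_mode1": mode_area(m1),
        "area_mode2": mode_area(m2),
        "bimodality": bimodality,
        "skewness": g1,
        "kurtosis": b2,
        "mode_ratio_norm": float(h1 / h2) / spacing,
    }


# ------------------------------------------------------- spectral flatness


def spectral_flatness(sub_image: np.ndarray, mask: np.ndarray) -> float:
    """Geometric over arithmetic mean of non-DC Fourier magnitudes.

    Computed on the zero-mean masked crop (mask bounding box, pixels outside
    the mask zeroed). Returns 0 for an (almost) all-zero spectrum; always in
    [0, 1] by the AM-GM inequality.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    rows, cols = np.nonzero(mask)
    crop = np.where(mask, np.asarray(sub_image, dtype=float), 0.0)[
        rows.min(): rows.max() + 1, cols.min(): cols.max() + 1
    ]
    crop = crop - crop.mean()
    mags = np.abs(np.fft.fft2(crop)).ravel()
    mags = np.delete(mags, 0)  # drop the DC coefficient
    if mags.size == 0 or mags.max() < 1e-12:
        return 0.0
    am = mags.mean()
    if np.any(mags < 1e-300):
        return 0.0  # a zero coefficient collapses the geometric mean
    gm = float(np.exp(np.mean(np.log(mags))))
    return min(gm / am, 1.0)


# ------------------------------------------------------------- profiles


def profile_stats(profile: np.ndarray, smooth_sigma: float = 0.0) -> dict[str, float]:
    """Statistics of a single 1-D profile (optionally Gaussian-smoothed).

    * ``rib_cross``: 1 if any peak of the (smoothed) profile exceeds its
      mean + 2 std, else 0
    * ``peak_ratio``: max peak value / min peak value (0 if no interior peak;
      a zero-valued minimum peak is floored at 1e-6)
    * ``slope_ratio``: min(diff) / max(diff) of the raw profile (0 if the
      maximum first difference is 0)
    * ``slope_smoothness``: mean absolute second difference
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile needs at least 3 samples")
    smooth = (
        ndi.gaussian_filter1d(profile, smooth_sigma) if smooth_sigma > 0 else profile
    )
    peaks, _ = find_peaks(smooth)
    if peaks.size:
        pv = smooth[peaks]
        peak_ratio = float(pv.max() / max(pv.min(), 1e-6))
        rib_cross = float(pv.max() > smooth.mean() + 2.0 * smooth.std())
    else:
        peak_ratio = 0.0
        rib_cross = 0.0
    d1 = np.diff(profile)
    slope_ratio = float(d1.min() / d1.max()) if d1.max() != 0 else 0.0
    d2 = np.diff(profile, n=2)
    return {
        "rib_cross": rib_cross,
        "peak_ratio": peak_ratio,
        "slope_ratio": slope_ratio,
        "slope_smoothness": float(np.abs(d2).mean()),
    }


def profile_features(edge_image: np.ndarray, mask: np.ndarray,
                     n_profiles: int = 16, smooth_sigma: float = 1.0) -> dict[str, float]:
    """Average profile statistics over equally spaced vertical columns.

    ``edge_image`` should be the gradient magnitude of the enhanced
    sub-image; ribs are roughly horizontal, so vertical profiles cross them.
    Columns whose masked run has fewer than 3 samples are skipped; if every
    column is skipped a ValueError is raised.
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    edge_image = np.asarray(edge_image, dtype=float)
    cols = np.nonzero(mask.any(axis=0))[0]
    picks = np.unique(np.linspace(cols.min(), cols.max(), n_profiles).round().astype(int))
    stats: list[dict[str, float]] = []
    for c in picks:
        rows = np.nonzero(mask[:, c])[0]
        if rows.size < 3:
            continue
        profile = edge_image[rows.min(): rows.max() + 1, c]
        if profile.size < 3:
            continue
        stats.append(profile_stats(profile, smooth_sigma))
    if not stats:
        raise ValueError("all profiles were skipped (mask too thin)")
    return {
        "rib_cross_score": float(np.mean([s["rib_cross"] for s in stats])),
        "peak_ratio": float(np.mean([s["peak_ratio"] for s in stats])),
        "slope_ratio": float(np.mean([s["slope_ratio"] for s in stats])),
        "slope_smoothness": float(np.mean([s["slope_smoothness"] for s in stats])),
    }


# ------------------------------------------------------------- edge chains


@dataclass(frozen=True)
class EdgeSegment:
    """A connected chain of edge pixels with its shape descriptors."""

    length: float  # pixel count of the chain
    slope: float  # least-squares d(row)/d(col); +-1e6 for vertical chains
    eccentricity: float  # of the chain's second-moment ellipse
    centroid: tuple[float, float]  # (row, col)
    coords: np.ndarray  # (n, 2) pixel coordinates


def detect_edges(sub_image: np.ndarray, kind: str = "rib",
                 config: FeatureConfig | None = None) -> list[EdgeSegment]:
    """Canny edge chains classified as rib or vessel candidates.

    Rib candidates are long (length >= ``l_rib``) near-horizontal
    (|slope| <= ``s_max``) chains; every other chain is a vessel candidate.
    Returns an empty list when no edges are found.
    """
    if kind not in ("rib", "vessel"):
        raise ValueError("kind must be 'rib' or 'vessel'")
    config = config or FeatureConfig()
    edges = canny(np.asarray(sub_image, dtype=float), sigma=config.canny_sigma)
    labels = sk_label(edges, connectivity=2)
    segments = []
    for p in regionprops(labels):
        coords = p.coords
        rows, cols = coords[:, 0].astype(float), coords[:, 1].astype(float)
        if np.ptp(cols) == 0:
            slope = 1e6
        else:
            slope = float(np.polyfit(cols, rows, 1)[0])
        seg = EdgeSegment(
            length=float(len(coords)),
            slope=slope,
            eccentricity=float(p.eccentricity),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            coords=coords,
        )
        is_rib = seg.length >= config.l_rib and abs(seg.slope) <= config.s_max
        if (kind == "rib") == is_rib:
            segments.append(seg)
    return segments


def on_rib_features(nodule_centroid: tuple[float, float],
                    rib_chains: list[EdgeSegment],
                    distance_cap: float = 1e4) -> dict[str, float]:
    """Geometric evidence that the candidate lesion sits on a rib.

    ``d_min`` is the distance from the centroid to the nearest rib chain;
    ``inter_rib`` the median distance between consecutive rib-chain
    centroids (sorted by row). The lesion is flagged on-rib when it is
    closer to a rib than ribs are to each other. Missing chains map to the
    finite ``distance_cap`` / zeros.
    """
    if not rib_chains:
        return {
            "min_centroid_segment_dist": distance_cap,
            "inter_rib_dist": distance_cap,
            "on_rib_flag": 0.0,
            "seg_length": 0.0,
            "seg_slope": 0.0,
            "seg_eccentricity": 0.0,
        }
    cen = np.asarray(nodule_centroid, dtype=float)
    dists = [
        float(np.sqrt(((chain.coords - cen) ** 2).sum(axis=1)).min())
        for chain in rib_chains
    ]
    nearest = int(np.argmin(dists))
    d_min = dists[nearest]
    if len(rib_chains) >= 2:
        cents = np.array(sorted((c.centroid for c in rib_chains), key=lambda t: t[0]))
        gaps = np.sqrt((np.diff(cents, axis=0) ** 2).sum(axis=1))
        inter_rib = float(np.median(gaps))
    else:
        inter_rib = distance_cap
    chain = rib_chains[nearest]
    return {
        "min_centroid_segment_dist": d_min,
        "inter_rib_dist": inter_rib,
        "on_rib_flag": float(d_min < inter_rib),
        "seg_length": chain.length,
        "seg_slope": float(np.clip(chain.slope, -1e6, 1e6)),
        "seg_eccentricity": chain.eccentricity,
    }


def on_vessel_features(sub_image_shape: tuple[int, int],
                       vessel_chains: list[EdgeSegment],
                       d_floor: float = 0.5) -> dict[str, float]:
    """Vessel-evidence pair for a sub-image.

    ``vessel1`` is the product of the two longest chain lengths over the
    sub-image area (0 with fewer than two chains); ``vessel2`` the inverse
    of the smallest chain-to-center distance, capped at ``1/d_floor``.
    """
    h, w = sub_image_shape
    if not vessel_chains:
        return {"vessel1": 0.0, "vessel2": 0.0}
    lengths = sorted((c.length for c in vessel_chains), reverse=True)
    vessel1 = lengths[0] * lengths[1] / (h * w) if len(lengths) >= 2 else 0.0
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    mindist = min(
        float(np.sqrt(((chain.coords - center) ** 2).sum(axis=1)).min())
        for chain in vessel_chains
    )
    return {"vessel1": float(vessel1), "vessel2": 1.0 / max(mindist, d_floor)}


# --------------------------------------------------------------- assembly


def nodule_candidate(sub_image: np.ndarray, mask: np.ndarray,
                     pct: float = 99.0, max_ecc: float = 0.95,
                     open_radius: int = 2) -> tuple[tuple[float, float], float]:
    """Centroid and equivalent radius of the candidate lesion blob.

    Candidate pixels are those at or above the ``pct`` brightness percentile
    within the mask. A morphological opening (disk of ``open_radius``)
    detaches compact blobs from thin bright bands; lesions are compact, so
    among the surviving components those with second-moment eccentricity
    <= ``max_ecc`` are preferred and the brightest-peak one wins. The
    reported equivalent radius sqrt(area/pi) is compensated by the opening
    radius. Falls back to the unopened brightest component, then to the mask
    centroid with radius 0.
    """
    mask = np.asarray(mask, dtype=bool)
    sub_image = np.asarray(sub_image, dtype=float)
    vals = sub_image[mask]
    if vals.size == 0:
        return (0.0, 0.0), 0.0
    thr = np.percentile(vals, pct)
    bright = (sub_image >= thr) & mask
    opened = morphology.opening(bright, morphology.disk(open_radius))
    compensation = float(open_radius)
    labels = sk_label(opened, connectivity=2)
    props = regionprops(labels)
    if not props:  # nothing compact: fall back to the raw bright components
        labels = sk_label(bright, connectivity=2)
        props = regionprops(labels)
        compensation = 0.0
    if not props:
        rows, cols = np.nonzero(mask)
        return (float(rows.mean()), float(cols.mean())), 0.0
    compact = [p for p in props if p.eccentricity <= max_ecc]
    pool = compact or props

    def peak(p) -> float:
        return float(sub_image[tuple(p.coords.T)].max())

    best = max(pool, key=peak)
    radius = float(np.sqrt(best.area / np.pi)) + compensation
    return (float(best.centroid[0]), float(best.centroid[1])), radius


def _degenerate_block(config: FeatureConfig) -> dict[str, float]:
    """Finite defaults for an empty sub-image (no mask pixels)."""
    block = {k: 0.0 for k in BLOCK_KEYS}
    block["mode_spacing"] = 1.0
    block["area_mode1"] = block["area_mode2"] = 1.0
    block["mode_ratio_norm"] = 1.0
    block["min_centroid_segment_dist"] = config.distance_cap
    block["inter_rib_dist"] = config.distance_cap
    return block


def _quadrant_block(enhanced: np.ndarray, mask: np.ndarray,
                    config: FeatureConfig,
                    region: np.ndarray | None = None) -> dict[str, float]:
    if not mask.any():
        return _degenerate_block(config)
    rows, cols = np.nonzero(mask)
    rs = slice(rows.min(), rows.max() + 1)
    cs = slice(cols.min(), cols.max() + 1)
    sub = enhanced[rs, cs]
    sub_mask = mask[rs, cs]
    blob_sub = region[rs, cs] if region is not None else sub

    block: dict[str, float] = {}
    block.update(gradient_features(sub, sub_mask, config))
    block["spectral_flatness"] = spectral_flatness(sub, sub_mask)
    edge_image = sobel(sub)
    try:
        block.update(
            profile_features(edge_image, sub_mask, config.n_profiles,
                             config.profile_smooth_sigma)
        )
    except ValueError:  # mask too thin for any profile
        block.update({k: 0.0 for k in PROFILE_KEYS})
    rib_chains = detect_edges(sub, "rib", config)
    vessel_chains = detect_edges(sub, "vessel", config)
    # search the whole lung area of the bbox (positive support), not just the
    # grown part: the homogeneity criterion stops at lesion boundaries, so a
    # part mask can exclude exactly the blob being looked for
    blob_mask = blob_sub > 0
    if not blob_mask.any():
        blob_mask = sub_mask
    centroid, radius = nodule_candidate(blob_sub, blob_mask, config.nodule_pct,
                                        config.max_blob_ecc)
    block.update(on_rib_features(centroid, rib_chains, config.distance_cap))
    block["nodule_blob_radius"] = radius
    block.update(on_vessel_features(sub.shape, vessel_chains, config.d_floor))
    return block


def extract_features(seg, enhanced: np.ndarray,
                     config: FeatureConfig | None = None,
                     region: np.ndarray | None = None) -> FeatureVector:
    """Assemble the 84-element named feature vector for one image.

    ``seg`` is a :class:`lungscreen.segment.SegmentationResult`; its four
    quadrant masks select the sub-images of the enhanced frame. When the
    pre-enhancement lung region is supplied via ``region``, the candidate
    lesion blob is detected on it (it carries no unsharp overshoot); all
    other features consume the enhanced frame. Values are concatenated
    quadrant by quadrant (TL, TR, BL, BR) in the :func:`feature_names` order
    and are always finite.
    """
    config = config or FeatureConfig()
    enhanced = np.asarray(enhanced, dtype=float)
    if region is not None:
        region = np.asarray(region, dtype=float)
    values: list[float] = []
    for mask in seg.masks:
        block = _quadrant_block(enhanced, np.asarray(mask, dtype=bool), config, region)
        values.extend(block[k] for k in BLOCK_KEYS)
    return FeatureVector(np.array(values))
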