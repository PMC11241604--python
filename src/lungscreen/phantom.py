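"""Synthetic chest-phantom generator with full ground truth.

Renders 2-D grayscale chest-like images: two elliptical lung fields set into a
brighter thorax, curved bright rib bands, thin bright vessel spokes radiating
from each hilum, and optional bright nodule blobs placed on a rib, on a vessel,
or free in the parenchyma. Every structure is returned as a boolean truth mask
together with normal/abnormal and low/high-risk labels, so each downstream
stage of the screening pipeline can be tested without any external data.

Geometry choices that matter downstream (documented in docs/methods.md):

* Rib bands cross only the lateral portion of each lung field and vessel
  spokes stop short of both the pleural boundary and the rib bands. The lung
  parenchyma therefore stays 8-connected, which is what makes a single
  region-growing flood able to cover a lung field.
* The intensity palette is fixed and ordered
  background < lung < thorax < vessels < ribs < nodules, so brightness-based
  feature operators (nodule blob = brightest structure) are well posed.

Noise and augmentation operators mirror the usual CT corruption models
(additive Gaussian, scaled Poisson counts) and the standard augmentation set
(rotate / scale / flip / translate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology

__all__ = [
    "Palette",
    "NoiseModel",
    "Nodule",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "add_noise",
    "augment",
    "random_spec",
]

PLACEMENTS = ("on_rib", "on_vessel", "free")


@dataclass(frozen=True)
class Palette:
    """Nominal intensities of each rendered structure, all in [0, 1]."""

    background: float = 0.05
    lung: float = 0.25
    thorax: float = 0.45
    vessel: float = 0.65
    rib: float = 0.75
    nodule: float = 0.90


@dataclass(frozen=True)
class NoiseModel:
    """Image corruption model: ``gaussian(sigma)``, ``poisson(scale)`` or none."""

    kind: str = "none"
    sigma: float = 0.0  # gaussian std, intensity units
    scale: float = 0.0  # poisson photon count at intensity 1.0

    @staticmethod
    def gaussian(sigma: float) -> "NoiseModel":
        if sigma < 0:
            raise ValueError(f"gaussian sigma must be >= 0, got {sigma}")
        return NoiseModel("gaussian", sigma=float(sigma))

    @staticmethod
    def poisson(scale: float) -> "NoiseModel":
        if scale <= 0:
            raise ValueError(f"poisson scale must be > 0, got {scale}")
        return NoiseModel("poisson", scale=float(scale))

    @staticmethod
    def none() -> "NoiseModel":
        return NoiseModel("none")


@dataclass(frozen=True)
class Nodule:
    """A circular lesion: center (row, col), radius in px, placement tag."""

    row: float
    col: float
    radius: float
    placement: str = "free"

    def __post_init__(self) -> None:
        if self.radius < 2:
            raise ValueError(f"nodule radius must be >= 2 px, got {self.radius}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; rendering is deterministic in ``seed``."""

    height: int = 160
    width: int = 160
    n_ribs: int = 4
    n_vessels: int = 6
    nodules: tuple[Nodule, ...] = ()
    noise: NoiseModel = field(default_factory=lambda: NoiseModel.gaussian(0.03))
    seed: int = 0
    palette: Palette = field(default_factory=Palette)
    # risk rule: high iff any on_rib placement or radius >= this threshold
    high_risk_radius: float = 8.0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom must be at least 64x64")
        object.__setattr__(self, "nodules", tuple(self.nodules))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks and labels for one rendered phantom."""

    lung_mask: np.ndarray
    rib_mask: np.ndarray
    vessel_mask: np.ndarray
    nodule_masks: tuple[np.ndarray, ...]
    class_label: str  # "Normal" | "Abnormal"
    risk_label: str  # "low" | "high" | "none"


# ---------------------------------------------------------------- geometry


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _lung_geometry(h: int, w: int):
    """Thorax ellipse and the two lung-field ellipses (cy, cx, ry, rx)."""
    thorax = (0.50 * h, 0.50 * w, 0.46 * h, 0.45 * w)
    left = (0.50 * h, 0.28 * w, 0.36 * h, 0.16 * w)
    right = (0.50 * h, 0.72 * w, 0.36 * h, 0.16 * w)
    return thorax, left, right


def _draw_ribs(spec: PhantomSpec, thorax: np.ndarray, lungs, rng) -> np.ndarray:
    """Curved bands across the thorax, clipped medially inside each lung.

    Each band is a downward-bowing parabola of half-thickness 2 px. Inside a
    lung ellipse only the lateral part (|col - cx| >= 0.35 rx) is kept so the
    parenchyma stays connected around the medial ends of the bands.
    """
    h, w = spec.height, spec.width
    rib = np.zeros((h, w), dtype=bool)
    if spec.n_ribs < 1:
        return rib
    yy, xx = np.mgrid[0:h, 0:w]
    rows = np.linspace(0.22 * h, 0.78 * h, spec.n_ribs)
    for r0 in rows:
        bow = (0.10 + 0.04 * rng.random()) * h  # curvature amplitude
        center = r0 + bow * ((xx - 0.5 * w) / (0.5 * w)) ** 2
        band = np.abs(yy - center) <= 2.0
        rib |= band
    rib &= thorax
    # medial clipping inside the lung fields
    keep = np.ones((h, w), dtype=bool)
    for (cy, cx, ry, rx) in lungs:
        inside = _ellipse_mask(h, w, cy, cx, ry, rx)
        medial = np.abs(xx - cx) < 0.35 * rx
        keep &= ~(inside & medial)
    return rib & keep


def _draw_vessels(spec: PhantomSpec, lungs, lung_mask: np.ndarray, rib: np.ndarray, rng) -> np.ndarray:
    """Thin bright spokes from each hilum, truncated at ribs and the pleura."""
    h, w = spec.height, spec.width
    vessel = np.zeros((h, w), dtype=bool)
    n_per_lung = [spec.n_vessels // 2, spec.n_vessels - spec.n_vessels // 2]
    for (cy, cx, ry, rx), n_sp in zip(lungs, n_per_lung):
        medial_sign = 1.0 if cx < 0.5 * w else -1.0  # toward image center
        hy, hx = cy, cx + medial_sign * 0.40 * rx
        for i in range(n_sp):
            ang = (-75 + 150 * (i + 0.5) / max(n_sp, 1)) + rng.uniform(-8, 8)
            ang_rad = math.radians(ang)
            # radiate laterally and up/down, away from the hilum
            d_r = math.sin(ang_rad)
            d_c = -medial_sign * abs(math.cos(ang_rad))
            length = (0.45 + 0.2 * rng.random()) * min(ry, 2.0 * rx)
            er, ec = hy + d_r * length, hx + d_c * length
            rr, cc = skdraw.line(int(round(hy)), int(round(hx)), int(round(er)), int(round(ec)))
            for r_, c_ in zip(rr, cc):
                if not (0 <= r_ < h and 0 <= c_ < w):
                    break
                if not lung_mask[r_, c_] or rib[r_, c_]:
                    break
                vessel[r_, c_] = True
    # thicken to ~2 px so vessels are visible structures
    vessel = morphology.dilation(vessel, morphology.footprint_rectangle((2, 2)))
    return vessel & lung_mask & ~rib


def _labels(spec: PhantomSpec) -> tuple[str, str]:
    if not spec.nodules:
        return "Normal", "none"
    high = any(
        n.placement == "on_rib" or n.radius >= spec.high_risk_radius for n in spec.nodules
    )
    return "Abnormal", ("high" if high else "low")


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom and its ground truth; bit-reproducible for a fixed seed.

    Raises ``ValueError`` if any nodule center lies outside the lung-field
    ellipses. The returned image is float64 in [0, 1].
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    pal = spec.palette

    (tcy, tcx, t_ry, t_rx), left, right = _lung_geometry(h, w)
    thorax = _ellipse_mask(h, w, tcy, tcx, t_ry, t_rx)
    lung_l = _ellipse_mask(h, w, *left)
    lung_r = _ellipse_mask(h, w, *right)
    lung = lung_l | lung_r

    for i, nod in enumerate(spec.nodules):
        r_, c_ = int(round(nod.row)), int(round(nod.col))
        if not (0 <= r_ < h and 0 <= c_ < w) or not lung[r_, c_]:
            raise ValueError(
                f"nodule {i} center ({nod.row}, {nod.col}) lies outside the lung fields"
            )

    rib = _draw_ribs(spec, thorax, (left, right), rng)
    vessel = _draw_vessels(spec, (left, right), lung, rib, rng)

    image = np.full((h, w), pal.background, dtype=float)
    image[thorax] = pal.thorax
    image[lung] = pal.lung
    image[vessel] = pal.vessel
    image[rib] = pal.rib

    nodule_masks = []
    for nod in spec.nodules:
        rr, cc = skdraw.disk((nod.row, nod.col), nod.radius, shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        nodule_masks.append(m)
        image[m] = pal.nodule

    if spec.noise.kind != "none":
        image = add_noise(image, spec.noise, seed=int(rng.integers(0, 2**31 - 1)))

    class_label, risk_label = _labels(spec)
    truth = PhantomTruth(
        lung_mask=lung,
        rib_mask=rib,
        vessel_mask=vessel,
        nodule_masks=tuple(nodule_masks),
        class_label=class_label,
        risk_label=risk_label,
    )
    return image, truth


# ---------------------------------------------------------------- corruption


def add_noise(image: np.ndarray, model: NoiseModel, seed: int) -> np.ndarray:
    """Apply the noise model to an image in [0, 1]; output clipped to [0, 1].

    ``gaussian`` adds i.i.d. zero-mean noise of the stated sigma; ``poisson``
    draws photon counts at ``scale`` expected counts per unit intensity and
    rescales back.
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    if model.kind == "none":
        return image.copy()
    if model.kind == "gaussian":
        if model.sigma < 0:
            raise ValueError("gaussian sigma must be >= 0")
        if model.sigma == 0:
            return image.copy()
        out = image + rng.normal(0.0, model.sigma, size=image.shape)
    elif model.kind == "poisson":
        if model.scale <= 0:
            raise ValueError("poisson scale must be > 0")
        out = rng.poisson(np.clip(image, 0, None) * model.scale) / model.scale
    else:
        raise ValueError(f"unknown noise kind {model.kind!r}")
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------- augmentation


def augment(
    image: np.ndarray,
    op: str,
    *,
    angle: float = 0.0,
    factor: float = 1.0,
    axis: str = "horizontal",
    dr: int = 0,
    dc: int = 0,
    order: int = 1,
    cval: float | None = None,
) -> np.ndarray:
    """Shape-preserving augmentation: rotate / scale / flip / translate.

    ``order=1`` (bilinear) suits images; pass ``order=0`` to transform masks
    with nearest-neighbour interpolation. Out-of-frame areas are filled with
    ``cval`` (default: the image minimum, i.e. the background value).
    """
    image = np.asarray(image)
    fill = float(image.min()) if cval is None else cval
    if op == "rotate":
        if angle % 360 == 0:
            return image.copy()
        return ndi.rotate(
            image.astype(float), angle, reshape=False, order=order, mode="constant", cval=fill
        )
    if op == "scale":
        if factor <= 0:
            raise ValueError(f"scale factor must be > 0, got {factor}")
        if factor == 1.0:
            return image.copy()
        h, w = image.shape
        # zoom about the image center, keeping the original shape
        matrix = np.array([[1.0 / factor, 0.0], [0.0, 1.0 / factor]])
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - matrix @ center
        return ndi.affine_transform(
            image.astype(float), matrix, offset=offset, order=order, mode="constant", cval=fill
        )
    if op == "flip":
        if axis not in ("horizontal", "vertical"):
            raise ValueError("flip axis must be 'horizontal' or 'vertical'")
        return np.flip(image, axis=1 if axis == "horizontal" else 0).copy()
    if op == "translate":
        return ndi.shift(
            image.astype(float), (dr, dc), order=order, mode="constant", cval=fill
        )
    raise ValueError(f"unknown augmentation op {op!r}")


# ---------------------------------------------------------------- sampling


def random_spec(
    seed: int,
    abnormal: bool,
    *,
    height: int = 160,
    width: int = 160,
    n_ribs: int = 4,
    n_vessels: int = 6,
    noise: NoiseModel | None = None,
    max_nodules: int = 2,
) -> PhantomSpec:
    """Draw a random phantom specification, optionally with nodules.

    Nodule centers are sampled from the structure they claim to sit on: an
    ``on_rib`` nodule from rib∩lung pixels, ``on_vessel`` from vessel pixels,
    ``free`` from parenchyma away from ribs and vessels. Radii are uniform in
    [3, 10] px, so abnormal phantoms span both risk classes.
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec(
        height=height,
        width=width,
        n_ribs=n_ribs,
        n_vessels=n_vessels,
        nodules=(),
        noise=NoiseModel.none(),
        seed=seed,
    )
    if not abnormal:
        return replace(base, noise=noise if noise is not None else NoiseModel.gaussian(0.03))

    _, truth = generate_phantom(base)
    interior = ndi.binary_erosion(truth.lung_mask, iterations=6)
    parenchyma = interior & ~truth.rib_mask & ~truth.vessel_mask
    nodules = []
    n_nod = int(rng.integers(1, max_nodules + 1))
    for _ in range(n_nod):
        placement = PLACEMENTS[int(rng.integers(0, len(PLACEMENTS)))]
        pool = {
            "on_rib": truth.rib_mask & interior,
            "on_vessel": truth.vessel_mask & interior,
            "free": parenchyma,
        }[placement]
        if not pool.any():  # e.g. a spec with no ribs: fall back to parenchyma
            placement, pool = "free", parenchyma
        rows, cols = np.nonzero(pool)
        k = int(rng.integers(0, len(rows)))
        radius = float(rng.uniform(3.0, 10.0))
        nodules.append(Nodule(float(rows[k]), float(cols[k]), radius, placement))
    return replace(
        base,
        nodules=tuple(nodules),
        noise=noise if noise is not None else NoiseModel.gaussian(0.03),
    )
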