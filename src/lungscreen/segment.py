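"""Metaheuristic-seeded region-growing segmentation (B-RGS).

A coati optimization algorithm (COA) whose random steps are Bates-distributed
(the mean of ``phi`` i.i.d. uniform(0,1) draws) selects one "knuckle" seed
pixel per lung-field quadrant; a classic region-growing flood from each seed
yields the four-part segmentation of the enhanced image.

The COA is a population metaheuristic with two phases per iteration:

* *iguana hunt* — half the population moves toward the current best position
  (the iguana in the tree); the other half reacts to a randomly re-sampled
  "ground iguana", moving toward it when it is better than the coati's own
  position and away otherwise;
* *predator escape* — every coati takes a small random step whose scale is
  the decision-variable bounds divided by the iteration counter, so steps
  shrink as the search progresses.

Both phases accept a candidate only if it strictly improves fitness
(minimisation), so the best-so-far fitness is non-increasing by construction.

The default seed fitness is the within-region intensity variance of the
region grown from the candidate pixel — low for seeds anchored in
homogeneous parenchyma — with a pluggable interface for custom fitness
functions (e.g. end-to-end classifier accuracy, at much higher cost).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "Bounds",
    "CoatiPopulation",
    "SegmentConfig",
    "SegmentationResult",
    "bates_random",
    "coa_init",
    "coa_step",
    "coa_minimize",
    "region_grow",
    "select_seeds",
    "segment_lungs",
]


@dataclass(frozen=True)
class Bounds:
    """Box bounds per decision variable: lower[y] < upper[y]."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        up = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lo < up):
            raise ValueError("need lower < upper for every decision variable")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def n(self) -> int:
        return self.lower.size

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lower, self.upper)


@dataclass
class CoatiPopulation:
    """Candidate positions with fitness values and the iteration counter."""

    positions: np.ndarray  # (m, n)
    fitness: np.ndarray  # (m,)
    tn: int  # current iteration (1-based once stepping starts)
    tn_max: int

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best_position(self) -> np.ndarray:
        return self.positions[self.best_index].copy()

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])


def bates_random(phi: int, rng: np.random.Generator, size=None):
    """Bates(phi) draw(s): mean of ``phi`` i.i.d. uniform(0,1) variables.

    Mean 1/2 and variance 1/(12 phi) for any ``phi >= 1``; ``phi=1`` is plain
    uniform(0,1). Returns a scalar when ``size`` is None.
    """
    if phi < 1 or int(phi) != phi:
        raise ValueError(f"phi must be an integer >= 1, got {phi}")
    shape = (int(phi),) if size is None else (int(phi),) + tuple(np.atleast_1d(size))
    draws = rng.random(shape).mean(axis=0)
    return float(draws) if size is None else draws


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness_fn(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        raise ValueError("fitness_fn returned a non-finite value")
    return vals


def coa_init(
    bounds: Bounds,
    m: int,
    fitness_fn: Callable[[np.ndarray], float],
    phi: int = 3,
    rng: np.random.Generator | None = None,
) -> CoatiPopulation:
    """Initialise the population uniformly (Bates-jittered) inside the bounds."""
    if m < 4:
        raise ValueError("population size m must be >= 4")
    rng = rng or np.random.default_rng()
    varsigma = bates_random(phi, rng, size=(m, bounds.n))
    positions = bounds.lower + varsigma * (bounds.upper - bounds.lower)
    return CoatiPopulation(
        positions=positions,
        fitness=_evaluate(fitness_fn, positions),
        tn=0,
        tn_max=1,
    )


def coa_step(
    pop: CoatiPopulation,
    fitness_fn: Callable[[np.ndarray], float],
    bounds: Bounds,
    phi: int = 3,
    rng: np.random.Generator | None = None,
) -> CoatiPopulation:
    """One COA iteration: iguana-hunt phase then predator-escape phase.

    Candidates are clamped to the bounds and accepted greedily (strict
    improvement under minimisation), so the population's best fitness never
    increases.
    """
    rng = rng or np.random.default_rng()
    m, n = pop.positions.shape
    positions = pop.positions.copy()
    fitness = pop.fitness.copy()
    tn = pop.tn + 1

    # --- phase 1a: first half assaults the iguana in the tree (current best)
    iguana = positions[int(np.argmin(fitness))].copy()
    half = m // 2
    for x in range(half):
        varsigma = bates_random(phi, rng, size=n)
        theta = int(rng.integers(1, 3))
        cand = positions[x] + varsigma * (iguana - theta * positions[x])
        cand = bounds.clamp(cand)
        f = float(fitness_fn(cand))
        if not np.isfinite(f):
            raise ValueError("fitness_fn returned a non-finite value")
        if f < fitness[x]:
            positions[x], fitness[x] = cand, f

    # --- phase 1b: second half reacts to a ground iguana
    for x in range(half, m):
        varsigma = bates_random(phi, rng, size=n)
        ground = bounds.lower + varsigma * (bounds.upper - bounds.lower)
        f_ground = float(fitness_fn(ground))
        if not np.isfinite(f_ground):
            raise ValueError("fitness_fn returned a non-finite value")
        varsigma = bates_random(phi, rng, size=n)
        theta = int(rng.integers(1, 3))
        if f_ground < fitness[x]:
            cand = positions[x] + varsigma * (ground - theta * positions[x])
        else:
            cand = positions[x] + varsigma * (positions[x] - ground)
        cand = bounds.clamp(cand)
        f = float(fitness_fn(cand))
        if not np.isfinite(f):
            raise ValueError("fitness_fn returned a non-finite value")
        if f < fitness[x]:
            positions[x], fitness[x] = cand, f

    # --- phase 2: predator escape with iteration-shrinking local bounds
    lw_local = bounds.lower / tn
    up_local = bounds.upper / tn
    for x in range(m):
        varsigma = bates_random(phi, rng, size=n)
        step = (1.0 - 2.0 * varsigma) * (lw_local + varsigma * (up_local - lw_local))
        cand = bounds.clamp(positions[x] + step)
        f = float(fitness_fn(cand))
        if not np.isfinite(f):
            raise ValueError("fitness_fn returned a non-finite value")
        if f < fitness[x]:
            positions[x], fitness[x] = cand, f

    return CoatiPopulation(positions=positions, fitness=fitness, tn=tn, tn_max=pop.tn_max)


def coa_minimize(
    fitness_fn: Callable[[np.ndarray], float],
    bounds: Bounds,
    m: int = 20,
    tn_max: int = 50,
    phi: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full COA loop; returns (best position, best fitness, trace).

    The trace records the best-so-far fitness after initialisation and after
    each iteration; it is non-increasing by the greedy acceptance rule.
    """
    rng = rng or np.random.default_rng()
    pop = coa_init(bounds, m, fitness_fn, phi, rng)
    pop.tn_max = tn_max
    trace = [pop.best_fitness]
    for _ in range(tn_max):
        pop = coa_step(pop, fitness_fn, bounds, phi, rng)
        trace.append(pop.best_fitness)
    return pop.best_position, pop.best_fitness, trace


# ------------------------------------------------------------ region growing


_STRUCTURES = {
    4: ndi.generate_binary_structure(2, 1),
    8: ndi.generate_binary_structure(2, 2),
}


def region_grow(
    image: np.ndarray,
    seed: tuple[int, int],
    threshold: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Grow a connected region from ``seed``.

    A pixel joins the region iff it is connectivity-adjacent to it and
    ``|image[p] - image[seed]| < threshold``; with ``threshold == 0`` the
    criterion degenerates to exact equality with the seed value. Because the
    membership predicate depends only on the seed value, the grown region is
    the connected component of the predicate mask containing the seed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    image = np.asarray(image, dtype=float)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")
    seed_val = image[r, c]
    if threshold == 0:
        candidate = image == seed_val
    else:
        candidate = np.abs(image - seed_val) < threshold
    labels, _ = ndi.label(candidate, structure=_STRUCTURES[connectivity])
    return labels == labels[r, c]


# ------------------------------------------------------------- seed search


@dataclass(frozen=True)
class SegmentConfig:
    """Knobs of the B-RGS stage."""

    m: int = 20  # COA population size
    tn_max: int = 50  # COA iterations
    phi: int = 3  # Bates order of the random steps
    grow_c: float = 3.0  # threshold = grow_c * local std + grow_floor
    grow_floor: float = 0.05
    connectivity: int = 8


@dataclass(frozen=True)
class SegmentationResult:
    """Four quadrant-ordered (TL, TR, BL, BR) grown masks and their seeds."""

    seeds: tuple[tuple[int, int], ...]
    masks: tuple[np.ndarray, ...]
    thresholds: tuple[float, ...]


def _quadrant_slices(lung_mask: np.ndarray):
    """TL/TR/BL/BR slices of the lung-mask bounding box."""
    rows, cols = np.nonzero(lung_mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
    return [
        (slice(r0, rm), slice(c0, cm)),  # TL
        (slice(r0, rm), slice(cm, c1)),  # TR
        (slice(rm, r1), slice(c0, cm)),  # BL
        (slice(rm, r1), slice(cm, c1)),  # BR
    ]


def _local_std(image: np.ndarray, r: int, c: int, half: int = 2) -> float:
    win = image[
        max(r - half, 0): r + half + 1, max(c - half, 0): c + half + 1
    ]
    return float(win.std())


def _grow_threshold(image: np.ndarray, seed: tuple[int, int], config: SegmentConfig) -> float:
    return config.grow_c * _local_std(image, *seed) + config.grow_floor


def _seed_fitness_factory(
    crop: np.ndarray, crop_mask: np.ndarray, config: SegmentConfig
) -> Callable[[np.ndarray], float]:
    """Default fitness: ``(1 + within-region variance) / region size`` of the
    region grown from the candidate pixel (restricted to the quadrant crop),
    minimised — the best seed anchors the *largest* region admissible under
    the growing criterion, with within-region homogeneity as the tie-break.
    Candidates outside the quadrant's lung mask are penalised by their
    distance to it."""
    dist_out = ndi.distance_transform_edt(~crop_mask)

    def fitness(pos: np.ndarray) -> float:
        r, c = int(round(pos[0])), int(round(pos[1]))
        r = min(max(r, 0), crop.shape[0] - 1)
        c = min(max(c, 0), crop.shape[1] - 1)
        if not crop_mask[r, c]:
            return 1e6 + float(dist_out[r, c])
        thr = _grow_threshold(crop, (r, c), config)
        region = region_grow(crop, (r, c), thr, config.connectivity) & crop_mask
        vals = crop[region]
        if vals.size < 2:
            return 1e3
        return (1.0 + float(vals.var())) / vals.size

    return fitness


def select_seeds(
    image: np.ndarray,
    lung_mask: np.ndarray,
    config: SegmentConfig | None = None,
    rng: np.random.Generator | None = None,
    fitness_factory=None,
) -> list[tuple[int, int]]:
    """COA-selected knuckle seed points, one per lung-field quadrant.

    Runs an independent COA instance per quadrant of the lung-mask bounding
    box (bounds = the quadrant's own bounding box) and returns integer pixel
    seeds guaranteed to lie inside the lung mask, in TL, TR, BL, BR order. A
    quadrant with an empty mask borrows the seed of the nearest nonempty
    quadrant (with a logged warning).

    ``fitness_factory(crop, crop_mask, config) -> fitness_fn`` may be passed
    to replace the default within-region-variance objective.
    """
    config = config or SegmentConfig()
    rng = rng or np.random.default_rng()
    if not np.any(lung_mask):
        raise ValueError("lung mask is empty")
    factory = fitness_factory or _seed_fitness_factory

    quads = _quadrant_slices(lung_mask)
    seeds: list[tuple[int, int] | None] = []
    for rs, cs in quads:
        crop_mask = lung_mask[rs, cs]
        if not crop_mask.any():
            seeds.append(None)
            continue
        crop = np.asarray(image, dtype=float)[rs, cs]
        rows, cols = np.nonzero(crop_mask)
        bounds = Bounds(
            np.array([rows.min(), cols.min()], dtype=float),
            np.array([rows.max() + 1.0, cols.max() + 1.0]),
        )
        fitness_fn = factory(crop, crop_mask, config)
        best, _, _ = coa_minimize(
            fitness_fn, bounds, m=config.m, tn_max=config.tn_max, phi=config.phi, rng=rng
        )
        r = min(max(int(round(best[0])), 0), crop.shape[0] - 1)
        c = min(max(int(round(best[1])), 0), crop.shape[1] - 1)
        if not crop_mask[r, c]:  # snap to the nearest in-mask pixel
            k = int(np.argmin((rows - r) ** 2 + (cols - c) ** 2))
            r, c = int(rows[k]), int(cols[k])
        seeds.append((r + rs.start, c + cs.start))

    # borrow seeds for empty quadrants from the nearest nonempty one
    centers = [
        ((rs.start + rs.stop) / 2, (cs.start + cs.stop) / 2) for rs, cs in quads
    ]
    for i, s in enumerate(seeds):
        if s is None:
            warnings.warn(f"quadrant {i} has no lung pixels; borrowing a seed")
            logger.warning("quadrant %d empty; borrowing nearest seed", i)
            others = [j for j, t in enumerate(seeds) if t is not None]
            if not others:
                raise ValueError("lung mask empty in every quadrant")
            j = min(
                others,
                key=lambda j: (centers[i][0] - centers[j][0]) ** 2
                + (centers[i][1] - centers[j][1]) ** 2,
            )
            seeds[i] = seeds[j]
    return [s for s in seeds if s is not None]


def segment_lungs(
    image: np.ndarray,
    lung_mask: np.ndarray,
    config: SegmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentationResult:
    """Four-part segmentation of the enhanced lung image.

    Seeds come from :func:`select_seeds`; each region is grown within its
    quadrant's bounding box with an adaptive threshold
    ``grow_c * std(5x5 neighbourhood of the seed) + grow_floor`` and
    intersected with the lung mask. Growing inside the quadrant keeps the
    four parts disjoint by construction (see docs/methods.md for why a
    gray-value contest cannot separate parts grown on the full frame).
    """
    config = config or SegmentConfig()
    rng = rng or np.random.default_rng()
    image = np.asarray(image, dtype=float)
    seeds = select_seeds(image, lung_mask, config, rng)
    quads = _quadrant_slices(lung_mask)

    masks, thresholds = [], []
    for (r, c), (rs, cs) in zip(seeds, quads):
        thr = _grow_threshold(image, (r, c), config)
        full = np.zeros_like(lung_mask, dtype=bool)
        rr = min(max(r - rs.start, 0), rs.stop - rs.start - 1)
        cc = min(max(c - cs.start, 0), cs.stop - cs.start - 1)
        crop_grow = region_grow(image[rs, cs], (rr, cc), thr, config.connectivity)
        full[rs, cs] = crop_grow
        masks.append(full & lung_mask)
        thresholds.append(thr)
    return SegmentationResult(
        seeds=tuple(seeds), masks=tuple(masks), thresholds=tuple(thresholds)
    )


def resolve_overlaps(
    image: np.ndarray,
    seeds: Sequence[tuple[int, int]],
    masks: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Assign pixels claimed by several masks to the seed with the closest
    gray value (ties go to the lower quadrant index). Utility for callers
    that grow regions on the full frame instead of per quadrant."""
    image = np.asarray(image, dtype=float)
    stack = np.stack([m.astype(bool) for m in masks])
    claimed = stack.sum(axis=0)
    out = [m.copy() for m in stack]
    rows, cols = np.nonzero(claimed > 1)
    for r, c in zip(rows, cols):
        owners = [i for i in range(len(out)) if out[i][r, c]]
        best = min(owners, key=lambda i: (abs(image[r, c] - image[seeds[i]]), i))
        for i in owners:
            if i != best:
                out[i][r, c] = False
    return out
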