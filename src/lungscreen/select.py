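"""Chi-square feature selection with a binomially derived significance level.

Each continuous feature is binarised at its median and cross-tabulated
against the binary class label in a 2x2 contingency table

    W = feature-high & class-positive      X = feature-high & class-negative
    Y = feature-low  & class-positive      Z = feature-low  & class-negative

scored with the closed-form Pearson statistic

    chi2 = e (WZ - YX)^2 / ((W+Y)(X+Z)(W+X)(Y+Z)),   e = W+X+Y+Z,

which is algebraically identical to sum (O - E)^2 / E over the four cells
(the test suite verifies the identity on random tables). The significance
level is not fixed a priori: it is the binomial pmf value

    R = C(e, rho) g^rho (1-g)^(e-rho)

for configurable trials/successes/success-probability (defaults e=20, rho=1,
g=0.05 give R ~ 0.377), used as the alpha of a chi-square test with one
degree of freedom; features scoring at or above the critical value survive.
A plain alpha override is available for conventional testing. Critical
values come from a bisection on the regularised incomplete gamma function,
so they are identical across platforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc

__all__ = [
    "ContingencyTable2x2",
    "AlphaConfig",
    "SelectionResult",
    "significance_rank",
    "dof",
    "chi_square_score",
    "chi2_critical",
    "binarize_feature",
    "select_features",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Co-occurrence counts of a binarised feature and the class label."""

    w: int  # feature-high, class-positive
    x: int  # feature-high, class-negative
    y: int  # feature-low, class-positive
    z: int  # feature-low, class-negative

    def __post_init__(self) -> None:
        for name in ("w", "x", "y", "z"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.w + self.x + self.y + self.z


def significance_rank(e: int, rho: int, g: float) -> float:
    """Binomial pmf R = C(e, rho) g^rho (1-g)^(e-rho).

    ``e`` trials, ``rho`` successes, ``g`` per-trial success probability.
    """
    if e < 0 or rho < 0 or rho > e:
        raise ValueError("need 0 <= rho <= e")
    if not (0.0 <= g <= 1.0):
        raise ValueError("g must be in [0, 1]")
    return math.comb(e, rho) * g**rho * (1.0 - g) ** (e - rho)


def dof(levels_a: int, levels_b: int) -> int:
    """Degrees of freedom (a-1)(b-1) of an a x b contingency test."""
    if levels_a < 2 or levels_b < 2:
        raise ValueError("each categorical variable needs >= 2 levels")
    return (levels_a - 1) * (levels_b - 1)


def chi_square_score(table: ContingencyTable2x2) -> float:
    """Closed-form Pearson chi-square statistic of a 2x2 table.

    A zero marginal makes the feature (or the labels) constant; the score is
    0 with a warning — such a feature carries no class information.
    """
    w, x, y, z = table.w, table.x, table.y, table.z
    marginals = (w + y, x + z, w + x, y + z)
    if 0 in marginals:
        warnings.warn("zero marginal in contingency table; score set to 0")
        return 0.0
    num = table.total * (w * z - y * x) ** 2
    den = math.prod(marginals)
    return num / den


def chi2_critical(alpha: float, k: int = 1, tol: float = 1e-12) -> float:
    """Upper critical value of the chi-square(k) distribution at level alpha.

    Solves CDF(x) = 1 - alpha by bisection on the regularised lower
    incomplete gamma function P(k/2, x/2).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    target = 1.0 - alpha
    lo, hi = 0.0, 1.0
    while gammainc(k / 2.0, hi / 2.0) < target:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("chi2_critical failed to bracket")
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if gammainc(k / 2.0, mid / 2.0) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def binarize_feature(values: np.ndarray, labels: np.ndarray) -> ContingencyTable2x2:
    """Median-split a continuous feature against binary labels.

    ``labels`` may be bools/0-1 ints; positives are truthy. A value is
    "high" when strictly above the median (ties count as low). Raises when
    only one class is present.
    """
    values = np.asarray(values, dtype=float)
    pos = np.asarray(labels).astype(bool)
    if values.shape != pos.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if values.size < 2:
        raise ValueError("need at least 2 samples")
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    high = values > np.median(values)
    return ContingencyTable2x2(
        w=int(np.sum(high & pos)),
        x=int(np.sum(high & ~pos)),
        y=int(np.sum(~high & pos)),
        z=int(np.sum(~high & ~pos)),
    )


@dataclass(frozen=True)
class AlphaConfig:
    """Parameters of the binomial significance rank (and its override)."""

    e: int = 20
    rho: int = 1
    g: float = 0.05
    alpha_override: float | None = None  # set to use a plain alpha (e.g. 0.05)
    top_k: int = 10  # fallback when no feature clears the critical value


@dataclass(frozen=True)
class SelectionResult:
    """Per-feature chi-square scores and the surviving feature indices."""

    scores: np.ndarray
    significance_rank: float
    critical_value: float
    selected: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "selected", tuple(int(i) for i in self.selected))


def select_features(
    matrix: np.ndarray,
    labels: np.ndarray,
    alpha_config: AlphaConfig | None = None,
) -> SelectionResult:
    """Score every feature column and keep the class-informative ones.

    The significance level is the binomial rank R (or ``alpha_override``);
    the critical value is the chi-square(1) quantile at 1 - alpha. Selected
    indices are ordered by descending score. If nothing survives, the top-k
    features by score are kept with a warning.
    """
    cfg = alpha_config or AlphaConfig()
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be (n_samples, n_features)")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix must be finite")
    rank = significance_rank(cfg.e, cfg.rho, cfg.g)
    alpha = cfg.alpha_override if cfg.alpha_override is not None else rank
    critical = chi2_critical(alpha, k=dof(2, 2))
    scores = np.array(
        [chi_square_score(binarize_feature(x[:, j], labels)) for j in range(x.shape[1])]
    )
    surviving = [int(j) for j in np.argsort(-scores, kind="stable") if scores[j] >= critical]
    if not surviving:
        warnings.warn(
            f"no feature reached the critical value {critical:.3f}; "
            f"keeping the top {cfg.top_k} by score"
        )
        surviving = [int(j) for j in np.argsort(-scores, kind="stable")[: cfg.top_k]]
    return SelectionResult(
        scores=scores,
        significance_rank=rank,
        critical_value=critical,
        selected=tuple(surviving),
    )
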