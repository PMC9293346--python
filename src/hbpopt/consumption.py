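"""Gamma model of per-capita household consumption and catastrophic-spending risk.

Per-capita total consumption expenditure ``y_h`` is modelled as a gamma
random variable whose shape and scale are calibrated from the economy-wide
mean consumption and Gini coefficient. An out-of-pocket payment ``OOP`` is
catastrophic when ``OOP > t * y_h`` for the threshold share ``t`` (10% in
the main analysis, 25% in sensitivity analyses), so the probability that a
care-seeking household is pushed into catastrophic spending is the gamma
CDF evaluated at ``OOP / t``.

The Gini coefficient of a gamma distribution depends only on the shape
``alpha`` through the closed form

    G(alpha) = Gamma(alpha + 1/2) / (sqrt(pi) * Gamma(alpha + 1)),

which is strictly decreasing in ``alpha`` (G(1) = 1/2, the exponential
case). Calibration inverts this by bracketed bisection and then sets the
scale from the mean.

Counting is expectation-based throughout: expected catastrophic cases are
``probability x number of payers``. A seeded sampling helper exists for
Monte-Carlo cross-checks only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .core_data import EconomyConfig, ValidationError

_SHAPE_LO = 1e-3
_SHAPE_HI = 1e3
_GINI_TOL = 1e-10


class CalibrationError(ValueError):
    """Requested Gini is outside the range achievable on the shape bracket."""


def gini_of_gamma_shape(shape: float) -> float:
    """Gini coefficient of a gamma distribution with the given shape.

    Scale-free: the Gini of Gamma(alpha, theta) does not depend on theta.
    Uses log-gamma differences for numerical stability at large shape.
    """
    if shape <= 0:
        raise ValueError(f"shape must be > 0, got {shape}")
    return math.exp(
        special.gammaln(shape + 0.5) - special.gammaln(shape + 1.0)
    ) / math.sqrt(math.pi)


@dataclass(frozen=True)
class ConsumptionModel:
    """Calibrated gamma consumption distribution plus the CHE threshold."""

    shape: float
    scale: float
    mean_consumption: float
    gini: float
    che_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValidationError("gamma shape and scale must be > 0")
        if not math.isclose(self.shape * self.scale, self.mean_consumption,
                            rel_tol=1e-9):
            raise ValidationError(
                f"shape*scale = {self.shape * self.scale} does not reproduce "
                f"mean_consumption = {self.mean_consumption}"
            )
        if abs(gini_of_gamma_shape(self.shape) - self.gini) > 1e-6:
            raise ValidationError(
                f"shape {self.shape} implies Gini "
                f"{gini_of_gamma_shape(self.shape)}, not {self.gini}"
            )
        if not (0.0 < self.che_threshold < 1.0):
            raise ValidationError("che_threshold must lie in (0, 1)")

    def with_threshold(self, che_threshold: float) -> "ConsumptionModel":
        return ConsumptionModel(self.shape, self.scale, self.mean_consumption,
                                self.gini, che_threshold)


def calibrate(mean_consumption: float, gini: float,
              che_threshold: float = 0.10) -> ConsumptionModel:
    """Fit the gamma shape to the Gini and the scale to the mean.

    Deterministic bracketed bisection on shape in [1e-3, 1e3]; raises
    :class:`CalibrationError` when the Gini is outside the bracket's
    achievable range.
    """
    if mean_consumption <= 0:
        raise ValueError("mean_consumption must be > 0")
    if not (0.0 < gini < 1.0):
        raise ValueError("gini must lie in (0, 1)")
    lo, hi = _SHAPE_LO, _SHAPE_HI
    g_lo, g_hi = gini_of_gamma_shape(lo), gini_of_gamma_shape(hi)
    if not (g_hi <= gini <= g_lo):
        raise CalibrationError(
            f"gini {gini} not achievable for shape in [{lo}, {hi}] "
            f"(range [{g_hi:.4g}, {g_lo:.4g}])"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g_mid = gini_of_gamma_shape(mid)
        if abs(g_mid - gini) < _GINI_TOL:
            lo = hi = mid
            break
        if g_mid > gini:  # Gini decreasing in shape: need larger shape
            lo = mid
        else:
            hi = mid
    shape = 0.5 * (lo + hi)
    return ConsumptionModel(
        shape=shape,
        scale=mean_consumption / shape,
        mean_consumption=mean_consumption,
        gini=gini,
        che_threshold=che_threshold,
    )


def from_economy(economy: EconomyConfig) -> ConsumptionModel:
    return calibrate(economy.mean_consumption, economy.gini,
                     economy.che_threshold)


def che_probability(oop_amount: float, model: ConsumptionModel) -> float:
    """P(a payer's OOP exceeds the threshold share of their consumption).

    Equals ``P(y_h < OOP / t)``, the gamma CDF at ``OOP / t``. Zero OOP is
    never catastrophic.
    """
    if oop_amount < 0:
        raise ValueError(f"oop_amount must be >= 0, got {oop_amount}")
    if oop_amount == 0:
        return 0.0
    return float(stats.gamma.cdf(oop_amount / model.che_threshold,
                                 a=model.shape, scale=model.scale))


def sample_consumption(model: ConsumptionModel, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Seeded draws of y_h; used only as a Monte-Carlo oracle in tests."""
    return rng.gamma(shape=model.shape, scale=model.scale, size=n)
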