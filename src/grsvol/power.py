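"""Sample-size and power for a Pearson correlation via the Fisher z-transformation.

atanh(r) is approximately normal with variance 1/(n-3), giving the closed
forms

    n     = ((z_{1-alpha(/2)} + z_{power}) / atanh(r))^2 + 3
    power = Phi( sqrt(n-3) * atanh(|r|) - z_{1-alpha(/2)} )

The default is one-sided: with r=0.1, alpha=0.05 and power=0.85 the one-sided
formula gives n=717 (rounded to the nearest integer); the two-sided variant
gives a strictly larger n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import ValidationError

__all__ = ["PowerSpec", "sample_size", "power_at_n"]


@dataclass(frozen=True)
class PowerSpec:
    r: float
    alpha: float = 0.05
    power: float = 0.85
    sided: str = "one"

    def __post_init__(self) -> None:
        if not -1 < self.r < 1 or self.r == 0:
            raise ValidationError("r must be in (-1, 1) and nonzero")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValidationError("sided must be 'one' or 'two'")


def _z_alpha(alpha: float, sided: str) -> float:
    return norm.ppf(1.0 - alpha / (2.0 if sided == "two" else 1.0))


def sample_size(spec: PowerSpec) -> int:
    """Minimum n (nearest integer, Fisher small-sample +3 correction included)."""
    z = _z_alpha(spec.alpha, spec.sided) + norm.ppf(spec.power)
    n = (z / np.arctanh(abs(spec.r))) ** 2 + 3.0
    return int(round(float(n)))


def power_at_n(r: float, n: int, alpha: float = 0.05, sided: str = "one") -> float:
    """Achieved power to detect correlation r at sample size n."""
    spec = PowerSpec(r=r, alpha=alpha, power=0.5, sided=sided)  # validates r/alpha/sided
    if n < 4:
        raise ValidationError("n must be >= 4")
    z = np.sqrt(n - 3.0) * np.arctanh(abs(spec.r)) - _z_alpha(alpha, sided)
    return float(norm.cdf(z))
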