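"""Sample-size design for estimating the sensitivity of a diagnostic test.

The Buderer-type calculation: the number of truly positive (difficult) cases
needed to estimate sensitivity Se to absolute half-width d at a given
confidence is n_cases = z^2 Se (1-Se) / d^2; dividing by the expected
prevalence of difficult procedures gives the total enrolment, which is then
inflated for anticipated losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

from scipy import stats

from .cohort import ValidationError

__all__ = ["SampleSizeSpec", "SampleSizeResult", "sample_size_sensitivity"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs, all proportions in (0,1).

    ``precision`` is the absolute half-width of the confidence interval for
    sensitivity; ``loss_fraction`` the anticipated attrition.
    """

    expected_sensitivity: float
    prevalence: float
    confidence_level: float = 0.95
    precision: float = 0.05
    loss_fraction: float = 0.10

    def __post_init__(self):
        for name in ("expected_sensitivity", "prevalence", "confidence_level",
                     "precision"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValidationError(
                f"loss_fraction must be in [0,1), got {self.loss_fraction}"
            )
        if self.precision >= self.expected_sensitivity:
            raise ValidationError("precision must be smaller than the sensitivity")


class SampleSizeResult(NamedTuple):
    n_cases: int
    n_total: int
    n_total_with_loss: int


def sample_size_sensitivity(
    spec: SampleSizeSpec,
    loss_mode: Literal["divide", "multiply"] = "divide",
) -> SampleSizeResult:
    """Required cases, total enrolment, and loss-inflated enrolment.

    Loss inflation divides by (1 - loss) by default, the conservative
    convention; ``loss_mode="multiply"`` uses n_total * (1 + loss) instead.
    Each stage is rounded up to whole patients.
    """
    z = stats.norm.ppf(0.5 + spec.confidence_level / 2.0)
    se = spec.expected_sensitivity
    n_cases = math.ceil(z * z * se * (1.0 - se) / (spec.precision ** 2))
    n_total = math.ceil(n_cases / spec.prevalence)
    if loss_mode == "divide":
        n_loss = math.ceil(n_total / (1.0 - spec.loss_fraction))
    elif loss_mode == "multiply":
        n_loss = math.ceil(n_total * (1.0 + spec.loss_fraction))
    else:
        raise ValidationError(f"unknown loss_mode {loss_mode!r}")
    return SampleSizeResult(n_cases, n_total, n_loss)
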