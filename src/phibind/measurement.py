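"""A scalar measurement with a standard error.

Every derived quantity in the pipeline (rate constants, dissociation
constants, free-energy changes, phi-values) travels as a value plus a
first-order (delta-method) standard error, so the container is deliberately
minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Measurement:
    """A value with a standard error (same units as the value)."""

    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")

    @property
    def rel_se(self) -> float:
        """Relative standard error; inf for a zero value with nonzero SE."""
        if self.value == 0.0:
            return math.inf if self.se > 0 else 0.0
        return self.se / abs(self.value)

    def __iter__(self):
        yield self.value
        yield self.se

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec}} +/- {self.se:{spec}}"


def as_measurement(x) -> Measurement:
    """Coerce a Measurement, (value, se) pair, or bare number."""
    if isinstance(x, Measurement):
        return x
    if isinstance(x, (tuple, list)) and len(x) == 2:
        return Measurement(float(x[0]), float(x[1]))
    return Measurement(float(x))
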