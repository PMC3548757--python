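"""Gompertz scanner response: fraction bound -> expected fluorescent intensity.

    I(alpha) = MAX * exp(log(MIN / MAX) * exp(-alpha * GOMP))

MIN is the scanner background (I(0) = MIN), MAX the linear cutoff
(sup over alpha of I = MAX) and GOMP the dimensionless shape.  The log is the
natural logarithm, which is what makes I(0) = MIN exact.  The curve is
strictly increasing in alpha, so the map preserves the ordering of
occupancies -- the property the intensity fit relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScannerModel", "expected_intensity"]


@dataclass(frozen=True)
class ScannerModel:
    """Scanner response parameters; defaults 100 / 65536 / 7."""

    min_intensity: float = 100.0
    max_intensity: float = 65536.0
    gompertz_shape: float = 7.0

    def __post_init__(self) -> None:
        if not 0 < self.min_intensity < self.max_intensity:
            raise ValueError("scanner requires 0 < MIN < MAX")
        if self.gompertz_shape <= 0:
            raise ValueError("scanner GOMP shape must be > 0")


def expected_intensity(alpha, model: ScannerModel):
    """Expected intensity for a fraction bound (scalar or array), alpha >= 0."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0):
        raise ValueError("fraction bound must be >= 0")
    out = model.max_intensity * np.exp(
        np.log(model.min_intensity / model.max_intensity)
        * np.exp(-a * model.gompertz_shape)
    )
    return float(out) if np.ndim(alpha) == 0 else out
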