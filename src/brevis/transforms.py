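"""Predictor transformations used by the correction regressions.

A correction model enters each demographic predictor through one of a small
set of monotone transformations. ``reflected_log`` is ``ln(offset - x)``,
the "inverse additive logarithmic" form used for age: it flattens the age
effect in young adults and steepens it towards the offset, which must lie
above every observed age.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormDomainError, ValidationError

FAMILIES = ("identity", "square", "cube", "inverse", "log", "reflected_log")


@dataclass(frozen=True)
class TransformSpec:
    """One transformation family, with an offset for ``reflected_log``."""

    family: str
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown transform family {self.family!r}")
        if self.family == "reflected_log":
            if self.offset is None:
                raise ValidationError("reflected_log requires an offset")
        elif self.offset is not None:
            raise ValidationError(f"{self.family} takes no offset")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "identity":
            out = x
        elif self.family == "square":
            out = x ** 2
        elif self.family == "cube":
            out = x ** 3
        elif self.family == "inverse":
            if np.any(x == 0):
                raise NormDomainError("inverse transform undefined at 0")
            out = 1.0 / x
        elif self.family == "log":
            if np.any(x <= 0):
                raise NormDomainError("log transform requires positive values")
            out = np.log(x)
        else:  # reflected_log
            if np.any(x >= self.offset):
                raise NormDomainError(
                    f"reflected log transform ln({self.offset} - x) requires "
                    f"values below {self.offset}"
                )
            out = np.log(self.offset - x)
        return float(out) if out.ndim == 0 else out

    def label(self) -> str:
        if self.family == "reflected_log":
            return f"ln({self.offset:g} - x)"
        return {
            "identity": "x", "square": "x^2", "cube": "x^3",
            "inverse": "1/x", "log": "ln(x)",
        }[self.family]
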