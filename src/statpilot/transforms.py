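"""The three guided transformations: log10, Box-Cox, arcsine-square-root.

Domain violations are hard errors — no silent offsets, shifts or clipping,
because they would change the inference invisibly.  The Box-Cox exponent
``lambda`` is estimated once by maximum likelihood on the pooled values of
all selected groups and then applied identically to every group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

#: Box-Cox search interval for the ML exponent
LAMBDA_RANGE = (-5.0, 5.0)


class TransformDomainError(ValueError):
    """Input values outside the transform's domain."""


@dataclass
class TransformRecord:
    name: str  # "log10" | "boxcox" | "arcsine_sqrt" | "none"
    lambda_: Optional[float] = None
    input_domain_note: str = ""
    applied: bool = False

    def __post_init__(self) -> None:
        if (self.name == "boxcox") != (self.lambda_ is not None):
            raise ValueError("lambda must be present iff the transform is boxcox")
        if self.lambda_ is not None and not (
            LAMBDA_RANGE[0] <= self.lambda_ <= LAMBDA_RANGE[1]
        ):
            raise ValueError(f"lambda {self.lambda_} outside search interval {LAMBDA_RANGE}")


def _require_positive(x: np.ndarray, what: str) -> None:
    bad = int(np.sum(x <= 0))
    if bad:
        raise TransformDomainError(
            f"{what} requires strictly positive values; {bad} non-positive value(s) "
            "present (consider whether these data are on an appropriate scale)"
        )


def log10_transform(values: Sequence[float]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    _require_positive(x, "log10")
    return np.log10(x)


def boxcox_transform(values: Sequence[float], lambda_: float) -> np.ndarray:
    """Box-Cox power transform: (x^l - 1)/l, or ln x in the l -> 0 limit."""
    x = np.asarray(values, dtype=float)
    _require_positive(x, "Box-Cox")
    if abs(lambda_) < 1e-10:
        return np.log(x)
    return (np.power(x, lambda_) - 1.0) / lambda_


def boxcox_mle_lambda(values: Sequence[float]) -> float:
    """Maximum-likelihood Box-Cox exponent over lambda in [-5, 5].

    Maximizes the profile log-likelihood
    ``LL(l) = -(n/2) ln sigma2(l) + (l - 1) sum(ln x)`` (scipy's
    ``boxcox_llf``) with a bounded scalar optimizer, tolerance 1e-5.
    """
    x = np.asarray(values, dtype=float)
    _require_positive(x, "Box-Cox")
    if x.size < 3:
        raise ValueError("Box-Cox ML estimation requires n >= 3")
    if np.ptp(x) == 0.0:
        raise ValueError("Box-Cox ML estimation requires nonzero variance")
    res = optimize.minimize_scalar(
        lambda lm: -stats.boxcox_llf(lm, x),
        bounds=LAMBDA_RANGE, method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x)


def arcsine_sqrt_transform(values: Sequence[float], percent_scale: bool = False) -> np.ndarray:
    """arcsin(sqrt(x)) for proportions in [0, 1]; ``percent_scale`` divides by 100 first."""
    x = np.asarray(values, dtype=float)
    if percent_scale:
        if np.any(x < 0) or np.any(x > 100):
            raise TransformDomainError(
                "arcsine-square-root with percent scale requires values in [0, 100]")
        x = x / 100.0
    if np.any(x < 0) or np.any(x > 1):
        raise TransformDomainError(
            "arcsine-square-root requires proportions in [0, 1] "
            "(use percent_scale for 0-100 data)")
    return np.arcsin(np.sqrt(x))


def apply_transform(values: Sequence[float], name: str,
                    percent_scale: bool = False) -> tuple[np.ndarray, TransformRecord]:
    """Apply a named transform to pooled values, returning data + record."""
    if name == "log10":
        out = log10_transform(values)
        return out, TransformRecord("log10", applied=True,
                                    input_domain_note="all values > 0")
    if name == "boxcox":
        lam = boxcox_mle_lambda(values)
        out = boxcox_transform(values, lam)
        return out, TransformRecord(
            "boxcox", lambda_=lam, applied=True,
            input_domain_note=f"all values > 0; pooled ML lambda in {LAMBDA_RANGE}")
    if name == "arcsine":
        out = arcsine_sqrt_transform(values, percent_scale=percent_scale)
        return out, TransformRecord(
            "arcsine_sqrt", applied=True,
            input_domain_note="proportions" + (" on percent scale" if percent_scale else ""))
    raise ValueError(f"unknown transform {name!r} (expected log10, boxcox or arcsine)")
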