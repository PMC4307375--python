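"""Candidate link functions for the proportion-scale association model.

Three links are supported, selected by name:

``odds``
    ``g(p) = p / (1 - p)``, mapping (0, 1) onto (0, inf).
``logit``
    ``g(p) = log(p / (1 - p))``, mapping (0, 1) onto the real line.
    This is the package default.
``cloglog``
    ``g(p) = log(-log(1 - p))``, mapping (0, 1) onto the real line.

The odds link is the only one whose inverse is partial: the linear
predictor must be positive, and samplers treat non-positive values as
zero-likelihood states rather than clipping them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LINK_NAMES", "LinkSpec", "link", "inverse_link"]

LINK_NAMES = ("odds", "logit", "cloglog")

#: integer codes shared with the compiled sampler kernels
LINK_CODES = {"odds": 0, "logit": 1, "cloglog": 2}


@dataclass(frozen=True)
class LinkSpec:
    """A validated link-function choice."""

    name: str = "logit"

    def __post_init__(self) -> None:
        if self.name not in LINK_NAMES:
            raise ValueError(
                f"unknown link {self.name!r}; expected one of {LINK_NAMES}"
            )

    @property
    def code(self) -> int:
        return LINK_CODES[self.name]


def _as_spec(spec: "LinkSpec | str") -> LinkSpec:
    return spec if isinstance(spec, LinkSpec) else LinkSpec(spec)


def link(p, spec: "LinkSpec | str" = "logit"):
    """Transform a proportion ``p`` in (0, 1) to the linear-predictor scale.

    Scalar or array valued.  Raises :class:`ValueError` for proportions on
    the closed boundary; user data is never silently clamped.
    """
    spec = _as_spec(spec)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("link() requires proportions strictly inside (0, 1)")
    if spec.name == "odds":
        out = p / (1.0 - p)
    elif spec.name == "logit":
        out = np.log(p / (1.0 - p))
    else:  # cloglog
        out = np.log(-np.log1p(-p))
    return out if out.ndim else float(out)


def inverse_link(y, spec: "LinkSpec | str" = "logit"):
    """Map a linear-predictor value back to a proportion.

    For the odds link the inverse only exists for ``y > 0``; other values
    raise :class:`ValueError` (sampler code treats them as zero-likelihood
    proposals instead of calling this function).
    """
    spec = _as_spec(spec)
    y = np.asarray(y, dtype=float)
    if spec.name == "odds":
        if np.any(y <= 0.0):
            raise ValueError("odds inverse link requires y > 0")
        out = y / (1.0 + y)
    elif spec.name == "logit":
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(-y))
    else:  # cloglog
        with np.errstate(over="ignore"):
            out = -np.expm1(-np.exp(y))
    return out if out.ndim else float(out)
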