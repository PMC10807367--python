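"""V-shaped transfer functions.

A V-shaped transfer function maps a real-valued update (of any sign and
magnitude) to a probability in [0, 1) of flipping a binary position
component.  All four variants are symmetric around zero, vanish exactly at
zero, and increase strictly with the magnitude of the input, so a large
continuous step translates into a near-certain bit flip while a vanishing
step leaves the bit alone.  The four closed forms share unit slope at the
origin, which makes them interchangeable near zero and increasingly
different in their tails.
"""

from __future__ import annotations

import enum

import numpy as np
from scipy import special

__all__ = ["TransferFunction", "evaluate_transfer"]

_HALF_PI = np.pi / 2.0
_HALF_SQRT_PI = np.sqrt(np.pi) / 2.0


class TransferFunction(enum.Enum):
    """The four V-shaped variants.

    V1
        hyperbolic tangent, ``tanh(|x|)``
    V2
        error function, ``erf((sqrt(pi)/2)|x|)``
    V3
        algebraic sigmoid, ``|x| / sqrt(1 + x^2)``
    V4
        arctangent, ``(2/pi) * arctan((pi/2)|x|)`` — the algorithm default
    """

    V1 = "v1"
    V2 = "v2"
    V3 = "v3"
    V4 = "v4"

    @classmethod
    def from_name(cls, name: "str | TransferFunction") -> "TransferFunction":
        """Resolve a case-insensitive name like ``"v4"`` to a variant."""
        if isinstance(name, cls):
            return name
        try:
            return cls(str(name).lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown transfer function {name!r}; expected one of {valid}"
            ) from None

    def __call__(self, x):
        return evaluate_transfer(self, x)


def evaluate_transfer(kind: TransferFunction, x):
    """Evaluate a V-shaped transfer function.

    Parameters
    ----------
    kind
        Which of the four variants to apply.
    x
        Scalar or array of finite reals.  The formula is applied to ``|x|``
        so that positive and negative updates of equal magnitude yield the
        same flip probability.

    Returns
    -------
    float or ndarray
        Flip probability in ``[0, 1)``; exactly 0 iff ``x == 0``.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("transfer function input must be finite")
    a = np.abs(arr)
    kind = TransferFunction.from_name(kind)
    if kind is TransferFunction.V1:
        out = np.tanh(a)
    elif kind is TransferFunction.V2:
        out = special.erf(_HALF_SQRT_PI * a)
    elif kind is TransferFunction.V3:
        out = a / np.sqrt(1.0 + a * a)
    else:
        out = (2.0 / np.pi) * np.arctan(_HALF_PI * a)
    # tanh/erf round to 1.0 in double precision for large |x|; clamp to keep
    # the half-open [0, 1) probability contract
    out = np.minimum(out, np.nextafter(1.0, 0.0))
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out
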