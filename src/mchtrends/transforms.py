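"""Logit-scale transforms with delta-method variance propagation.

All trend modelling happens on the logit scale, which bounds back-transformed
results in (0, 1). A proportion estimate (p, var_p) maps to
y = logit(p) = ln(p/(1-p)) with var_y = var_p / (p(1-p))^2 by the delta
method; ``from_logit`` inverts both.
"""

from __future__ import annotations

import numpy as np

#: clamping band applied to tabulated proportions before the logit transform;
#: bounds the delta-method variance and avoids infinite logits from zero cells
CLAMP_LO = 0.001
CLAMP_HI = 0.999

#: pre-policy pseudo-observations (0.01% coverage) sit below the clamp floor
#: by design; they are exempt from clamping
PSEUDO_P = 0.0001
PSEUDO_VAR = 1e-8


def clamp(p):
    """Clamp proportions into [CLAMP_LO, CLAMP_HI]."""
    return np.clip(p, CLAMP_LO, CLAMP_HI)


def to_logit(p, var_p=None):
    """Logit-transform a proportion and (optionally) its sampling variance.

    Parameters
    ----------
    p : float or array
        Proportion(s), strictly inside (0, 1).
    var_p : float or array, optional
        Sampling variance(s) of ``p``.

    Returns
    -------
    y, or (y, var_y) when ``var_p`` is given.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1); clamp upstream")
    y = np.log(p / (1.0 - p))
    if var_p is None:
        return y if y.ndim else float(y)
    var_p = np.asarray(var_p, dtype=float)
    var_y = var_p / (p * (1.0 - p)) ** 2
    if y.ndim:
        return y, var_y
    return float(y), float(var_y)


def from_logit(y, var_y=None):
    """Inverse-logit a value and (optionally) its variance (delta method)."""
    y = np.asarray(y, dtype=float)
    p = 1.0 / (1.0 + np.exp(-y))
    if var_y is None:
        return p if p.ndim else float(p)
    var_y = np.asarray(var_y, dtype=float)
    var_p = var_y * (p * (1.0 - p)) ** 2
    if p.ndim:
        return p, var_p
    return float(p), float(var_p)
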