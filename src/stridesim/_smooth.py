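"""Smooth scalar primitives shared by the mechanics modules.

Every function here is a composition of operations that are analytic in a
neighbourhood of the real axis (exp, log, tanh, sqrt of strictly positive
arguments, polynomials).  The optimal-control layer differentiates the whole
pipeline by complex-step, so nothing in a solver-facing code path may branch
on the *value* of an input (``np.where`` on data, ``abs``, ``clip``, ...).
"""

from __future__ import annotations

import numpy as np

__all__ = ["smooth_abs", "smooth_pos", "smooth_step", "smooth_max", "smooth_min"]


def smooth_abs(x, eps=1e-8):
    """sqrt(x^2 + eps^2): analytic everywhere, -> |x| as eps -> 0."""
    return np.sqrt(x * x + eps * eps)


def smooth_pos(x, eps=1e-8):
    """Smooth max(x, 0); exact to O(eps) away from the origin."""
    return 0.5 * (x + smooth_abs(x, eps))


def smooth_step(x, width=1e-2):
    """Smooth Heaviside: 0.5*(1 + tanh(x/width))."""
    return 0.5 * (1.0 + np.tanh(x / width))


def smooth_max(a, b, eps=1e-8):
    return 0.5 * (a + b + smooth_abs(a - b, eps))


def smooth_min(a, b, eps=1e-8):
    return 0.5 * (a + b - smooth_abs(a - b, eps))
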