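"""Smooth scalar primitives and complex-step differentiation helpers.

Every nonlinearity that enters an optimal-control constraint must be C1 and
evaluable with a complex-step perturbation (real branch conditions, analytic
branches), so that constraint Jacobians are exact to machine precision.
"""
from __future__ import annotations

import numpy as np

__all__ = ["softplus", "smooth_pos", "smooth_tanh", "cs_jacobian", "cs_gradient"]

_CS_H = 1e-100


def softplus(x, scale):
    """Smooth positive part ``scale*log(1+exp(x/scale))``.

    Decays exponentially for x << 0 and approaches the identity for x >> 0.
    The large-argument branch switches to the exact asymptote (identity) at
    x/scale = 40, where the two branches agree to double precision; the
    branch is selected on the real part so complex-step derivatives remain
    valid.
    """
    x = np.asarray(x)
    z = x / scale
    big = np.real(z) > 40.0
    safe = np.where(big, 0.0, z)
    return np.where(big, x, scale * np.log1p(np.exp(safe)))


def smooth_pos(x, scale):
    """Sqrt-regularized positive part ``0.5*(x + sqrt(x^2 + scale^2))``.

    Heavier-tailed than :func:`softplus`; used where a slowly vanishing
    lower clamp is acceptable (e.g. the Hunt-Crossley dissipation bracket).
    """
    x = np.asarray(x)
    return 0.5 * (x + np.sqrt(x * x + scale * scale))


def smooth_tanh(x, scale):
    """tanh(x/scale); bounded odd sigmoid used for regularized friction."""
    return np.tanh(np.asarray(x) / scale)


def cs_jacobian(fun, x, *args, **kwargs):
    """Jacobian of ``fun`` at ``x`` by complex-step differentiation.

    ``fun`` must accept a complex-valued vector and be composed of analytic
    operations (branch conditions on real parts are fine). Accuracy is at
    machine-precision level; cost is one evaluation per input dimension.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    f0 = np.asarray(fun(x, *args, **kwargs))
    jac = np.empty((f0.size, n))
    for j in range(n):
        xp = x.astype(complex)
        xp[j] += 1j * _CS_H
        jac[:, j] = np.imag(np.asarray(fun(xp, *args, **kwargs)).ravel()) / _CS_H
    return jac


def cs_gradient(fun, x, *args, **kwargs):
    """Gradient of a scalar function by complex-step differentiation."""
    x = np.asarray(x, dtype=float)
    g = np.empty(x.size)
    for j in range(x.size):
        xp = x.astype(complex)
        xp[j] += 1j * _CS_H
        g[j] = np.imag(fun(xp, *args, **kwargs)) / _CS_H
    return g
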