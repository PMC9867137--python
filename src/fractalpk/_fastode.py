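"""Jitted adaptive RK45 (Dormand-Prince) for non-transit compartment models.

Population estimation and simulation-based diagnostics need tens of
thousands of profile solves; this module provides a compiled fast path for
the structures that dominate that workload: 1- or 2-compartment models with
optional first-order depot and fractal exponents on any of Ka/Ke/Kcp/Kpc.
Transit-chain absorption and other general structures go through scipy's
solve_ivp in :mod:`fractalpk.simulate`.

State layout is fixed: ``[depot, central, peripheral, eliminated]`` (unused
slots stay zero).  Parameter packing (float64 array):

    p = [ka, ke, kcp, kpc, h_ka, h_ke, h_kcp, h_kpc, eps, t_ref,
         n_cmp, has_depot]

with ``h = -1`` marking a constant (non-fractal) rate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATE = 4

# Dormand-Prince 5(4) tableau
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def _rate(base: float, h: float, t: float, t_ref: float, eps: float) -> float:
    if h < 0.0 or h == 0.0:
        return base
    e = t - t_ref
    if e < eps:
        e = eps
    return base / e**h


@njit(cache=True)
def _rhs(t: float, y: np.ndarray, p: np.ndarray, dy: np.ndarray) -> None:
    ka = _rate(p[0], p[4], t, p[9], p[8])
    ke = _rate(p[1], p[5], t, p[9], p[8])
    two = p[10] > 1.5
    depot = p[11] > 0.5
    dy[0] = 0.0
    dy[1] = 0.0
    dy[2] = 0.0
    if depot:
        a = ka * y[0]
        dy[0] = -a
        dy[1] += a
    if two:
        kcp = _rate(p[2], p[6], t, p[9], p[8])
        kpc = _rate(p[3], p[7], t, p[9], p[8])
        dy[1] += kpc * y[2] - kcp * y[1]
        dy[2] = kcp * y[1] - kpc * y[2]
    dy[1] -= ke * y[1]
    dy[3] = ke * y[1]


@njit(cache=True)
def integrate(
    t0: float,
    t1: float,
    y: np.ndarray,
    p: np.ndarray,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
    out: np.ndarray,
) -> int:
    """Integrate from t0 to t1, writing states at sorted ``t_eval`` into
    ``out`` (shape ``(len(t_eval), 4)``).  ``y`` is updated in place to the
    state at ``t1``.  Returns 0 on success, 1 on step-count overflow."""
    n_eval = t_eval.shape[0]
    i_eval = 0
    while i_eval < n_eval and t_eval[i_eval] <= t0:
        for j in range(N_STATE):
            out[i_eval, j] = y[j]
        i_eval += 1

    t = t0
    if t1 <= t0:
        return 0
    h = (t1 - t0) * 1e-4
    if h > 0.1:
        h = 0.1
    hmin = (t1 - t0) * 1e-15

    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    k5 = np.empty(N_STATE)
    k6 = np.empty(N_STATE)
    k7 = np.empty(N_STATE)
    ytmp = np.empty(N_STATE)
    ynew = np.empty(N_STATE)

    # generous for legitimate problems (a steep fractal profile over 400 h
    # needs ~1e4 steps); bounds the cost of unsolvable parameter proposals
    max_steps = 500_000
    steps = 0
    while t < t1:
        steps += 1
        if steps > max_steps:
            return 1
        clipped = False
        h_full = h
        t_target = t1
        if i_eval < n_eval and t_eval[i_eval] > t and t_eval[i_eval] < t_target:
            t_target = t_eval[i_eval]
        if t + h >= t_target:
            h = t_target - t
            clipped = True

        _rhs(t, y, p, k1)
        for j in range(N_STATE):
            ytmp[j] = y[j] + h * _A21 * k1[j]
        _rhs(t + h / 5.0, ytmp, p, k2)
        for j in range(N_STATE):
            ytmp[j] = y[j] + h * (_A31 * k1[j] + _A32 * k2[j])
        _rhs(t + 3.0 * h / 10.0, ytmp, p, k3)
        for j in range(N_STATE):
            ytmp[j] = y[j] + h * (_A41 * k1[j] + _A42 * k2[j] + _A43 * k3[j])
        _rhs(t + 4.0 * h / 5.0, ytmp, p, k4)
        for j in range(N_STATE):
            ytmp[j] = y[j] + h * (
                _A51 * k1[j] + _A52 * k2[j] + _A53 * k3[j] + _A54 * k4[j]
            )
        _rhs(t + 8.0 * h / 9.0, ytmp, p, k5)
        for j in range(N_STATE):
            ytmp[j] = y[j] + h * (
                _A61 * k1[j] + _A62 * k2[j] + _A63 * k3[j] + _A64 * k4[j] + _A65 * k5[j]
            )
        _rhs(t + h, ytmp, p, k6)
        for j in range(N_STATE):
            ynew[j] = y[j] + h * (
                _B1 * k1[j] + _B3 * k3[j] + _B4 * k4[j] + _B5 * k5[j] + _B6 * k6[j]
            )
        _rhs(t + h, ynew, p, k7)

        finite = True
        for j in range(N_STATE):
            if not np.isfinite(ynew[j]):
                finite = False
        if not finite:
            if h <= hmin:
                return 2  # diverged at the minimum step: parameters unusable
            h = h * 0.1
            if h < hmin:
                h = hmin
            continue

        errnorm = 0.0
        for j in range(N_STATE):
            err_j = h * (
                _E1 * k1[j]
                + _E3 * k3[j]
                + _E4 * k4[j]
                + _E5 * k5[j]
                + _E6 * k6[j]
                + _E7 * k7[j]
            )
            ay = abs(y[j])
            ayn = abs(ynew[j])
            sc = atol + rtol * (ay if ay > ayn else ayn)
            q = err_j / sc
            errnorm += q * q
        errnorm = (errnorm / N_STATE) ** 0.5

        if errnorm <= 1.0 or h <= hmin:
            t = t_target if clipped else t + h
            for j in range(N_STATE):
                y[j] = ynew[j]
            while i_eval < n_eval and t_eval[i_eval] <= t:
                for j in range(N_STATE):
                    out[i_eval, j] = y[j]
                i_eval += 1
            # step-size growth; resume from the pre-clip step after event landings
            if errnorm == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * errnorm ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            if clipped and fac > 1.0:
                h = h_full
            else:
                h = h * fac
            if h <= 0.0:
                h = hmin
        else:
            fac = 0.9 * errnorm ** (-0.2)
            if fac < 0.1:
                fac = 0.1
            h = h * fac
            if h < hmin:
                h = hmin
    # any remaining eval points numerically equal to t1
    while i_eval < n_eval:
        for j in range(N_STATE):
            out[i_eval, j] = y[j]
        i_eval += 1
    return 0


def pack_params(values: dict, t_ref: float, n_cmp: int, has_depot: bool, eps: float) -> np.ndarray:
    """Pack rate values / fractal exponents into the parameter vector.

    ``values`` maps rate name -> (theta, h) with ``h = -1`` for constant.
    """
    p = np.zeros(12)
    order = ("Ka", "Ke", "Kcp", "Kpc")
    for i, name in enumerate(order):
        theta, h = values.get(name, (0.0, -1.0))
        p[i] = theta
        p[4 + i] = h
    p[8] = eps
    p[9] = t_ref
    p[10] = float(n_cmp)
    p[11] = 1.0 if has_depot else 0.0
    return p
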