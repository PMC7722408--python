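"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the closed forms used by the
package: derivatives come from finite differences or complex-step
differentiation of the raw sigmoid vector field, characteristic values
from an explicit 4x4 determinant, and crossing delays from a dense
(omega, T) sweep of the characteristic magnitude.
"""

from __future__ import annotations

import numpy as np
import pytest

import betaloop as bl
from betaloop.model_core import ModelParameters


@pytest.fixture(scope="session")
def p3() -> ModelParameters:
    """Bundled analysis point (calibrated cortical completion)."""
    return bl.section3_params()


@pytest.fixture(scope="session")
def report3(p3):
    return bl.hopf_report(p3)


@pytest.fixture(scope="session")
def lin3(report3):
    return report3.linearization


@pytest.fixture(scope="session")
def fixtures10():
    return bl.generate_fixtures(seed=20260930, n=10)


@pytest.fixture(scope="session")
def admissible_lins(fixtures10):
    """Linearizations of the fixture sets that admit an equilibrium."""
    out = []
    for p in fixtures10.members:
        try:
            eq = bl.solve_equilibrium(p)
            out.append((p, eq, bl.linearize(p, eq)))
        except (RuntimeError, ValueError):
            pass
    assert len(out) >= 5
    return out


# ---------------------------------------------------------------------------
# Oracles


def char_matrix(lam, T, lin):
    """Explicit characteristic matrix lam*I - B1 - B2 e^{-lam T}."""
    return lam * np.eye(4) - lin.B1 - lin.B2 * np.exp(-lam * T)


def det_oracle(lam, T, lin):
    """4x4 determinant of the characteristic matrix."""
    return np.linalg.det(char_matrix(lam, T, lin))


def rhs_sigmoid_part(v, p, u0):
    """F-part of the vector field at state u0 + v (the leak term is
    linear and drops out of second/third derivatives)."""
    W, b = p.input_weights(), p.input_offsets()
    M, B = p.maxima(), p.baselines()
    inputs = W @ (u0 + v) + b
    return M / (1.0 + (M - B) / B * np.exp(-4.0 * inputs / M)) / p.tau


def dir1(v, p, u0, x, h=1e-20):
    """First directional derivative via complex step (exact to rounding)."""
    return np.imag(rhs_sigmoid_part(v + 1j * h * x, p, u0)) / h


def dir2(p, u0, x, y, h=1e-6):
    """Second directional derivative D^2 f(u0)[x, y] for real directions:
    central difference of complex-step first derivatives."""
    return (dir1(h * y, p, u0, x) - dir1(-h * y, p, u0, x)) / (2.0 * h)


def dir2c(p, u0, x, y):
    """Second directional derivative for complex directions by bilinearity."""
    xr, xi = np.real(x), np.imag(x)
    yr, yi = np.real(y), np.imag(y)
    return (
        dir2(p, u0, xr, yr) - dir2(p, u0, xi, yi)
        + 1j * (dir2(p, u0, xr, yi) + dir2(p, u0, xi, yr))
    )


def dir3(p, u0, x, y, z, h_in=1e-4, h_out=1e-2):
    """Third directional derivative for real directions.  The inner
    difference rides on exact complex-step first derivatives, so both
    steps can be kept large enough to swamp cancellation noise."""
    def d2_at(shift):
        return (dir1(shift + h_in * y, p, u0, x) - dir1(shift - h_in * y, p, u0, x)) / (2.0 * h_in)

    return (d2_at(h_out * z) - d2_at(-h_out * z)) / (2.0 * h_out)


def dir3c(p, u0, x, y, z):
    """Third directional derivative for complex x, y, z (trilinearity)."""
    total = 0.0 + 0.0j
    for xs, xf in ((np.real(x), 1.0), (np.imag(x), 1j)):
        for ys, yf in ((np.real(y), 1.0), (np.imag(y), 1j)):
            for zs, zf in ((np.real(z), 1.0), (np.imag(z), 1j)):
                total += xf * yf * zf * dir3(p, u0, xs, ys, zs)
    return total


def scan_first_crossing(lin, T_max=20.0, dT=0.02, n_omega=600):
    """Brute-force imaginary-axis crossing search: sweep |Delta(i omega, T)|
    over an (omega, T) grid, refine every candidate local minimum with
    Nelder-Mead, and return the smallest verified crossing delay (or
    None).  Uses only the factor definitions, not the quartic/arccos
    crossing algebra it checks."""
    from scipy.optimize import minimize

    from betaloop.linear_stability import characteristic_factors

    cf = characteristic_factors(lin)
    a_scale = max(abs(lin.a12 * lin.a21), abs(lin.a22) / lin.tau, abs(lin.a34 * lin.a43), 1e-6)
    omega = np.linspace(5e-4, 1.5 * np.sqrt(a_scale) * lin.tau / lin.tau + 0.8, n_omega)
    Ts = np.arange(dT, T_max, dT)
    W, TT = np.meshgrid(omega, Ts, indexing="ij")
    lam = 1j * W
    L = lam + 1.0 / lin.tau
    e1 = np.exp(-lam * TT)
    d1 = L * L - L * lin.a22 * e1 - lin.a12 * lin.a21 * e1 * e1
    d2 = L * L - lin.a34 * lin.a43 * e1 * e1
    g = np.abs(d1 * d2)
    gmin = g.min(axis=0)
    thresh = 0.05 * np.median(gmin) + 1e-12
    found = []
    for j in range(1, len(Ts) - 1):
        if gmin[j] < thresh and gmin[j] <= gmin[j - 1] and gmin[j] <= gmin[j + 1]:
            i = int(np.argmin(g[:, j]))
            res = minimize(
                lambda x: abs(cf.delta(1j * abs(x[0]), abs(x[1]))) ** 2,
                x0=[omega[i], Ts[j]], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-24, "maxiter": 400},
            )
            w_star, T_star = abs(res.x[0]), abs(res.x[1])
            if abs(cf.delta(1j * w_star, T_star)) < 1e-8 and T_star > 1e-3:
                found.append(T_star)
    return min(found) if found else None


def newton_root(lin, T, lam0, maxit=60):
    """Newton iteration on Delta(lam, T) = 0 using numerical derivative."""
    from betaloop.linear_stability import characteristic_factors

    cf = characteristic_factors(lin)
    lam = complex(lam0)
    for _ in range(maxit):
        f = cf.delta(lam, T)
        h = 1e-7 * (1.0 + abs(lam))
        df = (cf.delta(lam + h, T) - cf.delta(lam - h, T)) / (2.0 * h)
        if df == 0:
            break
        step = f / df
        lam -= step
        if abs(step) < 1e-14 * (1.0 + abs(lam)):
            break
    return lam


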