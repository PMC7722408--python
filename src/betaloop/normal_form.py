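"""Center-manifold reduction and Hopf normal form at a critical delay.

At the crossing (T0, omega0) the delay system restricted to its
two-dimensional center manifold takes the Poincare normal form

    xi' = i*omega0*xi + c1(0) * xi * |xi|^2 + O(|xi|^5),

with classification scalars

    mu2   = -Re c1(0) / Re lambda'(T0)              (direction)
    beta2 =  2 Re c1(0)                             (orbital stability)
    T2    = -(Im c1(0) + mu2 Im lambda') / omega0   (period trend)

mu2 > 0 means the periodic orbit exists for T > T0 (supercritical);
beta2 < 0 means it is orbitally stable; T2 > 0 means its period grows
with the delay.

All Taylor coefficients of the projected dynamics (g20, g11, g02, g21)
are computed in the time-rescaled frame (t -> t/T, delay normalized to
theta = -1) from the exact quadratic/cubic expansion of the model
nonlinearity: population X's nonlinear drive is

    c_X * (l_X . v(-1))^2 + e_X * (l_X . v(-1))^3,

where l_X is the row of synaptic input weights.  Deriving the z-Taylor
coefficients from these forms, instead of transcribing long component
formulas, keeps the algebra exact; the test suite cross-validates every
g against complex-step directional derivatives of the raw vector field
and the whole chain against simulated orbit amplitudes.

Two scalings of c1 appear.  ``c1`` uses the cross term
i/(2 omega0) (g20 g11 - 2|g11|^2 - |g02|^2/3) with the physical
lambda' = d(lambda)/dT, and feeds the reported mu2/beta2/T2.
``mu2_amp`` uses the time-rescaled (Hassard) normalization
c1s = i/(2 omega0 T0)(...) + g21/2 with the rescaled eigenvalue slope
T0 * Re lambda'; near onset the center-coordinate amplitude obeys
|xi|^2 ~ (T - T0)/mu2_amp, which is what simulation-based amplitude
fits measure (peak-to-peak of S ~ 4 |xi| for a basal-ganglia crossing).
The two conventions always agree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linear_stability import (
    HopfReport,
    characteristic_factors,
    transversality,
)
from .model_core import Linearization

__all__ = [
    "HopfEigenvectors",
    "NormalFormCoefficients",
    "hopf_eigenvectors",
    "bilinear_pairing",
    "g_second_order",
    "center_manifold_terms",
    "g21_coefficient",
    "classify_hopf",
    "normal_form_coefficients",
    "extend_report",
]

_DEGEN = 1e-12


@dataclass(frozen=True)
class HopfEigenvectors:
    """Right eigenvector q(theta) = q0 e^{i T0 omega0 theta} and adjoint
    direction v (q*(s) = (1/rho) v e^{i T0 omega0 s}), normalized so
    that <q*, q> = 1 under the delay bilinear form."""

    q0: np.ndarray            # (1, chi, beta, gamma)
    v: np.ndarray             # adjoint direction (un-normalized)
    rho_bar: complex
    loop: int
    T0: float
    omega0: float

    @property
    def chi(self) -> complex:
        return self.q0[1]

    @property
    def beta(self) -> complex:
        return self.q0[2]

    @property
    def gamma(self) -> complex:
        return self.q0[3]

    @property
    def weights(self) -> np.ndarray:
        """Projection row vector conj(q*(0)) = conj(v)/rho_bar."""
        return np.conj(self.v) / self.rho_bar


def hopf_eigenvectors(lin: Linearization, T0: float, omega0: float) -> HopfEigenvectors:
    """Closed-form eigenvectors of the infinitesimal generator at a crossing.

    The right eigenvector solves (i omega0 I - B1 - B2 e^{-i omega0 T0}) q0 = 0
    with first component 1: chi from the GPe row, beta from the STN row,
    gamma from the inhibitory-cortex row.  For a basal-ganglia (loop 1)
    crossing beta and gamma vanish identically -- the cortex receives no
    feedback -- and the adjoint direction is full with first component 1;
    for a cortical (loop 2) crossing the adjoint is supported on (E, I).
    """
    tau = lin.tau
    L = 1j * omega0 + 1.0 / tau
    e = np.exp(-1j * omega0 * T0)
    scale = abs(L) + abs(lin.a22)
    if abs(lin.a13) < _DEGEN or abs(L - lin.a22 * e) < _DEGEN * scale:
        raise ZeroDivisionError("degenerate eigenvector denominator")
    chi = lin.a21 * e / (L - lin.a22 * e)
    beta = (L - lin.a12 * chi * e) / (lin.a13 * e)
    gamma = lin.a43 * beta * e / L
    q0 = np.array([1.0 + 0j, chi, beta, gamma])

    cf = characteristic_factors(lin)
    loop = 1 if abs(cf.delta1(1j * omega0, T0)) <= abs(cf.delta2(1j * omega0, T0)) else 2
    Lb = np.conj(L)
    eb = np.exp(1j * omega0 * T0)
    if loop == 1:
        D2b = Lb * Lb - lin.a34 * lin.a43 * eb * eb
        if abs(D2b) < _DEGEN * abs(Lb) ** 2 or abs(lin.a21) < _DEGEN:
            raise ZeroDivisionError("degenerate adjoint denominator")
        v = np.array(
            [
                1.0 + 0j,
                Lb / (lin.a21 * eb),
                lin.a13 * eb * Lb / D2b,
                lin.a34 * lin.a13 * eb * eb / D2b,
            ]
        )
    else:
        v = np.array([0.0j, 0.0j, 1.0 + 0j, lin.a34 * eb / Lb])

    rho_bar = np.conj(v) @ q0 + T0 * e * (np.conj(v) @ (lin.B2 @ q0))
    if abs(rho_bar) < _DEGEN:
        raise ZeroDivisionError("vanishing normalization constant rho")
    return HopfEigenvectors(q0=q0, v=v, rho_bar=rho_bar, loop=loop, T0=T0, omega0=omega0)


def bilinear_pairing(ev: HopfEigenvectors, lin: Linearization, phi0: np.ndarray, phi_freq: float) -> complex:
    """<q*, phi> for phi(theta) = phi0 e^{i phi_freq T0 theta} under the
    bilinear form with eta(theta) = T0 [B1 delta(theta) + B2 delta(theta+1)].

    Used by the tests to verify <q*, q> = 1 (phi_freq = omega0) and
    <q*, q-bar> = 0 (phi_freq = -omega0).
    """
    T0, w0 = ev.T0, ev.omega0
    a = 1j * T0 * (phi_freq - w0)
    if abs(a) < 1e-12:
        integral = np.exp(-1j * w0 * T0)
    else:
        integral = np.exp(-1j * w0 * T0) * (np.exp(a) - 1.0) / a
    vb = np.conj(ev.v)
    return (vb @ phi0 + T0 * integral * (vb @ (lin.B2 @ phi0))) / ev.rho_bar


def _require_rows(lin: Linearization) -> np.ndarray:
    if lin.input_rows is None:
        raise ValueError("Linearization lacks input_rows; build it with model_core.linearize")
    return np.asarray(lin.input_rows, dtype=float)


def g_second_order(ev: HopfEigenvectors, lin: Linearization) -> tuple[complex, complex, complex]:
    """Quadratic Taylor coefficients (g20, g11, g02) of the projected flow.

    With a_X = l_X . q0 e^{-i omega0 T0} the quadratic drive of
    population X contributes c_X a_X^2 z^2 + 2 c_X |a_X|^2 z z-bar +
    c_X a_X-bar^2 z-bar^2; projecting with T0 conj(q*(0)) gives the g's.
    """
    rows = _require_rows(lin)
    T0, w0 = ev.T0, ev.omega0
    a = rows @ (ev.q0 * np.exp(-1j * w0 * T0))
    c = lin.c_vec
    wts = ev.weights
    g20 = 2.0 * T0 * np.sum(wts * c * a * a)
    g11 = 2.0 * T0 * np.sum(wts * c * a * np.conj(a))
    g02 = 2.0 * T0 * np.sum(wts * c * np.conj(a) * np.conj(a))
    return g20, g11, g02


def center_manifold_terms(
    ev: HopfEigenvectors,
    lin: Linearization,
    g20: complex,
    g11: complex,
    g02: complex,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Correction vectors E1, E2 and center-manifold terms W20(-1), W11(-1).

    E1 solves (2 i omega0 I - B1 - B2 e^{-2 i omega0 T0}) E1 =
    2 e^{-2 i omega0 T0} F2 with F2_X = c_X (l_X . q0)^2, and E2 solves
    -(B1 + B2) E2 = 2 F11 with F11_X = c_X |l_X . q0|^2 (real, so E2 is
    real).  The W terms then follow from the variation-of-constants
    profile evaluated at the delayed argument theta = -1.
    """
    rows = _require_rows(lin)
    T0, w0 = ev.T0, ev.omega0
    a0 = rows @ ev.q0
    c = lin.c_vec
    F2 = c * a0 * a0
    F11 = (c * a0 * np.conj(a0)).real
    e2 = np.exp(-2j * w0 * T0)
    M1 = 2j * w0 * np.eye(4) - lin.B1 - lin.B2 * e2
    if abs(np.linalg.det(M1)) < _DEGEN * np.linalg.norm(M1) ** 4:
        raise np.linalg.LinAlgError("2:1 resonance: 2 i omega0 is a characteristic root")
    E1 = np.linalg.solve(M1, 2.0 * e2 * F2)
    M2 = -(lin.B1 + lin.B2)
    E2 = np.linalg.solve(M2, 2.0 * F11).astype(complex)

    e1 = np.exp(-1j * w0 * T0)
    qd = ev.q0 * e1
    qdbar = np.conj(qd)
    W20m1 = (1j * g20 / (T0 * w0)) * qd + (1j * np.conj(g02) / (3.0 * T0 * w0)) * qdbar + E1 * e2
    W11m1 = (-1j * g11 / (T0 * w0)) * qd + (1j * np.conj(g11) / (T0 * w0)) * qdbar + E2
    return E1, E2, W20m1, W11m1


def g21_coefficient(
    ev: HopfEigenvectors,
    lin: Linearization,
    W20m1: np.ndarray,
    W11m1: np.ndarray,
) -> complex:
    """Cubic coefficient g21: pure-cubic part plus quadratic-times-W part.

    g21 = 2 T0 sum_X wts_X [ 3 e_X a_X^2 a_X-bar
                             + c_X (2 a_X w11_X + a_X-bar w20_X) ]
    with w20_X = l_X . W20(-1), w11_X = l_X . W11(-1).
    """
    rows = _require_rows(lin)
    T0, w0 = ev.T0, ev.omega0
    a = rows @ (ev.q0 * np.exp(-1j * w0 * T0))
    w20 = rows @ W20m1
    w11 = rows @ W11m1
    contrib = 6.0 * lin.e_vec * a * a * np.conj(a) + 2.0 * lin.c_vec * (2.0 * a * w11 + np.conj(a) * w20)
    return T0 * np.sum(ev.weights * contrib)


@dataclass(frozen=True)
class NormalFormCoefficients:
    g20: complex
    g11: complex
    g02: complex
    g21: complex
    E1: np.ndarray
    E2: np.ndarray
    W20m1: np.ndarray
    W11m1: np.ndarray
    c1: complex               # i/(2 omega0)(g20 g11 - 2|g11|^2 - |g02|^2/3) + g21/2
    c1_rescaled: complex      # same with 1/(2 omega0 T0) cross term (Hassard frame)
    mu2: float
    beta2: float
    T2: float
    mu2_amp: float            # |xi|^2 ~ (T - T0)/mu2_amp near onset
    lam_prime: complex
    omega0: float
    T0: float

    @property
    def direction(self) -> str:
        return "supercritical" if self.mu2 > 0 else "subcritical"

    @property
    def orbit_stability(self) -> str:
        return "stable" if self.beta2 < 0 else "unstable"

    @property
    def period_trend(self) -> str:
        return "increasing" if self.T2 > 0 else "decreasing"

    def to_dict(self) -> dict:
        return {
            "g20": [self.g20.real, self.g20.imag],
            "g11": [self.g11.real, self.g11.imag],
            "g02": [self.g02.real, self.g02.imag],
            "g21": [self.g21.real, self.g21.imag],
            "c1": [self.c1.real, self.c1.imag],
            "c1_rescaled": [self.c1_rescaled.real, self.c1_rescaled.imag],
            "mu2": self.mu2,
            "beta2": self.beta2,
            "T2": self.T2,
            "mu2_amp": self.mu2_amp,
            "re_dlam_dT": self.lam_prime.real,
            "im_dlam_dT": self.lam_prime.imag,
            "direction": self.direction,
            "orbit_stability": self.orbit_stability,
            "period_trend": self.period_trend,
        }


def classify_hopf(
    g20: complex,
    g11: complex,
    g02: complex,
    g21: complex,
    omega0: float,
    T0: float,
    lam_prime: complex,
    **extras,
) -> NormalFormCoefficients:
    """Assemble c1(0) and the classification scalars mu2, beta2, T2."""
    if lam_prime.real == 0:
        raise ZeroDivisionError("transversality violated: Re lambda' = 0")
    cross = g20 * g11 - 2.0 * abs(g11) ** 2 - abs(g02) ** 2 / 3.0
    c1 = 1j / (2.0 * omega0) * cross + g21 / 2.0
    c1s = 1j / (2.0 * omega0 * T0) * cross + g21 / 2.0
    mu2 = -c1.real / lam_prime.real
    beta2 = 2.0 * c1.real
    T2 = -(c1.imag + mu2 * lam_prime.imag) / omega0
    mu2_amp = -c1s.real / (T0 * lam_prime.real)
    defaults = dict(
        E1=np.zeros(4, complex), E2=np.zeros(4, complex),
        W20m1=np.zeros(4, complex), W11m1=np.zeros(4, complex),
    )
    defaults.update(extras)
    return NormalFormCoefficients(
        g20=g20, g11=g11, g02=g02, g21=g21,
        c1=c1, c1_rescaled=c1s,
        mu2=mu2, beta2=beta2, T2=T2, mu2_amp=mu2_amp,
        lam_prime=lam_prime, omega0=omega0, T0=T0,
        **defaults,
    )


def normal_form_coefficients(
    lin: Linearization,
    T0: float,
    omega0: float,
    lam_prime: complex | None = None,
) -> NormalFormCoefficients:
    """Full normal-form pipeline at a verified crossing (T0, omega0)."""
    if lam_prime is None:
        lam_prime = transversality(T0, omega0, lin).dlam_dT
    ev = hopf_eigenvectors(lin, T0, omega0)
    g20, g11, g02 = g_second_order(ev, lin)
    E1, E2, W20m1, W11m1 = center_manifold_terms(ev, lin, g20, g11, g02)
    g21 = g21_coefficient(ev, lin, W20m1, W11m1)
    return classify_hopf(
        g20, g11, g02, g21, omega0, T0, lam_prime,
        E1=E1, E2=E2, W20m1=W20m1, W11m1=W11m1,
    )


def extend_report(report: HopfReport) -> HopfReport:
    """Attach normal-form coefficients to a Hopf existence report."""
    if not report.delays.has_crossing:
        return report
    nf = normal_form_coefficients(
        report.linearization,
        report.delays.T0,
        report.delays.omega0,
        report.transversality.dlam_dT if report.transversality else None,
    )
    import dataclasses as _dc

    return _dc.replace(report, normal_form=nf)
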