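"""Linear stability of the delayed linearization and Hopf crossing search.

The characteristic function of du/dt = B1 u(t) + B2 u(t-T) factorizes
into two loop factors,

    Delta_1(lam) = (lam + 1/tau)^2 - (lam + 1/tau) a22 e^{-lam T}
                   - a12 a21 e^{-2 lam T}          (STN-GPe loop)
    Delta_2(lam) = (lam + 1/tau)^2 - a34 a43 e^{-2 lam T}
                                                   (cortical E-I loop)

because the cortical pair (E, I) receives no feedback from the basal
ganglia.  Purely imaginary roots lam = i*omega of either factor mark
delay values at which a conjugate eigenvalue pair crosses the imaginary
axis.  This module computes:

* all imaginary-axis crossing frequencies (quartic in omega^2 for loop
  1, a closed form for loop 2) and their critical delays on every
  branch,
* the minimal critical delay T0 and its loop attribution,
* the transversality derivative d(lam)/dT at the crossing,
* the zero-delay Routh-Hurwitz stability conditions,
* an orchestrated Hopf existence report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import Equilibrium, Linearization, ModelParameters, linearize, solve_equilibrium

__all__ = [
    "CharacteristicFactors",
    "Crossing",
    "CriticalDelaySet",
    "TransversalityResult",
    "ZeroDelayStability",
    "HopfReport",
    "characteristic_factors",
    "characteristic_value",
    "loop1_crossings",
    "loop2_crossings",
    "minimal_critical_delay",
    "transversality",
    "zero_delay_stability",
    "hopf_report",
]

_RESID_TOL = 1e-8


@dataclass(frozen=True)
class CharacteristicFactors:
    """Quartic coefficients for the loop-1 crossing polynomial
    z^4 + k1 z^3 + k2 z^2 + k3 z + k4 (z = omega^2), the loop-2
    discriminant -a34*a43 - 1/tau^2, and the linearization itself."""

    k1: float
    k2: float
    k3: float
    k4: float
    loop2_discriminant: float
    lin: Linearization

    def delta1(self, lam: complex, T: float) -> complex:
        L = lam + 1.0 / self.lin.tau
        e = np.exp(-lam * T)
        return L * L - L * self.lin.a22 * e - self.lin.a12 * self.lin.a21 * e * e

    def delta2(self, lam: complex, T: float) -> complex:
        L = lam + 1.0 / self.lin.tau
        e = np.exp(-lam * T)
        return L * L - self.lin.a34 * self.lin.a43 * e * e

    def delta(self, lam: complex, T: float) -> complex:
        return self.delta1(lam, T) * self.delta2(lam, T)


def characteristic_factors(lin: Linearization) -> CharacteristicFactors:
    tau = lin.tau
    a22 = lin.a22
    P = lin.a12 * lin.a21
    k1 = 4.0 / tau**2 - a22**2
    k2 = 6.0 / tau**4 - 3.0 * a22**2 / tau**2 - 2.0 * P * (P + a22**2)
    k3 = 4.0 / tau**6 - 3.0 * a22**2 / tau**4 - 4.0 * P * (P + a22**2) / tau**2 - P**2 * a22**2
    k4 = (
        1.0 / tau**8
        - a22**2 / tau**6
        - 2.0 * P * (P + a22**2) / tau**4
        - P**2 * a22**2 / tau**2
        + P**4
    )
    return CharacteristicFactors(
        k1=k1, k2=k2, k3=k3, k4=k4,
        loop2_discriminant=-lin.a34 * lin.a43 - 1.0 / tau**2,
        lin=lin,
    )


def characteristic_value(lam: complex, T: float, lin: Linearization) -> complex:
    """Delta(lam) = Delta_1(lam) * Delta_2(lam) at delay T."""
    cf = characteristic_factors(lin)
    return cf.delta(lam, T)


@dataclass(frozen=True)
class Crossing:
    omega: float      # rad/ms, > 0
    T: float          # ms, > 0
    loop: int         # 1 = STN-GPe, 2 = cortical E-I
    branch: int       # j index (period 2*pi/omega for loop 1, pi/omega for loop 2)


def _delays_from_unit_root(x: complex, omega: float, loop: int, n_branches: int) -> list[Crossing]:
    """Given x = e^{-i omega T} solving the factor equation, enumerate
    positive delays on successive branches."""
    theta = (-np.angle(x)) % (2.0 * np.pi)
    out = []
    for j in range(n_branches):
        T = (theta + 2.0 * np.pi * j) / omega
        if T > 1e-12:
            out.append(Crossing(omega=float(omega), T=float(T), loop=loop, branch=j))
    return out


def loop1_crossings(lin: Linearization, n_branches: int = 3, tol: float = 1e-10) -> list[Crossing]:
    """Imaginary-axis crossings of the STN-GPe factor Delta_1.

    Real positive roots z_k of the quartic give omega_k = sqrt(z_k);
    the delay follows from the unit-circle root x = e^{-i omega T} of
    the quadratic a12*a21*x^2 + a22*(i omega + 1/tau)*x
    - (i omega + 1/tau)^2 = 0, which enforces the sine and cosine
    conditions simultaneously (no arccos branch ambiguity).
    """
    cf = characteristic_factors(lin)
    tau = lin.tau
    P = lin.a12 * lin.a21
    coeffs = np.array([1.0, cf.k1, cf.k2, cf.k3, cf.k4])
    dcoeffs = np.polyder(coeffs)
    zs = np.roots(coeffs)
    scale = np.max(np.abs(coeffs)) + 1e-300
    reals: list[float] = []
    for z in zs:
        # near-double roots acquire spurious imaginary parts; polish on the
        # real axis and let the residual decide
        if abs(z.imag) > 1e-4 * (1.0 + abs(z)):
            continue
        zr = float(z.real)
        for _ in range(50):
            q = np.polyval(coeffs, zr)
            dq = np.polyval(dcoeffs, zr)
            if dq == 0:
                break
            step = q / dq
            zr -= step
            if abs(step) < 1e-15 * (1.0 + abs(zr)):
                break
        if zr <= tol:
            continue
        if abs(np.polyval(coeffs, zr)) > 1e-9 * scale * max(1.0, zr**4):
            continue
        if not any(abs(zr - other) < 1e-9 * (1.0 + abs(zr)) for other in reals):
            reals.append(zr)
    out: list[Crossing] = []
    for zr in reals:
        omega = float(np.sqrt(zr))
        L = 1j * omega + 1.0 / tau
        if abs(P) > 1e-14:
            xs = np.roots([P, lin.a22 * L, -L * L])
        elif abs(lin.a22) > 1e-14:
            xs = [L / lin.a22]
        else:
            continue
        for x in xs:
            if abs(abs(x) - 1.0) > 1e-6:
                continue
            for c in _delays_from_unit_root(x, omega, loop=1, n_branches=n_branches):
                if abs(cf.delta1(1j * omega, c.T)) < _RESID_TOL:
                    out.append(c)
    return sorted(out, key=lambda c: c.T)


def loop2_crossings(lin: Linearization, n_branches: int = 3) -> list[Crossing]:
    """Imaginary-axis crossings of the cortical factor Delta_2.

    A real crossing frequency exists iff -a34*a43 > 1/tau^2, namely
    omega_5 = sqrt(-a34*a43 - 1/tau^2); the two square roots of
    (i omega + 1/tau)^2 / (a34 a43) on the unit circle generate delays
    spaced pi/omega apart.
    """
    cf = characteristic_factors(lin)
    if cf.loop2_discriminant <= 0:
        return []
    omega = float(np.sqrt(cf.loop2_discriminant))
    Q = lin.a34 * lin.a43
    L = 1j * omega + 1.0 / lin.tau
    r = np.sqrt(L * L / Q + 0j)
    out: list[Crossing] = []
    for x in (r, -r):
        if abs(abs(x) - 1.0) > 1e-6:
            continue
        for c in _delays_from_unit_root(x, omega, loop=2, n_branches=2 * n_branches):
            if abs(cf.delta2(1j * omega, c.T)) < _RESID_TOL:
                out.append(c)
    # re-index branches by order in T
    out = sorted(out, key=lambda c: c.T)
    return [Crossing(c.omega, c.T, 2, j) for j, c in enumerate(out)]


@dataclass(frozen=True)
class CriticalDelaySet:
    crossings: list[Crossing] = field(default_factory=list)
    T0: float | None = None
    omega0: float | None = None
    loop0: int | None = None
    tie: bool = False

    @property
    def has_crossing(self) -> bool:
        return self.T0 is not None

    @property
    def f0_hz(self) -> float | None:
        if self.omega0 is None:
            return None
        return 1000.0 * self.omega0 / (2.0 * np.pi)


def minimal_critical_delay(lin: Linearization, n_branches: int = 3) -> CriticalDelaySet:
    """Merge loop-1 and loop-2 candidates and take the smallest positive
    delay.  Ties (equal minimal delay from distinct frequencies) keep
    the largest omega and set the tie flag."""
    cand = loop1_crossings(lin, n_branches) + loop2_crossings(lin, n_branches)
    if not cand:
        return CriticalDelaySet(crossings=[])
    cand = sorted(cand, key=lambda c: c.T)
    T0 = cand[0].T
    at_min = [c for c in cand if abs(c.T - T0) < 1e-9]
    best = max(at_min, key=lambda c: c.omega)
    return CriticalDelaySet(
        crossings=cand,
        T0=best.T,
        omega0=best.omega,
        loop0=best.loop,
        tie=len({round(c.omega, 12) for c in at_min}) > 1,
    )


@dataclass(frozen=True)
class TransversalityResult:
    dlam_dT: complex          # lambda'(T0), 1/ms per ms
    dlam_dT_inv: complex      # (d lambda / d T)^{-1}
    P_R: float
    P_I: float
    Q_R: float
    Q_I: float
    satisfied: bool           # H2: P_R Q_R + P_I Q_I != 0

    @property
    def re_dlam_dT(self) -> float:
        return self.dlam_dT.real


def _char_partials(lam: complex, T: float, lin: Linearization):
    """(dDelta2/dlam, dDelta1/dlam, dDelta2/dT, dDelta1/dT) = (d1..d4)."""
    tau = lin.tau
    a22 = lin.a22
    P = lin.a12 * lin.a21
    Q = lin.a34 * lin.a43
    L = lam + 1.0 / tau
    e1 = np.exp(-lam * T)
    e2 = np.exp(-2.0 * lam * T)
    d1 = 2.0 * L + 2.0 * T * Q * e2
    d2 = 2.0 * L - a22 * e1 + T * L * a22 * e1 + 2.0 * T * P * e2
    d3 = 2.0 * lam * Q * e2
    d4 = lam * L * a22 * e1 + 2.0 * lam * P * e2
    return d1, d2, d3, d4


def transversality(T0: float, omega0: float, lin: Linearization) -> TransversalityResult:
    """Speed of the eigenvalue pair across the imaginary axis at (T0, omega0).

    Implicit differentiation of Delta = Delta_1 * Delta_2 gives
    lambda' = -(dDelta/dT)/(dDelta/dlam); the components are assembled
    from the loop factors and their partials so that the same formula
    serves crossings of either loop.
    """
    cf = characteristic_factors(lin)
    lam = 1j * omega0
    d1, d2, d3, d4 = _char_partials(lam, T0, lin)
    D1 = cf.delta1(lam, T0)
    D2 = cf.delta2(lam, T0)
    P = d1 * D1 + d2 * D2      # dDelta/dlam
    Q = d3 * D1 + d4 * D2      # dDelta/dT
    if abs(Q) ** 2 < 1e-300:
        raise ZeroDivisionError("degenerate transversality: dDelta/dT vanishes")
    inv = -P / Q
    dot = P.real * Q.real + P.imag * Q.imag
    return TransversalityResult(
        dlam_dT=-Q / P,
        dlam_dT_inv=inv,
        P_R=P.real,
        P_I=P.imag,
        Q_R=Q.real,
        Q_I=Q.imag,
        satisfied=bool(abs(dot) > 1e-14 * (abs(P) * abs(Q) + 1e-300)),
    )


@dataclass(frozen=True)
class ZeroDelayStability:
    d0: float
    d1: float
    d2: float
    d3: float
    conditions: dict
    stable: bool


def zero_delay_stability(lin: Linearization) -> ZeroDelayStability:
    """Routh-Hurwitz test of the T = 0 quartic.

    At zero delay the characteristic function is the product of the two
    quadratic loop factors; the quartic coefficients are obtained by
    expanding that product (lam^4 + d3 lam^3 + d2 lam^2 + d1 lam + d0).
    """
    r = 1.0 / lin.tau
    a22 = lin.a22
    P = lin.a12 * lin.a21
    Q = lin.a34 * lin.a43
    # (L^2 - a22 L - P)(L^2 - Q), L = lam + r, expanded in lam
    d3 = 4.0 * r - a22
    d2 = 6.0 * r**2 - 3.0 * a22 * r - (P + Q)
    d1 = 4.0 * r**3 - 3.0 * a22 * r**2 - 2.0 * (P + Q) * r + a22 * Q
    d0 = r**4 - a22 * r**3 - (P + Q) * r**2 + a22 * Q * r + P * Q
    conds = {
        "d0>0": d0 > 0,
        "d1>0": d1 > 0,
        "d2>0": d2 > 0,
        "d3>0": d3 > 0,
        "d3*d2>d1": d3 * d2 > d1,
        "d3*d2*d1>d1^2+d3^2*d0": d3 * d2 * d1 > d1**2 + d3**2 * d0,
    }
    return ZeroDelayStability(d0=d0, d1=d1, d2=d2, d3=d3, conditions=conds, stable=all(conds.values()))


@dataclass(frozen=True)
class HopfReport:
    params: ModelParameters
    equilibrium: Equilibrium
    linearization: Linearization
    delays: CriticalDelaySet
    transversality: TransversalityResult | None
    zero_delay: ZeroDelayStability
    hopf: bool
    reason: str
    # filled by normal_form.extend_report
    normal_form: object | None = None

    def to_dict(self) -> dict:
        d = {
            "hopf": self.hopf,
            "reason": self.reason,
            "T0_ms": self.delays.T0,
            "omega0_rad_per_ms": self.delays.omega0,
            "f0_hz": self.delays.f0_hz,
            "loop": self.delays.loop0,
            "H1_crossing_exists": self.delays.has_crossing,
            "H2_transversal": None if self.transversality is None else self.transversality.satisfied,
            "H3_zero_delay_stable": self.zero_delay.stable,
            "equilibrium": list(self.equilibrium.u0),
            "equilibrium_residual": self.equilibrium.residual,
            "re_dlam_dT": None if self.transversality is None else self.transversality.re_dlam_dT,
            "crossings": [
                {"omega": c.omega, "T": c.T, "loop": c.loop, "branch": c.branch}
                for c in self.delays.crossings
            ],
        }
        if self.normal_form is not None:
            d["normal_form"] = self.normal_form.to_dict()
        return d


def hopf_report(p: ModelParameters) -> HopfReport:
    """Equilibrium -> linearization -> crossings -> transversality ->
    zero-delay stability, with a combined existence verdict.

    The verdict is affirmative only when a positive crossing delay
    exists (H1), the eigenvalue pair crosses with nonzero speed (H2)
    and the zero-delay equilibrium is stable (H3); then increasing the
    delay through T0 destabilizes the equilibrium in a Hopf bifurcation.
    """
    try:
        eq = solve_equilibrium(p)
    except RuntimeError as exc:
        raise RuntimeError(f"[equilibrium] {exc}") from exc
    try:
        lin = linearize(p, eq)
    except ValueError as exc:
        raise ValueError(f"[linearization] {exc}") from exc
    delays = minimal_critical_delay(lin)
    zd = zero_delay_stability(lin)
    tv = None
    if delays.has_crossing:
        tv = transversality(delays.T0, delays.omega0, lin)
    if not delays.has_crossing:
        verdict, reason = False, "(H1) fails: no imaginary-axis crossing for any delay"
    elif not tv.satisfied:
        verdict, reason = False, "(H2) fails: eigenvalue pair crosses with zero speed"
    elif not zd.stable:
        verdict, reason = False, "(H3) fails: equilibrium already unstable at T = 0"
    else:
        verdict, reason = True, f"Hopf at T0 = {delays.T0:.4f} ms (loop {delays.loop0})"
    return HopfReport(
        params=p,
        equilibrium=eq,
        linearization=lin,
        delays=delays,
        transversality=tv,
        zero_delay=zd,
        hopf=verdict,
        reason=reason,
    )
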