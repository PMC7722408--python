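"""Core definition of the reduced cortex-STN-GPe firing-rate model.

The model couples four neural populations -- subthalamic nucleus (S),
external globus pallidus (G), cortical excitatory (E) and cortical
inhibitory (I) -- through sigmoid activation functions, a single shared
membrane time constant ``tau`` and a single shared transmission delay
``T``:

    tau * S' = F_S(w_CS * E(t-T) - w_GS * G(t-T)) - S
    tau * G' = F_G(w_SG * S(t-T) - w_GG * G(t-T) - Str) - G
    tau * E' = F_E(-w_CC * I(t-T) + C) - E
    tau * I' = F_I( w_CC * E(t-T)) - I

with F_X(x) = M_X / (1 + (M_X - B_X)/B_X * exp(-4 x / M_X)).

This module provides the parameter container, the sigmoid activation and
its exact derivative identities, the vector field, an equilibrium solver
and the closed-form linearization (delayed-Jacobian entries plus the
quadratic and cubic Taylor coefficients of the sigmoids that feed the
Hopf normal form).

Conventions: time in ms, firing rates in spk/s, angular frequencies in
rad/ms (reported frequencies in Hz are 1000*omega/(2*pi)).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import root

__all__ = [
    "ModelParameters",
    "Equilibrium",
    "Linearization",
    "activation",
    "activation_deriv",
    "reduced_rhs",
    "solve_equilibrium",
    "linearize",
    "load_params",
    "save_params",
    "section3_params",
]

_POPS = ("S", "G", "E", "I")

#: Table-1 admissible ranges for the four cortical sigmoid constants.
CORTICAL_RANGES = {
    "M_E": (50.0, 80.0),
    "B_E": (0.0, 20.0),
    "M_I": (20.0, 330.0),
    "B_I": (0.0, 20.0),
}


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the reduced model.

    Defaults are the point values used throughout the analysis
    (weights/inputs from the fitted resonance model, basal-ganglia
    sigmoid constants from physiological estimates) together with the
    repository's calibrated cortical completion, which is documented in
    ``data/params_section3.json``.
    """

    tau: float = 10.0          # membrane time constant (ms)
    w_SG: float = 2.56         # STN -> GPe (excitatory)
    w_GS: float = 3.22         # GPe -> STN (inhibitory)
    w_CC: float = 2.75         # intracortical E <-> I
    w_CS: float = 6.60         # cortex -> STN (excitatory)
    w_GG: float = 0.90         # GPe -> GPe (inhibitory collaterals)
    C: float = 277.94          # constant cortical drive (spk/s)
    Str: float = 40.51         # constant striatal inhibition of GPe (spk/s)
    M_S: float = 300.0
    B_S: float = 10.0
    M_G: float = 400.0
    B_G: float = 20.0
    # Calibrated cortical completion (see data/params_section3.json).
    M_E: float = 80.0
    B_E: float = 20.0
    M_I: float = 100.0
    B_I: float = 0.47216082644523416
    T: float = 0.0             # transmission delay (ms)

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError("tau must be positive and finite")
        if not np.isfinite(self.T) or self.T < 0:
            raise ValueError("delay T must be non-negative")
        for w in ("w_SG", "w_GS", "w_CC", "w_CS", "w_GG"):
            if getattr(self, w) < 0:
                raise ValueError(f"{w} must be non-negative")
        for X in _POPS:
            M, B = getattr(self, f"M_{X}"), getattr(self, f"B_{X}")
            if not (0 < B < M):
                raise ValueError(f"need 0 < B_{X} < M_{X}, got B={B}, M={M}")

    def maxima(self) -> np.ndarray:
        return np.array([self.M_S, self.M_G, self.M_E, self.M_I])

    def baselines(self) -> np.ndarray:
        return np.array([self.B_S, self.B_G, self.B_E, self.B_I])

    def input_weights(self) -> np.ndarray:
        """Linear functionals mapping a (delayed) state to the synaptic
        input of each population; row X of the returned matrix dotted
        with the delayed state, plus :meth:`input_offsets`, is the
        argument of F_X."""
        return np.array(
            [
                [0.0, -self.w_GS, self.w_CS, 0.0],
                [self.w_SG, -self.w_GG, 0.0, 0.0],
                [0.0, 0.0, 0.0, -self.w_CC],
                [0.0, 0.0, self.w_CC, 0.0],
            ]
        )

    def input_offsets(self) -> np.ndarray:
        return np.array([0.0, -self.Str, self.C, 0.0])

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Equilibrium:
    """Fixed point u0 = (S*, G*, E*, I*) of the reduced model.

    The fixed point does not depend on the delay: setting the delayed
    state equal to the current state removes T from the equations.
    """

    u0: np.ndarray
    residual: float
    unique_flag: bool


@dataclass(frozen=True)
class Linearization:
    """Delayed-Jacobian entries and sigmoid Taylor coefficients at u0.

    ``a12..a43`` are the nonzero entries of the delay matrix B2 (units
    1/ms); the instantaneous part is B1 = -(1/tau) I.  ``c_X`` and
    ``e_X`` are the quadratic and cubic Taylor coefficients of
    F_X(input)/tau at the equilibrium input (F''/(2 tau), F'''/(6 tau)).
    """

    a12: float
    a13: float
    a21: float
    a22: float
    a34: float
    a43: float
    c_S: float
    c_G: float
    c_E: float
    c_I: float
    e_S: float
    e_G: float
    e_E: float
    e_I: float
    tau: float
    #: rows l_X of the synaptic input functionals (input_X = l_X . state + offset)
    input_rows: np.ndarray = None

    @property
    def B1(self) -> np.ndarray:
        return -np.eye(4) / self.tau

    @property
    def B2(self) -> np.ndarray:
        return np.array(
            [
                [0.0, self.a12, self.a13, 0.0],
                [self.a21, self.a22, 0.0, 0.0],
                [0.0, 0.0, 0.0, self.a34],
                [0.0, 0.0, self.a43, 0.0],
            ]
        )

    @property
    def c_vec(self) -> np.ndarray:
        return np.array([self.c_S, self.c_G, self.c_E, self.c_I])

    @property
    def e_vec(self) -> np.ndarray:
        return np.array([self.e_S, self.e_G, self.e_E, self.e_I])


def activation(x, M: float, B: float):
    """Sigmoid firing-rate response F(x) = M / (1 + (M-B)/B e^{-4x/M}).

    Strictly increasing, F(0) = B, range (0, M).  Accepts scalars or
    arrays.  The maximal slope is 4F(M-F)/M^2 <= 1, attained where
    F = M/2.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation input must be finite")
    if not 0 < B < M:
        raise ValueError("need 0 < B < M")
    with np.errstate(over="ignore"):  # deep-tail exp saturates cleanly to 0
        out = M / (1.0 + (M - B) / B * np.exp(-4.0 * x / M))
    return out if out.ndim else float(out)


def activation_deriv(x, M: float, B: float):
    """dF/dx expressed through the output value: F' = 4 F (M - F) / M^2."""
    F = activation(x, M, B)
    return 4.0 * F * (M - F) / M**2


def _sigmoid_gain(X: float, M: float) -> float:
    """F' as a function of the output level X* (4 X (M - X) / M^2)."""
    return 4.0 * X * (M - X) / M**2


def reduced_rhs(state: Sequence[float], delayed: Sequence[float], p: ModelParameters) -> np.ndarray:
    """Vector field of the reduced model: (F_X(delayed inputs) - X)/tau."""
    state = np.asarray(state, dtype=float)
    delayed = np.asarray(delayed, dtype=float)
    if not (np.all(np.isfinite(state)) and np.all(np.isfinite(delayed))):
        raise ValueError("states must be finite")
    inputs = p.input_weights() @ delayed + p.input_offsets()
    M, B = p.maxima(), p.baselines()
    F = M / (1.0 + (M - B) / B * np.exp(-4.0 * inputs / M))
    return (F - state) / p.tau


def solve_equilibrium(p: ModelParameters, tol: float = 1e-12, n_starts: int = 8) -> Equilibrium:
    """Find the fixed point u0 with multistart damped iteration + Newton polish.

    The fixed point satisfies X = F_X(inputs(u0)) for all four
    populations.  A damped fixed-point sweep from each of ``n_starts``
    grid seeds inside (0, M_X)^4 is followed by a Newton (hybr) polish;
    distinct converged points flip ``unique_flag``.
    """
    M, B = p.maxima(), p.baselines()
    W, b = p.input_weights(), p.input_offsets()

    def fp_map(u):
        inputs = W @ u + b
        return M / (1.0 + (M - B) / B * np.exp(-4.0 * inputs / M))

    fractions = np.linspace(0.05, 0.95, max(2, int(np.ceil(n_starts / 2))))
    seeds = [B.copy()] + [f * M for f in fractions][: n_starts - 1]

    solutions = []
    for u in seeds:
        u = np.asarray(u, dtype=float)
        # short damped sweep to reach the Newton basin; the polish below
        # does the final convergence
        for _ in range(80):
            un = 0.5 * u + 0.5 * fp_map(u)
            if np.max(np.abs(un - u)) < 1e-9:
                u = un
                break
            u = un
        sol = root(lambda v: fp_map(v) - v, u, method="hybr", tol=1e-13)
        if sol.success:
            cand = sol.x
            res = float(np.max(np.abs(reduced_rhs(cand, cand, p))))
            if res <= max(tol, 1e-10) and np.all(cand > 0) and np.all(cand < M):
                solutions.append(cand)
    if not solutions:
        raise RuntimeError("equilibrium solver failed to converge from all starts")
    ref = solutions[0]
    unique = all(np.max(np.abs(s - ref)) < 1e-6 * (1 + np.max(np.abs(ref))) for s in solutions)
    res = float(np.max(np.abs(reduced_rhs(ref, ref, p))))
    return Equilibrium(u0=ref, residual=res, unique_flag=unique)


def linearize(p: ModelParameters, eq: Equilibrium) -> Linearization:
    """Closed-form delayed Jacobian and second/third-order coefficients.

    Each delay-matrix entry is (+/- w/tau) * F'_X evaluated through the
    equilibrium output level; c_X = F''_X/(2 tau) and e_X = F'''_X/(6 tau)
    likewise have closed forms in (X*, M_X).
    """
    S, G, E, I = eq.u0
    tau = p.tau
    for X, val, M in zip(_POPS, eq.u0, p.maxima()):
        if abs(val) < 1e-9 or abs(M - val) < 1e-9:
            raise ValueError(
                f"equilibrium component {X}* = {val} is at a sigmoid saturation "
                "bound; derivative formulas are degenerate"
            )
    gS = _sigmoid_gain(S, p.M_S)
    gG = _sigmoid_gain(G, p.M_G)
    gE = _sigmoid_gain(E, p.M_E)
    gI = _sigmoid_gain(I, p.M_I)

    def c_of(X, M):
        return -8.0 * X * (M - X) * (2.0 * X - M) / (tau * M**4)

    def e_of(X, M):
        return 32.0 * X * (M - X) * (M**2 + 6.0 * X**2 - 6.0 * M * X) / (3.0 * tau * M**6)

    return Linearization(
        a12=-p.w_GS / tau * gS,
        a13=p.w_CS / tau * gS,
        a21=p.w_SG / tau * gG,
        a22=-p.w_GG / tau * gG,
        a34=-p.w_CC / tau * gE,
        a43=p.w_CC / tau * gI,
        c_S=c_of(S, p.M_S),
        c_G=c_of(G, p.M_G),
        c_E=c_of(E, p.M_E),
        c_I=c_of(I, p.M_I),
        e_S=e_of(S, p.M_S),
        e_G=e_of(G, p.M_G),
        e_E=e_of(E, p.M_E),
        e_I=e_of(I, p.M_I),
        tau=tau,
        input_rows=p.input_weights(),
    )


# ---------------------------------------------------------------------------
# Parameter file I/O

_FIELD_NAMES = [f.name for f in dataclasses.fields(ModelParameters)]


def load_params(path_or_dict) -> ModelParameters:
    """Read a parameter set from a JSON file (or a mapping).

    Keys are exactly the ``ModelParameters`` field names; unknown keys
    starting with an underscore or named ``notes`` are ignored so that
    files can carry provenance annotations.
    """
    if isinstance(path_or_dict, dict):
        d = path_or_dict
    else:
        with open(path_or_dict) as fh:
            d = json.load(fh)
    clean = {k: float(v) for k, v in d.items() if k in _FIELD_NAMES}
    unknown = [k for k in d if k not in _FIELD_NAMES and not k.startswith("_") and k != "notes"]
    if unknown:
        raise KeyError(f"unknown parameter keys: {unknown}")
    return ModelParameters(**clean)


def save_params(p: ModelParameters, path, notes: str | None = None) -> None:
    d = p.to_dict()
    if notes:
        d["notes"] = notes
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


def section3_params(T: float | None = None) -> ModelParameters:
    """The bundled analysis point: fitted weights/inputs with the
    calibrated cortical completion (``data/params_section3.json``)."""
    with resources.files("betaloop.data").joinpath("params_section3.json").open() as fh:
        p = load_params(json.load(fh))
    if T is not None:
        p = p.replace(T=T)
    return p
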