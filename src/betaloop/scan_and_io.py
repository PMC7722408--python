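"""Bifurcation scans, cortical-constant calibration, fixtures and file I/O.

One-parameter diagrams are produced by ramped continuation: the model is
integrated at each grid value in sequence, carrying the final history of
one point into the next, with a small perturbation re-injected so that
the run can leave a destabilized fixed point quickly.  Whether a grid
point is oscillatory is decided by the saturated excursion when it is
large, and otherwise by the sign of the envelope growth rate of the
deviation from the analytic fixed point -- near a Hopf point, critical
slowing makes raw amplitude thresholds lag the true onset by many grid
steps, while the growth-rate sign resolves it to about one step.

Two-parameter maps come either from per-cell linear analysis (stable iff
the cell's delay is below its minimal critical delay, or no crossing
exists) or from rows of ramped simulations; band labels use the onset
frequency (analysis) or the measured dominant frequency (simulation).

The calibration utilities complete the four cortical sigmoid constants,
which are only known as physiological ranges, by grid search + bisection
so that the minimal critical delay of the full model matches a target
value; the repository's default completion was produced this way.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dde_sim import (
    AttractorSummary,
    classify_band,
    envelope_growth_rate,
    integrate,
    summarize_attractor,
)
from .linear_stability import minimal_critical_delay
from .model_core import (
    CORTICAL_RANGES,
    ModelParameters,
    linearize,
    solve_equilibrium,
)

log = logging.getLogger("betaloop")

__all__ = [
    "BifurcationDiagram1D",
    "Codim2Map",
    "FixtureSet",
    "CalibrationResult",
    "ramp_scan",
    "hopf_boundary_2d",
    "frequency_profile",
    "generate_fixtures",
    "analytic_minimal_delay",
    "analytic_onset",
    "calibrate_cortical_constants",
]

RAMPABLE = ("T", "w_SG", "w_GS", "w_CS", "w_CC", "w_GG", "C", "Str")


def analytic_minimal_delay(p: ModelParameters):
    """Minimal critical delay of the parameter set (None if no crossing)."""
    eq = solve_equilibrium(p, n_starts=2)
    lin = linearize(p, eq)
    ds = minimal_critical_delay(lin)
    return ds


def _point_summary(p, history, h, settle_ms, measure_ms, perturbation, eq_u0):
    """Integrate settle+measure at fixed parameters; classify the attractor."""
    hist = np.array(history, dtype=float)
    if hist.ndim == 1:
        hist = hist[None, :]
    hist = hist.copy()
    hist[-1, 0] += perturbation
    hist[-1, 2] += perturbation
    tr = integrate(p, duration=settle_ms + measure_ms, h=h, history=hist)
    summary = summarize_attractor(tr, transient_fraction=settle_ms / (settle_ms + measure_ms))
    # near onset a small excursion may be a slowly decaying transient
    # (critical slowing); the envelope trend of the deviation decides.
    # A clearly decaying envelope (more than ~20% over 1000 ms) marks a
    # fixed point; a flat envelope is a saturated small orbit.
    if summary.kind == "oscillation" and summary.amplitude < 5.0 and eq_u0 is not None:
        rate = envelope_growth_rate(tr, eq_u0, window_fraction=measure_ms / (settle_ms + measure_ms))
        if rate is None or rate < -2e-4:
            summary = AttractorSummary(
                kind="fixed_point", amplitude=summary.amplitude, frequency=None,
                band="steady", extrema=summary.extrema, fixed_point=eq_u0,
            )
    tail = tr.y[-(tr.delay_steps + 2) :]
    return summary, tail


@dataclass(frozen=True)
class BifurcationDiagram1D:
    param: str
    grid: np.ndarray
    direction: str
    summaries: list
    analytic_critical: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, s in zip(self.grid, self.summaries):
            rows.append(
                {
                    self.param: v,
                    "kind": s.kind,
                    "amplitude": s.amplitude,
                    "frequency": s.frequency,
                    "band": s.band,
                    "S_min": s.extrema["S"][0],
                    "S_max": s.extrema["S"][1],
                }
            )
        return pd.DataFrame(rows)

    def onset_value(self):
        """First grid value (in ramp order) classified as oscillation."""
        order = range(len(self.grid)) if self.direction == "up" else range(len(self.grid) - 1, -1, -1)
        seq = list(order)
        for i in seq:
            if self.summaries[i].kind == "oscillation":
                return float(self.grid[i])
        return None


def ramp_scan(
    p: ModelParameters,
    param_name: str,
    grid,
    direction: str = "up",
    h: float = 0.01,
    settle_ms: float = 1000.0,
    measure_ms: float = 1000.0,
    perturbation: float = 0.5,
) -> BifurcationDiagram1D:
    """Ramped-continuation bifurcation diagram along one parameter."""
    if param_name not in RAMPABLE:
        raise ValueError(f"param must be one of {RAMPABLE}")
    grid = np.asarray(grid, dtype=float)
    if not (np.all(np.diff(grid) > 0)):
        raise ValueError("grid must be strictly increasing")
    order = grid if direction == "up" else grid[::-1]
    t_start = time.perf_counter()

    summaries: dict[float, AttractorSummary] = {}
    failures = []
    history = None
    for v in order:
        pi = p.replace(**{param_name: float(v)})
        try:
            eq = solve_equilibrium(pi, n_starts=2)
            if history is None:
                history = eq.u0.copy()
            s, history = _point_summary(pi, history, h, settle_ms, measure_ms, perturbation, eq.u0)
            summaries[float(v)] = s
        except (RuntimeError, FloatingPointError, ValueError) as exc:
            failures.append((float(v), str(exc)))
            summaries[float(v)] = AttractorSummary(
                kind="failed", amplitude=np.nan, frequency=None, band="steady",
                extrema={k: (np.nan, np.nan) for k in "SGEI"}, fixed_point=None,
            )
            history = None
    log.info("ramp_scan %s %s: %d points in %.1fs", param_name, direction,
             len(grid), time.perf_counter() - t_start)
    crit = []
    try:
        if param_name == "T":
            ds = analytic_minimal_delay(p)
            if ds.has_crossing:
                crit = [ds.T0]
        else:
            crit = analytic_onset(p, param_name, float(grid[0]), float(grid[-1]))
    except Exception:  # analytic overlay is best-effort
        crit = []
    return BifurcationDiagram1D(
        param=param_name, grid=grid, direction=direction,
        summaries=[summaries[float(v)] for v in grid],
        analytic_critical=crit, failures=failures,
    )


def _excess_delay(p: ModelParameters, param_name: str, v: float) -> float:
    """p.T - T0min at param=v; positive means the fixed delay exceeds the
    critical one (oscillatory side).  No crossing maps to -inf."""
    pi = p.replace(**{param_name: float(v)})
    ds = analytic_minimal_delay(pi)
    if not ds.has_crossing:
        return -np.inf
    return p.T - ds.T0


def analytic_onset(p: ModelParameters, param_name: str, lo: float, hi: float,
                   n_probe: int = 41) -> list[float]:
    """Parameter values in [lo, hi] where the fixed delay p.T equals the
    minimal critical delay (Hopf boundary crossings along the scan)."""
    xs = np.linspace(lo, hi, n_probe)
    fs = [_excess_delay(p, param_name, x) for x in xs]
    roots = []
    for x0, x1, f0, f1 in zip(xs[:-1], xs[1:], fs[:-1], fs[1:]):
        if not (np.isfinite(f0) and np.isfinite(f1)):
            continue
        if f0 == 0:
            roots.append(float(x0))
        elif f0 * f1 < 0:
            roots.append(float(brentq(lambda v: _excess_delay(p, param_name, v), x0, x1, xtol=1e-8)))
    return roots


@dataclass(frozen=True)
class Codim2Map:
    x_name: str
    y_name: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    stable: np.ndarray        # bool, shape (len(y), len(x))
    band: np.ndarray          # str labels, same shape
    frequency: np.ndarray     # Hz or nan
    boundary: list            # (x, y) points on the Hopf boundary
    mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, yv in enumerate(self.y_grid):
            for ix, xv in enumerate(self.x_grid):
                rows.append(
                    {
                        self.x_name: xv,
                        self.y_name: yv,
                        "stable": bool(self.stable[iy, ix]),
                        "band": self.band[iy, ix],
                        "frequency": self.frequency[iy, ix],
                    }
                )
        return pd.DataFrame(rows)


def _analysis_cell(p: ModelParameters):
    """(stable, onset frequency in Hz) for one parameter cell."""
    ds = analytic_minimal_delay(p)
    if not ds.has_crossing:
        return True, np.nan
    return (p.T < ds.T0), ds.f0_hz


def hopf_boundary_2d(
    p: ModelParameters,
    names: tuple[str, str],
    grids: tuple,
    mode: str = "analysis",
    sim_kwargs: dict | None = None,
) -> Codim2Map:
    """Codimension-two stability/band map over two parameters.

    ``analysis`` evaluates the linear-stability verdict per cell (the
    fixed delay against the cell's minimal critical delay -- with
    zero-delay stability, roots enter the right half-plane only through
    imaginary-axis crossings, so delays below every crossing are stable)
    and refines the boundary along the y-direction by bisection.
    ``simulation`` classifies cells from ramped Euler runs along y.
    """
    xn, yn = names
    xg = np.asarray(grids[0], float)
    yg = np.asarray(grids[1], float)
    stable = np.zeros((len(yg), len(xg)), dtype=bool)
    band = np.full((len(yg), len(xg)), "steady", dtype=object)
    freq = np.full((len(yg), len(xg)), np.nan)
    t0 = time.perf_counter()
    if mode == "analysis":
        for ix, xv in enumerate(xg):
            for iy, yv in enumerate(yg):
                pc = p.replace(**{xn: float(xv), yn: float(yv)})
                st, f = _analysis_cell(pc)
                stable[iy, ix] = st
                freq[iy, ix] = f
                band[iy, ix] = "steady" if st else classify_band(f)
        boundary = []
        for ix, xv in enumerate(xg):
            col = stable[:, ix]
            for iy in range(len(yg) - 1):
                if col[iy] != col[iy + 1]:
                    func = lambda yv: (1.0 if _analysis_cell(p.replace(**{xn: float(xv), yn: float(yv)}))[0] else -1.0)
                    try:
                        yb = brentq(func, yg[iy], yg[iy + 1], xtol=1e-6)
                        boundary.append((float(xv), float(yb)))
                    except ValueError:
                        boundary.append((float(xv), float(0.5 * (yg[iy] + yg[iy + 1]))))
    elif mode == "simulation":
        kw = dict(h=0.02, settle_ms=800.0, measure_ms=800.0)
        kw.update(sim_kwargs or {})
        for ix, xv in enumerate(xg):
            diag = ramp_scan(p.replace(**{xn: float(xv)}), yn, yg, **kw)
            for iy, s in enumerate(diag.summaries):
                stable[iy, ix] = s.kind != "oscillation"
                band[iy, ix] = s.band if s.kind == "oscillation" else "steady"
                freq[iy, ix] = s.frequency if s.frequency is not None else np.nan
        boundary = []
        for ix, xv in enumerate(xg):
            col = stable[:, ix]
            for iy in range(len(yg) - 1):
                if col[iy] != col[iy + 1]:
                    boundary.append((float(xv), float(0.5 * (yg[iy] + yg[iy + 1]))))
    else:
        raise ValueError("mode must be 'analysis' or 'simulation'")
    log.info("hopf_boundary_2d %s x %s (%s): %dx%d in %.1fs",
             xn, yn, mode, len(xg), len(yg), time.perf_counter() - t0)
    return Codim2Map(
        x_name=xn, y_name=yn, x_grid=xg, y_grid=yg,
        stable=stable, band=band, frequency=freq, boundary=boundary, mode=mode,
    )


def frequency_profile(
    p: ModelParameters,
    T_grid,
    w_CS: float | None = 8.0,
    **sim_kwargs,
) -> pd.DataFrame:
    """Dominant oscillation frequency and band label along a delay ramp
    (optionally at a fixed cortex-to-STN weight)."""
    base = p if w_CS is None else p.replace(w_CS=w_CS)
    kw = dict(h=0.01, settle_ms=1000.0, measure_ms=1500.0)
    kw.update(sim_kwargs)
    diag = ramp_scan(base, "T", T_grid, **kw)
    df = diag.to_frame()[["T", "kind", "amplitude", "frequency", "band"]]
    return df


# ---------------------------------------------------------------------------
# Calibration of the four cortical sigmoid constants


@dataclass(frozen=True)
class CalibrationResult:
    M_E: float
    B_E: float
    M_I: float
    B_I: float
    T0: float
    omega0: float
    loop: int
    E_star: float
    cortical_loop_T: float | None   # first cortical-loop crossing delay

    def apply(self, p: ModelParameters) -> ModelParameters:
        return p.replace(M_E=self.M_E, B_E=self.B_E, M_I=self.M_I, B_I=self.B_I)


def _min_delay_of(p: ModelParameters):
    try:
        ds = analytic_minimal_delay(p)
    except (RuntimeError, ValueError):
        return None
    return ds


def calibrate_cortical_constants(
    p: ModelParameters,
    target_T0: float = 3.6807,
    tol: float = 1e-3,
    coarse: tuple[int, int, int, int] = (4, 5, 10, 6),
    max_results: int = 20,
) -> list[CalibrationResult]:
    """Grid search + bisection over (M_E, B_E, M_I, B_I) within their
    physiological ranges so that the model's minimal critical delay hits
    ``target_T0``.

    The coarse grid brackets sign changes of T0 - target along the B_E
    axis (the equilibrium cortical rate E*, and with it the critical
    delay, is monotone in B_E); each bracket is refined by bisection.
    Results are sorted by |T0 - target|, preferring completions whose
    minimal crossing is the basal-ganglia loop and for which the
    cortical loop also crosses at some larger delay (so that at long
    delays the cortex oscillates too, as observed).
    """
    (nME, nBE, nMI, nBI) = coarse
    MEs = np.linspace(*CORTICAL_RANGES["M_E"], nME)
    BEs = np.linspace(2.0, CORTICAL_RANGES["B_E"][1], nBE)
    MIs = np.linspace(max(25.0, CORTICAL_RANGES["M_I"][0]), CORTICAL_RANGES["M_I"][1], nMI)
    BIs = np.linspace(0.4, CORTICAL_RANGES["B_I"][1], nBI)
    t0 = time.perf_counter()

    def excess(ME, BE, MI, BI):
        pc = p.replace(M_E=ME, B_E=BE, M_I=MI, B_I=BI)
        ds = _min_delay_of(pc)
        if ds is None or not ds.has_crossing:
            return None, None
        return ds.T0 - target_T0, ds

    results: list[CalibrationResult] = []
    for ME in MEs:
        for MI in MIs:
            for BI in BIs:
                prev = None
                for BE in BEs:
                    f, ds = excess(ME, BE, MI, BI)
                    if f is not None and prev is not None and prev[1] is not None and np.sign(f) != np.sign(prev[1]):
                        lo, hi = prev[0], BE
                        flo = prev[1]
                        for _ in range(60):
                            mid = 0.5 * (lo + hi)
                            fm, _ = excess(ME, mid, MI, BI)
                            if fm is None:
                                break
                            if np.sign(fm) == np.sign(flo):
                                lo, flo = mid, fm
                            else:
                                hi = mid
                            if hi - lo < 1e-10:
                                break
                        BE_star = 0.5 * (lo + hi)
                        fs, ds_star = excess(ME, BE_star, MI, BI)
                        if fs is not None and abs(fs) < tol:
                            pc = p.replace(M_E=ME, B_E=BE_star, M_I=MI, B_I=BI)
                            eq = solve_equilibrium(pc, n_starts=2)
                            cortical = [c.T for c in ds_star.crossings if c.loop == 2]
                            results.append(
                                CalibrationResult(
                                    M_E=float(ME), B_E=float(BE_star), M_I=float(MI), B_I=float(BI),
                                    T0=float(ds_star.T0), omega0=float(ds_star.omega0),
                                    loop=int(ds_star.loop0), E_star=float(eq.u0[2]),
                                    cortical_loop_T=float(min(cortical)) if cortical else None,
                                )
                            )
                    prev = (BE, f)
    results.sort(
        key=lambda r: (
            abs(r.T0 - target_T0),
            r.loop != 1,
            r.cortical_loop_T is None,
        )
    )
    results.sort(key=lambda r: (r.loop != 1, r.cortical_loop_T is None, abs(r.T0 - target_T0)))
    log.info("calibration: %d completions within %.1e ms of target in %.1fs",
             len(results), tol, time.perf_counter() - t0)
    return results[:max_results]


# ---------------------------------------------------------------------------
# Fixture generation


@dataclass(frozen=True)
class FixtureSet:
    seed: int
    members: list


def generate_fixtures(seed: int, n: int, require_crossing_fraction: float = 0.3) -> FixtureSet:
    """Deterministic admissible parameter sets for tests and demos.

    Member 0 is the bundled analysis point (with its calibrated cortical
    completion and its critical delay as the set delay); member 1 is the
    same circuit with a mid-range cortical completion.  The remainder
    draws weights within +/-50% of the fitted values, inputs within
    +/-20%, cortical constants within their physiological ranges, and
    delays uniform on [1, 15] ms; enough members are rejection-sampled
    to exhibit a Hopf crossing that at least ``require_crossing_fraction``
    of the delayed members do.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    from .model_core import section3_params

    rng = np.random.default_rng(seed)
    base = section3_params()
    members = [base.replace(T=3.6807)]
    if n > 1:
        members.append(base.replace(M_E=65.0, B_E=10.0, M_I=175.0, B_I=10.0, T=5.0))

    def draw(force_crossing: bool):
        for _ in range(200):
            cand = base.replace(
                w_SG=base.w_SG * rng.uniform(0.5, 1.5),
                w_GS=base.w_GS * rng.uniform(0.5, 1.5),
                w_CC=base.w_CC * rng.uniform(0.5, 1.5),
                w_CS=base.w_CS * rng.uniform(0.5, 1.5),
                w_GG=base.w_GG * rng.uniform(0.5, 1.5),
                C=base.C * rng.uniform(0.8, 1.2),
                Str=base.Str * rng.uniform(0.8, 1.2),
                M_E=rng.uniform(55.0, 80.0),
                B_E=rng.uniform(2.0, 20.0),
                M_I=rng.uniform(25.0, 330.0),
                B_I=rng.uniform(0.5, 20.0),
                T=rng.uniform(1.0, 15.0),
            )
            if not force_crossing:
                return cand
            ds = _min_delay_of(cand)
            if ds is not None and ds.has_crossing:
                return cand
        raise RuntimeError("fixture rejection sampling exhausted")

    n_forced = int(np.ceil(require_crossing_fraction * max(n - 2, 0)))
    while len(members) < n:
        members.append(draw(force_crossing=len(members) - 2 < n_forced))
    return FixtureSet(seed=seed, members=members[:n])
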