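"""Stochastic model of cooperative thin-filament regulation.

A thin-filament strand is a linear chain of regulatory units, each in one of
three states: blocked (B, myosin binding forbidden), closed (C, weakly
permitted) or myosin-bound (M).  Transitions are first order:

    B -> C   a = k_on_max * ca^n / (ca^n + ca50^n) + theta * k_act
    C -> B   b = k_off
    C -> M   f = f_app
    M -> C   g = g_app

where theta is the fractional occupancy of an N-terminal MyBP-C fragment.
Nearest-neighbour cooperativity multiplies a unit's B->C rate by
gamma^(active neighbours) and divides its C->B rate by the same factor, so
activation spreads along the strand.  The chain is advanced by fixed-step
kinetic Monte Carlo (transition probability = rate * dt, with a stability
guard rate * dt <= 0.1); the force proxy is the fraction of units in M.

Three experimental protocols are provided: steady-state force-pCa curves,
the release-restretch tension-redevelopment (k_tr) manoeuvre, and unloaded
shortening of a twitching myocyte driven by a calcium transient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecificationError, TimestepError
from .params import IsoformEffect, ThinFilamentParams
from .trace import Trace

__all__ = [
    "Rates",
    "FilamentState",
    "effective_rates",
    "steady_state_single_unit",
    "stable_dt",
    "simulate_chain",
    "force_pca_curve",
    "simulate_ktr",
    "ca_transient",
    "integrate_shortening",
    "simulate_twitch",
]

MAX_RATE_DT = 0.1  # stability guard: largest admissible transition probability

_B, _C, _M = 0, 1, 2
_STATE_LABELS = np.array(["B", "C", "M"])


class Rates(NamedTuple):
    """Per-unit transition rates (s^-1), before neighbour coupling."""

    a: float  # B -> C
    b: float  # C -> B
    f: float  # C -> M
    g: float  # M -> C


@dataclass
class FilamentState:
    """Snapshot of one chain: integer unit states (0=B, 1=C, 2=M)."""

    unit_states: np.ndarray
    time: float
    rng_seed: int

    @property
    def labels(self) -> np.ndarray:
        return _STATE_LABELS[self.unit_states]


def _ca_activation(p: ThinFilamentParams, ca):
    """Troponin Ca occupancy (Hill equilibrium); accepts scalars or arrays."""
    can = np.asarray(ca, dtype=float) ** p.n_tn
    return can / (can + p.ca50_tn**p.n_tn)


def effective_rates(
    p: ThinFilamentParams, e: IsoformEffect, frag_conc: float, ca: float
) -> Rates:
    """Per-unit rates at a given free [Ca2+] and fragment concentration (M).

    Calcium acts through an instantaneous Hill equilibrium on troponin; the
    fragment adds a Ca-independent B->C component proportional to its
    occupancy.  Crossbridge attachment/detachment are Ca-independent.
    """
    if frag_conc < 0 or ca < 0:
        raise InvalidSpecificationError("concentrations must be >= 0")
    theta = e.occupancy(frag_conc)
    a = p.k_on_max * _ca_activation(p, ca) + theta * e.k_act
    return Rates(a=a, b=p.k_off, f=p.f_app, g=p.g_app)


def steady_state_single_unit(rates: Rates) -> tuple[float, float, float]:
    """Analytic stationary occupancy (pi_B, pi_C, pi_M) of one isolated unit.

    The chain B<->C<->M is a linear Markov chain, so detailed balance of the
    two fluxes gives pi_C = pi_B * a/b and pi_M = pi_C * f/g.  Degenerate
    cases with an absorbing state return the absorbing distribution.
    """
    a, b, f, g = rates
    if a == 0:
        return (1.0, 0.0, 0.0)
    if g == 0:
        # a > 0 and f > 0 make M absorbing; f == 0 makes {B, C} closed
        if f > 0:
            return (0.0, 0.0, 1.0)
        g = 1.0  # unused: pi_M = 0 below since f = 0
    if b == 0:
        # B drains irreversibly into {C, M}
        pi_c = 1.0 / (1.0 + f / g)
        return (0.0, pi_c, 1.0 - pi_c)
    w_b, w_c, w_m = 1.0, a / b, a * f / (b * g)
    z = w_b + w_c + w_m
    return (w_b / z, w_c / z, w_m / z)


def stable_dt(
    p: ThinFilamentParams, e: IsoformEffect, frag_conc: float, ca_max: float
) -> float:
    """Largest timestep satisfying the stability guard for these conditions."""
    r = effective_rates(p, e, frag_conc, ca_max)
    worst = max(r.a * p.gamma**2, r.b + r.f, r.g)
    if worst == 0:
        return 1e-3
    return MAX_RATE_DT / worst


def _check_dt(p, e, frag_conc, ca_max, dt) -> None:
    limit = stable_dt(p, e, frag_conc, ca_max)
    if dt > limit * (1 + 1e-12):
        raise TimestepError(
            f"dt={dt:g} s violates the stability guard (max total exit rate * dt "
            f"<= {MAX_RATE_DT}); use dt <= {limit:.3g} s",
            required_dt=limit,
        )


# ---------------------------------------------------------------------------
# Monte-Carlo kernel.  One uniform variate per unit per step decides the
# transition; updates are synchronous on the state at the start of the step.
# numba accelerates the loop when available; the pure-Python path is
# stream-identical because all randomness is drawn outside the kernel.
# ---------------------------------------------------------------------------


def _step_chunk_py(states, scratch, a_arr, b, f, g, gamma, dt, U, pm):
    n_steps, n_units = U.shape
    for s in range(n_steps):
        a = a_arr[s]
        for i in range(n_units):
            nact = 0
            if i > 0 and states[i - 1] > 0:
                nact += 1
            if i < n_units - 1 and states[i + 1] > 0:
                nact += 1
            if nact == 0:
                gf = 1.0
            elif nact == 1:
                gf = gamma
            else:
                gf = gamma * gamma
            u = U[s, i]
            st = states[i]
            new = st
            if st == 0:
                if u < a * gf * dt:
                    new = 1
            elif st == 1:
                pb = (b / gf) * dt
                if u < pb:
                    new = 0
                elif u < pb + f * dt:
                    new = 2
            else:
                if u < g * dt:
                    new = 1
            scratch[i] = new
        cnt = 0
        for i in range(n_units):
            states[i] = scratch[i]
            if states[i] == 2:
                cnt += 1
        pm[s] = cnt / n_units
    return states


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _step_chunk = njit(cache=False)(_step_chunk_py)
except Exception:  # pragma: no cover
    _step_chunk = _step_chunk_py


def _run_chain(
    p: ThinFilamentParams,
    e: IsoformEffect,
    frag_conc: float,
    ca_of_t: Callable[[np.ndarray], np.ndarray],
    ca_max: float,
    duration: float,
    dt: float | None,
    seed: int,
    record_dt: float | None,
    initial: np.ndarray | None,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance one chain for ``duration`` seconds; return (t, pi_M, final)."""
    if duration <= 0:
        raise InvalidSpecificationError("duration must be > 0")
    if dt is None:
        dt = min(1e-4, stable_dt(p, e, frag_conc, ca_max))
    _check_dt(p, e, frag_conc, ca_max, dt)
    n_steps = max(1, int(round(duration / dt)))
    if record_dt is None:
        record_dt = max(dt, duration / 20000)
    stride = max(1, int(round(record_dt / dt)))

    theta = e.occupancy(frag_conc)
    b, f, g = p.k_off, p.f_app, p.g_app
    states = (
        np.zeros(p.n_units, dtype=np.int64)
        if initial is None
        else np.asarray(initial, dtype=np.int64).copy()
    )
    scratch = np.empty_like(states)
    rng = np.random.Generator(np.random.PCG64(seed))

    chunk = 100_000
    rec_t, rec_pm = [], []
    done = 0
    while done < n_steps:
        n = min(chunk, n_steps - done)
        t_steps = t0 + (done + np.arange(n)) * dt
        ca_vals = np.asarray(ca_of_t(t_steps), dtype=float)
        a_arr = np.ascontiguousarray(
            p.k_on_max * _ca_activation(p, ca_vals) + theta * e.k_act
        )
        U = rng.random((n, p.n_units))
        pm = np.empty(n)
        _step_chunk(states, scratch, a_arr, b, f, g, p.gamma, dt, U, pm)
        # record global steps k with (k + 1) % stride == 0
        k0 = (-(done + 1)) % stride
        sel = np.arange(k0, n, stride)
        rec_t.append(t0 + (done + sel + 1) * dt)
        rec_pm.append(pm[sel])
        done += n
    return np.concatenate(rec_t), np.concatenate(rec_pm), states


def simulate_chain(
    p: ThinFilamentParams,
    e: IsoformEffect,
    frag_conc: float,
    ca: float,
    duration: float,
    dt: float | None = None,
    seed: int = 0,
    record_dt: float | None = None,
    initial: np.ndarray | None = None,
) -> tuple[Trace, FilamentState]:
    """Simulate one chain at constant free [Ca2+].

    Returns the fraction of units in M over time (the force proxy) and the
    final chain state.  Identical (params, seed) pairs give bit-identical
    traces.
    """
    if frag_conc < 0 or ca < 0:
        raise InvalidSpecificationError("concentrations must be >= 0")
    t, pm, states = _run_chain(
        p, e, frag_conc, lambda ts: np.full(len(ts), ca), ca, duration, dt, seed,
        record_dt, initial,
    )
    meta = {"seed": seed, "ca": ca, "frag_conc": frag_conc, "isoform": e.isoform}
    return Trace(t, pm, units="fraction M", meta=meta), FilamentState(states, t[-1], seed)


def force_pca_curve(
    p: ThinFilamentParams,
    e: IsoformEffect,
    frag_conc: float,
    pca_grid: Sequence[float],
    duration: float = 10.0,
    seed: int = 0,
    dt: float | None = None,
    normalized: bool = False,
    settle_frac: float = 0.5,
) -> pd.DataFrame:
    """Steady-state occupancy versus pCa.

    Each pCa level runs an independent chain (sub-seeded from ``seed``); the
    reported value is the time average of pi_M over the final
    ``1 - settle_frac`` of the simulation.  With ``normalized`` the curve is
    divided by its value at the lowest pCa (highest calcium).
    """
    pca_grid = list(pca_grid)
    if not pca_grid:
        raise InvalidSpecificationError("pca_grid must be non-empty")
    rows = []
    for i, pca in enumerate(pca_grid):
        sub_seed = (seed * 1009 + i) % 2**31
        trace, _ = simulate_chain(
            p, e, frag_conc, 10.0**-pca, duration, dt=dt, seed=sub_seed
        )
        tail = trace.y[trace.t >= settle_frac * duration]
        rows.append({"pca": pca, "pi_m": float(np.mean(tail))})
    df = pd.DataFrame(rows)
    if normalized:
        ref = df.loc[df["pca"].idxmin(), "pi_m"]
        if ref <= 0:
            raise InvalidSpecificationError("cannot normalize: zero occupancy at minimum pCa")
        df["pi_m"] = df["pi_m"] / ref
    return df


def simulate_ktr(
    p: ThinFilamentParams,
    e: IsoformEffect,
    frag_conc: float,
    ca: float,
    t_release: float,
    duration: float,
    dt: float | None = None,
    seed: int = 0,
    record_dt: float | None = None,
) -> Trace:
    """Release-restretch manoeuvre: detach every crossbridge, watch recovery.

    The chain runs to steady state for ``t_release`` seconds; at the release
    every M unit is set to C (tropomyosin positions untouched) and the
    simulation continues.  The returned trace is aligned so t = 0 is the
    release (its first sample is the post-detachment occupancy, exactly 0);
    the pre-release steady occupancy is stored in
    ``meta["pre_release_pi_m"]``.
    """
    if not 0 < t_release < duration:
        raise InvalidSpecificationError("need 0 < t_release < duration")
    t1, pm1, states = _run_chain(
        p, e, frag_conc, lambda ts: np.full(len(ts), ca), ca, t_release, dt, seed,
        record_dt, None,
    )
    plateau = float(np.mean(pm1[t1 >= 0.5 * t_release]))
    states[states == _M] = _C  # mechanical detachment
    t2, pm2, _ = _run_chain(
        p, e, frag_conc, lambda ts: np.full(len(ts), ca), ca,
        duration - t_release, dt, (seed + 1) % 2**31, record_dt, states,
    )
    t = np.concatenate([[0.0], t2])
    y = np.concatenate([[np.mean(states == _M)], pm2])
    meta = {
        "seed": seed,
        "ca": ca,
        "t_release": t_release,
        "isoform": e.isoform,
        "pre_release_pi_m": plateau,
    }
    return Trace(t, y, units="fraction M", meta=meta)


def ca_transient(
    t_grid: np.ndarray,
    pca_dia: float,
    pca_peak: float,
    tau_rise: float = 0.03,
    tau_decay: float = 0.2,
) -> Trace:
    """Two-exponential intracellular calcium transient on a time grid.

    Ca(t) = Ca_dia + A * (exp(-t/tau_decay) - exp(-t/tau_rise)) for t >= 0
    with A normalised so the maximum equals Ca_peak; Ca = Ca_dia for t < 0.
    Defaults emulate a 1-Hz paced rat ventricular myocyte at room
    temperature (rise ~30 ms, decay ~200 ms).
    """
    if pca_dia < pca_peak:
        raise InvalidSpecificationError("diastolic pCa must be >= peak pCa")
    if tau_rise >= tau_decay:
        raise InvalidSpecificationError("tau_rise must be < tau_decay")
    t_grid = np.asarray(t_grid, dtype=float)
    ca_dia, ca_peak = 10.0**-pca_dia, 10.0**-pca_peak
    y = np.full(len(t_grid), ca_dia)
    if ca_peak > ca_dia:
        t_max = (
            np.log(tau_decay / tau_rise)
            * (tau_rise * tau_decay)
            / (tau_decay - tau_rise)
        )
        peak_unit = np.exp(-t_max / tau_decay) - np.exp(-t_max / tau_rise)
        amp = (ca_peak - ca_dia) / peak_unit
        pos = t_grid >= 0
        y[pos] = ca_dia + amp * (
            np.exp(-t_grid[pos] / tau_decay) - np.exp(-t_grid[pos] / tau_rise)
        )
    return Trace(t_grid, y, units="M", meta={"pca_dia": pca_dia, "pca_peak": pca_peak})


def integrate_shortening(
    pi_m: Trace, sl_rest: float, v_eff: float, k_restore: float
) -> Trace:
    """Integrate dSL/dt = -v_eff * pi_M(t) + k_restore * (sl_rest - SL).

    Exact exponential integrator for piecewise-constant pi_M, so a
    rectangular occupancy pulse relaxes as a clean single exponential with
    rate ``k_restore`` after the pulse.
    """
    if sl_rest <= 0 or k_restore <= 0:
        raise InvalidSpecificationError("sl_rest and k_restore must be > 0")
    dt = pi_m.dt
    sl = np.empty(len(pi_m))
    sl[0] = sl_rest
    decay = np.exp(-k_restore * dt)
    for k in range(len(pi_m) - 1):
        target = sl_rest - v_eff * pi_m.y[k] / k_restore
        sl[k + 1] = target + (sl[k] - target) * decay
    return Trace(pi_m.t, sl, units="um", meta=dict(pi_m.meta))


def simulate_twitch(
    p: ThinFilamentParams,
    e: IsoformEffect,
    frag_conc: float,
    transient: Trace,
    sl_rest: float = 1.8,
    v_max: float = 2.0,
    k_restore: float = 5.0,
    dt: float | None = None,
    seed: int = 0,
) -> Trace:
    """Unloaded sarcomere-length twitch driven by a calcium transient.

    The chain is driven by the time-varying free [Ca2+]; sarcomere length
    obeys dSL/dt = -v_max (1 - drag * theta) pi_M + k_restore (sl_rest - SL),
    i.e. shortening is proportional to crossbridge occupancy with a passive
    restoring force and no external load.  Returns SL(t) on the transient's
    time grid.
    """
    if v_max <= 0:
        raise InvalidSpecificationError("v_max must be > 0")
    t_grid = transient.t
    ca_max = float(np.max(transient.y))
    duration = float(t_grid[-1] - t_grid[0])

    def ca_of_t(ts):
        return np.interp(ts, t_grid, transient.y)

    t, pm, _ = _run_chain(
        p, e, frag_conc, ca_of_t, ca_max, duration, dt, seed,
        record_dt=transient.dt, initial=None, t0=float(t_grid[0]),
    )
    pm_on_grid = np.interp(t_grid, t, pm)
    theta = e.occupancy(frag_conc)
    v_eff = v_max * (1.0 - e.drag * theta)
    pi_trace = Trace(t_grid, pm_on_grid, units="fraction M",
                     meta={"seed": seed, "isoform": e.isoform})
    sl = integrate_shortening(pi_trace, sl_rest, v_eff, k_restore)
    sl.meta.update({"sl_rest": sl_rest, "v_max": v_max, "k_restore": k_restore})
    return sl
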