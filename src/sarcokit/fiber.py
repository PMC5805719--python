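"""Fitting and quality control for permeabilized-fiber contractility data.

Covers the standard steady-state fiber workflow: force-pCa curves fitted
with a four-parameter Hill (logistic in pCa, base-10 exponent), the
tension-redevelopment rate k_tr from a single-exponential fit after a
release-restretch manoeuvre, ATPase rates from NADH-coupled absorbance
records calibrated by ADP injections, linear tension-cost fits, and the
integrity filter that excludes fibers losing more than 20% of maximal
tension over an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .errors import CalibrationError, FitError, InvalidSpecificationError
from .trace import Trace

__all__ = [
    "ForcePCaDataset",
    "HillFit",
    "ExpFit",
    "hill_curve",
    "fit_hill",
    "normalize_force",
    "fit_ktr",
    "atpase_rate",
    "tension_cost",
    "qc_fiber",
    "qc_roster",
]


@dataclass
class ForcePCaDataset:
    """One fiber's steady-state measurements across a pCa series."""

    pca: np.ndarray
    force: np.ndarray
    atpase: np.ndarray | None = None
    stiffness: np.ndarray | None = None
    fiber_id: str = ""

    def __post_init__(self):
        self.pca = np.asarray(self.pca, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.pca.shape != self.force.shape:
            raise InvalidSpecificationError("pca and force must have equal length")
        if not np.all(np.isfinite(self.pca)):
            raise InvalidSpecificationError("pca values must be finite")
        for name in ("atpase", "stiffness"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.pca.shape:
                    raise InvalidSpecificationError(f"{name} length mismatch")
                setattr(self, name, arr)


@dataclass(frozen=True)
class HillFit:
    """Result of a sigmoidal force-pCa (or dose-response) fit."""

    pca50: float
    n_h: float
    floor: float
    ceiling: float
    rss: float

    def predict(self, pca):
        return hill_curve(pca, self.pca50, self.n_h, self.floor, self.ceiling)


@dataclass(frozen=True)
class ExpFit:
    """Result of a rising single-exponential fit y = offset + amp(1-e^-rt)."""

    rate: float
    amplitude: float
    offset: float
    rss: float


def hill_curve(pca, pca50, n_h, floor=0.0, ceiling=1.0):
    """F(pCa) = floor + (ceiling-floor) / (1 + 10^(n_h (pCa - pCa50)))."""
    pca = np.asarray(pca, dtype=float)
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (n_h * (pca - pca50)))


def _hill_residual(params, pca, y):
    return (
        hill_curve(pca, params["pca50"], params["n_h"], params["floor"],
                   params["floor"] + params["delta"])
        - y
    )


def fit_hill(ds: ForcePCaDataset) -> HillFit:
    """Least-squares Hill fit of force versus pCa.

    Runs five deterministic starts over a (pCa50, n_H) grid and keeps the
    global best (ties broken by lower n_H).  The ceiling is parameterised as
    floor + delta with delta >= 0, so ceiling >= floor by construction.
    Degenerate data (no response across the pCa range) raise
    :class:`FitError` with diagnostics.
    """
    pca, y = ds.pca, ds.force
    if len(np.unique(pca)) < 4:
        raise InvalidSpecificationError("need at least 4 distinct pCa points")
    span = float(np.max(y) - np.min(y))
    if span <= 1e-12:
        raise FitError(
            "degenerate force-pCa data: response is constant",
            diagnostics={"span": span, "fiber_id": ds.fiber_id},
        )

    lo, hi = float(np.min(pca)), float(np.max(pca))
    q = lambda f: lo + f * (hi - lo)
    starts = [(q(0.3), 1.0), (q(0.5), 2.0), (q(0.5), 4.0), (q(0.7), 2.0), (q(0.4), 0.7)]

    best, tried = None, []
    for pca50_0, nh_0 in starts:
        params = lmfit.Parameters()
        params.add("pca50", value=pca50_0, min=lo - 2.0, max=hi + 2.0)
        params.add("n_h", value=nh_0, min=1e-3, max=50.0)
        params.add("floor", value=float(np.min(y)))
        params.add("delta", value=span, min=0.0)
        try:
            res = lmfit.minimize(_hill_residual, params, args=(pca, y), method="leastsq")
        except Exception as exc:  # pragma: no cover - lmfit rarely raises here
            tried.append({"start": (pca50_0, nh_0), "error": str(exc)})
            continue
        rss = float(np.sum(res.residual**2))
        cand = (rss, float(res.params["n_h"].value), res)
        tried.append({"start": (pca50_0, nh_0), "rss": rss})
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitError("Hill fit failed for all starts", diagnostics={"tried": tried})

    rss, _, res = best
    delta = float(res.params["delta"].value)
    if delta < 0.05 * span:
        raise FitError(
            "degenerate Hill fit: ceiling ~ floor, n_H unidentifiable",
            diagnostics={"delta": delta, "span": span, "tried": tried},
        )
    floor = float(res.params["floor"].value)
    return HillFit(
        pca50=float(res.params["pca50"].value),
        n_h=float(res.params["n_h"].value),
        floor=floor,
        ceiling=floor + delta,
        rss=rss,
    )


def normalize_force(raw, f_max: float) -> np.ndarray:
    """Express forces relative to the fiber's maximal tension ``f_max``."""
    if f_max <= 0:
        raise InvalidSpecificationError("f_max must be > 0")
    return np.asarray(raw, dtype=float) / f_max


def fit_ktr(trace: Trace, t_window: tuple[float, float], skip_samples: int = 2) -> ExpFit:
    """Tension-redevelopment rate from a rising-exponential fit.

    Fits y(t) = offset + amplitude (1 - e^(-rate (t - t_start))) on the
    window, starting ``skip_samples`` samples after the window opening to
    skip the restretch artifact.  Flat or shrinking records raise
    :class:`FitError`.
    """
    t0, t1 = t_window
    sub = trace.window(t0, t1)
    if len(sub) < 20:
        raise InvalidSpecificationError("k_tr window must contain >= 20 samples")
    t = sub.t[skip_samples:] - sub.t[skip_samples]
    y = sub.y[skip_samples:]
    span = float(np.ptp(y))
    if span <= 1e-12 or y[-1] <= y[0]:
        raise FitError(
            "tension redevelopment is flat or non-increasing",
            diagnostics={"span": span, "y_first": float(y[0]), "y_last": float(y[-1])},
        )

    offset0, amp0 = float(y[0]), float(y[-1] - y[0])
    # initial rate from the 63% crossing time
    cross = np.nonzero(y - offset0 >= 0.632 * amp0)[0]
    rate0 = 1.0 / max(t[cross[0]], t[1]) if len(cross) and t[cross[0]] > 0 else 1.0 / t[-1]

    model = lmfit.Model(lambda t, rate, amplitude, offset:
                        offset + amplitude * (1 - np.exp(-rate * t)))
    params = model.make_params(rate=rate0, amplitude=amp0, offset=offset0)
    params["rate"].set(min=0.0)
    try:
        res = model.fit(y, params, t=t)
    except Exception as exc:
        raise FitError(f"k_tr fit failed: {exc}") from exc
    if not res.success or res.params["amplitude"].value <= 0:
        raise FitError("k_tr fit did not converge to a rising exponential",
                       diagnostics={"report": res.fit_report()})
    return ExpFit(
        rate=float(res.params["rate"].value),
        amplitude=float(res.params["amplitude"].value),
        offset=float(res.params["offset"].value),
        rss=float(np.sum(res.residual**2)),
    )


#: moles of ADP delivered by one 50 nl injection of 10 mM ADP
ADP_PER_INJECTION = 5e-10


def atpase_rate(
    absorbance: Trace,
    injections: list[tuple[float, float]],
    step_window: float = 1.0,
) -> float:
    """ATPase rate (mol/s) from an NADH-coupled absorbance record.

    ATP hydrolysis is stoichiometrically coupled to NADH oxidation, so the
    baseline absorbance slope at 340 nm tracks ATP consumption.  Known ADP
    injections produce calibration steps; the calibration factor is the mean
    absorbance step per injected mole (steps measured as median over
    ``step_window`` seconds after minus before each injection) and the rate
    is -(baseline slope)/factor.
    """
    if not injections:
        raise InvalidSpecificationError("need at least one calibration injection")
    t, y = absorbance.t, absorbance.y

    first_inj = min(t_inj for t_inj, _ in injections)
    base = (t < first_inj - step_window) if np.any(t < first_inj - step_window) else (t < first_inj)
    if np.count_nonzero(base) < 3:
        raise InvalidSpecificationError("no baseline segment before first injection")
    slope = float(np.polyfit(t[base], y[base], 1)[0])

    # measure calibration steps on the detrended record so the ongoing NADH
    # consumption does not leak into the step estimate
    y_det = y - slope * t
    factors = []
    for t_inj, moles in injections:
        before = y_det[(t >= t_inj - step_window) & (t < t_inj)]
        after = y_det[(t > t_inj) & (t <= t_inj + step_window)]
        if len(before) < 2 or len(after) < 2:
            raise InvalidSpecificationError(f"injection at t={t_inj} lacks samples")
        step = float(np.median(after) - np.median(before))
        if step >= 0:
            raise CalibrationError(
                f"injection at t={t_inj}: absorbance step {step:+.3g} is not negative"
            )
        factors.append(-step / moles)  # A per mol, positive
    factor = float(np.mean(factors))
    return -slope / factor


def tension_cost(force, atpase) -> tuple[float, float]:
    """Ordinary least-squares line of ATPase versus force.

    Returns (slope, intercept); the slope is the tension cost.
    """
    force = np.asarray(force, dtype=float)
    atpase = np.asarray(atpase, dtype=float)
    if force.shape != atpase.shape or len(force) < 3:
        raise InvalidSpecificationError("need equal-length arrays with >= 3 points")
    if np.var(force) == 0:
        raise InvalidSpecificationError("force has zero variance; slope undefined")
    res = stats.linregress(force, atpase)
    return float(res.slope), float(res.intercept)


def qc_fiber(max_tension_pre: float, max_tension_post: float) -> bool:
    """Integrity filter: pass iff the fiber kept >= 80% of maximal tension."""
    if max_tension_pre <= 0:
        raise InvalidSpecificationError("pre-experiment maximal tension must be > 0")
    return max_tension_post / max_tension_pre >= 0.80


def qc_roster(roster) -> "pd.DataFrame":
    """Apply :func:`qc_fiber` to a table with columns (fiber_id, pre, post).

    Returns the passing subset, preserving order.
    """
    import pandas as pd

    df = pd.DataFrame(roster)
    keep = [qc_fiber(row.pre, row.post) for row in df.itertuples()]
    return df[np.asarray(keep)]
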