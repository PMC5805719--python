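"""Unloaded-shortening analysis of paced-cardiomyocyte sarcomere length.

An intact myocyte paced at 1 Hz shortens and re-lengthens freely; the
sarcomere-length (SL) trace of a beat yields peak shortening, times to
recover 10/50/90% of the deflection, and the relaxation constant tau from a
log-linear ("logarithmic") fit of the recovery phase.  Beats are averaged
across ~10 contractions before analysis.  The module also carries the
Western-blot replacement-level formula used to quantify adenoviral
replacement of endogenous protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, InvalidSpecificationError
from .trace import Trace

__all__ = [
    "TwitchMetrics",
    "average_beats",
    "twitch_metrics",
    "fit_relaxation_tau",
    "replacement_level",
    "BASELINE_WINDOW",
]

#: seconds of pre-stimulus trace used for the resting-SL baseline median
BASELINE_WINDOW = 0.1


@dataclass
class TwitchMetrics:
    """Kinetic summary of one averaged beat.

    ``t_baseline_p`` is the time after peak shortening at which the cell has
    recovered p% of the deflection back toward resting SL (so "90% baseline"
    means 90% recovered).  Unrecoverable metrics are None, never fabricated.
    """

    sl_rest: float
    peak_shortening: float  # % of resting SL
    t_peak: float
    t_baseline_10: float | None
    t_baseline_50: float | None
    t_baseline_90: float | None
    tau: float | None


def average_beats(trace: Trace, stim_times: list[float]) -> Trace:
    """Average pacing epochs of a long SL record into one beat.

    Epochs start ``BASELINE_WINDOW`` seconds before each stimulus and span
    one pacing period; they are aligned on the stimulus and averaged
    pointwise.  The returned beat has t = 0 at the stimulus.  Requires at
    least two full epochs of uniform pacing.
    """
    stim = np.sort(np.asarray(stim_times, dtype=float))
    if len(stim) < 2:
        raise InvalidSpecificationError("need at least 2 stimulus epochs")
    periods = np.diff(stim)
    if not np.allclose(periods, periods[0], rtol=1e-3):
        raise InvalidSpecificationError("pacing must be uniform")
    period = float(periods[0])
    dt = trace.dt
    n_pre = int(round(BASELINE_WINDOW / dt))
    n_len = int(round(period / dt))

    epochs = []
    for s in stim:
        i0 = int(round((s - trace.t[0]) / dt)) - n_pre
        i1 = i0 + n_len
        if i0 < 0 or i1 > len(trace):
            continue  # epoch not fully inside the record
        epochs.append(trace.y[i0:i1])
    if len(epochs) < 2:
        raise InvalidSpecificationError("fewer than 2 complete epochs inside the trace")
    lengths = {len(e) for e in epochs}
    if len(lengths) != 1:
        raise InvalidSpecificationError("mismatched epoch lengths")
    mean = np.mean(np.stack(epochs), axis=0)
    t = (np.arange(n_len) - n_pre) * dt
    return Trace(t, mean, units=trace.units,
                 meta={**trace.meta, "n_beats": len(epochs)})


def fit_relaxation_tau(
    beat: Trace,
    sl_rest: float | None = None,
    noise_floor: float | None = None,
) -> float:
    """Relaxation constant tau (s) from a log-linear fit of the recovery.

    Regresses ln(sl_rest - SL(t)) against t from peak shortening to the end
    of the beat; tau = -1/slope.  Samples with deflection at or below the
    noise floor (default 2% of the peak deflection) are excluded; fewer than
    5 usable samples raise :class:`FitError`.
    """
    if sl_rest is None:
        pre = beat.y[beat.t < 0]
        sl_rest = float(np.median(pre)) if len(pre) else float(beat.y[0])
    i_min = int(np.argmin(beat.y))
    deflection = sl_rest - beat.y[i_min]
    if deflection <= 0:
        raise FitError("no shortening below resting SL; nothing to fit")
    if noise_floor is None:
        noise_floor = 0.02 * deflection

    t = beat.t[i_min:]
    d = sl_rest - beat.y[i_min:]
    if len(t) < 10:
        raise InvalidSpecificationError("need >= 10 samples between peak and end")
    usable = d > noise_floor
    # stop at the first sample that has returned to baseline: beyond it the
    # log is noise-dominated even if SL dips again
    first_bad = np.argmax(~usable) if not usable.all() else len(usable)
    if first_bad < 5:
        raise FitError(
            "fewer than 5 usable samples in the relaxation segment",
            diagnostics={"n_usable": int(first_bad)},
        )
    t, d = t[:first_bad], d[:first_bad]
    slope = np.polyfit(t, np.log(d), 1)[0]
    if slope >= 0:
        raise FitError("relaxation segment does not decay",
                       diagnostics={"slope": float(slope)})
    return float(-1.0 / slope)


def twitch_metrics(beat: Trace) -> TwitchMetrics:
    """Extract twitch kinetics from one averaged beat (t = 0 at stimulus).

    Resting SL is the median of the ``BASELINE_WINDOW`` before the stimulus;
    recovery times are linearly interpolated between samples.  Metrics the
    beat does not reach (e.g. 90% recovery in a truncated record) are None.
    """
    pre = beat.y[(beat.t < 0) & (beat.t >= -BASELINE_WINDOW)]
    if len(pre) == 0:
        pre = beat.y[: max(2, int(round(BASELINE_WINDOW / beat.dt)))]
    sl_rest = float(np.median(pre))

    post = beat.t >= 0
    t_post, y_post = beat.t[post], beat.y[post]
    i_min = int(np.argmin(y_post))
    deflection = sl_rest - y_post[i_min]
    if deflection <= 1e-12 or i_min == len(y_post) - 1:
        raise InvalidSpecificationError("no shortening peak followed by recovery")
    t_peak = float(t_post[i_min])
    peak_pct = 100.0 * deflection / sl_rest

    def time_to_recover(p: float) -> float | None:
        target = sl_rest - (1 - p / 100.0) * deflection
        seg_t, seg_y = t_post[i_min:], y_post[i_min:]
        above = np.nonzero(seg_y >= target)[0]
        if len(above) == 0:
            return None
        j = above[0]
        if j == 0:
            return 0.0
        frac = (target - seg_y[j - 1]) / (seg_y[j] - seg_y[j - 1])
        return float(seg_t[j - 1] + frac * (seg_t[j] - seg_t[j - 1]) - t_peak)

    try:
        tau = fit_relaxation_tau(beat, sl_rest=sl_rest)
    except FitError:
        tau = None
    return TwitchMetrics(
        sl_rest=sl_rest,
        peak_shortening=peak_pct,
        t_peak=t_peak,
        t_baseline_10=time_to_recover(10),
        t_baseline_50=time_to_recover(50),
        t_baseline_90=time_to_recover(90),
        tau=tau,
    )


def replacement_level(signal_myc: float, signal_endog: float) -> float:
    """Fraction of tagged protein: myc / (myc + endogenous) densitometry."""
    if signal_myc < 0 or signal_endog < 0:
        raise InvalidSpecificationError("densitometry signals must be >= 0")
    total = signal_myc + signal_endog
    if total == 0:
        raise InvalidSpecificationError("both signals are zero")
    return signal_myc / total
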