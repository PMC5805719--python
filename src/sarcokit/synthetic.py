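"""Seeded generators emulating every input the analysis modules consume.

Each generator draws from a declared ground-truth model with Gaussian noise
and a mandatory seed, and returns (data, GroundTruth) so analyzer-vs-truth
round trips are testable without any external data.  Defaults reproduce the
study conditions of the assays they emulate: the seven-point fiber pCa
series, 10 frames/s motility movies down-sampled to 2 frames/s with 95 nm
localization jitter, NADH records calibrated by 50 nl x 10 mM ADP
injections, and 1-Hz paced myocyte twitches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecificationError
from .fiber import ADP_PER_INJECTION, ForcePCaDataset, hill_curve
from .motility import FilamentTrack
from .params import IsoformEffect, isoform_effect
from .trace import Trace

__all__ = [
    "GroundTruth",
    "PCA_GRID",
    "MotilityTruth",
    "gen_force_pca",
    "gen_tracks",
    "gen_ktr_trace",
    "gen_nadh_trace",
    "gen_twitch",
]

#: the standard fiber activation series (pCa of titrated mixtures)
PCA_GRID = (4.50, 5.11, 5.42, 5.61, 5.77, 6.00, 10.00)


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic dataset, with its seed."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "seed": self.seed, "params": self.params},
                      fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"])


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def gen_force_pca(
    pca50: float = 5.8,
    n_h: float = 2.0,
    floor: float = 0.0,
    ceiling: float = 1.0,
    noise_sd: float = 0.02,
    pca_grid=PCA_GRID,
    seed: int = 0,
    fiber_id: str = "synthetic",
) -> tuple[ForcePCaDataset, GroundTruth]:
    """Logistic force-pCa data with i.i.d. Gaussian noise, clipped to >= 0."""
    if noise_sd < 0:
        raise InvalidSpecificationError("noise_sd must be >= 0")
    rng = _rng(seed)
    pca = np.asarray(pca_grid, dtype=float)
    force = hill_curve(pca, pca50, n_h, floor, ceiling)
    force = np.clip(force + rng.normal(0.0, noise_sd, size=len(pca)), 0.0, None)
    truth = GroundTruth(
        "force_pca", seed,
        {"pca50": pca50, "n_h": n_h, "floor": floor, "ceiling": ceiling,
         "noise_sd": noise_sd, "pca_grid": list(pca)},
    )
    return ForcePCaDataset(pca=pca, force=force, fiber_id=fiber_id), truth


@dataclass(frozen=True)
class MotilityTruth:
    """Generating model for filament tracks.

    Mobile probability is logistic in pCa; a bound fragment shifts the
    half-activation point leftward in proportion to its activating rate
    (``shift_per_kact``, pCa units per s^-1 of k_act) and scales mobile
    sliding speed by (1 - drag * occupancy).  Every localization carries
    i.i.d. Gaussian jitter of 95 nm per coordinate; immobile filaments are
    stationary apart from that jitter.
    """

    v0: float = 5.0                 # um/s, uninhibited sliding speed
    frac_floor: float = 0.02
    frac_ceiling: float = 0.85
    pca50: float = 6.5
    n_h: float = 1.8
    shift_per_kact: float = 0.4     # pCa units per s^-1
    jitter_sd: float = 0.095        # um per coordinate per frame
    frame_rate: float = 10.0        # Hz (acquisition)
    duration: float = 15.0          # s per movie

    def mobile_fraction(self, pca: float, effect: IsoformEffect, frag_conc: float) -> float:
        shift = self.shift_per_kact * effect.occupancy(frag_conc) * effect.k_act
        return float(
            hill_curve(pca, self.pca50 + shift, self.n_h, self.frac_floor,
                       self.frac_ceiling)
        )

    def velocity(self, effect: IsoformEffect, frag_conc: float) -> float:
        return self.v0 * (1.0 - effect.drag * effect.occupancy(frag_conc))


def gen_tracks(
    pca: float,
    n_filaments: int,
    seed: int,
    effect: IsoformEffect | str = "none",
    frag_conc: float = 0.0,
    truth: MotilityTruth = MotilityTruth(),
    n_movies: int = 3,
) -> tuple[list[FilamentTrack], GroundTruth]:
    """Synthetic filament tracks for one (pCa, isoform, dose) condition."""
    if n_filaments < 1:
        raise InvalidSpecificationError("n_filaments must be >= 1")
    if isinstance(effect, str):
        effect = isoform_effect(effect)
    rng = _rng(seed)
    n_frames = int(round(truth.duration * truth.frame_rate)) + 1
    t = np.arange(n_frames) / truth.frame_rate
    p_mobile = truth.mobile_fraction(pca, effect, frag_conc)
    v = truth.velocity(effect, frag_conc)

    tracks = []
    for i in range(n_filaments):
        movie = f"movie{i % n_movies}"
        origin = rng.uniform(0.0, 50.0, size=2)
        mobile = rng.random() < p_mobile
        if mobile:
            phi = rng.uniform(0.0, 2 * np.pi)
            drift = np.outer(t, v * np.array([np.cos(phi), np.sin(phi)]))
        else:
            drift = np.zeros((n_frames, 2))
        pos = origin + drift + rng.normal(0.0, truth.jitter_sd, size=(n_frames, 2))
        tracks.append(
            FilamentTrack(
                filament_id=f"f{i:04d}", t=t, x=pos[:, 0], y=pos[:, 1],
                frame_rate=truth.frame_rate, movie_id=movie,
            )
        )
    gt = GroundTruth(
        "tracks", seed,
        {"pca": pca, "isoform": effect.isoform, "frag_conc": frag_conc,
         "mobile_fraction": p_mobile, "velocity": v,
         "product": p_mobile * v, "n_filaments": n_filaments},
    )
    return tracks, gt


def gen_ktr_trace(
    rate: float,
    noise_sd: float = 0.01,
    duration: float = 2.0,
    dt: float = 1e-3,
    amplitude: float = 1.0,
    offset: float = 0.0,
    seed: int = 0,
) -> tuple[Trace, GroundTruth]:
    """Rising-exponential tension redevelopment plus Gaussian noise."""
    rng = _rng(seed)
    t = np.arange(0.0, duration, dt)
    y = offset + amplitude * (1 - np.exp(-rate * t))
    y = y + rng.normal(0.0, noise_sd, size=len(t))
    truth = GroundTruth("ktr", seed, {"rate": rate, "amplitude": amplitude,
                                      "offset": offset, "noise_sd": noise_sd})
    return Trace(t, y, units="relative force", meta={"seed": seed}), truth


def gen_nadh_trace(
    atpase_rate: float,
    calib_factor: float = 4e7,
    injection_times=(20.0, 40.0),
    noise_sd: float = 0.0005,
    duration: float = 60.0,
    dt: float = 0.05,
    a0: float = 1.2,
    seed: int = 0,
) -> tuple[Trace, list[tuple[float, float]], GroundTruth]:
    """NADH absorbance record: linear consumption plus ADP calibration steps.

    ``atpase_rate`` is in mol/s, ``calib_factor`` in absorbance units per
    mole of ADP (each injection delivers 5e-10 mol and drops the absorbance
    by calib_factor * 5e-10).  Returns the trace and the injection schedule
    consumed by :func:`sarcokit.fiber.atpase_rate`.
    """
    rng = _rng(seed)
    t = np.arange(0.0, duration, dt)
    y = a0 - atpase_rate * calib_factor * t
    injections = [(float(ti), ADP_PER_INJECTION) for ti in injection_times]
    for ti, moles in injections:
        y = y - (t > ti) * calib_factor * moles
    y = y + rng.normal(0.0, noise_sd, size=len(t))
    truth = GroundTruth(
        "nadh", seed,
        {"atpase_rate": atpase_rate, "calib_factor": calib_factor,
         "injection_times": list(injection_times), "noise_sd": noise_sd},
    )
    return Trace(t, y, units="A340", meta={"seed": seed}), injections, truth


def gen_twitch(
    sl_rest: float = 1.8,
    peak_shortening_pct: float = 8.0,
    t_peak: float = 0.12,
    tau: float = 0.2,
    noise_sd: float = 0.0,
    pre: float = 0.2,
    duration: float = 1.0,
    dt: float = 1e-3,
    seed: int = 0,
) -> tuple[Trace, GroundTruth]:
    """Idealized sarcomere-length twitch: smooth descent, exponential return.

    SL sits at ``sl_rest`` before the stimulus at t = 0, descends with a
    raised-cosine profile to the peak deflection at ``t_peak`` and recovers
    exponentially with time constant ``tau``.
    """
    if tau <= 0 or t_peak <= 0:
        raise InvalidSpecificationError("tau and t_peak must be > 0")
    rng = _rng(seed)
    t = np.arange(-pre, duration - pre, dt)
    amp = sl_rest * peak_shortening_pct / 100.0
    y = np.full(len(t), sl_rest)
    rising = (t >= 0) & (t < t_peak)
    y[rising] = sl_rest - amp * np.sin(0.5 * np.pi * t[rising] / t_peak) ** 2
    rec = t >= t_peak
    y[rec] = sl_rest - amp * np.exp(-(t[rec] - t_peak) / tau)
    y = y + rng.normal(0.0, noise_sd, size=len(t))
    truth = GroundTruth(
        "twitch", seed,
        {"sl_rest": sl_rest, "peak_shortening_pct": peak_shortening_pct,
         "t_peak": t_peak, "tau": tau, "noise_sd": noise_sd},
    )
    return Trace(t, y, units="um", meta={"seed": seed, "pacing_hz": 1.0}), truth
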