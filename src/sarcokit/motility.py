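"""In vitro motility analysis of fluorescent thin-filament tracks.

The assay statistic is the product of the mean sliding velocity of mobile
filaments and the fraction of filaments that move at all; plotted against
pCa and fitted with a sigmoidal dose-response it measures calcium-dependent
thin-filament activation.  Tracks arrive as frame-indexed centroid
positions; analysis follows the conventional recipe of down-sampling the
acquisition (10 frames/s) to 2 frames/s so localization jitter does not
dominate the frame-to-frame path length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecificationError
from .fiber import ForcePCaDataset, HillFit, fit_hill

__all__ = [
    "FilamentTrack",
    "MotilityStat",
    "downsample",
    "track_velocity",
    "classify_mobile",
    "motility_statistic",
    "dose_response",
    "tracks_to_frame",
    "frame_to_tracks",
    "V_MIN_DEFAULT",
    "STRAIGHTNESS_MIN_DEFAULT",
]

#: minimum mean velocity (um/s) for a track to count as mobile
V_MIN_DEFAULT = 0.3
#: minimum net-displacement / path-length ratio for a mobile track
STRAIGHTNESS_MIN_DEFAULT = 0.5


@dataclass
class FilamentTrack:
    """Frame-indexed 2-D centroid positions of one filament (um)."""

    filament_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    movie_id: str | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) < 2:
            raise InvalidSpecificationError("a track needs at least 2 frames")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidSpecificationError("t, x, y must have equal length")
        if self.frame_rate <= 0:
            raise InvalidSpecificationError("frame_rate must be > 0")
        steps = np.diff(self.t)
        if not np.allclose(steps, 1.0 / self.frame_rate, rtol=1e-6, atol=1e-9):
            raise InvalidSpecificationError("frame spacing must equal 1/frame_rate")


@dataclass(frozen=True)
class MotilityStat:
    """Summary of one condition: velocity of movers x fraction moving."""

    mean_velocity: float
    fraction_moving: float
    product: float
    sem: float
    n_filaments: int


def downsample(track: FilamentTrack, target_rate: float) -> FilamentTrack:
    """Keep every (frame_rate/target_rate)-th frame, starting at frame 0."""
    ratio = track.frame_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise InvalidSpecificationError(
            f"frame rate {track.frame_rate} Hz is not an integer multiple of "
            f"{target_rate} Hz"
        )
    k = int(round(ratio))
    return FilamentTrack(
        filament_id=track.filament_id,
        t=track.t[::k],
        x=track.x[::k],
        y=track.y[::k],
        frame_rate=target_rate,
        movie_id=track.movie_id,
    )


def _path_steps(track: FilamentTrack) -> np.ndarray:
    return np.hypot(np.diff(track.x), np.diff(track.y))


def track_velocity(track: FilamentTrack) -> float:
    """Mean frame-to-frame path length divided by the frame interval (um/s)."""
    return float(np.mean(_path_steps(track)) * track.frame_rate)


def straightness(track: FilamentTrack) -> float:
    """Net displacement over summed path length, in [0, 1] (1 for stationary)."""
    path = float(np.sum(_path_steps(track)))
    if path == 0:
        return 1.0
    net = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    return net / path


def classify_mobile(
    track: FilamentTrack,
    v_min: float = V_MIN_DEFAULT,
    straightness_min: float = STRAIGHTNESS_MIN_DEFAULT,
) -> bool:
    """Mobile iff velocity >= v_min and straightness >= straightness_min.

    Both thresholds are inclusive.  The straightness requirement separates
    processive sliding from the near-random walk that localization jitter
    produces on a stuck filament.
    """
    return (
        track_velocity(track) >= v_min
        and straightness(track) >= straightness_min
    )


def motility_statistic(
    tracks: Sequence[FilamentTrack],
    v_min: float = V_MIN_DEFAULT,
    straightness_min: float = STRAIGHTNESS_MIN_DEFAULT,
) -> MotilityStat:
    """Mean velocity of mobile filaments x fraction moving, with SEM.

    The mean velocity is computed over mobile filaments only, so the product
    does not penalise stuck filaments twice.  When tracks carry movie labels
    the SEM is that of per-movie products (matching triplicate-experiment
    reporting); otherwise it is the SEM of mobile velocities scaled by the
    mobile fraction.
    """
    if not tracks:
        raise InvalidSpecificationError("need at least one track")
    mobile = [classify_mobile(tr, v_min, straightness_min) for tr in tracks]
    velocities = np.array([track_velocity(tr) for tr in tracks])
    frac = float(np.mean(mobile))
    v_mobile = velocities[np.asarray(mobile)]
    mean_v = float(np.mean(v_mobile)) if len(v_mobile) else 0.0
    product = mean_v * frac

    movies = {tr.movie_id for tr in tracks}
    if len(movies) > 1 and None not in movies:
        per_movie = []
        for m in sorted(movies):
            sub = [tr for tr in tracks if tr.movie_id == m]
            sub_mob = [classify_mobile(tr, v_min, straightness_min) for tr in sub]
            sub_v = np.array([track_velocity(tr) for tr in sub])[np.asarray(sub_mob)]
            sub_frac = float(np.mean(sub_mob))
            per_movie.append((float(np.mean(sub_v)) if len(sub_v) else 0.0) * sub_frac)
        sem = float(np.std(per_movie, ddof=1) / np.sqrt(len(per_movie)))
    elif len(v_mobile) > 1:
        sem = float(np.std(v_mobile, ddof=1) / np.sqrt(len(v_mobile)) * frac)
    else:
        sem = 0.0
    return MotilityStat(
        mean_velocity=mean_v,
        fraction_moving=frac,
        product=product,
        sem=sem,
        n_filaments=len(tracks),
    )


def dose_response(stats_by_pca: pd.DataFrame) -> HillFit:
    """Sigmoidal fit of the motility product versus pCa.

    ``stats_by_pca`` needs columns ``pca`` and ``product``; the fit is the
    same four-parameter Hill used for force-pCa data, and its pCa50 tracks
    calcium sensitivity.
    """
    df = pd.DataFrame(stats_by_pca)
    ds = ForcePCaDataset(
        pca=df["pca"].to_numpy(), force=df["product"].to_numpy(), fiber_id="motility"
    )
    return fit_hill(ds)


def tracks_to_frame(tracks: Sequence[FilamentTrack]) -> pd.DataFrame:
    """Long-format table (movie_id, filament_id, frame, t, x_um, y_um)."""
    rows = []
    for tr in tracks:
        for k in range(len(tr.t)):
            rows.append(
                (tr.movie_id or "", tr.filament_id, k, tr.t[k], tr.x[k], tr.y[k])
            )
    return pd.DataFrame(
        rows, columns=["movie_id", "filament_id", "frame", "t", "x_um", "y_um"]
    )


def frame_to_tracks(df: pd.DataFrame) -> list[FilamentTrack]:
    """Rebuild :class:`FilamentTrack` objects from a long-format table."""
    tracks = []
    for (movie, fid), sub in df.groupby(["movie_id", "filament_id"], sort=False):
        sub = sub.sort_values("frame")
        t = sub["t"].to_numpy(dtype=float)
        rate = 1.0 / np.median(np.diff(t))
        tracks.append(
            FilamentTrack(
                filament_id=str(fid),
                t=t,
                x=sub["x_um"].to_numpy(dtype=float),
                y=sub["y_um"].to_numpy(dtype=float),
                frame_rate=rate,
                movie_id=str(movie) if movie != "" else None,
            )
        )
    return tracks
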