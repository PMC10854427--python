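"""Spectral feature extraction for detected sounds, PCA embedding, and
assignment of localized sounds to arena zones and tracked individuals."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from shapely.geometry import Point, Polygon
from sklearn.decomposition import PCA

from .behavior import Trajectory


@dataclass
class SpectralFeatures:
    """Bioacoustic summary of one sound clip.

    peak_frequency_hz: frequency with the most power.
    center_frequency_hz: frequency below which half of the power falls.
    bandwidth90_hz: f(95% cumulative power) - f(5% cumulative power).
    duration90_s: time between 5% and 95% cumulative energy.
    inflection_points: slope sign changes of the per-frame peak-frequency
    contour. aggregate_entropy_bits: Shannon entropy of the normalized mean
    spectrum.
    """

    peak_frequency_hz: float
    center_frequency_hz: float
    bandwidth90_hz: float
    duration90_s: float
    inflection_points: int
    aggregate_entropy_bits: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _quantile_freq(freqs: np.ndarray, power: np.ndarray, q: float) -> float:
    cdf = np.cumsum(power)
    cdf = cdf / cdf[-1]
    return float(np.interp(q, cdf, freqs))


def spectral_features(clip: np.ndarray, fs: float,
                      nperseg: int = 512, overlap: float = 0.75,
                      contour_floor: float = 1e-4) -> SpectralFeatures:
    """Compute frequency, temporal, shape and entropy metrics for a clip.

    The peak-frequency contour uses a Hann STFT (default 512 samples, 75%
    overlap), keeps frames with at least ``contour_floor`` of the maximum
    frame energy, and is median-smoothed over 3 frames before counting
    inflections.
    """
    clip = np.asarray(clip, dtype=float)
    if clip.ndim != 1:
        raise ValueError("clip must be mono")
    if not np.any(clip):
        raise ValueError("all-zero clip")

    freqs, psd = signal.periodogram(clip, fs=fs)
    peak = float(freqs[np.argmax(psd)])
    center = _quantile_freq(freqs, psd, 0.50)
    bw90 = _quantile_freq(freqs, psd, 0.95) - _quantile_freq(freqs, psd, 0.05)

    energy = clip ** 2
    cume = np.cumsum(energy)
    cume = cume / cume[-1]
    t = np.arange(len(clip)) / fs
    duration90 = float(np.interp(0.95, cume, t) - np.interp(0.05, cume, t))

    nseg = min(nperseg, len(clip))
    f_stft, _, z = signal.stft(clip, fs=fs, window="hann", nperseg=nseg,
                               noverlap=int(nseg * overlap))
    frame_pow = np.abs(z) ** 2
    frame_energy = frame_pow.sum(axis=0)
    keep = frame_energy >= contour_floor * frame_energy.max()
    contour = f_stft[np.argmax(frame_pow[:, keep], axis=0)]
    if len(contour) >= 3:
        contour = signal.medfilt(contour, kernel_size=3)
    slopes = np.diff(contour)
    signs = np.sign(slopes)
    signs = signs[signs != 0]
    inflections = int(np.sum(np.diff(signs) != 0))

    mean_spec = frame_pow.mean(axis=1)
    p = mean_spec / mean_spec.sum()
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))

    return SpectralFeatures(peak, center, float(bw90), duration90,
                            inflections, entropy)


def features_to_csv(rows: Sequence[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray           # (n_components, n_kept_features)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    kept_columns: list[int]


def pca_embed(features: np.ndarray, n_components: int = 2) -> PCAResult:
    """PCA on z-scored feature columns; constant columns dropped with a
    warning."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D matrix with >= 2 rows")
    std = x.std(axis=0, ddof=0)
    kept = [j for j in range(x.shape[1]) if std[j] > 1e-12]
    if len(kept) < x.shape[1]:
        warnings.warn(
            f"dropping constant feature columns: "
            f"{[j for j in range(x.shape[1]) if j not in kept]}",
            stacklevel=2)
    if not kept:
        raise ValueError("all feature columns are constant")
    xz = (x[:, kept] - x[:, kept].mean(axis=0)) / std[kept]
    n_components = min(n_components, len(kept), x.shape[0])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(xz)
    return PCAResult(scores, pca.components_, pca.explained_variance_,
                     pca.explained_variance_ratio_, kept)


@dataclass
class ZonePlan:
    """Floor plan of behaviorally meaningful regions.

    Points below ``z_low_m`` inside the foraging polygon are the foraging
    zone; points between ``z_low_m`` and ``z_high_m`` over a perch polygon are
    the perching zone; everything else inside the arena box is flight space.
    """

    arena_min: np.ndarray
    arena_max: np.ndarray
    foraging_polygon_xy: np.ndarray      # (k, 2) floor polygon
    perch_polygons_xy: list[np.ndarray] = field(default_factory=list)
    z_low_m: float = 0.5
    z_high_m: float = 3.0

    def __post_init__(self) -> None:
        self.arena_min = np.asarray(self.arena_min, dtype=float)
        self.arena_max = np.asarray(self.arena_max, dtype=float)
        self.foraging_polygon_xy = np.asarray(self.foraging_polygon_xy,
                                              dtype=float)
        self._forage_poly = Polygon(self.foraging_polygon_xy)
        self._perch_polys = [Polygon(np.asarray(p, dtype=float))
                             for p in self.perch_polygons_xy]

    def to_dict(self) -> dict:
        return {
            "arena_min": self.arena_min.tolist(),
            "arena_max": self.arena_max.tolist(),
            "foraging_polygon_xy": self.foraging_polygon_xy.tolist(),
            "perch_polygons_xy": [np.asarray(p).tolist()
                                  for p in self.perch_polygons_xy],
            "z_low_m": self.z_low_m,
            "z_high_m": self.z_high_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZonePlan":
        return cls(
            arena_min=np.asarray(d["arena_min"]),
            arena_max=np.asarray(d["arena_max"]),
            foraging_polygon_xy=np.asarray(d["foraging_polygon_xy"]),
            perch_polygons_xy=[np.asarray(p)
                               for p in d.get("perch_polygons_xy", [])],
            z_low_m=d.get("z_low_m", 0.5),
            z_high_m=d.get("z_high_m", 3.0),
        )


def assign_zone(position: np.ndarray, plan: ZonePlan) -> str:
    """Zone of a 3D point: foraging / perching / flight / outside."""
    p = np.asarray(position, dtype=float)
    if np.any(p < plan.arena_min - 1e-9) or np.any(p > plan.arena_max + 1e-9):
        return "outside"
    pt = Point(p[0], p[1])
    if p[2] < plan.z_low_m:
        if plan._forage_poly.is_empty or plan._forage_poly.covers(pt):
            return "foraging"
        return "flight"
    if p[2] < plan.z_high_m and any(pp.covers(pt) for pp in plan._perch_polys):
        return "perching"
    return "flight"


def assign_individual(position: np.ndarray, time_s: float,
                      trajectories: Sequence[Trajectory],
                      max_distance_m: float = 0.30,
                      next_ratio: float = 1.5
                      ) -> tuple[Optional[str], str]:
    """Assign a localized sound to the individual nearest at its midpoint time.

    Assignment requires (i) the closest individual within ``max_distance_m``
    and (ii) the next-closest at least ``next_ratio`` times farther. Returns
    ``(individual_id, "ok")`` or ``(None, reason)`` with reason one of
    ``no-track``, ``too-far``, ``ambiguous``.
    """
    cands = []
    for traj in trajectories:
        p = traj.interpolate(time_s)
        if p is None:
            continue
        cands.append((float(np.linalg.norm(p - np.asarray(position))),
                      traj.individual_id))
    if not cands:
        return None, "no-track"
    cands.sort()
    d1, best = cands[0]
    if d1 > max_distance_m:
        return None, "too-far"
    if len(cands) > 1 and cands[1][0] < next_ratio * d1 * (1 - 1e-9):
        return None, "ambiguous"
    return best, "ok"
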