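"""Head-centric gaze reconstruction.

The head frame has its origin at the midpoint of the two eyes, +y toward the
beak tip, +x toward the right eye (orthogonalized against y) and +z = x cross
y. Euler angles use the intrinsic z-x'-y'' (yaw, pitch, roll) convention:
yaw about the world vertical, pitch about the head's right axis, roll about
the head's forward axis. Azimuth of a gaze direction is measured clockwise
from +y (beak) toward +x (right eye); elevation from the horizon plane.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .fusion import Correspondences, RigidTransform, fit_rigid_transform

EULER_ORDER = "ZXY"  # intrinsic yaw (z), pitch (x), roll (y)


@dataclass
class HeadCalibration:
    """Fixed mapping from a marker rigid body to the head frame.

    ``markers_head`` are the calibration marker coordinates expressed in the
    head frame; fitting them to observed markers yields the head pose.
    """

    markers_head: np.ndarray
    eye_left_head: np.ndarray
    eye_right_head: np.ndarray
    beak_head: np.ndarray

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: np.asarray(v).tolist()
                       for k, v in self.__dict__.items()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HeadCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class HeadPose:
    """Head frame at one instant: origin in world coordinates and the
    rotation mapping head-frame vectors into the world."""

    time_s: float
    origin: np.ndarray
    rotation_head_to_world: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        r = np.asarray(self.rotation_head_to_world, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        self.rotation_head_to_world = r

    @property
    def yaw_pitch_roll_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation_head_to_world).as_euler(
            EULER_ORDER, degrees=True)


@dataclass
class GazeRay:
    origin: np.ndarray
    direction: np.ndarray
    specialization: str

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero gaze direction")
        self.direction = d / n


def _head_axes(eye_l: np.ndarray, eye_r: np.ndarray,
               beak: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    origin = 0.5 * (np.asarray(eye_l, float) + np.asarray(eye_r, float))
    y = np.asarray(beak, float) - origin
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise ValueError("beak tip coincides with the eye midpoint")
    y = y / ny
    x0 = np.asarray(eye_r, float) - origin
    x = x0 - np.dot(x0, y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("beak tip lies on the eye axis (degenerate frame)")
    x = x / nx
    z = np.cross(x, y)
    # rows of R map world/calibration coords into the head frame
    return origin, np.vstack([x, y, z])


def calibrate_head(markers_cal: np.ndarray, eye_left: np.ndarray,
                   eye_right: np.ndarray, beak: np.ndarray
                   ) -> HeadCalibration:
    """Express markers and keypoints in the head frame defined by the
    morphological keypoints (eye midpoint origin, beak +y, right eye +x)."""
    markers_cal = np.asarray(markers_cal, dtype=float)
    if len(markers_cal) < 3:
        raise ValueError("need at least 3 markers")
    centered = markers_cal - markers_cal.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12):
        raise ValueError("markers are collinear")
    if np.allclose(eye_left, eye_right):
        raise ValueError("eye centers must be distinct")
    origin, rot = _head_axes(eye_left, eye_right, beak)
    to_head = lambda p: (np.asarray(p, float) - origin) @ rot.T
    return HeadCalibration(
        markers_head=to_head(markers_cal),
        eye_left_head=to_head(eye_left),
        eye_right_head=to_head(eye_right),
        beak_head=to_head(beak),
    )


def head_pose_from_markers(calib: HeadCalibration,
                           markers_world: np.ndarray,
                           time_s: float = 0.0) -> HeadPose:
    """Fit the calibrated marker template to observed markers (Kabsch)."""
    t, _ = fit_rigid_transform(
        Correspondences(calib.markers_head, np.asarray(markers_world, float)))
    return HeadPose(time_s, t.translation, t.rotation)


def horizon_correction(poses: Sequence[HeadPose]) -> list[HeadPose]:
    """Remove the per-recording median roll and pitch from every frame.

    Yaw is untouched. The corrected series has exactly zero median roll and
    pitch.
    """
    if len(poses) == 0:
        raise ValueError("need at least one pose")
    ypr = np.array([p.yaw_pitch_roll_deg for p in poses])
    med_pitch = float(np.median(ypr[:, 1]))
    med_roll = float(np.median(ypr[:, 2]))
    out = []
    for p, (yaw, pitch, roll) in zip(poses, ypr):
        r = Rotation.from_euler(
            EULER_ORDER, [yaw, pitch - med_pitch, roll - med_roll],
            degrees=True).as_matrix()
        out.append(HeadPose(p.time_s, p.origin.copy(), r))
    return out


# ---------------------------------------------------------------------------
# marker label repair
# ---------------------------------------------------------------------------

@dataclass
class RepairReport:
    sections: list[tuple[int, int]]
    permutations: list[tuple[int, ...]]
    unrepairable_boundaries: list[int]


def _pairwise_dists(frame: np.ndarray) -> np.ndarray:
    return np.linalg.norm(frame[:, None, :] - frame[None, :, :], axis=-1)


def _jump_frames(tracks: np.ndarray, jump_m: float) -> np.ndarray:
    """Frames t where any inter-marker distance changed > jump_m vs t-1."""
    t_count, k, _ = tracks.shape
    iu = np.triu_indices(k, 1)
    d = np.array([_pairwise_dists(tracks[t])[iu] for t in range(t_count)])
    missing = np.any(np.isnan(tracks.reshape(t_count, -1)), axis=1)
    jumps = np.zeros(t_count, dtype=bool)
    dd = np.abs(np.diff(d, axis=0)).max(axis=1)
    jumps[1:] = dd > jump_m
    jumps |= missing
    jumps[1:] |= missing[:-1]  # resume after a missing frame starts a section
    return np.flatnonzero(jumps)


def repair_marker_labels(tracks: np.ndarray, jump_m: float = 0.005
                         ) -> tuple[np.ndarray, RepairReport]:
    """Undo per-section marker-label permutations on one rigid body.

    ``tracks`` is (frames, k, 3) with NaN rows for missing markers, k <= 6.
    The series is split wherever any inter-marker distance changes by more
    than ``jump_m`` between adjacent frames (or a marker goes missing); each
    section is relabeled with the permutation minimizing total marker
    displacement across the preceding boundary. Boundaries whose jump cannot
    be removed by any permutation are flagged as unrepairable.
    """
    tracks = np.asarray(tracks, dtype=float)
    t_count, k, _ = tracks.shape
    if k > 6:
        raise ValueError("at most 6 markers per rigid body")
    boundaries = _jump_frames(tracks, jump_m)
    edges = [0] + [int(b) for b in boundaries] + [t_count]
    sections = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)
                if edges[i + 1] > edges[i]]
    repaired = tracks.copy()
    perms: list[tuple[int, ...]] = []
    unrepairable: list[int] = []
    prev_valid_frame: np.ndarray | None = None
    for (s, e) in sections:
        seg = repaired[s:e]
        first = seg[0]
        if np.any(np.isnan(first)) or prev_valid_frame is None:
            perms.append(tuple(range(k)))
        else:
            best, best_cost = tuple(range(k)), np.inf
            for perm in itertools.permutations(range(k)):
                cost = float(np.sum(np.linalg.norm(
                    first[list(perm)] - prev_valid_frame, axis=1)))
                if cost < best_cost:
                    best_cost, best = cost, perm
            repaired[s:e] = seg[:, list(best), :]
            perms.append(best)
            iu = np.triu_indices(k, 1)
            d_prev = _pairwise_dists(prev_valid_frame)[iu]
            d_new = _pairwise_dists(repaired[s])[iu]
            if np.max(np.abs(d_new - d_prev)) > jump_m:
                unrepairable.append(s)
        last = repaired[e - 1]
        if not np.any(np.isnan(last)):
            prev_valid_frame = last
    return repaired, RepairReport(sections, perms, unrepairable)


# ---------------------------------------------------------------------------
# gaze projection and dome density
# ---------------------------------------------------------------------------

@dataclass
class GazeSpecConfig:
    fovea_azimuth_deg: float = 75.0
    fovea_elevation_deg: float = 0.0
    red_area_azimuth_deg: tuple[float, float] = (-30.0, 30.0)
    red_area_elevation_deg: tuple[float, float] = (-90.0, -10.0)
    red_area_step_deg: float = 20.0


def gaze_direction_head(azimuth_deg: float, elevation_deg: float
                        ) -> np.ndarray:
    """Unit vector in the head frame for an (azimuth, elevation) pair."""
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    return np.array([np.sin(az) * np.cos(el),
                     np.cos(az) * np.cos(el),
                     np.sin(el)])


def project_gaze(pose: HeadPose, spec: GazeSpecConfig | None = None
                 ) -> list[GazeRay]:
    """World-frame rays for both foveas and a sampled red-area sector."""
    spec = spec or GazeSpecConfig()
    r = pose.rotation_head_to_world
    rays = [
        GazeRay(pose.origin, r @ gaze_direction_head(
            spec.fovea_azimuth_deg, spec.fovea_elevation_deg), "right_fovea"),
        GazeRay(pose.origin, r @ gaze_direction_head(
            -spec.fovea_azimuth_deg, spec.fovea_elevation_deg), "left_fovea"),
    ]
    az_lo, az_hi = spec.red_area_azimuth_deg
    el_lo, el_hi = spec.red_area_elevation_deg
    for az in np.arange(az_lo, az_hi + 1e-9, spec.red_area_step_deg):
        for el in np.arange(el_lo, el_hi + 1e-9, spec.red_area_step_deg):
            rays.append(GazeRay(pose.origin,
                                r @ gaze_direction_head(az, el), "red_area"))
    return rays


@dataclass
class DomeDensity:
    histogram: np.ndarray         # (n_el_bins, n_az_bins) counts
    azimuth_edges_deg: np.ndarray
    elevation_edges_deg: np.ndarray
    excluded_below_band: int
    excluded_outside: int

    @property
    def total_rays(self) -> int:
        return (int(self.histogram.sum()) + self.excluded_below_band
                + self.excluded_outside)

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.histogram)
        with open(path, "w") as fh:
            fh.write("# azimuth_edges_deg: "
                     + ",".join(f"{v:g}" for v in self.azimuth_edges_deg)
                     + "\n")
            fh.write("# elevation_edges_deg: "
                     + ",".join(f"{v:g}" for v in self.elevation_edges_deg)
                     + "\n")
            df.to_csv(fh, index=False, header=False)


def dome_density(rays: Sequence[GazeRay], centroid: np.ndarray,
                 dome_diameter_m: float = 20.0,
                 n_azimuth_bins: int = 36, n_elevation_bins: int = 15,
                 elevation_band_deg: tuple[float, float] = (15.0, 90.0)
                 ) -> DomeDensity:
    """Histogram of ray intersections with a hemispherical sky dome.

    Each ray is intersected with the sphere of radius ``dome_diameter_m / 2``
    about the group centroid (forward branch). Intersections below the
    elevation band are excluded but counted, as are rays whose origin lies
    outside the dome.
    """
    centroid = np.asarray(centroid, dtype=float)
    radius = dome_diameter_m / 2.0
    el_lo, el_hi = elevation_band_deg
    az_edges = np.linspace(0.0, 360.0, n_azimuth_bins + 1)
    el_edges = np.linspace(el_lo, el_hi, n_elevation_bins + 1)
    hist = np.zeros((n_elevation_bins, n_azimuth_bins))
    below = outside = 0
    for ray in rays:
        o = ray.origin - centroid
        if np.linalg.norm(o) > radius:
            outside += 1
            continue
        d = ray.direction
        # |o + t d|^2 = r^2 with |d| = 1 -> t^2 + 2 t (o.d) + |o|^2 - r^2 = 0
        b = float(np.dot(o, d))
        disc = b * b - (float(np.dot(o, o)) - radius ** 2)
        t = -b + np.sqrt(max(disc, 0.0))
        q = o + t * d
        el = np.degrees(np.arctan2(q[2], np.hypot(q[0], q[1])))
        if el < el_lo or el > el_hi:
            below += 1
            continue
        az = np.degrees(np.arctan2(q[1], q[0])) % 360.0
        i_el = min(int((el - el_lo) / (el_hi - el_lo) * n_elevation_bins),
                   n_elevation_bins - 1)
        i_az = min(int(az / 360.0 * n_azimuth_bins), n_azimuth_bins - 1)
        hist[i_el, i_az] += 1
    return DomeDensity(hist, az_edges, el_edges, below, outside)
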