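"""Trajectory analytics: speed, behavior classes, synchronized foraging
initiations, Jaccard similarity and directional-correlation leadership
networks.

Behavior classes follow height/speed thresholds with half-open boundary
conventions: foraging ``z < z_low``; perching ``z_low <= z < z_high`` and
``v < v_split``; flying ``z >= z_low`` and ``v >= v_split``; everything else
(high and slow) is labelled ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

LABELS = ("perching", "foraging", "flying", "other")


@dataclass
class Trajectory:
    """Uniformly sampled 3D track of one individual.

    ``positions`` is (n, 3) meters; ``quaternions`` optionally holds unit
    orientation quaternions (n, 4) as ``qw, qx, qy, qz``. ``labels`` may carry
    per-frame ground-truth behavior labels (synthetic scenes).
    """

    individual_id: str
    times_s: np.ndarray
    positions: np.ndarray
    frame_rate_hz: float
    quaternions: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times_s), 3):
            raise ValueError("positions must be (n, 3) matching times")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.quaternions is not None:
            self.quaternions = np.asarray(self.quaternions, dtype=float)
            if self.quaternions.shape != (len(self.times_s), 4):
                raise ValueError("quaternions must be (n, 4)")

    def __len__(self) -> int:
        return len(self.times_s)

    def interpolate(self, t_s: float) -> Optional[np.ndarray]:
        """Linear position at time ``t_s``; None outside the track's span."""
        if not (self.times_s[0] <= t_s <= self.times_s[-1]):
            return None
        return np.array([
            np.interp(t_s, self.times_s, self.positions[:, k])
            for k in range(3)
        ])


def trajectories_to_csv(trajectories: Sequence[Trajectory], path) -> None:
    """Write tracks as ``frame,time_s,id,x_m,y_m,z_m[,qw,qx,qy,qz]``."""
    frames = []
    with_quat = any(t.quaternions is not None for t in trajectories)
    for traj in trajectories:
        df = pd.DataFrame({
            "frame": np.arange(len(traj)),
            "time_s": traj.times_s,
            "id": traj.individual_id,
            "x_m": traj.positions[:, 0],
            "y_m": traj.positions[:, 1],
            "z_m": traj.positions[:, 2],
        })
        if with_quat:
            q = traj.quaternions
            if q is None:
                q = np.tile([1.0, 0.0, 0.0, 0.0], (len(traj), 1))
            df["qw"], df["qx"], df["qy"], df["qz"] = q.T
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")


def trajectories_from_csv(path, frame_rate_hz: float | None = None
                          ) -> list[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "time_s", "id", "x_m", "y_m", "z_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    has_quat = {"qw", "qx", "qy", "qz"} <= set(df.columns)
    out = []
    for ind, sub in df.groupby("id", sort=False):
        sub = sub.sort_values("frame")
        t = sub["time_s"].to_numpy(dtype=float)
        if frame_rate_hz is None:
            fr = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        else:
            fr = frame_rate_hz
        out.append(Trajectory(
            individual_id=str(ind),
            times_s=t,
            positions=sub[["x_m", "y_m", "z_m"]].to_numpy(dtype=float),
            frame_rate_hz=fr,
            quaternions=(sub[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
                         if has_quat else None),
        ))
    return out


@dataclass
class BehaviorThresholds:
    z_low_m: float = 0.5
    z_high_m: float = 3.0
    v_split_mps: float = 1.0
    dt_sync_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.z_low_m < self.z_high_m):
            raise ValueError("need 0 < z_low < z_high")
        if self.v_split_mps <= 0 or self.dt_sync_s <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class BehaviorSeries:
    individual_id: str
    times_s: np.ndarray
    labels: np.ndarray  # str array over LABELS
    thresholds: BehaviorThresholds


def compute_speed(traj: Trajectory, smooth_window_s: float = 0.2) -> np.ndarray:
    """Per-frame speed from central differences, moving-average smoothed.

    Endpoints use one-sided differences (as np.gradient does). Raises on
    irregular timestamps.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames")
    dts = np.diff(traj.times_s)
    if np.max(np.abs(dts - dts[0])) > 1e-6 * max(dts[0], 1e-12):
        raise ValueError("irregular timestamps")
    vel = np.gradient(traj.positions, traj.times_s, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    win = int(round(smooth_window_s * traj.frame_rate_hz))
    if win > 1:
        speed = uniform_filter1d(speed, size=win, mode="nearest")
    return speed


def classify_behavior(traj: Trajectory,
                      thresholds: BehaviorThresholds | None = None,
                      speed: np.ndarray | None = None,
                      smooth_window_s: float = 0.2) -> BehaviorSeries:
    """Label every frame as perching / foraging / flying / other."""
    th = thresholds or BehaviorThresholds()
    v = compute_speed(traj, smooth_window_s) if speed is None else speed
    z = traj.positions[:, 2]
    labels = np.full(len(traj), "other", dtype=object)
    labels[z < th.z_low_m] = "foraging"
    labels[(z >= th.z_low_m) & (v >= th.v_split_mps)] = "flying"
    labels[(z >= th.z_low_m) & (z < th.z_high_m)
           & (v < th.v_split_mps)] = "perching"
    return BehaviorSeries(traj.individual_id, traj.times_s,
                          labels.astype(str), th)


@dataclass
class ForagingEvent:
    start_time_s: float
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _foraging_arrivals(series: BehaviorSeries) -> np.ndarray:
    is_forage = series.labels == "foraging"
    prev = np.concatenate([[False], is_forage[:-1]])
    return series.times_s[is_forage & ~prev]


def foraging_initiations(series_list: Sequence[BehaviorSeries],
                         dt_threshold_s: float = 10.0) -> list[ForagingEvent]:
    """Chain foraging arrivals whose consecutive gaps are below the threshold.

    An arrival is a transition into the foraging class. Arrivals are chained
    while the gap between consecutive arrivals is strictly below
    ``dt_threshold_s``; each chain is one synchronized initiation event, and an
    individual is counted once per event even if it re-enters.
    """
    arrivals: list[tuple[float, str]] = []
    for s in series_list:
        for t in _foraging_arrivals(s):
            arrivals.append((float(t), s.individual_id))
    arrivals.sort()
    events: list[ForagingEvent] = []
    for t, ind in arrivals:
        if events and t - events[-1]._last_arrival < dt_threshold_s:  # type: ignore[attr-defined]
            ev = events[-1]
            if ind not in ev.member_ids:
                ev.member_ids.append(ind)
            ev._last_arrival = t  # type: ignore[attr-defined]
        else:
            ev = ForagingEvent(start_time_s=t, member_ids=[ind])
            ev._last_arrival = t  # type: ignore[attr-defined]
            events.append(ev)
    return events


@dataclass
class JaccardResult:
    per_category: dict[str, float]
    overall: float      # ratio of summed intersections to summed unions
    mean_category: float


def jaccard_similarity(series_i: BehaviorSeries,
                       series_j: BehaviorSeries) -> JaccardResult:
    """Per-category and overall Jaccard indices of two label series."""
    if (len(series_i.times_s) != len(series_j.times_s)
            or not np.allclose(series_i.times_s, series_j.times_s)):
        raise ValueError("series must share a common time base")
    per = {}
    both_total = either_total = 0
    for cat in LABELS:
        in_i = series_i.labels == cat
        in_j = series_j.labels == cat
        both = int(np.sum(in_i & in_j))
        either = int(np.sum(in_i | in_j))
        both_total += both
        either_total += either
        if either > 0:
            per[cat] = both / either
    overall = both_total / either_total if either_total else float("nan")
    mean_cat = float(np.mean(list(per.values()))) if per else float("nan")
    return JaccardResult(per, overall, mean_cat)


def _unit_velocities(traj: Trajectory, v_min: float,
                     smooth_window_s: float) -> tuple[np.ndarray, np.ndarray]:
    vel = np.gradient(traj.positions, traj.times_s, axis=0)
    speed = compute_speed(traj, smooth_window_s)
    mask = speed >= v_min
    unit = np.zeros_like(vel)
    nz = np.linalg.norm(vel, axis=1) > 0
    unit[nz] = vel[nz] / np.linalg.norm(vel[nz], axis=1, keepdims=True)
    return unit, mask


def directional_correlation(traj_i: Trajectory, traj_j: Trajectory,
                            tau_range_s: tuple[float, float] = (-2.0, 2.0),
                            v_min_mps: float = 1.0,
                            smooth_window_s: float = 0.2,
                            frame_slice: slice | None = None,
                            min_frames: int = 1
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Directional correlation with delay, ``C(tau) = <v_i(t) . v_j(t+tau)>``.

    Averages unit flight-velocity dot products over all frames where both
    individuals are in flight (speed >= ``v_min_mps``). Returns ``(taus, C)``;
    both empty when the pair shares no flight frames at any delay.
    """
    if len(traj_i) != len(traj_j) or not np.allclose(traj_i.times_s,
                                                     traj_j.times_s):
        raise ValueError("trajectories must share a common time base")
    fr = traj_i.frame_rate_hz
    ui, mi = _unit_velocities(traj_i, v_min_mps, smooth_window_s)
    uj, mj = _unit_velocities(traj_j, v_min_mps, smooth_window_s)
    if frame_slice is not None:
        sel = np.zeros(len(traj_i), dtype=bool)
        sel[frame_slice] = True
        mi = mi & sel
        mj = mj & sel
    lo = int(round(tau_range_s[0] * fr))
    hi = int(round(tau_range_s[1] * fr))
    shifts = np.arange(lo, hi + 1)
    taus, cs = [], []
    n = len(traj_i)
    for s in shifts:
        # frames t where t valid for i and t+s valid for j
        t0, t1 = max(0, -s), min(n, n - s)
        if t1 <= t0:
            continue
        valid = mi[t0:t1] & mj[t0 + s:t1 + s]
        if valid.sum() < max(min_frames, 1):
            continue
        dots = np.sum(ui[t0:t1][valid] * uj[t0 + s:t1 + s][valid], axis=1)
        taus.append(s / fr)
        cs.append(float(np.mean(dots)))
    return np.asarray(taus), np.asarray(cs)


@dataclass
class HCSNetwork:
    """Symmetric leadership/coordination network; edge weight is total
    highly-correlated-segment duration in seconds."""

    graph: nx.Graph
    c_min: float
    window_s: float
    tau_range_s: tuple[float, float]

    def edge_weight(self, i: str, j: str) -> float:
        if self.graph.has_edge(i, j):
            return self.graph[i][j]["weight_s"]
        return 0.0

    def to_edgelist_csv(self, path) -> None:
        rows = [{"id_i": u, "id_j": v, "weight_s": d["weight_s"]}
                for u, v, d in self.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["id_i", "id_j", "weight_s"]).to_csv(
            path, index=False)


def hcs_network(trajectories: Sequence[Trajectory], c_min: float = 0.9,
                window_s: float = 2.0,
                tau_range_s: tuple[float, float] = (-2.0, 2.0),
                v_min_mps: float = 1.0) -> HCSNetwork:
    """Network of summed highly-correlated-segment durations per pair.

    The common timeline is tiled into consecutive ``window_s`` windows; a
    window is highly correlated when ``max_tau C(tau) >= c_min`` computed over
    the pair's flight frames inside that window.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 individuals")
    g = nx.Graph()
    for t in trajectories:
        g.add_node(t.individual_id)
    for a in range(len(trajectories)):
        for b in range(a + 1, len(trajectories)):
            ti, tj = trajectories[a], trajectories[b]
            n = min(len(ti), len(tj))
            win = int(round(window_s * ti.frame_rate_hz))
            total = 0.0
            for s0 in range(0, n - win + 1, win):
                taus, cs = directional_correlation(
                    ti, tj, tau_range_s, v_min_mps,
                    frame_slice=slice(s0, s0 + win), min_frames=win // 2)
                if len(cs) and np.max(cs) >= c_min:
                    total += window_s
            if total > 0:
                g.add_edge(ti.individual_id, tj.individual_id, weight_s=total)
    return HCSNetwork(g, c_min, window_s, tau_range_s)
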