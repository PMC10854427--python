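"""Acoustic event detection, TDOA estimation and 3D source multilateration.

The processing chain mirrors a ceiling microphone array pipeline: band-pass
filter, energy-envelope event detection on one channel, automatic channel
selection by SNR, cross-correlation time-delay estimation against a reference
channel, and over-determined nonlinear least-squares localization with a
leave-one-receiver-out spread as a relative error estimate.

All positions are in meters, times in seconds. TOAD vectors are arrival-time
differences relative to a reference channel (``tau[ref] == 0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal


class DegenerateArrayError(ValueError):
    """Raised when the receiver set cannot support the requested solve."""


@dataclass
class MicArray:
    """Receiver geometry plus acquisition parameters.

    Parameters
    ----------
    ids : sequence of str
        One identifier per receiver.
    positions : (n, 3) array
        Receiver coordinates in the acoustic frame, meters.
    fs_hz : float
        Sample rate of the associated recordings.
    speed_of_sound_m_s : float
        Propagation speed used for localization.
    """

    ids: list[str]
    positions: np.ndarray
    fs_hz: float = 100_000.0
    speed_of_sound_m_s: float = 343.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.ids) != len(self.positions):
            raise ValueError("ids and positions length mismatch")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        if np.any(d < 1e-9):
            raise ValueError("receiver positions must be distinct")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "MicArray":
        idx = list(indices)
        return MicArray(
            ids=[self.ids[i] for i in idx],
            positions=self.positions[idx],
            fs_hz=self.fs_hz,
            speed_of_sound_m_s=self.speed_of_sound_m_s,
        )

    @classmethod
    def from_csv(cls, path, fs_hz: float = 100_000.0,
                 speed_of_sound_m_s: float = 343.0) -> "MicArray":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("id", "x", "y", "z"):
            if col not in df.columns:
                raise ValueError(f"mic CSV missing column {col!r}")
        return cls(
            ids=[str(i) for i in df["id"]],
            positions=df[["x", "y", "z"]].to_numpy(dtype=float),
            fs_hz=fs_hz,
            speed_of_sound_m_s=speed_of_sound_m_s,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "id": self.ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        ).to_csv(path, index=False, float_format="%.17g")


@dataclass
class AudioBlock:
    """Synchronized multichannel samples, shape (channels, time)."""

    samples: np.ndarray
    fs_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time_to_index(self, t_s: float) -> int:
        return int(round((t_s - self.start_time_s) * self.fs_hz))


@dataclass
class LocalizationResult:
    position: np.ndarray
    residual_rms_s: float
    residuals_s: np.ndarray
    at_bounds: bool = False

    def __iter__(self):
        # allow (position, rms, residuals) unpacking
        return iter((self.position, self.residual_rms_s, self.residuals_s))


@dataclass
class SoundEvent:
    """A detected sound with optional localization and downstream annotations."""

    t_start_s: float
    t_end_s: float
    ref_channel: Optional[int] = None
    channels: Optional[list[int]] = None
    toads_s: Optional[np.ndarray] = None
    est_position: Optional[np.ndarray] = None
    residual_rms_s: Optional[float] = None
    jackknife_spread_m: Optional[float] = None
    snr_db: Optional[float] = None
    features: Optional[dict] = None
    assigned_id: Optional[str] = None
    assignment_reason: Optional[str] = None
    zone: Optional[str] = None

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError("t_end_s must exceed t_start_s")

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SoundEvent":
        d = dict(d)
        for key in ("toads_s", "est_position"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def events_to_json(events: Sequence[SoundEvent], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=1)


def events_from_json(path) -> list[SoundEvent]:
    with open(path) as fh:
        return [SoundEvent.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# filtering and detection
# ---------------------------------------------------------------------------

def bandpass_filter(audio: AudioBlock, low_hz: float, high_hz: float,
                    order: int = 4) -> AudioBlock:
    """Zero-phase Butterworth band-pass; ``low_hz <= 0`` degrades to low-pass.

    Length is preserved (forward-backward filtering).
    """
    nyq = audio.fs_hz / 2.0
    if high_hz <= low_hz or high_hz >= nyq or low_hz < 0:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] for fs={audio.fs_hz}"
        )
    if low_hz <= 0:
        sos = signal.butter(order, high_hz / nyq, btype="low", output="sos")
    else:
        sos = signal.butter(
            order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos"
        )
    filtered = signal.sosfiltfilt(sos, audio.samples, axis=-1)
    return AudioBlock(filtered, audio.fs_hz, audio.start_time_s)


@dataclass
class DetectorParams:
    envelope_window_s: float = 0.005
    threshold_k: float = 8.0
    min_duration_s: float = 0.005
    merge_gap_s: float = 0.01


def _envelope(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    win = max(1, int(round(window_s * fs)))
    kernel = np.ones(win) / win
    return np.sqrt(np.convolve(x * x, kernel, mode="same"))


def detect_events(audio: AudioBlock, channel: int = 0,
                  params: DetectorParams | None = None) -> list[tuple[float, float]]:
    """Detect events where the energy envelope exceeds ``median + k*MAD``.

    Returns sorted, non-overlapping ``(t_start, t_end)`` pairs in absolute
    seconds. Events separated by less than ``merge_gap_s`` are fused; events
    shorter than ``min_duration_s`` are dropped.
    """
    if params is None:
        params = DetectorParams()
    if audio.n_samples == 0:
        return []
    x = audio.samples[channel]
    env = _envelope(x, audio.fs_hz, params.envelope_window_s)
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    thresh = med + params.threshold_k * max(mad, 1e-30)
    above = env > thresh
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    runs = list(zip(starts, ends))
    # fuse runs closer than the merge gap
    gap = int(round(params.merge_gap_s * audio.fs_hz))
    fused: list[list[int]] = []
    for s, e in runs:
        if fused and s - fused[-1][1] < gap:
            fused[-1][1] = e
        else:
            fused.append([s, e])
    min_len = int(round(params.min_duration_s * audio.fs_hz))
    out = []
    for s, e in fused:
        if e - s >= min_len:
            out.append(
                (audio.start_time_s + s / audio.fs_hz,
                 audio.start_time_s + e / audio.fs_hz)
            )
    return out


# ---------------------------------------------------------------------------
# SNR and channel selection
# ---------------------------------------------------------------------------

def compute_snr(audio: AudioBlock, event: tuple[float, float],
                channel: int) -> float:
    """SNR in dB: event power over an equal-length pre-event noise window."""
    t0, t1 = event
    i0, i1 = audio.time_to_index(t0), audio.time_to_index(t1)
    n = i1 - i0
    if n <= 0:
        raise ValueError("empty event window")
    if i0 - n < 0:
        raise ValueError("no pre-event noise window of equal length")
    x = audio.samples[channel]
    p_event = float(np.mean(x[i0:i1] ** 2))
    p_noise = float(np.mean(x[i0 - n:i0] ** 2))
    if p_noise <= 0:
        raise ValueError("zero noise power in pre-event window")
    return 10.0 * np.log10(p_event / p_noise)


def select_channels(audio: AudioBlock, event: tuple[float, float],
                    min_snr_db: float = 6.0,
                    min_channels: int = 8) -> list[int]:
    """Channels whose event SNR clears ``min_snr_db``; top-up to ``min_channels``.

    Channels without a valid noise window or with zero noise power fall back to
    -inf SNR and are only used to top up.
    """
    snrs = np.full(audio.n_channels, -np.inf)
    for ch in range(audio.n_channels):
        try:
            snrs[ch] = compute_snr(audio, event, ch)
        except ValueError:
            pass
    passing = [ch for ch in range(audio.n_channels) if snrs[ch] >= min_snr_db]
    if len(passing) >= min_channels:
        return sorted(passing)
    order = np.argsort(snrs)[::-1]
    k = min(min_channels, audio.n_channels)
    return sorted(int(c) for c in order[:k])


def pick_loudest_channel(audio: AudioBlock, event: tuple[float, float]) -> int:
    """Channel with maximum RMS inside the event window; ties -> lowest index."""
    i0 = max(0, audio.time_to_index(event[0]))
    i1 = min(audio.n_samples, audio.time_to_index(event[1]))
    if i1 <= i0:
        raise ValueError("event outside audio block")
    rms = np.sqrt(np.mean(audio.samples[:, i0:i1] ** 2, axis=1))
    return int(np.argmax(rms))


# ---------------------------------------------------------------------------
# TOAD estimation
# ---------------------------------------------------------------------------

def _xcorr_delay(x: np.ndarray, ref: np.ndarray, fs: float,
                 max_lag: int, phat: bool = False) -> float:
    """Delay of x relative to ref (positive: x arrives later), sub-sample."""
    if phat:
        n = len(x) + len(ref) - 1
        nfft = 1 << (n - 1).bit_length()
        X = np.fft.rfft(x, nfft)
        R = np.fft.rfft(ref, nfft)
        cs = X * np.conj(R)
        mag = np.abs(cs)
        cs = cs / np.maximum(mag, 1e-30)
        cc = np.fft.irfft(cs, nfft)
        cc = np.concatenate([cc[-(len(ref) - 1):], cc[:len(x)]])
    else:
        cc = signal.correlate(x, ref, mode="full", method="fft")
    lags = np.arange(-len(ref) + 1, len(x))
    keep = np.abs(lags) <= max_lag
    cc, lags = cc[keep], lags[keep]
    if np.allclose(cc, 0):
        raise ValueError("flat cross-correlation (all-zero signal?)")
    peak = np.max(cc)
    # tie-break equal peaks toward the smaller |lag|
    cand = np.flatnonzero(cc >= peak * (1 - 1e-12))
    k = int(cand[np.argmin(np.abs(lags[cand]))])
    lag = float(lags[k])
    if 0 < k < len(cc) - 1:
        y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-30:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) < 1:
                lag += delta
    return lag / fs


def estimate_toads(audio: AudioBlock, event: tuple[float, float],
                   channels: Sequence[int], ref_channel: int | None = None,
                   max_delay_s: float | None = None,
                   pad_s: float = 0.01, phat: bool = False) -> np.ndarray:
    """Cross-correlation TOADs for ``channels`` relative to ``ref_channel``.

    ``tau[i]`` is the arrival-time of channel ``channels[i]`` minus that of the
    reference (so the entry for the reference channel is exactly 0). Peak
    position is refined by 3-point parabolic interpolation.
    """
    channels = list(channels)
    if len(channels) < 2:
        raise ValueError("need at least 2 channels")
    if ref_channel is None:
        ref_channel = pick_loudest_channel(audio, event)
        if ref_channel not in channels:
            channels = sorted(channels + [ref_channel])
    if ref_channel not in channels:
        raise ValueError("reference channel must be among selected channels")
    i0 = max(0, audio.time_to_index(event[0]) - int(pad_s * audio.fs_hz))
    i1 = min(audio.n_samples,
             audio.time_to_index(event[1]) + int(pad_s * audio.fs_hz))
    if max_delay_s is None:
        max_lag = (i1 - i0) - 1
    else:
        max_lag = int(np.ceil(max_delay_s * audio.fs_hz)) + 1
    ref = audio.samples[ref_channel, i0:i1]
    taus = np.zeros(len(channels))
    for j, ch in enumerate(channels):
        if ch == ref_channel:
            continue
        taus[j] = _xcorr_delay(audio.samples[ch, i0:i1], ref,
                               audio.fs_hz, max_lag, phat=phat)
    return taus


# ---------------------------------------------------------------------------
# multilateration
# ---------------------------------------------------------------------------

def toads_from_position(position: np.ndarray, mic_array: MicArray,
                        ref: int = 0) -> np.ndarray:
    """Forward model: geometric TOADs of a source at ``position``."""
    d = np.linalg.norm(mic_array.positions - np.asarray(position), axis=1)
    return (d - d[ref]) / mic_array.speed_of_sound_m_s


def _toad_residuals(x: np.ndarray, mics: np.ndarray, ref: int,
                    toads: np.ndarray, c: float) -> np.ndarray:
    d = np.linalg.norm(mics - x, axis=1)
    return (d - d[ref]) / c - toads


def localize_source(toads: np.ndarray, mic_array: MicArray,
                    bounds: np.ndarray | None = None, ref: int = 0,
                    grid_step_m: float = 0.5) -> LocalizationResult:
    """Bounded least-squares source position from a TOAD vector.

    Minimizes ``sum_i ((|x-m_i| - |x-m_ref|)/c - tau_i)^2`` over the bounding
    box, seeding a local solver from the best point of a coarse grid.

    Parameters
    ----------
    toads : (n,) array
        Arrival-time differences, seconds, relative to receiver ``ref``.
    bounds : (2, 3) array, optional
        ``[[xmin, ymin, zmin], [xmax, ymax, zmax]]`` search box. Defaults to
        the receiver bounding box padded by 1 m.
    """
    toads = np.asarray(toads, dtype=float)
    mics = mic_array.positions
    finite = np.isfinite(toads)
    if finite.sum() < 4:
        raise DegenerateArrayError("need >= 4 receivers with finite TOADs")
    if not finite.all():
        if not finite[ref]:
            raise ValueError("reference receiver TOAD must be finite")
        sub_idx = np.flatnonzero(finite)
        sub = mic_array.subset(sub_idx)
        new_ref = int(np.searchsorted(sub_idx, ref))
        res = localize_source(toads[finite], sub, bounds=bounds, ref=new_ref,
                              grid_step_m=grid_step_m)
        full = np.full(len(toads), np.nan)
        full[finite] = res.residuals_s
        return LocalizationResult(res.position, res.residual_rms_s, full,
                                  res.at_bounds)

    c = mic_array.speed_of_sound_m_s
    if bounds is None:
        lo = mics.min(axis=0) - 1.0
        hi = mics.max(axis=0) + 1.0
    else:
        bounds = np.asarray(bounds, dtype=float)
        lo, hi = bounds[0], bounds[1]

    # coarse grid seed
    axes = [np.unique(np.clip(
        np.arange(lo[k], hi[k] + grid_step_m, grid_step_m), lo[k], hi[k]))
        for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.linalg.norm(grid[:, None, :] - mics[None, :, :], axis=-1)
    pred = (d - d[:, ref:ref + 1]) / c
    cost = np.sum((pred - toads) ** 2, axis=1)
    x0 = grid[np.argmin(cost)]

    sol = optimize.least_squares(
        _toad_residuals, x0, args=(mics, ref, toads, c),
        bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    residuals = _toad_residuals(sol.x, mics, ref, toads, c)
    rms = float(np.sqrt(np.mean(residuals ** 2)))
    at_bounds = bool(np.any(np.isclose(sol.x, lo, atol=1e-6)) or
                     np.any(np.isclose(sol.x, hi, atol=1e-6)))
    return LocalizationResult(sol.x, rms, residuals, at_bounds)


def jackknife_error(toads: np.ndarray, mic_array: MicArray,
                    bounds: np.ndarray | None = None, ref: int = 0,
                    grid_step_m: float = 0.5) -> float:
    """Leave-one-receiver-out localization spread (RMS distance to centroid)."""
    toads = np.asarray(toads, dtype=float)
    n = len(toads)
    if n < 5:
        raise DegenerateArrayError("jackknife needs >= 5 receivers")
    solutions = []
    for drop in range(n):
        keep = [i for i in range(n) if i != drop]
        sub = mic_array.subset(keep)
        t = toads[keep]
        if drop == ref:
            new_ref = 0
            t = t - t[new_ref]
        else:
            new_ref = keep.index(ref)
        res = localize_source(t, sub, bounds=bounds, ref=new_ref,
                              grid_step_m=grid_step_m)
        solutions.append(res.position)
    pts = np.asarray(solutions)
    centroid = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def localize_events(audio: AudioBlock, mic_array: MicArray,
                    band: tuple[float, float] | None = (300.0, 15_000.0),
                    detector: DetectorParams | None = None,
                    detect_channel: int | None = None,
                    min_snr_db: float = 6.0, min_channels: int = 8,
                    bounds: np.ndarray | None = None,
                    jackknife: bool = False) -> list[SoundEvent]:
    """Full chain: filter, detect, select channels, TOADs, localize."""
    if audio.n_channels != len(mic_array):
        raise ValueError("channel count does not match receiver count")
    proc = bandpass_filter(audio, *band) if band else audio
    if detect_channel is None:
        rms = np.sqrt(np.mean(proc.samples ** 2, axis=1))
        detect_channel = int(np.argmax(rms))
    events = []
    diam = np.max(np.linalg.norm(
        mic_array.positions[:, None] - mic_array.positions[None, :], axis=-1))
    max_delay = diam / mic_array.speed_of_sound_m_s
    for (t0, t1) in detect_events(proc, detect_channel, detector):
        ev = SoundEvent(t_start_s=t0, t_end_s=t1)
        channels = select_channels(proc, (t0, t1), min_snr_db=min_snr_db,
                                   min_channels=min_channels)
        try:
            ref = pick_loudest_channel(proc, (t0, t1))
            if ref not in channels:
                channels = sorted(channels + [ref])
            taus = estimate_toads(proc, (t0, t1), channels, ref_channel=ref,
                                  max_delay_s=max_delay)
            sub = mic_array.subset(channels)
            res = localize_source(taus, sub, bounds=bounds,
                                  ref=channels.index(ref))
            ev.ref_channel = ref
            ev.channels = channels
            ev.toads_s = taus
            ev.est_position = res.position
            ev.residual_rms_s = res.residual_rms_s
            if jackknife and len(channels) >= 5:
                ev.jackknife_spread_m = jackknife_error(
                    taus, sub, bounds=bounds, ref=channels.index(ref))
        except (ValueError, DegenerateArrayError):
            pass
        try:
            ev.snr_db = compute_snr(proc, (t0, t1),
                                    ev.ref_channel or detect_channel)
        except ValueError:
            pass
        events.append(ev)
    return events
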