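"""Registration of the acoustic frame into the motion-capture global frame,
and constant-offset timestamp alignment between event streams."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegeneracyError(ValueError):
    """Correspondences are collinear or coincident."""


@dataclass
class RigidTransform:
    """6-DOF pose ``x -> R x + t`` (no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns T with T(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rotation": self.rotation.tolist(),
                       "translation": self.translation.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class Correspondences:
    """Paired 3D points: ``source`` (acoustic frame) and ``target`` (mo-cap)."""

    source: np.ndarray
    target: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.source.shape != self.target.shape or self.source.shape[1] != 3:
            raise ValueError("source/target must be matching (n, 3) arrays")
        if self.weights is None:
            self.weights = np.ones(len(self.source))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.source):
                raise ValueError("weights length mismatch")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def from_csv(cls, path) -> "Correspondences":
        df = pd.read_csv(path, float_precision="round_trip")
        cols = ["xa", "ya", "za", "xb", "yb", "zb"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"pairs CSV missing columns: {missing}")
        w = df["weight"].to_numpy(float) if "weight" in df.columns else None
        return cls(df[cols[:3]].to_numpy(float),
                   df[cols[3:]].to_numpy(float), w)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.source, self.target]),
            columns=["xa", "ya", "za", "xb", "yb", "zb"])
        df["weight"] = self.weights
        df.to_csv(path, index=False, float_format="%.17g")


def fit_rigid_transform(corr: Correspondences
                        ) -> tuple[RigidTransform, float]:
    """Weighted least-squares rotation+translation via SVD of the centered
    cross-covariance (Kabsch), with determinant sign correction.

    Returns the transform mapping source points onto target points and the
    RMS residual in meters. Fewer than 4 pairs triggers a warning (protocol
    minimum); fewer than 3 or a degenerate configuration raises.
    """
    n = len(corr)
    if n < 3:
        raise DegeneracyError("need at least 3 point pairs")
    if n < 4:
        warnings.warn("fewer than 4 correspondences: below protocol minimum",
                      stacklevel=2)
    w = corr.weights / corr.weights.sum()
    src_c = (w[:, None] * corr.source).sum(axis=0)
    tgt_c = (w[:, None] * corr.target).sum(axis=0)
    a = corr.source - src_c
    b = corr.target - tgt_c
    h = (w[:, None] * a).T @ b
    # degeneracy: collinear points give a rank-<2 centered configuration
    sv_cfg = np.linalg.svd(a * np.sqrt(w)[:, None], compute_uv=False)
    if sv_cfg[1] < 1e-9 * max(sv_cfg[0], 1e-12) or sv_cfg[0] < 1e-12:
        raise DegeneracyError("correspondences are collinear or coincident")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tgt_c - rot @ src_c
    t = RigidTransform(rot, trans)
    resid = t.apply(corr.source) - corr.target
    rms = float(np.sqrt(np.sum(w * np.sum(resid ** 2, axis=1))))
    return t, rms


def apply_transform(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to one point or an (n, 3) array."""
    return t.apply(points)


def align_timestamps(events_a: np.ndarray, events_b: np.ndarray,
                     max_lag_s: float, match_tol_s: float = 0.05) -> float:
    """Constant clock offset ``b - a`` between two event-time streams.

    Scans candidate offsets (all pairwise differences within ``max_lag_s``)
    for the one matching the most events within ``match_tol_s``, then refines
    it as the median of matched differences (robust to spurious events).
    """
    a = np.sort(np.asarray(events_a, dtype=float))
    b = np.sort(np.asarray(events_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both event streams must be non-empty")
    diffs = (b[None, :] - a[:, None]).ravel()
    diffs = diffs[np.abs(diffs) <= max_lag_s]
    if len(diffs) == 0:
        raise ValueError("no candidate offsets within max_lag_s")
    diffs.sort()
    # densest window of width 2*tol -> modal offset
    right = np.searchsorted(diffs, diffs + 2 * match_tol_s, side="right")
    counts = right - np.arange(len(diffs))
    k = int(np.argmax(counts))
    coarse = float(np.median(diffs[k:right[k]]))
    # refine: nearest-neighbour matching at the coarse offset
    matched = []
    for t in a:
        j = np.searchsorted(b, t + coarse)
        for cand in (j - 1, j):
            if 0 <= cand < len(b) and abs(b[cand] - t - coarse) <= match_tol_s:
                matched.append(b[cand] - t)
                break
    if not matched:
        raise ValueError("no matches within tolerance at the modal offset")
    return float(np.median(matched))
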