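"""Y-maze closed-loop trial control.

Three identical arms joined at 120 degrees; a settled animal at an arm end
triggers a randomized left/right signal, the next crossing into another arm's
evaluation zone is scored against the signal, and correct turns are rewarded.
A return to the signal arm within the detour window does not re-trigger a
signal and the detour is ignored.

Arms are labeled clockwise (viewed from above); for a bird walking from arm
``a`` toward the center, arm ``(a + 1) % 3`` is on its left and
``(a + 2) % 3`` on its right.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon


@dataclass
class MazeGeometry:
    """Planar Y-maze: three arms at 120 degrees around a central junction."""

    arm_length_m: float = 0.92
    arm_width_m: float = 0.27
    center_radius_m: float = 0.16
    eval_zone_span: tuple[float, float] = (0.35, 0.6)   # fraction of arm length
    end_zone_span: tuple[float, float] = (0.75, 1.0)
    n_arms: int = 3

    def __post_init__(self) -> None:
        if self.n_arms != 3:
            raise ValueError("geometry is defined for 3 arms")
        self._axes = []
        self._arm_polys = []
        for a in range(self.n_arms):
            # clockwise arm labeling: arm 0 at +y, then -120 deg steps
            theta = math.radians(90.0 - 120.0 * a)
            u = np.array([math.cos(theta), math.sin(theta)])
            v = np.array([-u[1], u[0]])
            self._axes.append(u)
            h = self.arm_width_m / 2.0
            r0, r1 = self.center_radius_m * 0.5, \
                self.center_radius_m + self.arm_length_m
            self._arm_polys.append(Polygon([
                r0 * u - h * v, r1 * u - h * v, r1 * u + h * v,
                r0 * u + h * v]))

    def _arm_coord(self, arm: int, position: np.ndarray) -> float:
        """Distance along the arm axis from the junction edge, as a fraction
        of arm length."""
        r = float(np.dot(np.asarray(position[:2]), self._axes[arm]))
        return (r - self.center_radius_m) / self.arm_length_m

    def arm_point(self, arm: int, fraction: float) -> np.ndarray:
        """2D point on the axis of ``arm`` at a fraction of its length."""
        r = self.center_radius_m + fraction * self.arm_length_m
        return r * self._axes[arm]

    def locate_zone(self, position: np.ndarray) -> str:
        """"center", "arm<k>", or "outside"."""
        p = np.asarray(position, dtype=float)[:2]
        if np.linalg.norm(p) <= self.center_radius_m:
            return "center"
        pt = Point(*p)
        for a in range(self.n_arms):
            if self._arm_polys[a].covers(pt):
                return f"arm{a}"
        return "outside"

    def subzone(self, position: np.ndarray) -> tuple[str, Optional[str]]:
        """Zone plus arm sub-zone ("eval", "end" or None)."""
        zone = self.locate_zone(position)
        if not zone.startswith("arm"):
            return zone, None
        arm = int(zone[3:])
        frac = self._arm_coord(arm, np.asarray(position, dtype=float))
        if self.end_zone_span[0] <= frac <= self.end_zone_span[1]:
            return zone, "end"
        if self.eval_zone_span[0] <= frac <= self.eval_zone_span[1]:
            return zone, "eval"
        return zone, None


def locate_zone(position: np.ndarray, maze: MazeGeometry) -> str:
    return maze.locate_zone(position)


def evaluate_turn(entry_arm: int, exit_arm: int, signal_side: str,
                  n_arms: int = 3) -> str:
    """Score a turn: with clockwise arm labels, exiting into
    ``(entry + 1) % n`` is a left turn. Returns "correct" or "incorrect"."""
    if signal_side not in ("left", "right"):
        raise ValueError("signal_side must be 'left' or 'right'")
    if entry_arm == exit_arm:
        raise ValueError("exit equals entry: not a turn")
    turned = "left" if exit_arm == (entry_arm + 1) % n_arms else "right"
    return "correct" if turned == signal_side else "incorrect"


@dataclass
class TrialRecord:
    time_s: float
    event: str            # signal_left/signal_right/turn_correct/turn_incorrect/reward/missed
    position: tuple[float, float]
    signal_arm: Optional[int] = None
    exit_arm: Optional[int] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrialLog:
    records: list[TrialRecord] = field(default_factory=list)

    def events(self, kind: str) -> list[TrialRecord]:
        return [r for r in self.records if r.event == kind]

    def count(self, kind: str) -> int:
        return len(self.events(kind))

    @property
    def n_signals(self) -> int:
        return (self.count("signal_left") + self.count("signal_right"))

    @property
    def n_correct(self) -> int:
        return self.count("turn_correct")

    @property
    def n_evaluated(self) -> int:
        return self.n_correct + self.count("turn_incorrect")

    def validate(self) -> None:
        """Every reward must directly follow a correct turn."""
        for i, r in enumerate(self.records):
            if r.event == "reward":
                if i == 0 or self.records[i - 1].event != "turn_correct":
                    raise ValueError("reward without preceding correct turn")

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r.to_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "TrialLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                d["position"] = tuple(d["position"])
                log.records.append(TrialRecord(**d))
        return log


@dataclass
class ControllerParams:
    settle_s: float = 0.5
    detour_s: float = 5.0
    timeout_s: float = 30.0


class Controller:
    """Stateful trial controller; feed it time-ordered positions.

    Signals use balanced-block randomization: each consecutive pair of
    signals contains one left and one right in shuffled order.
    """

    def __init__(self, maze: MazeGeometry,
                 params: ControllerParams | None = None, seed: int = 0,
                 on_signal: Optional[Callable[[str, int], None]] = None):
        self.maze = maze
        self.params = params or ControllerParams()
        self.rng = np.random.default_rng(seed)
        self.log = TrialLog()
        self.on_signal = on_signal
        self._state = "idle"
        self._dwell_arm: Optional[int] = None
        self._dwell_since: Optional[float] = None
        self._signal_arm: Optional[int] = None
        self._signal_side: Optional[str] = None
        self._signal_time: Optional[float] = None
        self._block: list[str] = []
        self._last_time: Optional[float] = None

    def _next_side(self) -> str:
        if not self._block:
            self._block = ["left", "right"]
            self.rng.shuffle(self._block)
        return self._block.pop()

    def _issue_signal(self, t: float, pos, arm: int) -> None:
        side = self._next_side()
        self._signal_arm = arm
        self._signal_side = side
        self._signal_time = t
        self._state = "signaled"
        self.log.records.append(TrialRecord(
            t, f"signal_{side}", (float(pos[0]), float(pos[1])),
            signal_arm=arm))
        if self.on_signal:
            self.on_signal(side, arm)

    def step(self, t: float, position) -> None:
        if self._last_time is not None and t < self._last_time:
            raise ValueError("position stream is not time-ordered")
        self._last_time = t
        pos = np.asarray(position, dtype=float)
        zone, sub = self.maze.subzone(pos)

        if self._state == "idle":
            if zone.startswith("arm") and sub == "end":
                arm = int(zone[3:])
                if self._dwell_arm != arm:
                    self._dwell_arm, self._dwell_since = arm, t
                elif t - self._dwell_since >= self.params.settle_s:
                    self._issue_signal(t, pos, arm)
                    self._dwell_arm = self._dwell_since = None
            else:
                self._dwell_arm = self._dwell_since = None
            return

        # signaled: waiting for an evaluation-zone crossing in another arm
        if t - self._signal_time > self.params.timeout_s:
            self.log.records.append(TrialRecord(
                t, "missed", (float(pos[0]), float(pos[1])),
                signal_arm=self._signal_arm))
            self._state = "idle"
            self._dwell_arm = self._dwell_since = None
            return
        if zone.startswith("arm"):
            arm = int(zone[3:])
            if arm != self._signal_arm and sub == "eval":
                outcome = evaluate_turn(self._signal_arm, arm,
                                        self._signal_side, self.maze.n_arms)
                self.log.records.append(TrialRecord(
                    t, f"turn_{outcome}", (float(pos[0]), float(pos[1])),
                    signal_arm=self._signal_arm, exit_arm=arm))
                if outcome == "correct":
                    self.log.records.append(TrialRecord(
                        t, "reward", (float(pos[0]), float(pos[1])),
                        signal_arm=self._signal_arm, exit_arm=arm))
                self._state = "idle"
                self._dwell_arm = self._dwell_since = None
            # re-entry of the signal arm within the detour window: the
            # detour is ignored and no new signal is issued (handled by
            # simply staying in the signaled state)

    @property
    def pending(self) -> int:
        return 1 if self._state == "signaled" else 0


def run_controller(times: np.ndarray, positions: np.ndarray,
                   maze: MazeGeometry,
                   params: ControllerParams | None = None,
                   seed: int = 0) -> TrialLog:
    """Replay a recorded position stream through the trial state machine."""
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ctl = Controller(maze, params, seed)
    for t, p in zip(times, positions):
        ctl.step(float(t), p)
    return ctl.log


# ---------------------------------------------------------------------------
# simulated agents
# ---------------------------------------------------------------------------

def simulate_session(maze: MazeGeometry, policy: str = "random",
                     n_trials: int = 20, seed: int = 0,
                     frame_rate_hz: float = 50.0,
                     speed_mps: float = 0.8,
                     params: ControllerParams | None = None
                     ) -> TrialLog:
    """Drive an agent through the maze under closed-loop control.

    ``policy`` is "random" (ignores the signal, picks a random other arm) or
    "obedient" (always turns to the signaled side).
    """
    if policy not in ("random", "obedient"):
        raise ValueError("policy must be 'random' or 'obedient'")
    rng = np.random.default_rng(seed + 1)
    params = params or ControllerParams()
    pending_signal: list[tuple[str, int]] = []
    ctl = Controller(maze, params, seed,
                     on_signal=lambda side, arm: pending_signal.append(
                         (side, arm)))
    dt = 1.0 / frame_rate_hz
    t = 0.0
    pos = maze.arm_point(0, 0.85)

    def walk_to(target: np.ndarray) -> None:
        nonlocal t, pos
        vec = target - pos
        dist = float(np.linalg.norm(vec))
        steps = max(1, int(math.ceil(dist / (speed_mps * dt))))
        for k in range(1, steps + 1):
            t += dt
            ctl.step(t, pos + vec * (k / steps))
        pos = target

    def dwell(duration: float) -> None:
        nonlocal t
        steps = int(math.ceil(duration / dt))
        for _ in range(steps):
            t += dt
            ctl.step(t, pos)

    while ctl.log.n_signals < n_trials:
        dwell(params.settle_s + 3 * dt)  # settle until a signal arrives
        if not pending_signal:
            break  # safety: controller refused to signal
        side, arm = pending_signal.pop()
        if policy == "obedient":
            target_arm = (arm + 1) % 3 if side == "left" else (arm + 2) % 3
        else:
            target_arm = (arm + rng.integers(1, 3)) % 3
        walk_to(maze.arm_point(arm, 0.1))
        walk_to(maze.arm_point(target_arm, 0.85))
    ctl.log.validate()
    return ctl.log


def binomial_success(k_correct: int, n_trials: int, p0: float = 0.5) -> float:
    """Exact upper-tail cumulative binomial probability P(X >= k)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not (0 <= k_correct <= n_trials):
        raise ValueError("need 0 <= k <= n")
    total = 0.0
    for i in range(k_correct, n_trials + 1):
        total += math.comb(n_trials, i) * p0 ** i * (1 - p0) ** (n_trials - i)
    return min(total, 1.0)
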