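"""Agent-based generator of free-running group trajectories.

Two behavioural regimes bracket what the analysis is designed to detect:

* ``rotation`` — everyone runs around the hall centre on a loose annulus
  with a common sense of rotation, the regime younger groups show.  High
  angular momentum, few close encounters.
* ``tag`` — a pursuit game: one chaser steers at a target, the target flees
  when the chaser is near, roles switch on contact (< 50 cm) and a new
  target is drawn; everyone else wanders.  Frequent sub-50 cm encounters and
  approach angles concentrated near 0 degrees in the second before contact.
* ``mixed`` — each agent is independently a pursuit participant with
  probability ``p_social``; non-participants orbit.  ``p_social = 0`` equals
  rotation and ``p_social = 1`` equals tag at the same seed.

Agents are discrete-time kinematic particles (heading + speed) on a 0.05 s
grid, reflected specularly at the walls.  Same seed and config give
byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .trajectory import DEFAULT_ARENA, DEFAULT_FRAME_INTERVAL, SessionMeta, TrajectorySet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_rotation",
    "simulate_tag",
    "simulate_mixed",
    "simulate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated session.

    Defaults emulate the recorded sessions: 11-13 children in a
    10 m x 8.5 m hall, ~40 s of running at speeds typical of running
    children (~2.2 m/s mean), 0.05 s frames.
    """

    arena: tuple[float, float] = DEFAULT_ARENA
    n_agents: int = 12
    duration: float = 40.0
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    speed_mean: float = 220.0  # cm/s
    speed_sd: float = 40.0
    heading_noise: float = 0.12  # radians per step
    mode: str = "mixed"  # rotation | tag | mixed
    p_social: float = 0.0
    contact_radius: float = 50.0
    flee_radius: float = 200.0
    chase_boost: float = 1.2  # chaser speed multiplier
    refractory: float = 1.0  # s of no chasing after a tag, so the pair separates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        if not 0.0 <= self.p_social <= 1.0:
            raise ValueError("p_social must lie in [0, 1]")
        if min(self.speed_sd, self.heading_noise, self.speed_mean) < 0:
            raise ValueError("rates and spreads must be non-negative")
        if self.mode not in ("rotation", "tag", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the analysis."""

    mode_labels: list[str]  # per agent: "pursuit" or "orbit"
    chaser: np.ndarray  # (T,) agent index or -1
    target: np.ndarray  # (T,) agent index or -1
    contacts: list[tuple[int, int, int]]  # (frame, chaser, target)

    def to_json(self, path: str | Path, individuals: list[str]) -> None:
        payload = {
            "mode_labels": dict(zip(individuals, self.mode_labels)),
            "contacts": [
                {"frame": f, "chaser": individuals[c], "target": individuals[t]}
                for f, c, t in self.contacts
            ],
            "n_contacts": len(self.contacts),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


#: distance (cm) at which an orbiting runner starts slowing behind the one ahead
_FOLLOW_DISTANCE = 120.0


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + math.pi) % (2 * math.pi) - math.pi


def simulate(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Run the generator in the regime named by ``config.mode``."""
    if config.mode == "rotation":
        return _simulate(replace(config, p_social=0.0))
    if config.mode == "tag":
        return _simulate(replace(config, p_social=1.0))
    return _simulate(config)


def simulate_rotation(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Rotation regime: all agents orbit the hall centre."""
    return _simulate(replace(config, mode="rotation", p_social=0.0))


def simulate_tag(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Tag regime: all agents participate in the pursuit game."""
    return _simulate(replace(config, mode="tag", p_social=1.0))


def simulate_mixed(config: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Mixture regime: each agent is a pursuit participant w.p. ``p_social``."""
    return _simulate(replace(config, mode="mixed"))


def _simulate(cfg: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_agents
    dt = cfg.frame_interval
    n_frames = int(round(cfg.duration / dt)) + 1
    width, height = cfg.arena
    center = np.array([width / 2.0, height / 2.0])

    # per-agent draws; the draw order is fixed so that p_social only gates
    # behaviour, never the stream, keeping the regime identities exact
    social = rng.random(n) < cfg.p_social
    base_speed = np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd, n), 0.0, None)
    ring = 0.33 * min(width, height)
    r_pref = np.clip(rng.normal(ring, 25.0, n), 60.0, 0.5 * min(width, height) - 60.0)
    phi0 = rng.permutation(n) * (2 * math.pi / n) + rng.normal(0.0, 0.15, n)

    pos = center + np.column_stack([np.cos(phi0), np.sin(phi0)]) * r_pref[:, None]
    heading = phi0 + math.pi / 2.0  # counter-clockwise tangent
    positions = np.empty((n, n_frames, 2))
    positions[:, 0] = pos

    chaser = -1
    target = -1
    soc_idx = np.flatnonzero(social)
    if len(soc_idx) >= 2:
        pick = rng.choice(len(soc_idx), size=2, replace=False)
        chaser, target = int(soc_idx[pick[0]]), int(soc_idx[pick[1]])

    chaser_series = np.full(n_frames, -1, dtype=int)
    target_series = np.full(n_frames, -1, dtype=int)
    chaser_series[0], target_series[0] = chaser, target
    contacts: list[tuple[int, int, int]] = []
    turn_rate = 0.5  # chaser heading relaxation per step
    refractory_frames = int(round(cfg.refractory / dt))
    suspended_until = 0  # no chasing before this frame (post-tag pause)

    for t in range(1, n_frames):
        noise = rng.normal(0.0, cfg.heading_noise, n) if cfg.heading_noise > 0 else np.zeros(n)
        speed = base_speed.copy()

        # orbiting agents: steer along the tangent with a weak radial
        # restoring pull toward the preferred ring radius; follow the agent
        # ahead at a distance (slow down when closing) so runners keep
        # spacing instead of passing through each other
        orbit = ~social
        if orbit.any():
            oi = np.flatnonzero(orbit)
            rel = pos[oi] - center
            r = np.linalg.norm(rel, axis=1)
            r = np.where(r == 0, 1e-9, r)
            r_hat = rel / r[:, None]
            t_hat = np.column_stack([-r_hat[:, 1], r_hat[:, 0]])  # ccw
            correction = 0.8 * (r_pref[oi] - r) / r_pref[oi]
            vec = t_hat + correction[:, None] * r_hat
            # midpoint-tangent correction: aim half a step ahead along the
            # circle so the chord stays tangential up to second order
            half_turn = 0.5 * base_speed[oi] * dt / r
            heading[oi] = np.arctan2(vec[:, 1], vec[:, 0]) + half_turn
            if len(oi) > 1:
                phi = np.arctan2(rel[:, 1], rel[:, 0])
                gap_ahead = (phi[None, :] - phi[:, None]) % (2 * math.pi)
                np.fill_diagonal(gap_ahead, np.inf)
                sep = np.linalg.norm(pos[oi][None, :] - pos[oi][:, None], axis=2)
                ahead = (gap_ahead < math.pi) & (sep < _FOLLOW_DISTANCE)
                crowd = np.where(ahead, sep, np.inf).min(axis=1)
                close = crowd < _FOLLOW_DISTANCE
                speed[oi[close]] *= np.maximum(0.25, crowd[close] / _FOLLOW_DISTANCE)

        chasing = chaser >= 0 and t >= suspended_until
        if chasing:
            los = pos[target] - pos[chaser]
            dist_ct = float(np.linalg.norm(los))
            desired = math.atan2(los[1], los[0])
            heading[chaser] += turn_rate * float(
                _wrap_angle(np.array([desired - heading[chaser]]))[0]
            )
            speed[chaser] = base_speed[chaser] * cfg.chase_boost
            if dist_ct < cfg.flee_radius:
                heading[target] = math.atan2(-los[1], -los[0])

        heading = heading + noise
        pos = pos + speed[:, None] * dt * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )

        # specular reflection at the walls
        for axis, bound in ((0, width), (1, height)):
            low = pos[:, axis] < 0
            highm = pos[:, axis] > bound
            pos[low, axis] = -pos[low, axis]
            pos[highm, axis] = 2 * bound - pos[highm, axis]
            flip = low | highm
            if flip.any():
                if axis == 0:
                    heading[flip] = math.pi - heading[flip]
                else:
                    heading[flip] = -heading[flip]

        if chasing:
            gap = float(np.linalg.norm(pos[target] - pos[chaser]))
            if gap < cfg.contact_radius:
                contacts.append((t, chaser, target))
                chaser = target
                others = soc_idx[(soc_idx != chaser)]
                if len(others) == 1:
                    target = int(others[0])
                else:
                    target = int(rng.choice(others))
                suspended_until = t + refractory_frames

        positions[:, t] = pos
        chaser_series[t], target_series[t] = chaser, target

    individuals = [f"c{k + 1}" for k in range(n)]
    label = {"rotation": "rotation", "tag": "tag", "mixed": "mixed"}[cfg.mode]
    traj = TrajectorySet(
        frame_interval=dt,
        individuals=individuals,
        positions=positions,
        meta=SessionMeta(
            class_label=label,
            duration=(n_frames - 1) * dt,
            participant_count=n,
        ),
    )
    truth = GroundTruth(
        mode_labels=["pursuit" if s else "orbit" for s in social],
        chaser=chaser_series,
        target=target_series,
        contacts=contacts,
    )
    return traj, truth
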