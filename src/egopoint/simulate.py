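"""Seeded generative model of pointing-test sessions.

Emulates the statistical structure the analysis pipeline assumes for a
two-day cohort: a fixed room and 15-target roster, per-participant
pointing biases, von Mises azimuth noise and truncated-normal elevation
noise whose dispersion grows with condition difficulty (EO < EC < RR <
MR), bimodal 90/180-degree flip errors in the mental-rotation condition,
inflated variability for eccentric targets contralateral to the pointing
hand, and an optional 180-degree compass-flip artifact for strongly
downward targets.

Only the baseline (EO) dispersions are anchored to observed cohort values
(7.93 deg azimuth, 3.83 deg elevation within-subject SD); the condition
multipliers are free parameters chosen to reproduce the qualitative
difficulty ordering, not measured values.

Every draw comes from a named, independent random stream derived from
``(seed, participant_index)``, so enabling one artifact never perturbs
the other draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._angles import azel_to_enu, wrap_deg
from .session_model import (
    PointingVector,
    RoomLayout,
    Session,
    TargetSpec,
    Trial,
    build_schedule,
    default_roster,
    write_session,
)

#: (condition, day, repetitions) in administration order
DEFAULT_PROTOCOL = (
    ("EO", 1, 8),
    ("EC", 1, 6),
    ("EO", 2, 6),
    ("RR", 2, 6),
    ("MR", 2, 6),
)

_STREAMS = ("bias", "schedule", "azimuth", "elevation", "mr_flip", "sensor_flip")


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort generator.

    Angles in degrees.  ``azimuth_sd_deg``/``elevation_sd_deg`` are the
    baseline (EO) within-subject SDs; each condition's noise SD is the
    baseline times ``condition_multipliers[condition]``.
    """

    n_participants: int = 20
    layout: RoomLayout = field(default_factory=RoomLayout)
    roster: list[TargetSpec] | None = None
    protocol: tuple = DEFAULT_PROTOCOL
    azimuth_sd_deg: float = 7.93
    elevation_sd_deg: float = 3.83
    condition_multipliers: dict = field(default_factory=lambda: {
        "EO": 1.0, "EC": 1.5, "RR": 2.0, "MR": 2.5})
    participant_bias_sd_deg: float = 2.0
    mr_flip_prob: float = 0.2
    mr_flip_angles: tuple = (-90.0, 90.0, 180.0)
    contralateral_factor: float = 2.0
    contralateral_min_azimuth_deg: float = 75.0
    sensor_flip_prob: float = 0.0
    sensor_flip_elevation_deg: float = -15.0
    schedule_mode: str = "fixed"
    left_hand_fraction: float = 0.1
    female_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.roster is None:
            self.roster = default_roster(self.layout)
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.azimuth_sd_deg < 0 or self.elevation_sd_deg < 0:
            raise ValueError("noise SDs must be >= 0")
        for p in (self.mr_flip_prob, self.sensor_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(m < 1.0 for m in self.condition_multipliers.values()):
            raise ValueError("condition multipliers must be >= 1")
        if self.contralateral_factor < 1.0:
            raise ValueError("contralateral_factor must be >= 1")


def _streams(config: SimConfig, participant_index: int) -> dict[str, np.random.Generator]:
    """Independent named generators for one participant."""
    return {
        name: np.random.default_rng(
            np.random.SeedSequence([config.seed, participant_index, i]))
        for i, name in enumerate(_STREAMS)
    }


def _participant_meta(config: SimConfig, i: int) -> dict:
    n_left = round(config.left_hand_fraction * config.n_participants)
    n_female = round(config.female_fraction * config.n_participants)
    return {
        "pointing_hand": "left" if i < n_left else "right",
        "handedness": "left" if i < n_left else "right",
        "sex": "F" if i < n_female else "M",
        # balanced to within one across the cohort
        "rotation_side": "right" if i % 2 == 0 else "left",
        "birthdate": f"{1994 + (i % 10)}-06-15",
    }


def _draw_azimuth(rng, mu_deg: float, sd_deg: float) -> float:
    if sd_deg == 0.0:
        return wrap_deg(mu_deg)
    kappa = (180.0 / (math.pi * sd_deg)) ** 2
    draw = rng.vonmises(math.radians(mu_deg), kappa)
    return wrap_deg(math.degrees(draw))


def _draw_elevation(rng, mu_deg: float, sd_deg: float) -> float:
    if sd_deg == 0.0:
        return float(np.clip(mu_deg, -90.0, 90.0))
    a, b = (-90.0 - mu_deg) / sd_deg, (90.0 - mu_deg) / sd_deg
    if a >= b:
        raise ValueError("infeasible elevation truncation")
    return float(stats.truncnorm.rvs(a, b, loc=mu_deg, scale=sd_deg,
                                     random_state=rng))


def simulate_session(config: SimConfig, participant_index: int
                     ) -> tuple[list[Session], dict]:
    """Simulate both days for one participant.

    Returns (sessions, truth): one :class:`Session` per day plus the
    ground-truth record of every latent draw (biases, expected directions,
    MR flips, sensor flips) for recovery tests.  Fully reproducible from
    ``(config.seed, participant_index)``.
    """
    rngs = _streams(config, participant_index)
    meta = _participant_meta(config, participant_index)
    pid = f"P{participant_index + 1:03d}"
    roster = [t.resolved(config.layout) for t in config.roster]
    target_map = {t.name: t for t in roster}
    facing = config.layout.facing_heading_deg

    bias_az = float(rngs["bias"].normal(0.0, config.participant_bias_sd_deg)) \
        if config.participant_bias_sd_deg > 0 else 0.0
    bias_el = float(rngs["bias"].normal(0.0, config.participant_bias_sd_deg)) \
        if config.participant_bias_sd_deg > 0 else 0.0

    mr_side = "left" if meta["rotation_side"] == "right" else "right"
    truth = {
        "participant_id": pid,
        "bias_azimuth_deg": bias_az,
        "bias_elevation_deg": bias_el,
        "rotation_side": meta["rotation_side"],
        "mr_side": mr_side,
        "trials": [],
    }

    sessions: dict[int, Session] = {}
    index_by_day: dict[int, int] = {}
    for condition, day, repetitions in config.protocol:
        if day not in sessions:
            sessions[day] = Session(
                participant_id=pid, day=day, roster=roster,
                layout=config.layout, **meta)
            index_by_day[day] = 0
        session = sessions[day]
        sched_seed = int(rngs["schedule"].integers(0, 2 ** 31))
        schedule = build_schedule(roster, repetitions, mode=config.schedule_mode,
                                  seed=sched_seed)
        block_size = len(roster)
        for pos, name in enumerate(schedule):
            target = target_map[name]
            true_dir = target.true_direction
            mult = config.condition_multipliers.get(condition, 1.0)
            az_sd = config.azimuth_sd_deg * mult
            el_sd = config.elevation_sd_deg * mult

            # expected direction in the original body frame
            exp_az = true_dir.azimuth_deg
            if condition == "MR" and true_dir.azimuth_defined:
                exp_az = wrap_deg(exp_az + (-90.0 if mr_side == "right" else 90.0))
            exp_el = true_dir.elevation_deg

            # contralateral inflation for eccentric targets
            contra = (true_dir.azimuth_defined
                      and abs(true_dir.azimuth_deg) >= config.contralateral_min_azimuth_deg
                      and ((true_dir.azimuth_deg < 0)
                           == (meta["pointing_hand"] == "right")))
            if contra:
                az_sd *= config.contralateral_factor

            flip_angle = 0.0
            if condition == "MR" and config.mr_flip_angles:
                if rngs["mr_flip"].random() < config.mr_flip_prob:
                    flip_angle = float(
                        rngs["mr_flip"].choice(np.asarray(config.mr_flip_angles)))

            mu_az = exp_az + bias_az + flip_angle
            azimuth = _draw_azimuth(rngs["azimuth"], mu_az, az_sd)
            mu_el = float(np.clip(exp_el + bias_el, -90.0, 90.0))
            elevation = _draw_elevation(rngs["elevation"], mu_el, el_sd)

            sensor_flip = False
            if config.sensor_flip_prob > 0 and \
                    true_dir.elevation_deg < config.sensor_flip_elevation_deg:
                if rngs["sensor_flip"].random() < config.sensor_flip_prob:
                    azimuth = wrap_deg(azimuth + 180.0)
                    sensor_flip = True

            e, n, u = azel_to_enu(azimuth, elevation, facing)
            session.trials.append(Trial(
                participant_id=pid, day=day, condition=condition,
                target_name=name, repetition=pos // block_size + 1,
                presentation_index=index_by_day[day],
                vector=PointingVector(e, n, u),
            ))
            truth["trials"].append({
                "day": day, "condition": condition, "target": name,
                "repetition": pos // block_size + 1,
                "expected_azimuth_deg": exp_az, "expected_elevation_deg": exp_el,
                "azimuth_sd_deg": az_sd, "elevation_sd_deg": el_sd,
                "mr_flip_angle_deg": flip_angle, "sensor_flip": sensor_flip,
                "contralateral_inflated": contra,
            })
            index_by_day[day] += 1
    return [sessions[d] for d in sorted(sessions)], truth


def simulate_cohort(config: SimConfig) -> tuple[list[Session], dict]:
    """Simulate the full cohort; rotation sides balanced to within one.

    Returns (sessions, truth) where ``truth['participants']`` keeps every
    latent draw for parameter-recovery tests.
    """
    if config.n_participants < 2:
        raise ValueError("a cohort needs >= 2 participants")
    sessions: list[Session] = []
    truth = {"config": config_to_dict(config), "participants": []}
    for i in range(config.n_participants):
        part_sessions, part_truth = simulate_session(config, i)
        sessions.extend(part_sessions)
        truth["participants"].append(part_truth)
    return sessions, truth


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["layout"] = dataclasses.asdict(config.layout)
    d["roster"] = [t.name for t in config.roster]
    d["protocol"] = [list(p) for p in config.protocol]
    d["mr_flip_angles"] = list(config.mr_flip_angles)
    return d


def write_cohort(config: SimConfig, outdir) -> dict:
    """Simulate and write one session JSON per participant-day plus a
    ground-truth sidecar and a manifest; returns the manifest."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sessions, truth = simulate_cohort(config)
    files = []
    for s in sessions:
        name = f"{s.participant_id}_day{s.day}.json"
        write_session(s, out / name)
        files.append(name)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
        fh.write("\n")
    manifest = {"seed": config.seed, "n_participants": config.n_participants,
                "files": files, "ground_truth": "ground_truth.json"}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
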