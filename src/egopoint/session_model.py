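"""Domain model, JSON dialect and schedule generation for pointing sessions.

A *session* is one participant-day of an egocentric pointing test: the
participant stands at a fixed spot in a room and points a mobile device at
named targets under one of four conditions — eyes open (EO, the baseline),
eyes closed (EC), after a real 90-degree body rotation (RR), or after an
imagined 90-degree rotation (MR).  Each trial stores the device's pointing
direction as a unit vector in East/North/Up world coordinates.

The on-disk format is a small JSON dialect (format_version 1, flat trial
list) documented by ``schemas/session.schema.json``.  The reader is
forward-tolerant: unknown keys at any level are preserved in ``extras``
maps and written back verbatim.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._angles import azel_to_enu, azimuth_defined, enu_to_azel, great_circle_deg, wrap_deg

CONDITIONS = ("EO", "EC", "RR", "MR")
FORMAT_VERSION = 1

#: |azimuth| below this is "center" for left/right alternation purposes.
SIDE_CENTER_BAND_DEG = 5.0

# Vector norms outside this window indicate a corrupt record, not mere
# floating-point drift from serialisation.
_NORM_OK = (0.5, 1.5)


class SessionFormatError(ValueError):
    """Malformed session file (bad JSON, wrong dialect, corrupt record)."""


class ScheduleConstraintError(ValueError):
    """A requested target schedule cannot satisfy the alternation constraint."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointingVector:
    """Unit pointing vector in East/North/Up world coordinates.

    ``raw_norm`` records the norm of the components as read from disk,
    before normalisation (the app stores each component in [-1, 1]).
    """

    e: float
    n: float
    u: float
    raw_norm: float = 1.0

    @classmethod
    def from_components(cls, e: float, n: float, u: float) -> "PointingVector":
        norm = math.sqrt(e * e + n * n + u * u)
        if norm < 1e-12:
            raise ValueError("zero pointing vector")
        if abs(norm - 1.0) < 1e-12:
            # already unit: keep the stored digits so round trips are bit-exact
            return cls(e, n, u, raw_norm=norm)
        return cls(e / norm, n / norm, u / norm, raw_norm=norm)

    def as_array(self) -> np.ndarray:
        return np.array([self.e, self.n, self.u], dtype=float)

    def angles(self, facing_heading_deg: float = 0.0) -> "DirectionAngles":
        az, el = enu_to_azel(self.e, self.n, self.u, facing_heading_deg)
        return DirectionAngles(az, el, azimuth_defined=azimuth_defined(el))


@dataclass(frozen=True)
class DirectionAngles:
    """Body-referenced direction: azimuth in (-180, 180] (+ = right),
    elevation in [-90, 90] (+ = up)."""

    azimuth_deg: float
    elevation_deg: float
    azimuth_defined: bool = True

    def __post_init__(self):
        object.__setattr__(self, "azimuth_deg", wrap_deg(self.azimuth_deg))
        if not -90.0 <= self.elevation_deg <= 90.0:
            raise ValueError(f"elevation {self.elevation_deg} outside [-90, 90]")


@dataclass(frozen=True)
class RoomLayout:
    """Testing-room geometry: footprint, observer position and facing.

    ``facing_heading_deg`` is the compass heading the participant faces
    (degrees clockwise from North); the default layout has the participant
    at the near end of a 6 x 7 m room facing into it (North).
    """

    width_m: float = 6.0
    depth_m: float = 7.0
    height_m: float = 3.0
    observer_xy: tuple[float, float] = (3.0, 1.0)
    eye_height_m: float = 1.6
    facing_heading_deg: float = 0.0

    def __post_init__(self):
        for name in ("width_m", "depth_m", "height_m", "eye_height_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        x, y = self.observer_xy
        if not (0 <= x <= self.width_m and 0 <= y <= self.depth_m):
            raise ValueError("observer must stand inside the room footprint")


def side_for_azimuth(azimuth_deg: float) -> str:
    if azimuth_deg < -SIDE_CENTER_BAND_DEG:
        return "left"
    if azimuth_deg > SIDE_CENTER_BAND_DEG:
        return "right"
    return "center"


@dataclass(frozen=True)
class TargetSpec:
    """A named pointing target: a room position and/or a true direction.

    ``analyse_azimuth`` is False for targets whose azimuth is physically
    meaningless (straight overhead).
    """

    name: str
    position_xyz_m: tuple[float, float, float] | None = None
    true_direction: DirectionAngles | None = None
    side: str = "center"
    analyse_azimuth: bool = True

    def direction(self, layout: RoomLayout) -> DirectionAngles:
        """True body-referenced direction, derived from position if needed."""
        if self.true_direction is not None:
            return self.true_direction
        if self.position_xyz_m is None:
            raise ValueError(f"target {self.name!r} has neither position nor direction")
        x, y, z = self.position_xyz_m
        ox, oy = layout.observer_xy
        e, n, u = x - ox, y - oy, z - layout.eye_height_m
        horiz = math.hypot(e, n)
        if horiz < 1e-12:
            # directly overhead (or underfoot): azimuth undefined
            el = 90.0 if u >= 0 else -90.0
            return DirectionAngles(0.0, el, azimuth_defined=False)
        az, el = enu_to_azel(e, n, u, layout.facing_heading_deg)
        return DirectionAngles(az, el, azimuth_defined=azimuth_defined(el))

    def resolved(self, layout: RoomLayout) -> "TargetSpec":
        """Return a copy with ``true_direction`` and ``side`` filled in."""
        d = self.direction(layout)
        side = side_for_azimuth(d.azimuth_deg) if d.azimuth_defined else "center"
        return replace(self, true_direction=d, side=side,
                       analyse_azimuth=self.analyse_azimuth and d.azimuth_defined)


@dataclass
class Trial:
    participant_id: str
    day: int
    condition: str
    target_name: str
    repetition: int
    presentation_index: int
    vector: PointingVector
    flags: set[str] = field(default_factory=set)
    extras: dict = field(default_factory=dict)


@dataclass
class Session:
    """One participant-day of ordered pointing trials plus metadata."""

    participant_id: str
    sex: str = ""
    birthdate: str = ""
    handedness: str = "right"
    pointing_hand: str = "right"
    rotation_side: str = "right"
    day: int | None = 1
    roster: list[TargetSpec] = field(default_factory=list)
    layout: RoomLayout = field(default_factory=RoomLayout)
    trials: list[Trial] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def mental_rotation_side(self) -> str:
        """MR is imagined to the side opposite the real rotation."""
        return "left" if self.rotation_side == "right" else "right"

    def roster_map(self) -> dict[str, TargetSpec]:
        return {t.name: t.resolved(self.layout) for t in self.roster}

    def validate(self) -> list[str]:
        """Return a list of invariant-violation messages (empty if clean)."""
        issues: list[str] = []
        names = {t.name for t in self.roster}
        last_index = -1
        for t in self.trials:
            if names and t.target_name not in names:
                issues.append(
                    f"trial {t.presentation_index}: unknown target {t.target_name!r}")
            if t.presentation_index <= last_index:
                issues.append(
                    f"trial {t.presentation_index}: presentation_index not increasing")
            last_index = t.presentation_index
            if t.condition not in CONDITIONS:
                issues.append(
                    f"trial {t.presentation_index}: unknown condition {t.condition!r}")
            norm = float(np.linalg.norm(t.vector.as_array()))
            if abs(norm - 1.0) > 1e-6:
                issues.append(
                    f"trial {t.presentation_index}: vector norm {norm:.6f} != 1")
            if t.repetition < 1:
                issues.append(f"trial {t.presentation_index}: repetition < 1")
        if self.rotation_side not in ("left", "right"):
            issues.append(f"rotation_side {self.rotation_side!r} not left/right")
        return issues


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

_PARTICIPANT_KEYS = ("id", "sex", "birthdate", "handedness", "pointing_hand",
                     "rotation_side")
_LAYOUT_KEYS = ("width_m", "depth_m", "height_m", "observer_xy", "eye_height_m",
                "facing_heading_deg")
_TRIAL_KEYS = ("index", "day", "condition", "target", "repetition", "vector")


def _split_extras(obj: dict, known: tuple[str, ...]) -> dict:
    return {k: v for k, v in obj.items() if k not in known}


def read_session(path, strict: bool = True) -> Session:
    """Read a session file in the pointing-app JSON dialect (v1).

    In strict mode any invariant violation raises :class:`SessionFormatError`;
    in lenient mode violations become per-trial quality flags (corrupt
    vectors drop the trial, counted in ``session.extras['n_dropped']``).
    Unknown keys are preserved so that lossless round trips are possible.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise SessionFormatError(
            f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise SessionFormatError(f"{path}: top level must be a JSON object")
    version = doc.get("format_version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise SessionFormatError(f"{path}: unsupported format_version {version!r}")

    part = doc.get("participant", {})
    layout_doc = doc.get("layout", {})
    layout_kwargs = {k: layout_doc[k] for k in _LAYOUT_KEYS if k in layout_doc}
    if "observer_xy" in layout_kwargs:
        layout_kwargs["observer_xy"] = tuple(layout_kwargs["observer_xy"])
    layout = RoomLayout(**layout_kwargs)

    roster = []
    for tgt in doc.get("roster", []):
        direction = None
        if "true_direction" in tgt:
            d = tgt["true_direction"]
            direction = DirectionAngles(d["azimuth_deg"], d["elevation_deg"],
                                        d.get("azimuth_defined", True))
        roster.append(TargetSpec(
            name=tgt["name"],
            position_xyz_m=tuple(tgt["position_xyz_m"]) if tgt.get("position_xyz_m") else None,
            true_direction=direction,
            side=tgt.get("side", "center"),
            analyse_azimuth=tgt.get("analyse_azimuth", True),
        ))

    session = Session(
        participant_id=str(part.get("id", "")),
        sex=part.get("sex", ""),
        birthdate=part.get("birthdate", ""),
        handedness=part.get("handedness", "right"),
        pointing_hand=part.get("pointing_hand", "right"),
        rotation_side=part.get("rotation_side", "right"),
        day=doc.get("day"),
        roster=roster,
        layout=layout,
        extras={
            **_split_extras(doc, ("format_version", "participant", "layout",
                                  "roster", "trials", "day")),
            "participant_extras": _split_extras(part, _PARTICIPANT_KEYS),
            "layout_extras": _split_extras(layout_doc, _LAYOUT_KEYS),
        },
    )

    n_dropped = 0
    for i, rec in enumerate(doc.get("trials", [])):
        try:
            comps = [float(c) for c in rec["vector"]]
            if len(comps) != 3:
                raise ValueError("vector must have 3 components")
        except (KeyError, TypeError, ValueError) as exc:
            if strict:
                raise SessionFormatError(f"{path}: trial {i}: bad vector: {exc}") from exc
            n_dropped += 1
            continue
        norm = math.sqrt(sum(c * c for c in comps))
        if not _NORM_OK[0] <= norm <= _NORM_OK[1]:
            if strict:
                raise SessionFormatError(
                    f"{path}: trial {i}: corrupt vector norm {norm:.4f}")
            n_dropped += 1
            continue
        trial = Trial(
            participant_id=session.participant_id,
            day=int(rec.get("day", session.day or 1)),
            condition=rec.get("condition", ""),
            target_name=rec.get("target", ""),
            repetition=int(rec.get("repetition", 1)),
            presentation_index=int(rec.get("index", i)),
            vector=PointingVector.from_components(*comps),
            extras=_split_extras(rec, _TRIAL_KEYS),
        )
        session.trials.append(trial)
    if n_dropped:
        session.extras["n_dropped"] = n_dropped

    issues = session.validate()
    if issues:
        if strict:
            raise SessionFormatError(f"{path}: " + "; ".join(issues))
        for t in session.trials:
            prefix = f"trial {t.presentation_index}:"
            if any(msg.startswith(prefix) for msg in issues):
                t.flags.add("invariant_violation")
        session.extras["validation_issues"] = issues
    return session


def write_session(session: Session, path, order: str = "collected") -> None:
    """Write a session in the JSON dialect.

    ``order='collected'`` preserves presentation order (research use);
    ``order='by_target'`` groups repetitions of each target with targets
    alphabetical (diagnostic read-out).
    """
    if order not in ("collected", "by_target"):
        raise ValueError(f"unknown order {order!r}")
    trials = sorted(session.trials, key=lambda t: t.presentation_index)
    if order == "by_target":
        trials = sorted(trials, key=lambda t: (t.target_name, t.repetition,
                                               t.presentation_index))
    doc = {
        "format_version": FORMAT_VERSION,
        "day": session.day,
        "participant": {
            "id": session.participant_id,
            "sex": session.sex,
            "birthdate": session.birthdate,
            "handedness": session.handedness,
            "pointing_hand": session.pointing_hand,
            "rotation_side": session.rotation_side,
            **session.extras.get("participant_extras", {}),
        },
        "layout": {
            "width_m": session.layout.width_m,
            "depth_m": session.layout.depth_m,
            "height_m": session.layout.height_m,
            "observer_xy": list(session.layout.observer_xy),
            "eye_height_m": session.layout.eye_height_m,
            "facing_heading_deg": session.layout.facing_heading_deg,
            **session.extras.get("layout_extras", {}),
        },
        "roster": [_target_doc(t) for t in session.roster],
        "trials": [
            {
                "index": t.presentation_index,
                "day": t.day,
                "condition": t.condition,
                "target": t.target_name,
                "repetition": t.repetition,
                "vector": [t.vector.e, t.vector.n, t.vector.u],
                **t.extras,
            }
            for t in trials
        ],
        **{k: v for k, v in session.extras.items()
           if k not in ("participant_extras", "layout_extras", "n_dropped",
                        "validation_issues")},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _target_doc(t: TargetSpec) -> dict:
    doc: dict = {"name": t.name, "side": t.side, "analyse_azimuth": t.analyse_azimuth}
    if t.position_xyz_m is not None:
        doc["position_xyz_m"] = list(t.position_xyz_m)
    if t.true_direction is not None:
        doc["true_direction"] = {
            "azimuth_deg": t.true_direction.azimuth_deg,
            "elevation_deg": t.true_direction.elevation_deg,
            "azimuth_defined": t.true_direction.azimuth_defined,
        }
    return doc


# ---------------------------------------------------------------------------
# Default roster
# ---------------------------------------------------------------------------

# (name, body azimuth deg, elevation deg, horizontal distance m).  The study
# room's own target names/coordinates are not published; these are systematic
# stand-ins at geometrically plausible positions in a 6 x 7 m room, spanning
# exactly [-90, +90] azimuth and [-20, +90] elevation (one straight-up target).
_DEFAULT_TARGET_TABLE = (
    ("left_floor_corner",    -90.0, -20.0, 2.8),
    ("left_wall_shelf",      -90.0,  15.0, 2.8),
    ("left_ceiling_lamp",    -75.0,  60.0, 0.7),
    ("left_door_handle",     -60.0,   0.0, 3.0),
    ("left_picture_frame",   -45.0,  30.0, 2.0),
    ("left_window_latch",    -30.0,   5.0, 3.0),
    ("left_cabinet_top",     -15.0,  45.0, 1.2),
    ("ceiling_above",          0.0,  90.0, 0.0),
    ("right_air_vent",        15.0,  55.0, 0.8),
    ("right_door_sign",       30.0,   0.0, 3.0),
    ("right_clock",           45.0,  40.0, 1.4),
    ("right_monitor",         60.0,  10.0, 3.0),
    ("right_smoke_detector",  75.0,  70.0, 0.45),
    ("right_waste_bin",       90.0, -10.0, 2.8),
    ("right_light_switch",    90.0,  20.0, 2.8),
)


def default_roster(layout: RoomLayout | None = None) -> list[TargetSpec]:
    """Fifteen named targets spanning 180 deg azimuth and 110 deg elevation.

    Positions are placed on the stated azimuth/elevation rays at plausible
    ranges inside the room; true directions are re-derived from position and
    layout, so the roster is geometrically self-consistent.
    """
    layout = layout or RoomLayout()
    ox, oy = layout.observer_xy
    targets = []
    for name, az, el, dist in _DEFAULT_TARGET_TABLE:
        if dist == 0.0:
            pos = (ox, oy, layout.height_m)
        else:
            e, n, u = azel_to_enu(az, el, layout.facing_heading_deg)
            horiz = math.hypot(e, n)
            pos = (ox + dist * e / horiz,
                   oy + dist * n / horiz,
                   layout.eye_height_m + dist * u / horiz)
        targets.append(TargetSpec(name=name, position_xyz_m=pos).resolved(layout))
    return targets


def roster_spans(roster: list[TargetSpec], layout: RoomLayout | None = None
                 ) -> tuple[float, float]:
    """(azimuth span, elevation span) in degrees over a roster.

    Azimuth span uses only targets whose azimuth is analysable.
    """
    layout = layout or RoomLayout()
    azs, els = [], []
    for t in roster:
        d = t.direction(layout)
        els.append(d.elevation_deg)
        if d.azimuth_defined:
            azs.append(d.azimuth_deg)
    return max(azs) - min(azs), max(els) - min(els)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def _violates_alternation(sides: list[str]) -> bool:
    return any(a == b and a in ("left", "right")
               for a, b in zip(sides, sides[1:]))


def build_schedule(roster: list[TargetSpec], repetitions: int,
                   mode: str = "fixed", seed: int | None = None,
                   alternate: bool = True) -> list[str]:
    """Ordered target-name schedule: ``repetitions`` blocks, each a
    permutation of the roster with no two consecutive same-side lateral
    targets (center targets may sit anywhere).

    ``mode='fixed'`` yields one canonical order regardless of seed (the
    original app hard-coded its order); ``mode='randomized'`` permutes each
    block independently under the constraint, reproducibly under ``seed``.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if mode not in ("fixed", "randomized"):
        raise ValueError(f"unknown schedule mode {mode!r}")
    side_of = {t.name: t.side for t in roster}
    lefts = sorted(n for n, s in side_of.items() if s == "left")
    rights = sorted(n for n, s in side_of.items() if s == "right")
    centers = sorted(n for n, s in side_of.items() if s == "center")
    if alternate and (lefts or rights):
        if not lefts or not rights:
            if len(lefts) + len(rights) > 1:
                raise ScheduleConstraintError(
                    "alternation requires at least one target on each side")
        big, small = max(len(lefts), len(rights)), min(len(lefts), len(rights))
        if big > small + len(centers) + 1:
            raise ScheduleConstraintError(
                f"cannot alternate {big} same-side targets with only "
                f"{small} opposite and {len(centers)} center targets")

    if mode == "fixed":
        block = _canonical_block(lefts, rights, centers)
        schedule = block * repetitions
        if alternate and _violates_alternation([side_of[n] for n in schedule]):
            raise ScheduleConstraintError(
                "fixed canonical order violates alternation for this roster; "
                "use mode='randomized'")
        return schedule

    rng = np.random.default_rng(seed)
    names = [t.name for t in roster]
    schedule: list[str] = []
    prev_side: str | None = None
    for _ in range(repetitions):
        block = _randomized_block(names, side_of, prev_side, rng,
                                  alternate=alternate)
        schedule.extend(block)
        prev_side = side_of[block[-1]]
    return schedule


def _canonical_block(lefts, rights, centers) -> list[str]:
    """Deterministic L/R interleave with center targets in the middle."""
    block: list[str] = []
    li = ri = 0
    take_left = len(lefts) >= len(rights)
    while li < len(lefts) or ri < len(rights):
        if take_left and li < len(lefts):
            block.append(lefts[li]); li += 1
        elif ri < len(rights):
            block.append(rights[ri]); ri += 1
        elif li < len(lefts):
            block.append(lefts[li]); li += 1
        take_left = not take_left
    mid = len(block) // 2
    return block[:mid] + list(centers) + block[mid:]


def _randomized_block(names, side_of, prev_side, rng, alternate=True) -> list[str]:
    """One random permutation of ``names`` with no two adjacent same-side
    laterals, built constructively (with balanced sides the side pattern is
    forced to alternate, so rejection sampling is infeasible)."""

    def _shuffled(items):
        items = list(items)
        return [items[i] for i in rng.permutation(len(items))] if items else []

    if not alternate:
        return _shuffled(names)
    lefts = _shuffled(n for n in names if side_of[n] == "left")
    rights = _shuffled(n for n in names if side_of[n] == "right")
    centers = _shuffled(n for n in names if side_of[n] == "center")
    if not lefts and not rights:
        return centers
    if len(lefts) == len(rights):
        first_left = bool(rng.integers(2)) if prev_side not in ("left", "right") \
            else (prev_side == "right")
        big, small = (lefts, rights) if first_left else (rights, lefts)
    elif abs(len(lefts) - len(rights)) >= 1:
        big, small = (lefts, rights) if len(lefts) > len(rights) else (rights, lefts)
    need = len(big) - 1 - len(small)
    seps = small + centers[:max(need, 0)]
    rest = centers[max(need, 0):]
    if len(seps) < len(big) - 1:
        raise ScheduleConstraintError(
            "cannot alternate: too many same-side targets for the available "
            "separators")
    seps = _shuffled(seps)
    block: list[str] = []
    for i, name in enumerate(big):
        block.append(name)
        if i < len(seps):
            block.append(seps[i])
    # leftover separators (when small side is larger than gaps) go at the end
    block.extend(seps[len(big):])
    # remaining centers are safe anywhere
    for name in rest:
        pos = int(rng.integers(0, len(block) + 1))
        block.insert(pos, name)
    if prev_side in ("left", "right") and side_of[block[0]] == prev_side:
        if rest or centers:
            # move a center to the front if one exists in the block
            for i, name in enumerate(block):
                if side_of[name] == "center":
                    block.insert(0, block.pop(i))
                    break
            else:
                raise ScheduleConstraintError(
                    "cannot satisfy alternation across block boundary")
        else:
            raise ScheduleConstraintError(
                "cannot satisfy alternation across block boundary")
    return block
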