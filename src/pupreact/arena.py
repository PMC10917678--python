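"""Arena-based behavioral indices from tracked trajectories.

Covers the four adult arena assays: open field (center-time fraction and
distance traveled in a 40 x 40 cm chamber, center defined as >5 cm from
every wall), elevated plus maze (open-arm time fraction over arm time,
four 30 x 5 cm arms), three-chamber social interaction (preference for the
chamber or cup containing a novel mouse over an empty-cup chamber, three
20 cm x 40 cm compartments) and texture novel-object recognition
(preference for the novel-texture object, with the learning-phase
both-objects criterion).

Boundary convention: every zone membership below uses strict inequalities
as documented per metric; a sample exactly on a boundary falls to the
non-preferred side (e.g. exactly 5.0 cm from an open-field wall is not
center).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARENA_KINDS = ("open_field", "epm", "three_chamber", "nort")


@dataclass
class ArenaGeometry:
    """Arena layout in cm.  Only the fields for ``kind`` are used.

    open_field: ``width`` x ``height`` box, center = > ``center_margin``
        from every wall.
    epm: four arms of ``arm_length`` x ``arm_width`` around a central
        square; open arms extend along x, closed (walled) arms along y.
    three_chamber: three side-by-side compartments each ``chamber_width``
        wide and ``chamber_length`` long (x spans 3 x width); wire-mesh
        cups sit at the centers of the side chambers.
    nort: the open-field box with two objects; investigation is presence
        within ``investigation_radius`` of an object center (object
        half-width + 2 cm by default).
    """

    kind: str
    width: float = 40.0
    height: float = 40.0
    center_margin: float = 5.0
    arm_length: float = 30.0
    arm_width: float = 5.0
    chamber_width: float = 20.0
    chamber_length: float = 40.0
    cup_radius: float = 4.0
    mouse_side: str = "left"
    objects: dict = field(default_factory=dict)   # label -> (x, y)
    novel_object: str = "left"
    investigation_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ARENA_KINDS:
            raise ValueError(f"unknown arena kind {self.kind!r}")
        if self.kind == "nort" and not self.objects:
            self.objects = {"left": (self.width / 3, self.height / 2),
                            "right": (2 * self.width / 3, self.height / 2)}

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the arena footprint."""
        if self.kind in ("open_field", "nort"):
            return 0.0, self.width, 0.0, self.height
        if self.kind == "epm":
            e = self.arm_width / 2 + self.arm_length
            return -e, e, -e, e
        return 0.0, 3 * self.chamber_width, 0.0, self.chamber_length


@dataclass
class Trajectory:
    """Tracked body-centroid positions: time in s, x/y in cm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    arena: ArenaGeometry

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        xmin, xmax, ymin, ymax = self.arena.bounds()
        tol = 1e-9
        inside = ((self.x >= xmin - tol) & (self.x <= xmax + tol) &
                  (self.y >= ymin - tol) & (self.y <= ymax + tol))
        if self.arena.kind == "epm":
            hw = self.arena.arm_width / 2
            on_cross = (np.abs(self.x) <= hw + tol) | (np.abs(self.y) <= hw + tol)
            inside &= on_cross
        if not inside.all():
            raise ValueError("trajectory leaves arena bounds")


def _require(traj: Trajectory, kind: str) -> None:
    if traj.arena.kind != kind:
        raise ValueError(f"metric requires a {kind} arena, got {traj.arena.kind!r}")


def center_time_fraction(traj: Trajectory) -> float:
    """Fraction of samples strictly more than 5 cm from every wall.

    A sample exactly at the margin does not count as center.
    """
    _require(traj, "open_field")
    g = traj.arena
    m = g.center_margin
    d = np.minimum.reduce([traj.x, g.width - traj.x, traj.y, g.height - traj.y])
    return float(np.mean(d > m))


def epm_zone(traj: Trajectory) -> np.ndarray:
    """Per-sample EPM zone: 'open', 'closed' or 'center'.

    Open arms lie along x, closed arms along y.  A sample is in an open
    arm iff |x| strictly exceeds the center half-width and |y| does not;
    symmetric for closed arms; everything else (including boundaries) is
    center.
    """
    _require(traj, "epm")
    hw = traj.arena.arm_width / 2
    zone = np.full(traj.x.shape, "center", dtype=object)
    zone[(np.abs(traj.x) > hw) & (np.abs(traj.y) <= hw)] = "open"
    zone[(np.abs(traj.y) > hw) & (np.abs(traj.x) <= hw)] = "closed"
    return zone


def open_arm_fraction(traj: Trajectory) -> float:
    """Open-arm time / (open-arm + closed-arm time); center time excluded."""
    zone = epm_zone(traj)
    n_open = int(np.sum(zone == "open"))
    n_closed = int(np.sum(zone == "closed"))
    if n_open + n_closed == 0:
        raise ValueError("animal never entered an arm; fraction undefined")
    return n_open / (n_open + n_closed)


def chamber_zone(traj: Trajectory) -> np.ndarray:
    """Per-sample three-chamber zone: 'left', 'center' or 'right'.

    Samples exactly on a partition line are assigned to the center
    chamber.
    """
    _require(traj, "three_chamber")
    w = traj.arena.chamber_width
    zone = np.full(traj.x.shape, "center", dtype=object)
    zone[traj.x < w] = "left"
    zone[traj.x > 2 * w] = "right"
    return zone


def chamber_preference(traj: Trajectory, *, method: str = "chamber") -> float:
    """Preference for the novel-mouse side over the empty-cup side.

    ``method="chamber"`` uses chamber dwell time (as in the headline
    sociability panels); ``method="investigation"`` uses time within
    ``cup_radius + investigation margin`` of each cup (the investigation-
    time reading).  The mouse side comes from the geometry's
    ``mouse_side`` ('left' or 'right'; sides are switched between
    sessions).
    """
    _require(traj, "three_chamber")
    g = traj.arena
    mouse = g.mouse_side
    obj = "right" if mouse == "left" else "left"
    if method == "chamber":
        zone = chamber_zone(traj)
        tm = int(np.sum(zone == mouse))
        to = int(np.sum(zone == obj))
    elif method == "investigation":
        cups = {"left": (g.chamber_width / 2, g.chamber_length / 2),
                "right": (2.5 * g.chamber_width, g.chamber_length / 2)}
        r = g.cup_radius
        def near(side: str) -> int:
            cx, cy = cups[side]
            return int(np.sum(np.hypot(traj.x - cx, traj.y - cy) < r))
        tm, to = near(mouse), near(obj)
    else:
        raise ValueError(f"unknown method {method!r}")
    if tm + to == 0:
        raise ValueError("zero total investigation time; preference undefined")
    return tm / (tm + to)


def _investigation_counts(traj: Trajectory) -> dict[str, int]:
    g = traj.arena
    out = {}
    for label, (cx, cy) in g.objects.items():
        out[label] = int(np.sum(np.hypot(traj.x - cx, traj.y - cy)
                                < g.investigation_radius))
    return out


def object_preference(test: Trajectory, learning: Trajectory) -> float:
    """Novel-object preference during the test phase.

    novel / (novel + familiar) investigation time, where investigation is
    presence within the investigation radius of an object.  Animals that
    did not investigate both objects during the learning phase are
    excluded (ValueError).
    """
    _require(test, "nort")
    _require(learning, "nort")
    learn_counts = _investigation_counts(learning)
    missed = [k for k, v in learn_counts.items() if v == 0]
    if missed:
        raise ValueError(
            f"animal excluded: object(s) {missed} not investigated during learning")
    counts = _investigation_counts(test)
    novel = test.arena.novel_object
    familiar = next(k for k in counts if k != novel)
    total = counts[novel] + counts[familiar]
    if total == 0:
        raise ValueError("zero test-phase investigation time")
    return counts[novel] / total


def distance_traveled(traj: Trajectory) -> float:
    """Total path length in cm (sum of successive Euclidean steps)."""
    if traj.t.size < 2:
        raise ValueError("need at least two samples")
    return float(np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y))))


def zone_dwell_times(traj: Trajectory) -> dict[str, float]:
    """Per-zone dwell time in s (sample count / frame rate)."""
    if traj.arena.kind == "open_field":
        g = traj.arena
        d = np.minimum.reduce([traj.x, g.width - traj.x,
                               traj.y, g.height - traj.y])
        zone = np.where(d > g.center_margin, "center", "border").astype(object)
    elif traj.arena.kind == "epm":
        zone = epm_zone(traj)
    elif traj.arena.kind == "three_chamber":
        zone = chamber_zone(traj)
    else:
        g = traj.arena
        zone = np.full(traj.x.shape, "elsewhere", dtype=object)
        for label, (cx, cy) in g.objects.items():
            zone[np.hypot(traj.x - cx, traj.y - cy) < g.investigation_radius] = label
    labels, counts = np.unique(zone.astype(str), return_counts=True)
    return {lab: c / traj.frame_rate for lab, c in zip(labels, counts)}
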