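"""NRt scoring: state-space boundaries, transition space, the six rules, bouts.

The pipeline turns a manually scored 3-stage hypnogram (W/N/R) plus the
state-space trajectory into a 4-stage hypnogram (W/N/R/t) in four steps:

1. ``find_intersections`` — locate trajectory self-intersections inside a
   5-epoch moving window. Bounded (within-state) trajectories loop and cross
   themselves; directed transition trajectories do not, so crossing points
   concentrate inside the NREM and REM clusters.
2. ``fit_state_boundaries`` — assign the crossing-bounding points to the N or
   R cluster by their manual labels, drop extreme outliers (beyond mean + 5 SD
   centroid distance, single pass), and fit a convex envelope to each cluster.
3. ``define_nrt_space`` — the region traversed by complete NREM-to-REM
   transitions: the convex envelope of all between-boundary points on such
   transitions, minus the interiors of the two state polygons.
4. ``score_4stage`` — relabel sleep epochs to ``t`` where an excursion out of
   a state polygon satisfies all six scoring rules (see the function).

``bout_stats`` then summarises the 4-stage hypnogram into per-bout records and
the NRt metrics (densities per origin state, % of total sleep time, durations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

from .spectral import StateTrajectory

logger = logging.getLogger(__name__)

EPOCH_S = 5.0
LABELS3 = ("W", "N", "R")
LABELS4 = ("W", "N", "R", "t")


# ---------------------------------------------------------------------------
# hypnogram helpers


def check_hypnogram(labels, stages: int = 3) -> np.ndarray:
    """Validate and normalise a label sequence to a numpy array of str."""
    arr = np.asarray(list(labels), dtype=object)
    allowed = set(LABELS3 if stages == 3 else LABELS4)
    bad = sorted({str(v) for v in arr} - allowed)
    if bad:
        raise ValueError(f"unknown hypnogram labels: {bad}")
    return arr.astype(str)


def read_hypnogram(path, stages: int = 3) -> np.ndarray:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("hypnogram CSV needs a 'label' column")
    return check_hypnogram(df["label"].to_numpy(), stages=stages)


def write_hypnogram(labels: np.ndarray, path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(labels)), "label": labels}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 1. trajectory intersections


@dataclass(frozen=True)
class IntersectionEvent:
    """A proper crossing of two non-adjacent trajectory segments.

    ``bounding_epochs`` are the four epoch indices whose two segments cross;
    all four lie within one 5-epoch window.
    """

    point: tuple[float, float]
    bounding_epochs: tuple[int, int, int, int]


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _proper_cross(a0, a1, b0, b1):
    """Return the crossing point if segments a and b properly intersect."""
    d1 = _orient(a0, a1, b0)
    d2 = _orient(a0, a1, b1)
    d3 = _orient(b0, b1, a0)
    d4 = _orient(b0, b1, a1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != d2 and d3 != d4:
        t = d3 / (d3 - d4)
        return (a0[0] + t * (a1[0] - a0[0]), a0[1] + t * (a1[1] - a0[1]))
    return None


def find_intersections(
    traj: StateTrajectory, window: int = 5
) -> list[IntersectionEvent]:
    """All proper segment crossings occurring within a moving epoch window.

    For every window of ``window`` consecutive valid epochs, every pair of
    non-adjacent segments in the window is tested for a proper crossing.
    A crossing found in several overlapping windows is reported once (keyed
    by its segment pair). Degenerate (zero-length) segments are skipped with
    a log entry.
    """
    if traj.n_epochs < window:
        raise ValueError("trajectory shorter than the moving window")
    pts = traj.points()
    seen: dict[tuple[int, int], IntersectionEvent] = {}
    for start in range(traj.n_epochs - window + 1):
        idx = np.arange(start, start + window)
        if not traj.valid[idx].all():
            continue
        segs = [(i, i + 1) for i in idx[:-1]]
        for a in range(len(segs)):
            for b in range(a + 2, len(segs)):  # skip adjacent (shared endpoint)
                ia, ja = segs[a]
                ib, jb = segs[b]
                key = (ia, ib)
                if key in seen:
                    continue
                p0, p1 = pts[ia], pts[ja]
                q0, q1 = pts[ib], pts[jb]
                if np.allclose(p0, p1) or np.allclose(q0, q1):
                    logger.debug("degenerate segment near epoch %d skipped", ia)
                    continue
                hit = _proper_cross(p0, p1, q0, q1)
                if hit is not None:
                    seen[key] = IntersectionEvent(
                        point=hit, bounding_epochs=(ia, ja, ib, jb)
                    )
    return list(seen.values())


# ---------------------------------------------------------------------------
# 2. state boundaries


@dataclass
class StateBoundary:
    """Convex envelope of one sleep state's cluster in state space."""

    state: str
    polygon: Polygon
    centroid: tuple[float, float]
    excluded_points: int
    points: np.ndarray = field(repr=False, default=None)

    def covers(self, x: float, y: float) -> bool:
        """Membership test; a point on the boundary counts as inside."""
        return self.polygon.covers(Point(x, y))

    def vertices(self) -> list[tuple[float, float]]:
        return list(self.polygon.exterior.coords)


class InsufficientControlSleepError(RuntimeError):
    pass


def fit_state_boundaries(
    events: list[IntersectionEvent],
    traj: StateTrajectory,
    labels3: np.ndarray,
    outlier_sd: float = 5.0,
) -> tuple[StateBoundary, StateBoundary]:
    """Fit convex envelopes to the N and R intersection-point clusters.

    Each event contributes its four bounding epochs; each such epoch's
    coordinate point joins the N or R cluster according to the manual 3-stage
    label of that epoch (W-labelled points are discarded; an epoch is counted
    once no matter how many crossings it bounds). Per cluster, points farther
    than mean + ``outlier_sd``*SD of the centroid distance are excluded in a
    single pass, then the convex hull of the survivors is the boundary.
    """
    labels3 = check_hypnogram(labels3, stages=3)
    if len(labels3) != traj.n_epochs:
        raise ValueError("hypnogram length does not match trajectory")
    epochs: dict[str, set[int]] = {"N": set(), "R": set()}
    for ev in events:
        for e in ev.bounding_epochs:
            lab = labels3[e]
            if lab in epochs:
                epochs[lab].add(e)

    bounds = {}
    for state in ("N", "R"):
        idx = np.array(sorted(epochs[state]), dtype=int)
        pts = traj.points()[idx] if idx.size else np.empty((0, 2))
        pts = pts[np.isfinite(pts).all(axis=1)]
        if len(pts) < 3:
            raise InsufficientControlSleepError(
                f"fewer than 3 usable {state}-cluster points: extend the "
                "control period or check the 3-stage scoring"
            )
        centroid = pts.mean(axis=0)
        dist = np.linalg.norm(pts - centroid, axis=1)
        keep = dist <= dist.mean() + outlier_sd * dist.std(ddof=0)
        excluded = int((~keep).sum())
        pts = pts[keep]
        if len(pts) < 3:
            raise InsufficientControlSleepError(
                f"outlier exclusion left fewer than 3 {state}-cluster points"
            )
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if not isinstance(hull, Polygon):
            raise InsufficientControlSleepError(
                f"{state}-cluster points are collinear; no area to bound"
            )
        bounds[state] = StateBoundary(
            state=state,
            polygon=hull,
            centroid=(float(pts.mean(axis=0)[0]), float(pts.mean(axis=0)[1])),
            excluded_points=excluded,
            points=pts,
        )

    if bounds["N"].polygon.intersection(bounds["R"].polygon).area > 0:
        raise ValueError(
            "N and R state boundaries overlap; the control-period clusters "
            "are not separable"
        )
    return bounds["N"], bounds["R"]


# ---------------------------------------------------------------------------
# 3. NRt space


@dataclass
class NRtSpace:
    """Region of state space demarcated by complete N-to-R transitions."""

    hull: Polygon | object  # LineString for degenerate (collinear) cases
    n_transitions: int
    region: object = None  # hull minus state-polygon interiors

    def covers(self, x: float, y: float) -> bool:
        return self.hull.covers(Point(x, y))


class NoCompleteTransitionError(RuntimeError):
    pass


def _positions(traj: StateTrajectory, labels3: np.ndarray,
               bound_n: StateBoundary, bound_r: StateBoundary) -> np.ndarray:
    """Per-epoch position category: W, X (invalid), N, R, or o (outside)."""
    pos = np.empty(traj.n_epochs, dtype="U1")
    pts = traj.points()
    for i in range(traj.n_epochs):
        if labels3[i] == "W":
            pos[i] = "W"
        elif not traj.valid[i]:
            pos[i] = "X"
        elif bound_n.covers(pts[i, 0], pts[i, 1]):
            pos[i] = "N"
        elif bound_r.covers(pts[i, 0], pts[i, 1]):
            pos[i] = "R"
        else:
            pos[i] = "o"
    return pos


def complete_transitions(
    pos: np.ndarray, origin: str = "N", target: str = "R"
) -> list[list[int]]:
    """Index lists of between-boundary epochs on complete origin→target paths.

    A complete transition leaves the origin polygon and enters the target
    polygon with no intervening wake and no return to the origin polygon.
    Direct jumps (no between-boundary epoch) contribute an empty list.
    """
    out: list[list[int]] = []
    n = len(pos)
    i = 0
    while i < n:
        if pos[i] != origin:
            i += 1
            continue
        # last epoch of this origin run
        while i + 1 < n and pos[i + 1] == origin:
            i += 1
        j = i + 1
        between: list[int] = []
        ok = False
        while j < n:
            if pos[j] == "o":
                between.append(j)
                j += 1
            elif pos[j] == target:
                ok = True
                break
            else:  # W, X, or back in origin
                break
        if ok:
            out.append(between)
        i = j if j > i else i + 1
    return out


def define_nrt_space(
    traj: StateTrajectory,
    labels3: np.ndarray,
    bound_n: StateBoundary,
    bound_r: StateBoundary,
) -> NRtSpace:
    """Convex envelope of all between-boundary points on complete N→R paths,
    minus the interiors of the state polygons."""
    labels3 = check_hypnogram(labels3, stages=3)
    pos = _positions(traj, labels3, bound_n, bound_r)
    trans = complete_transitions(pos, "N", "R")
    pts_idx = [e for path in trans for e in path]
    if not trans or not pts_idx:
        raise NoCompleteTransitionError(
            "no complete NREM-to-REM transition with between-boundary points "
            "in the control period; extend the control period"
        )
    pts = traj.points()[pts_idx]
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    region = hull.difference(bound_n.polygon).difference(bound_r.polygon) \
        if isinstance(hull, Polygon) else hull
    return NRtSpace(hull=hull, n_transitions=len(trans), region=region)


# ---------------------------------------------------------------------------
# 4. the six scoring rules


@dataclass
class ScoringResult:
    labels4: np.ndarray
    positions: np.ndarray
    log: list[str] = field(default_factory=list)


def score_4stage(
    traj: StateTrajectory,
    labels3: np.ndarray,
    bound_n: StateBoundary,
    bound_r: StateBoundary,
    nrt_space: NRtSpace,
    arousal_merge_epochs: int = 3,
) -> ScoringResult:
    """Apply the six NRt scoring rules to produce a 4-stage hypnogram.

    Sleep epochs whose trajectory points sit outside both state polygons are
    candidate ``t`` epochs. A maximal run of candidates (an *excursion*,
    possibly continued across single-epoch polygon dips and across manual
    arousals of <= ``arousal_merge_epochs`` epochs) is relabelled ``t`` iff:

    1. it is preceded by two consecutive epochs inside one state polygon
       (the origin);
    2. a landing in a state polygon terminates the excursion only after two
       consecutive in-polygon epochs there;
    3. excursions ending in arousal or returning to the origin polygon last
       at least two epochs;
    4. segments separated by manual arousals of <= 3 epochs belong to one
       excursion (the wake epochs themselves are never relabelled);
    5. excursions out of the N polygon qualify only if they move toward the
       R polygon (the mean x of the first two excursion epochs lies strictly
       on the R side of the x of the last in-N epoch);
    6. every relabelled point falls inside the NRt space demarcated by
       complete N-to-R transitions.

    Wake epochs are never relabelled; epochs with invalid coordinates keep
    their 3-stage label (logged).
    """
    labels3 = check_hypnogram(labels3, stages=3)
    if len(labels3) != traj.n_epochs:
        raise ValueError("hypnogram length does not match trajectory")
    pos = _positions(traj, labels3, bound_n, bound_r)
    n = len(pos)
    out = labels3.copy()
    log: list[str] = []
    for i in np.where(pos == "X")[0]:
        log.append(f"epoch {i}: invalid coordinates, kept 3-stage label")

    # direction toward R along x, from the fitted cluster centroids
    toward_r = np.sign(bound_r.centroid[0] - bound_n.centroid[0]) or 1.0
    x = traj.x

    def rule5_ok(excursion: list[int], last_in_n: int) -> bool:
        head = excursion[:2]
        mean_x = float(np.nanmean(x[head]))
        return (mean_x - x[last_in_n]) * toward_r > 0

    i = 0
    while i < n:
        if pos[i] != "o":
            i += 1
            continue
        # rule 1: two consecutive epochs inside one polygon immediately before
        if i >= 2 and pos[i - 1] == pos[i - 2] and pos[i - 1] in ("N", "R"):
            origin = pos[i - 1]
            origin_last = i - 1
        else:
            origin = None
            origin_last = None

        # assemble the excursion: candidate epochs, continued across brief
        # polygon dips (rule 2) and brief manual arousals (rule 4)
        excursion: list[int] = []
        j = i
        termination = "end"
        while j < n:
            c = pos[j]
            if c == "o":
                excursion.append(j)
                j += 1
            elif c in ("N", "R"):
                if j + 1 < n and pos[j + 1] == c:
                    termination = c
                    break
                j += 1  # 1-epoch dip: not a scored transition, keep going
            elif c == "W":
                k = j
                while k < n and pos[k] == "W":
                    k += 1
                if (k - j) <= arousal_merge_epochs and k < n and pos[k] == "o":
                    j = k  # brief arousal inside one NRt bout
                else:
                    termination = "W"
                    break
            else:  # invalid coordinates end the excursion assessment
                termination = "X"
                break

        scored = False
        if origin is not None and excursion:
            ok = True
            if termination in ("W", "X", "end") or termination == origin:
                ok = len(excursion) >= 2  # rule 3
            if ok and origin == "N":
                ok = rule5_ok(excursion, origin_last)  # rule 5
            if ok:
                # rule 6: only points inside the demarcated NRt space are
                # relabelled; the excursion must pass through that space
                pts = traj.points()
                covered = [e for e in excursion if nrt_space.covers(*pts[e])]
                if covered:
                    out[np.asarray(covered)] = "t"
                    scored = True
        if not scored and excursion:
            log.append(
                f"epochs {excursion[0]}-{excursion[-1]}: excursion not scored "
                f"(origin={origin}, termination={termination}, "
                f"len={len(excursion)})"
            )
        i = max(j, i + 1)

    return ScoringResult(labels4=out, positions=pos, log=log)


# ---------------------------------------------------------------------------
# 5. bout statistics


@dataclass
class BoutTable:
    """Per-bout records and NRt summary metrics for a 4-stage hypnogram."""

    bouts: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.bouts.to_csv(path, index=False)


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encoding: (start, length, label)."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((i, j - i, labels[i]))
        i = j
    return runs


def bout_stats(
    labels4: np.ndarray,
    epoch_s: float = EPOCH_S,
    short_rem_epochs: int = 15,
    long_nrt_epochs: int = 3,
    arousal_merge_epochs: int = 3,
) -> BoutTable:
    """Bout table and NRt summary for a 4-stage hypnogram.

    Bouts are maximal runs of one label. Two t-bouts separated only by a
    manual arousal of <= ``arousal_merge_epochs`` wake epochs count as a
    single bout (its length is the number of t epochs; the wake epochs stay
    wake). A t-bout's origin is the state immediately preceding it. NRt
    density per origin state is bouts per minute spent in the origin state;
    NRt amount is expressed as % of total sleep time (N + R + t epochs).
    """
    labels4 = check_hypnogram(labels4, stages=4)
    runs = _runs(labels4)

    records = []
    consumed: set[int] = set()  # t-runs absorbed into an earlier bout
    for k, (start, length, lab) in enumerate(runs):
        if k in consumed:
            continue
        if lab != "t":
            records.append(
                {"state": lab, "start_epoch": start, "length_epochs": length,
                 "origin": ""}
            )
            continue
        # merge t ... (W<=3) ... t chains into one bout; the wake runs in
        # between remain wake bouts of their own
        total = length
        origin = runs[k - 1][2] if k > 0 else ""
        m = k + 1
        while (
            m + 1 < len(runs)
            and runs[m][2] == "W"
            and runs[m][1] <= arousal_merge_epochs
            and runs[m + 1][2] == "t"
        ):
            total += runs[m + 1][1]
            consumed.add(m + 1)
            m += 2
        records.append(
            {"state": "t", "start_epoch": start, "length_epochs": total,
             "origin": origin}
        )
    bouts = pd.DataFrame.from_records(
        records, columns=["state", "start_epoch", "length_epochs", "origin"]
    )

    counts = {s: int((labels4 == s).sum()) for s in LABELS4}
    minutes = {s: counts[s] * epoch_s / 60.0 for s in LABELS4}
    tst_epochs = counts["N"] + counts["R"] + counts["t"]

    rem = bouts[bouts.state == "R"]
    t_bouts = bouts[bouts.state == "t"]
    summary: dict = {
        "bout_counts": {
            s: int((bouts.state == s).sum()) for s in LABELS4
        },
        "epoch_counts": counts,
        "short_rem_bouts": int((rem.length_epochs <= short_rem_epochs).sum()),
        "long_rem_bouts": int((rem.length_epochs > short_rem_epochs).sum()),
        "long_nrt_bouts": int((t_bouts.length_epochs >= long_nrt_epochs).sum()),
        "nrt_pct_tst": 100.0 * counts["t"] / tst_epochs if tst_epochs else np.nan,
    }
    for origin in ("N", "R"):
        sel = t_bouts[t_bouts.origin == origin]
        n_bouts = int(len(sel))
        if minutes[origin] > 0:
            dens = n_bouts / minutes[origin]
        else:
            dens = np.nan  # undefined, never infinite
        summary[f"nrt_from_{origin}_bouts"] = n_bouts
        summary[f"nrt_from_{origin}_density_per_min"] = dens
        summary[f"nrt_from_{origin}_mean_duration_s"] = (
            float(sel.length_epochs.mean() * epoch_s) if n_bouts else np.nan
        )
        summary[f"nrt_from_{origin}_pct_tst"] = (
            100.0 * float(sel.length_epochs.sum()) / tst_epochs
            if tst_epochs else np.nan
        )
    return BoutTable(bouts=bouts, summary=summary)
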