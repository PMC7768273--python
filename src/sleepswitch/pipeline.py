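"""End-to-end orchestration: the scoring pipeline, seeds, and run manifests.

``score_recording`` is the canonical path from a band-power table plus a
manual 3-stage hypnogram to a 4-stage hypnogram with bout statistics:
boundaries and NRt space are defined on a control epoch range and applied to
the whole recording (control-period boundaries are reused for later periods,
so drug-period scoring never redefines the geometry it is scored against).

Every CLI run writes a manifest (config snapshot, seeds, file hashes,
derived thresholds/calibrations, package version) sufficient to re-run the
stage bit-identically. A single top-level seed fans out to per-stage
sub-seeds via ``numpy.random.SeedSequence`` spawn keys, so adding a stage
never perturbs the streams of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scoring import (
    BoutTable,
    NRtSpace,
    ScoringResult,
    StateBoundary,
    bout_stats,
    check_hypnogram,
    define_nrt_space,
    find_intersections,
    fit_state_boundaries,
    score_4stage,
)
from .spectral import EpochBandPowers, StateTrajectory, compute_trajectory

STAGE_KEYS = {"synth": 1, "spectral": 2, "score": 3, "flipflop": 4,
              "diffusion": 5, "stats": 6}


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a stable per-stage sub-seed from the top-level seed."""
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(root_seed, spawn_key=(STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ScoredRecording:
    trajectory: StateTrajectory
    bound_n: StateBoundary
    bound_r: StateBoundary
    nrt_space: NRtSpace
    result: ScoringResult
    bouts: BoutTable
    control_range: tuple[int, int]

    @property
    def labels4(self) -> np.ndarray:
        return self.result.labels4


def score_recording(
    powers: EpochBandPowers,
    labels3: np.ndarray,
    control_range: tuple[int, int] | None = None,
    smooth_window: int = 5,
) -> ScoredRecording:
    """Run the full NRt scoring pipeline on one recording.

    Boundaries, and the NRt space demarcated by complete transitions, are
    fit on ``control_range`` (default: the whole recording) and then applied
    to every epoch.
    """
    labels3 = check_hypnogram(labels3, stages=3)
    if len(labels3) != powers.n_epochs:
        raise ValueError("hypnogram length does not match band powers")
    traj = compute_trajectory(powers, smooth_window=smooth_window)
    lo, hi = control_range if control_range is not None else (0, powers.n_epochs)
    if not (0 <= lo < hi <= powers.n_epochs):
        raise ValueError("invalid control range")
    ctraj = traj.slice(lo, hi)
    clabels = labels3[lo:hi]
    events = find_intersections(ctraj)
    bound_n, bound_r = fit_state_boundaries(events, ctraj, clabels)
    nrt = define_nrt_space(ctraj, clabels, bound_n, bound_r)
    result = score_4stage(traj, labels3, bound_n, bound_r, nrt)
    bouts = bout_stats(result.labels4)
    return ScoredRecording(
        trajectory=traj,
        bound_n=bound_n,
        bound_r=bound_r,
        nrt_space=nrt,
        result=result,
        bouts=bouts,
        control_range=(lo, hi),
    )


# ---------------------------------------------------------------------------
# manifests


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    seed: int | None
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    version: str = __version__

    def add_input(self, name: str, path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": file_sha256(path)}

    def add_output(self, name: str, path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": file_sha256(path)}

    def write(self, out_dir) -> Path:
        out = Path(out_dir) / "manifest.json"
        payload = {
            "stage": self.stage,
            "seed": self.seed,
            "version": self.version,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "derived": self.derived,
        }
        with open(out, "w") as fh:
            json.dump(payload, fh, indent=2, default=_coerce)
        return out


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def effect_table(
    metrics: pd.DataFrame,
    value: str,
    condition_col: str,
    pair: tuple[str, str],
    id_col: str,
    n_boot: int = 5000,
    seed: int | None = None,
) -> dict:
    """Paired effect estimate between two conditions of a metrics table."""
    from .estimation import paired_mean_difference

    a_df = metrics[metrics[condition_col] == pair[0]].set_index(id_col)[value]
    b_df = metrics[metrics[condition_col] == pair[1]].set_index(id_col)[value]
    common = a_df.index.intersection(b_df.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 paired observations")
    est = paired_mean_difference(
        a_df.loc[common].to_numpy(), b_df.loc[common].to_numpy(),
        n_boot=n_boot, seed=seed,
    )
    out = est.as_dict()
    out.update({"metric": value, "pair": list(pair), "n_pairs": int(len(common))})
    return out
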