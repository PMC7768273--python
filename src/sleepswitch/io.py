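"""File-format plumbing: raw EEG input and boundary serialisation."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .scoring import NRtSpace, StateBoundary


def read_raw_csv(path) -> tuple[np.ndarray, float]:
    """Read a 2-column (time, value) CSV; the sampling rate is inferred
    from the median time step."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("raw CSV needs two columns: time, value")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError("time column must be increasing")
    return v, 1.0 / dt


def read_raw_edf(path, channel: str):
    """Read one EEG channel from an EDF file (requires the ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF input needs the optional dependency mne "
            "(pip install sleepswitch[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True,
                              verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"channel {channel!r} not found in {path}")
    data = raw.get_data(picks=[channel])[0]
    return data, float(raw.info["sfreq"])


def boundaries_to_json(
    bound_n: StateBoundary, bound_r: StateBoundary, nrt: NRtSpace
) -> dict:
    """GeoJSON-style vertex lists for plotting or re-use."""
    def poly(g):
        if hasattr(g, "exterior"):
            return [list(c) for c in g.exterior.coords]
        return [list(c) for c in g.coords]  # degenerate (line) hull

    return {
        "N": {
            "vertices": poly(bound_n.polygon),
            "centroid": list(bound_n.centroid),
            "excluded_points": bound_n.excluded_points,
        },
        "R": {
            "vertices": poly(bound_r.polygon),
            "centroid": list(bound_r.centroid),
            "excluded_points": bound_r.excluded_points,
        },
        "NRt": {
            "vertices": poly(nrt.hull),
            "n_transitions": nrt.n_transitions,
        },
    }


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
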