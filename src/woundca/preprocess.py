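"""Flag-based QC, four-step percentile normalization, and fold-change computation.

The normalization protocol for a 4 time point x 4 replicate one-color array
study is:

1. signals below background (negative values) are set to 1 ("not expressed");
2. the four replicate signals of a gene at one time point are collapsed to
   their geometric mean (the representative value);
3. representative values are log2-transformed;
4. the 75th percentile of each time point's log2 values is subtracted from
   every gene at that time point (quantile-anchored inter-array correction,
   under the assumption that most genes do not fluctuate).

Fold changes FC6/FC12/FC24 are ratios of the *non-log* normalized value at
each post-injury time to the control's.

Two value tracks are produced: the *representative* track above (one value
per gene per time point) feeding fold changes and correspondence analysis,
and a *per-array* track (clip, log2, per-array 75th-percentile shift) that
keeps replicates separate so that ANOVA / Tukey HSD can consume them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FLAG_VALUES",
    "SignalMatrix",
    "NormalizedTable",
    "clip_negative_signals",
    "summarize_replicates",
    "percentile_shift",
    "call_feature_status",
    "qc_retained",
    "normalize",
    "normalize_per_array",
    "compute_fold_change",
]

#: Per-feature per-array flag calls: Detected / Not Detected / Compromised.
FLAG_VALUES = ("Dt", "NDt", "Cm")

_ARRAY_RE = re.compile(r"^t(\d+)_r(\d+)$")


def parse_array_id(array_id: str) -> tuple[str, int]:
    """Split an array id like ``t6_r2`` into (time label ``t6``, replicate 2)."""
    m = _ARRAY_RE.match(str(array_id))
    if m is None:
        raise ValueError(
            f"array id {array_id!r} does not match the 't<time>_r<rep>' dialect"
        )
    return f"t{int(m.group(1))}", int(m.group(2))


@dataclass
class SignalMatrix:
    """Raw per-feature, per-array signals plus flag calls.

    ``signals`` and ``flags`` are gene x array DataFrames with identical
    index/columns; array ids encode time point and replicate as ``t6_r2``
    (``t0`` is the uninjured control).
    """

    signals: pd.DataFrame
    flags: pd.DataFrame
    time_points: tuple[str, ...] = field(init=False)
    n_replicates: int = field(init=False)

    def __post_init__(self) -> None:
        if self.signals.index.has_duplicates:
            raise ValueError("duplicate gene ids in signal table")
        if not self.signals.index.equals(self.flags.index) or not self.signals.columns.equals(
            self.flags.columns
        ):
            raise ValueError("signals and flags tables have mismatched shape or labels")
        bad = set(np.unique(self.flags.to_numpy())) - set(FLAG_VALUES)
        if bad:
            raise ValueError(f"unknown flag tokens: {sorted(bad)}")
        parsed = [parse_array_id(c) for c in self.signals.columns]
        times = list(dict.fromkeys(t for t, _ in parsed))  # preserve order
        reps = {t: sum(1 for tt, _ in parsed if tt == t) for t in times}
        if len(set(reps.values())) != 1:
            raise ValueError(f"unbalanced replicate counts per time point: {reps}")
        self.time_points = tuple(times)
        self.n_replicates = next(iter(reps.values()))

    @property
    def control(self) -> str:
        return self.time_points[0]

    def arrays_at(self, time_point: str) -> list[str]:
        """Column labels of the arrays belonging to one time point."""
        return [c for c in self.signals.columns if parse_array_id(c)[0] == time_point]


@dataclass
class NormalizedTable:
    """Per gene x time point normalized values, log2 and non-log tracks."""

    log2: pd.DataFrame     # shifted log2 representative values
    nonlog: pd.DataFrame   # 2 ** log2, the "normalized non-logarithmic signal values"
    control: str

    def __post_init__(self) -> None:
        if not np.allclose(self.nonlog.to_numpy(), 2.0 ** self.log2.to_numpy(), atol=1e-9):
            raise ValueError("log2 and non-log tracks are inconsistent")


def clip_negative_signals(raw_signal):
    """Replace below-background (negative) signals with 1.

    A negative scanner signal means the feature did not express above
    background; it is mapped to 1 so that its log2 is 0. Nonnegative values
    pass through unchanged. Accepts scalars or arrays.
    """
    arr = np.asarray(raw_signal, dtype=float)
    out = np.where(arr < 0, 1.0, arr)
    if np.ndim(raw_signal) == 0:
        return float(out)
    return out


def summarize_replicates(values) -> float:
    """Geometric mean of one gene's replicate signals at one time point."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty replicate set")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive signals (clip first)")
    return float(stats.gmean(arr))


def percentile_shift(log2_values, q: float = 75.0, method: str = "linear"):
    """Subtract the ``q``-th percentile of a time point's log2 values from each gene.

    Uses linear interpolation between order statistics by default
    (numpy's convention); after the shift the column's ``q``-th percentile is 0.
    """
    arr = np.asarray(log2_values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot percentile-shift an empty column")
    return arr - np.percentile(arr, q, method=method)


def call_feature_status(flags) -> str:
    """Collapse one feature's per-array flags into a single Dt/NDt/Cm status.

    ``Cm`` if any array is Compromised; else ``NDt`` if any array is
    Not Detected; else ``Dt`` (detected on every single array).
    """
    arr = np.asarray(flags, dtype=object)
    if arr.size == 0:
        raise ValueError("feature has no array flags")
    bad = set(arr.ravel()) - set(FLAG_VALUES)
    if bad:
        raise ValueError(f"unknown flag tokens: {sorted(bad)}")
    if np.any(arr == "Cm"):
        return "Cm"
    if np.any(arr == "NDt"):
        return "NDt"
    return "Dt"


def feature_status(flags: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`call_feature_status` over a gene x array flag table."""
    arr = flags.to_numpy(dtype=object)
    bad = set(arr.ravel()) - set(FLAG_VALUES)
    if bad:
        raise ValueError(f"unknown flag tokens: {sorted(bad)}")
    status = np.where(
        (arr == "Cm").any(axis=1),
        "Cm",
        np.where((arr == "NDt").any(axis=1), "NDt", "Dt"),
    )
    return pd.Series(status, index=flags.index, name="status")


def qc_retained(sm: SignalMatrix) -> pd.Series:
    """Boolean mask of genes kept for analysis (status Dt or NDt; Cm excluded)."""
    return feature_status(sm.flags) != "Cm"


def normalize(sm: SignalMatrix, percentile: float = 75.0, method: str = "linear") -> NormalizedTable:
    """Run the four-step representative-track normalization.

    Replicates are collapsed by geometric mean before the log2 / percentile
    steps; the output has one column per time point.
    """
    clipped = clip_negative_signals(sm.signals.to_numpy())
    cols = {}
    for t in sm.time_points:
        idx = [sm.signals.columns.get_loc(c) for c in sm.arrays_at(t)]
        cols[t] = stats.gmean(clipped[:, idx], axis=1)
    rep = pd.DataFrame(cols, index=sm.signals.index)
    log2 = np.log2(rep)
    shifted = log2.apply(lambda col: percentile_shift(col.to_numpy(), percentile, method), axis=0)
    shifted = pd.DataFrame(shifted, index=rep.index, columns=rep.columns)
    return NormalizedTable(log2=shifted, nonlog=2.0 ** shifted, control=sm.control)


def normalize_per_array(sm: SignalMatrix, percentile: float = 75.0, method: str = "linear") -> pd.DataFrame:
    """Per-array track: clip, log2, per-array percentile shift. Keeps replicates."""
    clipped = clip_negative_signals(sm.signals.to_numpy())
    log2 = np.log2(clipped)
    shifted = log2 - np.percentile(log2, percentile, axis=0, method=method)
    return pd.DataFrame(shifted, index=sm.signals.index, columns=sm.signals.columns)


def compute_fold_change(normalized: NormalizedTable) -> pd.DataFrame:
    """Non-log fold change of each post-control time point vs the control.

    Returns a gene x time DataFrame with columns named ``FC6``-style
    (``FC`` + the numeric part of the time label).
    """
    ctrl = normalized.nonlog[normalized.control].to_numpy()
    if np.any(ctrl <= 0):
        raise ValueError("non-positive control signal; normalization output is corrupt")
    out = {}
    for t in normalized.nonlog.columns:
        if t == normalized.control:
            continue
        out[f"FC{t.lstrip('t')}"] = normalized.nonlog[t].to_numpy() / ctrl
    return pd.DataFrame(out, index=normalized.nonlog.index)
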