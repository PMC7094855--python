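"""ANOVA + Tukey HSD differential calling and the 27-pattern fluctuation taxonomy.

Per gene, a one-way fixed-effects ANOVA across the four time groups screens
for any fluctuation; genes passing a Benjamini-Hochberg screen (corrected
p < alpha) get all-pairs Tukey HSD, of which the three control-vs-time
contrasts drive the calls. Each gene ends with a triple over {U, D, -}
(up / down / unchanged at 6, 12, 24 h), one of 27 pattern codes.

BH families: one family per test type — the ANOVA p-values across genes form
one family; each control contrast's Tukey p-values across the tested genes
form another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import parse_array_id

__all__ = [
    "ALL_PATTERNS",
    "SignificanceCalls",
    "ThresholdGeneSet",
    "anova_per_gene",
    "tukey_control_contrasts",
    "bh_adjust",
    "call_significance",
    "classify_pattern",
    "pattern_counts",
    "build_threshold_sets",
]

#: The 27 fluctuation codes, e.g. "U-D" = up at 6 h, unchanged at 12 h, down at 24 h.
ALL_PATTERNS = tuple("".join(p) for p in itertools.product("UD-", repeat=3))


def anova_per_gene(groups) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F and p for one gene.

    ``groups`` is a sequence of per-time-point replicate value arrays.
    Zero between- and within-group variance yields an undefined F reported
    as (nan, nan) — a no-call.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 replicates each")
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _anova_vectorized(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """F and p per gene; each element of ``groups`` is genes x replicates."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups, axis=1)
    return np.asarray(f, dtype=float), np.asarray(p, dtype=float)


@lru_cache(maxsize=8)
def _sf_grid(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Monotone grid of the studentized-range survival function for interpolation."""
    q = np.concatenate(
        [
            np.linspace(0.0, 8.0, 400, endpoint=False),
            np.linspace(8.0, 30.0, 220, endpoint=False),
            np.linspace(30.0, 120.0, 91),
        ]
    )
    sf = stats.studentized_range.sf(q, k, df)
    return q, sf


def studentized_range_sf(q, k: int, df: int, method: str = "auto"):
    """Upper tail of the studentized range; ``method`` 'exact', 'interp' or 'auto'.

    'exact' integrates numerically (scipy); 'interp' evaluates a cached grid
    (absolute error ~2e-5, adequate for screening thousands of genes); 'auto'
    picks 'exact' for <= 64 values.
    """
    q = np.asarray(q, dtype=float)
    if method == "auto":
        method = "exact" if q.size <= 64 else "interp"
    if method == "exact":
        return stats.studentized_range.sf(q, k, df)
    if method == "interp":
        grid_q, grid_sf = _sf_grid(k, df)
        return np.interp(q, grid_q, grid_sf)
    raise ValueError(f"unknown method {method!r}")


def tukey_control_contrasts(groups, method: str = "exact") -> np.ndarray:
    """Tukey HSD p-values of the control-vs-time contrasts for one gene.

    All pairwise contrasts are part of the HSD procedure (the studentized
    range is taken over all k group means); only the contrasts against the
    first group (the control) are returned, in time order.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("Tukey HSD needs >= 2 groups with >= 2 replicates each")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(ns.sum() - k)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    if mse == 0:
        return np.where(means[1:] == means[0], 1.0, 0.0)
    # Tukey-Kramer standard error for possibly unequal n
    se = np.sqrt(mse / 2.0 * (1.0 / ns[0] + 1.0 / ns[1:]))
    q = np.abs(means[1:] - means[0]) / se
    return np.asarray(studentized_range_sf(q, k, df, method=method), dtype=float)


def _tukey_vectorized(groups: list[np.ndarray], method: str = "auto"):
    """Control-contrast Tukey p and mean differences, genes x (k-1)."""
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    df = int(ns.sum() - k)
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)  # genes x k
    sse = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    mse = sse / df
    diffs = means[:, 1:] - means[:, [0]]
    se = np.sqrt(mse[:, None] / 2.0 * (1.0 / ns[0] + 1.0 / ns[1:])[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.abs(diffs) / se
    p = np.asarray(studentized_range_sf(q.ravel(), k, df, method=method)).reshape(q.shape)
    # zero pooled variance: identical means -> p 1, any difference -> p 0
    degenerate = mse == 0
    if degenerate.any():
        p[degenerate] = np.where(diffs[degenerate] == 0, 1.0, 0.0)
    return p, diffs


def bh_adjust(p_values, family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family per call)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"p-values outside [0, 1] in family {family!r}")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignificanceCalls:
    """Per-gene ANOVA/Tukey p-values (raw and BH-adjusted) and U/D/- calls."""

    anova_p: pd.Series
    anova_q: pd.Series
    tukey_p: pd.DataFrame   # genes x time, NaN where Tukey was not run
    tukey_q: pd.DataFrame
    calls: pd.DataFrame     # genes x time with values in {"U", "D", "-"}
    alpha: float

    @property
    def patterns(self) -> pd.Series:
        """Three-character pattern code per gene, e.g. ``U-D``."""
        codes = self.calls.apply(lambda row: "".join(row), axis=1)
        codes.name = "pattern"
        return codes


def call_significance(
    per_array_log2: pd.DataFrame, alpha: float = 0.05, method: str = "auto"
) -> SignificanceCalls:
    """Run the ANOVA -> BH -> Tukey HSD -> BH calling cascade over all genes.

    ``per_array_log2`` is a gene x array table (array ids ``t0_r1`` ...);
    the first time point in column order is the control. Genes failing the
    BH-corrected ANOVA screen at ``alpha`` receive ``-`` at every time point
    without Tukey testing.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    times = list(dict.fromkeys(parse_array_id(c)[0] for c in per_array_log2.columns))
    by_time = [
        per_array_log2[[c for c in per_array_log2.columns if parse_array_id(c)[0] == t]].to_numpy()
        for t in times
    ]
    genes = per_array_log2.index
    contrast_times = times[1:]

    f, p = _anova_vectorized(by_time)
    anova_p = pd.Series(p, index=genes, name="anova_p")
    valid = np.isfinite(p)
    anova_q = pd.Series(np.nan, index=genes, name="anova_q")
    if valid.any():
        anova_q[valid] = bh_adjust(p[valid], family="anova")

    tested = (anova_q < alpha).to_numpy(dtype=bool) & valid
    tukey_p = pd.DataFrame(np.nan, index=genes, columns=contrast_times)
    tukey_q = pd.DataFrame(np.nan, index=genes, columns=contrast_times)
    calls = pd.DataFrame("-", index=genes, columns=contrast_times)
    if tested.any():
        sub = [g[tested] for g in by_time]
        p_mat, diffs = _tukey_vectorized(sub, method=method)
        tukey_p.loc[tested, :] = p_mat
        q_mat = np.column_stack(
            [bh_adjust(p_mat[:, j], family=f"tukey_{t}") for j, t in enumerate(contrast_times)]
        )
        tukey_q.loc[tested, :] = q_mat
        sig = q_mat < alpha
        call_mat = np.where(sig & (diffs > 0), "U", np.where(sig & (diffs < 0), "D", "-"))
        calls.loc[tested, :] = call_mat
    return SignificanceCalls(
        anova_p=anova_p, anova_q=anova_q, tukey_p=tukey_p, tukey_q=tukey_q,
        calls=calls, alpha=alpha,
    )


def classify_pattern(calls: SignificanceCalls, gene) -> str:
    """The gene's fluctuation code: its three U/D/- calls joined in time order."""
    return "".join(calls.calls.loc[gene])


def pattern_counts(patterns: pd.Series) -> pd.Series:
    """Tabulate pattern codes over all 27 categories (zeros included)."""
    counts = patterns.value_counts().reindex(ALL_PATTERNS, fill_value=0)
    counts.name = "n_genes"
    counts.index.name = "pattern"
    return counts


@dataclass
class ThresholdGeneSet:
    """Tukey-significant genes whose FC clears a 3- or 5-fold threshold."""

    genes: tuple[str, ...]
    time: str
    direction: str          # "up" or "down"
    threshold: float        # 3 or 5; down means FC < 1/threshold

    def __len__(self) -> int:
        return len(self.genes)


def build_threshold_sets(
    calls: SignificanceCalls, fc: pd.DataFrame, threshold: float, direction: str, time: str
) -> ThresholdGeneSet:
    """Genes significantly up (down) at ``time`` with FC > threshold (< 1/threshold).

    Strict inequalities ("more than" 3- or 5-fold); the 3-fold set is by
    construction a superset of the 5-fold set in the same direction.
    """
    fc_col = f"FC{time.lstrip('t')}"
    if time not in calls.calls.columns or fc_col not in fc.columns:
        raise ValueError(f"unknown time label {time!r}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    common = calls.calls.index.intersection(fc.index)
    call_col = calls.calls.loc[common, time]
    fc_vals = fc.loc[common, fc_col]
    if direction == "up":
        mask = (call_col == "U") & (fc_vals > threshold)
    else:
        mask = (call_col == "D") & (fc_vals < 1.0 / threshold)
    return ThresholdGeneSet(
        genes=tuple(sorted(common[mask])), time=time, direction=direction, threshold=threshold
    )
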