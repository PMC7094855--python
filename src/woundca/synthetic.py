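"""Synthetic microarray time-course studies with planted ground truth.

Emulates a one-color array design of 4 time points (uninjured control, 6,
12, 24 h post-injury) x 4 replicate animals: per-gene baselines are drawn
lognormally (normal on the log2 scale), each gene carries one of 27
fluctuation codes over {U, D, -} whose planted shifts of +-effect_log2fc are
added at the corresponding time points, replicate noise is additive Gaussian
on log2 signals, and Dt/NDt/Cm flags are drawn independently per feature per
array. An annotation catalog with planted-enriched terms accompanies the
signals so the enrichment stage is testable end to end.

All randomness flows from a single seed; substreams are spawned
deterministically, so an identical config yields a bitwise-identical study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .differential import ALL_PATTERNS
from .enrichment import AnnotationCatalog, CATEGORIES
from .preprocess import SignalMatrix

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "default_pattern_mix",
    "generate_study",
    "generate_worked_fixture",
    "simulate_fold_change_triples",
]


def default_pattern_mix() -> dict[str, float]:
    """Default proportions over the 27 fluctuation codes.

    Injured-muscle arrays are dominated by unchanged and downregulated
    genes: 40% ``---``, 12% ``DDD``, 5% ``UUU``, and the remaining 43%
    spread uniformly over the other 24 codes.
    """
    mix = {p: 0.43 / 24.0 for p in ALL_PATTERNS}
    mix["---"] = 0.40
    mix["DDD"] = 0.12
    mix["UUU"] = 0.05
    return mix


@dataclass
class StudyConfig:
    """Generative model parameters for one synthetic study.

    Defaults describe a realistic incision-injury screen: baselines centered
    at log2 signal 7 with spread 2, replicate noise sd 0.25 on log2 (typical
    array technical + biological variation), planted shifts of 3 log2 units
    (8-fold, a strong injury response), and sparse QC failures.
    """

    n_genes: int = 2000
    n_replicates: int = 4
    time_points: tuple[str, ...] = ("t0", "t6", "t12", "t24")
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.25
    pattern_mix: dict[str, float] = field(default_factory=default_pattern_mix)
    effect_log2fc: float = 3.0
    flag_ndt_rate: float = 0.05
    flag_cm_rate: float = 0.01
    n_terms: int = 50
    term_size: int = 40
    n_enriched_terms: int = 5
    enrichment_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_replicates", "n_terms", "term_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_enriched_terms < 0 or self.n_enriched_terms > self.n_terms:
            raise ValueError("n_enriched_terms must lie in [0, n_terms]")
        for name in ("baseline_log2_sd", "noise_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("flag_ndt_rate", "flag_cm_rate", "enrichment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.flag_ndt_rate + self.flag_cm_rate > 1.0:
            raise ValueError("flag_ndt_rate + flag_cm_rate must not exceed 1")
        if len(self.time_points) < 2:
            raise ValueError("need a control plus at least one post-injury time point")
        unknown = set(self.pattern_mix) - set(ALL_PATTERNS)
        if unknown:
            raise ValueError(f"pattern_mix has unknown codes: {sorted(unknown)}")
        total = float(sum(self.pattern_mix.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"pattern_mix proportions sum to {total}, not 1")


@dataclass
class GroundTruth:
    """What was planted: per-gene pattern code, true FC triple, enriched terms."""

    patterns: pd.Series        # gene -> 27-category code, e.g. "U-D"
    true_fc: pd.DataFrame      # gene x (FC6, FC12, FC24), 2**(planted shift)
    enriched_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        # pattern codes must match the sign of the planted log2 effects
        shifts = np.log2(self.true_fc.to_numpy())
        codes = np.array([list(p) for p in self.patterns])
        ok = (
            ((codes == "U") & (shifts > 0))
            | ((codes == "D") & (shifts < 0))
            | ((codes == "-") & (shifts == 0))
        )
        if not ok.all():
            raise ValueError("planted pattern codes inconsistent with planted effects")


_SHIFT = {"U": 1.0, "D": -1.0, "-": 0.0}


def generate_study(config: StudyConfig) -> tuple[SignalMatrix, AnnotationCatalog, GroundTruth]:
    """Draw one full synthetic study from the generative model.

    Returns the raw signal/flag matrix, the annotation catalog (with the
    planted-enriched terms listed first), and the ground truth. The same
    config (including seed) reproduces the output bitwise.
    """
    root = np.random.default_rng(config.seed)
    rng_expr, rng_flags, rng_terms = root.spawn(3)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    codes = np.array(sorted(config.pattern_mix))
    probs = np.array([config.pattern_mix[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    patterns = rng_expr.choice(codes, size=config.n_genes, p=probs)

    n_post = len(config.time_points) - 1
    shifts = np.array(
        [[_SHIFT[ch] * config.effect_log2fc for ch in p[:n_post]] for p in patterns]
    )  # genes x post-injury times
    baseline = rng_expr.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes
    )

    cols, data = [], []
    for j, t in enumerate(config.time_points):
        mean = baseline if j == 0 else baseline + shifts[:, j - 1]
        for r in range(config.n_replicates):
            noise = rng_expr.normal(0.0, config.noise_log2_sd, size=config.n_genes)
            data.append(2.0 ** (mean + noise))
            cols.append(f"{t}_r{r + 1}")
    signals = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)

    u = rng_flags.random(size=signals.shape)
    flag_arr = np.where(
        u < config.flag_cm_rate,
        "Cm",
        np.where(u < config.flag_cm_rate + config.flag_ndt_rate, "NDt", "Dt"),
    )
    flags = pd.DataFrame(flag_arr, index=genes, columns=cols)

    catalog, enriched = _generate_catalog(config, genes, patterns, rng_terms)
    truth = GroundTruth(
        patterns=pd.Series(patterns, index=genes, name="pattern"),
        true_fc=pd.DataFrame(
            2.0**shifts,
            index=genes,
            columns=[f"FC{t.lstrip('t')}" for t in config.time_points[1:]],
        ),
        enriched_terms=tuple(enriched),
    )
    return SignalMatrix(signals=signals, flags=flags), catalog, truth


def _generate_catalog(config, genes, patterns, rng):
    """Annotation catalog; enriched terms get an exact planted up-gene fraction."""
    genes = np.array(genes)
    up_pool = genes[patterns == "UUU"]
    other_pool = genes[patterns != "UUU"]
    n_up = int(round(config.enrichment_fraction * config.term_size))
    terms, names, cats = {}, {}, {}
    enriched = []
    for i in range(config.n_terms):
        tid = f"T{i + 1:04d}"
        planted = i < config.n_enriched_terms
        if planted:
            if len(up_pool) < n_up or len(other_pool) < config.term_size - n_up:
                raise ValueError(
                    "not enough genes of the required patterns to plant enriched terms"
                )
            members = np.concatenate(
                [
                    rng.choice(up_pool, size=n_up, replace=False),
                    rng.choice(other_pool, size=config.term_size - n_up, replace=False),
                ]
            )
            enriched.append(tid)
        else:
            members = rng.choice(genes, size=min(config.term_size, len(genes)), replace=False)
        terms[tid] = tuple(sorted(members))
        names[tid] = f"synthetic term {i + 1}"
        cats[tid] = "pathway" if planted else CATEGORIES[i % len(CATEGORIES)]
    return AnnotationCatalog(terms=terms, names=names, categories=cats), enriched


def simulate_fold_change_triples(
    n_genes: int, log2_spread: float = 1.5, min_log2_gap: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """FC triples with continuous orderings, for geometry experiments.

    Draws independent N(0, log2_spread) log2 fold changes per time point;
    with ``min_log2_gap`` > 0, genes whose closest FC pair is nearer than
    the gap are redrawn, yielding well-separated strict orderings.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_genes, 3))
    filled = 0
    while filled < n_genes:
        batch = rng.normal(0.0, log2_spread, size=(2 * (n_genes - filled) + 16, 3))
        if min_log2_gap > 0:
            srt = np.sort(batch, axis=1)
            ok = np.diff(srt, axis=1).min(axis=1) >= min_log2_gap
            batch = batch[ok]
        take = min(len(batch), n_genes - filled)
        out[filled : filled + take] = batch[:take]
        filled += take
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    return pd.DataFrame(2.0**out, index=genes, columns=["FC6", "FC12", "FC24"])


# ---------------------------------------------------------------------------
# Worked fixture: 9 genes with hand-computable normalization and geometry.
#
# log2 geometric means (gene x time); replicates are constant at 2**value
# except WG01 whose replicates are (2, 8, 2, 8) at every time (geometric
# mean 4, log2 = 2). Each 9-value column's 75th percentile is its 7th order
# statistic: (5, 9, 9, 9), so the percentile shift is 4 at every post-injury
# time relative to control and the realized log2 FC is (shift - 4).
_FIXTURE_LOG2 = {
    #        t0  t6  t12 t24
    "WG01": (2, 2, 2, 2),      # FC (1/16, 1/16, 1/16): exact tie -> no area
    "WG02": (5, 8, 9, 10),     # FC (0.5, 1, 2)   -> area A
    "WG03": (5, 8, 10, 9),     # FC (0.5, 2, 1)   -> area B
    "WG04": (5, 9, 10, 8),     # FC (1, 2, 0.5)   -> area C
    "WG05": (5, 10, 9, 8),     # FC (2, 1, 0.5)   -> area D
    "WG06": (5, 10, 8, 9),     # FC (2, 0.5, 1)   -> area E
    "WG07": (5, 9, 8, 10),     # FC (1, 0.5, 2)   -> area F
    "WG08": (6, 4, 3, 2),      # FC (2**-6, 2**-7, 2**-8) -> area D (down)
    "WG09": (4, 4, 4, 4),      # carries a Cm flag -> excluded by QC
}

#: Expected area annotation per fixture gene (ties marked).
FIXTURE_AREAS = {
    "WG01": "tie", "WG02": "A", "WG03": "B", "WG04": "C",
    "WG05": "D", "WG06": "E", "WG07": "F", "WG08": "D",
}

#: Expected fold changes of the QC-retained fixture genes.
FIXTURE_FC = {
    "WG01": (2**-4, 2**-4, 2**-4),
    "WG02": (0.5, 1.0, 2.0),
    "WG03": (0.5, 2.0, 1.0),
    "WG04": (1.0, 2.0, 0.5),
    "WG05": (2.0, 1.0, 0.5),
    "WG06": (2.0, 0.5, 1.0),
    "WG07": (1.0, 0.5, 2.0),
    "WG08": (2.0**-6, 2.0**-7, 2.0**-8),
}


def generate_worked_fixture() -> tuple[SignalMatrix, AnnotationCatalog, GroundTruth]:
    """The fixed 9-gene worked example shipped with the package.

    Signals are exact powers of two, every column's 75th percentile is an
    order statistic, and the fold-change triples land in each of the six
    areas once (plus one exact tie and one Cm-excluded gene), so every
    pipeline stage can be checked by hand against the frozen annotations in
    :data:`FIXTURE_FC` and :data:`FIXTURE_AREAS`.
    """
    times = ("t0", "t6", "t12", "t24")
    cols = [f"{t}_r{r}" for t in times for r in range(1, 5)]
    rows = {}
    for gene, log2s in _FIXTURE_LOG2.items():
        vals = []
        for tval in log2s:
            if gene == "WG01":
                vals.extend([2.0, 8.0, 2.0, 8.0])
            else:
                vals.extend([2.0**tval] * 4)
        rows[gene] = vals
    signals = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    flags = pd.DataFrame("Dt", index=signals.index, columns=cols)
    flags.loc["WG09", "t12_r3"] = "Cm"
    flags.loc["WG08", "t6_r2"] = "NDt"

    catalog = AnnotationCatalog(
        terms={
            "WT001": ("WG02", "WG03", "WG04", "WG05"),
            "WT002": ("WG05", "WG06", "WG07", "WG08"),
            "WT003": ("WG01", "WG08"),
        },
        names={"WT001": "early responders", "WT002": "late responders", "WT003": "flat"},
        categories={"WT001": "pathway", "WT002": "pathway", "WT003": "biological_process"},
    )

    retained = [g for g in _FIXTURE_LOG2 if g != "WG09"]
    patterns = pd.Series(
        {g: "".join("U" if f > 1 else "D" if f < 1 else "-" for f in FIXTURE_FC[g]) for g in retained},
        name="pattern",
    )
    true_fc = pd.DataFrame.from_dict(
        {g: FIXTURE_FC[g] for g in retained}, orient="index", columns=["FC6", "FC12", "FC24"]
    )
    truth = GroundTruth(patterns=patterns, true_fc=true_fc, enriched_terms=())
    return SignalMatrix(signals=signals, flags=flags), catalog, truth


def config_to_dict(config: StudyConfig) -> dict:
    """Plain-dict form of a config (for manifests and YAML round trips)."""
    d = asdict(config)
    d["time_points"] = list(config.time_points)
    return d
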