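"""TSV / GMT / YAML readers and writers and the pipeline configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import AnnotationCatalog
from .preprocess import FLAG_VALUES, SignalMatrix

log = logging.getLogger("woundca")

__all__ = [
    "read_signals",
    "write_signal_matrix",
    "read_gmt",
    "write_gmt",
    "read_catalogs",
    "PipelineConfig",
    "load_config",
]


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_signals(path, flags_path) -> SignalMatrix:
    """Read the signals and flags TSVs (rows = features, columns = array ids).

    Raises distinct errors for shape mismatches, duplicate gene ids, and
    unknown flag tokens (all enforced by :class:`SignalMatrix`).
    """
    signals = _read_tsv(path)
    flags = _read_tsv(flags_path).astype(str)
    if signals.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    if signals.shape != flags.shape or not signals.columns.equals(flags.columns):
        raise ValueError(
            f"signals {path} and flags {flags_path} have mismatched shapes: "
            f"{signals.shape} vs {flags.shape}"
        )
    sm = SignalMatrix(signals=signals.astype(float), flags=flags)
    log.info(
        "read %d features x %d arrays (%s x %d replicates)",
        *signals.shape, "/".join(sm.time_points), sm.n_replicates,
    )
    return sm


def write_signal_matrix(sm: SignalMatrix, signals_path, flags_path) -> None:
    sm.signals.rename_axis("gene").to_csv(signals_path, sep="\t")
    sm.flags.rename_axis("gene").to_csv(flags_path, sep="\t")


def read_gmt(path, category: str = "pathway") -> AnnotationCatalog:
    """Read one GMT catalog (term id, description, tab-separated members).

    GMT carries no category column, so the category is supplied per file
    (one catalog file per category, as gene-set collections are shipped).
    """
    terms, names, cats = {}, {}, {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line has fewer than 3 fields")
            tid, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            terms[tid] = tuple(members)
            names[tid] = desc
            cats[tid] = category
    return AnnotationCatalog(terms=terms, names=names, categories=cats)


def write_gmt(catalog: AnnotationCatalog, path) -> None:
    with open(path, "w") as fh:
        for tid, members in catalog.terms.items():
            fh.write("\t".join([tid, catalog.names[tid], *members]) + "\n")


def read_catalogs(entries) -> AnnotationCatalog:
    """Merge several GMT files, each tagged with its category."""
    terms, names, cats = {}, {}, {}
    for entry in entries:
        cat = read_gmt(entry["path"], category=entry.get("category", "pathway"))
        terms.update(cat.terms)
        names.update(cat.names)
        cats.update(cat.categories)
    return AnnotationCatalog(terms=terms, names=names, categories=cats)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; inputs are either files or a simulation."""

    outdir: str
    signals: str | None = None
    flags: str | None = None
    catalogs: list[dict] = field(default_factory=list)
    simulate: dict | None = None
    alpha: float = 0.05
    fold_thresholds: tuple[float, ...] = (3.0, 5.0)
    top_k: tuple[int, ...] = (100, 300, 500, 1000)
    anchor_pool: int = 100
    n_query: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.signals is not None and self.flags is not None
        if self.simulate is None and not has_files:
            raise ValueError("config needs either signals+flags paths or a simulate block")
        if self.simulate is not None and has_files:
            raise ValueError("config has both input files and a simulate block; pick one")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.fold_thresholds = tuple(float(t) for t in self.fold_thresholds)
        self.top_k = tuple(int(k) for k in self.top_k)
        if any(t <= 1 for t in self.fold_thresholds):
            raise ValueError("fold thresholds must exceed 1")
        if any(k < 1 for k in self.top_k):
            raise ValueError("top-k values must be positive")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


FLAG_TOKENS = FLAG_VALUES  # re-exported for adapters mapping scanner flag columns


def agilent_flags_to_calls(features: pd.DataFrame) -> pd.DataFrame:
    """Map Feature-Extraction boolean flag columns onto Dt/NDt/Cm calls.

    Expects boolean columns ``saturated``, ``uniform``,
    ``positive_and_significant``, ``well_above_background`` and
    ``population_outlier`` per (feature, array). Compromised wins over Not
    Detected; everything else is Detected.
    """
    required = [
        "saturated", "uniform", "positive_and_significant",
        "well_above_background", "population_outlier",
    ]
    missing = [c for c in required if c not in features.columns]
    if missing:
        raise ValueError(f"missing Feature-Extraction flag columns: {missing}")
    cm = features["saturated"] | ~features["uniform"] | features["population_outlier"]
    ndt = ~features["positive_and_significant"] | ~features["well_above_background"]
    calls = pd.Series("Dt", index=features.index)
    calls[ndt] = "NDt"
    calls[cm] = "Cm"
    return calls.to_frame("flag")
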