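"""Fisher's exact over-representation and PAGE gene-set statistics.

Over-representation of a gene set in an annotation term is scored with the
one-sided Fisher exact (hypergeometric upper-tail) test on the 2x2 table of
set x term membership within a declared gene universe. Pathway-level shifts
in expression change are scored with PAGE (parametric analysis of gene set
enrichment): for per-gene scores with global mean mu and standard deviation
delta, a term of size m with member mean Sm gets

    Z = (Sm - mu) * sqrt(m) / delta

and a two-sided normal p-value. Both are BH-corrected within one family per
(gene set x catalog category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "AnnotationCatalog",
    "EnrichmentResult",
    "PAGEResult",
    "fisher_enrichment",
    "page_test",
    "enrich_all",
]

CATEGORIES = ("biological_process", "cellular_component", "molecular_function", "pathway")


@dataclass
class AnnotationCatalog:
    """Flat term -> member-genes catalog with a category label per term."""

    terms: dict[str, tuple[str, ...]]                 # term id -> member gene ids
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, members in self.terms.items():
            if len(members) == 0:
                raise ValueError(f"term {tid!r} has no member genes")
        self.names = {t: self.names.get(t, t) for t in self.terms}
        self.categories = {t: self.categories.get(t, "pathway") for t in self.terms}

    def of_category(self, category: str) -> list[str]:
        return [t for t in self.terms if self.categories[t] == category]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher over-representation test: margins, overlap, and p-values."""

    term_id: str
    set_size: int        # m: genes drawn (the query set)
    term_size: int       # K: genes annotated to the term (within the universe)
    overlap: int         # x
    universe_size: int   # N
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


@dataclass(frozen=True)
class PAGEResult:
    """One PAGE test: set mean vs global score distribution."""

    term_id: str
    set_size: int
    set_mean: float
    global_mean: float
    global_sd: float
    z: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def fisher_enrichment(gene_set, term_genes, universe) -> EnrichmentResult:
    """One-sided Fisher exact over-representation of ``gene_set`` in a term.

    All inputs are gene-id collections; term and set members outside the
    universe are dropped. p = P(X >= x) under the hypergeometric null.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty gene universe")
    gset = set(map(str, gene_set)) & uni
    if not gset:
        raise ValueError("empty gene set (after restriction to the universe)")
    term = set(map(str, term_genes)) & uni
    N, K, m = len(uni), len(term), len(gset)
    x = len(gset & term)
    p = float(stats.hypergeom.sf(x - 1, N, K, m))
    return EnrichmentResult(
        term_id="", set_size=m, term_size=K, overlap=x, universe_size=N,
        p_value=min(p, 1.0),
    )


def page_test(scores: pd.Series, term_genes, term_id: str = "") -> PAGEResult:
    """PAGE z-statistic of a term's mean score against the global distribution.

    ``scores`` holds one score (canonically a log2 fold change) per universe
    gene; members missing from ``scores`` are an error, as is a degenerate
    global standard deviation.
    """
    members = [str(g) for g in term_genes]
    if len(members) == 0:
        raise ValueError("empty term")
    missing = set(members) - set(scores.index.astype(str))
    if missing:
        raise ValueError(f"term members without scores: {sorted(missing)[:5]}")
    mu = float(scores.mean())
    delta = float(scores.std(ddof=1))
    if not np.isfinite(delta) or delta == 0:
        raise ValueError("global score standard deviation is zero")
    sm = float(scores.loc[members].mean())
    m = len(members)
    z = (sm - mu) * np.sqrt(m) / delta
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PAGEResult(
        term_id=term_id, set_size=m, set_mean=sm, global_mean=mu,
        global_sd=delta, z=float(z), p_value=min(p, 1.0),
    )


def enrich_all(
    sets: dict[str, object],
    catalog: AnnotationCatalog,
    universe,
    alpha: float = 0.05,
    scores: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Fisher (and PAGE, for pathway terms) over every (gene set, term) pair.

    BH correction is applied within one family per (set x category); PAGE
    forms its own family per set over the pathway terms. ``scores`` is one
    per-universe-gene score Series, or a dict mapping set name to such a
    Series (each set scored at its own defining time point). Returns the
    per-term Fisher table, the PAGE table (None without ``scores``), and a
    per-set significant-term count summary (rows: set, columns: category).
    """
    if len(catalog) == 0:
        raise ValueError("empty annotation catalog")
    uni = sorted(set(map(str, universe)))
    rows = []
    for set_name, genes in sets.items():
        for tid, members in catalog.terms.items():
            res = fisher_enrichment(genes, members, uni)
            rows.append(
                {
                    "set": set_name,
                    "term_id": tid,
                    "term_name": catalog.names[tid],
                    "category": catalog.categories[tid],
                    "set_size": res.set_size,
                    "term_size": res.term_size,
                    "overlap": res.overlap,
                    "universe_size": res.universe_size,
                    "p_value": res.p_value,
                }
            )
    fisher = pd.DataFrame(rows)
    fisher["q_value"] = np.nan
    for (_, _), idx in fisher.groupby(["set", "category"]).groups.items():
        fisher.loc[idx, "q_value"] = bh_adjust(fisher.loc[idx, "p_value"].to_numpy())
    fisher["significant"] = fisher["q_value"] < alpha

    page = None
    if scores is not None:
        page_rows = []
        pathway_terms = catalog.of_category("pathway")
        for set_name in sets:
            sc = scores[set_name] if isinstance(scores, dict) else scores
            scored = set(sc.index.astype(str))
            for tid in pathway_terms:
                members = [g for g in catalog.terms[tid] if g in scored]
                if not members:  # term entirely outside the scored universe
                    continue
                res = page_test(sc, members, term_id=tid)
                page_rows.append(
                    {
                        "set": set_name,
                        "term_id": tid,
                        "term_name": catalog.names[tid],
                        "set_size": res.set_size,
                        "set_mean": res.set_mean,
                        "global_mean": res.global_mean,
                        "global_sd": res.global_sd,
                        "z": res.z,
                        "p_value": res.p_value,
                    }
                )
        if page_rows:
            page = pd.DataFrame(page_rows)
            page["q_value"] = np.nan
            for _, idx in page.groupby("set").groups.items():
                page.loc[idx, "q_value"] = bh_adjust(page.loc[idx, "p_value"].to_numpy())
            page["significant"] = page["q_value"] < alpha

    summary = (
        fisher[fisher["significant"]]
        .groupby(["set", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(sets), fill_value=0)
    )
    for cat in sorted({catalog.categories[t] for t in catalog.terms}):
        if cat not in summary.columns:
            summary[cat] = 0
    summary = summary[sorted(summary.columns)]
    return fisher, page, summary
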