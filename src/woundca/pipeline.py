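"""End-to-end orchestration: preprocess -> differential -> CA -> geometry -> enrichment.

One :func:`run_pipeline` call reads (or simulates) a study, runs every
stage, and writes all stage tables plus a machine-readable ``manifest.json``
into the output directory. Identical config + seed reproduce the outputs
byte for byte. Counts are logged at every filter so the conservation checks
(features in -> QC-retained -> per-set sizes) are auditable from the log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ca import correspondence_analysis, fold_change_to_degrees, transition_check
from .differential import build_threshold_sets, call_significance, pattern_counts
from .enrichment import enrich_all
from .geometry import build_geometry
from .io import PipelineConfig, read_catalogs, read_signals, write_gmt, write_signal_matrix
from .preprocess import compute_fold_change, feature_status, normalize, normalize_per_array

log = logging.getLogger("woundca")

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index_label="gene") -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole analysis described by ``config``; returns the output dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        from .synthetic import StudyConfig, generate_study

        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        if "time_points" in sim:
            sim["time_points"] = tuple(sim["time_points"])
        study_config = StudyConfig(**sim)
        sm, catalog, truth = generate_study(study_config)
        write_signal_matrix(sm, outdir / "signals.tsv", outdir / "flags.tsv")
        write_gmt(catalog, outdir / "catalog.gmt")
        truth_tbl = truth.true_fc.copy()
        truth_tbl.insert(0, "pattern", truth.patterns)
        _write(truth_tbl, outdir / "truth.tsv")
    else:
        sm = read_signals(config.signals, config.flags)
        catalog = read_catalogs(config.catalogs) if config.catalogs else None

    # --- QC + normalization -------------------------------------------------
    status = feature_status(sm.flags)
    retained = status != "Cm"
    log.info("QC: %d features in, %d retained (Dt %d / NDt %d / Cm %d)",
             len(status), int(retained.sum()), int((status == "Dt").sum()),
             int((status == "NDt").sum()), int((status == "Cm").sum()))
    # percentiles are taken over every feature present in the table; the QC
    # filter then restricts all downstream stages to retained genes
    norm = normalize(sm)
    fc = compute_fold_change(norm).loc[retained]
    per_array = normalize_per_array(sm).loc[retained]
    _write(pd.concat([status.to_frame(), retained.rename("retained")], axis=1),
           outdir / "qc_status.tsv")
    _write(norm.log2.add_prefix("log2_").join(norm.nonlog.add_prefix("nonlog_")),
           outdir / "normalized.tsv")
    _write(fc, outdir / "fold_change.tsv")

    # --- differential calling ----------------------------------------------
    calls = call_significance(per_array, alpha=config.alpha)
    patterns = calls.patterns
    calls_tbl = pd.concat(
        [
            calls.anova_p, calls.anova_q,
            calls.tukey_p.add_prefix("tukey_p_"), calls.tukey_q.add_prefix("tukey_q_"),
            calls.calls.add_prefix("call_"), patterns,
        ],
        axis=1,
    )
    _write(calls_tbl, outdir / "calls.tsv")
    _write(pattern_counts(patterns).to_frame(), outdir / "pattern_counts.tsv", "pattern")

    threshold_sets = {}
    rows = []
    times = list(calls.calls.columns)
    for thr in config.fold_thresholds:
        for direction in ("up", "down"):
            for t in times:
                ts = build_threshold_sets(calls, fc, thr, direction, t)
                threshold_sets[(thr, direction, t)] = ts
                rows += [
                    {"threshold": thr, "direction": direction, "time": t, "gene": g}
                    for g in ts.genes
                ]
                log.info("threshold set %s %s-fold %s: %d genes", t, thr, direction, len(ts))
    _write(pd.DataFrame(rows, columns=["threshold", "direction", "time", "gene"]),
           outdir / "threshold_sets.tsv", "row")

    # --- correspondence analysis -------------------------------------------
    degrees = fold_change_to_degrees(fc)
    res = correspondence_analysis(degrees)
    if not transition_check(res, degrees):
        raise RuntimeError("CA transition identities failed; result rejected")
    _write(res.row_coords, outdir / "row_coordinates.tsv")
    _write(res.col_coords, outdir / "column_scores.tsv", "time")
    eig = pd.DataFrame(
        {
            "eigenvalue": res.eigenvalues,
            "contribution": res.contributions,
            "cumulative_contribution": np.cumsum(res.contributions),
        },
        index=pd.RangeIndex(1, len(res.eigenvalues) + 1, name="factor"),
    )
    _write(eig, outdir / "eigenvalues.tsv", "factor")

    # --- biplot geometry ----------------------------------------------------
    geom = build_geometry(
        fc, res.row_coords, res.col_coords,
        q=config.anchor_pool, top_k=config.top_k, n_query=config.n_query,
    )
    geom_tbl = res.row_coords.join(geom.areas).join(geom.distance1.add_prefix("dist_"))
    _write(geom_tbl, outdir / "geometry.tsv")
    lines_tbl = pd.DataFrame(
        [
            {
                "line": bid, "slope": ln.slope, "intercept": ln.intercept,
                "anchor1": ln.anchors[0], "anchor2": ln.anchors[1],
            }
            for bid, ln in geom.lines.items()
        ]
    ).set_index("line")
    lines_tbl.loc["P"] = {
        "slope": geom.point_p[0], "intercept": geom.point_p[1], "anchor1": "", "anchor2": "",
    }
    _write(lines_tbl, outdir / "boundary_lines.tsv", "line")
    set_rows = [
        {"kind": key[0], "anchor": key[1], "k": key[2], "rank": i + 1,
         "gene": g, "distance": d}
        for key, tbl in geom.distance_sets.items()
        for i, (g, d) in enumerate(tbl["distance"].items())
    ]
    _write(pd.DataFrame(set_rows, columns=["kind", "anchor", "k", "rank", "gene", "distance"]),
           outdir / "gene_sets.tsv", "row")

    # --- enrichment ---------------------------------------------------------
    if catalog is not None and len(catalog) > 0:
        universe = list(fc.index.astype(str))
        sets_for_enrich = {
            f"fc{int(thr)}_{direction}_{t}": ts.genes
            for (thr, direction, t), ts in threshold_sets.items()
            if len(ts) > 0
        }
        log2fc = np.log2(fc)
        scores = {
            name: log2fc[f"FC{name.rsplit('_', 1)[-1].lstrip('t')}"]
            for name in sets_for_enrich
        }
        if sets_for_enrich:
            fisher, page, summary = enrich_all(
                sets_for_enrich, catalog, universe, alpha=config.alpha, scores=scores
            )
            _write(fisher.set_index("term_id"), outdir / "enrichment_fisher.tsv", "term_id")
            if page is not None:
                _write(page.set_index("term_id"), outdir / "enrichment_page.tsv", "term_id")
            _write(summary, outdir / "enrichment_summary.tsv", "set")

    manifest = {
        "package": "woundca",
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "fold_thresholds": list(config.fold_thresholds),
        "top_k": list(config.top_k),
        "anchor_pool": config.anchor_pool,
        "n_features_in": int(len(status)),
        "n_qc_retained": int(retained.sum()),
        "gene_universe": int(len(fc)),
        "versions": {m.__name__: m.__version__ for m in _dep_modules()},
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _dep_modules():
    import numpy, pandas, scipy, statsmodels

    return (numpy, scipy, pandas, statsmodels)
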