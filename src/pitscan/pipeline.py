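"""Pipeline orchestration: simulate → analyze → stats, with run reports.

Each stage is a plain function over files (the CLI wraps these); every run
writes its resolved configuration and a report reconciling input traces with
analyzed / skipped counts. :func:`run_in_memory` executes the same
simulate + analyze + summarize path without touching disk, for fast
repeated-simulation studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, pit_analysis, synthetic, trace_io
from .cohort_stats import SubjectSummary
from .trace_io import RunConfig, ValidationError

__all__ = [
    "simulate",
    "analyze",
    "run_stats",
    "run_all",
    "run_in_memory",
    "summaries_to_frame",
    "frame_to_summaries",
]

log = logging.getLogger("pitscan")

PIT_COLUMNS = ("trace_id", "pit_index", "start_um", "end_um", "width_um",
               "depth_um", "fwhm_um", "area_um2", "dent_count", "shape_class")


def simulate(spec: synthetic.CohortSpec, out_dir: str | Path) -> dict:
    """Generate a cohort to disk and echo the resolved spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = synthetic.generate_cohort(spec, out_dir)
    resolved = _spec_to_dict(spec)
    with open(out_dir / "resolved_cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    log.info("simulate: %d traces, %d masks -> %s",
             report["n_traces"], report["n_masks"], out_dir)
    return report


def _spec_to_dict(spec: synthetic.CohortSpec) -> dict:
    return {
        "n_subjects": dict(spec.n_subjects),
        "scans_per_subject": spec.scans_per_subject,
        "discs": spec.discs,
        "jitter_sd": spec.jitter_sd,
        "master_seed": spec.master_seed,
        "mask_grid": spec.mask_grid,
        "scan": dataclasses.asdict(spec.scan),
        "presets": {
            f"{g}/{c}": dataclasses.asdict(p) for (g, c), p in sorted(spec.presets.items())
        },
    }


def _pits_to_rows(trace_id: str, pits: Sequence[pit_analysis.Pit]) -> list[dict]:
    return [
        dict(trace_id=trace_id, pit_index=i, start_um=p.start_pos, end_um=p.end_pos,
             width_um=p.width, depth_um=p.depth, fwhm_um=p.fwhm, area_um2=p.area,
             dent_count=p.dent_count, shape_class=p.shape_class)
        for i, p in enumerate(pits)
    ]


def analyze(manifest_path: str | Path, config: RunConfig,
            out_dir: str | Path) -> dict:
    """Analyze every trace in a manifest; write pit tables and summaries.

    Traces that fail parsing or baseline estimation are skipped with a
    logged reason (never fatal); the report reconciles analyzed + skipped
    with the manifest row count.
    """
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables_dir = out_dir / "pit_tables"
    tables_dir.mkdir(exist_ok=True)

    manifest = trace_io.read_manifest(manifest_path)
    base = manifest_path.parent

    all_rows: list[dict] = []
    skipped: list[dict] = []
    pits_by_cell: dict[tuple[str, str], list] = {}
    scans_by_cell: dict[tuple[str, str], list] = {}
    meta_by_subject: dict[str, str] = {}

    for rec in manifest.records.itertuples(index=False):
        trace_file = base / rec.trace_path
        trace_id = Path(rec.trace_path).stem
        try:
            trace = trace_io.read_trace(trace_file)
            pits = pit_analysis.analyze_trace(trace, config)
        except (trace_io.TraceParseError, trace_io.ValidationError,
                pit_analysis.BaselineError, FileNotFoundError, OSError) as exc:
            skipped.append(dict(trace_path=str(rec.trace_path), reason=str(exc)))
            log.warning("skipping %s: %s", rec.trace_path, exc)
            continue
        rows = _pits_to_rows(trace_id, pits)
        all_rows.extend(rows)
        pd.DataFrame(rows, columns=PIT_COLUMNS).to_csv(
            tables_dir / f"{trace_id}.csv", index=False)
        cell = (rec.subject_id, rec.condition)
        key = (rec.subject_id, rec.disc_index) if config.per_disc else rec.subject_id
        pits_by_cell.setdefault(cell, []).extend(pits)
        scans_by_cell.setdefault(cell, []).extend([trace_id] * len(pits))
        meta_by_subject[rec.subject_id] = rec.group

    pd.DataFrame(all_rows, columns=PIT_COLUMNS).to_csv(out_dir / "pits.csv", index=False)

    planar = _read_planar_percents(base)
    summaries = []
    seen_cells = {(r.subject_id, r.condition) for r in manifest.records.itertuples(index=False)}
    for subject_id, condition in sorted(seen_cells):
        cell = (subject_id, condition)
        summaries.append(cohort_stats.summarize_subject(
            pits_by_cell.get(cell, []),
            planar.get(cell),
            subject_id=subject_id,
            group=meta_by_subject.get(subject_id, ""),
            condition=condition,
            scan_ids=scans_by_cell.get(cell, []),
            area_mode=config.area_mode,
        ))

    frame = summaries_to_frame(summaries)
    frame.to_csv(out_dir / "subject_summaries.csv", index=False)

    report = {
        "n_manifest_rows": len(manifest),
        "n_analyzed": len(manifest) - len(skipped),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "n_pits": len(all_rows),
        "n_summaries": len(summaries),
        "config": config.to_dict(),
    }
    with open(out_dir / "analyze_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    log.info("analyze: %d/%d traces, %d pits, %d summaries",
             report["n_analyzed"], len(manifest), len(all_rows), len(summaries))
    return report


def _read_planar_percents(base: Path) -> dict[tuple[str, str], float]:
    """Measure planar resorption from masks listed in masks.csv, if present."""
    masks_csv = base / "masks.csv"
    if not masks_csv.exists():
        return {}
    out = {}
    for rec in pd.read_csv(masks_csv).itertuples(index=False):
        grid = trace_io.read_pgm_mask(base / rec.mask_path)
        mask = pit_analysis.PlanarMask(grid=grid)
        out[(str(rec.subject_id), str(rec.condition))] = (
            pit_analysis.resorbed_area_percent(mask))
    return out


# ---------------------------------------------------------------------------
# Summary frame round-trip
# ---------------------------------------------------------------------------


def summaries_to_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(subject_id=s.subject_id, group=s.group, condition=s.condition,
                   n_pits=s.n_pits, median_pit_area_um2=s.median_pit_area,
                   planar_resorption_percent=s.planar_resorption_percent)
        for cls in cohort_stats.SHAPE_CLASSES:
            row[f"n_{cls}"] = s.class_counts[cls]
            row[f"pct_{cls}"] = s.shape_percentages[cls]
            row[f"{cls}_median_width_um"] = s.median_width[cls]
            row[f"{cls}_median_depth_um"] = s.median_depth[cls]
            row[f"{cls}_median_fwhm_um"] = s.median_fwhm[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_summaries(frame: pd.DataFrame) -> list[SubjectSummary]:
    summaries = []
    for rec in frame.itertuples(index=False):
        counts = {cls: int(getattr(rec, f"n_{cls}")) for cls in cohort_stats.SHAPE_CLASSES}
        n = int(rec.n_pits)
        planar = getattr(rec, "planar_resorption_percent", None)
        if planar is not None and pd.isna(planar):
            planar = None
        summaries.append(SubjectSummary(
            subject_id=str(rec.subject_id), group=str(rec.group),
            condition=str(rec.condition), n_pits=n, class_counts=counts,
            shape_percentages={cls: float(getattr(rec, f"pct_{cls}"))
                               for cls in cohort_stats.SHAPE_CLASSES},
            median_width={cls: float(getattr(rec, f"{cls}_median_width_um"))
                          for cls in cohort_stats.SHAPE_CLASSES},
            median_depth={cls: float(getattr(rec, f"{cls}_median_depth_um"))
                          for cls in cohort_stats.SHAPE_CLASSES},
            median_fwhm={cls: float(getattr(rec, f"{cls}_median_fwhm_um"))
                         for cls in cohort_stats.SHAPE_CLASSES},
            median_pit_area=float(rec.median_pit_area_um2),
            planar_resorption_percent=None if planar is None else float(planar),
        ))
    return summaries


# ---------------------------------------------------------------------------
# Stats stage
# ---------------------------------------------------------------------------


def run_stats(summaries: str | Path | pd.DataFrame | Sequence[SubjectSummary],
              config: RunConfig, out_dir: str | Path) -> dict:
    """Run the comparison design over subject summaries and write reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(summaries, (str, Path)):
        summaries = frame_to_summaries(pd.read_csv(summaries))
    elif isinstance(summaries, pd.DataFrame):
        summaries = frame_to_summaries(summaries)
    summaries = list(summaries)

    cell_sizes: dict[tuple[str, str], int] = {}
    for s in summaries:
        cell_sizes[(s.group, s.condition)] = cell_sizes.get((s.group, s.condition), 0) + 1
    if not any(n >= 2 for n in cell_sizes.values()):
        raise ValidationError("nothing to compare: fewer than 2 subjects in every cell")

    table = cohort_stats.compare_groups(summaries, config)
    dist = cohort_stats.shape_distribution(summaries)

    table.rows.to_csv(out_dir / "comparisons.csv", index=False)
    dist.to_csv(out_dir / "shape_distribution.csv", index=False)
    comparison_json = {
        "alpha": table.alpha,
        "rows": table.rows.to_dict(orient="records"),
    }
    with open(out_dir / "comparisons.json", "w") as fh:
        json.dump(comparison_json, fh, indent=1, default=float)

    n_sig = int(table.rows["significant"].sum())
    report = {
        "n_summaries": len(summaries),
        "cells": {f"{g}/{c}": n for (g, c), n in sorted(cell_sizes.items())},
        "n_comparisons": int(len(table.rows)),
        "n_significant": n_sig,
        "alpha": table.alpha,
        "config": config.to_dict(),
    }
    with open(out_dir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    with open(out_dir / "stats_report.txt", "w") as fh:
        fh.write(f"Subjects x conditions summarized: {len(summaries)}\n")
        for (g, c), n in sorted(cell_sizes.items()):
            fh.write(f"  cell {g}/{c}: n={n}\n")
        fh.write(f"Comparisons run: {len(table.rows)}\n")
        fh.write(f"Significant at alpha={table.alpha}: {n_sig}\n")
        sig = table.rows[table.rows["significant"]]
        for rec in sig.itertuples(index=False):
            fh.write(f"  {rec.endpoint} [{rec.comparison}; {rec.condition}; "
                     f"{rec.members}] p={rec.p_value:.4g}\n")
    log.info("stats: %d comparisons, %d significant", len(table.rows), n_sig)
    return report


def run_all(spec: synthetic.CohortSpec, config: RunConfig,
            out_dir: str | Path) -> dict:
    """simulate → analyze → stats in one deterministic run."""
    out_dir = Path(out_dir)
    sim = simulate(spec, out_dir / "sim")
    ana = analyze(out_dir / "sim" / "manifest.csv", config, out_dir / "analysis")
    sta = run_stats(out_dir / "analysis" / "subject_summaries.csv", config,
                    out_dir / "stats")
    report = {"simulate": sim, "analyze": ana, "stats": sta}
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


# ---------------------------------------------------------------------------
# In-memory pipeline (no disk)
# ---------------------------------------------------------------------------


def run_in_memory(spec: synthetic.CohortSpec,
                  config: RunConfig | None = None,
                  with_masks: bool = False) -> list[SubjectSummary]:
    """Simulate and analyze a cohort entirely in memory.

    Returns one :class:`SubjectSummary` per subject × condition, produced by
    the same per-trace analysis as the disk pipeline (traces that fail
    baseline estimation are silently skipped, as in :func:`analyze`).
    """
    config = config or RunConfig()
    pits_by_cell: dict[tuple[str, str], list] = {}
    group_of: dict[str, str] = {}
    for scan in synthetic.iter_cohort(spec):
        group_of[scan.subject_id] = scan.group
        cell = (scan.subject_id, scan.condition)
        pits_by_cell.setdefault(cell, [])
        try:
            pits_by_cell[cell].extend(pit_analysis.analyze_trace(scan.trace, config))
        except pit_analysis.BaselineError:
            continue
    planar: dict[tuple[str, str], float] = {}
    if with_masks:
        for subject_id, _group, condition, mask, _pct in synthetic.iter_masks(spec):
            planar[(subject_id, condition)] = pit_analysis.resorbed_area_percent(mask)
    summaries = []
    for (subject_id, condition), pits in sorted(pits_by_cell.items()):
        summaries.append(cohort_stats.summarize_subject(
            pits, planar.get((subject_id, condition)),
            subject_id=subject_id, group=group_of[subject_id],
            condition=condition, area_mode="per_pit"))
    return summaries
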