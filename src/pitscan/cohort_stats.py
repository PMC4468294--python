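"""Per-subject aggregation and nonparametric cohort statistics.

Pits are pooled per subject × culture condition, summarized to medians and
pit-shape percentages, and compared with the study's design: Kruskal-Wallis
across the three groups (Charcot, diabetic, control), pairwise and
between-condition Mann-Whitney U tests, and Pearson chi-square for pooled
categorical pit-shape counts. Data are summarized as median [25th–75th
percentile] with quartiles by linear interpolation; significance is assessed
per test at the configured alpha with no multiplicity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pit_analysis import SHAPE_CLASSES, Pit
from .trace_io import CONDITIONS, GROUPS, RunConfig, ValidationError

__all__ = [
    "SubjectSummary",
    "TestResult",
    "ComparisonTable",
    "summarize_subject",
    "shape_distribution",
    "mann_whitney_u",
    "kruskal_wallis",
    "chi_square",
    "compare_groups",
]

METRICS = ("width", "depth", "fwhm")


@dataclass
class SubjectSummary:
    """Medians and pit-shape distribution of one subject × condition.

    Medians are per shape class (NaN when the class is empty); percentages
    sum to 100 whenever ``n_pits > 0``.
    """

    subject_id: str
    group: str
    condition: str
    n_pits: int
    class_counts: dict[str, int]
    shape_percentages: dict[str, float]
    median_width: dict[str, float]
    median_depth: dict[str, float]
    median_fwhm: dict[str, float]
    median_pit_area: float
    planar_resorption_percent: float | None = None

    def __post_init__(self) -> None:
        if self.n_pits != sum(self.class_counts.values()):
            raise ValidationError("n_pits must equal the sum of class counts")
        if self.n_pits > 0:
            total = sum(self.shape_percentages.values())
            if abs(total - 100.0) > 1e-9:
                raise ValidationError("shape percentages must sum to 100")


@dataclass
class TestResult:
    """Outcome of one nonparametric comparison."""

    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValidationError("test statistic not finite")
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class ComparisonTable:
    """All configured endpoint comparisons of one cohort, one row per test."""

    rows: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.rows[self.rows["significant"] == True]  # noqa: E712


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def summarize_subject(
    pits: Sequence[Pit],
    planar_percent: float | None = None,
    *,
    subject_id: str = "",
    group: str = "",
    condition: str = "",
    scan_ids: Sequence[str] | None = None,
    area_mode: str = "per_pit",
) -> SubjectSummary:
    """Summarize all pits of one subject × condition (pooled across scans).

    ``area_mode='per_pit'`` reports the median of individual pit areas (μm²);
    ``'per_scan_total'`` the median across scans of each scan's total eroded
    area, which requires ``scan_ids`` aligned with ``pits``.
    """
    counts = {cls: 0 for cls in SHAPE_CLASSES}
    for pit in pits:
        counts[pit.shape_class] += 1
    n = len(pits)
    if n > 0:
        percentages = {cls: 100.0 * counts[cls] / n for cls in SHAPE_CLASSES}
    else:
        percentages = {cls: float("nan") for cls in SHAPE_CLASSES}

    def _median(values: list[float]) -> float:
        return float(np.median(values)) if values else float("nan")

    med_w, med_d, med_f = {}, {}, {}
    for cls in SHAPE_CLASSES:
        members = [p for p in pits if p.shape_class == cls]
        med_w[cls] = _median([p.width for p in members])
        med_d[cls] = _median([p.depth for p in members])
        med_f[cls] = _median([p.fwhm for p in members])

    if area_mode == "per_scan_total":
        if scan_ids is None or len(scan_ids) != n:
            raise ValidationError("per_scan_total area mode requires scan_ids per pit")
        totals: dict[str, float] = {}
        for pit, sid in zip(pits, scan_ids):
            totals[sid] = totals.get(sid, 0.0) + pit.area
        median_area = _median(list(totals.values()))
    elif area_mode == "per_pit":
        median_area = _median([p.area for p in pits])
    else:
        raise ValidationError(f"unknown area_mode {area_mode!r}")

    return SubjectSummary(
        subject_id=subject_id,
        group=group,
        condition=condition,
        n_pits=n,
        class_counts=counts,
        shape_percentages=percentages,
        median_width=med_w,
        median_depth=med_d,
        median_fwhm=med_f,
        median_pit_area=median_area,
        planar_resorption_percent=planar_percent,
    )


def shape_distribution(summaries: Iterable[SubjectSummary]) -> pd.DataFrame:
    """Cross-subject median [Q1–Q3] of shape percentages per group × condition.

    Quartiles use the inclusive linear-interpolation method. Subjects with no
    pits contribute no value; an empty cell yields a flagged row with NaNs.
    """
    summaries = list(summaries)
    rows = []
    cells = sorted({(s.group, s.condition) for s in summaries})
    for group, condition in cells:
        for cls in SHAPE_CLASSES:
            values = [
                s.shape_percentages[cls]
                for s in summaries
                if s.group == group and s.condition == condition and s.n_pits > 0
            ]
            values = [v for v in values if not math.isnan(v)]
            if values:
                med = float(np.percentile(values, 50, method="linear"))
                q1 = float(np.percentile(values, 25, method="linear"))
                q3 = float(np.percentile(values, 75, method="linear"))
                flag = ""
            else:
                med = q1 = q3 = float("nan")
                flag = "empty cell"
            rows.append(
                dict(group=group, condition=condition, shape_class=cls,
                     n_subjects=len(values), median_pct=med, q1_pct=q1,
                     q3_pct=q3, flag=flag)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def _check_finite(name: str, values: np.ndarray) -> None:
    if values.size == 0:
        raise ValidationError(f"{name}: empty sample")
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{name}: non-finite values")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; U reported as min(U1, U2).

    The p-value is exact (full enumeration of rank assignments) when
    n1 + n2 ≤ 12 and there are no ties, otherwise a normal approximation
    with tie and continuity correction. Identical constant samples yield
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite("mann_whitney_u x", x)
    _check_finite("mann_whitney_u y", y)
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult("mann_whitney_u", n1 * n2 / 2.0, 1.0, (n1, n2),
                          note="degenerate: all values identical")
    has_ties = np.unique(combined).size < combined.size
    if n1 + n2 <= 12 and not has_ties:
        method, note = "exact", "exact (enumeration)"
    else:
        method, note = "asymptotic", "normal approximation, tie + continuity correction"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return TestResult("mann_whitney_u", u, min(float(res.pvalue), 1.0), (n1, n2), note)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square with k−1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("kruskal_wallis requires at least 2 groups")
    for i, g in enumerate(arrays):
        _check_finite(f"kruskal_wallis group {i}", g)
    combined = np.concatenate(arrays)
    ns = tuple(g.size for g in arrays)
    if np.all(combined == combined[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, ns,
                          note="degenerate: all values identical")
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p), ns,
                      note=f"chi-square approximation, df={len(arrays) - 1}")


def chi_square(table: Sequence[Sequence[int]] | np.ndarray) -> TestResult:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("chi_square requires a 2-D table of at least 2x2")
    if np.any(table < 0) or not np.all(np.isfinite(table)):
        raise ValidationError("chi_square table must contain non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("chi_square table has a zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue),
                      tuple(int(v) for v in table.sum(axis=1)),
                      note=f"Pearson, df={df}, no continuity correction")


# ---------------------------------------------------------------------------
# Comparison design
# ---------------------------------------------------------------------------


def _endpoint_accessors() -> dict[str, callable]:
    accessors: dict[str, callable] = {}
    for cls in SHAPE_CLASSES:
        accessors[f"{cls}_median_width"] = (
            lambda s, c=cls: s.median_width[c])
        accessors[f"{cls}_median_depth"] = (
            lambda s, c=cls: s.median_depth[c])
        accessors[f"{cls}_median_fwhm"] = (
            lambda s, c=cls: s.median_fwhm[c])
        accessors[f"pct_{cls}"] = (
            lambda s, c=cls: s.shape_percentages[c])
    accessors["median_pit_area"] = lambda s: s.median_pit_area
    accessors["planar_resorption_percent"] = (
        lambda s: float("nan") if s.planar_resorption_percent is None
        else s.planar_resorption_percent)
    return accessors


def compare_groups(summaries: Sequence[SubjectSummary],
                   config: RunConfig | None = None) -> ComparisonTable:
    """Run the full comparison design over subject summaries.

    For every endpoint (per-class median width/depth/FWHM, per-class shape
    percentage, median pit area, planar resorption %): a three-group
    Kruskal-Wallis per condition, pairwise between-group Mann-Whitney tests
    per condition, and within-group between-condition Mann-Whitney tests.
    Cells with fewer than 2 subjects are flagged ``insufficient n`` and not
    tested. Optionally (``shape_test='chi_square'``) the pooled pit-shape
    counts are also compared between conditions per group with chi-square.
    """
    config = config or RunConfig()
    summaries = list(summaries)
    groups_present = [g for g in GROUPS if any(s.group == g for s in summaries)]
    conditions_present = [c for c in CONDITIONS if any(s.condition == c for s in summaries)]

    def cell_values(endpoint_fn, group: str, condition: str) -> np.ndarray:
        vals = [endpoint_fn(s) for s in summaries
                if s.group == group and s.condition == condition]
        return np.asarray([v for v in vals if v is not None and math.isfinite(v)])

    rows = []

    def add_row(endpoint, comparison, condition, members, result: TestResult | None,
                flag: str = "") -> None:
        rows.append(dict(
            endpoint=endpoint,
            comparison=comparison,
            condition=condition,
            members="|".join(members),
            test_name=result.test_name if result else "",
            statistic=result.statistic if result else float("nan"),
            p_value=result.p_value if result else float("nan"),
            n="/".join(str(v) for v in result.n) if result else "",
            significant=bool(result and result.p_value < config.alpha),
            note=result.note if result else "",
            flag=flag,
        ))

    for endpoint, fn in _endpoint_accessors().items():
        all_vals = [fn(s) for s in summaries]
        if not any(v is not None and math.isfinite(v) for v in all_vals):
            continue  # endpoint absent from this cohort (e.g. no masks)

        for condition in conditions_present:
            cells = {g: cell_values(fn, g, condition) for g in groups_present}
            if len(groups_present) >= 3:
                if all(v.size >= 2 for v in cells.values()):
                    result = kruskal_wallis([cells[g] for g in groups_present])
                    add_row(endpoint, "between_groups", condition, groups_present, result)
                else:
                    add_row(endpoint, "between_groups", condition, groups_present,
                            None, flag="insufficient n")
            for g1, g2 in itertools.combinations(groups_present, 2):
                if cells[g1].size >= 2 and cells[g2].size >= 2:
                    result = mann_whitney_u(cells[g1], cells[g2])
                    add_row(endpoint, "between_groups_pairwise", condition,
                            (g1, g2), result)
                else:
                    add_row(endpoint, "between_groups_pairwise", condition,
                            (g1, g2), None, flag="insufficient n")

        if len(conditions_present) == 2:
            c1, c2 = conditions_present
            for g in groups_present:
                v1 = cell_values(fn, g, c1)
                v2 = cell_values(fn, g, c2)
                if v1.size >= 2 and v2.size >= 2:
                    result = mann_whitney_u(v1, v2)
                    add_row(endpoint, "between_conditions", g, (c1, c2), result)
                else:
                    add_row(endpoint, "between_conditions", g, (c1, c2),
                            None, flag="insufficient n")

    if config.shape_test == "chi_square" and len(conditions_present) == 2:
        c1, c2 = conditions_present
        for g in groups_present:
            table = []
            for condition in (c1, c2):
                counts = np.zeros(len(SHAPE_CLASSES), dtype=int)
                for s in summaries:
                    if s.group == g and s.condition == condition:
                        counts += np.array([s.class_counts[cls] for cls in SHAPE_CLASSES])
                table.append(counts)
            table = np.asarray(table).T  # classes x conditions
            try:
                result = chi_square(table)
                add_row("shape_distribution_pooled", "between_conditions", g,
                        (c1, c2), result)
            except ValidationError as exc:
                add_row("shape_distribution_pooled", "between_conditions", g,
                        (c1, c2), None, flag=str(exc))

    return ComparisonTable(rows=pd.DataFrame(rows), alpha=config.alpha)
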