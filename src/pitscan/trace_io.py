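"""Reading and writing profilometry traces, cohort manifests, and run configuration.

A trace is one stylus scan across a resorbed bone disc: a column of sampling
positions (μm from scan start) and a column of surface heights (μm relative to
the instrument zero). Erosion is *downward*: resorption pits appear as
negative excursions below the unresorbed-surface baseline.

The on-disk trace dialect is plain text, two numeric columns (whitespace- or
comma-delimited), with optional ``#``-prefixed metadata header lines::

    # scan_length_um: 1000.0
    # sample_interval_um: 0.056
    # vertical_range_um: 65.5
    # source_id: subject01_rankl_scan03
    0.000000000 -0.012000000
    0.056000000 0.004000000
    ...
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trace",
    "CohortManifest",
    "RunConfig",
    "TraceParseError",
    "ValidationError",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "read_pgm_mask",
    "write_pgm_mask",
    "GROUPS",
    "CONDITIONS",
]

GROUPS = ("charcot", "diabetic", "control")
CONDITIONS = ("rankl", "rankl_anti_tnf")

#: default Dektak-style scan metadata applied when a file carries no header
DEFAULT_SCAN_LENGTH_UM = 1000.0
DEFAULT_SAMPLE_INTERVAL_UM = 0.056
DEFAULT_VERTICAL_RANGE_UM = 65.5

MIN_SAMPLES = 16

_GROUP_ALIASES = {
    "charcot": "charcot",
    "diabetic": "diabetic",
    "diabetes": "diabetic",
    "control": "control",
    "healthy": "control",
    "healthy_control": "control",
}
_CONDITION_ALIASES = {
    "rankl": "rankl",
    "mcsf_rankl": "rankl",
    "m_csf_rankl": "rankl",
    "rankl_anti_tnf": "rankl_anti_tnf",
    "anti_tnf": "rankl_anti_tnf",
    "mcsf_rankl_anti_tnf": "rankl_anti_tnf",
    "m_csf_rankl_anti_tnf": "rankl_anti_tnf",
}


class TraceParseError(ValueError):
    """A trace file could not be parsed as two numeric columns."""


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """One profilometry scan.

    Parameters
    ----------
    positions
        Strictly increasing sampling positions, μm from scan start.
    heights
        Surface heights, μm relative to instrument zero (erosion negative).
    scan_length
        Nominal scan length in μm; the observed span may not exceed it.
    sample_interval
        Nominal sampling interval in μm.
    vertical_range
        Instrument vertical measurement range in μm; all ``|heights|`` must
        lie within it.
    source_id
        Free-text identifier (defaults to the file stem on read).
    """

    positions: np.ndarray
    heights: np.ndarray
    scan_length: float = DEFAULT_SCAN_LENGTH_UM
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL_UM
    vertical_range: float = DEFAULT_VERTICAL_RANGE_UM
    source_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.positions.ndim != 1 or self.heights.ndim != 1:
            raise ValidationError("positions and heights must be 1-D")
        if self.positions.size != self.heights.size:
            raise ValidationError("positions and heights differ in length")
        if self.positions.size < MIN_SAMPLES:
            raise ValidationError(
                f"trace has {self.positions.size} samples, fewer than {MIN_SAMPLES}"
            )
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.heights))):
            raise ValidationError("non-finite values in trace")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions not increasing")
        span = float(self.positions[-1] - self.positions[0])
        if span > self.scan_length + 1e-6:
            raise ValidationError(
                f"position span {span:.6f} μm exceeds scan_length {self.scan_length} μm"
            )
        if np.max(np.abs(self.heights)) > self.vertical_range + 1e-9:
            raise ValidationError(
                f"heights exceed vertical range ±{self.vertical_range} μm"
            )

    @property
    def n_samples(self) -> int:
        return int(self.positions.size)

    @property
    def median_interval(self) -> float:
        """Median sample spacing in μm (equals sample_interval on a uniform grid)."""
        return float(np.median(np.diff(self.positions)))

    def equals(self, other: "Trace", tol: float = 1e-9) -> bool:
        return (
            self.n_samples == other.n_samples
            and np.allclose(self.positions, other.positions, atol=tol, rtol=0)
            and np.allclose(self.heights, other.heights, atol=tol, rtol=0)
        )


_HEADER_RE = re.compile(r"^#\s*([A-Za-z0-9_]+)\s*[:=]\s*(.*?)\s*$")


def read_trace(path: str | Path) -> Trace:
    """Read a two-column trace file, applying metadata defaults when absent.

    Raises
    ------
    TraceParseError
        If a data row is not two numeric fields (the message names the line).
    ValidationError
        If the parsed trace violates a Trace invariant.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    first_data_line = ""
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                m = _HEADER_RE.match(stripped)
                if m:
                    headers[m.group(1).lower()] = m.group(2)
                continue
            first_data_line = stripped
            break
    if not first_data_line:
        raise TraceParseError(f"{path}: no data rows")
    sep = "," if "," in first_data_line else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=None, dtype=float)
    except ValueError:
        _locate_bad_row(path)
        raise  # pragma: no cover - _locate_bad_row always raises first
    if df.shape[1] != 2:
        raise TraceParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    positions = df.iloc[:, 0].to_numpy()
    heights = df.iloc[:, 1].to_numpy()
    if positions.size >= 2:
        observed_span = float(positions[-1] - positions[0])
        observed_dx = float(np.median(np.diff(positions)))
    else:  # pragma: no cover - rejected by validation anyway
        observed_span, observed_dx = 0.0, DEFAULT_SAMPLE_INTERVAL_UM
    return Trace(
        positions=positions,
        heights=heights,
        scan_length=float(headers.get("scan_length_um", observed_span)),
        sample_interval=float(headers.get("sample_interval_um", observed_dx)),
        vertical_range=float(headers.get("vertical_range_um", DEFAULT_VERTICAL_RANGE_UM)),
        source_id=headers.get("source_id", path.stem),
    )


def _locate_bad_row(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = re.split(r"[,\s]+", stripped)
            try:
                [float(f) for f in fields if f]
            except ValueError:
                raise TraceParseError(
                    f"{path}: non-numeric data at line {lineno}: {stripped!r}"
                ) from None
    raise TraceParseError(f"{path}: could not parse numeric data")


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace in the plain-text dialect; round-trips within 1e-9 μm."""
    trace.validate()
    path = Path(path)
    header = (
        f"# scan_length_um: {trace.scan_length:.9g}\n"
        f"# sample_interval_um: {trace.sample_interval:.9g}\n"
        f"# vertical_range_um: {trace.vertical_range:.9g}\n"
        f"# source_id: {trace.source_id}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.column_stack([trace.positions, trace.heights]), fmt="%.9f")


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("trace_path", "subject_id", "group", "condition", "disc_index", "scan_index")


@dataclass
class CohortManifest:
    """Mapping from trace files to subject / group / condition / disc / scan.

    ``records`` is a DataFrame with the columns in :data:`MANIFEST_COLUMNS`;
    labels are normalized to the controlled vocabularies on construction.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        df["group"] = df["group"].map(_normalize_group)
        df["condition"] = df["condition"].map(_normalize_condition)
        df["subject_id"] = df["subject_id"].astype(str)
        df["disc_index"] = df["disc_index"].astype(int)
        df["scan_index"] = df["scan_index"].astype(int)
        key_cols = ["subject_id", "condition", "disc_index", "scan_index"]
        dup = df.duplicated(subset=key_cols, keep=False)
        if dup.any():
            first = df.loc[dup, key_cols].iloc[0].tolist()
            raise ValidationError(f"duplicate manifest key {tuple(first)}")
        n_groups = df.groupby("subject_id")["group"].nunique()
        if (n_groups > 1).any():
            bad = n_groups[n_groups > 1].index[0]
            raise ValidationError(f"subject {bad!r} assigned to more than one group")
        if not set(df["disc_index"]) <= {1, 2}:
            raise ValidationError("disc_index must be 1 or 2")
        self.records = df[list(MANIFEST_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> pd.DataFrame:
        return self.records[["subject_id", "group"]].drop_duplicates().reset_index(drop=True)


def _normalize_label(raw: object) -> str:
    return re.sub(r"[^a-z0-9]+", "_", str(raw).strip().lower()).strip("_")


def _normalize_group(raw: object) -> str:
    label = _normalize_label(raw)
    if label not in _GROUP_ALIASES:
        raise ValidationError(
            f"unknown group label {raw!r}; allowed: {sorted(set(_GROUP_ALIASES.values()))}"
        )
    return _GROUP_ALIASES[label]


def _normalize_condition(raw: object) -> str:
    label = _normalize_label(raw)
    if label not in _CONDITION_ALIASES:
        raise ValidationError(
            f"unknown condition label {raw!r}; allowed: {sorted(set(_CONDITION_ALIASES.values()))}"
        )
    return _CONDITION_ALIASES[label]


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: manifest has no rows")
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Detection, aggregation and testing parameters for an analysis run.

    All length parameters are in μm. ``min_width`` must be at least twice the
    trace sampling interval (checked against each trace at analysis time).
    """

    min_depth: float = 0.5
    min_width: float = 1.0
    smoothing_window: float = 1.0
    ridge_fraction: float = 0.10
    baseline_trend: str = "auto"  # constant | linear | auto
    min_unresorbed_fraction: float = 0.25
    alpha: float = 0.05
    area_mode: str = "per_pit"  # per_pit | per_scan_total
    per_disc: bool = False
    shape_test: str = "mann_whitney"  # mann_whitney | chi_square
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.min_depth > 0:
            raise ValidationError("min_depth must be > 0")
        if not self.min_width > 0:
            raise ValidationError("min_width must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.min_unresorbed_fraction < 1:
            raise ValidationError("min_unresorbed_fraction must be in (0, 1)")
        if self.baseline_trend not in ("constant", "linear", "auto"):
            raise ValidationError("baseline_trend must be constant, linear or auto")
        if self.area_mode not in ("per_pit", "per_scan_total"):
            raise ValidationError("area_mode must be per_pit or per_scan_total")
        if self.shape_test not in ("mann_whitney", "chi_square"):
            raise ValidationError("shape_test must be mann_whitney or chi_square")
        if not self.smoothing_window >= 0:
            raise ValidationError("smoothing_window must be >= 0")
        if not 0 <= self.ridge_fraction < 1:
            raise ValidationError("ridge_fraction must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Planar mask I/O (text PGM, P2)
# ---------------------------------------------------------------------------


def write_pgm_mask(grid: np.ndarray, path: str | Path) -> None:
    """Write a binary resorption mask as a text PGM (P2, maxval 1).

    Resorbed pixels are written as 1, unresorbed as 0.
    """
    grid = np.asarray(grid).astype(int)
    with open(path, "w") as fh:
        fh.write(f"P2\n{grid.shape[1]} {grid.shape[0]}\n1\n")
        np.savetxt(fh, grid, fmt="%d")


def read_pgm_mask(path: str | Path) -> np.ndarray:
    """Read a text PGM mask back to a boolean grid (True = resorbed)."""
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != "P2":
            raise TraceParseError(f"{path}: not a text PGM (P2) file")
        width, height = (int(v) for v in fh.readline().split())
        maxval = int(fh.readline())
        data = np.loadtxt(fh, dtype=int)
    grid = data.reshape(height, width)
    return grid > (maxval // 2)
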