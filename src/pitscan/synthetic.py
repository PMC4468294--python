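"""Synthetic profilometry traces, planar masks and cohorts with ground truth.

The generator emulates stylus scans across resorbed bovine bone discs: a
flat unresorbed surface carrying Gaussian stylus noise, pocked by resorption
pits placed by a Poisson process. Each pit is a train of one or more smooth
dents (raised-cosine bumps by default); internal ridges between dents rise
back to within ``ridge_relief`` of the baseline, so compound (bidented /
multidented) pits remain a single excavation bounded by the unresorbed
surface. Per group × condition presets encode the cohort contrasts: Charcot
cultures stimulated with M-CSF + RANKL erode deeper, wider, predominantly
multidented pits and a larger planar area than the same cultures with TNF-α
neutralised, while diabetic and control cultures are unaffected by the
neutralising antibody.

Reproducibility contract: every random stream is derived from the master
seed with ``numpy`` ``SeedSequence`` entropy lists
``[master_seed, stream, subject_index, substream]`` where stream 1 is the
per-subject parameter jitter, stream 2 the per-scan trace noise/pits
(substream = condition_index · 10**4 + scan_index) and stream 3 the planar
mask (substream = condition_index). No generator state is shared between
subjects, so any subject can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from skimage.draw import ellipse as draw_ellipse

from .pit_analysis import PlanarMask
from .trace_io import (
    CONDITIONS,
    DEFAULT_SAMPLE_INTERVAL_UM,
    DEFAULT_SCAN_LENGTH_UM,
    DEFAULT_VERTICAL_RANGE_UM,
    CohortManifest,
    Trace,
    ValidationError,
    write_manifest,
    write_pgm_mask,
    write_trace,
)

__all__ = [
    "SyntheticPreset",
    "CohortSpec",
    "ScanMetadata",
    "PitShape",
    "PlacedPit",
    "TraceTruth",
    "InfeasibleDensityError",
    "default_presets",
    "sample_pit",
    "generate_trace",
    "render_trace",
    "generate_surface_mask",
    "generate_cohort",
    "iter_cohort",
    "iter_masks",
]

MIN_GAP_UM = 5.0  # minimum spacing between placed pit extents
MAX_PLACEMENT_TRIES = 100


class InfeasibleDensityError(RuntimeError):
    """Pit placement failed too often; lower pits_per_mm or pit sizes."""


@dataclass
class SyntheticPreset:
    """Generative parameters of one group × condition cell.

    ``dent_count_mixture`` gives the probabilities of 1, 2 and ≥3 dents
    (≥3 resolved uniformly over {3, 4}); depth and per-dent width are
    log-normal with the stated median (μm) and log-sd. ``ridge_relief`` is
    the fraction of the shallower neighbouring dent's depth to which an
    internal ridge rises below the baseline. ``planar_resorption_median_pct``
    drives the planar mask generator.
    """

    pits_per_mm: float = 7.5
    dent_count_mixture: tuple[float, float, float] = (0.36, 0.24, 0.40)
    depth_median_um: float = 5.0
    depth_log_sd: float = 0.35
    width_median_um: float = 15.0
    width_log_sd: float = 0.30
    ridge_relief: float = 0.05
    noise_sigma_um: float = 0.05
    planar_resorption_median_pct: float = 20.0
    dent_shape: str = "raised_cosine"  # raised_cosine | gaussian

    def __post_init__(self) -> None:
        self.dent_count_mixture = tuple(float(v) for v in self.dent_count_mixture)
        if abs(sum(self.dent_count_mixture) - 1.0) > 1e-9:
            raise ValidationError("dent_count_mixture must sum to 1")
        if any(v < 0 for v in self.dent_count_mixture):
            raise ValidationError("dent_count_mixture probabilities must be >= 0")
        for name in ("pits_per_mm", "depth_median_um", "depth_log_sd",
                     "width_median_um", "width_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.ridge_relief < 1:
            raise ValidationError("ridge_relief must be in (0, 1)")
        if self.noise_sigma_um < 0:
            raise ValidationError("noise_sigma_um must be >= 0")
        if self.dent_shape not in ("raised_cosine", "gaussian"):
            raise ValidationError("dent_shape must be raised_cosine or gaussian")


def default_presets() -> dict[tuple[str, str], SyntheticPreset]:
    """Calibrated per-cell presets.

    Charcot M-CSF+RANKL pits are predominantly multidented (mixture
    0.36/0.24/0.40 unidented/bidented/multidented), deeper and wider, with
    the largest planar resorption; TNF-α neutralisation shifts the Charcot
    mixture to 0.53/0.22/0.25, shrinks the pits and reduces the planar
    median by 30%. Diabetic and control cultures share the normalised
    mixture and geometry in both conditions (the antibody has no effect).
    """
    charcot_rankl = SyntheticPreset(
        dent_count_mixture=(0.36, 0.24, 0.40),
        depth_median_um=5.0, width_median_um=15.0,
        planar_resorption_median_pct=20.0,
    )
    charcot_anti = SyntheticPreset(
        dent_count_mixture=(0.53, 0.22, 0.25),
        depth_median_um=3.5, width_median_um=10.0,
        planar_resorption_median_pct=14.0,
    )
    normal = SyntheticPreset(
        dent_count_mixture=(0.53, 0.22, 0.25),
        depth_median_um=3.5, width_median_um=10.0,
        planar_resorption_median_pct=8.0,
    )
    return {
        ("charcot", "rankl"): charcot_rankl,
        ("charcot", "rankl_anti_tnf"): charcot_anti,
        ("diabetic", "rankl"): normal,
        ("diabetic", "rankl_anti_tnf"): normal,
        ("control", "rankl"): normal,
        ("control", "rankl_anti_tnf"): normal,
    }


@dataclass
class ScanMetadata:
    """Scan geometry shared by all generated traces."""

    scan_length_um: float = DEFAULT_SCAN_LENGTH_UM
    sample_interval_um: float = DEFAULT_SAMPLE_INTERVAL_UM
    vertical_range_um: float = DEFAULT_VERTICAL_RANGE_UM


# ---------------------------------------------------------------------------
# Pit shapes
# ---------------------------------------------------------------------------


def _raised_cosine(u: np.ndarray, depth: float, width: float) -> np.ndarray:
    out = np.zeros_like(u, dtype=float)
    inside = np.abs(u) <= width / 2
    out[inside] = depth / 2 * (1 + np.cos(2 * np.pi * u[inside] / width))
    return out


def _gaussian_bump(u: np.ndarray, depth: float, width: float) -> np.ndarray:
    # width is the compact support; sigma chosen so the bump is ~0 at +-w/2
    sigma = width / 6
    out = depth * np.exp(-(u ** 2) / (2 * sigma ** 2))
    out[np.abs(u) > width / 2] = 0.0
    return out


def _halfwidth_at(depth: float, width: float, target: float, shape: str) -> float:
    """Distance from a dent centre at which its deficit falls to ``target``."""
    target = min(target, depth)
    if shape == "raised_cosine":
        c = np.clip(2 * target / depth - 1, -1.0, 1.0)
        return width / (2 * np.pi) * float(np.arccos(c))
    sigma = width / 6
    if target <= 0:
        return width / 2
    return min(width / 2, sigma * float(np.sqrt(2 * np.log(depth / target))))


@dataclass
class PitShape:
    """Analytic description of one pit: a train of dents centred at 0."""

    dent_depths: np.ndarray
    dent_widths: np.ndarray
    dent_offsets: np.ndarray  # dent centres relative to the pit centre
    dent_shape: str = "raised_cosine"

    @property
    def dent_count(self) -> int:
        return int(self.dent_depths.size)

    @property
    def depth(self) -> float:
        return float(np.max(self.dent_depths))

    @property
    def extent_width(self) -> float:
        left = float(self.dent_offsets[0] - self.dent_widths[0] / 2)
        right = float(self.dent_offsets[-1] + self.dent_widths[-1] / 2)
        return right - left

    def deficit(self, x: np.ndarray, center: float) -> np.ndarray:
        """Height deficit (positive downward) of the pit at positions ``x``."""
        bump = _raised_cosine if self.dent_shape == "raised_cosine" else _gaussian_bump
        out = np.zeros_like(x, dtype=float)
        for d, w, off in zip(self.dent_depths, self.dent_widths, self.dent_offsets):
            out = np.maximum(out, bump(x - center - off, d, w))
        return out


def sample_pit(preset: SyntheticPreset, rng: np.random.Generator) -> PitShape:
    """Draw one pit: dent count from the mixture, then per-dent geometry.

    Consecutive dents are spaced so the ridge between them rises to
    ``ridge_relief`` × the shallower dent's depth below the baseline.
    """
    r = rng.random()
    p1, p2, _ = preset.dent_count_mixture
    if r < p1:
        count = 1
    elif r < p1 + p2:
        count = 2
    else:
        count = int(rng.integers(3, 5))
    depths = rng.lognormal(np.log(preset.depth_median_um), preset.depth_log_sd, count)
    widths = rng.lognormal(np.log(preset.width_median_um), preset.width_log_sd, count)
    offsets = np.zeros(count)
    for i in range(1, count):
        # ridge deficit scales with the deeper neighbour (the pit depth scale),
        # floored at 3·noise so surface roughness cannot sever the ridge, and
        # capped at half the shallower dent so both lobes stay distinct
        target = max(preset.ridge_relief * max(depths[i - 1], depths[i]),
                     3 * preset.noise_sigma_um)
        target = min(target, 0.5 * min(depths[i - 1], depths[i]))
        gap = (_halfwidth_at(depths[i - 1], widths[i - 1], target, preset.dent_shape)
               + _halfwidth_at(depths[i], widths[i], target, preset.dent_shape))
        offsets[i] = offsets[i - 1] + gap
    # centre the pit support at 0
    left = offsets[0] - widths[0] / 2
    right = offsets[-1] + widths[-1] / 2
    offsets -= (left + right) / 2
    return PitShape(dent_depths=depths, dent_widths=widths, dent_offsets=offsets,
                    dent_shape=preset.dent_shape)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


@dataclass
class PlacedPit:
    """Ground-truth record of one pit placed on a trace."""

    center: float
    dent_centers: list[float]
    dent_count: int
    depth: float
    start: float
    end: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TraceTruth:
    """Ground truth of one generated trace."""

    pits: list[PlacedPit]
    dropped: int = 0

    def to_dict(self) -> dict:
        return {"pits": [p.to_dict() for p in self.pits], "dropped": self.dropped}


def render_trace(
    shapes: list[PitShape],
    centers: list[float],
    meta: ScanMetadata,
    noise_sigma: float,
    rng: np.random.Generator | None = None,
    source_id: str = "synthetic",
) -> tuple[Trace, TraceTruth]:
    """Render pits at explicit positions into a trace (zero baseline)."""
    dx = meta.sample_interval_um
    n = int(np.floor(meta.scan_length_um / dx)) + 1
    x = np.arange(n) * dx
    deficit = np.zeros(n)
    pits = []
    for shape, c in zip(shapes, centers):
        deficit += shape.deficit(x, c)
        half = shape.extent_width / 2
        pits.append(PlacedPit(
            center=float(c),
            dent_centers=[float(c + o) for o in shape.dent_offsets],
            dent_count=shape.dent_count,
            depth=shape.depth,
            start=float(c - half),
            end=float(c + half),
        ))
    heights = -deficit
    if noise_sigma > 0:
        if rng is None:
            raise ValidationError("rng required when noise_sigma > 0")
        heights = heights + noise_sigma * rng.standard_normal(n)
    pits.sort(key=lambda p: p.center)
    trace = Trace(positions=x, heights=heights,
                  scan_length=meta.scan_length_um,
                  sample_interval=dx,
                  vertical_range=meta.vertical_range_um,
                  source_id=source_id)
    return trace, TraceTruth(pits=pits)


def generate_trace(
    preset: SyntheticPreset,
    meta: ScanMetadata | None = None,
    rng: np.random.Generator | None = None,
    source_id: str = "synthetic",
) -> tuple[Trace, TraceTruth]:
    """Generate one scan: Poisson pit count, rejection-sampled placement.

    The pit count is Poisson with mean ``pits_per_mm × scan_length / 1000``;
    centres are uniform with full extents kept inside the scan and at least
    ``MIN_GAP_UM`` between extents, re-drawn up to 100 times then dropped.
    Raises :class:`InfeasibleDensityError` when more than half the drawn
    pits cannot be placed.
    """
    meta = meta or ScanMetadata()
    rng = rng if rng is not None else np.random.default_rng()
    L = meta.scan_length_um
    count = int(rng.poisson(preset.pits_per_mm * L / 1000.0))
    shapes = [sample_pit(preset, rng) for _ in range(count)]
    placed: list[tuple[float, float]] = []
    kept_shapes: list[PitShape] = []
    centers: list[float] = []
    dropped = 0
    for shape in shapes:
        half = shape.extent_width / 2
        if 2 * half >= L:
            dropped += 1
            continue
        ok = False
        for _ in range(MAX_PLACEMENT_TRIES):
            c = rng.uniform(half, L - half)
            lo, hi = c - half, c + half
            if all(hi + MIN_GAP_UM <= s or lo - MIN_GAP_UM >= e for s, e in placed):
                ok = True
                break
        if ok:
            placed.append((lo, hi))
            kept_shapes.append(shape)
            centers.append(c)
        else:
            dropped += 1
    if count > 0 and dropped > 0.5 * count:
        raise InfeasibleDensityError(
            f"dropped {dropped}/{count} pits during placement; "
            "lower pits_per_mm or pit widths"
        )
    trace, truth = render_trace(kept_shapes, centers, meta, preset.noise_sigma_um,
                                rng, source_id=source_id)
    truth.dropped = dropped
    return trace, truth


# ---------------------------------------------------------------------------
# Planar masks
# ---------------------------------------------------------------------------


def generate_surface_mask(
    preset: SyntheticPreset,
    rng: np.random.Generator,
    grid_size: int = 512,
) -> tuple[PlanarMask, float]:
    """Generate a planar resorption mask as a union of random ellipses.

    Ellipse placement follows a Boolean model: the total drawn ellipse area
    is −ln(1 − p)·A so that the expected union fraction equals the target
    fraction ``p = planar_resorption_median_pct / 100``. Returns the mask and
    the exact rasterized resorbed percentage.
    """
    p = preset.planar_resorption_median_pct / 100.0
    if p >= 0.8:
        raise ValidationError(
            "planar resorption fraction >= 80% is a non-physical overlap regime"
        )
    grid = np.zeros((grid_size, grid_size), dtype=bool)
    if p > 0:
        target_area = -np.log(1.0 - p) * grid_size * grid_size
        drawn = 0.0
        while drawn < target_area:
            a = rng.lognormal(np.log(12.0), 0.4)  # semi-major axis, px
            b = a * rng.uniform(0.5, 1.0)
            rot = rng.uniform(0, np.pi)
            r0 = rng.uniform(0, grid_size)
            c0 = rng.uniform(0, grid_size)
            rr, cc = draw_ellipse(r0, c0, a, b, shape=grid.shape, rotation=rot)
            grid[rr, cc] = True
            drawn += np.pi * a * b
    mask = PlanarMask(grid=grid, pixel_size=1.0)
    return mask, 100.0 * float(grid.mean())


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Specification of a simulated study cohort."""

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"charcot": 10, "diabetic": 8, "control": 9})
    scans_per_subject: int = 10
    discs: int = 2
    presets: dict[tuple[str, str], SyntheticPreset] = field(default_factory=default_presets)
    jitter_sd: float = 0.15
    master_seed: int = 1
    scan: ScanMetadata = field(default_factory=ScanMetadata)
    mask_grid: int = 512

    def __post_init__(self) -> None:
        if self.scans_per_subject < 1:
            raise ValidationError("scans_per_subject must be >= 1")
        if self.discs not in (1, 2):
            raise ValidationError("discs must be 1 or 2")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        for group, n in self.n_subjects.items():
            if n < 1:
                raise ValidationError(f"n_subjects[{group!r}] must be >= 1")
        for group in self.n_subjects:
            for condition in CONDITIONS:
                if (group, condition) not in self.presets:
                    raise ValidationError(
                        f"missing preset for cell ({group}, {condition})"
                    )

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        kwargs: dict = {}
        if "n_subjects" in data:
            kwargs["n_subjects"] = {str(k): int(v) for k, v in data["n_subjects"].items()}
        for key in ("scans_per_subject", "discs", "mask_grid", "master_seed"):
            if key in data:
                kwargs[key] = int(data[key])
        if "jitter_sd" in data:
            kwargs["jitter_sd"] = float(data["jitter_sd"])
        if "scan" in data:
            kwargs["scan"] = ScanMetadata(**{k: float(v) for k, v in data["scan"].items()})
        if "presets" in data:
            presets = default_presets()
            for cell_key, overrides in data["presets"].items():
                group, _, condition = str(cell_key).partition("/")
                cell = (group, condition)
                if cell not in presets:
                    raise ValidationError(f"unknown preset cell {cell_key!r}")
                presets[cell] = replace(presets[cell], **overrides)
            kwargs["presets"] = presets
        unknown = set(data) - {"n_subjects", "scans_per_subject", "discs", "mask_grid",
                               "master_seed", "jitter_sd", "scan", "presets"}
        if unknown:
            raise ValidationError(f"unknown cohort spec fields: {sorted(unknown)}")
        return cls(**kwargs)

    def subject_table(self) -> list[tuple[int, str, str]]:
        """(global subject index, subject_id, group) in deterministic order."""
        table = []
        idx = 0
        for group in ("charcot", "diabetic", "control"):
            if group not in self.n_subjects:
                continue
            for i in range(self.n_subjects[group]):
                table.append((idx, f"{group}_{i + 1:02d}", group))
                idx += 1
        return table


def _jittered_preset(preset: SyntheticPreset, factors: dict) -> SyntheticPreset:
    mixture = np.asarray(preset.dent_count_mixture) * factors["mixture"]
    mixture = tuple(mixture / mixture.sum())
    return replace(
        preset,
        pits_per_mm=preset.pits_per_mm * factors["density"],
        depth_median_um=preset.depth_median_um * factors["depth"],
        width_median_um=preset.width_median_um * factors["width"],
        planar_resorption_median_pct=min(
            preset.planar_resorption_median_pct * factors["planar"], 79.0),
        dent_count_mixture=mixture,
    )


def subject_jitter_factors(spec: CohortSpec, subject_index: int) -> dict:
    """Per-subject multiplicative log-normal jitter, shared across conditions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, 1, subject_index]))
    sd = spec.jitter_sd
    return {
        "density": float(rng.lognormal(0.0, sd)),
        "depth": float(rng.lognormal(0.0, sd)),
        "width": float(rng.lognormal(0.0, sd)),
        "planar": float(rng.lognormal(0.0, sd)),
        "mixture": rng.lognormal(0.0, sd, 3),
    }


@dataclass
class SimScan:
    """One simulated scan with its provenance and ground truth."""

    subject_id: str
    group: str
    condition: str
    disc_index: int
    scan_index: int
    trace: Trace
    truth: TraceTruth


def iter_cohort(spec: CohortSpec) -> Iterator[SimScan]:
    """Yield every simulated scan of the cohort, deterministically."""
    for s_idx, subject_id, group in spec.subject_table():
        factors = subject_jitter_factors(spec, s_idx)
        for c_idx, condition in enumerate(CONDITIONS):
            preset = _jittered_preset(spec.presets[(group, condition)], factors)
            for scan_index in range(1, spec.scans_per_subject + 1):
                disc = 1 + (scan_index - 1) * spec.discs // spec.scans_per_subject
                rng = np.random.default_rng(np.random.SeedSequence(
                    [spec.master_seed, 2, s_idx, c_idx * 10_000 + scan_index]))
                source = f"{subject_id}_{condition}_scan{scan_index:02d}"
                trace, truth = generate_trace(preset, spec.scan, rng, source_id=source)
                yield SimScan(subject_id, group, condition, disc, scan_index,
                              trace, truth)


def iter_masks(spec: CohortSpec) -> Iterator[tuple[str, str, str, PlanarMask, float]]:
    """Yield (subject_id, group, condition, mask, resorbed %) per cell."""
    for s_idx, subject_id, group in spec.subject_table():
        factors = subject_jitter_factors(spec, s_idx)
        for c_idx, condition in enumerate(CONDITIONS):
            preset = _jittered_preset(spec.presets[(group, condition)], factors)
            rng = np.random.default_rng(np.random.SeedSequence(
                [spec.master_seed, 3, s_idx, c_idx]))
            mask, pct = generate_surface_mask(preset, rng, spec.mask_grid)
            yield subject_id, group, condition, mask, pct


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Simulate the cohort to disk: traces, manifest, ground truth, masks.

    Returns a summary dict with record counts and output paths. Output is
    byte-identical for identical (spec, master_seed).
    """
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    masks_dir = out_dir / "masks"
    traces_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    truth: dict[str, dict] = {}
    n_traces = 0
    for scan in iter_cohort(spec):
        fname = f"{scan.subject_id}_{scan.condition}_scan{scan.scan_index:02d}.txt"
        write_trace(scan.trace, traces_dir / fname)
        manifest_rows.append(dict(
            trace_path=f"traces/{fname}",
            subject_id=scan.subject_id,
            group=scan.group,
            condition=scan.condition,
            disc_index=scan.disc_index,
            scan_index=scan.scan_index,
        ))
        truth[scan.trace.source_id] = scan.truth.to_dict()
        n_traces += 1

    import pandas as pd  # local import to keep module import light

    manifest = CohortManifest(pd.DataFrame(manifest_rows))
    write_manifest(manifest, out_dir / "manifest.csv")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    mask_rows = []
    for subject_id, group, condition, mask, pct in iter_masks(spec):
        mname = f"{subject_id}_{condition}.pgm"
        write_pgm_mask(mask.grid, masks_dir / mname)
        mask_rows.append(dict(mask_path=f"masks/{mname}", subject_id=subject_id,
                              group=group, condition=condition,
                              resorbed_percent=pct))
    pd.DataFrame(mask_rows).to_csv(out_dir / "masks.csv", index=False)

    return {
        "n_traces": n_traces,
        "n_manifest_rows": len(manifest),
        "n_masks": len(mask_rows),
        "manifest": str(out_dir / "manifest.csv"),
        "ground_truth": str(out_dir / "ground_truth.json"),
        "masks": str(out_dir / "masks.csv"),
    }
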