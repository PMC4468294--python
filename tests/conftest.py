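import numpy as np
import pytest

from pitscan.trace_io import RunConfig, Trace

DX = 0.056  # default sampling interval, μm


def make_grid(length_um: float, dx: float = DX) -> np.ndarray:
    return np.arange(int(np.floor(length_um / dx)) + 1) * dx


def trace_from_heights(x: np.ndarray, heights: np.ndarray, **kwargs) -> Trace:
    kwargs.setdefault("scan_length", float(x[-1] - x[0]) + 1e-6)
    kwargs.setdefault("sample_interval", float(np.median(np.diff(x))))
    return Trace(positions=x, heights=heights, **kwargs)


def piecewise_pit_trace(length_um: float, vertices: list[tuple[float, float]],
                        noise_sigma: float = 0.0,
                        rng: np.random.Generator | None = None) -> Trace:
    """Trace with zero baseline and piecewise-linear pits through vertices."""
    x = make_grid(length_um)
    xs = [0.0] + [v[0] for v in vertices] + [length_um]
    hs = [0.0] + [v[1] for v in vertices] + [0.0]
    heights = np.interp(x, xs, hs)
    if noise_sigma > 0:
        heights = heights + noise_sigma * rng.standard_normal(x.size)
    return trace_from_heights(x, heights)


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
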