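import numpy as np
import pytest

from thermotype import synthgen
from thermotype.thermal import PlotLayout, PlotRegion, ThermalFrame


@pytest.fixture
def tiny_field():
    """Noiseless 6-line, 2-replicate field on a 4x3 grid, one season."""
    return synthgen.FieldSpec(
        n_lines=6, plots_per_line=2, grid_shape=(4, 3), plot_shape=(8, 8),
        gap=3, base_temp={"S1": 25.0}, noise_sd=0.0, seed=7)


@pytest.fixture
def two_season_field():
    """Two-season field with planted cold/warm/mediate labels and noise."""
    offsets, slopes, types = synthgen.plant_line_effects(3, 3, 6, seed=11)
    spec = synthgen.FieldSpec(
        n_lines=12, plots_per_line=3, grid_shape=(6, 6), plot_shape=(10, 10),
        gap=4, line_offset=offsets, trend_slope=slopes,
        noise_sd=0.2, replicate_sd=0.1, seed=11)
    return spec, types


@pytest.fixture
def square_frame():
    """3x3-plot frame with a hand-built layout and constant 30 degC canopy."""
    regions = [PlotRegion(f"P{r}{c}", f"L{r}{c}", 1,
                          2 + 6 * r, 6 + 6 * r, 2 + 6 * c, 6 + 6 * c)
               for r in range(3) for c in range(3)]
    adjacency = {}
    for r in range(3):
        for c in range(3):
            adjacency[f"P{r}{c}"] = [
                f"P{rr}{cc}"
                for rr, cc in [(r, c - 1), (r, c + 1), (r - 1, c), (r + 1, c)]
                if 0 <= rr < 3 and 0 <= cc < 3]
    layout = PlotLayout(regions, adjacency)
    pixels = np.full((20, 20), 30.0, dtype=np.float32)
    frame = ThermalFrame(pixels, date=0, season="S1")
    return frame, layout
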