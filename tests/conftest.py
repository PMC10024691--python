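"""Shared fixtures: a scaled-down chip and cached simulation outputs.

The full chip (38 channels, 3x3 areas, 0.24 µm/px imaging) produces
multi-gigapixel rasters and millions of reads; tests exercise the same
code paths on a small chip (8 channels, 20 µm channels at 40 µm pitch,
1-2 capture areas) where every stage runs in seconds.
"""

import pathlib

import pytest

from xdbit import ChipLayout, SimulationConfig, render_images, simulate_inputs
from xdbit.simulate import write_fastq


@pytest.fixture(scope="session")
def small_layout() -> ChipLayout:
    return ChipLayout(
        n_channels=8,
        channel_width=20.0,
        pitch=40.0,
        alignment_channels=frozenset({0, 7}),
        grid_rows=1,
        grid_cols=2,
    )


@pytest.fixture(scope="session")
def sim_config(small_layout) -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        layout=small_layout,
        n_genes=30,
        mean_expression_per_gene=2.0,
        reads_per_umi=3,
        intronic_read_fraction=0.1,
        nuclei_per_area=250,
    )


@pytest.fixture(scope="session")
def sim(sim_config) -> dict:
    """Noise-free simulation of the small chip (legend, reads, truth, scene)."""
    return simulate_inputs(sim_config)


@pytest.fixture(scope="session")
def sim_fastq(sim, tmp_path_factory) -> tuple[pathlib.Path, pathlib.Path]:
    d = tmp_path_factory.mktemp("fastq")
    r1, r2 = d / "r1.fastq", d / "r2.fastq"
    write_fastq(sim["r1"], r1)
    write_fastq(sim["r2"], r2)
    return r1, r2


@pytest.fixture(scope="session")
def one_area_layout() -> ChipLayout:
    return ChipLayout(
        n_channels=8,
        channel_width=20.0,
        pitch=40.0,
        alignment_channels=frozenset({0, 7}),
        grid_rows=1,
        grid_cols=1,
    )


@pytest.fixture(scope="session")
def scene(one_area_layout):
    """Rendered image pair of one capture area with truth transforms."""
    cfg = SimulationConfig(seed=2, layout=one_area_layout, nuclei_per_area=250)
    return render_images(cfg)
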