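"""Microfluidic chip geometry for deterministic barcoding in tissue.

The xDBiT chip barcodes tissue sections with two orthogonal sets of
parallel microchannels.  The intersections of one horizontal and one
vertical channel define square capture spots; a serpentine routing of the
channels addresses a 3x3 grid of capture areas ("wells") in parallel.  The
two outermost channels of each axis are filled with a fluorescent
alignment-marker solution instead of DNA barcodes, producing a frame of
fiducial marks around each capture area.

This module models that geometry and derives all quantities that depend
on it: the spot grid, spot center coordinates in micrometres, the total
scan area, and the counts of barcoded versus alignment intersections.

Conventions
-----------
* Origin at the top-left corner of each capture area, x rightward,
  y downward, micrometre units, 0-based channel indices.
* Ligation round #1 (horizontal channels) encodes the row index (y);
  ligation round #2 (vertical channels) encodes the column index (x).
  ``ChipLayout.swap_xy_axes`` flips this convention if a chip was run the
  other way around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "ChipLayout",
    "Spot",
    "SpotGrid",
    "build_spot_grid",
    "compute_scan_area",
    "spot_center",
    "default_well_ids",
]

#: Scan area of the original single-section DBiT-seq chip, used as the
#: reference when reporting the fold-increase in addressable tissue area.
DBIT_REFERENCE_AREA_MM2 = 25.0


class ChipConfigurationError(ValueError):
    """Raised when a chip layout is internally inconsistent."""


def default_well_ids(rows: int, cols: int) -> list[str]:
    """Well identifiers in plate convention: rows A.., columns 1.. .

    A 3x3 chip yields ``A1..A3, B1..B3, C1..C3`` in row-major order.
    """
    return [f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(cols)]


@dataclass(frozen=True)
class ChipLayout:
    """Geometry of one xDBiT chip pair.

    Parameters
    ----------
    n_channels
        Number of parallel microchannels per axis (default 38).
    channel_width
        Channel width in µm (default 50); spots are squares of this side.
    pitch
        Center-to-center channel distance in µm (default 100).
    alignment_channels
        Channel indices (per axis) carrying alignment marker instead of
        barcodes; default the two outermost channels {0, 37}.
    grid_rows, grid_cols
        Arrangement of capture areas on the slide (default 3x3).
    section_origins
        Mapping well_id -> (x, y) offset of the capture area's top-left
        corner in the global slide frame, µm.  If empty, areas tile the
        slide contiguously with a span of ``n_channels * pitch`` each.
    swap_xy_axes
        Flip the convention that ligation round #1 encodes y and round #2
        encodes x.
    """

    n_channels: int = 38
    channel_width: float = 50.0
    pitch: float = 100.0
    alignment_channels: frozenset[int] = frozenset({0, 37})
    grid_rows: int = 3
    grid_cols: int = 3
    section_origins: dict[str, tuple[float, float]] = field(default_factory=dict)
    swap_xy_axes: bool = False

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ChipConfigurationError("n_channels must be >= 1")
        if self.channel_width > self.pitch:
            raise ChipConfigurationError(
                f"channel_width ({self.channel_width}) exceeds pitch ({self.pitch})"
            )
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ChipConfigurationError("capture-area grid must be at least 1x1")
        bad = [i for i in self.alignment_channels if not 0 <= i < self.n_channels]
        if bad:
            raise ChipConfigurationError(
                f"alignment channel indices {bad} outside [0, {self.n_channels})"
            )
        if not self.section_origins:
            span = self.n_channels * self.pitch
            origins = {
                wid: (c * span, r * span)
                for r in range(self.grid_rows)
                for c in range(self.grid_cols)
                for wid in [f"{chr(ord('A') + r)}{c + 1}"]
            }
            object.__setattr__(self, "section_origins", origins)
        object.__setattr__(
            self, "alignment_channels", frozenset(self.alignment_channels)
        )

    # -- derived quantities -------------------------------------------------

    @property
    def well_ids(self) -> list[str]:
        return list(self.section_origins)

    @property
    def n_capture_areas(self) -> int:
        return len(self.section_origins)

    @property
    def n_barcoded_channels(self) -> int:
        """Channels per axis that carry spatial barcodes (not marker)."""
        return self.n_channels - len(self.alignment_channels)

    @property
    def spots_per_area(self) -> int:
        """All channel intersections per capture area (38x38 -> 1444)."""
        return self.n_channels**2

    @property
    def barcoded_spots_per_area(self) -> int:
        """Intersections of two barcoded channels (36x36 -> 1296)."""
        return self.n_barcoded_channels**2

    @property
    def area_span_um(self) -> float:
        """Side length of one capture area's channel region, µm."""
        return self.n_channels * self.pitch


@dataclass(frozen=True)
class Spot:
    """One channel intersection on the chip.

    ``is_barcoded`` is False where either channel carries alignment
    marker; such spots exist physically but receive no spatial barcode.
    """

    well_id: str
    x_idx: int
    y_idx: int
    center_um: tuple[float, float]
    is_barcoded: bool


@dataclass(frozen=True)
class SpotGrid:
    """The ordered collection of spots generated by a chip layout."""

    layout: ChipLayout
    spots: tuple[Spot, ...]

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self) -> Iterator[Spot]:
        return iter(self.spots)

    @property
    def n_barcoded(self) -> int:
        return sum(s.is_barcoded for s in self.spots)

    def to_frame(self) -> pd.DataFrame:
        """Grid as a table (well_id, x_idx, y_idx, x_um, y_um, is_barcoded)."""
        return pd.DataFrame(
            {
                "well_id": [s.well_id for s in self.spots],
                "x_idx": [s.x_idx for s in self.spots],
                "y_idx": [s.y_idx for s in self.spots],
                "x_um": [s.center_um[0] for s in self.spots],
                "y_um": [s.center_um[1] for s in self.spots],
                "is_barcoded": [s.is_barcoded for s in self.spots],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def spot_center(
    layout: ChipLayout, well_id: str, x_idx: int, y_idx: int
) -> tuple[float, float]:
    """Global µm coordinates of a spot center.

    The center sits at ``section_origin + idx * pitch + channel_width / 2``
    along each axis.
    """
    if well_id not in layout.section_origins:
        raise KeyError(f"unknown well_id {well_id!r}")
    if not (0 <= x_idx < layout.n_channels and 0 <= y_idx < layout.n_channels):
        raise IndexError(
            f"channel indices ({x_idx}, {y_idx}) outside [0, {layout.n_channels})"
        )
    ox, oy = layout.section_origins[well_id]
    half = layout.channel_width / 2.0
    return (ox + x_idx * layout.pitch + half, oy + y_idx * layout.pitch + half)


def build_spot_grid(layout: ChipLayout) -> SpotGrid:
    """Enumerate every channel intersection of every capture area.

    Ordering is deterministic: well-major (in ``section_origins`` order),
    then y_idx, then x_idx.  A spot is barcoded iff neither of its two
    channels is an alignment channel.
    """
    spots: list[Spot] = []
    for well_id in layout.section_origins:
        for y_idx in range(layout.n_channels):
            for x_idx in range(layout.n_channels):
                barcoded = (
                    x_idx not in layout.alignment_channels
                    and y_idx not in layout.alignment_channels
                )
                spots.append(
                    Spot(
                        well_id=well_id,
                        x_idx=x_idx,
                        y_idx=y_idx,
                        center_um=spot_center(layout, well_id, x_idx, y_idx),
                        is_barcoded=barcoded,
                    )
                )
    return SpotGrid(layout=layout, spots=tuple(spots))


def compute_scan_area(
    layout: ChipLayout, reference_area_mm2: float = DBIT_REFERENCE_AREA_MM2
) -> tuple[float, float]:
    """Total addressable scan area and its fold-change vs a reference chip.

    The scanned region of one capture area is the square spanned by the
    barcoded channels, ``(n_barcoded_channels * pitch)^2``; the chip total
    multiplies by the number of capture areas.  With the default layout
    (9 areas, 36 barcoded channels, 100 µm pitch) this is 116.64 mm², a
    4.66-fold increase over the 25 mm² single-section reference.

    Returns
    -------
    (area_mm2, fold_change)
    """
    side_mm = layout.n_barcoded_channels * layout.pitch / 1000.0
    area = layout.n_capture_areas * side_mm**2
    return area, area / reference_area_mm2


def load_layout_config(path) -> ChipLayout:
    """Read a chip layout from a key-value config file.

    Recognised keys (one ``key = value`` pair per line, ``#`` comments):
    n_channels, channel_width, pitch, alignment_channels (comma-separated
    indices), grid_rows, grid_cols, swap_xy_axes.  Missing keys take the
    default xDBiT values.
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    kwargs: dict = {}
    if "n_channels" in kv:
        kwargs["n_channels"] = int(kv["n_channels"])
    if "channel_width" in kv:
        kwargs["channel_width"] = float(kv["channel_width"])
    if "pitch" in kv:
        kwargs["pitch"] = float(kv["pitch"])
    if "alignment_channels" in kv:
        txt = kv["alignment_channels"]
        kwargs["alignment_channels"] = frozenset(
            int(t) for t in txt.split(",") if t.strip()
        )
    if "grid_rows" in kv:
        kwargs["grid_rows"] = int(kv["grid_rows"])
    if "grid_cols" in kv:
        kwargs["grid_cols"] = int(kv["grid_cols"])
    if "swap_xy_axes" in kv:
        kwargs["swap_xy_axes"] = kv["swap_xy_axes"].lower() in {"1", "true", "yes"}
    return ChipLayout(**kwargs)
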