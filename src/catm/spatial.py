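"""Electrode-grid mapping and multi-feature fusion.

Per-channel scalars are scattered onto an 8 x 9 flattening of the 10-20
montage (zeros at cells with no electrode), the four band maps are
stacked into a 4 x 8 x 9 block per feature, and the four feature blocks
are fused — by default concatenated into 16 planes, with elementwise add
and multiply available as ablation modes.  Channel-subset experiments
(18- and 5-electrode montages) zero out the masked-out electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .features import BAND_ORDER, FEATURE_ORDER, FeatureFrameSeries

__all__ = [
    "GridLayout",
    "default_layout",
    "CHANNELS_18",
    "CHANNELS_5",
    "map_to_grid",
    "stack_bands",
    "fuse",
    "series_to_frames",
]

#: Emotion-relevant reduced montages.
CHANNELS_18 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3",
    "Cz", "C4", "T8", "P7", "P3", "P4", "P8", "O1", "O2",
)
CHANNELS_5 = ("Fp1", "Fp2", "F7", "F8", "O1")

FUSION_MODES = ("concat", "add", "mult")


class LayoutError(ValueError):
    """Unknown electrode or inconsistent grid placement."""


@dataclass(frozen=True)
class GridLayout:
    rows: int
    cols: int
    placement: dict  # electrode name -> (row, col), injective
    mask: frozenset | None = None  # if set, electrodes to keep

    def __post_init__(self) -> None:
        seen = set()
        for name, (r, c) in self.placement.items():
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise LayoutError(f"{name} placed outside the {self.rows}x{self.cols} grid")
            if (r, c) in seen:
                raise LayoutError(f"cell {(r, c)} assigned twice")
            seen.add((r, c))
        if self.mask is not None:
            unknown = set(self.mask) - set(self.placement)
            if unknown:
                raise LayoutError(f"mask names unknown electrodes: {sorted(unknown)}")

    def with_mask(self, channels) -> "GridLayout":
        return GridLayout(self.rows, self.cols, self.placement, frozenset(channels))

    def keeps(self, name: str) -> bool:
        return self.mask is None or name in self.mask


def default_layout(mask=None) -> GridLayout:
    """The packaged 8 x 9 layout of the 32 DEAP electrodes."""
    text = resources.files("catm.data").joinpath("grid_8x9.yaml").read_text()
    raw = yaml.safe_load(text)
    placement = {name: tuple(rc) for name, rc in raw["placement"].items()}
    layout = GridLayout(rows=raw["rows"], cols=raw["cols"], placement=placement)
    return layout.with_mask(mask) if mask is not None else layout


def map_to_grid(values: np.ndarray, channel_names, layout: GridLayout) -> np.ndarray:
    """Scatter one scalar per electrode onto the grid; unplaced cells and
    masked-out electrodes are zero."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(channel_names),):
        raise ValueError("one value per channel name required")
    grid = np.zeros((layout.rows, layout.cols))
    for v, name in zip(values, channel_names):
        if name not in layout.placement:
            raise LayoutError(f"electrode {name!r} not in layout")
        if layout.keeps(name):
            r, c = layout.placement[name]
            grid[r, c] = v
    return grid


def stack_bands(maps: dict) -> np.ndarray:
    """Stack the four band maps (theta, alpha, beta, gamma order) into a
    (4, rows, cols) block."""
    missing = [b for b in BAND_ORDER if b not in maps]
    if missing:
        raise ValueError(f"missing band map(s): {missing}")
    return np.stack([maps[b] for b in BAND_ORDER], axis=0)


def fuse(blocks: dict, mode: str = "concat") -> np.ndarray:
    """Fuse the four per-feature (4, rows, cols) blocks.

    concat -> 16 planes ordered [DE bands, PSD bands, NE bands, FD bands];
    add / mult -> elementwise, 4 planes.
    """
    missing = [f for f in FEATURE_ORDER if f not in blocks]
    if missing:
        raise ValueError(f"missing feature block(s): {missing}")
    blocks_list = [np.asarray(blocks[f], dtype=float) for f in FEATURE_ORDER]
    if mode == "concat":
        return np.concatenate(blocks_list, axis=0)
    if mode == "add":
        out = blocks_list[0].copy()
        for b in blocks_list[1:]:
            out += b
        return out
    if mode == "mult":
        out = blocks_list[0].copy()
        for b in blocks_list[1:]:
            out *= b
        return out
    raise ValueError(f"unknown fusion mode {mode!r}; expected one of {FUSION_MODES}")


def series_to_frames(
    series: FeatureFrameSeries,
    channel_names,
    layout: GridLayout | None = None,
    mode: str = "concat",
    features: tuple[str, ...] = FEATURE_ORDER,
) -> np.ndarray:
    """Turn one trial's feature series into network-ready frames.

    Returns (windows, planes, rows, cols) with planes = 4 * n_features for
    concat, 4 for add/mult.  ``features`` selects a subset for feature
    ablations (order follows FEATURE_ORDER).
    """
    layout = layout if layout is not None else default_layout()
    features = tuple(f for f in FEATURE_ORDER if f in features)
    if not features:
        raise ValueError("at least one feature required")
    n_win = series.n_windows
    # vectorized scatter: build (channels,) -> grid index map once
    rows_idx, cols_idx, ch_idx = [], [], []
    for i, name in enumerate(channel_names):
        if name not in layout.placement:
            raise LayoutError(f"electrode {name!r} not in layout")
        if layout.keeps(name):
            r, c = layout.placement[name]
            rows_idx.append(r)
            cols_idx.append(c)
            ch_idx.append(i)
    feat_pos = [series.feature_names.index(f) for f in features]
    vals = series.values[:, :, feat_pos, :]  # (W, B, Fsel, C)
    frames = np.zeros((n_win, len(features), len(BAND_ORDER), layout.rows, layout.cols))
    frames[:, :, :, rows_idx, cols_idx] = np.transpose(vals[..., ch_idx], (0, 2, 1, 3))
    if mode == "concat":
        return frames.reshape(n_win, len(features) * len(BAND_ORDER), layout.rows, layout.cols)
    per_feature = [frames[:, i] for i in range(len(features))]
    if mode == "add":
        out = per_feature[0].copy()
        for b in per_feature[1:]:
            out += b
        return out
    if mode == "mult":
        out = per_feature[0].copy()
        for b in per_feature[1:]:
            out *= b
        return out
    raise ValueError(f"unknown fusion mode {mode!r}")
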