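"""Registration-grid geometry, patch extraction and spot-annotation I/O.

A *registration grid* is the regular lattice of spot centroids (Cartesian
ST arrays or hexagonally packed Visium arrays) at which full-resolution
patches are sampled from a whole-slide histology image. Patches are stacked
into a 5-D array (H_ST, W_ST, Hp, Wp, C); slide-background positions are
all-zero arrays and carry label 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

# Channel normalization constants conventional for RGB histology patches.
DEFAULT_CHANNEL_MEANS = (0.485, 0.456, 0.406)
DEFAULT_CHANNEL_STDS = (0.229, 0.224, 0.225)

SQRT3_2 = np.sqrt(3.0) / 2.0


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationGrid:
    """Geometry of a spot array: maps array indices to pixel centroids.

    ``layout`` is ``"cartesian"`` or ``"hexagonal"``. For hexagonal grids,
    rows of ``row_offset_parity`` are shifted +spacing/2 in x and the row
    pitch is spacing * sqrt(3)/2, so the six neighbors of an interior spot
    are all at center-to-center distance ``spacing_px``.
    """

    layout: str
    n_rows: int
    n_cols: int
    spacing_px: float
    origin_px: tuple[float, float] = (0.0, 0.0)
    row_offset_parity: str | None = None

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def spot_centroid(self, i: int, j: int) -> tuple[float, float]:
        """Pixel (x, y) of spot (row i, col j); x right, y down, 0-based."""
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise IndexError(f"spot ({i}, {j}) outside grid {self.shape}")
        ox, oy = self.origin_px
        s = self.spacing_px
        if self.layout == "cartesian":
            return (ox + j * s, oy + i * s)
        shifted = (i % 2 == 1) if self.row_offset_parity == "odd" else (i % 2 == 0)
        x = ox + j * s + (s / 2.0 if shifted else 0.0)
        y = oy + i * s * SQRT3_2
        return (x, y)

    def centroids(self) -> np.ndarray:
        """(n_rows, n_cols, 2) array of (x, y) centroids."""
        out = np.empty((self.n_rows, self.n_cols, 2))
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                out[i, j] = self.spot_centroid(i, j)
        return out

    def neighbors(self, i: int, j: int) -> list[tuple[int, int]]:
        """In-grid neighbors: 4-neighborhood (cartesian) or 6 (hexagonal)."""
        if self.layout == "cartesian":
            offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        else:
            from .nn.hexconv import hex_neighbor_offsets
            offs = hex_neighbor_offsets(i, self.row_offset_parity)
        return [(i + di, j + dj) for di, dj in offs
                if 0 <= i + di < self.n_rows and 0 <= j + dj < self.n_cols]


def make_grid(layout: str, n_rows: int, n_cols: int, spacing_px: float,
              origin_px: tuple[float, float] = (0.0, 0.0),
              row_offset_parity: str | None = None) -> RegistrationGrid:
    """Construct and validate a :class:`RegistrationGrid`."""
    if layout not in ("cartesian", "hexagonal"):
        raise ValueError(f"unknown layout {layout!r}")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if spacing_px <= 0:
        raise ValueError("spacing_px must be positive")
    if layout == "hexagonal":
        if row_offset_parity is None:
            row_offset_parity = "odd"
        if row_offset_parity not in ("odd", "even"):
            raise ValueError(f"row_offset_parity must be 'odd' or 'even', got {row_offset_parity!r}")
    elif row_offset_parity is not None:
        raise ValueError("row_offset_parity only applies to hexagonal grids")
    return RegistrationGrid(layout, int(n_rows), int(n_cols), float(spacing_px),
                            (float(origin_px[0]), float(origin_px[1])), row_offset_parity)


# ---------------------------------------------------------------------------
# Label grids and patch arrays
# ---------------------------------------------------------------------------


@dataclass
class LabelGrid:
    """Per-spot class labels: 0 = background, 1..n_classes = tissue classes."""

    labels: np.ndarray  # (H_ST, W_ST) int
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.min() < 0 or self.labels.max() > self.n_classes:
            raise ValueError(f"labels must lie in [0, {self.n_classes}]")

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class PatchArray:
    """5-D stack of image patches sampled at grid positions.

    ``values`` has shape (H_ST, W_ST, Hp, Wp, C); background positions are
    all-zero sub-arrays. The background mask is computed from raw pixels at
    extraction time and cached, so it survives normalization (after which
    zero is no longer special).
    """

    values: np.ndarray
    normalized: bool = False
    channel_means: tuple[float, ...] | None = None
    channel_stds: tuple[float, ...] | None = None
    background: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 5:
            raise ValueError("values must be 5-D (H_ST, W_ST, Hp, Wp, C)")
        if self.values.shape[2] != self.values.shape[3]:
            raise ValueError("patches must be square (Hp == Wp)")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def patch_px(self) -> int:
        return self.values.shape[2]

    @property
    def n_channels(self) -> int:
        return self.values.shape[4]


def detect_background(patches: PatchArray | np.ndarray) -> np.ndarray:
    """Boolean (H_ST, W_ST) mask, true exactly where max over the patch is 0.

    For a :class:`PatchArray` whose mask was cached at extraction the cache
    is returned, which keeps the mask identical before and after
    normalization.
    """
    if isinstance(patches, PatchArray):
        if patches.background is not None:
            return patches.background
        if patches.normalized:
            raise ValueError("background mask of a normalized PatchArray was not "
                             "cached before normalization")
        values = patches.values
    else:
        values = np.asarray(patches)
    return values.max(axis=(2, 3, 4)) == 0


def extract_patches(image: np.ndarray, grid: RegistrationGrid, patch_px: int,
                    foreground: LabelGrid | np.ndarray) -> PatchArray:
    """Sample patch_px-square crops centered at each foreground spot centroid.

    The crop spans the half-open window [c - patch_px/2, c + patch_px/2) in
    each axis (centroids rounded to the nearest pixel); regions outside the
    image are zero-padded, since tissue-edge spots are valid foreground.
    Background spots yield all-zero patches. Output is unnormalized.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.size == 0:
        raise ValueError("image is empty")
    if patch_px < 2 or patch_px % 2 != 0:
        raise ValueError("patch_px must be an even count >= 2")
    fg = foreground.foreground if isinstance(foreground, LabelGrid) else np.asarray(foreground, bool)
    if fg.shape != grid.shape:
        raise ValueError(f"foreground shape {fg.shape} != grid shape {grid.shape}")
    h_img, w_img, c = image.shape
    half = patch_px // 2
    out = np.zeros((grid.n_rows, grid.n_cols, patch_px, patch_px, c))
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            if not fg[i, j]:
                continue
            x, y = grid.spot_centroid(i, j)
            cx, cy = int(round(x)), int(round(y))
            if not (0 <= cx < w_img and 0 <= cy < h_img):
                raise ValueError(
                    f"centroid of foreground spot ({i}, {j}) at pixel ({cx}, {cy}) "
                    f"lies outside the {w_img}x{h_img} image")
            y0, y1 = cy - half, cy + half
            x0, x1 = cx - half, cx + half
            sy0, sy1 = max(y0, 0), min(y1, h_img)
            sx0, sx1 = max(x0, 0), min(x1, w_img)
            out[i, j, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    arr = PatchArray(out, normalized=False)
    arr.background = detect_background(arr.values)
    return arr


def normalize_patches(patches: PatchArray,
                      channel_means=DEFAULT_CHANNEL_MEANS,
                      channel_stds=DEFAULT_CHANNEL_STDS) -> PatchArray:
    """Per-channel standardization x_c -> (x_c - mu_c) / sigma_c.

    Background patches are re-zeroed afterwards (their background status is
    recorded from the raw pixels first), so they stay all-zero arrays.
    """
    if patches.normalized:
        raise ValueError("PatchArray is already normalized")
    mu = np.asarray(channel_means, dtype=np.float64)
    sd = np.asarray(channel_stds, dtype=np.float64)
    if mu.shape != (patches.n_channels,) or sd.shape != (patches.n_channels,):
        raise ValueError("normalization constants must have one entry per channel")
    if np.any(sd <= 0):
        raise ValueError("channel stds must be positive")
    bg = detect_background(patches)
    values = (patches.values - mu) / sd
    values[bg] = 0.0
    return PatchArray(values, normalized=True, channel_means=tuple(mu),
                      channel_stds=tuple(sd), background=bg)


# ---------------------------------------------------------------------------
# Spot-annotation tables
# ---------------------------------------------------------------------------

_COLUMNS = ["array_row", "array_col", "pixel_x", "pixel_y", "label"]


@dataclass
class SpotAnnotationTable:
    """Foreground spot records: array indices, pixel centroid, class name."""

    records: pd.DataFrame
    class_vocabulary: list[str]

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        dup = df.duplicated(subset=["array_row", "array_col"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["array_row", "array_col"]].tolist()
            raise ValueError(f"duplicate spot ({pair[0]}, {pair[1]}) in annotation table")
        bad = set(df["label"]) - set(self.class_vocabulary)
        if bad:
            raise ValueError(f"labels outside vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def to_label_grid(self, grid: RegistrationGrid) -> LabelGrid:
        """LabelGrid over the grid; spots not listed are background (0)."""
        labels = np.zeros(grid.shape, dtype=np.int64)
        idx = {name: k + 1 for k, name in enumerate(self.class_vocabulary)}
        for _, rec in self.records.iterrows():
            i, j = int(rec["array_row"]), int(rec["array_col"])
            if not (0 <= i < grid.n_rows and 0 <= j < grid.n_cols):
                raise ValueError(f"spot ({i}, {j}) outside grid {grid.shape}")
            labels[i, j] = idx[rec["label"]]
        return LabelGrid(labels, n_classes=len(self.class_vocabulary))


def label_grid_to_table(labels: LabelGrid, grid: RegistrationGrid,
                        class_vocabulary: list[str]) -> SpotAnnotationTable:
    """Inverse of :meth:`SpotAnnotationTable.to_label_grid` on foreground spots."""
    rows = []
    for i, j in zip(*np.nonzero(labels.labels)):
        x, y = grid.spot_centroid(int(i), int(j))
        rows.append((int(i), int(j), x, y, class_vocabulary[labels.labels[i, j] - 1]))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return SpotAnnotationTable(df, list(class_vocabulary))


def write_spot_annotations(table: SpotAnnotationTable, path) -> None:
    """Write a tab-separated annotation file with a class-vocabulary directive."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# classes: " + ",".join(table.class_vocabulary) + "\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for _, rec in table.records.iterrows():
            fh.write("\t".join([
                str(int(rec["array_row"])), str(int(rec["array_col"])),
                repr(float(rec["pixel_x"])), repr(float(rec["pixel_y"])),
                str(rec["label"]),
            ]) + "\n")


def read_spot_annotations(path, grid: RegistrationGrid | None = None,
                          class_vocabulary: list[str] | None = None) -> SpotAnnotationTable:
    """Read a tab-separated annotation file ('#'-prefixed comments ignored).

    The class vocabulary is taken from a ``# classes:`` directive if present,
    else it must be supplied. If ``grid`` is given, indices are bounds-checked.
    """
    path = Path(path)
    vocab = class_vocabulary
    with path.open() as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.lower().startswith("classes:"):
                vocab = [c.strip() for c in stripped.split(":", 1)[1].split(",") if c.strip()]
            continue
        if line.strip():
            body.append(line)
    if vocab is None:
        raise ValueError(f"{path}: no '# classes:' directive and no vocabulary supplied")
    if not body:
        df = pd.DataFrame(columns=_COLUMNS)
    else:
        from io import StringIO
        df = pd.read_csv(StringIO("".join(body)), sep="\t")
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        df = df[_COLUMNS]
    table = SpotAnnotationTable(df, list(vocab))
    if grid is not None:
        bad = df[(df["array_row"] < 0) | (df["array_row"] >= grid.n_rows)
                 | (df["array_col"] < 0) | (df["array_col"] >= grid.n_cols)]
        if len(bad):
            i, j = bad.iloc[0][["array_row", "array_col"]]
            raise ValueError(f"{path}: spot ({i}, {j}) outside grid {grid.shape}")
    return table


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG raster as float64 RGB scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        warnings.warn("float image with values above 1; rescaling by max")
        arr = arr / arr.max()
    return arr


def write_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float RGB raster as PNG/JPEG (8-bit) or TIFF (float)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="rgb")
    else:
        arr = np.clip(np.asarray(image) * 255.0, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr).save(path)


__all__ = [
    "RegistrationGrid", "LabelGrid", "PatchArray", "SpotAnnotationTable",
    "make_grid", "extract_patches", "normalize_patches", "detect_background",
    "read_spot_annotations", "write_spot_annotations", "label_grid_to_table",
    "read_image", "write_image",
    "DEFAULT_CHANNEL_MEANS", "DEFAULT_CHANNEL_STDS",
]
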