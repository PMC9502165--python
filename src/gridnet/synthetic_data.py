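"""Seeded generator of grid-structured synthetic tissue datasets.

Real spot-annotated histology has (i) spatially contiguous tissue-type
regions surrounded by slide background, (ii) per-class textural differences
at sub-patch scale, and (iii) local corruption ("damaged tissue") where the
patch alone is uninformative although the true class is clear from context.
This module emulates exactly those properties with controllable, license-free
dot-density textures: each class renders as Poisson-placed dots of a
class-specific density and radius over a class-specific base color, inside an
elliptic tissue mask whose outside is all-zero background.

Every artifact is a pure function of (spec, seed): identical specs yield
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid_data import (LabelGrid, PatchArray, RegistrationGrid,
                        label_grid_to_table, make_grid, write_image,
                        write_spot_annotations)

REGION_MODELS = ("voronoi", "layered_bands", "nested_rings")
DAMAGE_MODES = ("blank", "blur")

# value floor for rendered tissue pixels, keeps foreground patches nonzero
_PIXEL_FLOOR = 0.01

_BASE_COLORS = [
    (0.85, 0.55, 0.62), (0.55, 0.68, 0.85), (0.68, 0.85, 0.55),
    (0.85, 0.80, 0.50), (0.75, 0.55, 0.85), (0.55, 0.85, 0.80),
    (0.85, 0.65, 0.45), (0.60, 0.60, 0.88),
]


@dataclass(frozen=True)
class ClassTexture:
    """Rendering parameters of one tissue class.

    ``density`` is expected dots per pixel of patch area, so a patch of side
    P carries Poisson(density * P^2) dots of radius ``radius_px`` drawn in a
    darkened shade of ``base_rgb``; ``jitter`` is the sd of additive pixel
    noise.
    """

    density: float
    radius_px: int
    base_rgb: tuple[float, float, float]
    jitter: float = 0.02


def default_textures(n_classes: int, patch_px: int) -> tuple[ClassTexture, ...]:
    """Distinct, well-separated textures: dot densities form a geometric-ish
    ladder and base colors are distinct hues."""
    densities = np.linspace(0.003, 0.003 + 0.007 * (n_classes - 1), n_classes)
    out = []
    for k in range(n_classes):
        color = _BASE_COLORS[k % len(_BASE_COLORS)]
        out.append(ClassTexture(float(densities[k]), max(patch_px // 16, 1), color))
    return tuple(out)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset (the study conditions).

    Defaults describe the desk-scale benchmark: 24 arrays on a 9x9 grid of
    32-px patches with 4 classes, clean labels and undamaged tissue. Noise
    rates are off by default and switched on per experiment.
    """

    layout: str = "cartesian"
    n_rows: int = 9
    n_cols: int = 9
    patch_px: int = 32
    n_classes: int = 4
    n_arrays: int = 24
    region_model: str = "voronoi"
    textures: tuple[ClassTexture, ...] | None = None
    tissue_ellipse_fraction: float = 0.65
    label_flip_rate: float = 0.0
    damaged_patch_rate: float = 0.0
    damage_mode: str = "blank"
    row_offset_parity: str = "odd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_model not in REGION_MODELS:
            raise ValueError(f"unknown region model {self.region_model!r}")
        if self.damage_mode not in DAMAGE_MODES:
            raise ValueError(f"unknown damage mode {self.damage_mode!r}")
        if not (0 <= self.label_flip_rate <= 1 and 0 <= self.damaged_patch_rate <= 1):
            raise ValueError("noise rates must lie in [0, 1]")
        if self.layout not in ("cartesian", "hexagonal"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.textures is None:
            object.__setattr__(self, "textures",
                               default_textures(self.n_classes, self.patch_px))
        elif len(self.textures) != self.n_classes:
            raise ValueError("one texture per class required")

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)

    @property
    def class_vocabulary(self) -> list[str]:
        return [f"class_{k}" for k in range(1, self.n_classes + 1)]

    def registration_grid(self, spacing_px: float | None = None) -> RegistrationGrid:
        spacing = spacing_px if spacing_px is not None else float(self.patch_px)
        parity = self.row_offset_parity if self.layout == "hexagonal" else None
        half = self.patch_px / 2.0
        return make_grid(self.layout, self.n_rows, self.n_cols, spacing,
                         origin_px=(half, half), row_offset_parity=parity)


@dataclass
class ArraySample:
    """One synthetic array: raw patches, training labels, and the truth.

    ``labels`` may differ from ``truth`` after label-flip noise; damaged
    patches keep their true labels (the damage is in the pixels).
    """

    patches: PatchArray
    labels: LabelGrid
    truth: LabelGrid


@dataclass
class SyntheticDataset:
    arrays: list[ArraySample]
    split: dict[str, list[int]]
    spec: SyntheticSpec
    seed: int

    def _subset(self, name: str) -> list[ArraySample]:
        return [self.arrays[i] for i in self.split[name]]

    @property
    def train(self) -> list[ArraySample]:
        return self._subset("train")

    @property
    def val(self) -> list[ArraySample]:
        return self._subset("val")

    @property
    def test(self) -> list[ArraySample]:
        return self._subset("test")

    @property
    def class_vocabulary(self) -> list[str]:
        return self.spec.class_vocabulary


# ---------------------------------------------------------------------------
# Label maps
# ---------------------------------------------------------------------------


def _tissue_mask(spec: SyntheticSpec) -> np.ndarray:
    """Elliptic foreground mask covering ~tissue_ellipse_fraction of the grid."""
    scale = np.sqrt(4.0 * spec.tissue_ellipse_fraction / np.pi)
    ci, cj = (spec.n_rows - 1) / 2.0, (spec.n_cols - 1) / 2.0
    ri, rj = spec.n_rows / 2.0 * scale, spec.n_cols / 2.0 * scale
    ii, jj = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    return ((ii - ci) / ri) ** 2 + ((jj - cj) / rj) ** 2 <= 1.0


def _spot_coords(spec: SyntheticSpec) -> np.ndarray:
    """(H, W, 2) geometric coordinates of spots in units of spacing."""
    ii, jj = np.mgrid[0:spec.n_rows, 0:spec.n_cols].astype(float)
    if spec.layout == "cartesian":
        return np.stack([ii, jj], axis=-1)
    shift = (ii % 2 == 1) if spec.row_offset_parity == "odd" else (ii % 2 == 0)
    x = jj + 0.5 * shift
    y = ii * (np.sqrt(3) / 2.0)
    return np.stack([y, x], axis=-1)


def _grid_neighbors(spec: SyntheticSpec):
    """In-grid neighborhood function for the spec's layout."""
    from .nn.hexconv import hex_neighbor_offsets
    h, w = spec.n_rows, spec.n_cols

    def fn(i: int, j: int):
        if spec.layout == "cartesian":
            offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        else:
            offs = hex_neighbor_offsets(i, spec.row_offset_parity)
        return [(i + di, j + dj) for di, dj in offs
                if 0 <= i + di < h and 0 <= j + dj < w]

    return fn


def _components(mask: np.ndarray, spec: SyntheticSpec) -> list[list[tuple[int, int]]]:
    neighbors = _grid_neighbors(spec)
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        seen[start] = True
        comp, stack = [start], [start]
        while stack:
            i, j = stack.pop()
            for n in neighbors(i, j):
                if mask[n] and not seen[n]:
                    seen[n] = True
                    comp.append(n)
                    stack.append(n)
        comps.append(comp)
    return comps


def _regions_connected(labels: np.ndarray, spec: SyntheticSpec) -> bool:
    for c in range(1, spec.n_classes + 1):
        mask = labels == c
        if not mask.any() or len(_components(mask, spec)) != 1:
            return False
    return True


def _repair_connectivity(labels: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Merge minor components of each class into an adjacent class.

    Geometric region constructions (e.g. elliptic rings) can split on a
    coarse grid's neighborhood; each spot of a non-largest component is
    reassigned to the modal label among its already-labeled neighbors, which
    preserves the receiving regions' connectedness.
    """
    labels = labels.copy()
    neighbors = _grid_neighbors(spec)
    for _ in range(50):
        if _regions_connected(labels, spec):
            return labels
        for c in range(1, spec.n_classes + 1):
            comps = _components(labels == c, spec)
            if len(comps) <= 1:
                continue
            comps.sort(key=len, reverse=True)
            for comp in comps[1:]:
                for i, j in comp:
                    cand = [labels[n] for n in neighbors(i, j)
                            if labels[n] > 0 and labels[n] != c]
                    if cand:
                        labels[i, j] = np.bincount(cand).argmax()
    return labels


def generate_label_map(spec: SyntheticSpec, array_seed) -> LabelGrid:
    """Spatially coherent multi-class label map inside the tissue ellipse.

    Region layouts are re-drawn (deterministically) until every class is
    present and forms one connected region under the grid's neighborhood.
    """
    mask = _tissue_mask(spec)
    n_fg = int(mask.sum())
    if n_fg < spec.n_classes:
        raise ValueError(f"tissue mask holds {n_fg} spots; cannot place "
                         f"{spec.n_classes} classes")
    coords = _spot_coords(spec)
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence([_as_seed(array_seed), 1, attempt]))
        labels = np.zeros((spec.n_rows, spec.n_cols), dtype=np.int64)
        if spec.region_model == "layered_bands":
            rows = np.nonzero(mask.any(axis=1))[0]
            if len(rows) < spec.n_classes:
                raise ValueError("too few tissue rows for layered bands")
            edges = np.array_split(rows, spec.n_classes)
            for c, band in enumerate(edges, start=1):
                for i in band:
                    labels[i, mask[i]] = c
        elif spec.region_model == "voronoi":
            fg = np.argwhere(mask)
            seeds = fg[rng.choice(len(fg), size=spec.n_classes, replace=False)]
            seed_xy = coords[seeds[:, 0], seeds[:, 1]]
            d = np.linalg.norm(coords[mask][:, None, :] - seed_xy[None], axis=2)
            labels[mask] = d.argmin(axis=1) + 1
        else:  # nested_rings
            center = coords[mask].mean(axis=0)
            r = np.linalg.norm(coords[mask] - center, axis=1)
            qs = np.quantile(r, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
            labels[mask] = np.searchsorted(qs, r, side="right") + 1
        labels = _repair_connectivity(labels, spec)
        if _regions_connected(labels, spec):
            return LabelGrid(labels, spec.n_classes)
    raise RuntimeError(f"could not draw a connected {spec.region_model} label map "
                       f"in 200 attempts (seed {array_seed})")


def _as_seed(seed) -> int:
    return int(seed) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return dy[keep], dx[keep]


def render_array(labels: LabelGrid, spec: SyntheticSpec, array_seed) -> PatchArray:
    """Render every foreground spot as its class texture; background is zero."""
    rng = np.random.default_rng(np.random.SeedSequence([_as_seed(array_seed), 2]))
    p = spec.patch_px
    values = np.zeros((spec.n_rows, spec.n_cols, p, p, 3))
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            c = labels.labels[i, j]
            if c == 0:
                continue
            tex = spec.textures[c - 1]
            patch = np.tile(np.asarray(tex.base_rgb), (p, p, 1))
            count = rng.poisson(tex.density * p * p)
            if count:
                cy = rng.integers(0, p, size=count)
                cx = rng.integers(0, p, size=count)
                dy, dx = _disk_offsets(tex.radius_px)
                yy = (cy[:, None] + dy[None, :]).ravel()
                xx = (cx[:, None] + dx[None, :]).ravel()
                ok = (yy >= 0) & (yy < p) & (xx >= 0) & (xx < p)
                patch[yy[ok], xx[ok]] = np.asarray(tex.base_rgb) * 0.35
            if tex.jitter > 0:
                patch += rng.normal(0.0, tex.jitter, size=patch.shape)
            values[i, j] = np.clip(patch, _PIXEL_FLOOR, 1.0)
    out = PatchArray(values, normalized=False)
    out.background = ~labels.foreground
    return out


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------


def inject_noise(dataset: SyntheticDataset, spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Flip training labels and damage patch pixels at the spec's rates.

    Flipped spots keep their truth separately so correction can be scored;
    damaged spots keep their true labels but their pixels are blanked to a
    constant mid-gray or blurred, removing the class-discriminative texture
    while staying foreground.
    """
    spec = spec or dataset.spec
    arrays = []
    for idx, sample in enumerate(dataset.arrays):
        rng = np.random.default_rng(np.random.SeedSequence([_as_seed(dataset.seed), 3, idx]))
        labels = sample.labels.labels.copy()
        values = sample.patches.values.copy()
        fg = sample.truth.foreground
        fi, fj = np.nonzero(fg)
        if spec.label_flip_rate > 0 and spec.n_classes > 1:
            flip = rng.random(len(fi)) < spec.label_flip_rate
            for i, j in zip(fi[flip], fj[flip]):
                others = [c for c in range(1, spec.n_classes + 1) if c != labels[i, j]]
                labels[i, j] = others[rng.integers(0, len(others))]
        if spec.damaged_patch_rate > 0:
            damage = rng.random(len(fi)) < spec.damaged_patch_rate
            for i, j in zip(fi[damage], fj[damage]):
                if spec.damage_mode == "blank":
                    values[i, j] = 0.5
                else:
                    for ch in range(values.shape[-1]):
                        values[i, j, :, :, ch] = ndimage.gaussian_filter(
                            values[i, j, :, :, ch], sigma=spec.patch_px / 6.0,
                            mode="nearest")
        patches = PatchArray(values, normalized=False)
        patches.background = ~fg
        arrays.append(ArraySample(patches, LabelGrid(labels, spec.n_classes),
                                  sample.truth))
    return SyntheticDataset(arrays, dataset.split, spec, dataset.seed)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def split_sizes(n_arrays: int) -> tuple[int, int, int]:
    """70/10/20 split by array; validation gets at least one array."""
    n_train = int(np.floor(0.7 * n_arrays))
    n_val = max(int(np.floor(0.1 * n_arrays)), 1)
    n_test = n_arrays - n_train - n_val
    if n_test < 1 or n_train < 1:
        raise ValueError(f"cannot split {n_arrays} arrays 70/10/20")
    return n_train, n_val, n_test


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate ``n_arrays`` seeded arrays and assign the 70/10/20 split."""
    master = np.random.SeedSequence(spec.seed)
    array_seeds = master.generate_state(spec.n_arrays) % (2 ** 31 - 1)
    arrays = []
    for k in range(spec.n_arrays):
        labels = generate_label_map(spec, array_seeds[k])
        patches = render_array(labels, spec, array_seeds[k])
        truth = LabelGrid(labels.labels.copy(), spec.n_classes)
        arrays.append(ArraySample(patches, labels, truth))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    order = rng.permutation(spec.n_arrays)
    n_train, n_val, _ = split_sizes(spec.n_arrays)
    split = {
        "train": sorted(order[:n_train].tolist()),
        "val": sorted(order[n_train:n_train + n_val].tolist()),
        "test": sorted(order[n_train + n_val:].tolist()),
    }
    dataset = SyntheticDataset(arrays, split, spec, spec.seed)
    if spec.label_flip_rate > 0 or spec.damaged_patch_rate > 0:
        dataset = inject_noise(dataset, spec)
    return dataset


def write_dataset(dataset: SyntheticDataset, directory) -> None:
    """Write per-array images + spot-annotation TSVs (the dialect grid_data
    reads), plus a provenance file.

    Cartesian arrays tile exactly into a mosaic whose extraction reproduces
    the patches (up to 8-bit quantization); hexagonal arrays are written by
    pasting patches at their centroids (later rows overwrite overlaps).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = dataset.spec
    grid = spec.registration_grid()
    p = spec.patch_px
    for idx, sample in enumerate(dataset.arrays):
        if spec.layout == "cartesian":
            from .models import stitch_patches
            image = stitch_patches(sample.patches)
        else:
            xs = grid.centroids()
            h_img = int(np.ceil(xs[..., 1].max() + p / 2))
            w_img = int(np.ceil(xs[..., 0].max() + p / 2))
            image = np.zeros((h_img, w_img, 3))
            for i in range(spec.n_rows):
                for j in range(spec.n_cols):
                    if sample.truth.labels[i, j] == 0:
                        continue
                    cx, cy = (int(round(v)) for v in grid.spot_centroid(i, j))
                    image[cy - p // 2: cy + p // 2, cx - p // 2: cx + p // 2] = \
                        sample.patches.values[i, j]
        write_image(image, directory / f"array_{idx:03d}.png")
        table = label_grid_to_table(sample.labels, grid, spec.class_vocabulary)
        write_spot_annotations(table, directory / f"array_{idx:03d}.tsv")
        truth_table = label_grid_to_table(sample.truth, grid, spec.class_vocabulary)
        write_spot_annotations(truth_table, directory / f"array_{idx:03d}.truth.tsv")
    prov = {
        "spec": dataclasses.asdict(spec),
        "seed": dataset.seed,
        "split": dataset.split,
    }
    import json
    (directory / "provenance.json").write_text(json.dumps(prov, indent=2, default=list))


def read_dataset(directory) -> SyntheticDataset:
    """Reconstruct a written dataset through the real raster/TSV readers.

    Patch pixels round-trip up to 8-bit quantization (cartesian layouts).
    """
    import json
    from .grid_data import extract_patches, read_image, read_spot_annotations
    directory = Path(directory)
    prov = json.loads((directory / "provenance.json").read_text())
    spec_dict = dict(prov["spec"])
    spec_dict["textures"] = tuple(
        ClassTexture(t["density"], t["radius_px"], tuple(t["base_rgb"]), t["jitter"])
        for t in spec_dict["textures"])
    spec = SyntheticSpec(**spec_dict)
    grid = spec.registration_grid()
    arrays = []
    for idx in range(spec.n_arrays):
        image = read_image(directory / f"array_{idx:03d}.png")
        labels = read_spot_annotations(directory / f"array_{idx:03d}.tsv", grid).to_label_grid(grid)
        truth = read_spot_annotations(directory / f"array_{idx:03d}.truth.tsv", grid).to_label_grid(grid)
        patches = extract_patches(image, grid, spec.patch_px, truth)
        arrays.append(ArraySample(patches, labels, truth))
    return SyntheticDataset(arrays, {k: list(v) for k, v in prov["split"].items()},
                            spec, prov["seed"])


__all__ = [
    "ClassTexture", "SyntheticSpec", "ArraySample", "SyntheticDataset",
    "default_textures", "generate_label_map", "render_array", "inject_noise",
    "generate_dataset", "write_dataset", "read_dataset", "split_sizes",
]
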