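"""Hexagonal convolution on offset-coordinate grids.

Spots on a hexagonal (Visium-style) array are stored in a rectangular
(row, col) raster where alternate rows are shifted half a spacing in x
("offset coordinates"). A hexagonal kernel of size ``k`` covers the center
spot plus ``k`` concentric hexagonal rings (ring ``r`` holds ``6*r`` spots),
so the raster offset of each kernel position depends on the parity of the
center row. Out-of-grid neighbors contribute zero (same padding, stride 1).
"""

from __future__ import annotations

import numpy as np

from .core import Layer, Param, _he_init

# axial (q, r) unit directions, counter-clockwise
_AXIAL_DIRS = [(1, -1), (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1)]


def axial_ring(radius: int) -> list[tuple[int, int]]:
    """Axial coordinates of the hexagonal ring at the given radius."""
    if radius == 0:
        return [(0, 0)]
    q, r = -radius, 0  # start at direction 4 scaled by radius
    out = []
    for d in range(6):
        dq, dr = _AXIAL_DIRS[d]
        for _ in range(radius):
            out.append((q, r))
            q, r = q + dq, r + dr
    return out


def hex_kernel_offsets(k: int, row_offset_parity: str) -> list[tuple[int, int, tuple[int, int]]]:
    """Raster offsets of a hex kernel with ``k`` rings.

    Returns a list of ``(ring, drow, (dcol_even_center, dcol_odd_center))``
    for every kernel position (center first). ``row_offset_parity`` states
    which rows of the grid are shifted +spacing/2 in x.
    """
    if row_offset_parity not in ("odd", "even"):
        raise ValueError(f"row_offset_parity must be 'odd' or 'even', got {row_offset_parity!r}")
    out = []
    for ring in range(k + 1):
        for dq, dr in axial_ring(ring):
            dcols = []
            for center_parity in (0, 1):
                # effective row parity under the grid's shift convention
                eff = center_parity if row_offset_parity == "odd" else 1 - center_parity
                dcols.append(dq + (eff + dr) // 2)  # floor division
            out.append((ring, dr, (dcols[0], dcols[1])))
    return out


def hex_neighbor_offsets(row: int, row_offset_parity: str) -> list[tuple[int, int]]:
    """(drow, dcol) raster offsets of the 6-neighborhood of a spot in ``row``."""
    parity = row % 2
    offs = []
    for ring, dr, dcols in hex_kernel_offsets(1, row_offset_parity):
        if ring == 1:
            offs.append((dr, dcols[parity]))
    return offs


def hex_conv(values: np.ndarray, ring_weights, row_offset_parity: str) -> np.ndarray:
    """Convolve a (H, W) or (H, W, C) hex-grid raster with per-ring weights.

    ``ring_weights[0]`` weights the center, ``ring_weights[r]`` every spot of
    ring ``r``; channels are treated independently. Same padding, stride 1.
    """
    v = np.asarray(values, dtype=np.float64)
    squeeze = v.ndim == 2
    if squeeze:
        v = v[:, :, None]
    h, w, _ = v.shape
    k = len(ring_weights) - 1
    out = np.zeros_like(v)
    for ring, dr, dcols in hex_kernel_offsets(k, row_offset_parity):
        wgt = ring_weights[ring]
        if wgt == 0:
            continue
        for parity in (0, 1):
            rows = np.arange(parity, h, 2)
            src_r = rows + dr
            ok = (src_r >= 0) & (src_r < h)
            rows, src_r = rows[ok], src_r[ok]
            if rows.size == 0:
                continue
            dc = dcols[parity]
            c0, c1 = max(0, -dc), min(w, w - dc)
            if c0 >= c1:
                continue
            out[np.ix_(rows, np.arange(c0, c1))] += wgt * v[np.ix_(src_r, np.arange(c0, c1) + dc)]
    return out[:, :, 0] if squeeze else out


class HexConv2d(Layer):
    """Hexagonal convolution layer, one weight per kernel position.

    Input/output are NCHW rasters over the hex grid; spatial size is
    preserved (stride 1, same padding). ``k`` counts concentric rings, so
    the kernel has ``1 + 3k(k+1)`` positions.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 row_offset_parity: str = "odd", bias: bool = True,
                 name: str = "hexconv") -> None:
        self.k = k
        self.row_offset_parity = row_offset_parity
        self.offsets = hex_kernel_offsets(k, row_offset_parity)
        n_pos = len(self.offsets)
        self.W = Param(_he_init((out_ch, in_ch, n_pos), in_ch * n_pos, rng), f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def out_channels(self) -> int:
        return self.W.value.shape[0]

    def n_weight_params(self) -> int:
        return self.W.value.size

    def _gather(self, x: np.ndarray, pos: int, parity: int):
        """Source block of ``x`` feeding rows of ``parity`` for kernel position ``pos``."""
        _, _, h, w = x.shape
        _, dr, dcols = self.offsets[pos]
        dc = dcols[parity]
        rows = np.arange(parity, h, 2)
        src_r = rows + dr
        ok = (src_r >= 0) & (src_r < h)
        rows, src_r = rows[ok], src_r[ok]
        c0, c1 = max(0, -dc), min(w, w - dc)
        if rows.size == 0 or c0 >= c1:
            return None
        cols = np.arange(c0, c1)
        return rows, cols, src_r, cols + dc

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.zeros((n, self.out_channels, h, w))
        for pos in range(len(self.offsets)):
            for parity in (0, 1):
                g = self._gather(x, pos, parity)
                if g is None:
                    continue
                rows, cols, src_r, src_c = g
                block = x[:, :, src_r[:, None], src_c[None, :]]
                out[:, :, rows[:, None], cols[None, :]] += np.einsum(
                    "oc,nchw->nohw", self.W.value[:, :, pos], block)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        self._x = x if cache else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called without a cached forward")
        dx = np.zeros_like(x)
        for pos in range(len(self.offsets)):
            for parity in (0, 1):
                g = self._gather(x, pos, parity)
                if g is None:
                    continue
                rows, cols, src_r, src_c = g
                dblock = dout[:, :, rows[:, None], cols[None, :]]
                xblock = x[:, :, src_r[:, None], src_c[None, :]]
                self.W.grad[:, :, pos] += np.einsum("nohw,nchw->oc", dblock, xblock)
                dx[:, :, src_r[:, None], src_c[None, :]] += np.einsum(
                    "oc,nohw->nchw", self.W.value[:, :, pos], dblock)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        return dx
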