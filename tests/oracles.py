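"""Brute-force reference implementations used only as test oracles.

Each oracle is written in the most literal style possible (explicit
padding, per-pixel loops, sorted windows, level-by-level flooding) and is
kept independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def median3x3_oracle(x: np.ndarray) -> np.ndarray:
    """Zero-pad, gather each 3x3 window, sort, take element index 4."""
    h, w = x.shape
    padded = np.zeros((h + 2, w + 2), dtype=float)
    padded[1 : h + 1, 1 : w + 1] = x
    out = np.empty_like(x, dtype=float)
    for r in range(h):
        for c in range(w):
            window = sorted(
                padded[r + dr, c + dc] for dr in (0, 1, 2) for dc in (0, 1, 2)
            )
            out[r, c] = window[4]
    return out


def gaussian3x3_kernel(sigma: float) -> np.ndarray:
    k = np.array(
        [
            [np.exp(-(dr * dr + dc * dc) / (2 * sigma * sigma)) for dc in (-1, 0, 1)]
            for dr in (-1, 0, 1)
        ]
    )
    return k / k.sum()


def gaussian3x3_oracle(x: np.ndarray, sigma: float) -> np.ndarray:
    """Sliding-window weighted sum with reflective (symmetric) borders."""
    k = gaussian3x3_kernel(sigma)
    padded = np.pad(x, 1, mode="symmetric")
    h, w = x.shape
    out = np.empty_like(x, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    acc += k[dr + 1, dc + 1] * padded[r + 1 + dr, c + 1 + dc]
            out[r, c] = acc
    return out


def _erode3x3(x: np.ndarray) -> np.ndarray:
    padded = np.pad(x, 1, mode="symmetric")
    h, w = x.shape
    return np.array(
        [
            [padded[r : r + 3, c : c + 3].min() for c in range(w)]
            for r in range(h)
        ]
    )


def _dilate3x3(x: np.ndarray) -> np.ndarray:
    padded = np.pad(x, 1, mode="symmetric")
    h, w = x.shape
    return np.array(
        [
            [padded[r : r + 3, c : c + 3].max() for c in range(w)]
            for r in range(h)
        ]
    )


def open_close_oracle(x: np.ndarray) -> np.ndarray:
    """Grayscale opening (erode, dilate) then closing (dilate, erode), 3x3 flat SE."""
    opened = _dilate3x3(_erode3x3(x))
    return _erode3x3(_dilate3x3(opened))


SOBEL_COL = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)  # d/dcol
SOBEL_ROW = SOBEL_COL.T  # d/drow


def sobel_oracle(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation with the two Sobel kernels, symmetric borders."""
    padded = np.pad(x, 1, mode="symmetric")
    h, w = x.shape
    gx = np.empty_like(x, dtype=float)
    gy = np.empty_like(x, dtype=float)
    for r in range(h):
        for c in range(w):
            win = padded[r : r + 3, c : c + 3]
            gx[r, c] = float((win * SOBEL_COL).sum())
            gy[r, c] = float((win * SOBEL_ROW).sum())
    return gx, gy, np.sqrt(gx * gx + gy * gy)


def flood_oracle(surface: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Literal level-by-level immersion flooding.

    Rules (identical, by design, to the library's documented tie-breaks):
    levels ascending; per level, seeds found by an exhaustive raster scan of
    the level's pixels for labelled neighbors, grown FIFO; one distinct
    neighboring basin -> join it, otherwise dam; leftover flat zones become
    new basins in raster order of discovery.
    """
    h, w = surface.shape
    offs = (
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        if connectivity == 8
        else [(-1, 0), (0, -1), (0, 1), (1, 0)]
    )

    def neighbors(r, c):
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    label: dict[tuple[int, int], object] = {}
    k = 0
    for lev in sorted(set(surface.ravel().tolist())):
        pix = [(r, c) for r in range(h) for c in range(w) if surface[r, c] == lev]
        for p in pix:
            label[p] = "M"
        fifo: list[tuple[int, int]] = []
        queued = set()
        for p in pix:
            if any(isinstance(label.get(q), int) for q in neighbors(*p)):
                fifo.append(p)
                queued.add(p)
        while fifo:
            p = fifo.pop(0)
            basins = set()
            for q in neighbors(*p):
                v = label.get(q)
                if isinstance(v, int) and v > 0:
                    basins.add(v)
            label[p] = basins.pop() if len(basins) == 1 else 0
            for q in neighbors(*p):
                if label.get(q) == "M" and q not in queued:
                    queued.add(q)
                    fifo.append(q)
        for p in pix:
            if label[p] == "M":
                k += 1
                label[p] = k
                grow = [p]
                while grow:
                    u = grow.pop(0)
                    for q in neighbors(*u):
                        if label.get(q) == "M":
                            label[q] = k
                            grow.append(q)

    out = np.zeros((h, w), dtype=int)
    for (r, c), v in label.items():
        out[r, c] = v
    return out, k


def extrema_oracle(dog: np.ndarray) -> set[tuple[int, int, int]]:
    """Exhaustive 26-neighbor scan over all strictly interior voxels."""
    ns, h, w = dog.shape
    found = set()
    for s in range(1, ns - 1):
        for r in range(1, h - 1):
            for c in range(1, w - 1):
                v = dog[s, r, c]
                nb = [
                    dog[s + ds, r + dr, c + dc]
                    for ds in (-1, 0, 1)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (ds, dr, dc) != (0, 0, 0)
                ]
                if all(v > n for n in nb) or all(v < n for n in nb):
                    found.add((s, r, c))
    return found


def scipy_gaussian_kernel1d(sigma: float) -> np.ndarray:
    """Discrete truncated Gaussian, radius int(4*sigma + 0.5), normalized."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * x * x / (sigma * sigma))
    return phi / phi.sum()
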