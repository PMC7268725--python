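"""Independent brute-force reference implementations.

Each oracle re-derives an operation from its definition using a
different computational route (explicit padding + window views or
breadth-first search) so that agreement with the library is a real
check, not the same code twice.
"""

from collections import deque

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BINOMIAL_1D = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def pyr_down_oracle(plane: np.ndarray, levels: int = 1) -> np.ndarray:
    """Replicate-pad, 5x5 binomial convolve pixel by pixel, take every 2nd."""
    out = plane.astype(np.float64)
    k = np.outer(BINOMIAL_1D, BINOMIAL_1D)
    for _ in range(levels):
        padded = np.pad(out, 2, mode="edge")
        h, w = out.shape
        conv = np.empty_like(out)
        for i in range(h):
            for j in range(w):
                conv[i, j] = (padded[i : i + 5, j : j + 5] * k).sum()
        out = conv[::2, ::2]
    return out


def adaptive_threshold_oracle(px: np.ndarray, blocksize: int) -> np.ndarray:
    """Window mean via padded sliding windows; strict > comparison."""
    pad = blocksize // 2
    padded = np.pad(px.astype(np.float64), pad, mode="edge")
    windows = sliding_window_view(padded, (blocksize, blocksize))
    means = windows.mean(axis=(-2, -1))
    return px > means


def local_maxima_oracle(px: np.ndarray, block: int) -> list[tuple[int, int]]:
    """Per-pixel block scan with the plateau-centroid rule."""
    h, w = px.shape
    half = block // 2
    cand = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            v = px[i, j]
            if v <= 0:
                continue
            r0, r1 = max(0, i - half), min(h, i + half + 1)
            c0, c1 = max(0, j - half), min(w, j + half + 1)
            blockvals = px[r0:r1, c0:c1]
            if v >= blockvals.max() and blockvals.min() < v:
                cand[i, j] = True
    # group equal-valued 8-connected plateaus, keep member nearest centroid
    seen = np.zeros_like(cand)
    points = []
    for i in range(h):
        for j in range(w):
            if not cand[i, j] or seen[i, j]:
                continue
            group = []
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                a, b = queue.popleft()
                group.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        u, v2 = a + da, b + db
                        if (
                            0 <= u < h
                            and 0 <= v2 < w
                            and cand[u, v2]
                            and not seen[u, v2]
                        ):
                            seen[u, v2] = True
                            queue.append((u, v2))
            cr = sum(g[0] for g in group) / len(group)
            cc = sum(g[1] for g in group) / len(group)
            best = min(group, key=lambda g: ((g[0] - cr) ** 2 + (g[1] - cc) ** 2, g))
            points.append(best)
    return sorted(points)


def fill_holes_oracle(fg: np.ndarray) -> np.ndarray:
    """Flood the 4-connected background from the border; the rest is filled."""
    h, w = fg.shape
    reach = np.zeros((h, w), dtype=bool)
    queue = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not fg[i, j] and not reach[i, j]:
                reach[i, j] = True
                queue.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not fg[i, j] and not reach[i, j]:
                reach[i, j] = True
                queue.append((i, j))
    while queue:
        a, b = queue.popleft()
        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            u, v = a + da, b + db
            if 0 <= u < h and 0 <= v < w and not fg[u, v] and not reach[u, v]:
                reach[u, v] = True
                queue.append((u, v))
    return fg | ~reach


def components_oracle(fg: np.ndarray):
    """8-connected foreground components via BFS."""
    h, w = fg.shape
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if not fg[i, j] or seen[i, j]:
                continue
            comp = []
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                a, b = queue.popleft()
                comp.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        u, v = a + da, b + db
                        if 0 <= u < h and 0 <= v < w and fg[u, v] and not seen[u, v]:
                            seen[u, v] = True
                            queue.append((u, v))
            comps.append(comp)
    return comps


def remove_small_oracle(fg: np.ndarray, min_area: int) -> np.ndarray:
    out = np.zeros_like(fg)
    for comp in components_oracle(fg):
        if len(comp) >= min_area:
            for a, b in comp:
                out[a, b] = True
    return out


def otsu_best_variance(values: np.ndarray) -> float:
    """Max between-class variance over all integer thresholds."""
    best = -1.0
    vals = values.astype(np.float64)
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        wl = lo.size / vals.size
        wh = hi.size / vals.size
        var = wl * wh * (lo.mean() - hi.mean()) ** 2
        best = max(best, var)
    return best


def between_class_variance(values: np.ndarray, split: np.ndarray) -> float:
    vals = values.astype(np.float64)
    lo = vals[~split]
    hi = vals[split]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    wl = lo.size / vals.size
    wh = hi.size / vals.size
    return wl * wh * (lo.mean() - hi.mean()) ** 2


def mean_shift_oracle(img: np.ndarray, sp: int, sr: float, max_iters: int, eps: float):
    """Direct per-pixel joint-domain mode seeking (pure python)."""
    h, w, _ = img.shape
    img = img.astype(np.float64)
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            x, y = float(i), float(j)
            c = img[i, j].copy()
            for _ in range(max_iters):
                r0, r1 = max(0, int(round(x)) - sp), min(h - 1, int(round(x)) + sp)
                q0, q1 = max(0, int(round(y)) - sp), min(w - 1, int(round(y)) + sp)
                acc_pos = np.zeros(2)
                acc_col = np.zeros(3)
                n = 0
                for u in range(r0, r1 + 1):
                    for v in range(q0, q1 + 1):
                        d = img[u, v] - c
                        if (d * d).sum() <= sr * sr:
                            acc_pos += (u, v)
                            acc_col += img[u, v]
                            n += 1
                if n == 0:
                    break
                nx, ny = acc_pos / n
                nc = acc_col / n
                move = abs(nx - x) + abs(ny - y)
                cmove = np.abs(nc - c).max()
                x, y, c = nx, ny, nc
                if move + cmove < eps:
                    break
            out[i, j] = c
    return out
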