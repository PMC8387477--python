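"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain per-voxel loops, deliberately sharing no
code with the package's vectorized builders.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = ((1, 0), (0, 1), (1, 1), (1, -1))


def brute_glcm(levels: np.ndarray, directions=DIRECTIONS, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts by looping over every ordered voxel pair."""
    ng = int(levels.max())
    counts = np.zeros((ng, ng), dtype=np.int64)
    nx, ny, nz = levels.shape
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for dx, dy in directions:
                    xx, yy = x + dx * distance, y + dy * distance
                    if 0 <= xx < nx and 0 <= yy < ny:
                        b = levels[xx, yy, z]
                        if b != 0:
                            counts[a - 1, b - 1] += 1
                            counts[b - 1, a - 1] += 1
    return counts


def brute_runs(levels: np.ndarray, directions=DIRECTIONS) -> dict[tuple[int, int], int]:
    """(level, length) -> count of maximal runs, per slice per direction."""
    runs: dict[tuple[int, int], int] = {}
    nx, ny, nz = levels.shape

    def at(x, y, z):
        if 0 <= x < nx and 0 <= y < ny:
            return levels[x, y, z]
        return 0

    for z in range(nz):
        for dx, dy in directions:
            for x in range(nx):
                for y in range(ny):
                    v = levels[x, y, z]
                    if v == 0:
                        continue
                    if at(x - dx, y - dy, z) == v:
                        continue  # not the start of a run
                    length = 1
                    while at(x + length * dx, y + length * dy, z) == v:
                        length += 1
                    key = (int(v), length)
                    runs[key] = runs.get(key, 0) + 1
    return runs


def brute_zones(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """(level, size) -> count of in-plane 8-connected equal-level zones."""
    zones: dict[tuple[int, int], int] = {}
    nx, ny, nz = levels.shape
    for z in range(nz):
        seen = np.zeros((nx, ny), dtype=bool)
        for x in range(nx):
            for y in range(ny):
                v = levels[x, y, z]
                if v == 0 or seen[x, y]:
                    continue
                stack = [(x, y)]
                seen[x, y] = True
                size = 0
                while stack:
                    cx, cy = stack.pop()
                    size += 1
                    for ddx in (-1, 0, 1):
                        for ddy in (-1, 0, 1):
                            if ddx == ddy == 0:
                                continue
                            px, py = cx + ddx, cy + ddy
                            if 0 <= px < nx and 0 <= py < ny and not seen[px, py] and levels[px, py, z] == v:
                                seen[px, py] = True
                                stack.append((px, py))
                key = (int(v), size)
                zones[key] = zones.get(key, 0) + 1
    return zones


def brute_ngtdm(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) over in-mask voxels with >= 1 in-mask in-plane 8-neighbour."""
    ng = int(levels.max())
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng, dtype=np.float64)
    nx, ny, nz = levels.shape
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                v = levels[x, y, z]
                if v == 0:
                    continue
                neigh = []
                for ddx in (-1, 0, 1):
                    for ddy in (-1, 0, 1):
                        if ddx == ddy == 0:
                            continue
                        px, py = x + ddx, y + ddy
                        if 0 <= px < nx and 0 <= py < ny and levels[px, py, z] != 0:
                            neigh.append(levels[px, py, z])
                if not neigh:
                    continue
                n[v - 1] += 1
                s[v - 1] += abs(v - sum(neigh) / len(neigh))
    return n, s


def naive_ccc(x, y) -> float:
    """Lin's coefficient straight from the published formula, no shortcuts."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def mcnemar_exact_enumeration(b: int, c: int) -> float:
    """Two-sided exact McNemar p by full enumeration of Bin(b+c, 1/2)."""
    from math import comb

    n = b + c
    k = max(b, c)
    tail = sum(comb(n, j) for j in range(k, n + 1)) / 2**n
    return min(1.0, 2.0 * tail)


def haar_subbands_2d(img: np.ndarray) -> dict[str, np.ndarray]:
    """Direct double-loop undecimated Haar subbands of one 2D slice.

    Tap convention: out[n] = sum_k w[k] * x[n+k], symmetric reflection at
    the edges; level-2 filters have one zero inserted between taps.
    """
    r = np.sqrt(2.0)
    lo1, hi1 = [1 / r, 1 / r], [1 / r, -1 / r]
    lo2, hi2 = [1 / r, 0.0, 1 / r], [1 / r, 0.0, -1 / r]

    def filt_axis(data, w, axis):
        n = data.shape[axis]

        def ref(i):
            while i < 0 or i >= n:
                i = -1 - i if i < 0 else 2 * n - 1 - i
            return i

        out = np.zeros_like(data, dtype=float)
        for idx in np.ndindex(data.shape):
            acc = 0.0
            for k, wk in enumerate(w):
                j = list(idx)
                j[axis] = ref(idx[axis] + k)
                acc += wk * data[tuple(j)]
            out[idx] = acc
        return out

    def filt2(data, wx, wy):
        return filt_axis(filt_axis(data, wx, 0), wy, 1)

    out = {
        "LL": filt2(img, lo1, lo1),
        "LH": filt2(img, lo1, hi1),
        "HL": filt2(img, hi1, lo1),
        "HH": filt2(img, hi1, hi1),
    }
    ll = out["LL"]
    out["LL2"] = filt2(ll, lo2, lo2)
    out["LH2"] = filt2(ll, lo2, hi2)
    out["HL2"] = filt2(ll, hi2, lo2)
    out["HH2"] = filt2(ll, hi2, hi2)
    return out


def random_discrete_roi(rng: np.random.Generator, shape=(6, 6, 2), ng: int = 4):
    """A random small discretized ROI (levels grid with holes) for oracle tests."""
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.75
    if not mask.any():
        mask[tuple(d // 2 for d in shape)] = True
    levels[~mask] = 0
    return levels, mask.astype(np.uint8)
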