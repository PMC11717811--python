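"""Independent brute-force per-pixel implementations used as test oracles.

Deliberately naive: explicit loops over pixels and structuring-element
offsets, no shared code with the package under test.
"""

import math

import numpy as np


def disk_offsets(radius):
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def square_offsets(radius):
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
    ]


def brute_dilation(binary, offsets):
    h, w = binary.shape
    out = np.zeros_like(binary, dtype=bool)
    for y in range(h):
        for x in range(w):
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                # out-of-bounds neighbors contribute background (False)
                if 0 <= yy < h and 0 <= xx < w and binary[yy, xx]:
                    out[y, x] = True
                    break
    return out


def brute_erosion(binary, offsets):
    h, w = binary.shape
    out = np.ones_like(binary, dtype=bool)
    for y in range(h):
        for x in range(w):
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                # out-of-bounds neighbors count as foreground (max padding)
                if 0 <= yy < h and 0 <= xx < w and not binary[yy, xx]:
                    out[y, x] = False
                    break
    return out


def brute_donut(grid, r_in, r_out, footprint="disk"):
    """Per-label ring = dilation(r_out) minus erosion(r_in); overlap goes to
    the label with the nearest cell pixel, ties to the smaller label."""
    make = disk_offsets if footprint == "disk" else square_offsets
    off_out = make(r_out)
    off_in = make(r_in)
    labels = sorted(int(v) for v in np.unique(grid) if v > 0)
    rings = {}
    for lab in labels:
        cell = grid == lab
        dil = brute_dilation(cell, off_out) if r_out > 0 else cell
        ero = brute_erosion(cell, off_in) if r_in > 0 else cell
        rings[lab] = dil & ~ero
    cell_pixels = {lab: np.argwhere(grid == lab) for lab in labels}
    out = np.zeros_like(grid)
    h, w = grid.shape
    for y in range(h):
        for x in range(w):
            claimants = [lab for lab in labels if rings[lab][y, x]]
            if not claimants:
                continue
            if len(claimants) == 1:
                out[y, x] = claimants[0]
                continue
            best_lab, best_d = None, None
            for lab in claimants:
                d = min(
                    math.hypot(y - py, x - px) for py, px in cell_pixels[lab]
                )
                if best_d is None or d < best_d - 1e-12:
                    best_lab, best_d = lab, d
            out[y, x] = best_lab
    return out


def brute_overlap_fractions(grid, marker):
    fractions = {}
    for lab in np.unique(grid):
        if lab == 0:
            continue
        area = 0
        hit = 0
        h, w = grid.shape
        for y in range(h):
            for x in range(w):
                if grid[y, x] == lab:
                    area += 1
                    if marker[y, x]:
                        hit += 1
        fractions[int(lab)] = hit / area
    return fractions


def brute_components(binary):
    """8-connected components by explicit flood fill."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    for y in range(h):
        for x in range(w):
            if not binary[y, x] or seen[y, x]:
                continue
            stack = [(y, x)]
            seen[y, x] = True
            pixels = []
            while stack:
                cy, cx = stack.pop()
                pixels.append((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = cy + dy, cx + dx
                        if 0 <= yy < h and 0 <= xx < w and binary[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            components.append(pixels)
    return components


def brute_count_migrated(binary, center_um, radius_um, cortex_mask, min_area, pixel_size):
    n_outside = n_cortex = 0
    for pixels in brute_components(binary):
        if len(pixels) < min_area:
            continue
        cy = sum(p[0] for p in pixels) / len(pixels)
        cx = sum(p[1] for p in pixels) / len(pixels)
        x_um, y_um = cx * pixel_size, cy * pixel_size
        if radius_um > 0 and math.hypot(x_um - center_um[0], y_um - center_um[1]) <= radius_um:
            continue
        n_outside += 1
        if cortex_mask is not None and cortex_mask[round(cy), round(cx)]:
            n_cortex += 1
    return n_outside, n_cortex


def wilcoxon_exact_p(x, y):
    """Exact two-sided rank-sum p by enumeration of all group assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks = {}
    for v, r in zip(sorted(pooled), range(1, len(pooled) + 1)):
        ranks.setdefault(v, []).append(r)
    # average ranks for ties
    rank_of = {v: sum(rs) / len(rs) for v, rs in ranks.items()}
    observed = sum(rank_of[v] for v in x)
    stats = []
    idx = list(range(len(pooled)))
    for combo in combinations(idx, n):
        stats.append(sum(rank_of[pooled[i]] for i in combo))
    stats = np.asarray(stats)
    mean = stats.mean()
    extreme = np.sum(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(stats)
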