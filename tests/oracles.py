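"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (python loops, explicit sorting, BFS,
radial sweeps) and shares no code with the package beyond the stated
conventions: replicate borders for median filters, 8-connectivity for
components, boundary polygons through outermost pixel centres.
"""

from __future__ import annotations

import math

import numpy as np


def brute_median(img: np.ndarray, kernel: int) -> np.ndarray:
    """Per-pixel median of the kernel x kernel replicate-padded neighbourhood."""
    h, w = img.shape
    half = kernel // 2
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    vals.append(img[rr, cc])
            vals.sort()
            out[r, c] = vals[len(vals) // 2]
    return out


def flood_components(binary: np.ndarray, min_pixels: int = 1) -> list[frozenset]:
    """8-connected components by breadth-first flood fill; sets of (x, y)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if not binary[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            pixels = []
            while stack:
                rr, cc = stack.pop()
                pixels.append((cc, rr))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            if len(pixels) >= min_pixels:
                comps.append(frozenset(pixels))
    return comps


def radial_sweep_boundary(pixel_coords) -> list[tuple[int, int]]:
    """Outer boundary by the radial-sweep method (clockwise, screen coords).

    From the current boundary pixel, a ray anchored at the previous boundary
    pixel sweeps clockwise until it hits a foreground neighbour.  Starts at
    the topmost-then-leftmost pixel with a virtual previous pixel to its
    west; stops on repeating the initial (pixel, previous) pair.
    """
    pixels = set((int(x), int(y)) for x, y in pixel_coords)
    start = min(pixels, key=lambda p: (p[1], p[0]))
    if len(pixels) == 1:
        return [start]

    def sweep(p, prev):
        # angle of prev around p, screen-clockwise; scan neighbours in
        # increasing clockwise angle strictly after prev's direction
        base = math.atan2(prev[1] - p[1], prev[0] - p[0])
        best = None
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                q = (p[0] + dx, p[1] + dy)
                if q not in pixels:
                    continue
                ang = (math.atan2(dy, dx) - base) % (2 * math.pi)
                if ang == 0.0:
                    ang = 2 * math.pi
                if best is None or ang < best[0]:
                    best = (ang, q)
        return None if best is None else best[1]

    prev = (start[0] - 1, start[1])
    boundary = [start]
    nxt = sweep(start, prev)
    if nxt is None:
        return [start]
    first = (nxt, start)
    p, q = nxt, start  # current, previous
    for _ in range(16 * len(pixels) + 16):
        boundary.append(p)
        nxt = sweep(p, q)
        p, q = nxt, p
        if (p, q) == first:
            break
    else:
        raise RuntimeError("radial sweep failed to close")
    return boundary


def polygon_area_perimeter(vertices) -> tuple[float, float]:
    """Shoelace area and arc length of the closed polygon through vertices."""
    if len(vertices) < 2:
        return 0.0, 0.0
    area2 = 0.0
    per = 0.0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        area2 += x0 * y1 - x1 * y0
        per += math.hypot(x1 - x0, y1 - y0)
    return abs(area2) / 2.0, per


def moving_average_naive(counts, window: int) -> np.ndarray:
    """Truncated centred moving average by explicit slicing."""
    counts = np.asarray(counts, dtype=float)
    half = window // 2
    out = np.empty_like(counts)
    for i in range(counts.size):
        lo = max(i - half, 0)
        hi = min(i + half, counts.size - 1)
        out[i] = counts[lo : hi + 1].mean()
    return out


def nearest_rank_naive(values, percentile: float):
    """ceil(p/100 * n)-th smallest value, by explicit sort."""
    vals = sorted(values)
    rank = math.ceil(percentile / 100.0 * len(vals))
    return vals[min(max(rank, 1), len(vals)) - 1]
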