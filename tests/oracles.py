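"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the library
calls) they are checking: flood fill by breadth-first search, per-pixel max
by explicit loops, tail probabilities by numerical quadrature of closed-form
densities.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.integrate import quad

OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
OFFSETS_8 = OFFSETS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels by BFS flood fill, labels in scan order."""
    offsets = OFFSETS_4 if connectivity == 4 else OFFSETS_8
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels


def partitions_equal(lab_a: np.ndarray, lab_b: np.ndarray) -> bool:
    """True when two labelings induce the same partition of foreground."""
    if not np.array_equal(lab_a > 0, lab_b > 0):
        return False
    pairs = set(zip(lab_a[lab_a > 0].ravel(), lab_b[lab_a > 0].ravel()))
    a_to_b = {}
    b_to_a = {}
    for a, b in pairs:
        if a_to_b.setdefault(a, b) != b or b_to_a.setdefault(b, a) != a:
            return False
    return True


def mip_loop(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across slices by explicit loops."""
    n, h, w = stack.shape
    out = stack[0].copy()
    for k in range(1, n):
        for i in range(h):
            for j in range(w):
                if stack[k, i, j] > out[i, j]:
                    out[i, j] = stack[k, i, j]
    return out


def t_sf_quadrature(t: float, df: float) -> float:
    """P(T >= t) for Student's t by quadrature of the closed-form density."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x: float) -> float:
        return const * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = quad(pdf, t, np.inf)
    return val


def normal_two_tail_quadrature(z: float) -> float:
    """2 * P(Z >= z) for a standard normal by quadrature of its density."""

    def pdf(x: float) -> float:
        return math.exp(-x * x / 2) / math.sqrt(2 * math.pi)

    val, _ = quad(pdf, abs(z), np.inf)
    return 2 * val
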