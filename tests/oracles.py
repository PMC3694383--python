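"""Independent brute-force oracles: plain nested loops, no shared code with
the library's vectorized implementations."""

import math

import numpy as np


def ring_points(d):
    """All (dr, dc) with max(|dr|, |dc|) == d, by exhaustive enumeration."""
    pts = []
    for dr in range(-d, d + 1):
        for dc in range(-d, d + 1):
            if max(abs(dr), abs(dc)) == d:
                pts.append((dr, dc))
    return pts


def brute_cooccurrence(pixels, levels, r0, c0, na, nb, d):
    """Pair counting with explicit per-center per-offset loops."""
    H, W = pixels.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(r0, r0 + na):
        for c in range(c0, c0 + nb):
            for dr, dc in ring_points(d):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    counts[pixels[r, c], pixels[rr, cc]] += 1
    return counts


def brute_marginals(p):
    L = p.shape[0]
    mu_x = sum(i * p[i, j] for i in range(L) for j in range(L))
    mu_y = sum(j * p[i, j] for i in range(L) for j in range(L))
    var_x = sum((i - mu_x) ** 2 * p[i, j] for i in range(L) for j in range(L))
    var_y = sum((j - mu_y) ** 2 * p[i, j] for i in range(L) for j in range(L))
    return mu_x, mu_y, math.sqrt(var_x), math.sqrt(var_y)


def brute_p_diff(p, q=1):
    L = p.shape[0]
    out = np.zeros(L)
    for i in range(L):
        for j in range(L):
            if p[i, j] > 0:
                out[abs(i - j)] += p[i, j] ** q
    return out


def brute_operator(name, params, p, variant="as_printed"):
    """Dense double-loop evaluation of any second-order operator."""
    L = p.shape[0]
    if name == "HG":
        return sum(p[i, j] ** params["n3"] for i in range(L) for j in range(L))
    if name == "CT":
        return sum(abs(i - j) ** params["n4"] * p[i, j] ** params["n5"]
                   for i in range(L) for j in range(L))
    if name == "ID":
        return sum(p[i, j] ** params["n6"] / (1 + abs(i - j) ** params["n7"])
                   for i in range(L) for j in range(L))
    if name == "ET":
        total = 0.0
        for i in range(L):
            for j in range(L):
                if p[i, j] > 0:
                    total += p[i, j] ** params["n8"] * \
                        (math.log(p[i, j], params["k1"])) ** params["n9"]
        return -total
    if name == "CR":
        mu_x, mu_y, sx, sy = brute_marginals(p)
        if sx * sy == 0:
            return 0.0
        total = 0.0
        for i in range(L):
            for j in range(L):
                second = (i - mu_y) if variant == "as_printed" else (j - mu_y)
                total += (i - mu_x) * second * p[i, j] ** params["n10"]
        return total / (sx * sy) ** params["n11"]
    if name == "DE":
        pd = brute_p_diff(p, params.get("q", 1))
        total = 0.0
        for k in range(L):
            if pd[k] > 0:
                total += pd[k] ** params["n12"] * \
                    (math.log(pd[k], params["k2"])) ** params["n13"]
        return -total
    raise ValueError(name)


def brute_histogram_moment(block, levels, n1):
    counts = [0] * levels
    for v in block.ravel():
        counts[int(v)] += 1
    n = block.size
    return sum(i ** n1 * counts[i] / n for i in range(levels))


def brute_central_moment(block, levels, n2):
    m1 = brute_histogram_moment(block, levels, 1)
    counts = [0] * levels
    for v in block.ravel():
        counts[int(v)] += 1
    n = block.size
    return sum((i - m1) ** n2 * counts[i] / n for i in range(levels))
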