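"""Independent brute-force oracles used by the tests.

These deliberately re-derive every quantity from first principles (explicit
pair enumeration, dictionary co-occurrence tables, plain loops) so they share
no code path with the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def quantize_minmax(values, levels):
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax <= vmin:
        return np.zeros(values.shape, dtype=int)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(int)
    return np.minimum(q, levels - 1)


def cooccurrence_pairs(q, valid, offset):
    """Enumerate symmetric co-occurring level pairs one by one."""
    dr, dc = offset
    H, W = q.shape
    pairs = []
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and valid[r, c] and valid[r2, c2]:
                pairs.append((q[r, c], q[r2, c2]))
                pairs.append((q[r2, c2], q[r, c]))
    return pairs


def glcm_stats_oracle(pairs, levels):
    """The 19 co-occurrence statistics from an explicit pair list.

    Returns them keyed by name; levels are re-indexed 1..L as in the
    textbook definitions, logs are base 2.
    """
    if not pairs:
        pairs = [(0, 0)]
    counts = Counter(pairs)
    total = sum(counts.values())
    p = {(i + 1, j + 1): v / total for (i, j), v in counts.items()}
    L = levels

    px = {}
    for (i, j), v in p.items():
        px[i] = px.get(i, 0.0) + v
    mu = sum(i * v for i, v in px.items())
    var = sum((i - mu) ** 2 * v for i, v in px.items())

    energy = sum(v * v for v in p.values())
    contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
    autocorr = sum(i * j * v for (i, j), v in p.items())
    corr = (autocorr - mu * mu) / var if var > 1e-15 else 0.0
    idmn = sum(v / (1 + (i - j) ** 2 / L ** 2) for (i, j), v in p.items())
    homog = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    dissim = sum(abs(i - j) * v for (i, j), v in p.items())

    psum = {}
    pdiff = {}
    for (i, j), v in p.items():
        psum[i + j] = psum.get(i + j, 0.0) + v
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + v
    sum_avg = sum(k * v for k, v in psum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in psum.items())
    entropy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    sum_ent = -sum(v * math.log2(v) for v in psum.values() if v > 0)
    diff_ent = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)
    mu_d = sum(k * v for k, v in pdiff.items())
    diff_var = sum((k - mu_d) ** 2 * v for k, v in pdiff.items())

    hx = -sum(v * math.log2(v) for v in px.values() if v > 0)
    hxy1 = -sum(v * math.log2(px[i] * px[j]) for (i, j), v in p.items()
                if px[i] * px[j] > 0 and v > 0)
    imc1 = (entropy - hxy1) / hx if hx > 1e-15 else 0.0

    shade = sum((i + j - 2 * mu) ** 3 * v for (i, j), v in p.items())
    prom = sum((i + j - 2 * mu) ** 4 * v for (i, j), v in p.items())
    max_prob = max(p.values())
    norm_ent = entropy / math.log2(L * L)

    return {
        "energy": energy, "contrast": contrast, "correlation": corr,
        "variance": var, "idmn": idmn, "sum_average": sum_avg,
        "sum_variance": sum_var, "entropy": entropy, "sum_entropy": sum_ent,
        "difference_entropy": diff_ent, "imc1": imc1, "homogeneity": homog,
        "autocorrelation": autocorr, "difference_variance": diff_var,
        "dissimilarity": dissim, "cluster_shade": shade,
        "cluster_prominence": prom, "max_probability": max_prob,
        "normalized_entropy": norm_ent,
    }


def kl_distinctiveness_oracle(mu_i, cov_i, mu_j, cov_j, u):
    """Term-by-term evaluation of the atom-pair distinctiveness statistic."""
    term_logdet = math.log(np.linalg.det(cov_j) / np.linalg.det(cov_i))
    term_trace = float(np.trace(np.linalg.inv(cov_j) @ cov_i))
    d = np.asarray(mu_j) - np.asarray(mu_i)
    term_maha = float(d @ np.linalg.inv(cov_j) @ d) / 2.0
    return term_logdet - u + term_trace + term_maha


def flood_fill_components(mask):
    """8-connected components by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    H, W = mask.shape
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                comp = set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < H and 0 <= cc < W and mask[rr, cc]
                                    and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps
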