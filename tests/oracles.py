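"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive — explicit loops and enumerations —
and shares no code with the package internals it checks.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np


def quantize_loop(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantisation via an explicit per-element loop."""
    flat = np.asarray(values, dtype=float)
    lo, hi = flat.min(), flat.max()
    out = np.zeros(flat.shape, dtype=int)
    if hi == lo:
        return out
    it = np.nditer(flat, flags=["multi_index"])
    for v in it:
        k = int((float(v) - lo) / (hi - lo) * n_levels)
        out[it.multi_index] = min(k, n_levels - 1)
    return out


def glcm_brute(
    data: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    offsets,
    distance: int = 1,
    symmetric: bool = True,
) -> np.ndarray:
    """Co-occurrence by explicit pair enumeration over every voxel."""
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask) > 0
    codes = np.zeros(data.shape, dtype=int)
    codes[mask] = quantize_loop(data[mask], n_levels)
    acc = np.zeros((n_levels, n_levels))
    n_dirs = 0
    shape = data.shape
    for off in offsets:
        off = tuple(distance * o for o in off)
        counts = np.zeros((n_levels, n_levels))
        for z, y, x in product(*[range(s) for s in shape]):
            z2, y2, x2 = z + off[0], y + off[1], x + off[2]
            if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]):
                continue
            if mask[z, y, x] and mask[z2, y2, x2]:
                a, b = codes[z, y, x], codes[z2, y2, x2]
                counts[a, b] += 1
                if symmetric:
                    counts[b, a] += 1
        if counts.sum() > 0:
            acc += counts / counts.sum()
            n_dirs += 1
    if n_dirs == 0:
        raise ValueError("no valid pairs")
    return acc / n_dirs


def haralick_brute(P: np.ndarray) -> dict[str, float]:
    """Haralick statistics by explicit double loops over matrix cells."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    contrast = dissim = homog = asm = ent = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            mu_i += (i + 1) * p
            mu_j += (j + 1) * p
    var_i = var_j = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            var_i += (i + 1 - mu_i) ** 2 * p
            var_j += (j + 1 - mu_j) ** 2 * p
    corr_num = 0.0
    sum_avg = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            d = i - j
            contrast += d * d * p
            dissim += abs(d) * p
            homog += p / (1 + d * d)
            asm += p * p
            if p > 0:
                ent -= p * np.log(p)
            corr_num += (i + 1 - mu_i) * (j + 1 - mu_j) * p
            sum_avg += (i + 1 + j + 1) * p
    sig = np.sqrt(var_i * var_j)
    corr = 1.0 if sig == 0 else corr_num / sig
    return {
        "Contrast": contrast,
        "Dissimilarity": dissim,
        "Homogeneity": homog,
        "ASM": asm,
        "GLCMEntropy": ent,
        "Correlation": corr,
        "SumAverage": sum_avg,
    }


def soft_threshold(beta_ols: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form lasso solution on an orthonormal design (linear response)."""
    return np.sign(beta_ols) * np.maximum(np.abs(beta_ols) - lam, 0.0)


def mcnemar_exact_enumeration(b: int, c: int) -> float:
    """Two-sided exact McNemar p by enumerating all 2^(b+c) discordance
    assignments under the null (each discordant pair favours either side
    with probability 1/2)."""
    n = b + c
    if n == 0:
        return 1.0
    observed = max(b, c)
    hits = 0
    for bits in range(2**n):
        k = bin(bits).count("1")  # pairs favouring the model
        if max(k, n - k) >= observed:
            hits += 1
    return min(1.0, hits / 2**n)
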