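"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths (and scipy.stats.rankdata)
so that agreement is a two-route check: midranks come from pairwise counting,
Spearman from Pearson on counted midranks, and scores from per-sample loops.
"""

from __future__ import annotations

import numpy as np


def midrank_oracle(column: np.ndarray) -> np.ndarray:
    """Midrank by counting: rank_i = #{j: v_j < v_i} + (#{j: v_j == v_i} + 1)/2."""
    v = np.asarray(column, dtype=float)
    less = (v[None, :] < v[:, None]).sum(axis=1)
    equal = (v[None, :] == v[:, None]).sum(axis=1)
    return less + (equal + 1) / 2.0


def rank_matrix_oracle(values: np.ndarray) -> np.ndarray:
    return np.column_stack([midrank_oracle(values[:, j]) for j in range(values.shape[1])])


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = midrank_oracle(np.asarray(x)), midrank_oracle(np.asarray(y))
    return float(np.corrcoef(rx, ry)[0, 1])


def extend_score_oracle(
    values: np.ndarray,
    gene_ids: list[str],
    constituent: tuple[str, str],
    markers: list[str],
    delta_bounds: tuple[float, float] = (0.5, 20.0),
) -> dict:
    """Loop-based reimplementation of the two-component rank-sum score.

    Mirrors the scoring contract (detected-constituent rule, delta clamp,
    min-max scaling) but shares no code with the package.
    """
    n_g, n_s = values.shape
    idx = {g: i for i, g in enumerate(gene_ids)}
    const_present = [
        g for g in constituent if g in idx and any(values[idx[g], j] > 0 for j in range(n_s))
    ]
    markers_present = [g for g in markers if g in idx]

    ranks = rank_matrix_oracle(values)
    v_const = np.zeros(n_s)
    v_marker = np.zeros(n_s)
    for j in range(n_s):
        if const_present:
            v_const[j] = max(ranks[idx[g], j] for g in const_present)
        v_marker[j] = sum(ranks[idx[g], j] for g in markers_present)

    if const_present and n_s >= 3 and np.ptp(v_const) > 0 and np.ptp(v_marker) > 0:
        rho = spearman_oracle(v_const, v_marker)
        delta = delta_bounds[1] if rho >= 1 else 1.0 / (1.0 - rho)
        delta = min(max(delta, delta_bounds[0]), delta_bounds[1])
    else:
        delta = 1.0

    n_m = len(const_present) + len(markers_present)
    raw = (delta * v_const + v_marker) / (n_g * n_m)
    if n_s == 1:
        scaled = raw.copy()
    elif np.ptp(raw) == 0:
        scaled = np.full_like(raw, 0.5)
    else:
        scaled = (raw - raw.min()) / (raw.max() - raw.min())
    return {
        "raw": raw,
        "scaled": scaled,
        "delta": delta,
        "v_const": v_const,
        "v_marker": v_marker,
        "n_m": n_m,
    }
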