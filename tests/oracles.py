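"""Independent reference implementations used only to verify the package.

Everything here is deliberately written as plain loops / brute force, with
no code shared with the package internals.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def rank_weight_scores(gene_ids, values, sets):
    """Loop-level transcription of the scoring transformation.

    For each sample: rank genes so that the highest-expressed gene gets
    rank ``|G|`` (ties averaged), weight each gene ``r * exp(-r/|G|)``,
    score each set as mean member weight minus mean non-member weight,
    then subtract the per-sample minimum raw score.

    Returns (raw, rescaled) dicts: ``{set_id: [score per sample]}``.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    raw = {sid: [] for sid in sets}
    for s in range(n_samples):
        col = values[:, s]
        weights = {}
        for gi, g in enumerate(gene_ids):
            less = sum(1 for v in col if v < col[gi])
            equal = sum(1 for v in col if v == col[gi])
            r = less + (equal + 1) / 2.0
            weights[g] = r * math.exp(-r / n_genes)
        for sid, members in sets.items():
            inside = [weights[g] for g in gene_ids if g in members]
            outside = [weights[g] for g in gene_ids if g not in members]
            raw[sid].append(
                sum(inside) / len(inside) - sum(outside) / len(outside)
            )
    rescaled = {}
    for s in range(n_samples):
        m = min(raw[sid][s] for sid in sets)
        for sid in sets:
            rescaled.setdefault(sid, []).append(raw[sid][s] - m)
    return raw, rescaled


def hypergeom_tail_by_enumeration(n_overlap, size_a, size_b, universe_size):
    """P(|A & B| >= n_overlap) by enumerating every draw of B."""
    universe = list(range(universe_size))
    set_a = set(universe[:size_a])
    hits = total = 0
    for draw in combinations(universe, size_b):
        total += 1
        if len(set_a & set(draw)) >= n_overlap:
            hits += 1
    return hits / total


def bh_step_up(p_values):
    """Literal Benjamini-Hochberg step-up, written independently."""
    p = list(p_values)
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_pos in range(m, 0, -1):
        i = indexed[rank_pos - 1]
        val = min(prev, p[i] * m / rank_pos)
        q[i] = min(val, 1.0)
        prev = val
    return q


def pam2_brute_force(dist):
    """Best 2-medoid configuration by exhaustive search; returns
    (best_cost, set of optimal medoid pairs)."""
    n = dist.shape[0]
    best = math.inf
    argbest = set()
    for i, j in combinations(range(n), 2):
        cost = sum(min(dist[k, i], dist[k, j]) for k in range(n))
        if cost < best - 1e-12:
            best, argbest = cost, {(i, j)}
        elif abs(cost - best) <= 1e-12:
            argbest.add((i, j))
    return best, argbest
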