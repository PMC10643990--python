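"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
likelihoods by exhaustive enumeration over ancestral states, MAD scores by
dense grid search from raw distance matrices, PSSM scans by naive
per-window scoring.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
import scipy.linalg

from halointein.ctmc import STATE_INDEX


def random_tree_newick(n: int, rng: np.random.Generator, min_len=0.05, max_len=2.0) -> str:
    """A random binary topology with uniform branch lengths, as Newick."""
    nodes = [f"T{i}:{rng.uniform(min_len, max_len):.6f}" for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(f"({a},{b}):{rng.uniform(min_len, max_len):.6f}")
    s = nodes[0]
    return s[: s.rfind(":")] + ";"


def enumeration_loglik(tree, tip_states: dict[str, str], Q: np.ndarray, pi: np.ndarray) -> float:
    """Likelihood by brute-force summation over all ancestral assignments."""
    dt = tree.dendropy_tree
    nodes = list(dt.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    P = {
        id(nd): scipy.linalg.expm(Q * nd.edge.length)
        for nd in nodes
        if nd.edge.length is not None
    }
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        amap = {id(nd): s for nd, s in zip(internals, assign)}
        lik = pi[amap[id(dt.seed_node)]]
        for nd in nodes:
            if nd is dt.seed_node:
                continue
            s_par = amap[id(nd.parent_node)]
            s_ch = (
                amap[id(nd)]
                if not nd.is_leaf()
                else STATE_INDEX[tip_states[nd.taxon.label]]
            )
            lik *= P[id(nd)][s_par, s_ch]
        total += lik
    return math.log(total)


def mad_grid_score(tree, step: float = 1e-4) -> float:
    """Minimal MAD score by dense grid search over all branches.

    Works from the tip distance matrix and node-to-tip distances only; an
    independent reimplementation of the deviation definition.
    """
    work = tree.copy()
    dt = work.dendropy_tree
    if len(dt.seed_node.child_nodes()) == 2:
        dt.collapse_basal_bifurcation()
    nodes, idx, tips, labels, dist, below = work._node_tip_distances()
    tipdist = np.array([dist[idx[id(t)]] for t in tips])
    n = len(tips)
    best = math.inf
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if tipdist[i, j] > 0]
    for nd in dt.postorder_node_iter():
        if nd is dt.seed_node:
            continue
        k, pk = idx[id(nd)], idx[id(nd.parent_node)]
        t = nd.edge.length or 0.0
        m = below[k]
        grid = np.arange(0.0, t + step, step) if t > 0 else np.array([0.0])
        grid = np.clip(grid, 0, t)
        for x in grid:
            sq = 0.0
            for i, j in pairs:
                d = tipdist[i, j]
                if m[i] == m[j]:
                    ref = dist[k] if m[i] else dist[pk]
                    r = abs(ref[i] - ref[j]) / d
                else:
                    u = j if m[i] else i  # tip on parent side
                    r = abs(2.0 * (dist[pk][u] + x) / d - 1.0)
                sq += r * r
            best = min(best, math.sqrt(sq / len(pairs)))
    return best


def brute_force_scan(pssm, seq: str) -> np.ndarray:
    """Naive window scores: per-window, per-position lookups in a loop."""
    from halointein.flanks import _AA_INDEX

    L = pssm.length
    out = []
    for off in range(len(seq) - L + 1):
        s = 0.0
        for p, res in enumerate(seq[off : off + L].upper()):
            j = _AA_INDEX.get(res, 20)
            s += pssm.matrix[p, j]
        out.append(s)
    return np.array(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
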