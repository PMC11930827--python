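"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import comorbnet as cn

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def records_frame(rows):
    """Build a visit-record frame from (patient_id, sex, age, code) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "sex", "age", "code"])


@pytest.fixture(scope="session")
def panel_rules():
    return cn.default_panel()


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_oracle(adj, groups, gamma=1.0):
    """Direct double-sum evaluation of Q for a partition given as groups."""
    adj = np.asarray(adj, dtype=float)
    p = adj.shape[0]
    label = np.empty(p, dtype=int)
    for g, members in enumerate(groups):
        for i in members:
            label[i] = g
    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    k = adj.sum(axis=1)
    q = 0.0
    for i in range(p):
        for j in range(p):
            if label[i] == label[j]:
                q += adj[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def best_partition_oracle(adj, gamma=1.0):
    """Exhaustive-search maximum modularity over all partitions (p <= 8)."""
    p = adj.shape[0]
    best = -np.inf
    for groups in set_partitions(range(p)):
        q = modularity_oracle(adj, groups, gamma)
        if q > best:
            best = q
    return best


def shortest_paths_oracle(weights, s, t, tol=1e-9):
    """All geodesics between s and t by enumerating every simple path.

    Edge length is 1/|w|.  Returns (distance, list of paths); distance is
    inf when unreachable.
    """
    p = weights.shape[0]
    others = [v for v in range(p) if v not in (s, t)]
    best, paths = np.inf, []
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                if weights[a, b] == 0:
                    ok = False
                    break
                length += 1.0 / abs(weights[a, b])
            if not ok:
                continue
            if length < best - tol:
                best, paths = length, [path]
            elif abs(length - best) <= tol:
                paths.append(path)
    return best, paths


def centrality_oracle(weights):
    """Brute-force strength/closeness/betweenness for a tiny network."""
    p = weights.shape[0]
    strength = np.abs(weights).sum(axis=1)
    closeness = []
    betweenness = np.zeros(p)
    for i in range(p):
        total = 0.0
        reachable = False
        for j in range(p):
            if j == i:
                continue
            d, _ = shortest_paths_oracle(weights, i, j)
            if np.isfinite(d):
                total += d
                reachable = True
        closeness.append(1.0 / total if reachable else None)
    for s in range(p):
        for t in range(s + 1, p):
            d, paths = shortest_paths_oracle(weights, s, t)
            if not np.isfinite(d) or not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    betweenness[v] += 1.0 / len(paths)
    return strength, closeness, betweenness
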