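"""Independent brute-force oracles used to validate the pipeline's
combinatorial operations. These deliberately re-derive each rule by
exhaustive enumeration (or via a different library path) and stay free of
the implementation modules' algorithms."""

from __future__ import annotations

import numpy as np


def exhaustive_modified_cosine(a, b, tol: float = 0.02) -> float:
    """Maximum-weight one-to-one peak matching by exhaustive recursion over
    all pairable (direct or precursor-shifted) peak pairs. Exponential; only
    for spectra with <= ~8 peaks."""
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0
    wa = np.sqrt(a.intensities)
    wa = wa / np.linalg.norm(wa)
    wb = np.sqrt(b.intensities)
    wb = wb / np.linalg.norm(wb)
    shift = b.precursor_mz - a.precursor_mz
    allowed = [(i, j) for i in range(a.n_peaks) for j in range(b.n_peaks)
               if abs(a.mz[i] - b.mz[j]) <= tol
               or abs(a.mz[i] + shift - b.mz[j]) <= tol]
    best = 0.0

    def recurse(k, used_a, used_b, total):
        nonlocal best
        best = max(best, total)
        for idx in range(k, len(allowed)):
            i, j = allowed[idx]
            if i in used_a or j in used_b:
                continue
            recurse(idx + 1, used_a | {i}, used_b | {j}, total + wa[i] * wb[j])

    recurse(0, frozenset(), frozenset(), 0.0)
    return min(best, 1.0) if best > 1.0 - 1e-12 else best


def mutual_topk_oracle(edges, k: int) -> set[frozenset]:
    """Edges (u, v, score) surviving the mutual top-k rule, keeping all ties
    at rank k; computed by explicit per-node ranking."""
    if k == 0:
        return set()
    nbrs: dict = {}
    for u, v, s in edges:
        nbrs.setdefault(u, []).append((s, v))
        nbrs.setdefault(v, []).append((s, u))
    tops = {}
    for node, lst in nbrs.items():
        ranked = sorted(lst, key=lambda t: (-t[0], t[1]))
        if len(ranked) <= k:
            tops[node] = {v for _, v in ranked}
        else:
            kth = ranked[k - 1][0]
            tops[node] = {v for s, v in ranked if s >= kth}
    return {frozenset((u, v)) for u, v, s in edges
            if v in tops[u] and u in tops[v]}


def greedy_cap_oracle(edges, cap: int) -> set[frozenset]:
    """Step-by-step simulation of the family-size cap: repeatedly delete the
    lowest-scoring (ties: lexicographically smallest) edge lying inside a
    connected component larger than `cap`. Components found by hand-rolled
    BFS, independent of networkx."""
    adj: dict = {}
    escore = {}
    for u, v, s in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
        escore[frozenset((u, v))] = s

    def component(start):
        seen, queue = {start}, [start]
        while queue:
            n = queue.pop()
            for m in adj.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    queue.append(m)
        return seen

    while True:
        visited = set()
        worst = None
        for node in sorted(adj):
            if node in visited:
                continue
            comp = component(node)
            visited |= comp
            if len(comp) <= cap:
                continue
            for u in comp:
                for v in adj[u]:
                    key = frozenset((u, v))
                    a, b = sorted(key)
                    item = (escore[key], a, b)
                    if worst is None or item < worst:
                        worst = item
        if worst is None:
            return set(escore)
        _, a, b = worst
        adj[a].discard(b)
        adj[b].discard(a)
        del escore[frozenset((a, b))]


def replicate_filter_oracle(detection: np.ndarray, n_required: int, co_min: int):
    """Rule oracle for the replicate filter on a (features, samples,
    replicates) boolean tensor: retained iff all replicates detected in some
    sample; presence per sample iff >= co_min replicates."""
    per_sample = detection.sum(axis=2)
    retained = (per_sample >= n_required).any(axis=1)
    presence = per_sample >= co_min
    return retained, presence


def blank_filter_oracle(intensity: np.ndarray, is_blank: np.ndarray,
                        ratio: float) -> np.ndarray:
    """Rows kept by the blank filter: mean over blank injections must not
    exceed ratio x the best biological per-sample replicate mean.
    intensity: (features, samples, replicates); is_blank: (samples,)."""
    blank_mean = intensity[:, is_blank, :].reshape(intensity.shape[0], -1).mean(axis=1)
    bio_best = intensity[:, ~is_blank, :].mean(axis=2).max(axis=1)
    return ~(blank_mean > ratio * bio_best)
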