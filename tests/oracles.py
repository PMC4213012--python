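"""Independent brute-force oracles used to cross-check the search engines.

These deliberately share no code with the package's indexed engines: the
aligner oracle is a full-scan Hamming search over every reference offset,
the perfect-match oracle is substring containment over every window length,
and the GLM oracle is Newton-Raphson on the binomial log-likelihood.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _codes(seq: str, n_code: int) -> np.ndarray:
    table = np.full(256, n_code, dtype=np.int16)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def naive_map_hits(
    reference: str,
    read: str,
    seed_length: int = 28,
    max_seed_mm: int = 3,
    max_other_mm: int = 2,
) -> set[tuple[int, str, int, int]]:
    """All (start, strand, seed_mm, total_mm) placements by full Hamming scan.

    N counts as a mismatch on either side.  The seed is the first
    ``seed_length`` bases of the read; on the reverse strand those are the
    last columns of the reverse-complemented query.
    """
    ref = _codes(reference, 97)  # distinct N codes so N never matches
    out: set[tuple[int, str, int, int]] = set()
    R = len(read)
    if R > len(reference):
        return out
    windows = np.lib.stride_tricks.sliding_window_view(ref, R)
    for strand, q in (("+", read), ("-", rc(read))):
        qc = _codes(q, 98)
        mm = windows != qc
        total = mm.sum(axis=1)
        seed_cols = slice(0, seed_length) if strand == "+" else slice(R - seed_length, R)
        seed = mm[:, seed_cols].sum(axis=1)
        ok = np.nonzero((seed <= max_seed_mm) & (total - seed <= max_other_mm))[0]
        for s in ok:
            out.add((int(s), strand, int(seed[s]), int(total[s])))
    return out


def naive_perfect_hits(db: dict[str, str], read: str, L: int) -> dict[tuple[str, str], int]:
    """Longest clean shared substring >= L per (subject, strand), by scanning.

    Existence of a common substring of length k is monotone in k, so the
    maximum is located by bisection over window containment checks; windows
    containing N are excluded.
    """
    out: dict[tuple[str, str], int] = {}
    for sid, subj in db.items():
        for strand, q in (("+", read), ("-", rc(read))):
            def has(k: int) -> bool:
                return any(
                    "N" not in q[i : i + k] and q[i : i + k] in subj
                    for i in range(len(q) - k + 1)
                )

            if not has(L):
                continue
            lo, hi = L, len(q)
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if has(mid):
                    lo = mid
                else:
                    hi = mid - 1
            out[(sid, strand)] = lo
    return out


def newton_binomial_logit(
    y: np.ndarray, n: np.ndarray, x: np.ndarray, tol: float = 1e-12, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson MLE of a binomial logit GLM with predictor x.

    Returns (beta, standard errors).  Independent of the package's IRLS
    implementation: raw score/Hessian iterations from a zero start.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - n * mu)
        H = (X.T * (n * mu * (1 - mu))) @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (X.T * (n * mu * (1 - mu))) @ X
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def random_additive_distance(rng: np.random.Generator, n_leaves: int) -> np.ndarray:
    """Additive (tree-metric) distance matrix from a random unrooted binary tree."""
    import collections

    adj: dict[int, list[tuple[int, float]]] = {}

    def add_edge(a: int, b: int, w: float) -> None:
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    nxt = n_leaves
    add_edge(0, nxt, rng.uniform(0.1, 1.0))
    add_edge(1, nxt, rng.uniform(0.1, 1.0))
    edges = [(0, nxt), (1, nxt)]
    for leaf in range(2, n_leaves):
        a, b = edges[rng.integers(len(edges))]
        wab = next(w for t, w in adj[a] if t == b)
        adj[a] = [(t, w) for t, w in adj[a] if t != b]
        adj[b] = [(t, w) for t, w in adj[b] if t != a]
        mid = nxt + 1
        nxt = mid
        u = rng.uniform(0.2, 0.8)
        add_edge(a, mid, wab * u)
        add_edge(b, mid, wab * (1 - u))
        add_edge(leaf, mid, rng.uniform(0.1, 1.0))
        edges = [e for e in edges if e not in ((a, b), (b, a))]
        edges += [(a, mid), (b, mid), (leaf, mid)]
    D = np.zeros((n_leaves, n_leaves))
    for s in range(n_leaves):
        dist = {s: 0.0}
        q = collections.deque([s])
        while q:
            v = q.popleft()
            for t, w in adj[v]:
                if t not in dist:
                    dist[t] = dist[v] + w
                    q.append(t)
        for t in range(n_leaves):
            D[s, t] = dist[t]
    return (D + D.T) / 2  # exact symmetry despite float summation order
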