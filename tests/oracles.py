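"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: naive loops,
exhaustive enumeration and direct formula transcriptions.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_seed_scan(mirna_seq: str, target_seq: str) -> list[tuple[str, int, int]]:
    """Position-by-position canonical seed-site scan with strongest-type
    suppression, written as plain slice comparisons."""
    mirna_seq = mirna_seq.upper().replace("T", "U")
    target_seq = target_seq.upper().replace("T", "U")
    patterns = [
        ("8mer", naive_revcomp(mirna_seq[1:8]) + "A"),
        ("7mer-m8", naive_revcomp(mirna_seq[1:8])),
        ("7mer-A1", naive_revcomp(mirna_seq[1:7]) + "A"),
        ("6mer", naive_revcomp(mirna_seq[1:7])),
    ]
    rank = {name: i for i, (name, _) in enumerate(patterns)}
    candidates = []
    for name, pat in patterns:
        for i in range(len(target_seq) - len(pat) + 1):
            if target_seq[i:i + len(pat)] == pat:
                candidates.append((name, i, i + len(pat)))
    kept: list[tuple[str, int, int]] = []
    for name, s, e in sorted(candidates, key=lambda c: (rank[c[0]], c[1])):
        if not any(rank[kn] < rank[name] and s < ke and ks < e
                   for kn, ks, ke in kept):
            kept.append((name, s, e))
    return sorted(kept, key=lambda c: (c[1], rank[c[0]]))


def naive_bh(pvalues) -> list[float]:
    """Quadratic transcription of the BH step-up definition."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_idx, i in enumerate(order, start=1):
        candidates = []
        for rank_j in range(rank_idx, m + 1):
            j = order[rank_j - 1]
            candidates.append(p[j] * m / rank_j)
        q[i] = min(1.0, min(candidates))
    return q


def auc_pair_count(case, control) -> float:
    """AUC = (concordant + 0.5 * tied) / (n_case * n_control), nested loops."""
    num = 0.0
    for c in case:
        for k in control:
            if c > k:
                num += 1.0
            elif c == k:
                num += 0.5
    return num / (len(case) * len(control))


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    term = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def exact_mannwhitney_enumeration(x, y) -> float:
    """Tie-aware exact two-sided Mann-Whitney p by assignment enumeration."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = _average_ranks(pooled)
    u_of = lambda idx: sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0
    n1n2 = n1 * (len(pooled) - n1)
    stat_obs = min(u_of(range(n1)), n1n2 - u_of(range(n1)))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = u_of(idx)
        if min(u, n1n2 - u) <= stat_obs + 1e-9:
            count += 1
        total += 1
    return count / total


def _average_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for idx in order[i:j]:
            ranks[idx] = avg
        i = j
    return ranks


def spearman_perm_p(x, y) -> float:
    """Exact two-sided permutation p for Spearman's rho (small n only)."""
    rx = np.array(_average_ranks(list(x)))
    ry = np.array(_average_ranks(list(y)))
    r_obs = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def naive_pearson(x, y) -> float:
    """Covariance-formula Pearson correlation, written out longhand."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = math.sqrt(sum((a - mx) ** 2 for a in x))
    vy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (vx * vy)


def triads_by_triple_loop(ml_edges, mm_edges) -> list[tuple[str, str, str]]:
    """All (lncRNA, miRNA, mRNA) triads by a brute-force triple loop."""
    lncs = sorted({l for _, l in ml_edges})
    mirnas = sorted({m for m, _ in ml_edges} | {m for m, _ in mm_edges})
    genes = sorted({g for _, g in mm_edges})
    out = []
    for l in lncs:
        for m in mirnas:
            for g in genes:
                if (m, l) in ml_edges and (m, g) in mm_edges:
                    out.append((l, m, g))
    return sorted(out)
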