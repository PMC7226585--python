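"""Independent brute-force oracles used to validate the package implementations.

Everything here is written as a literal transcription of the definitions,
deliberately ignoring efficiency, and shares no code with ribomech.
"""

from itertools import combinations
from math import comb

import numpy as np

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def naive_seed_sites(target, mirna):
    """Test all four patterns at every offset; strongest type per seed locus."""
    core = revcomp(mirna[1:7])
    m8 = revcomp(mirna[7])
    patterns = [
        ("8mer", m8 + core + "A"),
        ("7mer-m8", m8 + core),
        ("7mer-1a", core + "A"),
        ("6mer", core),
    ]
    # locus = start of the 6-nt core within the target
    hits = {}
    for name, pat in patterns:
        for start in range(len(target) - len(pat) + 1):
            if target[start : start + len(pat)] == pat:
                locus = start + 1 if name in ("8mer", "7mer-m8") else start
                if locus not in hits:  # patterns listed strongest-first
                    hits[locus] = (start, name)
    return sorted((s, n) for s, n in hits.values())


def straight_line_score(site_type, start, seq, base, w_au, w_pos):
    length = {"8mer": 8, "7mer-m8": 7, "7mer-1a": 7, "6mer": 6}[site_type]
    end = start + length
    flank = seq[max(0, start - 30) : start] + seq[end : end + 30]
    au = sum(1 for c in flank if c in "AU") / len(flank) if flank else 0.5
    dist = min(start, len(seq) - end)
    return base[site_type] + w_au * (au - 0.5) + w_pos * min(dist, 1500) / 1500


def bh_oracle(pvals):
    """Step-up definition: fdr_i = min over j with p_j >= p_i of m * p_(j) / rank(j)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, m * p[i] / rank_from_top)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return adj


def bh_reject_oracle(pvals, alpha):
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= alpha * rank / m:
            k = rank
    rejected = [False] * m
    for i in range(k):
        rejected[order[i]] = True
    return rejected


def bky_oracle(pvals, q=0.05):
    """Literal two-stage linear step-up definition."""
    m = len(pvals)
    q1 = q / (1 + q)
    stage1 = bh_reject_oracle(pvals, q1)
    r1 = sum(stage1)
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    m0 = m - r1
    return bh_reject_oracle(pvals, q1 * m / m0)


def ks_exact_oracle(x, y):
    """Exhaustive enumeration of all C(n+m, n) label assignments.

    Returns (D, p) where p is the fraction of assignments whose KS statistic
    is >= the observed one (assumes no ties across the pooled sample).
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)

    def ks_stat(xs, ys):
        xs, ys = sorted(xs), sorted(ys)
        d = 0.0
        for v in xs + ys:
            fx = sum(1 for u in xs if u <= v) / len(xs)
            fy = sum(1 for u in ys if u <= v) / len(ys)
            d = max(d, abs(fx - fy))
        return d

    d_obs = ks_stat(x, y)
    count = 0
    total = comb(n + m, n)
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        if ks_stat(xs, ys) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def conditional_binomial_oracle(s_a, total, n_a, n_b):
    """Two-sided conditional binomial p by full enumeration over splits."""
    from math import comb as C

    pr = n_a / (n_a + n_b)
    pmf = [C(total, s) * pr**s * (1 - pr) ** (total - s) for s in range(total + 1)]
    obs = pmf[s_a]
    return sum(p for p in pmf if p <= obs * (1 + 1e-10))


def cpm_oracle(counts):
    out = np.zeros_like(counts, dtype=float)
    for j in range(counts.shape[1]):
        lib = counts[:, j].sum()
        for i in range(counts.shape[0]):
            out[i, j] = counts[i, j] / lib * 1e6
    return out


def filter_oracle(counts, min_count, min_samples):
    libs = counts.sum(axis=0)
    threshold = min_count / libs.min() * 1e6
    keep = []
    for i in range(counts.shape[0]):
        n_ok = sum(
            counts[i, j] / libs[j] * 1e6 >= threshold for j in range(counts.shape[1])
        )
        keep.append(n_ok >= min_samples)
    return np.array(keep), threshold


def seed_family_oracle(seqs):
    """Brute-force pairwise grouping on identical nt 2-8."""
    names = list(seqs)
    groups = []
    for name in names:
        placed = False
        for g in groups:
            if seqs[g[0]][1:8] == seqs[name][1:8]:
                g.append(name)
                placed = True
                break
        if not placed:
            groups.append([name])
    return sorted(sorted(g) for g in groups)
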