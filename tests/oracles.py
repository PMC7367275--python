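"""Independent brute-force oracles used to validate the package's statistics.

Everything here is written from the defining formulas, deliberately naive
(explicit loops, exhaustive enumeration) and independent of the package's
implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def he_unbiased(alleles: list[int]) -> float:
    """Nei's unbiased expected heterozygosity from a flat list of gene copies."""
    n = len(alleles)
    freqs = {}
    for a in alleles:
        freqs[a] = freqs.get(a, 0) + 1
    ss = sum((c / n) ** 2 for c in freqs.values())
    return n / (n - 1) * (1 - ss)


def ho_observed(genotypes: list[tuple[int, int]]) -> float:
    return sum(1 for a, b in genotypes if a != b) / len(genotypes)


def haplotype_diversity(haplotypes: list[str]) -> float:
    n = len(haplotypes)
    freqs = {}
    for h in haplotypes:
        freqs[h] = freqs.get(h, 0) + 1
    ss = sum((c / n) ** 2 for c in freqs.values())
    return n / (n - 1) * (1 - ss)


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance with pairwise deletion of non-ACGT sites."""
    valid = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    if not valid:
        return float("nan")
    return sum(1 for x, y in valid if x != y) / len(valid)


def mean_pairwise(seqs: list[str]) -> tuple[float, float]:
    """(k, pi): mean raw differences and mean p-distance over all pairs."""
    diffs, pdists = [], []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            valid = [(x, y) for x, y in zip(seqs[i], seqs[j])
                     if x in "ACGT" and y in "ACGT"]
            d = sum(1 for x, y in valid if x != y)
            diffs.append(d)
            pdists.append(d / len(valid) if valid else float("nan"))
    return float(np.mean(diffs)), float(np.nanmean(pdists))


def psa_pair(g1: list[tuple[int, int]], g2: list[tuple[int, int]]) -> float:
    """Proportion of shared alleles over loci genotyped in both (MISSING=-1)."""
    shared = 0
    loci = 0
    for (a1, a2), (b1, b2) in zip(g1, g2):
        if -1 in (a1, a2, b1, b2):
            continue
        loci += 1
        counts1 = {a1: 0, a2: 0}
        counts1[a1] += 1
        counts1[a2] += 1
        counts2 = {b1: 0, b2: 0}
        counts2[b1] += 1
        counts2[b2] += 1
        shared += sum(min(counts1.get(a, 0), counts2.get(a, 0)) for a in counts1)
    if loci == 0:
        return float("nan")
    return shared / (2 * loci)


def by_exhaustive(pvals, alpha: float):
    """BY rejection set by exhaustive search over all candidate thresholds."""
    p = sorted(pvals)
    m = len(p)
    c_m = sum(1.0 / j for j in range(1, m + 1))
    best = 0
    for i in range(1, m + 1):
        if p[i - 1] <= i * alpha / (m * c_m) + 1e-15:
            best = i
    critical = best * alpha / (m * c_m) if best else 0.0
    mask = [pv <= (p[best - 1] + 1e-15) if best else False for pv in pvals]
    return np.array(mask), critical


def steiner_optimum_binary(haps: list[str], alphabet: str = "AG") -> int:
    """Exact Steiner minimal tree cost in the Hamming metric over
    alphabet^L (Dreyfus-Wagner on the metric closure)."""
    L = len(haps[0])
    V = ["".join(p) for p in itertools.product(alphabet, repeat=L)]
    idx = {v: i for i, v in enumerate(V)}
    arr = np.array([[c for c in v] for v in V])
    D = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    terms = [idx[h] for h in haps]
    k = len(terms)
    if k == 1:
        return 0
    dw = {1 << i: D[t].astype(np.int64).copy() for i, t in enumerate(terms)}
    INF = np.int64(10**9)
    for mask in range(1, 1 << k):
        if mask in dw:
            continue
        best = np.full(len(V), INF)
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:
                best = np.minimum(best, dw[sub] + dw[other])
            sub = (sub - 1) & mask
        dw[mask] = (best[None, :] + D).min(axis=1)
    return int(dw[(1 << k) - 1][terms[0]])


def rarefaction_enumeration(pool: list[str], n: int, k: int) -> float:
    """P(exactly k distinct labels) over all ordered with-replacement draws."""
    total = 0
    hits = 0
    for draw in itertools.product(range(len(pool)), repeat=n):
        total += 1
        if len({pool[i] for i in draw}) == k:
            hits += 1
    return hits / total


def hwe_exact_enumeration(genotypes: list[tuple[int, int]]) -> float:
    """Exact HWE p-value by enumerating every pairing of the gene copies."""
    copies = [a for g in genotypes for a in g]
    n = len(genotypes)

    def table_of(perm):
        out = {}
        for i in range(n):
            g = tuple(sorted((perm[2 * i], perm[2 * i + 1])))
            out[g] = out.get(g, 0) + 1
        return out

    def prob_weight(table):
        # conditional probability up to a constant: 2^h / prod(counts!)
        import math

        h = sum(c for (a, b), c in table.items() if a != b)
        w = 2.0**h
        for c in table.values():
            w /= math.factorial(c)
        return w

    obs = prob_weight(table_of(copies))
    tables = {}
    for perm in itertools.permutations(copies):
        t = table_of(perm)
        key = tuple(sorted(t.items()))
        tables[key] = prob_weight(t)
    z = sum(tables.values())
    return sum(w for w in tables.values() if w <= obs + 1e-12) / z
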