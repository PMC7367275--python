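"""Descriptive population-genetic statistics for microsatellites and mtDNA.

Microsatellite layer: per-locus diversity (allele counts, Nei's unbiased
expected heterozygosity, observed heterozygosity, F_IS with permutation
significance), Weir-Cockerham theta between populations, multiallelic HWE
exact/chi-squared tests, Benjamini-Yekutieli FDR control and an
allele-sharing matrix.

Sequence layer: haplotype and nucleotide diversity, segregating sites and
total mutations, uncorrected p-distances and Nei's G_ST on haplotype
frequencies with the Nei-Chesser small-sample corrections.

Missing data are handled by pairwise deletion throughout; nothing is imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .iodata import MISSING, GenotypeMatrix, PopulationMap, SequenceAlignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# helpers


def _pop_labels(G: GenotypeMatrix, pm: PopulationMap | None, by: str) -> list[str]:
    if by == "island" or pm is None:
        return list(G.populations)
    if by == "cluster":
        return [pm.cluster_of[p] for p in G.populations]
    raise ValueError(f"unknown grouping {by!r}")


def _allele_counts(column: np.ndarray) -> dict[int, int]:
    """Allele -> gene-copy count for one locus column (n, 2), skipping missing."""
    flat = column[column != MISSING]
    vals, cnts = np.unique(flat, return_counts=True)
    return dict(zip(vals.tolist(), cnts.tolist()))


def unbiased_expected_het(counts: np.ndarray) -> float:
    """Nei's unbiased gene diversity (n/(n-1))(1 - sum p_i^2) over n gene copies."""
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def plain_expected_het(counts: np.ndarray) -> float:
    n = counts.sum()
    if n < 1:
        return float("nan")
    p = counts / n
    return float(1.0 - np.sum(p**2))


# ---------------------------------------------------------------------------
# locus diversity (Table-2-style)


def locus_diversity(
    G: GenotypeMatrix,
    pm: PopulationMap | None = None,
    by: str = "island",
    fis_permutations: int = 0,
    seed: int | None = None,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Per locus-population NA/He/Ho/FIS (+ permutation p for FIS).

    Returns a tidy frame with one row per (locus, population) and one row per
    locus over the whole dataset (population ``"_all_"``). F_IS is defined as
    1 - Ho/He; for a monomorphic locus-population it is reported as NaN, not 0.
    Its p-value comes from permuting gene copies among individuals within the
    population (two-sided on \\|F_IS\\|).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(_pop_labels(G, pm, by))
    pops = list(dict.fromkeys(labels.tolist()))
    het_fn = unbiased_expected_het if unbiased else plain_expected_het
    rows = []
    for j, locus in enumerate(G.loci):
        col = G.calls[:, j, :]
        for pop in pops + ["_all_"]:
            mask = np.ones(len(labels), bool) if pop == "_all_" else labels == pop
            sub = col[mask]
            nonmiss = sub[:, 0] != MISSING
            sub = sub[nonmiss]
            if sub.size == 0:
                rows.append((locus, pop, 0, np.nan, np.nan, np.nan, np.nan, 0))
                continue
            counts = np.array(sorted(_allele_counts(sub).values()))
            na = len(counts)
            he = het_fn(counts)
            ho = float((sub[:, 0] != sub[:, 1]).mean())
            if na < 2 or not np.isfinite(he) or he == 0:
                he_out = 0.0 if na == 1 else he
                rows.append((locus, pop, na, he_out, ho, np.nan, np.nan, len(sub)))
                continue
            fis = 1.0 - ho / he
            pval = np.nan
            if fis_permutations > 0:
                copies = sub.ravel().copy()
                hits = 0
                for _ in range(fis_permutations):
                    rng.shuffle(copies)
                    pairs = copies.reshape(-1, 2)
                    ho_p = float((pairs[:, 0] != pairs[:, 1]).mean())
                    fis_p = 1.0 - ho_p / he  # He invariant under copy permutation
                    if abs(fis_p) >= abs(fis) - 1e-12:
                        hits += 1
                pval = (hits + 1) / (fis_permutations + 1)
            rows.append((locus, pop, na, he, ho, fis, pval, len(sub)))
    return pd.DataFrame(
        rows, columns=["locus", "population", "NA_alleles", "He", "Ho", "FIS", "FIS_p", "n"]
    )


def overall_summary(div: pd.DataFrame) -> pd.Series:
    """Across-locus means of whole-dataset NA/He/Ho (the Table-2 'Overall' row)."""
    whole = div[div["population"] == "_all_"]
    return whole[["NA_alleles", "He", "Ho"]].mean()


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


@dataclass
class DifferentiationMatrix:
    """Symmetric population differentiation matrix with optional permutation p."""

    labels: list[str]
    values: np.ndarray
    pvalues: np.ndarray | None = None
    global_value: float = float("nan")
    global_p: float = float("nan")
    statistic: str = "theta_WC"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _theta_components_locus(col: np.ndarray, pop_idx: np.ndarray, n_pops: int) -> tuple[float, float, float]:
    """Summed Weir-Cockerham variance components (a, b, c) over the alleles
    of one locus. ``col`` is (n, 2) allele sizes with MISSING."""
    genotyped = col[:, 0] != MISSING
    alleles, inv = np.unique(col[genotyped], return_inverse=True)
    if len(alleles) == 0:
        return 0.0, 0.0, 0.0
    inv = inv.reshape(-1, 2)
    pops = pop_idx[genotyped]
    sizes_all = np.bincount(pops, minlength=n_pops).astype(float)
    use = np.flatnonzero(sizes_all >= 1)
    r = len(use)
    if r < 2:
        return 0.0, 0.0, 0.0
    sizes = sizes_all[use]
    nbar = sizes.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (sizes**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    A = len(alleles)
    # per-pop allele-copy counts and heterozygote-carrier counts
    counts = np.zeros((n_pops, A))
    np.add.at(counts, (pops, inv[:, 0]), 1)
    np.add.at(counts, (pops, inv[:, 1]), 1)
    het = inv[:, 0] != inv[:, 1]
    hcounts = np.zeros((n_pops, A))
    np.add.at(hcounts, (pops[het], inv[het, 0]), 1)
    np.add.at(hcounts, (pops[het], inv[het, 1]), 1)
    p_i = counts[use] / (2 * sizes[:, None])
    h_i = hcounts[use] / sizes[:, None]
    pbar = (sizes[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (sizes[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (sizes[:, None] * h_i).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_theta(calls: np.ndarray, pop_idx: np.ndarray, n_pops: int) -> float:
    """Multiallelic Weir-Cockerham (1984) theta, ratio of summed components.

    ``calls`` is (n, L, 2) allele sizes with MISSING; ``pop_idx`` assigns each
    individual to one of ``n_pops`` populations. Components are summed over
    alleles and loci before the ratio, and negative estimates are reported
    as-is.
    """
    a_sum = b_sum = c_sum = 0.0
    for l in range(calls.shape[1]):
        a, b, c = _theta_components_locus(calls[:, l, :], pop_idx, n_pops)
        a_sum += a
        b_sum += b
        c_sum += c
    denom = a_sum + b_sum + c_sum
    if denom == 0:
        return float("nan")
    return float(a_sum / denom)


def pairwise_fst(
    G: GenotypeMatrix,
    pm: PopulationMap | None = None,
    by: str = "island",
    permutations: int = 0,
    seed: int | None = None,
) -> DifferentiationMatrix:
    """Pairwise and global Weir-Cockerham theta with permutation p-values.

    Populations with fewer than two genotyped individuals are excluded with a
    warning. Permutation p-values shuffle individuals between the two
    populations of a pair (upper-tail, add-one corrected).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(_pop_labels(G, pm, by))
    pops = list(dict.fromkeys(labels.tolist()))
    kept = []
    for p in pops:
        n_geno = int(((labels == p)[:, None] & ~G.is_missing()).any(axis=1).sum())
        if n_geno < 2:
            warnings.warn(f"population {p!r} has <2 genotyped individuals; excluded from FST")
        else:
            kept.append(p)
    k = len(kept)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if permutations > 0 else None
    for i in range(k):
        for j in range(i + 1, k):
            mask = (labels == kept[i]) | (labels == kept[j])
            sub = G.calls[mask]
            idx = (labels[mask] == kept[j]).astype(int)
            theta = wc_theta(sub, idx, 2)
            values[i, j] = values[j, i] = theta
            if permutations > 0:
                hits = 0
                for _ in range(permutations):
                    perm = rng.permutation(idx)
                    if wc_theta(sub, perm, 2) >= theta - 1e-12:
                        hits += 1
                p = (hits + 1) / (permutations + 1)
                pvals[i, j] = pvals[j, i] = p
    # global theta across all kept populations
    mask = np.isin(labels, kept)
    idx = np.array([kept.index(p) for p in labels[mask]])
    global_theta = wc_theta(G.calls[mask], idx, k) if k >= 2 else float("nan")
    global_p = float("nan")
    if permutations > 0 and k >= 2:
        hits = 0
        for _ in range(permutations):
            if wc_theta(G.calls[mask], rng.permutation(idx), k) >= global_theta - 1e-12:
                hits += 1
        global_p = (hits + 1) / (permutations + 1)
    return DifferentiationMatrix(kept, values, pvals, global_theta, global_p)


# ---------------------------------------------------------------------------
# Nei G_ST for sequences


def _hap_freqs(aln: SequenceAlignment, labels: list[str]) -> tuple[pd.DataFrame, list[str]]:
    hap_of = {}
    ids = []
    for s in aln.sequences:
        if s not in hap_of:
            hap_of[s] = len(hap_of)
        ids.append(hap_of[s])
    df = pd.DataFrame({"hap": ids, "pop": labels})
    table = df.groupby(["pop", "hap"]).size().unstack(fill_value=0)
    return table, list(table.index)


def nei_gst(freq_table: np.ndarray) -> float:
    """Nei's G_ST with Nei-Chesser (1983) small-sample corrections.

    ``freq_table`` is (r populations x haplotypes) of counts. The correction
    can push estimates below zero for undifferentiated populations.
    """
    counts = np.asarray(freq_table, dtype=float)
    sizes = counts.sum(axis=1)
    counts = counts[sizes > 0]
    sizes = sizes[sizes > 0]
    r = len(sizes)
    if r < 2:
        return float("nan")
    ntilde = r / (1.0 / sizes).sum()
    if ntilde <= 1:
        return float("nan")
    p = counts / sizes[:, None]
    hs_plug = 1.0 - np.mean((p**2).sum(axis=1))
    hs = ntilde / (ntilde - 1) * hs_plug
    pbar = p.mean(axis=0)
    ht = 1.0 - (pbar**2).sum() + hs / (r * ntilde)
    if ht == 0:
        return float("nan")
    return float((ht - hs) / ht)


def gst_sequences(
    aln: SequenceAlignment, pm: PopulationMap | None = None, by: str = "island"
) -> DifferentiationMatrix:
    """Pairwise Nei G_ST from haplotype frequencies; diagonal fixed at 0."""
    if by == "cluster" and pm is not None:
        labels = [pm.cluster_of[p] for p in aln.populations]
    else:
        labels = list(aln.populations)
    table, pops = _hap_freqs(aln, labels)
    arr = table.to_numpy(dtype=float)
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = nei_gst(arr[[i, j]])
    global_gst = nei_gst(arr) if k >= 2 else float("nan")
    return DifferentiationMatrix(list(pops), values, None, global_gst, statistic="G_ST_Nei")


# ---------------------------------------------------------------------------
# HWE exact / chi-squared tests


def _log_table_prob(geno_counts: dict[tuple[int, int], int], n: int) -> float:
    """Log conditional probability of a genotype table given allele counts
    (Levene/Guo-Thompson), up to a configuration-independent constant."""
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    return float(
        -sum(gammaln(c + 1) for c in geno_counts.values()) + h * np.log(2.0)
    )


def _geno_counts(pairs: np.ndarray) -> dict[tuple[int, int], int]:
    srt = np.sort(pairs, axis=1)
    out: dict[tuple[int, int], int] = {}
    for a, b in srt:
        out[(int(a), int(b))] = out.get((int(a), int(b)), 0) + 1
    return out


def hwe_exact(
    G: GenotypeMatrix,
    pm: PopulationMap | None = None,
    by: str = "global",
    mc_reps: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multiallelic HWE tests per locus (and per population if requested).

    Exact p-value: Monte-Carlo permutation of gene copies into genotypes,
    counting tables no more probable than the observed one conditional on the
    allele counts (Guo-Thompson style). The chi-squared variant compares
    observed genotype class counts with n p_i^2 / 2 n p_i p_j expectations on
    k(k-1)/2 degrees of freedom, without pooling of rare classes. A
    monomorphic locus gives p = 1 for both tests.
    """
    if mc_reps < 1000:
        warnings.warn(f"mc_reps={mc_reps} < 1000: exact p-values will be unstable")
    rng = np.random.default_rng(seed)
    if by == "global":
        labels = np.asarray(["_all_"] * G.n_individuals)
    else:
        labels = np.asarray(_pop_labels(G, pm, by))
    pops = list(dict.fromkeys(labels.tolist()))
    rows = []
    for j, locus in enumerate(G.loci):
        for pop in pops:
            sub = G.calls[labels == pop, j, :]
            sub = sub[sub[:, 0] != MISSING]
            n = len(sub)
            if n == 0:
                rows.append((locus, pop, n, np.nan, np.nan, np.nan, np.nan))
                continue
            alleles = np.unique(sub)
            k = len(alleles)
            if k < 2:
                rows.append((locus, pop, n, 1.0, 1.0, 0.0, 0))
                continue
            obs = _geno_counts(sub)
            lp_obs = _log_table_prob(obs, n)
            copies = sub.ravel().copy()
            hits = 0
            for _ in range(mc_reps):
                rng.shuffle(copies)
                perm = _geno_counts(copies.reshape(-1, 2))
                if _log_table_prob(perm, n) <= lp_obs + 1e-9:
                    hits += 1
            exact_p = (hits + 1) / (mc_reps + 1)
            # chi-squared variant
            flat = sub.ravel()
            freqs = {int(a): float((flat == a).sum()) / (2 * n) for a in alleles}
            chi2 = 0.0
            for ai in range(k):
                for bi in range(ai, k):
                    a, b = int(alleles[ai]), int(alleles[bi])
                    exp = n * freqs[a] ** 2 if a == b else 2 * n * freqs[a] * freqs[b]
                    o = obs.get((min(a, b), max(a, b)), 0)
                    if exp > 0:
                        chi2 += (o - exp) ** 2 / exp
            df = k * (k - 1) // 2
            chi2_p = float(chi2_dist.sf(chi2, df)) if df > 0 else 1.0
            rows.append((locus, pop, n, exact_p, chi2_p, chi2, df))
    return pd.DataFrame(
        rows, columns=["locus", "population", "n", "exact_p", "chi2_p", "chi2", "df"]
    )


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli FDR


def benjamini_yekutieli(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """BY step-up FDR control under arbitrary dependence.

    Returns a boolean rejection mask (aligned with the input order) and the
    critical value i* alpha / (m c(m)), c(m) = sum_{j<=m} 1/j; the critical
    value is 0 when nothing is rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = (1.0 / np.arange(1, m + 1)).sum()
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * alpha / (m * c_m)
    below = p[order] <= thresholds + 1e-15
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    i_star = int(np.flatnonzero(below).max())  # 0-based
    reject = np.zeros(m, dtype=bool)
    reject[order[: i_star + 1]] = True
    critical = (i_star + 1) * alpha / (m * c_m)
    return reject, float(critical)


# ---------------------------------------------------------------------------
# allele sharing


def allele_sharing(G: GenotypeMatrix) -> pd.DataFrame:
    """Individual x individual proportion of shared alleles (PSA).

    PSA sums the multiset overlap of the two diploid calls over loci genotyped
    in both individuals, divided by twice the number of shared loci; the
    distance used for mapping is 1 - PSA. Pairs sharing no genotyped locus
    get NaN; the diagonal is 1 by definition.
    """
    n, L, _ = G.calls.shape
    x1 = G.calls[:, :, 0]
    x2 = G.calls[:, :, 1]
    miss = G.is_missing()
    shared = np.zeros((n, n))
    nloci = np.zeros((n, n))
    for l in range(L):
        a1, a2 = x1[:, l], x2[:, l]
        ok = ~miss[:, l]
        both = ok[:, None] & ok[None, :]
        eq11 = a1[:, None] == a1[None, :]
        eq22 = a2[:, None] == a2[None, :]
        eq12 = a1[:, None] == a2[None, :]
        eq21 = a2[:, None] == a1[None, :]
        overlap = np.maximum(eq11.astype(int) + eq22, eq12.astype(int) + eq21)
        shared += np.where(both, overlap, 0)
        nloci += both
    with np.errstate(invalid="ignore", divide="ignore"):
        psa = shared / (2.0 * nloci)
    psa[nloci == 0] = np.nan
    np.fill_diagonal(psa, 1.0)
    return pd.DataFrame(psa, index=G.individuals, columns=G.individuals)


# ---------------------------------------------------------------------------
# sequence diversity


@dataclass
class SeqDiversity:
    n: int
    n_hap: int
    S: int
    eta: int
    pi: float
    k: float
    Hd: float
    max_p: float
    effective_length: float
    complete_sites: int = 0


_VALID = frozenset(b"ACGT")


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")


def sequence_diversity(aln: SequenceAlignment) -> SeqDiversity:
    """Haplotype/nucleotide diversity summary for one alignment.

    S and eta use complete deletion (any site holding N or '-' is dropped);
    distances (pi, k, max_p) use pairwise deletion; haplotypes are defined on
    the complete retained sites; Hd carries the n/(n-1) correction. With a
    single sequence pi, k and Hd are NaN.
    """
    arr = aln.to_array()
    n, L = arr.shape
    valid = _valid_mask(arr)
    complete = valid.all(axis=0)
    comp = arr[:, complete]
    # S and eta on complete sites
    S = 0
    eta = 0
    for j in range(comp.shape[1]):
        k_states = len(np.unique(comp[:, j]))
        if k_states >= 2:
            S += 1
            eta += k_states - 1
    # haplotypes on complete retained sites
    haps = {}
    for i in range(n):
        haps.setdefault(comp[i].tobytes(), 0)
        haps[comp[i].tobytes()] += 1
    n_hap = len(haps)
    if n < 2:
        return SeqDiversity(n, n_hap, S, eta, np.nan, np.nan, np.nan, np.nan, np.nan, int(complete.sum()))
    # pairwise deletion distances
    diffs = []
    pdists = []
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        m = both.sum(axis=1)
        diffs.append(d)
        with np.errstate(invalid="ignore", divide="ignore"):
            pdists.append(np.where(m > 0, d / m, np.nan))
    d_all = np.concatenate(diffs).astype(float)
    p_all = np.concatenate(pdists)
    k_mean = float(d_all.mean())
    pi = float(np.nanmean(p_all))
    max_p = float(np.nanmax(p_all)) if np.isfinite(p_all).any() else float("nan")
    freqs = np.array(list(haps.values())) / n
    hd = float(n / (n - 1) * (1.0 - (freqs**2).sum()))
    eff_len = k_mean / pi if pi > 0 else float(complete.sum())
    return SeqDiversity(n, n_hap, S, eta, pi, k_mean, hd, max_p, eff_len, int(complete.sum()))


def p_distance_matrix(aln: SequenceAlignment) -> pd.DataFrame:
    """Pairwise uncorrected p-distances with per-pair pairwise deletion."""
    arr = aln.to_array()
    n = arr.shape[0]
    valid = _valid_mask(arr)
    out = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        d = ((arr[i] != arr) & both).sum(axis=1)
        m = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(m > 0, d / m, np.nan)
        out[i] = row
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=aln.ids, columns=aln.ids)
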