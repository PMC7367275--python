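"""Structured coalescent simulation of joint mtDNA + microsatellite data.

Four demographic scenarios relate a North and a South cluster:

* Scenarios I-III: an ancestral population of size NA splits at ``t_div``
  into two precursor populations (N3, N4); at ``t_admix`` (< t_div) the
  extant North (N1) and South (N2) clusters are each formed as a 50:50
  admixture of the precursors. Backwards in time each lineage sampled in
  North or South is reassigned to precursor 3 or 4 with probability 1/2 at
  ``t_admix``. The three scenarios differ only in the prior placed on
  ``t_admix``.
* Scenario IV: the ancestral population splits directly into North and South
  at ``t_div``; no admixture event.

Genealogies follow the continuous-time Kingman coalescent: within a
population of diploid size N, each lineage pair coalesces at rate 1/(2N) per
generation for autosomal markers (2N gene copies) and 1/(N/2) for
mitochondrial markers (N/2 transmitting copies under an even sex ratio).
Times are supplied in years and converted with ``generation_time``
(default 1 year/generation).

Mutation layers: Kimura two-parameter substitution for sequences (transition
probability kappa/(kappa+2) per event) and a generalized stepwise model for
microsatellites (step size 1 + geometric, reflecting boundaries on a
bounded motif-repeat range, plus rare single-nucleotide indels in the
flanking region that shift the fragment length by 1 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SCENARIOS = ("I", "II", "III", "IV")


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class DemographicScenario:
    """Scenario topology: label and whether an admixture event occurs."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in SCENARIOS:
            raise ParameterError(f"scenario label must be one of {SCENARIOS}")

    @property
    def has_admixture(self) -> bool:
        return self.label != "IV"


@dataclass
class ScenarioParams:
    """Parameter vector for one scenario.

    Sizes are diploid effective population sizes; times in years; ``useq``
    is the per-site per-generation mtDNA mutation rate; ``kappa`` the K2P
    transition/transversion coefficient; ``mu_mic_mean`` the across-locus
    mean microsatellite rate; ``P_gsm`` the probability that a mutation
    moves more than one motif unit (geometric tail); ``sni`` the flanking
    single-nucleotide indel rate.
    """

    N1: float
    N2: float
    NA: float
    t_div: float
    useq: float
    kappa: float
    mu_mic_mean: float
    P_gsm: float
    sni: float
    N3: float | None = None
    N4: float | None = None
    t_admix: float | None = None
    mu_mic: np.ndarray | None = None
    generation_time: float = 1.0
    admixture_proportion: float = 0.5

    def validate(self, scenario: DemographicScenario) -> None:
        sizes = [self.N1, self.N2, self.NA]
        if scenario.has_admixture:
            if self.N3 is None or self.N4 is None or self.t_admix is None:
                raise ParameterError(f"scenario {scenario.label} needs N3, N4 and t_admix")
            sizes += [self.N3, self.N4]
            if not 0 < self.t_admix <= self.t_div:
                raise ParameterError("t_admix must satisfy 0 < t_admix <= t_div")
        else:
            if self.t_admix is not None:
                raise ParameterError("scenario IV does not accept t_admix")
        if any(s < 10 for s in sizes):
            raise ParameterError("effective sizes must be >= 10")
        if self.t_div <= 0:
            raise ParameterError("t_div must be positive")
        for name in ("useq", "kappa", "mu_mic_mean", "sni", "generation_time"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.P_gsm < 1:
            raise ParameterError("P_gsm must lie in [0, 1)")


@dataclass
class Genealogy:
    """Binary coalescent tree: ``parent[i]`` (-1 at root), node ``time`` in
    generations, tips 0..n_tips-1 (North tips first)."""

    parent: np.ndarray
    time: np.ndarray
    n_tips: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def tmrca(self) -> float:
        return float(self.time[-1])

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


def _gene_copies(N: float, marker_kind: str) -> float:
    if marker_kind == "autosomal":
        return 2.0 * N
    if marker_kind == "mitochondrial":
        return N / 2.0
    if marker_kind == "mitochondrial_quarter":
        return N / 4.0
    raise ParameterError(f"unknown marker kind {marker_kind!r}")


def _coalesce_phase(lineages, ncopies, t0, t_end, parent, times, next_id, rng):
    """Coalesce a lineage list within one population from t0 to t_end
    (t_end=None means run to a single lineage). Returns next_id."""
    k = len(lineages)
    t = t0
    if k < 2:
        return next_id
    waits = rng.exponential(size=k - 1)
    upicks = rng.random(size=2 * (k - 1))
    ev = 0
    while k > 1:
        rate = k * (k - 1) / 2.0 / ncopies
        t_next = t + waits[ev] / rate
        if t_end is not None and t_next > t_end:
            return next_id
        t = t_next
        i = int(upicks[2 * ev] * k)
        j = int(upicks[2 * ev + 1] * (k - 1))
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        parent[a] = next_id
        parent[b] = next_id
        times[next_id] = t
        lo, hi = (i, j) if i < j else (j, i)
        lineages[lo] = next_id
        lineages[hi] = lineages[-1]
        lineages.pop()
        next_id += 1
        k -= 1
        ev += 1
    return next_id


def single_population_genealogy(n: int, N: float, marker_kind: str, rng) -> Genealogy:
    """Panmictic constant-size coalescent genealogy for ``n`` lineages."""
    if n < 1:
        raise ParameterError("need at least one sampled lineage")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    _coalesce_phase(list(range(n)), _gene_copies(N, marker_kind), 0.0, None, parent, times, n, rng)
    return Genealogy(parent, times, n)


def simulate_genealogy(
    scenario: DemographicScenario,
    params: ScenarioParams,
    samples_per_cluster: tuple[int, int],
    marker_kind: str,
    rng: np.random.Generator,
) -> Genealogy:
    """Genealogy of ``samples_per_cluster`` = (nNorth, nSouth) gene copies.

    Tips 0..nN-1 belong to the North cluster, the rest to South. Times are in
    generations.
    """
    params.validate(scenario)
    nN, nS = samples_per_cluster
    if nN < 0 or nS < 0 or nN + nS < 1:
        raise ParameterError("sample sizes must be non-negative and sum to >= 1")
    gt = params.generation_time
    t_div = params.t_div / gt
    n = nN + nS
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    next_id = n
    north = list(range(nN))
    south = list(range(nN, n))
    if scenario.has_admixture:
        t_admix = params.t_admix / gt
        next_id = _coalesce_phase(north, _gene_copies(params.N1, marker_kind), 0.0, t_admix, parent, times, next_id, rng)
        next_id = _coalesce_phase(south, _gene_copies(params.N2, marker_kind), 0.0, t_admix, parent, times, next_id, rng)
        # 50:50 reassignment of every surviving lineage to precursor 3 or 4
        survivors = north + south
        pick = rng.random(len(survivors)) < params.admixture_proportion
        pop3 = [l for l, b in zip(survivors, pick) if b]
        pop4 = [l for l, b in zip(survivors, pick) if not b]
        next_id = _coalesce_phase(pop3, _gene_copies(params.N3, marker_kind), t_admix, t_div, parent, times, next_id, rng)
        next_id = _coalesce_phase(pop4, _gene_copies(params.N4, marker_kind), t_admix, t_div, parent, times, next_id, rng)
        remaining = pop3 + pop4
    else:
        next_id = _coalesce_phase(north, _gene_copies(params.N1, marker_kind), 0.0, t_div, parent, times, next_id, rng)
        next_id = _coalesce_phase(south, _gene_copies(params.N2, marker_kind), 0.0, t_div, parent, times, next_id, rng)
        remaining = north + south
    _coalesce_phase(remaining, _gene_copies(params.NA, marker_kind), t_div, None, parent, times, next_id, rng)
    return Genealogy(parent, times, n)


# ---------------------------------------------------------------------------
# mutation models

_TS_XOR = 2  # A<->G, C<->T under encoding A=0, C=1, G=2, T=3
BASES = np.frombuffer(b"ACGT", dtype="S1")


def mutate_sequence(
    gen: Genealogy, length_bp: int, useq: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Drop K2P mutations on a genealogy; returns (n_tips, length) uint8 codes.

    Per site and branch the number of mutation events is Poisson with mean
    useq * branch generations (so the branch total is Poisson with mean
    useq * length * branch, with events hitting sites uniformly); each event
    is a transition with probability kappa/(kappa+2) and each of the two
    transversions with probability 1/(kappa+2). Under the A=0,C=1,G=2,T=3
    encoding every event is an xor jump (transition = ^2, transversions =
    ^1/^3), and marginalising the Poisson event count analytically gives the
    per-site net-jump probabilities of the K2P chain over a branch of
    per-site intensity v = useq * t:

        P(jump 0) = (1 + e1 + 2 e2) / 4,  P(jump 2) = (1 + e1 - 2 e2) / 4,
        P(jump 1) = P(jump 3) = (1 - e1) / 4,

    with e1 = exp(v (l1 - 1)), e2 = exp(v (l2 - 1)), l1 = 2a - 1, l2 = -a,
    a = kappa/(kappa+2). Jumps are independent of the parental state, so the
    whole mutation field is drawn at once before propagating sequences down
    the tree. The root sequence is uniform over {A, C, G, T}.
    """
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    if useq < 0:
        raise ParameterError("useq must be non-negative")
    n_nodes = gen.n_nodes
    bl = gen.branch_lengths()
    alpha = kappa / (kappa + 2.0)
    l1, l2 = 2 * alpha - 1.0, -alpha
    v = useq * bl
    e1 = np.exp(v * (l1 - 1.0))
    e2 = np.exp(v * (l2 - 1.0))
    p_same = (0.25 * (1.0 + e1 + 2.0 * e2))[:, None]
    p_ts = (0.25 * (1.0 + e1 - 2.0 * e2))[:, None]
    p_tv = (0.25 * (1.0 - e1))[:, None]
    u = rng.random((n_nodes, length_bp))
    jump = np.zeros((n_nodes, length_bp), dtype=np.uint8)
    jump[u >= p_same] = 2
    jump[u >= p_same + p_ts] = 1
    jump[u >= p_same + p_ts + p_tv] = 3
    seqs = np.empty((n_nodes, length_bp), dtype=np.uint8)
    order = np.argsort(-gen.time, kind="stable")
    for node in order:
        par = gen.parent[node]
        if par < 0:
            seqs[node] = rng.integers(0, 4, size=length_bp, dtype=np.uint8)
        else:
            seqs[node] = seqs[par] ^ jump[node]
    return seqs[: gen.n_tips]


def codes_to_strings(codes: np.ndarray) -> list[str]:
    arr = BASES[codes]
    return [row.tobytes().decode() for row in arr]


def draw_gsm_steps(n: int, P_gsm: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` signed GSM mutation steps in motif units.

    Step magnitude is 1 + (Geometric(1 - P_gsm) - 1), i.e. geometric on
    {1, 2, ...} with mean 1/(1 - P_gsm); P_gsm = 0 reduces to the strict
    single-step model. Direction is +/- with probability 1/2.
    """
    if not 0 <= P_gsm < 1:
        raise ParameterError("P_gsm must lie in [0, 1)")
    sizes = rng.geometric(1.0 - P_gsm, size=n) if P_gsm > 0 else np.ones(n, dtype=np.int64)
    signs = np.where(rng.random(n) < 0.5, 1, -1)
    return sizes * signs


def fold_reflect(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Triangular fold of integer positions into [lo, hi] (billiard
    reflection at both boundaries)."""
    if hi == lo:
        return np.full_like(np.asarray(x), lo)
    period = 2 * (hi - lo)
    y = np.mod(np.asarray(x) - lo, period)
    y = np.where(y > hi - lo, period - y, y)
    return y + lo


# branches with at most this many mutation events get exact per-step draws;
# beyond it the signed-geometric sum uses a moment-matched normal draw (the
# walk has long since mixed over the folded allele range there)
_GSM_EXACT_MAX = 64


def mutate_microsat(
    gen: Genealogy,
    mu_locus: float,
    P_gsm: float,
    sni: float,
    rng: np.random.Generator,
    range_units: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized stepwise mutation along a genealogy.

    Returns (repeat_counts, sni_offsets) per tip. The ancestral repeat count
    sits mid-range; per-branch mutation counts are Poisson at rate
    ``mu_locus``; each mutation takes a signed step from
    :func:`draw_gsm_steps`, reflecting at the boundaries of a
    ``range_units``-unit contiguous allele range. Because step directions
    are symmetric, the reflected walk's endpoint is distributed as the
    triangular fold of the free walk's endpoint, so steps accumulate freely
    down the tree and tips are folded once. Independent single-nucleotide
    indels at rate ``sni`` shift fragment length by +/-1 bp outside the
    motif.
    """
    if not 0 <= P_gsm < 1:
        raise ParameterError("P_gsm must lie in [0, 1)")
    bl = gen.branch_lengths()
    n_nodes = gen.n_nodes
    m = rng.poisson(mu_locus * bl)
    delta = np.zeros(n_nodes, dtype=np.int64)
    small = np.flatnonzero((m > 0) & (m <= _GSM_EXACT_MAX))
    if small.size:
        steps = draw_gsm_steps(int(m[small].sum()), P_gsm, rng)
        bounds = np.concatenate([[0], np.cumsum(m[small])[:-1]])
        delta[small] = np.add.reduceat(steps, bounds)
    big = np.flatnonzero(m > _GSM_EXACT_MAX)
    if big.size:
        var_step = (1.0 + P_gsm) / (1.0 - P_gsm) ** 2
        delta[big] = np.rint(rng.normal(0.0, np.sqrt(m[big] * var_step))).astype(np.int64)
    msni = rng.poisson(sni * bl)
    sni_delta = 2 * rng.binomial(msni, 0.5) - msni
    # propagate free sums down the tree, then fold tips into the range
    walk = np.zeros(n_nodes, dtype=np.int64)
    offset = np.zeros(n_nodes, dtype=np.int64)
    order = np.argsort(-gen.time, kind="stable")
    root_repeat = range_units // 2
    for node in order:
        par = gen.parent[node]
        if par < 0:
            walk[node] = root_repeat
            offset[node] = 0
        else:
            walk[node] = walk[par] + delta[node]
            offset[node] = offset[par] + sni_delta[node]
    repeat = fold_reflect(walk[: gen.n_tips], 0, range_units - 1)
    return repeat, offset[: gen.n_tips]


# ---------------------------------------------------------------------------
# full dataset simulation


@dataclass
class SimDesign:
    """Sampling design for one simulated dataset.

    ``n_diploid`` are microsatellite sample sizes (diploid individuals) per
    cluster, ``n_seq`` mtDNA sample sizes (sequences) per cluster.
    """

    n_diploid: tuple[int, int] = (70, 70)
    n_seq: tuple[int, int] = (62, 61)
    n_loci: int = 13
    seq_length: int = 403
    motif_bp: int = 4
    base_length: int = 150
    range_units: int = 40
    mu_gamma_shape: float = 2.0
    mu_bounds: tuple[float, float] = (1e-7, 1e-2)


@dataclass
class SimulatedDataset:
    """Raw arrays from one simulation run.

    ``genotypes``: (n_ind, n_loci, 2) allele sizes in bp; ``sequences``:
    (n_seq, L) uint8 base codes; cluster labels are 0 = North, 1 = South.
    """

    genotypes: np.ndarray
    genotype_clusters: np.ndarray
    sequences: np.ndarray
    sequence_clusters: np.ndarray
    mu_mic: np.ndarray = field(default_factory=lambda: np.zeros(0))


def draw_locus_rates(
    mu_mean: float, n_loci: int, rng: np.random.Generator, shape: float = 2.0,
    bounds: tuple[float, float] = (1e-7, 1e-2),
) -> np.ndarray:
    """Per-locus rates ~ Gamma(shape, mu_mean/shape), truncated to bounds."""
    rates = rng.gamma(shape, mu_mean / shape, size=n_loci)
    return np.clip(rates, bounds[0], bounds[1])


def simulate_dataset(
    scenario: DemographicScenario,
    params: ScenarioParams,
    design: SimDesign,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """One joint microsatellite + mtDNA dataset under a scenario.

    Each autosomal locus gets an independent genealogy over 2x the diploid
    sample; gene copies are paired within cluster into individuals. One
    mitochondrial genealogy covers all sampled sequences.
    """
    params.validate(scenario)
    nN, nS = design.n_diploid
    mN, mS = design.n_seq
    mu = params.mu_mic
    if mu is None:
        mu = draw_locus_rates(params.mu_mic_mean, design.n_loci, rng,
                              design.mu_gamma_shape, design.mu_bounds)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (design.n_loci,):
        raise ParameterError("per-locus mutation rates must match n_loci")
    genotypes = np.zeros((nN + nS, design.n_loci, 2), dtype=np.int64)
    for l in range(design.n_loci):
        gen = simulate_genealogy(scenario, params, (2 * nN, 2 * nS), "autosomal", rng)
        repeat, off = mutate_microsat(gen, mu[l], params.P_gsm, params.sni, rng, design.range_units)
        sizes = design.base_length + design.motif_bp * repeat + off
        # copies 2i, 2i+1 form individual i within each cluster block
        genotypes[:, l, 0] = sizes[0::2]
        genotypes[:, l, 1] = sizes[1::2]
    genotypes = np.sort(genotypes, axis=2)
    gen_clusters = np.concatenate([np.zeros(nN, np.int64), np.ones(nS, np.int64)])
    if mN + mS > 0:
        gen_mt = simulate_genealogy(scenario, params, (mN, mS), "mitochondrial", rng)
        seqs = mutate_sequence(gen_mt, design.seq_length, params.useq, params.kappa, rng)
    else:
        seqs = np.zeros((0, design.seq_length), dtype=np.uint8)
    seq_clusters = np.concatenate([np.zeros(mN, np.int64), np.ones(mS, np.int64)])
    return SimulatedDataset(genotypes, gen_clusters, seqs, seq_clusters, mu)


def scenario_iv_equivalent(params: ScenarioParams) -> ScenarioParams:
    """Scenario-I parameters with t_admix = t_div collapse structurally to
    scenario IV; used for distributional-identity checks."""
    return replace(params, t_admix=params.t_div)
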