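"""Study-shaped pseudo-observed data with known ground truth.

The generator emulates the sampling design of the Andaman archipelago
survey: nine island populations grouped into a North and a South cluster,
13 tetranucleotide microsatellite loci typed for 140 diploid individuals
with ~7.4% missing calls, a 123-sequence COI alignment of 403 bp and a
17-sequence 16S panel. The demographic model operates at the cluster level
only; islands serve as labels and individuals are assigned to islands at
random within their cluster (the model has no island substructure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import coalsim
from .coalsim import DemographicScenario, ScenarioParams, SimDesign, simulate_dataset
from .iodata import (
    GenotypeMatrix,
    PopulationMap,
    SequenceAlignment,
    default_cluster_map,
)

#: Per-island microsatellite sample sizes. Table-2-listed islands carry their
#: printed n; Interview, Neil and Long are not printed individually and are
#: set to 2, 2 and 1 so the total is the study's 140 genotyped individuals.
DEFAULT_ISLAND_SIZES = {
    "North Andaman": 47,
    "Middle Andaman": 50,
    "Interview": 2,
    "Baratang": 11,
    "Neil": 2,
    "Long": 1,
    "Havelock": 9,
    "South Andaman": 12,
    "Little Andaman": 6,
}


@dataclass
class StudyDesign:
    """Sampling design mirroring the field study."""

    island_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ISLAND_SIZES))
    cluster_of: dict[str, str] = field(default_factory=default_cluster_map)
    n_loci: int = 13
    motif_bp: int = 4
    coi_n: int = 123
    coi_length: int = 403
    missingness: float = 0.074
    per_locus_missingness: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.island_sizes.values()):
            raise ValueError("island sample sizes must be positive")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must lie in [0, 1)")
        missing_cluster = set(self.island_sizes) - set(self.cluster_of)
        if missing_cluster:
            raise ValueError(f"islands without cluster assignment: {sorted(missing_cluster)}")

    def cluster_sizes(self) -> tuple[int, int]:
        north = sum(n for isl, n in self.island_sizes.items() if self.cluster_of[isl] == "North")
        south = sum(n for isl, n in self.island_sizes.items() if self.cluster_of[isl] == "South")
        return north, south

    def coi_cluster_sizes(self) -> tuple[int, int]:
        north, south = self.cluster_sizes()
        total = north + south
        n_coi = round(self.coi_n * north / total)
        return n_coi, self.coi_n - n_coi

    def sim_design(self) -> SimDesign:
        return SimDesign(
            n_diploid=self.cluster_sizes(),
            n_seq=self.coi_cluster_sizes(),
            n_loci=self.n_loci,
            seq_length=self.coi_length,
            motif_bp=self.motif_bp,
        )


def _assign_islands(design: StudyDesign, cluster: str, count: int, rng) -> list[str]:
    islands = [i for i in design.island_sizes if design.cluster_of[i] == cluster]
    weights = np.array([design.island_sizes[i] for i in islands], dtype=float)
    weights /= weights.sum()
    # deterministic counts proportional to design sizes, randomised remainder
    base = np.floor(weights * count).astype(int)
    short = count - base.sum()
    if short > 0:
        extra = rng.choice(len(islands), size=short, replace=True, p=weights)
        for e in extra:
            base[e] += 1
    labels = []
    for isl, b in zip(islands, base):
        labels.extend([isl] * int(b))
    rng.shuffle(labels)
    return labels


def generate_pseudoobserved(
    scenario: DemographicScenario,
    params: ScenarioParams,
    design: StudyDesign,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, SequenceAlignment, PopulationMap, dict]:
    """Simulate a study-shaped dataset and return observed-data containers.

    Simulates at the cluster level, distributes individuals over islands in
    proportion to the design's island sizes, masks genotype calls at the
    missingness rate (uniform, or per-locus if a rate vector is supplied)
    and returns the ground-truth parameters alongside.
    """
    sim = simulate_dataset(scenario, params, design.sim_design(), rng)
    nN, nS = design.cluster_sizes()
    north_islands = _exact_island_labels(design, "North")
    south_islands = _exact_island_labels(design, "South")
    rng.shuffle(north_islands)
    rng.shuffle(south_islands)
    pops = north_islands + south_islands
    individuals = [f"ind{i + 1:03d}" for i in range(nN + nS)]
    calls = sim.genotypes.copy()
    rates = design.per_locus_missingness
    if rates is None:
        mask = rng.random((len(individuals), design.n_loci)) < design.missingness
    else:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (design.n_loci,):
            raise ValueError("per-locus missingness vector must match n_loci")
        mask = rng.random((len(individuals), design.n_loci)) < rates[None, :]
    calls[mask] = -1
    G = GenotypeMatrix(individuals, [f"Pand_sim{l + 1}" for l in range(design.n_loci)], calls, pops)
    mN, mS = design.coi_cluster_sizes()
    seq_pops = _proportional_island_labels(design, "North", mN, rng) + \
        _proportional_island_labels(design, "South", mS, rng)
    seq_ids = [f"coi{i + 1:03d}" for i in range(mN + mS)]
    aln = SequenceAlignment(seq_ids, seq_pops, coalsim.codes_to_strings(sim.sequences))
    island_of = {ind: pop for ind, pop in zip(individuals, pops)}
    island_of.update({sid: pop for sid, pop in zip(seq_ids, seq_pops)})
    pm = PopulationMap(island_of, dict(design.cluster_of))
    truth = {
        "scenario": scenario.label,
        "params": {k: v for k, v in vars(params).items()
                   if v is not None and not isinstance(v, np.ndarray)},
        "mu_mic": sim.mu_mic.tolist(),
    }
    return G, aln, pm, truth


def _exact_island_labels(design: StudyDesign, cluster: str) -> list[str]:
    labels = []
    for isl, n in design.island_sizes.items():
        if design.cluster_of[isl] == cluster:
            labels.extend([isl] * n)
    return labels


def _proportional_island_labels(design: StudyDesign, cluster: str, count: int, rng) -> list[str]:
    return _assign_islands(design, cluster, count, rng)


# ---------------------------------------------------------------------------
# hand-checkable toy fixtures


def make_toy_fixtures() -> dict:
    """Tiny datasets whose expected statistics were derived by hand or by
    exhaustive enumeration; used throughout the test-suite examples.

    * ``he_toy``: two individuals (100/104), (100/100) at one locus ->
      unbiased He = 0.5, Ho = 0.5, FIS = 0.
    * ``mj_star``: binary haplotypes {000, 110, 101} -> one median vector
      100 and a three-edge star of total cost 3.
    * ``rarefy_49``: pool {A, A, B}; P(exactly 2 haplotypes in a draw of 2,
      with replacement) = 4/9.
    """
    he_toy = GenotypeMatrix(
        ["ind1", "ind2"], ["locusA"],
        np.array([[[100, 104]], [[100, 100]]]), ["PopX", "PopX"],
    )
    mj_star = SequenceAlignment(
        ["h1", "h2", "h3"], ["PopX", "PopX", "PopY"], ["AAA", "GGA", "GAG"],
    )
    rarefy_pool = SequenceAlignment(
        ["s1", "s2", "s3"], ["PopX", "PopX", "PopX"], ["A", "A", "C"],
    )
    return {
        "he_toy": {"data": he_toy, "expected": {"He": 0.5, "Ho": 0.5, "FIS": 0.0}},
        "mj_star": {"data": mj_star, "expected": {"median": "GAA", "n_edges": 3, "cost": 3}},
        "rarefy_49": {"data": rarefy_pool, "expected": {"p_exactly_2_of_2": 4.0 / 9.0}},
    }
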