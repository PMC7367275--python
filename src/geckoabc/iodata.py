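"""On-disk formats and the shared observed-data model.

Microsatellite genotypes are diploid fragment-length alleles (base pairs);
mtDNA data are equal-length alignments. Everything downstream (diversity
statistics, haplotype networks, ABC) consumes the three containers defined
here: :class:`GenotypeMatrix`, :class:`PopulationMap` and
:class:`SequenceAlignment`.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele call (whole-call missing only).
MISSING = -1

#: Default island -> cluster assignment for the Andaman archipelago study
#: system: the North cluster holds every island except Havelock, South
#: Andaman and Little Andaman.
NORTH_ISLANDS = (
    "North Andaman",
    "Middle Andaman",
    "Interview",
    "Baratang",
    "Neil",
    "Long",
)
SOUTH_ISLANDS = ("Havelock", "South Andaman", "Little Andaman")

VALID_CLUSTERS = ("North", "South")


class ParseError(ValueError):
    """Malformed input file."""


class LabelingError(ValueError):
    """Individual without a usable population label."""


@dataclass
class PopulationMap:
    """Maps individuals to islands and islands to North/South clusters."""

    island_of: dict[str, str]
    cluster_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cluster_of:
            self.cluster_of = default_cluster_map()
        bad = set(self.cluster_of.values()) - set(VALID_CLUSTERS)
        if bad:
            raise LabelingError(f"cluster labels must be in {VALID_CLUSTERS}, got {sorted(bad)}")

    def cluster_of_individual(self, ind: str) -> str:
        return self.cluster_of[self.island_of[ind]]

    def islands(self) -> list[str]:
        seen: dict[str, None] = {}
        for isl in self.island_of.values():
            seen.setdefault(isl, None)
        return list(seen)


def default_cluster_map() -> dict[str, str]:
    out = {isl: "North" for isl in NORTH_ISLANDS}
    out.update({isl: "South" for isl in SOUTH_ISLANDS})
    return out


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele-size calls with missingness.

    ``calls`` has shape (n_individuals, n_loci, 2) and holds allele sizes in
    base pairs; a missing call stores :data:`MISSING` in both slots. Calls are
    unordered pairs; parsers normalise them to (small, large).
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, loci_n = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, loci_n, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {loci_n}, 2)")
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if len(set(self.individuals)) != n:
            raise ValueError("individual IDs must be unique")
        if len(set(self.loci)) != loci_n:
            raise ValueError("locus names must be unique")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls must be coerced to MISSING before construction")
        nonmiss = self.calls[self.calls != MISSING]
        if nonmiss.size and (nonmiss <= 0).any():
            raise ValueError("allele sizes must be positive integers")
        # canonical order within call
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def is_missing(self) -> np.ndarray:
        """Boolean (n, L) mask of missing calls."""
        return self.calls[:, :, 0] == MISSING

    def missing_fraction(self) -> float:
        return float(self.is_missing().mean())


@dataclass
class SequenceAlignment:
    """Equal-length mtDNA sequences over {A,C,G,T,N,-} with population labels."""

    ids: list[str]
    populations: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence IDs must be unique")
        if not (len(self.ids) == len(self.populations) == len(self.sequences)):
            raise ValueError("ids, populations and sequences must align")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ParseError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        alphabet = set("ACGTN-")
        for sid, s in zip(self.ids, self.sequences):
            extra = set(s) - alphabet
            if extra:
                raise ParseError(f"sequence {sid} contains invalid characters {sorted(extra)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.sequences)

    def to_array(self) -> np.ndarray:
        """(n, length) byte matrix for vectorised site operations."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(self.n, self.length)


# ---------------------------------------------------------------------------
# genotype parsing / writing


def _decode_genepop_allele_pair(token: str, line_no: int) -> tuple[int, int]:
    if not re.fullmatch(r"\d{6}", token):
        raise ParseError(f"line {line_no}: allele field {token!r} is not 6 digits (3-digit "
                         "per-allele encoding required; 2-digit files are not supported)")
    a, b = int(token[:3]), int(token[3:])
    if a == 0 and b == 0:
        return (MISSING, MISSING)
    if a == 0 or b == 0:
        logger.warning("line %d: half-missing call %r coerced to MISSING", line_no, token)
        return (MISSING, MISSING)
    return (a, b)


def parse_genotypes(path, dialect: str = "genepop", popmap: PopulationMap | None = None) -> GenotypeMatrix:
    """Parse a genotype table in GENEPOP or CSV dialect.

    GENEPOP: 3-digit-per-allele encoding, ``000000`` missing; each ``Pop``
    block becomes a population labelled by the first individual's label when
    no ``popmap`` is supplied. CSV: columns ``individual,population,<locus...>``
    with calls ``a/b`` and missing as empty or ``NA``.
    """
    if dialect == "genepop":
        return _parse_genepop(path, popmap)
    if dialect == "csv":
        return _parse_genotype_csv(path, popmap)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_genepop(path, popmap: PopulationMap | None) -> GenotypeMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty GENEPOP file")
    # line 0 is the title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].replace(",", " ").split():
            loci.append(name)
        i += 1
    if not loci:
        raise ParseError("no locus names before first 'Pop'")
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    block = 0
    block_label = None
    while i < len(lines):
        line = lines[i]
        if line.strip().lower() == "pop":
            block += 1
            block_label = None
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise ParseError(f"line {i + 1}: expected 'name , alleles...'")
        name, rest = line.split(",", 1)
        name = name.strip()
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ParseError(f"line {i + 1}: {len(tokens)} allele fields for {len(loci)} loci")
        rows.append([_decode_genepop_allele_pair(t, i + 1) for t in tokens])
        individuals.append(name)
        if popmap is not None:
            if name not in popmap.island_of:
                raise LabelingError(f"individual {name!r} missing from population map")
            populations.append(popmap.island_of[name])
        else:
            if block_label is None:
                block_label = name
            populations.append(block_label)
        i += 1
    calls = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(individuals, loci, calls, populations)


def _parse_genotype_csv(path, popmap: PopulationMap | None) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ParseError("empty CSV genotype file")
        if [h.strip().lower() for h in header[:2]] != ["individual", "population"]:
            raise ParseError("CSV header must start with 'individual,population'")
        loci = [h.strip() for h in header[2:]]
        individuals, populations, rows = [], [], []
        for ln, rec in enumerate(reader, start=2):
            if not rec or not any(f.strip() for f in rec):
                continue
            if len(rec) != len(loci) + 2:
                raise ParseError(f"line {ln}: {len(rec) - 2} call fields for {len(loci)} loci")
            name = rec[0].strip()
            pop = rec[1].strip()
            if popmap is not None:
                if name not in popmap.island_of:
                    raise LabelingError(f"individual {name!r} missing from population map")
                pop = popmap.island_of[name]
            row = []
            for locus, cell in zip(loci, rec[2:]):
                cell = cell.strip()
                if cell in ("", "NA", "NaN", "-9"):
                    row.append((MISSING, MISSING))
                    continue
                m = re.fullmatch(r"(\d+)\s*/\s*(\d+)", cell)
                if not m:
                    raise ParseError(f"line {ln}: malformed call {cell!r} at locus {locus}")
                a, b = int(m.group(1)), int(m.group(2))
                if a == 0 or b == 0:
                    logger.warning("line %d: half-missing call %r coerced to MISSING", ln, cell)
                    row.append((MISSING, MISSING))
                else:
                    row.append((a, b))
            rows.append(row)
            individuals.append(name)
            populations.append(pop)
    calls = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(individuals, loci, calls, populations)


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "genepop", title: str = "geckoabc export") -> None:
    """Write a GenotypeMatrix; round-trips exactly through :func:`parse_genotypes`.

    The GENEPOP format has no population-name field, so recovering labels on
    re-parse requires passing the population map; the CSV dialect is
    self-contained.
    """
    if dialect == "genepop":
        if (G.calls[G.calls != MISSING] > 999).any():
            raise ValueError("allele size exceeds 3-digit GENEPOP encoding")
        with open(path, "w") as fh:
            fh.write(title + "\n")
            for locus in G.loci:
                fh.write(locus + "\n")
            # group consecutive individuals by population into Pop blocks
            prev = None
            for ind, pop, row in zip(G.individuals, G.populations, G.calls):
                if pop != prev:
                    fh.write("Pop\n")
                    prev = pop
                fields = []
                for a, b in row:
                    if a == MISSING:
                        fields.append("000000")
                    else:
                        fields.append(f"{a:03d}{b:03d}")
                fh.write(f"{ind} , " + " ".join(fields) + "\n")
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["individual", "population"] + list(G.loci))
            for ind, pop, row in zip(G.individuals, G.populations, G.calls):
                cells = ["NA" if a == MISSING else f"{a}/{b}" for a, b in row]
                w.writerow([ind, pop] + cells)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# population map CSV


def parse_popmap(path) -> PopulationMap:
    """CSV with columns individual,island[,cluster]."""
    island_of: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ParseError("empty population map")
        for rec in reader:
            if not rec or not any(f.strip() for f in rec):
                continue
            ind, island = rec[0].strip(), rec[1].strip()
            island_of[ind] = island
            if len(rec) > 2 and rec[2].strip():
                cluster_of[island] = rec[2].strip()
    return PopulationMap(island_of, cluster_of)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "island", "cluster"])
        for ind, isl in pm.island_of.items():
            w.writerow([ind, isl, pm.cluster_of.get(isl, "")])


# ---------------------------------------------------------------------------
# alignments


def parse_alignment(path, delimiter: str = "|") -> SequenceAlignment:
    """Parse a FASTA alignment; population label follows ``delimiter`` in the header."""
    ids, pops, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        if delimiter in header:
            sid, pop = header.split(delimiter, 1)
            sid, pop = sid.strip(), pop.strip()
        else:
            sid, pop = header.strip(), "unknown"
            logger.warning("header %r has no %r delimiter; population set to 'unknown'", header, delimiter)
        ids.append(sid)
        pops.append(pop)
        seqs.append(str(rec.seq))
    if not ids:
        raise ParseError(f"no FASTA records in {path}")
    return SequenceAlignment(ids, pops, seqs)


def write_alignment(aln: SequenceAlignment, path, delimiter: str = "|") -> None:
    records = [
        SeqRecord(Seq(s), id=f"{sid}{delimiter}{pop}", description="")
        for sid, pop, s in zip(aln.ids, aln.populations, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# network export


def export_network(net: nx.Graph, path, format: str = "gml") -> None:
    """Serialise a haplotype network (nodes carry ``kind`` and ``frequencies``).

    Per-population frequencies are stored as a JSON string attribute so that
    GML viewers and :func:`import_network` can recover them.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    if not nx.is_connected(net):
        raise ValueError("refusing to export a disconnected haplotype network")
    out = nx.Graph()
    for node, data in net.nodes(data=True):
        attrs = {
            "kind": data.get("kind", "sampled"),
            "frequencies": json.dumps(data.get("frequencies", {})),
        }
        if "sequence" in data:
            attrs["sequence"] = data["sequence"]
        out.add_node(str(node), **attrs)
    for u, v, data in net.edges(data=True):
        out.add_edge(str(u), str(v), mutations=int(data.get("mutations", 1)))
    if format == "gml":
        nx.write_gml(out, str(path))
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# node\tkind\tfrequencies\n")
            for node, data in out.nodes(data=True):
                fh.write(f"#N\t{node}\t{data['kind']}\t{data['frequencies']}\n")
            for u, v, data in out.edges(data=True):
                fh.write(f"{u}\t{v}\t{data['mutations']}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path, format: str = "gml") -> nx.Graph:
    if format == "gml":
        g = nx.read_gml(str(path))
        for _, data in g.nodes(data=True):
            data["frequencies"] = json.loads(data.get("frequencies", "{}"))
        for _, _, data in g.edges(data=True):
            data["mutations"] = int(data["mutations"])
        return g
    if format == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#N\t"):
                    _, node, kind, freqs = line.split("\t", 3)
                    g.add_node(node, kind=kind, frequencies=json.loads(freqs))
                elif line.startswith("#") or not line.strip():
                    continue
                else:
                    u, v, m = line.split("\t")
                    g.add_edge(u, v, mutations=int(m))
        return g
    raise ValueError(f"unknown format {format!r}")
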