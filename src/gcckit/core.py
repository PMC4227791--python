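"""Domain types and file formats for genome conformation capture (GCC) networks.

A GCC experiment digests cross-linked chromatin with a restriction enzyme
(AseI here, recognizing AT^TAAT), ligates spatially proximal fragments and
sequences the junctions.  The resulting data reduce to a weighted graph whose
nodes are restriction fragments and whose edge weights are capture counts.
This module holds the coordinate conventions (0-based, half-open everywhere),
the fragment / interval / network containers, an in-silico digest, and the
plain-text readers and writers (FASTA, BED, GFF3, TSV) the rest of the
package speaks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gcckit")

PHASES = ("G1", "G2", "M")

#: AseI recognition site and the offset of its cut on the forward strand.
ASEI_SITE = "ATTAAT"
ASEI_CUT_OFFSET = 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment; fragments tile each chromosome.

    ``unique`` marks fragments whose sequence maps to a unique genomic
    position.  Mappability is not re-derived here; the flag is an input
    attribute (the synthetic generator clears it for fragments buried in
    repeat annotation).
    """

    id: int
    chrom: str
    start: int
    end: int
    unique: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment {self.id}: "
                             f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAssembly:
    """Ordered chromosomes with lengths and (optionally) sequences."""

    def __init__(self, chromosomes: Sequence[tuple[str, int]],
                 sequences: Mapping[str, str] | None = None):
        names = [n for n, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has length {length}")
        self.chromosomes: list[tuple[str, int]] = [(n, int(l)) for n, l in chromosomes]
        self.lengths: dict[str, int] = {n: int(l) for n, l in chromosomes}
        self.sequences: dict[str, str] | None = None
        if sequences is not None:
            for name, length in self.chromosomes:
                if name not in sequences:
                    raise ValueError(f"missing sequence for {name}")
                if len(sequences[name]) != length:
                    raise ValueError(f"sequence length mismatch for {name}")
            self.sequences = {n: str(sequences[n]).upper() for n, _ in chromosomes}

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str],
                       order: Sequence[str] | None = None) -> "GenomeAssembly":
        names = list(order) if order is not None else list(sequences)
        return cls([(n, len(sequences[n])) for n in names], sequences)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeAssembly({len(self.chromosomes)} chromosomes, " \
               f"{self.total_length} bp)"


class FragmentMap:
    """Indexed collection of the restriction fragments of one genome.

    Fragments are stored in genome order (chromosome order, then start) and
    must tile each chromosome without gaps or overlaps.  Provides O(log n)
    position-to-fragment lookup via the tiling property.
    """

    def __init__(self, fragments: Sequence[RestrictionFragment],
                 genome: GenomeAssembly | None = None):
        self.fragments = list(fragments)
        self.by_id = {f.id: f for f in self.fragments}
        if len(self.by_id) != len(self.fragments):
            raise ValueError("duplicate fragment ids")
        self._by_chrom: dict[str, list[RestrictionFragment]] = {}
        for f in self.fragments:
            self._by_chrom.setdefault(f.chrom, []).append(f)
        self._starts: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        self._rank: dict[int, int] = {}
        for chrom, frs in self._by_chrom.items():
            frs.sort(key=lambda f: f.start)
            prev_end = 0
            for rank, f in enumerate(frs):
                if f.start != prev_end:
                    raise ValueError(
                        f"fragments do not tile {chrom}: gap/overlap at {f.start}")
                prev_end = f.end
                self._rank[f.id] = rank
            if genome is not None and prev_end != genome.lengths[chrom]:
                raise ValueError(f"fragments do not cover {chrom}")
            self._starts[chrom] = np.array([f.start for f in frs])
            self._ids[chrom] = np.array([f.id for f in frs])

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[RestrictionFragment]:
        return iter(self.fragments)

    def chrom_of(self, frag_id: int) -> str:
        return self.by_id[frag_id].chrom

    def rank_of(self, frag_id: int) -> int:
        """Index of the fragment within its chromosome (linear order)."""
        return self._rank[frag_id]

    def fragment_at(self, chrom: str, pos: int) -> RestrictionFragment:
        """Fragment containing base ``pos`` (tiling guarantees exactly one)."""
        frs = self._by_chrom.get(chrom)
        if frs is None:
            raise KeyError(f"unknown chromosome {chrom}")
        if not (0 <= pos < frs[-1].end):
            raise ValueError(f"position {chrom}:{pos} out of bounds")
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return frs[i]

    def fragments_overlapping(self, chrom: str, start: int,
                              end: int) -> list[RestrictionFragment]:
        frs = self._by_chrom.get(chrom)
        if frs is None:
            return []
        lo = max(int(np.searchsorted(self._starts[chrom], start, side="right")) - 1, 0)
        hi = int(np.searchsorted(self._starts[chrom], end, side="left"))
        return [f for f in frs[lo:hi] if f.start < end and start < f.end]

    def adjacent(self, id_a: int, id_b: int) -> bool:
        fa, fb = self.by_id[id_a], self.by_id[id_b]
        return fa.chrom == fb.chrom and abs(self._rank[id_a] - self._rank[id_b]) == 1


@dataclass(frozen=True)
class Interaction:
    """Unordered fragment pair with its capture count (``frag_a <= frag_b``)."""

    frag_a: int
    frag_b: int
    frequency: int

    def __post_init__(self) -> None:
        if self.frag_a == self.frag_b:
            raise ValueError("self-pairs are not interactions")
        if self.frag_a > self.frag_b:
            raise ValueError("interaction endpoints must satisfy frag_a <= frag_b")
        if self.frequency < 1:
            raise ValueError("observed interactions have frequency >= 1")


class InteractionNetwork:
    """Weighted fragment-pair graph for one cell-cycle phase.

    Pairs are canonically unordered (``frag_a <= frag_b``); duplicates merge
    by summing frequency.  ``fdr_cutoff`` records the significance threshold
    once it has been computed for this network.
    """

    def __init__(self, phase: str,
                 interactions: Iterable[Interaction] | Mapping[tuple[int, int], int] = (),
                 fdr_cutoff: int | None = None):
        self.phase = phase
        self.fdr_cutoff = fdr_cutoff
        self.n_self_pairs = 0
        self._freq: dict[tuple[int, int], int] = {}
        if isinstance(interactions, Mapping):
            for (a, b), f in interactions.items():
                self.add(a, b, f)
        else:
            for itx in interactions:
                self.add(itx.frag_a, itx.frag_b, itx.frequency)

    def add(self, frag_a: int, frag_b: int, frequency: int = 1) -> None:
        if frag_a == frag_b:
            raise ValueError("self-pairs are not interactions")
        key = (frag_a, frag_b) if frag_a < frag_b else (frag_b, frag_a)
        self._freq[key] = self._freq.get(key, 0) + int(frequency)

    def frequency(self, frag_a: int, frag_b: int) -> int:
        key = (frag_a, frag_b) if frag_a < frag_b else (frag_b, frag_a)
        return self._freq.get(key, 0)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self._freq)

    def items(self) -> Iterator[tuple[tuple[int, int], int]]:
        return iter(sorted(self._freq.items()))

    @property
    def interactions(self) -> list[Interaction]:
        return [Interaction(a, b, f) for (a, b), f in sorted(self._freq.items())]

    def __len__(self) -> int:
        return len(self._freq)

    @property
    def total_frequency(self) -> int:
        return sum(self._freq.values())

    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in sorted(self._freq.items())], dtype=int)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"InteractionNetwork(phase={self.phase!r}, "
                f"n={len(self)}, events={self.total_frequency})")


class ExpressionTable:
    """Per-gene transcript levels (FPKM-like) across cell-cycle phases.

    Thin wrapper around a pandas DataFrame with columns
    ``gene, chrom, start, end`` followed by one column per phase.
    """

    def __init__(self, frame: pd.DataFrame, phases: Sequence[str] = PHASES):
        required = ["gene", "chrom", "start", "end", *phases]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        if frame["gene"].duplicated().any():
            raise ValueError("one row per gene required")
        if (frame[list(phases)] < 0).any().any():
            raise ValueError("transcript levels must be nonnegative")
        if (frame["start"] >= frame["end"]).any():
            raise ValueError("invalid gene coordinates")
        self.frame = frame.reset_index(drop=True)
        self.phases = tuple(phases)
        #: optional record of planted gene-set memberships (synthetic tables)
        self.planted: dict[str, set[str]] = {}

    def levels(self, phase: str) -> pd.Series:
        return self.frame.set_index("gene")[phase]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def digest_genome(genome: GenomeAssembly, site: str = ASEI_SITE,
                  cut_offset: int = ASEI_CUT_OFFSET) -> FragmentMap:
    """In-silico restriction digest of every chromosome.

    Cut positions are ``match_start + cut_offset`` for each occurrence of
    ``site`` on the forward strand; for a palindromic site (AseI is one) a
    single forward scan finds every cut.  Fragment ids are assigned in genome
    order starting from 0.

    Raises ``ValueError`` for degenerate IUPAC codes in the site or a genome
    without sequences.
    """
    if not site:
        raise ValueError("empty restriction site")
    site = site.upper()
    if set(site) - set("ACGT"):
        raise ValueError(f"degenerate IUPAC codes unsupported in site {site!r}")
    if not (0 <= cut_offset <= len(site)):
        raise ValueError("cut_offset outside site")
    if genome.sequences is None:
        raise ValueError("genome has no sequences; cannot digest")

    fragments: list[RestrictionFragment] = []
    next_id = 0
    for chrom, length in genome.chromosomes:
        seq = genome.sequences[chrom]
        cuts = [0]
        i = seq.find(site)
        while i != -1:
            cut = i + cut_offset
            if 0 < cut < length:
                cuts.append(cut)
            i = seq.find(site, i + 1)
        cuts.append(length)
        cuts = sorted(set(cuts))
        for start, end in zip(cuts[:-1], cuts[1:]):
            fragments.append(RestrictionFragment(next_id, chrom, start, end))
            next_id += 1
    return FragmentMap(fragments, genome)


def assign_pairs_to_fragments(
        read_pairs: Iterable[tuple[str, int, str, int]],
        fragments: FragmentMap, phase: str = "NA") -> InteractionNetwork:
    """Map positioned read-pair coordinates onto fragment pairs.

    Each pair increments the count of the unordered fragment pair containing
    its two positions.  Pairs whose mates fall in the same fragment are not
    interactions; they are dropped and tallied on ``net.n_self_pairs``.
    """
    counts: Counter[tuple[int, int]] = Counter()
    n_self = 0
    for chrom_a, pos_a, chrom_b, pos_b in read_pairs:
        fa = fragments.fragment_at(chrom_a, pos_a).id
        fb = fragments.fragment_at(chrom_b, pos_b).id
        if fa == fb:
            n_self += 1
            continue
        counts[(min(fa, fb), max(fa, fb))] += 1
    net = InteractionNetwork(phase, {k: v for k, v in counts.items()})
    net.n_self_pairs = n_self
    if n_self:
        logger.info("assign_pairs_to_fragments: dropped %d self-pairs", n_self)
    return net


def filter_network(net: InteractionNetwork, fragments: FragmentMap,
                   min_frequency: int = 1, require_unique: bool = False,
                   drop_adjacent: bool = False) -> InteractionNetwork:
    """Significance / uniqueness / adjacency filter.

    Retains interactions with ``frequency >= min_frequency``; optionally
    requires both fragments to be uniquely positioned and removes pairs of
    fragments that are neighbours in the linear genome sequence.
    """
    if min_frequency < 1:
        raise ValueError("min_frequency must be >= 1")
    kept: dict[tuple[int, int], int] = {}
    for (a, b), f in net.items():
        if f < min_frequency:
            continue
        if require_unique and not (fragments.by_id[a].unique
                                   and fragments.by_id[b].unique):
            continue
        if drop_adjacent and fragments.adjacent(a, b):
            continue
        kept[(a, b)] = f
    out = InteractionNetwork(net.phase, kept, fdr_cutoff=net.fdr_cutoff)
    if min_frequency > 1:
        out.fdr_cutoff = min_frequency
    return out


def classify_inter_intra(net: InteractionNetwork, fragments: FragmentMap
                         ) -> tuple[InteractionNetwork, InteractionNetwork]:
    """Partition a network into inter- and intrachromosomal subnetworks."""
    inter: dict[tuple[int, int], int] = {}
    intra: dict[tuple[int, int], int] = {}
    for (a, b), f in net.items():
        bucket = intra if fragments.chrom_of(a) == fragments.chrom_of(b) else inter
        bucket[(a, b)] = f
    return (InteractionNetwork(net.phase, inter, net.fdr_cutoff),
            InteractionNetwork(net.phase, intra, net.fdr_cutoff))


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------

def write_fasta(genome: GenomeAssembly, path: str | Path) -> None:
    if genome.sequences is None:
        raise ValueError("genome has no sequences")
    records = [SeqRecord(Seq(genome.sequences[name]), id=name, description="")
               for name in genome.names]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> GenomeAssembly:
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeAssembly.from_sequences(seqs)


def write_fragments_bed(fragments: FragmentMap, path: str | Path) -> None:
    """Fragments as BED6; score column carries the uniqueness flag (1/0)."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tunique\tstrand\n")
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tF{f.id}\t"
                     f"{int(f.unique)}\t.\n")


def read_fragments_bed(path: str | Path,
                       genome: GenomeAssembly | None = None) -> FragmentMap:
    fragments = []
    for line in _data_lines(path):
        chrom, start, end, name, unique, _strand = line.split("\t")[:6]
        fragments.append(RestrictionFragment(
            int(name.lstrip("F")), chrom, int(start), int(end),
            bool(int(unique))))
    return FragmentMap(fragments, genome)


def write_loci_bed(loci: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                     f"{iv.strand or '.'}\n")


def read_loci_bed(path: str | Path) -> list[GenomicInterval]:
    loci = []
    for line in _data_lines(path):
        cols = line.split("\t")
        chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        name = cols[3] if len(cols) > 3 and cols[3] != "." else ""
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else None
        loci.append(GenomicInterval(chrom, start, end, name, strand))
    return loci


def read_gff3_genes(path: str | Path,
                    feature_type: str = "gene") -> list[GenomicInterval]:
    """Extract features of one type from a GFF3 file as intervals.

    GFF3 is 1-based inclusive; starts are converted to the package's 0-based
    half-open convention on read.
    """
    loci = []
    for line in _data_lines(path):
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9 or cols[2] != feature_type:
            continue
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        name = attrs.get("ID", attrs.get("Name", ""))
        strand = cols[6] if cols[6] in "+-" else None
        loci.append(GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]),
                                    name, strand))
    return loci


def write_interactions_tsv(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phase\tfrag_a\tfrag_b\tfrequency\n")
        for (a, b), f in net.items():
            fh.write(f"{net.phase}\t{a}\t{b}\t{f}\n")


def read_interactions_tsv(path: str | Path,
                          phase: str | None = None) -> InteractionNetwork:
    """Read one phase's interactions; validates as it goes.

    Malformed rows raise ``ValueError`` naming the file and line number.
    """
    freq: dict[tuple[int, int], int] = {}
    seen_phase = phase
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.startswith("phase\t"):
                continue
            try:
                ph, a, b, f = line.split("\t")
                a, b, f = int(a), int(b), int(f)
                if a == b or f < 1:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"corrupt interaction record at {path}:{lineno}: {line!r}")
            if phase is not None and ph != phase:
                continue
            if seen_phase is None:
                seen_phase = ph
            key = (min(a, b), max(a, b))
            freq[key] = freq.get(key, 0) + f
    return InteractionNetwork(seen_phase or "NA", freq)


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path,
                        phases: Sequence[str] = PHASES) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return ExpressionTable(frame, phases)


def _data_lines(path: str | Path) -> Iterator[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                yield line
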