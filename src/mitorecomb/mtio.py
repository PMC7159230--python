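"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ and GenBank flat files are handled through Biopython; the
signed multichromosomal gene-order dialect (one ``>organism`` header line,
then one whitespace-separated chromosome per line, ``-`` prefix for the
minus strand, trailing ``)`` marking a circular chromosome) is parsed and
written here. Spacer extraction — the complement of all annotated gene
intervals — also lives here because it is pure coordinate bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from . import intervals as iv

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                           "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


class FormatError(ValueError):
    """A file did not conform to the expected format."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single DNA molecule with explicit topology."""

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise FormatError(f"non-DNA characters in sequence {self.id!r}: {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps around the origin on circular molecules."""
        n = self.length
        if start < 1 or end > n:
            if self.topology != "circular":
                raise IndexError(f"[{start},{end}] outside linear molecule of {n} bp")
            return "".join(self.seq[(p - 1) % n] for p in range(start, end + 1))
        return self.seq[start - 1:end]

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.id + "_rc", revcomp(self.seq), self.topology)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature, possibly spliced over several intervals."""

    gene: str
    kind: str  # protein_coding | tRNA | rRNA | intron | other
    strand: str  # '+' or '-'
    intervals: Tuple[Tuple[int, int], ...]
    origin: str = "unknown"  # native | plastid_derived | unknown

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if s > e or s < 1:
                raise ValueError(f"feature {self.gene!r}: bad interval ({s},{e})")


@dataclass(frozen=True)
class SpacerSet:
    """Intergenic spacers: disjoint sorted intervals outside all genes."""

    intervals: Tuple[Tuple[int, int], ...]
    genome_length: int

    @property
    def total_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def fraction_of_genome(self) -> float:
        return self.total_bp / self.genome_length if self.genome_length else 0.0


@dataclass(frozen=True)
class Chromosome:
    genes: Tuple[Tuple[str, int], ...]  # (label, +1/-1)
    circular: bool


@dataclass(frozen=True)
class GeneOrder:
    organism: str
    chromosomes: Tuple[Chromosome, ...]

    def gene_multiset(self) -> List[str]:
        return [g for chrom in self.chromosomes for g, _ in chrom.genes]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def load_genome(path: str | Path, topology: str = "linear",
                record: Optional[str] = None) -> GenomeSequence:
    """Load one genome from a FASTA file.

    Multi-record files require an explicit ``record`` id; a single-record
    file needs none. Sequence is uppercased; IUPAC ambiguity codes pass
    through, anything else is a :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if record is None:
        if len(records) > 1:
            raise FormatError(
                f"{path}: {len(records)} records; pass record=<id> to select one")
        chosen = records[0]
    else:
        matches = [r for r in records if r.id == record]
        if not matches:
            raise FormatError(f"{path}: no record with id {record!r}")
        chosen = matches[0]
    return GenomeSequence(chosen.id, str(chosen.seq).upper(), topology)


def iter_reads(path: str | Path) -> Iterator[Tuple[str, str]]:
    """Yield (id, uppercased sequence) from a FASTA or FASTQ read database."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(p), fmt):
        yield rec.id, str(rec.seq).upper()


def write_fasta(path: str | Path, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# GenBank feature tables

_KIND_BY_TYPE = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA",
                 "intron": "intron", "gene": "other"}


def load_features(path: str | Path) -> List[FeatureRecord]:
    """Parse gene/CDS/tRNA/rRNA/intron features from a GenBank flat file.

    ``join``/``complement`` locations are decomposed into 1-based inclusive
    intervals. Duplicate gene names are preserved; deduplication is the
    caller's job.
    """
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank records") from None
    out: List[FeatureRecord] = []
    n = len(record.seq)
    for feat in record.features:
        if feat.type not in _KIND_BY_TYPE:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag")
                or quals.get("product") or ["?"])[0]
        try:
            parts = tuple(sorted(
                (int(part.start) + 1, int(part.end)) for part in feat.location.parts))
            strand = "-" if feat.location.strand == -1 else "+"
        except (TypeError, AttributeError) as exc:
            raise FormatError(
                f"{path}: malformed location for feature {name!r}: {exc}") from exc
        for s, e in parts:
            if s < 1 or e > n:
                raise FormatError(
                    f"{path}: feature {name!r} interval ({s},{e}) outside record of {n} bp")
        out.append(FeatureRecord(gene=name, kind=_KIND_BY_TYPE[feat.type],
                                 strand=strand, intervals=parts))
    return out


# ---------------------------------------------------------------------------
# Gene-order dialect


def _parse_gene_token(token: str, organism: str) -> Tuple[str, int]:
    if token.startswith("-"):
        name = token[1:]
        sign = -1
    else:
        name, sign = token, +1
    if not name:
        raise FormatError(f"organism {organism!r}: bare '-' is not a gene token")
    return name, sign


def load_gene_orders(path: str | Path) -> List[GeneOrder]:
    """Parse the signed multichromosomal gene-order dialect.

    ``>``-prefixed lines name organisms; every following non-empty line is
    one chromosome of whitespace-separated signed gene tokens, circular when
    the line ends with ``)`` (standalone token or suffix of the last gene).
    """
    organisms: List[GeneOrder] = []
    name: Optional[str] = None
    chroms: List[Chromosome] = []

    def flush() -> None:
        nonlocal chroms
        if name is not None:
            organisms.append(GeneOrder(name, tuple(chroms)))
        chroms = []

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise FormatError(f"{path}: organism header with empty name")
            continue
        if name is None:
            raise FormatError(f"{path}: gene line before any '>' organism header")
        tokens = line.split()
        circular = False
        if tokens[-1] == ")":
            circular = True
            tokens = tokens[:-1]
        elif tokens[-1].endswith(")"):
            circular = True
            tokens[-1] = tokens[-1][:-1]
        if not tokens:
            raise FormatError(f"organism {name!r}: chromosome with no genes")
        genes = tuple(_parse_gene_token(t, name) for t in tokens)
        chroms.append(Chromosome(genes, circular))
    flush()
    return organisms


def write_gene_orders(path: str | Path, orders: Sequence[GeneOrder]) -> None:
    """Write the dialect back out; ``)`` is emitted as a standalone token."""
    with open(path, "w") as fh:
        for order in orders:
            fh.write(f">{order.organism}\n")
            for chrom in order.chromosomes:
                tokens = [("-" if sign < 0 else "") + gene for gene, sign in chrom.genes]
                if chrom.circular:
                    tokens.append(")")
                fh.write(" ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# Spacer extraction


def extract_spacers(genome: GenomeSequence, features: Sequence[FeatureRecord]) -> SpacerSet:
    """Intergenic spacers: the complement of the union of all feature intervals.

    Exons and introns both count as genic, so the spacer fraction is measured
    against total gene length.
    """
    all_ivs = [interval for feat in features for interval in feat.intervals]
    for s, e in all_ivs:
        if e > genome.length:
            raise ValueError(f"feature interval ({s},{e}) outside genome of {genome.length} bp")
    return SpacerSet(tuple(iv.complement(all_ivs, genome.length)), genome.length)


def write_spacers_tsv(path: str | Path, spacers: SpacerSet) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\n")
        for s, e in spacers.intervals:
            fh.write(f"{s}\t{e}\t{e - s + 1}\n")
        fh.write(f"# total_bp={spacers.total_bp}"
                 f"\tfraction={spacers.fraction_of_genome:.4f}\n")
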