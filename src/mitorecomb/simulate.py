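"""Synthetic mitogenomes, recombination products, and long reads.

The generator emulates the inputs of a plant-mitogenome recombination
survey: a circular (or linear) genome of random background sequence with
planted direct/inverted repeat pairs of chosen length and identity, the
molecules produced by homologous recombination at a repeat (an inversion
for inverted pairs, sub-circles / an excision for direct pairs), and long
reads drawn from a weighted mixture of conformations with a lognormal
length distribution and an i.i.d. substitution/indel error model
(2:1:1 substitution:insertion:deletion). Every stochastic choice comes
from one seeded generator and is recorded in a ground-truth sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .mtio import GenomeSequence, revcomp
from .recombination import (ConformationSet, build_conformation_set,
                            count_read_support, screen_recombinants)
from .repeats import RepeatPair, classify_size

BASES = np.frombuffer(b"ACGT", dtype="S1")


class PackingError(RuntimeError):
    """Planted repeats could not be placed without forced overlap."""


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat pair to plant: unit length, target identity, orientation."""

    length: int
    identity: float = 100.0
    orientation: str = "direct"
    #: optional (start1, start2) 1-based positions; None = random placement
    positions: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError("planted repeats must be at least 50 bp")
        if not (85.0 < self.identity <= 100.0):
            raise ValueError("identity must be in (85, 100]")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"orientation {self.orientation!r}")


@dataclass(frozen=True)
class ReadRecord:
    """Ground truth for one simulated read."""

    name: str
    source: str  # conformation label
    role: str  # master | alternative | mixture component name
    start: int  # 1-based start on the source (before errors)
    strand: str  # '+' or '-'
    length: int  # error-free template length
    n_errors: int


@dataclass
class SyntheticTruth:
    """Everything needed to audit a simulated dataset."""

    seed: int
    genome_id: str
    repeats: List[RepeatPair] = field(default_factory=list)
    #: per conformation label: mixture weight
    weights: Dict[str, float] = field(default_factory=dict)
    #: per repeat id: planted alternative-conformation fraction
    alt_fractions: Dict[int, float] = field(default_factory=dict)
    reads: List[ReadRecord] = field(default_factory=list)

    def write_reads_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read\tsource\trole\tstart\tstrand\tlength\tn_errors\n")
            for r in self.reads:
                fh.write(f"{r.name}\t{r.source}\t{r.role}\t{r.start}\t"
                         f"{r.strand}\t{r.length}\t{r.n_errors}\n")


# ---------------------------------------------------------------------------
# genome generation


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _degrade(unit: np.ndarray, identity: float, rng: np.random.Generator) -> np.ndarray:
    """Introduce substitutions bringing the copy to the target identity.

    Substitutions are placed at distinct interior positions so the planted
    coordinates remain the maximal extent of the repeat.
    """
    n_sub = int(round((100.0 - identity) / 100.0 * len(unit)))
    if n_sub == 0:
        return unit.copy()
    if len(unit) < n_sub + 2:
        raise ValueError("unit too short for the requested identity")
    out = unit.copy()
    pos = rng.choice(np.arange(1, len(unit) - 1), size=n_sub, replace=False)
    for p in pos:
        choices = BASES[BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def generate_genome(length: int, specs: Sequence[RepeatSpec], seed: int,
                    gc: float = 0.5, topology: str = "circular",
                    margin: int = 1200,
                    max_tries: int = 500) -> Tuple[GenomeSequence, SyntheticTruth]:
    """A random genome with the given repeat pairs planted.

    ``margin`` bp around every planted copy are kept free of other copies so
    that conformation flanks never collide. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    arr = _random_background(length, gc, rng)
    occupied: List[Tuple[int, int]] = []  # 0-based inclusive, margin included

    def free(start: int, size: int) -> bool:
        if start < margin or start + size + margin > length:
            return False
        lo, hi = start - margin, start + size + margin - 1
        return all(hi < s or lo > e for s, e in occupied)

    truth = SyntheticTruth(seed=seed, genome_id=f"synthetic_{seed}")
    pairs: List[RepeatPair] = []
    for i, spec in enumerate(specs):
        if spec.positions is not None:
            starts = [spec.positions[0] - 1, spec.positions[1] - 1]
            if not all(free(s, spec.length) for s in starts):
                raise PackingError(f"requested positions for spec {i} ({spec!r}) "
                                   "collide with other planted repeats")
        else:
            starts = []
            for _copy in range(2):
                for _try in range(max_tries):
                    cand = int(rng.integers(margin, length - spec.length - margin))
                    if free(cand, spec.length) and all(
                            abs(cand - s) >= spec.length + margin for s in starts):
                        starts.append(cand)
                        break
                else:
                    raise PackingError(f"could not place spec {i} ({spec!r}) "
                                       f"after {max_tries} tries")
        starts.sort()
        s1, s2 = starts
        unit = arr[s1:s1 + spec.length].copy()
        copy2 = _degrade(unit, spec.identity, rng)
        n_sub = int((copy2 != unit).sum())
        if spec.orientation == "inverted":
            comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
            copy2 = np.array([comp[bytes(x)] for x in copy2[::-1]], dtype="S1")
        arr[s2:s2 + spec.length] = copy2
        occupied += [(s1, s1 + spec.length - 1), (s2, s2 + spec.length - 1)]
        realized_identity = round(100.0 * (spec.length - n_sub) / spec.length, 2)
        pairs.append(RepeatPair(
            id=i + 1, copy1=(s1 + 1, s1 + spec.length), copy2=(s2 + 1, s2 + spec.length),
            orientation=spec.orientation, identity=realized_identity,
            length=spec.length, size_class=classify_size(spec.length)))
    truth.repeats = pairs
    genome = GenomeSequence(truth.genome_id, arr.tobytes().decode(), topology)
    return genome, truth


# ---------------------------------------------------------------------------
# recombination products


def recombination_products(genome: GenomeSequence, pair: RepeatPair,
                           ) -> List[Tuple[GenomeSequence, List[Tuple[int, int]]]]:
    """Molecules produced by one recombination event at ``pair``.

    Returns ``(molecule, junction_spans)`` tuples where the spans are the
    1-based intervals of the repeat copies carrying recombinant junctions
    within each product. Crossover is taken at the copy boundaries, so the
    repeat units themselves are carried over unchanged.
    """
    (s1, e1), (s2, e2) = pair.copy1, pair.copy2
    if e1 >= s2:
        raise ValueError("recombination product ill-defined for nested or "
                         "overlapping repeat copies")
    g = genome.seq
    if pair.orientation == "inverted":
        # invert the segment strictly between the two copies
        product = g[:e1] + revcomp(g[e1:s2 - 1]) + g[s2 - 1:]
        mol = GenomeSequence(f"{genome.id}_inv{pair.id}", product, genome.topology)
        return [(mol, [pair.copy1, pair.copy2])]
    if genome.topology == "circular":
        sub1 = g[s1 - 1:s2 - 1]  # R1 + intervening segment
        sub2 = g[s2 - 1:] + g[:s1 - 1]  # R2 + remainder through the origin
        m1 = GenomeSequence(f"{genome.id}_sub1_{pair.id}", sub1, "circular")
        m2 = GenomeSequence(f"{genome.id}_sub2_{pair.id}", sub2, "circular")
        r1_len = e1 - s1 + 1
        r2_len = e2 - s2 + 1
        return [(m1, [(1, r1_len)]), (m2, [(1, r2_len)])]
    # linear: excision circle + deletion remainder
    deletion = g[:e1] + g[e2:]
    circle = g[e1:e2]  # intervening segment + R2
    m1 = GenomeSequence(f"{genome.id}_del{pair.id}", deletion, "linear")
    m2 = GenomeSequence(f"{genome.id}_circ{pair.id}", circle, "circular")
    m_len = s2 - 1 - e1
    return [(m1, [pair.copy1]), (m2, [(m_len + 1, m_len + (e2 - s2 + 1))])]


def apply_recombination(genome: GenomeSequence, pair: RepeatPair,
                        seed: Optional[int] = None) -> List[GenomeSequence]:
    """Public wrapper over :func:`recombination_products` (molecules only)."""
    return [mol for mol, _spans in recombination_products(genome, pair)]


# ---------------------------------------------------------------------------
# read simulation


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> Tuple[str, int]:
    """Apply i.i.d. errors (substitution:insertion:deletion = 2:1:1)."""
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1")
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hit) == 0:
        return seq, 0
    kinds = rng.choice(3, size=len(hit), p=[0.5, 0.25, 0.25])  # sub, ins, del
    out: List[bytes] = []
    prev = 0
    for pos, kind in zip(hit, kinds):
        out.append(arr[prev:pos].tobytes())
        base = arr[pos]
        if kind == 0:
            out.append(bytes(rng.choice(BASES[BASES != base])))
            prev = pos + 1
        elif kind == 1:
            out.append(base)
            out.append(bytes(rng.choice(BASES)))
            prev = pos + 1
        else:
            prev = pos + 1
    out.append(arr[prev:].tobytes())
    return b"".join(out).decode(), len(hit)


def _extract(mol: GenomeSequence, start0: int, length: int) -> str:
    """0-based extraction with circular wrap."""
    n = mol.length
    if mol.topology == "circular":
        start0 %= n
        if start0 + length <= n:
            return mol.seq[start0:start0 + length]
        return mol.seq[start0:] + mol.seq[:(start0 + length) - n]
    return mol.seq[start0:start0 + length]


def _lognormal_length(rng: np.random.Generator, mean_len: float, sigma: float) -> int:
    mu = math.log(mean_len) - sigma * sigma / 2.0
    return int(round(rng.lognormal(mu, sigma)))


def simulate_reads(conformations: Sequence[GenomeSequence],
                   weights: Sequence[float], n_reads: int,
                   mean_len: float = 15000.0, error_rate: float = 0.0,
                   seed: int = 0, sigma: float = 0.5,
                   ) -> Tuple[List[Tuple[str, str]], List[ReadRecord]]:
    """Long reads from a weighted mixture of conformations.

    Lengths are lognormal with the given mean; starts uniform (wrapping on
    circular molecules); strand uniform; errors i.i.d. at ``error_rate``.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(conformations):
        raise ValueError("one weight per conformation required")
    if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    if any(mean_len >= c.length for c in conformations):
        raise ValueError("mean read length must be below every conformation length")
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, str]] = []
    records: List[ReadRecord] = []
    for i in range(n_reads):
        src = int(rng.choice(len(conformations), p=w))
        mol = conformations[src]
        length = min(max(_lognormal_length(rng, mean_len, sigma), 50), mol.length)
        if mol.topology == "circular":
            start0 = int(rng.integers(0, mol.length))
        else:
            start0 = int(rng.integers(0, mol.length - length + 1))
        template = _extract(mol, start0, length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = revcomp(template)
        seq, n_err = _mutate(template, error_rate, rng)
        name = f"read_{i:06d}"
        reads.append((name, seq))
        records.append(ReadRecord(name, mol.id, mol.id, start0 + 1, strand,
                                  length, n_err))
    return reads, records


def simulate_pair_reads(genome: GenomeSequence, pair: RepeatPair,
                        alt_fraction: float, n_reads: int,
                        mean_len: float = 15000.0, error_rate: float = 0.0,
                        seed: int = 0, sigma: float = 0.5,
                        config: Optional[PipelineConfig] = None,
                        ) -> Tuple[List[Tuple[str, str]], List[ReadRecord]]:
    """Reads guaranteed to span one repeat locus, from a master/alternative mix.

    Each read comes from the master genome with probability
    ``1 - alt_fraction`` (spanning one of the two repeat copies, chosen
    uniformly) or from a recombination product (spanning one recombinant
    junction, chosen uniformly), and always covers the repeat unit plus the
    configured flank coverage on both sides — the reads a read-support
    counter can actually use.
    """
    config = config or PipelineConfig()
    if not 0.0 <= alt_fraction <= 1.0:
        raise ValueError("alt_fraction must be in [0, 1]")
    pad = 50
    fc = config.read_support_flank_cov
    master_loci = [(genome, span) for span in (pair.copy1, pair.copy2)]
    alt_loci = [(mol, span) for mol, spans in recombination_products(genome, pair)
                for span in spans]
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, str]] = []
    records: List[ReadRecord] = []
    for i in range(n_reads):
        is_alt = rng.random() < alt_fraction
        loci = alt_loci if is_alt else master_loci
        mol, span = loci[int(rng.integers(0, len(loci)))]
        win_s0 = span[0] - 1 - fc - pad
        win_e0 = span[1] - 1 + fc + pad
        win_len = win_e0 - win_s0 + 1
        if mol.length < win_len + 100:
            raise ValueError(f"molecule {mol.id} too short to span the repeat window")
        length = min(max(_lognormal_length(rng, mean_len, sigma), win_len + 100),
                     mol.length)
        lo, hi = win_e0 - length + 1, win_s0
        if mol.topology == "linear":
            lo, hi = max(lo, 0), min(hi, mol.length - length)
        start0 = int(rng.integers(lo, hi + 1))
        template = _extract(mol, start0, length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = revcomp(template)
        seq, n_err = _mutate(template, error_rate, rng)
        name = f"pair{pair.id}_read_{i:06d}"
        reads.append((name, seq))
        records.append(ReadRecord(name, mol.id,
                                  "alternative" if is_alt else "master",
                                  start0 % mol.length + 1, strand, length, n_err))
    return reads, records


def write_reads_fastq(path: str | Path, reads: Sequence[Tuple[str, str]],
                      quality: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# recovery evaluation


def estimate_pair_fractions(genome: GenomeSequence, truth: SyntheticTruth,
                            reads_by_pair: Dict[int, Sequence[Tuple[str, str]]],
                            config: Optional[PipelineConfig] = None):
    """Run the read-support counter on simulated reads for each planted pair."""
    config = config or PipelineConfig()
    results = []
    for pair in truth.repeats:
        confs = screen_recombinants(
            build_conformation_set(pair, genome, config), genome, config)
        results.append(count_read_support(confs, reads_by_pair[pair.id], config))
    return results


def evaluate_recovery(results, truth: SyntheticTruth):
    """Compare estimated alternative fractions with the planted mixture.

    ``results`` is a list of read-support results (one per planted repeat).
    Raises when a result's pair id is not a planted repeat.
    """
    import pandas as pd

    planted_ids = {p.id for p in truth.repeats}
    rows = []
    for res in results:
        if res.pair_id not in planted_ids:
            raise ValueError(f"result for unknown repeat id {res.pair_id}")
        planted = truth.alt_fractions.get(res.pair_id, 0.0)
        total = res.reads_master + res.reads_alternative
        est = res.reads_alternative / total if total else float("nan")
        rows.append({
            "pair_id": res.pair_id,
            "planted_fraction": planted,
            "estimated_fraction": est,
            "abs_error": abs(est - planted) if total else float("nan"),
            "n_reads": total,
            "planted_active": planted > 0,
            "called_active": res.active,
        })
    return pd.DataFrame(rows)
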