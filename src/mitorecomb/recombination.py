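"""Repeat-mediated recombination detection from long reads.

For every repeat pair the genome (master) arrangement and the putative
recombination products are represented as *conformation references*: each
repeat copy with up to ``flank_len`` bp of upstream and downstream context.
With flanks A/B around copy 1 and C/D around copy 2 (copy 2 viewed in the
orientation that makes the two repeat units collinear), the two masters are
A–R1–B and C–R2–D and the alternatives are the recombinant junction
products of the {A,C} x {R1,R2} x {B,D} cross product: two of them when the
copies are identical (a single distinguishable repeat unit R), six when
identity < 100%.

Alternatives that themselves align to the genome — e.g. the A–R2–B style
shuffles of a high-identity pair, or products of adjacent copies — are
screened out, and the surviving references are scored against a long-read
database: a read supports a reference when one alignment (either strand)
exceeds the identity threshold and covers the repeat plus at least
``read_support_flank_cov`` bp of both flanks. Each read is counted once per
repeat pair, for its best-scoring reference; a repeat is *recombinationally
active* when at least one read supports an alternative conformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .alignment import AlignmentResult, infix_alignment
from .config import PipelineConfig
from .mtio import GenomeSequence, revcomp
from .repeats import RepeatPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceConformation:
    """One flanked reference sequence: flank + repeat copy + flank."""

    role: str  # master | alternative
    label: str  # e.g. "A-R1-B"
    seq: str
    #: 1-based inclusive span of the repeat unit within ``seq``
    repeat_span: Tuple[int, int]
    #: genomic provenance of the three segments, for audit output
    sources: Tuple[str, str, str] = ("", "", "")
    flank_overlaps_partner: bool = False


@dataclass(frozen=True)
class ConformationSet:
    pair: RepeatPair
    references: Tuple[ReferenceConformation, ...]

    @property
    def n_master(self) -> int:
        return sum(1 for r in self.references if r.role == "master")

    @property
    def n_alternative(self) -> int:
        return sum(1 for r in self.references if r.role == "alternative")


@dataclass(frozen=True)
class ReadSupportResult:
    pair_id: int
    reads_master: int
    reads_alternative: int

    @property
    def alt_percent(self) -> Optional[float]:
        return _pct(self.reads_alternative, self.reads_master)

    @property
    def master_percent(self) -> Optional[float]:
        return _pct(self.reads_master, self.reads_alternative)

    @property
    def active(self) -> bool:
        return self.reads_alternative >= 1


def _pct(part: int, other: int) -> Optional[float]:
    total = part + other
    if total == 0:
        return None
    raw = Decimal(100 * part) / Decimal(total)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# conformation construction


def _flank(genome: GenomeSequence, start: int, end: int,
           config: PipelineConfig) -> str:
    """Fetch a flank, wrapping on circular molecules, truncating on linear."""
    if genome.topology == "linear":
        t_start, t_end = max(1, start), min(genome.length, end)
        if (t_start, t_end) != (start, end):
            warnings.warn(
                f"flank [{start},{end}] truncated to [{t_start},{t_end}] at a "
                f"linear genome end")
        if t_end < t_start:
            return ""
        start, end = t_start, t_end
    seq = genome.fetch(start, end)
    if len(seq) < config.read_support_flank_cov:
        raise ValueError(
            f"flank of {len(seq)} bp is shorter than the required "
            f"{config.read_support_flank_cov} bp of read flank coverage; "
            "repeat too close to a linear genome end for this configuration")
    return seq


def build_conformation_set(pair: RepeatPair, genome: GenomeSequence,
                           config: Optional[PipelineConfig] = None) -> ConformationSet:
    """The 4 (identity = 100) or 8 (identity < 100) flanked references of a pair."""
    config = config or PipelineConfig()
    (s1, e1), (s2, e2) = pair.copy1, pair.copy2
    fl = config.flank_len
    a = _flank(genome, s1 - fl, s1 - 1, config)
    b = _flank(genome, e1 + 1, e1 + fl, config)
    c = _flank(genome, s2 - fl, s2 - 1, config)
    d = _flank(genome, e2 + 1, e2 + fl, config)
    r1 = genome.fetch(s1, e1)
    r2 = genome.fetch(s2, e2)

    def overlaps(f_start: int, f_end: int, copy: Tuple[int, int]) -> bool:
        return not (f_end < copy[0] or f_start > copy[1])

    flank_overlap = (overlaps(s1 - fl, s1 - 1, pair.copy2)
                     or overlaps(e1 + 1, e1 + fl, pair.copy2)
                     or overlaps(s2 - fl, s2 - 1, pair.copy1)
                     or overlaps(e2 + 1, e2 + fl, pair.copy1))
    if flank_overlap:
        logger.info("pair %d: a flank overlaps the partner copy", pair.id)

    if pair.orientation == "direct":
        u1, p1, v1 = a, r1, b
        u2, p2, v2 = c, r2, d
        src = {"U1": "A", "V1": "B", "U2": "C", "V2": "D", "P1": "R1", "P2": "R2"}
    else:
        # view copy 2 on the strand that makes the repeat units collinear
        u1, p1, v1 = a, r1, b
        u2, p2, v2 = revcomp(d), revcomp(r2), revcomp(c)
        src = {"U1": "A", "V1": "B", "U2": "rc(D)", "V2": "rc(C)",
               "P1": "R1", "P2": "rc(R2)"}

    def ref(role: str, u_key: str, p_key: str, v_key: str) -> ReferenceConformation:
        u = {"U1": u1, "U2": u2}[u_key]
        p = {"P1": p1, "P2": p2}[p_key]
        v = {"V1": v1, "V2": v2}[v_key]
        return ReferenceConformation(
            role=role, label=f"{src[u_key]}-{src[p_key]}-{src[v_key]}",
            seq=u + p + v, repeat_span=(len(u) + 1, len(u) + len(p)),
            sources=(src[u_key], src[p_key], src[v_key]),
            flank_overlaps_partner=flank_overlap)

    masters = [
        # masters are emitted as forward-strand genome substrings
        ReferenceConformation("master", "A-R1-B", a + r1 + b,
                              (len(a) + 1, len(a) + len(r1)), ("A", "R1", "B"),
                              flank_overlap),
        ReferenceConformation("master", "C-R2-D", c + r2 + d,
                              (len(c) + 1, len(c) + len(r2)), ("C", "R2", "D"),
                              flank_overlap),
    ]
    if pair.identity == 100.0:
        alternatives = [ref("alternative", "U1", "P1", "V2"),
                        ref("alternative", "U2", "P1", "V1")]
    else:
        alternatives = [ref("alternative", u_key, p_key, v_key)
                        for u_key in ("U1", "U2")
                        for p_key in ("P1", "P2")
                        for v_key in ("V1", "V2")
                        if not (u_key == "U1" and p_key == "P1" and v_key == "V1")
                        and not (u_key == "U2" and p_key == "P2" and v_key == "V2")]
    return ConformationSet(pair=pair, references=tuple(masters + alternatives))


# ---------------------------------------------------------------------------
# genome screening


def _aligns_to(seq: str, target: str, min_identity: float) -> bool:
    k = int(len(seq) * (1 - min_identity / 100.0) * 1.5) + 8
    hit = infix_alignment(seq, target, max_distance=k)
    return hit is not None and hit.identity >= min_identity


def screen_recombinants(confs: ConformationSet, genome: GenomeSequence,
                        config: Optional[PipelineConfig] = None) -> ConformationSet:
    """Drop alternative references that are themselves present in the genome.

    An alternative is removed when its full sequence (recombinant junction
    included) aligns to the genome on either strand at the configured
    screening identity; masters are never removed.
    """
    config = config or PipelineConfig()
    max_len = max(len(r.seq) for r in confs.references)
    fwd = genome.seq
    if genome.topology == "circular" and genome.length > max_len:
        fwd = genome.seq + genome.seq[:max_len]  # see junctions across the origin
    rev = revcomp(fwd)
    kept: List[ReferenceConformation] = []
    for r in confs.references:
        if r.role == "master":
            kept.append(r)
            continue
        if _aligns_to(r.seq, fwd, config.screen_identity) or \
           _aligns_to(r.seq, rev, config.screen_identity):
            logger.info("pair %d: alternative %s located in genome, removed",
                        confs.pair.id, r.label)
            continue
        kept.append(r)
    return ConformationSet(pair=confs.pair, references=tuple(kept))


# ---------------------------------------------------------------------------
# read support


def _support_hit(read_seq: str, ref: ReferenceConformation,
                 config: PipelineConfig) -> Optional[AlignmentResult]:
    """Best qualifying alignment of the required window of ``ref`` in the read.

    The window is the repeat unit plus ``read_support_flank_cov`` bp of each
    flank; a single alignment of the whole window (no HSP chaining) at
    identity above the threshold qualifies.
    """
    fc = config.read_support_flank_cov
    span_s, span_e = ref.repeat_span
    window = ref.seq[span_s - 1 - fc: span_e + fc]
    if len(window) != (span_e - span_s + 1) + 2 * fc:
        raise ValueError("reference flanks shorter than the required coverage; "
                         "rebuild the conformation set with a larger flank_len")
    if len(read_seq) < len(window):
        return None
    k = int(len(window) * (1 - config.read_support_identity / 100.0) * 1.3) + 8
    best: Optional[AlignmentResult] = None
    for target in (read_seq, revcomp(read_seq)):
        hit = infix_alignment(window, target, max_distance=k)
        if hit is None or hit.identity <= config.read_support_identity:
            continue
        if best is None or hit.distance < best.distance:
            best = hit
    return best


def read_supports_reference(read_seq: str, ref: ReferenceConformation,
                            config: Optional[PipelineConfig] = None) -> bool:
    """Does one read support one conformation reference?"""
    return _support_hit(read_seq, ref, config or PipelineConfig()) is not None


def count_read_support(confs: ConformationSet,
                       reads: Iterable[Tuple[str, str]],
                       config: Optional[PipelineConfig] = None) -> ReadSupportResult:
    """Assign each read to its single best-supported reference and tally roles.

    Ties break toward master, then toward the lowest reference index, so the
    active flag is conservative.
    """
    config = config or PipelineConfig()
    n_master = n_alt = 0
    for _read_id, seq in reads:
        best_key = None
        best_role = None
        for idx, ref in enumerate(confs.references):
            hit = _support_hit(seq, ref, config)
            if hit is None:
                continue
            key = (hit.distance, 0 if ref.role == "master" else 1, idx)
            if best_key is None or key < best_key:
                best_key = key
                best_role = ref.role
        if best_role == "master":
            n_master += 1
        elif best_role == "alternative":
            n_alt += 1
    return ReadSupportResult(pair_id=confs.pair.id, reads_master=n_master,
                             reads_alternative=n_alt)


def recombination_table(pairs: Sequence[RepeatPair], genome: GenomeSequence,
                        reads: Iterable[Tuple[str, str]],
                        config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Per-pair recombination frequency table, sorted by descending length."""
    config = config or PipelineConfig()
    read_list = list(reads)
    rows = []
    for pair in sorted(pairs, key=lambda p: (-p.length, p.copy1)):
        confs = screen_recombinants(
            build_conformation_set(pair, genome, config), genome, config)
        res = count_read_support(confs, read_list, config)
        rows.append({
            "repeat_no": pair.id, "repeat_length": pair.length,
            "identity": pair.identity,
            "copy1_start": pair.copy1[0], "copy1_end": pair.copy1[1],
            "copy2_start": pair.copy2[0], "copy2_end": pair.copy2[1],
            "direction": pair.orientation.capitalize(),
            "reads_alternative": res.reads_alternative,
            "alt_percent": res.alt_percent,
            "reads_master": res.reads_master,
            "master_percent": res.master_percent,
            "active": res.active,
        })
    return pd.DataFrame(rows)
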