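"""Repeat discovery and the repeat census.

The scan is a genome self-vs-self local-alignment search: blastn nominates
candidate pairs, which are then *polished* — terminal non-matching columns
trimmed, then both copies extended outward while bases match exactly — so
every reported pair is a maximal repeat whose coordinates do not depend on
engine internals. Each pair is re-verified by a direct edlib global
alignment of its two copies; identity is matches / alignment columns with
gaps counted and N never matching.

Size classes follow the plant-mitogenome census convention: small
[50, 100) bp, medium [100, 1000] bp, large > 1000 bp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from . import intervals as iv
from .alignment import blastn_self_scan, global_alignment
from .config import PipelineConfig
from .mtio import GenomeSequence, revcomp

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RepeatPair:
    """Two genomic copies of a repeated sequence (1-based inclusive)."""

    id: int
    copy1: Tuple[int, int]
    copy2: Tuple[int, int]
    orientation: str  # direct | inverted
    identity: float  # percent, 2 decimals
    length: int  # alignment columns of the repeat unit
    size_class: str = "small"

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"orientation {self.orientation!r}")
        if self.copy1[0] > self.copy2[0]:
            raise ValueError("copy1 must start at or before copy2 (canonical order)")


@dataclass(frozen=True)
class RepeatSummary:
    n_pairs: int
    n_small: int
    n_medium: int
    n_large: int
    gross_bp: int
    gross_fraction: float


def classify_size(length: int, config: Optional[PipelineConfig] = None) -> str:
    config = config or PipelineConfig()
    if length < config.min_repeat_len:
        raise ValueError(f"repeat length {length} below minimum {config.min_repeat_len}")
    if length < config.size_class_small_max:
        return "small"
    if length <= config.size_class_medium_max:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# candidate polishing (0-based inclusive internally)


def _expand_cigar(cigar: str):
    import re
    return [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cigar)]


#: repeat boundaries must end in at least this many exactly matching columns;
#: shorter terminal match runs (chance tails beyond the true boundary) are
#: trimmed together with the mismatch/gap block that precedes them
_END_ANCHOR = 8


def _trim_to_matches(ops, anchor: int = _END_ANCHOR):
    """Trim alignment ends to a solid exact anchor.

    Strips leading/trailing non-match columns and any terminal match run
    shorter than ``anchor`` columns (recursively). Returns the remaining ops
    and the consumed (query, target) bases at each end.
    """
    lead_q = lead_t = tail_q = tail_t = 0

    def consume_front():
        nonlocal lead_q, lead_t
        n, op = ops.pop(0)
        if op in ("X", "M", "=", "I"):
            lead_q += n
        if op in ("X", "M", "=", "D"):
            lead_t += n

    def consume_back():
        nonlocal tail_q, tail_t
        n, op = ops.pop()
        if op in ("X", "M", "=", "I"):
            tail_q += n
        if op in ("X", "M", "=", "D"):
            tail_t += n

    changed = True
    while changed and ops:
        changed = False
        while ops and ops[0][1] != "=":
            consume_front()
            changed = True
        if ops and ops[0][1] == "=" and ops[0][0] < anchor and len(ops) > 1:
            consume_front()
            changed = True
        while ops and ops[-1][1] != "=":
            consume_back()
            changed = True
        if ops and ops[-1][1] == "=" and ops[-1][0] < anchor and len(ops) > 1:
            consume_back()
            changed = True
    return ops, lead_q, lead_t, tail_q, tail_t


def _polish(genome: str, c1, c2, orientation: str):
    """Trim to matching ends, then extend both copies to exact maximality.

    Intervals are 0-based inclusive. Returns (c1, c2) or None when nothing
    alignable remains.
    """
    n = len(genome)
    (a1, b1), (a2, b2) = c1, c2
    s1 = genome[a1:b1 + 1]
    s2 = genome[a2:b2 + 1]
    if orientation == "inverted":
        s2 = revcomp(s2)
    res = global_alignment(s1, s2)
    ops, lead_q, lead_t, tail_q, tail_t = _trim_to_matches(_expand_cigar(res.cigar))
    if not ops:
        return None
    a1 += lead_q
    b1 -= tail_q
    if orientation == "direct":
        a2 += lead_t
        b2 -= tail_t
    else:  # leading columns of rc(copy2) sit at the genomic END of copy2
        b2 -= lead_t
        a2 += tail_t

    def match(x: str, y: str) -> bool:
        return x == y and x in "ACGT"

    if orientation == "direct":
        while a1 > 0 and a2 > 0 and match(genome[a1 - 1], genome[a2 - 1]):
            a1 -= 1
            a2 -= 1
        while b1 < n - 1 and b2 < n - 1 and match(genome[b1 + 1], genome[b2 + 1]):
            b1 += 1
            b2 += 1
    else:
        while (a1 > 0 and b2 < n - 1
               and match(genome[a1 - 1], _COMP.get(genome[b2 + 1], "?"))):
            a1 -= 1
            b2 += 1
        while (b1 < n - 1 and a2 > 0
               and match(genome[b1 + 1], _COMP.get(genome[a2 - 1], "?"))):
            b1 += 1
            a2 -= 1
    if b1 < a1 or b2 < a2:
        return None
    return (a1, b1), (a2, b2)


def _canonical(c1, c2, orientation):
    if (c1[0], c1[1]) > (c2[0], c2[1]):
        c1, c2 = c2, c1
    return c1, c2, orientation


def _verified_pair(genome: str, c1, c2, orientation: str,
                   config: PipelineConfig) -> Optional[RepeatPair]:
    """Re-align polished copies; keep only pairs passing the configured filters."""
    s1 = genome[c1[0]:c1[1] + 1]
    s2 = genome[c2[0]:c2[1] + 1]
    if orientation == "inverted":
        s2 = revcomp(s2)
    res = global_alignment(s1, s2)
    if res.columns < config.min_repeat_len or res.identity <= config.min_repeat_identity:
        return None
    return RepeatPair(id=0,
                      copy1=(c1[0] + 1, c1[1] + 1), copy2=(c2[0] + 1, c2[1] + 1),
                      orientation=orientation,
                      identity=round(res.identity, 2), length=res.columns,
                      size_class=classify_size(res.columns, config))


def _diagonal(c1, c2, orientation):
    return c2[0] - c1[0] if orientation == "direct" else c1[0] + c2[1]


def find_repeat_pairs(genome: GenomeSequence,
                      config: Optional[PipelineConfig] = None) -> List[RepeatPair]:
    """All repeated sequence pairs of the genome passing the length/identity filters.

    Pairs are deduplicated under copy reordering and strand flip,
    self-alignments are excluded, and same-diagonal fragments of one repeat
    are merged to the maximal pair. Output is sorted by descending repeat
    length with 1-based ids.
    """
    config = config or PipelineConfig()
    if genome.length < 2 * config.min_repeat_len:
        warnings.warn(f"genome of {genome.length} bp is shorter than two "
                      f"minimum-length repeat copies; no scan performed")
        return []
    hits = blastn_self_scan(genome.seq, evalue=config.scan_evalue,
                            word_size=config.scan_word_size)
    seen = {}
    for row in hits.itertuples(index=False):
        q = (min(row.qstart, row.qend) - 1, max(row.qstart, row.qend) - 1)
        s = (min(row.sstart, row.send) - 1, max(row.sstart, row.send) - 1)
        orientation = "direct" if (row.sstart <= row.send) else "inverted"
        if orientation == "direct" and q == s:
            continue  # trivial self-identity hit
        c1, c2, orientation = _canonical(q, s, orientation)
        polished = _polish(genome.seq, c1, c2, orientation)
        if polished is None:
            continue
        c1, c2 = polished
        c1, c2, orientation = _canonical(c1, c2, orientation)
        if orientation == "direct" and c1 == c2:
            continue
        seen[(c1, c2, orientation)] = (c1, c2, orientation)

    # merge same-diagonal fragments of one underlying repeat
    merged = True
    while merged:
        merged = False
        keys = list(seen)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                (p1, p2, po), (q1, q2, qo) = keys[i], keys[j]
                if po != qo or keys[i] not in seen or keys[j] not in seen:
                    continue
                if abs(_diagonal(p1, p2, po) - _diagonal(q1, q2, qo)) > 10:
                    continue
                if (iv.overlap_length((p1[0] + 1, p1[1] + 1), (q1[0] + 1, q1[1] + 1)) == 0
                        or iv.overlap_length((p2[0] + 1, p2[1] + 1), (q2[0] + 1, q2[1] + 1)) == 0):
                    continue
                u1 = (min(p1[0], q1[0]), max(p1[1], q1[1]))
                u2 = (min(p2[0], q2[0]), max(p2[1], q2[1]))
                polished = _polish(genome.seq, u1, u2, po)
                if polished is None:
                    continue
                c1, c2 = polished
                c1, c2, orientation = _canonical(c1, c2, po)
                del seen[keys[i]]
                del seen[keys[j]]
                seen[(c1, c2, orientation)] = (c1, c2, orientation)
                merged = True
                break
            if merged:
                break

    pairs: List[RepeatPair] = []
    for c1, c2, orientation in seen.values():
        pair = _verified_pair(genome.seq, c1, c2, orientation, config)
        if pair is not None:
            pairs.append(pair)
    # dedup identical verified pairs (fragments polished to the same maximum)
    unique = {(p.copy1, p.copy2, p.orientation): p for p in pairs}
    ordered = sorted(unique.values(),
                     key=lambda p: (-p.length, p.copy1, p.copy2))
    return [replace(p, id=i + 1) for i, p in enumerate(ordered)]


def repeat_summary(pairs: Sequence[RepeatPair], genome: GenomeSequence) -> RepeatSummary:
    """Census of a pair list: per-class counts and gross genome coverage.

    ``gross_bp`` is the union length of all copy intervals — positions
    covered by several copies are counted once.
    """
    covered = [p.copy1 for p in pairs] + [p.copy2 for p in pairs]
    gross = iv.union_length(covered) if covered else 0
    counts = {"small": 0, "medium": 0, "large": 0}
    for p in pairs:
        counts[p.size_class] += 1
    return RepeatSummary(n_pairs=len(pairs), n_small=counts["small"],
                         n_medium=counts["medium"], n_large=counts["large"],
                         gross_bp=gross,
                         gross_fraction=gross / genome.length if genome.length else 0.0)


def pairs_to_frame(pairs: Sequence[RepeatPair]) -> pd.DataFrame:
    """Tabular view mirroring the published repeat-table column layout."""
    return pd.DataFrame([{
        "repeat_no": p.id, "repeat_length": p.length, "identity": p.identity,
        "copy1_start": p.copy1[0], "copy1_end": p.copy1[1],
        "copy2_start": p.copy2[0], "copy2_end": p.copy2[1],
        "direction": p.orientation.capitalize(), "size_class": p.size_class,
    } for p in pairs])


def write_repeats_tsv(path: str | Path, pairs: Sequence[RepeatPair]) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
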