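"""Alignment primitives shared by the scan, screening and read-support steps.

Two engines sit behind this module:

* **edlib** for pairwise identity: global (NW) alignment of two repeat
  copies, and infix (HW) search of a reference window inside a long read or
  of an alternative conformation inside the genome. Identity is always
  matches / alignment columns (gaps count as columns) and an ``N`` never
  counts as a match, even against another ``N``.
* **NCBI blastn** (subprocess) for genome-scale local-alignment search:
  the genome self-scan for repeats and the spacer homology scan. blastn
  only nominates candidates; every hit that matters downstream is
  re-verified with edlib, so the engine choice is not observable in valid
  outputs.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import pandas as pd

import edlib

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment with column-wise identity accounting."""

    distance: int
    columns: int
    matches: int
    cigar: str
    #: 0-based inclusive span of the alignment on the target
    target_start: int
    target_end: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def _cigar_stats(cigar: str, query: str, target: str) -> tuple[int, int]:
    """(columns, matches) for an edlib extended cigar of query vs target.

    ``target`` must be the exact aligned target segment. Matches exclude any
    column where either base is N.
    """
    qi = ti = columns = matches = 0
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            for k in range(n):
                if query[qi + k] != "N" and target[ti + k] != "N":
                    matches += 1
            qi += n
            ti += n
        elif op in ("X", "M"):
            qi += n
            ti += n
        elif op == "I":  # consumes query only
            qi += n
        else:  # 'D' consumes target only
            ti += n
    return columns, matches


def global_alignment(query: str, target: str) -> AlignmentResult:
    """Needleman–Wunsch alignment of two sequences (edlib NW)."""
    res = edlib.align(query, target, mode="NW", task="path")
    columns, matches = _cigar_stats(res["cigar"], query, target)
    return AlignmentResult(res["editDistance"], columns, matches, res["cigar"],
                           0, len(target) - 1)


def infix_alignment(query: str, target: str,
                    max_distance: int = -1) -> Optional[AlignmentResult]:
    """Best alignment of the whole ``query`` inside ``target`` (edlib HW).

    Returns ``None`` when no alignment within ``max_distance`` exists
    (``-1`` = unbounded).
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path", k=max_distance)
    if res["editDistance"] < 0:
        return None
    t0, t1 = res["locations"][0]
    if t0 is None:  # whole-query deletion corner case
        t0 = t1 + 1
    columns, matches = _cigar_stats(res["cigar"], query, target[t0:t1 + 1])
    return AlignmentResult(res["editDistance"], columns, matches, res["cigar"], t0, t1)


def pair_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two sequences."""
    return global_alignment(a, b).identity


# ---------------------------------------------------------------------------
# blastn

BLAST_COLUMNS = ["qseqid", "sseqid", "qstart", "qend", "sstart", "send",
                 "pident", "length", "evalue", "bitscore"]


def blastn_available() -> bool:
    return shutil.which("blastn") is not None


def blastn_pairwise(query_fasta: str | Path, subject_fasta: str | Path, *,
                    evalue: float = 10.0, word_size: Optional[int] = None,
                    dust: bool = False, task: str = "blastn") -> pd.DataFrame:
    """Run ``blastn -subject`` and return tabular hits.

    Coordinates are blastn's 1-based inclusive; minus-strand subject hits
    have ``sstart > send``.
    """
    if not blastn_available():
        raise RuntimeError("blastn not found on PATH; the local-alignment "
                           "search engine is required for this step")
    cmd = ["blastn", "-task", task,
           "-query", str(query_fasta), "-subject", str(subject_fasta),
           "-evalue", str(evalue),
           "-outfmt", "6 " + " ".join(BLAST_COLUMNS)]
    if word_size is not None:
        cmd += ["-word_size", str(word_size)]
    if not dust:
        cmd += ["-dust", "no", "-soft_masking", "false"]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
    rows: List[list] = []
    for line in proc.stdout.splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(BLAST_COLUMNS):
            continue
        rows.append(parts)
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    if len(df):
        for col in ("qstart", "qend", "sstart", "send", "length"):
            df[col] = df[col].astype(int)
        for col in ("pident", "evalue", "bitscore"):
            df[col] = df[col].astype(float)
    return df


def blastn_self_scan(seq: str, *, evalue: float, word_size: int) -> pd.DataFrame:
    """All-vs-self local alignments of one sequence (repeat candidates)."""
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "genome.fa"
        with open(fasta, "w") as fh:
            fh.write(">g\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
        return blastn_pairwise(fasta, fasta, evalue=evalue, word_size=word_size)
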