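"""Homology annotation of mitochondrial spacers and alignment-matrix statistics.

Plastid-derived (and inter-mitogenome shared) segments are found with a
blastn search of the mitochondrial genome against a subject genome at an
e-value cutoff; hits overlapping on the query are merged into maximal
disjoint segments annotated with the subject genes they carry. Supermatrix
bookkeeping for the phylogenomic section — per-gene concatenation with
missing-data fill and parsimony-informative site counting — also lives
here.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .alignment import blastn_pairwise
from .config import PipelineConfig
from .mtio import FeatureRecord, GenomeSequence, SpacerSet, write_fasta


@dataclass(frozen=True)
class HomologySegment:
    """One merged homology segment on the query genome."""

    query: Tuple[int, int]  # 1-based inclusive
    subject_id: str
    subject: Tuple[int, int]
    identity: float
    evalue: float
    carried_features: Tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.query[1] - self.query[0] + 1


@dataclass(frozen=True)
class MatrixStats:
    n_taxa: int
    n_columns: int
    missing_fraction: float
    pi_sites: int

    @property
    def pi_fraction(self) -> float:
        return self.pi_sites / self.n_columns if self.n_columns else 0.0


# ---------------------------------------------------------------------------
# homology segments


def _carried(feature_list: Sequence[FeatureRecord],
             coverage: List[Tuple[int, int]]) -> Tuple[str, ...]:
    """Subject genes overlapped by ``coverage``, '(partial)' when incomplete."""
    out = []
    for feat in feature_list:
        total = sum(e - s + 1 for s, e in feat.intervals)
        overlap = sum(e - s + 1 for s, e in iv.intersect(feat.intervals, coverage))
        if overlap == 0:
            continue
        start = min(s for s, _ in feat.intervals)
        suffix = "" if overlap == total else " (partial)"
        out.append((start, feat.gene + suffix))
    out.sort()
    seen = set()
    names = []
    for _, name in out:
        if name not in seen:
            seen.add(name)
            names.append(name)
    return tuple(names)


def find_homologous_segments(query: GenomeSequence, subject: GenomeSequence,
                             subject_features: Optional[Sequence[FeatureRecord]] = None,
                             config: Optional[PipelineConfig] = None,
                             ) -> List[HomologySegment]:
    """Merged local-alignment segments of ``query`` against ``subject``.

    Hits at e-value above the configured cutoff are discarded; hits
    overlapping by at least 1 bp on the query are merged into one segment,
    whose identity and e-value are those of its best (highest-identity)
    constituent hit. Carried features come from the subject annotation.
    """
    config = config or PipelineConfig()
    if subject.length == 0:
        return []
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        write_fasta(qpath, [(query.id, query.seq)])
        write_fasta(spath, [(subject.id, subject.seq)])
        hits = blastn_pairwise(qpath, spath, evalue=config.homology_evalue)
    if not len(hits):
        return []
    hits = hits[hits["evalue"] <= config.homology_evalue].copy()
    if not len(hits):
        return []
    hits["q_lo"] = hits[["qstart", "qend"]].min(axis=1)
    hits["q_hi"] = hits[["qstart", "qend"]].max(axis=1)
    hits = hits.sort_values(["q_lo", "q_hi"]).reset_index(drop=True)

    segments: List[HomologySegment] = []
    group: List[pd.Series] = []

    def flush(rows: List[pd.Series]) -> None:
        if not rows:
            return
        q_lo = min(int(r.q_lo) for r in rows)
        q_hi = max(int(r.q_hi) for r in rows)
        best = max(rows, key=lambda r: (r.pident, r.bitscore))
        coverage = [(min(int(r.sstart), int(r.send)), max(int(r.sstart), int(r.send)))
                    for r in rows]
        carried = _carried(subject_features or (), iv.merge(coverage))
        segments.append(HomologySegment(
            query=(q_lo, q_hi), subject_id=str(best.sseqid),
            subject=(min(int(best.sstart), int(best.send)),
                     max(int(best.sstart), int(best.send))),
            identity=float(best.pident), evalue=float(best.evalue),
            carried_features=carried))

    current_end = -1
    for row in hits.itertuples(index=False):
        if group and row.q_lo > current_end:
            flush(group)
            group = []
            current_end = -1
        group.append(row)
        current_end = max(current_end, int(row.q_hi))
    flush(group)
    return segments


def segments_to_frame(segments: Sequence[HomologySegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "insertion_no": i + 1,
        "query_start": s.query[0], "query_end": s.query[1], "length": s.length,
        "subject_id": s.subject_id,
        "subject_start": s.subject[0], "subject_end": s.subject[1],
        "identity": s.identity, "evalue": s.evalue,
        "genes_carried": ", ".join(s.carried_features),
    } for i, s in enumerate(segments)])


def shared_spacer_total(query_spacers: SpacerSet,
                        segments: Sequence[HomologySegment]) -> Tuple[int, float]:
    """(bp, fraction) of the spacer set covered by homology segments."""
    if not segments:
        return 0, 0.0
    covered = iv.intersect([s.query for s in segments], query_spacers.intervals)
    bp = sum(e - s + 1 for s, e in covered)
    total = query_spacers.total_bp
    return bp, (bp / total if total else 0.0)


# ---------------------------------------------------------------------------
# alignment matrices

_STATES = np.frombuffer(b"ACGT", dtype="S1")


def _as_rows(alignment) -> List[Tuple[str, str]]:
    if isinstance(alignment, dict):
        return list(alignment.items())
    rows = []
    for item in alignment:
        if isinstance(item, str):
            rows.append((f"taxon_{len(rows)}", item))
        else:
            name, seq = item
            rows.append((name, str(seq)))
    return rows


def matrix_stats(alignment) -> MatrixStats:
    """Missing-data fraction and parsimony-informative site count.

    A column is parsimony-informative when at least two distinct unambiguous
    nucleotide states each occur in at least two rows; gaps and ambiguity
    codes count as missing, never as states.
    """
    rows = _as_rows(alignment)
    if not rows:
        return MatrixStats(0, 0, 0.0, 0)
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    arr = np.array([np.frombuffer(seq.upper().encode(), dtype="S1")
                    for _, seq in rows])
    n_taxa, n_cols = arr.shape
    is_state = np.isin(arr, _STATES)
    missing_fraction = float(1.0 - is_state.mean()) if arr.size else 0.0
    frequent = np.zeros(n_cols, dtype=int)
    for base in _STATES:
        frequent += ((arr == base).sum(axis=0) >= 2)
    pi_sites = int((frequent >= 2).sum())
    return MatrixStats(n_taxa, n_cols, missing_fraction, pi_sites)


def concat_alignments(gene_alignments: Sequence[Tuple[str, Sequence[Tuple[str, str]]]],
                      taxa: Optional[Sequence[str]] = None,
                      missing_char: str = "-",
                      ) -> Tuple[List[Tuple[str, str]], List[Tuple[str, int, int]]]:
    """Concatenate per-gene alignments over a taxon universe.

    Taxa absent from a gene are filled with ``missing_char``; the partition
    table records each gene's 1-based inclusive column range.
    """
    per_gene: List[Tuple[str, Dict[str, str], int]] = []
    universe: List[str] = list(taxa) if taxa is not None else []
    seen_taxa = set(universe)
    for gene, rows in gene_alignments:
        table: Dict[str, str] = {}
        for taxon, seq in rows:
            if taxon in table:
                raise ValueError(f"gene {gene!r}: duplicate taxon {taxon!r}")
            table[taxon] = str(seq)
            if taxon not in seen_taxa:
                seen_taxa.add(taxon)
                universe.append(taxon)
        lengths = {len(s) for s in table.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene {gene!r}: ragged alignment")
        per_gene.append((gene, table, lengths.pop() if lengths else 0))
    partitions: List[Tuple[str, int, int]] = []
    col = 1
    chunks: Dict[str, List[str]] = {t: [] for t in universe}
    for gene, table, width in per_gene:
        partitions.append((gene, col, col + width - 1))
        col += width
        for taxon in universe:
            chunks[taxon].append(table.get(taxon, missing_char * width))
    return [(t, "".join(chunks[t])) for t in universe], partitions
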