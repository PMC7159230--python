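"""Gene-order comparison: DCJ distance and conserved gene clusters.

Gene orders are signed, possibly multichromosomal, with circular or linear
chromosomes. The rearrangement distance is the unrestricted double-cut-and-
join (DCJ) distance d = N - (C + I/2), where N is the number of shared
genes and C and I are the cycles and odd paths of the adjacency graph of
the two genomes. Because compared mitogenomes differ in gene content, a
reduction step first restricts both orders to the genes present exactly
once in each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .mtio import Chromosome, GeneOrder

logger = logging.getLogger(__name__)

Extremity = Tuple[str, str]  # (gene, 't'|'h')
SignedGene = Tuple[str, int]


@dataclass(frozen=True)
class AdjacencySet:
    """Gene-extremity adjacencies of one genome; telomeric ends unpaired."""

    #: extremity -> partner extremity, or None for a telomere
    partner: Tuple[Tuple[Extremity, Optional[Extremity]], ...]

    def as_dict(self) -> Dict[Extremity, Optional[Extremity]]:
        return dict(self.partner)


@dataclass(frozen=True)
class ClusterReport:
    """Maximal signed gene runs shared by all compared organisms."""

    clusters: Tuple[Tuple[SignedGene, ...], ...]

    @property
    def lengths(self) -> Tuple[int, ...]:
        return tuple(len(c) for c in self.clusters)


def _ends(gene: str, sign: int) -> Tuple[Extremity, Extremity]:
    """(left, right) extremity of a signed gene read left to right."""
    if sign > 0:
        return (gene, "t"), (gene, "h")
    return (gene, "h"), (gene, "t")


def adjacency_set(order: GeneOrder) -> AdjacencySet:
    partner: Dict[Extremity, Optional[Extremity]] = {}

    def join(x: Extremity, y: Extremity) -> None:
        partner[x] = y
        partner[y] = x

    for chrom in order.chromosomes:
        sides = [_ends(g, s) for g, s in chrom.genes]
        for (_, right), (left, _) in zip(sides, sides[1:]):
            join(right, left)
        if chrom.circular:
            join(sides[-1][1], sides[0][0])
        else:
            partner.setdefault(sides[0][0], None)
            partner.setdefault(sides[-1][1], None)
    return AdjacencySet(tuple(sorted(partner.items())))


def reduce_to_shared_genes(a: GeneOrder, b: GeneOrder) -> Tuple[GeneOrder, GeneOrder]:
    """Restrict both orders to genes occurring exactly once in each.

    Duplicated genes and genes private to one organism are dropped (and
    logged); relative order, signs and chromosome topology are preserved.
    """
    reduced = reduce_many([a, b])
    return reduced[0], reduced[1]


def reduce_many(orders: Sequence[GeneOrder]) -> List[GeneOrder]:
    from collections import Counter

    counts = [Counter(o.gene_multiset()) for o in orders]
    shared: Set[str] = {g for g in counts[0]
                        if all(c.get(g, 0) == 1 for c in counts)}
    if not shared:
        raise ValueError("no genes occur exactly once in every organism; "
                         "orders cannot be compared")
    out: List[GeneOrder] = []
    for order, count in zip(orders, counts):
        dropped = sorted(g for g in count if g not in shared)
        if dropped:
            logger.info("%s: dropped %d genes not shared single-copy: %s",
                        order.organism, len(dropped), ", ".join(dropped))
        chroms = []
        for chrom in order.chromosomes:
            genes = tuple((g, s) for g, s in chrom.genes if g in shared)
            if genes:
                chroms.append(Chromosome(genes, chrom.circular))
        out.append(GeneOrder(order.organism, tuple(chroms)))
    return out


def dcj_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Unrestricted DCJ distance between two reduced gene orders.

    d = N - (C + I/2) over the adjacency graph; symmetric, zero iff the
    orders are identical up to chromosome rotation/reflection.
    """
    genes_a = a.gene_multiset()
    genes_b = b.gene_multiset()
    if len(set(genes_a)) != len(genes_a) or set(genes_a) != set(genes_b) or \
            len(set(genes_b)) != len(genes_b):
        raise ValueError("gene sets differ or contain duplicates; apply "
                         "reduce_to_shared_genes first")
    n = len(genes_a)
    if n == 0:
        return 0
    pa = adjacency_set(a).as_dict()
    pb = adjacency_set(b).as_dict()
    extremities = [(g, end) for g in genes_a for end in ("t", "h")]
    seen: Set[Extremity] = set()
    cycles = odd_paths = 0
    for start in extremities:
        if start in seen:
            continue
        # walk the component alternating A- and B-adjacencies both ways
        component = {start}
        frontier = [start]
        while frontier:
            x = frontier.pop()
            for partner_map in (pa, pb):
                y = partner_map.get(x)
                if y is not None and y not in component:
                    component.add(y)
                    frontier.append(y)
        seen |= component
        is_cycle = all(pa.get(x) is not None and pb.get(x) is not None
                       for x in component)
        if is_cycle:
            cycles += 1
        elif len(component) % 2 == 1:
            odd_paths += 1
    return n - cycles - odd_paths // 2


def dcj_distance_matrix(orders: Sequence[GeneOrder]):
    """Pairwise DCJ distances (after pairwise reduction) as a DataFrame."""
    import pandas as pd

    names = [o.organism for o in orders]
    mat = [[0] * len(orders) for _ in orders]
    for i in range(len(orders)):
        for j in range(i + 1, len(orders)):
            ra, rb = reduce_to_shared_genes(orders[i], orders[j])
            mat[i][j] = mat[j][i] = dcj_distance(ra, rb)
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# conserved clusters


def _rc_run(run: Tuple[SignedGene, ...]) -> Tuple[SignedGene, ...]:
    return tuple((g, -s) for g, s in reversed(run))


def _canonical_run(run: Tuple[SignedGene, ...]) -> Tuple[SignedGene, ...]:
    return min(run, _rc_run(run))


class _OrgIndex:
    def __init__(self, order: GeneOrder):
        self.chroms = [(list(c.genes), c.circular) for c in order.chromosomes]
        self.pos: Dict[str, Tuple[int, int, int]] = {}
        for ci, (genes, _circ) in enumerate(self.chroms):
            for pi, (g, s) in enumerate(genes):
                self.pos[g] = (ci, pi, s)

    def occurs_forward(self, run: Tuple[SignedGene, ...]) -> bool:
        g0, s0 = run[0]
        if g0 not in self.pos:
            return False
        ci, p0, sign0 = self.pos[g0]
        genes, circular = self.chroms[ci]
        n = len(genes)
        if sign0 != s0:
            return False
        if len(run) > n:
            return False
        for i, (g, s) in enumerate(run):
            p = p0 + i
            if p >= n:
                if not circular:
                    return False
                p %= n
            if genes[p] != (g, s):
                return False
        return True

    def occurs(self, run: Tuple[SignedGene, ...]) -> bool:
        return self.occurs_forward(run) or self.occurs_forward(_rc_run(run))


def find_conserved_clusters(orders: Sequence[GeneOrder],
                            min_len: int = 2) -> ClusterReport:
    """Maximal gene runs present (up to signed reversal) in every organism.

    Orders are first restricted to genes single-copy in all organisms; a
    run and its signed reversal count as the same cluster.
    """
    if len(orders) < 2:
        raise ValueError("need at least two organisms")
    reduced = reduce_many(orders)
    indexes = [_OrgIndex(o) for o in reduced[1:]]
    occurring: List[Tuple[SignedGene, ...]] = []
    for chrom in reduced[0].chromosomes:
        genes = list(chrom.genes)
        n = len(genes)
        max_len = n if chrom.circular else n
        for start in range(n):
            limit = n if chrom.circular else n - start
            best = None
            for length in range(min_len, min(limit, max_len) + 1):
                run = tuple(genes[(start + k) % n] for k in range(length))
                if all(idx.occurs(run) for idx in indexes):
                    best = run
                else:
                    break
            if best is not None:
                if chrom.circular and len(best) == n:
                    # a full circular chromosome: rotations are one cluster
                    rotations = [tuple(best[(i + k) % n] for k in range(n))
                                 for i in range(n)]
                    best = min(min(r, _rc_run(r)) for r in rotations)
                occurring.append(best)
    # keep maximal runs only: drop runs that are sub-runs of a longer one
    unique = {_canonical_run(r): r for r in occurring}
    runs = sorted(unique.values(), key=len, reverse=True)
    maximal: List[Tuple[SignedGene, ...]] = []

    def contained(small, big) -> bool:
        if len(small) >= len(big):
            return False
        for cand in (big, _rc_run(big)):
            for i in range(len(cand) - len(small) + 1):
                if tuple(cand[i:i + len(small)]) == small:
                    return True
        return False

    for run in runs:
        if not any(contained(run, kept) for kept in maximal):
            maximal.append(run)
    maximal.sort(key=lambda r: (-len(r), r))
    return ClusterReport(tuple(maximal))


def format_run(run: Tuple[SignedGene, ...]) -> str:
    return " ".join(("-" if s < 0 else "") + g for g, s in run)
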