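"""Homeologous triplet identification from three subgenome gene sets.

An allohexaploid genome (AABBDD) carries up to three homeologous copies of
each gene, one per subgenome.  This module finds "triplets" — clusters with
exactly one member per subgenome whose pairwise alignments pass identity and
coverage gates — and extracts the diagnostic SNP columns that let a short
read be attributed to a subgenome subset.

Pairwise scoring uses an in-package banded global (Needleman–Wunsch/Gotoh)
aligner.  Homeologs are near-identical, so a narrow band around the main
diagonal captures the optimal global alignment while keeping the scorer
exact and dependency-free.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")

# IUPAC nucleotide codes (unambiguous + ambiguity + gap-free).
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN")

_NEG = -(2 ** 40)  # effective -infinity for int64 DP cells


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its subgenome of origin and optional map position."""

    gene_id: str
    subgenome: str
    sequence: str
    chromosome: str | None = None
    start: int | None = None  # 0-based
    end: int | None = None    # half-open
    strand: str = "+"

    def __post_init__(self):
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"subgenome must be one of {SUBGENOMES}, "
                             f"got {self.subgenome!r}")
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float   # matches / aligned (substitution) columns
    coverage: float   # aligned columns / min(sequence lengths)
    score: int

    def passes(self, min_identity: float, min_coverage: float) -> bool:
        return self.identity >= min_identity and self.coverage >= min_coverage


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column at which the three homeolog alleles differ.

    ``site_class`` records which subgenome subset the column discriminates:
    ``A|BD`` means the A allele differs from a shared B=D allele, etc.;
    ``all-distinct`` means all three alleles differ.
    """

    position: int
    alleles: dict[str, str]
    site_class: str


@dataclass
class Triplet:
    triplet_id: str
    members: dict[str, GeneRecord]           # keyed by subgenome
    pair_hits: dict[tuple[str, str], AlignmentHit] = field(default_factory=dict)
    group_consistent: bool | None = None     # None = check skipped

    @property
    def gene_ids(self) -> dict[str, str]:
        return {sg: g.gene_id for sg, g in self.members.items()}

    def sequences(self) -> dict[str, str]:
        return {sg: g.sequence for sg, g in self.members.items()}


# ---------------------------------------------------------------------------
# Banded global alignment (Gotoh affine gaps)


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    aligned_columns: int  # columns where both sequences contribute a base
    matches: int
    # maps a-position (0-based) -> aligned b-position or None (gap)
    a_to_b: tuple


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int16)


@njit(cache=True)
def _dp_fill(ac, bc, band, match, mismatch, gap_open, gap_extend, neg):  # pragma: no cover
    la, lb = ac.size, bc.size
    W = 2 * band + 1
    M = np.full((la + 1, W), neg, np.int64)
    X = np.full((la + 1, W), neg, np.int64)  # gap in b (consumes a)
    Y = np.full((la + 1, W), neg, np.int64)  # gap in a (consumes b)
    M[0, band] = 0
    kmax = band if band < lb else lb
    for k in range(1, kmax + 1):
        Y[0, band + k] = gap_open + (k - 1) * gap_extend
    for i in range(1, la + 1):
        for w in range(W):
            j = i + w - band
            if j < 0 or j > lb:
                continue
            if j >= 1:
                pb = M[i - 1, w]
                if X[i - 1, w] > pb:
                    pb = X[i - 1, w]
                if Y[i - 1, w] > pb:
                    pb = Y[i - 1, w]
                if pb > neg // 2:
                    s = match if ac[i - 1] == bc[j - 1] else mismatch
                    M[i, w] = pb + s
            if w + 1 < W:
                v1 = M[i - 1, w + 1] + gap_open
                v2 = X[i - 1, w + 1] + gap_extend
                v = v1 if v1 > v2 else v2
                if v > neg // 2:
                    X[i, w] = v
            if w >= 1 and j >= 1:
                v1 = M[i, w - 1] + gap_open
                v2 = Y[i, w - 1] + gap_extend
                v = v1 if v1 > v2 else v2
                if v > neg // 2:
                    Y[i, w] = v
    return M, X, Y


def banded_global_align(a: str, b: str, match: int = 1, mismatch: int = -1,
                        gap_open: int = -5, gap_extend: int = -2,
                        band: int = 32) -> AlignmentResult:
    """Global alignment of ``a`` vs ``b`` restricted to a diagonal band.

    The first base of a gap scores ``gap_open``; each further base scores
    ``gap_extend``.  The band is widened automatically when the length
    difference exceeds it, so the end cell is always reachable.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    la, lb = len(a), len(b)
    band = max(band, abs(la - lb) + 8)

    M, X, Y = _dp_fill(_encode(a), _encode(b), band, match, mismatch,
                       gap_open, gap_extend, _NEG)

    w_end = lb - la + band
    finals = (M[la, w_end], X[la, w_end], Y[la, w_end])
    score = int(max(finals))
    if score <= _NEG // 2:
        raise AlignmentError("no alignment within band")  # unreachable after widening

    # traceback
    state = int(np.argmax(finals))  # 0=M, 1=X, 2=Y
    i, w = la, w_end
    matches = 0
    aligned = 0
    a_to_b: list[int | None] = [None] * la
    while i > 0 or (w != band):
        j = i + (w - band)
        if state == 0:
            aligned += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            a_to_b[i - 1] = j - 1
            prev = (M[i - 1, w], X[i - 1, w], Y[i - 1, w])
            state = int(np.argmax(prev))
            i -= 1
        elif state == 1:
            if X[i - 1, w + 1] + gap_extend == X[i, w]:
                state = 1
            else:
                state = 0
            i -= 1
            w += 1
        else:
            if i == 0:
                w -= 1  # leading gap row; walk back to origin
                continue
            if Y[i, w - 1] + gap_extend == Y[i, w]:
                state = 2
            else:
                state = 0
            w -= 1

    return AlignmentResult(score, aligned, matches, tuple(a_to_b))


# ---------------------------------------------------------------------------
# Pairwise scoring and triplet construction


def _validate_sequence(rec: GeneRecord) -> None:
    bad = set(rec.sequence.upper()) - IUPAC_CHARS
    if bad:
        raise ValueError(
            f"gene {rec.gene_id}: non-IUPAC characters {sorted(bad)!r}")
    if not rec.sequence:
        raise ValueError(f"gene {rec.gene_id}: empty sequence")


def score_pairwise(a: GeneRecord, b: GeneRecord, band: int = 32) -> AlignmentHit:
    """Score two genes by banded global alignment.

    identity = matches / aligned columns; coverage = aligned columns divided
    by the shorter sequence length.  Symmetric in its two arguments.
    """
    _validate_sequence(a)
    _validate_sequence(b)
    res = banded_global_align(a.sequence.upper(), b.sequence.upper(), band=band)
    identity = res.matches / res.aligned_columns if res.aligned_columns else 0.0
    coverage = res.aligned_columns / min(len(a.sequence), len(b.sequence))
    return AlignmentHit(a.gene_id, b.gene_id, identity, min(coverage, 1.0),
                        res.score)


_GROUP_RE = re.compile(r"(\d+)\s*([ABD])")


def homeologous_group(chromosome: str | None) -> int | None:
    """Parse the homeologous-group number from a chromosome name (e.g. 2A -> 2)."""
    if not chromosome:
        return None
    m = _GROUP_RE.search(chromosome)
    return int(m.group(1)) if m else None


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def build_triplets(genes_A: Sequence[GeneRecord], genes_B: Sequence[GeneRecord],
                   genes_D: Sequence[GeneRecord], min_identity: float = 0.90,
                   min_coverage: float = 0.75, band: int = 32,
                   prescreen_k: int | None = 21) -> list[Triplet]:
    """Cluster three subgenome gene sets into homeologous triplets.

    Cross-subgenome pairs are scored (after an optional shared-k-mer
    prescreen that skips pairs with no exact ``prescreen_k``-mer in common —
    near-identical homeologs always share many); pairs passing the identity
    and coverage gates become edges, and each connected component with
    exactly one gene per subgenome and all three pairwise edges passing is
    returned as a triplet.  Components with zero or multiple candidates in
    any subgenome are dropped without arbitration.  When chromosome names
    carry homeologous-group numbers the three members must agree on the
    group; with missing names the check is skipped with a warning.
    """
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    by_sg = {"A": list(genes_A), "B": list(genes_B), "D": list(genes_D)}
    for sg, genes in by_sg.items():
        if not genes:
            raise ValueError(f"subgenome {sg}: empty gene list")
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"subgenome {sg}: duplicate gene ids")
        for g in genes:
            _validate_sequence(g)

    kmers = {}
    if prescreen_k:
        kmers = {g.gene_id: _kmer_set(g.sequence.upper(), prescreen_k)
                 for genes in by_sg.values() for g in genes}

    lookup = {g.gene_id: g for genes in by_sg.values() for g in genes}
    hits: dict[tuple[str, str], AlignmentHit] = {}
    uf = _UnionFind()
    for sg1, sg2 in combinations(SUBGENOMES, 2):
        for g1 in sorted(by_sg[sg1], key=lambda g: g.gene_id):
            for g2 in sorted(by_sg[sg2], key=lambda g: g.gene_id):
                if prescreen_k and kmers[g1.gene_id].isdisjoint(kmers[g2.gene_id]):
                    continue
                hit = score_pairwise(g1, g2, band=band)
                if hit.passes(min_identity, min_coverage):
                    hits[(g1.gene_id, g2.gene_id)] = hit
                    uf.union(g1.gene_id, g2.gene_id)

    components: dict[str, list[str]] = {}
    for gid in {g for pair in hits for g in pair}:
        components.setdefault(uf.find(gid), []).append(gid)

    triplets: list[Triplet] = []
    warned_missing_group = False
    for root in sorted(components):
        member_ids = sorted(components[root])
        members = {lookup[gid].subgenome: lookup[gid] for gid in member_ids}
        if len(member_ids) != 3 or set(members) != set(SUBGENOMES):
            continue  # 0 or >=2 candidates in some subgenome: dropped
        pair_hits = {}
        ok = True
        for sg1, sg2 in combinations(SUBGENOMES, 2):
            key = (members[sg1].gene_id, members[sg2].gene_id)
            rkey = (key[1], key[0])
            hit = hits.get(key) or hits.get(rkey)
            if hit is None:
                ok = False
                break
            pair_hits[(sg1, sg2)] = hit
        if not ok:
            continue
        groups = [homeologous_group(members[sg].chromosome) for sg in SUBGENOMES]
        if any(g is None for g in groups):
            consistent = None
            if not warned_missing_group:
                logger.warning("chromosome names missing or unparsable; "
                               "homeologous-group consistency check skipped")
                warned_missing_group = True
        else:
            consistent = len(set(groups)) == 1
            if not consistent:
                continue
        triplets.append(Triplet("", members, pair_hits, consistent))

    triplets.sort(key=lambda t: t.members["A"].gene_id)
    for idx, t in enumerate(triplets):
        t.triplet_id = f"T{idx:06d}"
    return triplets


# ---------------------------------------------------------------------------
# Diagnostic SNP sites


def _classify(a: str, b: str, d: str) -> str | None:
    if a == b == d:
        return None
    if b == d:
        return "A|BD"
    if a == d:
        return "B|AD"
    if a == b:
        return "D|AB"
    return "all-distinct"


def call_diagnostic_sites(triplet: Triplet, band: int = 32) -> list[DiagnosticSite]:
    """Report every alignment column at which the homeolog alleles differ.

    Equal-length members are compared column-by-column.  Otherwise B and D
    are each aligned to A (the scaffold) and columns are read off in A
    coordinates; columns where any member contributes a gap or an ambiguity
    code are skipped.
    """
    seqs = {sg: triplet.members[sg].sequence.upper() for sg in SUBGENOMES}
    la = len(seqs["A"])
    if len(seqs["B"]) == la and len(seqs["D"]) == la:
        b_of = {i: seqs["B"][i] for i in range(la)}
        d_of = {i: seqs["D"][i] for i in range(la)}
    else:
        res_b = banded_global_align(seqs["A"], seqs["B"], band=band)
        res_d = banded_global_align(seqs["A"], seqs["D"], band=band)
        b_of = {i: seqs["B"][j] for i, j in enumerate(res_b.a_to_b) if j is not None}
        d_of = {i: seqs["D"][j] for i, j in enumerate(res_d.a_to_b) if j is not None}

    sites = []
    acgt = set("ACGT")
    for i in range(la):
        a = seqs["A"][i]
        b = b_of.get(i)
        d = d_of.get(i)
        if b is None or d is None:
            continue
        if not {a, b, d} <= acgt:
            continue  # ambiguity codes are not diagnostic
        cls = _classify(a, b, d)
        if cls is not None:
            sites.append(DiagnosticSite(i, {"A": a, "B": b, "D": d}, cls))
    return sites
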