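"""SNP-diagnostic read assignment and proportional homeolog quantification.

Each read is placed end-to-end against the three homeolog sequences of its
best-matching triplet and classified by the subgenome SNP information it
carries: the compatible set is the homeologs achieving the read's minimum
mismatch count (reads whose best match still has more than two mismatches
fail the quality gate and are UNASSIGNED).  A read covering at least one
diagnostic SNP column separating two homeologs is therefore specific with
respect to that pair, while reads from SNP-free stretches fall into the
shared classes AB/AD/BD/ABD.  Shared counts are then divided among their
member homeologs in proportion to the specific counts, which conserves the
assigned total exactly.

Candidate triplets are found by exact 31-mer seeding against all homeolog
sequences: a read carrying at most two substitutions always retains an
exact 31-mer match to its origin (the longest error-free stretch of a
125-mer with two errors is at least 41 bases), so seeding with a stride of
8 never misses the true placement for assignable reads.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .triplets import SUBGENOMES, Triplet

logger = logging.getLogger(__name__)

ASSIGNMENT_CLASSES = ("A", "B", "D", "AB", "AD", "BD", "ABD", "UNASSIGNED")
SHARED_MEMBERS = {"AB": ("A", "B"), "AD": ("A", "D"),
                  "BD": ("B", "D"), "ABD": ("A", "B", "D")}


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    triplet_id: str | None
    mismatches: dict[str, int] | None  # vs each homeolog at the best placement
    assignment: str                    # one of ASSIGNMENT_CLASSES


@dataclass
class HomeologCounts:
    triplet_id: str
    library_id: str
    specific: dict[str, int]
    shared: dict[str, int]
    allocated: dict[str, float]

    def as_row(self) -> dict:
        row = {"triplet": self.triplet_id, "library": self.library_id}
        row.update({f"n_{sg}": self.specific[sg] for sg in SUBGENOMES})
        row.update({f"n_{c}": self.shared[c] for c in ("AB", "AD", "BD", "ABD")})
        row.update({f"c_{sg}": self.allocated[sg] for sg in SUBGENOMES})
        return row


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _class_label(compatible: Sequence[str]) -> str:
    return "".join(sorted(compatible)) if compatible else "UNASSIGNED"


def _compatible(mm: Mapping[str, int], max_mismatches: int) -> list[str]:
    """Homeologs achieving the minimum mismatch count, if it passes the gate."""
    best = min(mm.values())
    if best > max_mismatches:
        return []
    return [sg for sg in SUBGENOMES if mm[sg] == best]


def assign_read(read_seq: str, homeolog_seqs: Mapping[str, str],
                max_mismatches: int = 2, read_id: str = "read",
                triplet_id: str | None = None,
                placements: Iterable[int] | None = None) -> ReadAssignment:
    """Classify one read against a triplet's three homeologs.

    Every end-to-end placement of the read (or only the candidate
    ``placements``, when supplied by the seeding index) is scored against
    each homeolog by mismatch count; the best common placement is the one
    minimising the smallest per-homeolog mismatch count (ties broken by the
    total).  At that placement the compatible set is the homeologs
    achieving the minimum mismatch count — the read's covered SNP alleles
    decide the subgenome subset — provided the minimum passes the
    ``max_mismatches`` quality gate; otherwise the read is UNASSIGNED.
    """
    read = _to_bytes(read_seq)
    seqs = {sg: _to_bytes(homeolog_seqs[sg]) for sg in SUBGENOMES}
    min_len = min(len(s) for s in seqs.values())
    if len(read) > min_len:
        raise ValueError("read longer than homeolog sequence")
    if placements is None:
        offsets = range(min_len - len(read) + 1)
    else:
        offsets = sorted({o for o in placements if 0 <= o <= min_len - len(read)})
    best = None  # (min_mm, total_mm, offset, per-homeolog mm)
    for o in offsets:
        mm = {sg: int((seqs[sg][o:o + len(read)] != read).sum()) for sg in SUBGENOMES}
        key = (min(mm.values()), sum(mm.values()), o)
        if best is None or key < best[:3]:
            best = (*key, mm)
    if best is None:
        return ReadAssignment(read_id, triplet_id, None, "UNASSIGNED")
    mm = best[3]
    return ReadAssignment(read_id, triplet_id, mm,
                          _class_label(_compatible(mm, max_mismatches)))


def allocate_counts(n_A: float, n_B: float, n_D: float, n_AB: float = 0,
                    n_AD: float = 0, n_BD: float = 0, n_ABD: float = 0
                    ) -> tuple[float, float, float]:
    """Divide shared read counts among homeologs proportionally.

    Each shared class is split among its member homeologs in proportion to
    those members' specific counts; when the relevant specific counts are
    all zero the class is split equally (the proportional rule is undefined
    at 0/0 and the equal split preserves both conservation and symmetry).
    The returned totals satisfy c_A + c_B + c_D = sum of all inputs exactly.
    """
    specific = {"A": n_A, "B": n_B, "D": n_D}
    shared = {"AB": n_AB, "AD": n_AD, "BD": n_BD, "ABD": n_ABD}
    if any(v < 0 for v in list(specific.values()) + list(shared.values())):
        raise ValueError("counts must be non-negative")
    alloc = dict(specific)
    for cls, members in SHARED_MEMBERS.items():
        count = shared[cls]
        if count == 0:
            continue
        denom = sum(specific[m] for m in members)
        if denom > 0:
            for m in members:
                alloc[m] += count * specific[m] / denom
        else:
            for m in members:
                alloc[m] += count / len(members)
    return alloc["A"], alloc["B"], alloc["D"]


class TripletReadIndex:
    """Exact k-mer index over the homeolog sequences of a triplet set."""

    def __init__(self, triplets: Sequence[Triplet], k: int = 31,
                 seed_stride: int = 8):
        if seed_stride > 11:
            logger.warning("seed_stride > 11 can miss placements for reads "
                           "with 2 mismatches at read length 125")
        self.k = k
        self.seed_stride = seed_stride
        self.triplets = {t.triplet_id: t for t in triplets}
        self.seqs = {t.triplet_id: {sg: _to_bytes(t.members[sg].sequence)
                                    for sg in SUBGENOMES}
                     for t in triplets}
        self.index: dict[bytes, list[tuple[str, int]]] = defaultdict(list)
        for tid, seqs in self.seqs.items():
            seen: dict[bytes, set[int]] = defaultdict(set)
            for sg in SUBGENOMES:
                s = seqs[sg].tobytes()
                for pos in range(len(s) - k + 1):
                    seen[s[pos:pos + k]].add(pos)
            for kmer, positions in seen.items():
                for pos in positions:
                    self.index[kmer].append((tid, pos))

    def candidates(self, read: bytes) -> dict[str, set[int]]:
        """Map candidate triplet id -> set of end-to-end start offsets."""
        out: dict[str, set[int]] = defaultdict(set)
        k = self.k
        starts = list(range(0, len(read) - k + 1, self.seed_stride))
        if starts and starts[-1] != len(read) - k:
            starts.append(len(read) - k)
        for off in starts:
            for tid, pos in self.index.get(read[off:off + k], ()):
                out[tid].add(pos - off)
        return out


def quantify(reads_by_library: Mapping[str, Sequence[tuple[str, str, str]]],
             triplets: Sequence[Triplet], max_mismatches: int = 2,
             k: int = 31, seed_stride: int = 8,
             return_assignments: bool = False
             ) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify homeolog expression for every (triplet, library).

    Reads are looked up in the 31-mer seed index; the triplet with the
    lowest best mismatch count wins, a cross-triplet tie at the best
    mismatch count discards the read (logged), and the per-class counts of
    the winner's compatible sets are proportionally allocated to A/B/D.
    Returns a table with one row per (triplet, library): specific counts
    (n_A..), shared counts (n_AB..n_ABD), and allocated counts (c_A..).
    """
    idx = TripletReadIndex(triplets, k=k, seed_stride=seed_stride)
    class_counts: dict[tuple[str, str], dict[str, int]] = defaultdict(
        lambda: {c: 0 for c in ASSIGNMENT_CLASSES})
    ambiguous = 0
    assignments = []
    for lib_id in reads_by_library:
        for read_id, seq, _qual in reads_by_library[lib_id]:
            read = seq.upper().encode("ascii")
            cands = idx.candidates(read)
            best_per_triplet = {}
            rarr = np.frombuffer(read, dtype=np.uint8)
            for tid, offsets in cands.items():
                seqs = idx.seqs[tid]
                tbest = None
                for o in sorted(offsets):
                    if o < 0 or o + len(rarr) > len(seqs["A"]):
                        continue
                    mm = {sg: int((seqs[sg][o:o + len(rarr)] != rarr).sum())
                          for sg in SUBGENOMES}
                    key = (min(mm.values()), sum(mm.values()), o)
                    if tbest is None or key < tbest[:3]:
                        tbest = (*key, mm)
                if tbest is not None:
                    best_per_triplet[tid] = tbest
            if not best_per_triplet:
                continue
            ranked = sorted(best_per_triplet.items(), key=lambda kv: kv[1][0])
            if len(ranked) > 1 and ranked[0][1][0] == ranked[1][1][0]:
                ambiguous += 1
                continue
            tid, (_, _, _, mm) = ranked[0]
            label = _class_label(_compatible(mm, max_mismatches))
            class_counts[(tid, lib_id)][label] += 1
            if return_assignments:
                assignments.append((read_id, lib_id, tid, mm["A"], mm["B"],
                                    mm["D"], label))
    if ambiguous:
        logger.info("%d reads tied between triplets at the best mismatch "
                    "count and were discarded", ambiguous)

    rows = []
    lib_ids = list(reads_by_library)
    for tid in sorted(t.triplet_id for t in triplets):
        for lib_id in lib_ids:
            counts = class_counts.get((tid, lib_id),
                                      {c: 0 for c in ASSIGNMENT_CLASSES})
            specific = {sg: counts[sg] for sg in SUBGENOMES}
            shared = {c: counts[c] for c in ("AB", "AD", "BD", "ABD")}
            cA, cB, cD = allocate_counts(specific["A"], specific["B"],
                                         specific["D"], shared["AB"],
                                         shared["AD"], shared["BD"],
                                         shared["ABD"])
            rows.append(HomeologCounts(tid, lib_id, specific, shared,
                                       {"A": cA, "B": cB, "D": cD}).as_row())
    table = pd.DataFrame(rows)
    if return_assignments:
        adf = pd.DataFrame(assignments, columns=[
            "read_id", "library", "triplet", "mm_A", "mm_B", "mm_D", "class"])
        return table, adf
    return table


def counts_from_sam(sam_path, triplets: Sequence[Triplet],
                    max_mismatches: int = 2) -> pd.DataFrame:
    """Build the homeolog counts table from an external SAM/BAM alignment.

    Alignments are grouped by read; reference names must be the triplet
    member gene ids and the NM tag supplies the mismatch count.  For each
    read the compatible set per triplet is the homeologs aligned with
    NM <= ``max_mismatches``; reads whose best NM ties between two triplets
    are discarded, mirroring the internal seeding path.
    """
    import pysam

    gene_to_member = {}
    for t in triplets:
        for sg in SUBGENOMES:
            gene_to_member[t.members[sg].gene_id] = (t.triplet_id, sg)

    per_read: dict[str, dict[tuple[str, str], int]] = defaultdict(dict)
    read_lib: dict[str, str] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name not in gene_to_member:
                continue
            tid, sg = gene_to_member[aln.reference_name]
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            key = (tid, sg)
            cur = per_read[aln.query_name].get(key)
            if cur is None or nm < cur:
                per_read[aln.query_name][key] = int(nm)
            rg = aln.get_tag("RG") if aln.has_tag("RG") else "library"
            read_lib[aln.query_name] = rg

    class_counts: dict[tuple[str, str], dict[str, int]] = defaultdict(
        lambda: {c: 0 for c in ASSIGNMENT_CLASSES})
    ambiguous = 0
    for read_id, hits in per_read.items():
        by_triplet: dict[str, dict[str, int]] = defaultdict(dict)
        for (tid, sg), nm in hits.items():
            by_triplet[tid][sg] = nm
        ranked = sorted(by_triplet.items(), key=lambda kv: min(kv[1].values()))
        if len(ranked) > 1 and min(ranked[0][1].values()) == min(ranked[1][1].values()):
            ambiguous += 1
            continue
        tid, mm = ranked[0]
        best_nm = min(mm.values())
        if best_nm > max_mismatches:
            continue
        compatible = [sg for sg in SUBGENOMES if mm.get(sg) == best_nm]
        class_counts[(tid, read_lib[read_id])][_class_label(compatible)] += 1
    if ambiguous:
        logger.info("%d SAM reads tied between triplets and were discarded",
                    ambiguous)

    rows = []
    libraries = sorted({lib for (_, lib) in class_counts})
    for tid in sorted(t.triplet_id for t in triplets):
        for lib_id in libraries:
            counts = class_counts.get((tid, lib_id),
                                      {c: 0 for c in ASSIGNMENT_CLASSES})
            specific = {sg: counts[sg] for sg in SUBGENOMES}
            shared = {c: counts[c] for c in ("AB", "AD", "BD", "ABD")}
            cA, cB, cD = allocate_counts(specific["A"], specific["B"],
                                         specific["D"], shared["AB"],
                                         shared["AD"], shared["BD"],
                                         shared["ABD"])
            rows.append(HomeologCounts(tid, lib_id, specific, shared,
                                       {"A": cA, "B": cB, "D": cD}).as_row())
    return pd.DataFrame(rows)
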