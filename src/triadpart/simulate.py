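"""Synthetic allohexaploid data with known ground truth.

Emulates the data structure of a salt-stress RNA-seq time course in
hexaploid wheat: homeologous triplets (one gene per A/B/D subgenome) that
diverged by substitution only, Dirichlet-distributed homeolog expression
proportions, per-homeolog stress fold changes across a
2 genotypes x {control, stress} x 4 timepoints design, uniform-error short
reads, and chromosome gene orders with planted runs of co-responsive
tandem-family genes.

Everything is driven by one integer seed; per-library read generation uses
the subseed ``seed + library index`` so adding a library never perturbs the
reads of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BedRecord

SUBGENOMES = ("A", "B", "D")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library of the factorial design."""

    library_id: str
    genotype: str
    condition: str
    timepoint_h: int
    index: int  # position in the design, used for subseeding


@dataclass(frozen=True)
class SimDesign:
    """Experimental design and read-generation parameters.

    Defaults mirror the salt-stress study design: two cultivars (one
    salt-tolerant, one salt-sensitive), control and stress conditions
    sampled at 6, 12, 24 and 48 h after stress onset, sequenced as 125-bp
    reads.  ``depth`` is the number of reads per library (exact in
    fixed-count mode, expected in Poisson mode); ``error_rate`` is the
    per-base substitution probability (default 0.001, a typical Illumina
    substitution rate).
    """

    genotypes: tuple[str, ...] = ("tolerant", "sensitive")
    timepoints_h: tuple[int, ...] = (6, 12, 24, 48)
    conditions: tuple[str, str] = ("control", "stress")
    read_length: int = 125
    error_rate: float = 0.001
    depth: int = 20_000
    depth_mode: str = "fixed"  # "fixed" (exactly depth reads) or "poisson"
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.depth_mode not in ("fixed", "poisson"):
            raise ValueError("depth_mode must be 'fixed' or 'poisson'")

    def libraries(self) -> list[LibrarySpec]:
        libs = []
        i = 0
        for geno in self.genotypes:
            for cond in self.conditions:
                for tp in self.timepoints_h:
                    libs.append(LibrarySpec(f"{geno}_{cond}_{tp}h", geno, cond, tp, i))
                    i += 1
        return libs


@dataclass
class TripletTruth:
    """Ground truth for one simulated homeolog triplet."""

    triplet_id: str
    sequences: dict[str, str]
    # alignment column -> {subgenome: allele}; only columns where alleles differ
    snp_sites: dict[int, dict[str, str]]
    base_total: float = 1.0                       # relative abundance scale
    base_proportions: dict[str, float] = field(default_factory=dict)
    # subgenome -> {timepoint: fold applied under stress}
    fold_changes: dict[str, dict[int, float]] = field(default_factory=dict)
    # library_id -> {subgenome: absolute abundance}
    abundance: dict[str, dict[str, float]] = field(default_factory=dict)

    def proportions(self, library_id: str) -> dict[str, float]:
        ab = self.abundance[library_id]
        tot = sum(ab.values())
        return {sg: ab[sg] / tot for sg in SUBGENOMES}

    def total(self, library_id: str) -> float:
        return sum(self.abundance[library_id].values())


@dataclass
class LayoutTruth:
    """Ground truth for one simulated chromosome gene order."""

    chromosome: str
    gene_ids: list[str]
    families: list[str]
    responsive: list[bool]
    hotspots: list[tuple[int, int]]  # half-open index intervals, length >= 3


# ---------------------------------------------------------------------------
# Triplet sequences


def simulate_triplets(n_triplets: int, gene_length: int = 1000,
                      divergence: float = 0.02, seed: int = 0
                      ) -> tuple[dict[str, list[tuple[str, str]]], list[TripletTruth]]:
    """Generate homeologous triplets by substitution-only divergence.

    Each triplet starts from a random ancestral sequence; every homeolog
    independently substitutes each site with probability ``divergence / 2``
    (to a uniformly chosen different base), giving an expected pairwise
    difference fraction of ``2m(1-m) + (2/3)m**2`` with ``m = divergence/2``
    — approximately ``divergence`` for the small rates of interest.  All
    columns at which the three homeologs are not identical are recorded as
    SNP truth.

    Returns ({subgenome: [(record id, sequence)]}, [TripletTruth]) with
    record ids like ``T000007_A``.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    if gene_length < 200:
        raise ValueError("gene_length must be >= 200")
    if not (0 < divergence <= 0.10):
        raise ValueError("divergence must lie in (0, 0.10]; divergence 0 "
                         "cannot produce diagnostic SNP sites")
    rng = np.random.default_rng(seed)
    m = divergence / 2.0
    genes: dict[str, list[tuple[str, str]]] = {sg: [] for sg in SUBGENOMES}
    truths = []
    for t in range(n_triplets):
        tid = f"T{t:06d}"
        anc = rng.choice(_BASES, size=gene_length)
        seqs = {}
        cols = np.zeros((3, gene_length), dtype=np.uint8)
        for si, sg in enumerate(SUBGENOMES):
            hom = anc.copy()
            mut = rng.random(gene_length) < m
            # substitute to a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=int(mut.sum()))
            base_idx = np.searchsorted(_BASES, hom[mut])
            hom[mut] = _BASES[(base_idx + shift) % 4]
            cols[si] = hom
            seqs[sg] = hom.tobytes().decode("ascii")
            genes[sg].append((f"{tid}_{sg}", seqs[sg]))
        diff = ~((cols[0] == cols[1]) & (cols[1] == cols[2]))
        snp_sites = {int(p): {sg: chr(cols[si][p])
                              for si, sg in enumerate(SUBGENOMES)}
                     for p in np.flatnonzero(diff)}
        truths.append(TripletTruth(tid, seqs, snp_sites))
    return genes, truths


def expected_pairwise_divergence(divergence: float) -> float:
    """Expected fraction of differing columns between two homeologs."""
    m = divergence / 2.0
    return 2 * m * (1 - m) + (2.0 / 3.0) * m * m


# ---------------------------------------------------------------------------
# Expression truth


def simulate_expression(truths: Sequence[TripletTruth], design: SimDesign,
                        bias_alpha: tuple[float, float, float] = (2.0, 2.0, 2.0),
                        fixed_proportions: tuple[float, float, float] | None = None,
                        de_fraction: float = 0.3,
                        fold_range: tuple[float, float] = (2.0, 8.0),
                        de_direction: str = "both",
                        abundance_sigma: float = 1.0,
                        seed: int = 0) -> list[TripletTruth]:
    """Fill expression ground truth for every triplet and library.

    Homeolog proportions are drawn once per triplet from a Dirichlet with
    concentration ``bias_alpha`` (or pinned to ``fixed_proportions``); each
    homeolog is independently responsive with probability ``de_fraction``,
    in which case a fold change drawn log-uniformly from ``fold_range`` is
    applied to its stress libraries at every timepoint.  ``de_direction``
    chooses up-regulation, down-regulation (reciprocal fold) or an even coin
    between the two ("up" / "down" / "both").  Non-responsive homeologs have
    fold exactly 1.  Triplet base totals are log-normal with log-sd
    ``abundance_sigma``.
    """
    if de_direction not in ("both", "up", "down"):
        raise ValueError("de_direction must be 'both', 'up' or 'down'")
    lo, hi = fold_range
    if not (1 / 16 <= lo <= hi <= 16):
        raise ValueError("fold_range must lie within [1/16, 16]")
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must lie in [0, 1]")
    if fixed_proportions is not None:
        p = np.asarray(fixed_proportions, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("fixed_proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    libs = design.libraries()
    out = []
    for truth in truths:
        if fixed_proportions is not None:
            pi = np.asarray(fixed_proportions, dtype=float)
        else:
            pi = rng.dirichlet(bias_alpha)
        total = float(np.exp(rng.normal(0.0, abundance_sigma)))
        folds: dict[str, dict[int, float]] = {}
        for sg in SUBGENOMES:
            if rng.random() < de_fraction:
                f = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                if de_direction == "down" or (de_direction == "both"
                                              and rng.random() < 0.5):
                    f = 1.0 / f
            else:
                f = 1.0
            folds[sg] = {tp: f for tp in design.timepoints_h}
        abundance = {}
        for lib in libs:
            ab = {}
            for si, sg in enumerate(SUBGENOMES):
                a = total * pi[si]
                if lib.condition == "stress":
                    a *= folds[sg][lib.timepoint_h]
                ab[sg] = a
            abundance[lib.library_id] = ab
        truth.base_total = total
        truth.base_proportions = {sg: float(pi[si])
                                  for si, sg in enumerate(SUBGENOMES)}
        truth.fold_changes = folds
        truth.abundance = abundance
        out.append(truth)
    return out


# ---------------------------------------------------------------------------
# Reads


def _mutate_read(seq: np.ndarray, error_rate: float, rng: np.random.Generator
                 ) -> np.ndarray:
    if error_rate <= 0:
        return seq
    err = rng.random(seq.size) < error_rate
    n = int(err.sum())
    if n:
        seq = seq.copy()
        base_idx = np.searchsorted(_BASES, seq[err])
        seq[err] = _BASES[(base_idx + rng.integers(1, 4, size=n)) % 4]
    return seq


def simulate_reads(truths: Sequence[TripletTruth], design: SimDesign,
                   seed: int | None = None,
                   libraries: Sequence[LibrarySpec] | None = None
                   ) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Draw reads for every library of the design.

    Each read picks a (triplet, homeolog) with probability proportional to
    its true abundance in that library, a uniform start position, and
    substitution errors at ``design.error_rate``; quality strings are
    constant 'I'.  In paired mode two reads are drawn from one fragment of
    length ``2 * read_length`` (mate 2 reverse-complemented).  Returns
    ({library_id: [(read id, sequence, quality)]}, origin table) where the
    origin table has columns read_id/library/triplet/homeolog/start.
    """
    if seed is None:
        seed = design.seed
    libs = list(libraries) if libraries is not None else design.libraries()
    if not truths:
        raise ValueError("no triplet truths supplied")
    if not truths[0].abundance:
        raise ValueError("expression truth not filled; run simulate_expression first")
    frag_len = 2 * design.read_length if design.paired else design.read_length
    for truth in truths:
        if min(len(s) for s in truth.sequences.values()) < frag_len:
            raise ValueError(
                f"triplet {truth.triplet_id}: read/fragment length {frag_len} "
                "exceeds gene length")

    encoded = {t.triplet_id: {sg: np.frombuffer(t.sequences[sg].encode(), dtype=np.uint8)
                              for sg in SUBGENOMES}
               for t in truths}
    reads_by_lib: dict[str, list[tuple[str, str, str]]] = {}
    origin_rows = []
    qual = "I" * design.read_length
    for lib in libs:
        rng = np.random.default_rng(seed + lib.index)
        weights = np.array([t.abundance[lib.library_id][sg]
                            for t in truths for sg in SUBGENOMES], dtype=float)
        wsum = weights.sum()
        if wsum <= 0:
            reads_by_lib[lib.library_id] = []
            continue
        weights /= wsum
        if design.depth_mode == "poisson":
            n_frags = int(rng.poisson(design.depth))
        else:
            n_frags = design.depth
        if design.paired:
            n_frags = max(n_frags // 2, 1)
        choices = rng.choice(len(weights), size=n_frags, p=weights)
        reads = []
        for r, flat in enumerate(choices):
            truth = truths[flat // 3]
            sg = SUBGENOMES[flat % 3]
            seq = encoded[truth.triplet_id][sg]
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            if design.paired:
                rid = f"{lib.library_id}:r{r:07d}"
                m1 = _mutate_read(seq[start:start + design.read_length],
                                  design.error_rate, rng)
                m2_raw = seq[start + design.read_length:start + frag_len]
                m2 = _mutate_read(m2_raw, design.error_rate, rng)
                m2 = np.frombuffer(m2.tobytes().translate(_COMPLEMENT),
                                   dtype=np.uint8)[::-1]
                reads.append((rid + "/1", m1.tobytes().decode(), qual))
                reads.append((rid + "/2", m2.tobytes().decode(), qual))
                origin_rows.append((rid + "/1", lib.library_id, truth.triplet_id, sg, start))
                origin_rows.append((rid + "/2", lib.library_id, truth.triplet_id, sg,
                                    start + design.read_length))
            else:
                rid = f"{lib.library_id}:r{r:07d}"
                m1 = _mutate_read(seq[start:start + design.read_length],
                                  design.error_rate, rng)
                reads.append((rid, m1.tobytes().decode(), qual))
                origin_rows.append((rid, lib.library_id, truth.triplet_id, sg, start))
        reads_by_lib[lib.library_id] = reads
    origin = pd.DataFrame(origin_rows,
                          columns=["read_id", "library", "triplet", "homeolog", "start"])
    return reads_by_lib, origin


# ---------------------------------------------------------------------------
# Chromosome layouts


def simulate_layout(n_chromosomes: int, genes_per_chromosome: int,
                    hotspot_spec: Sequence[tuple[int, int, int, str]] = (),
                    background_responsive_rate: float = 0.0,
                    seed: int = 0, gene_length: int = 1000
                    ) -> tuple[list[BedRecord], list[LayoutTruth]]:
    """Generate ordered chromosome gene maps with planted responsive runs.

    ``hotspot_spec`` entries are (chromosome index, start index, run length,
    family label); every planted run (length >= 3) is flagged responsive and
    its members share the family label.  Background genes are responsive
    independently at ``background_responsive_rate``; any accidental run of
    >= 3 responsive genes that is not exactly a planted interval is re-rolled
    (one background flag cleared at a time) so the planted intervals are the
    unique maximal runs of length >= 3.  Planted runs must not overlap and
    must be separated by at least one gene, or the truth intervals could not
    be unique maximal runs.
    """
    if not (0.0 <= background_responsive_rate <= 1.0):
        raise ValueError("background_responsive_rate must lie in [0, 1]")
    spec_by_chrom: dict[int, list[tuple[int, int, str]]] = {}
    for chrom_i, start, run, fam in hotspot_spec:
        if run < 3:
            raise ValueError("planted hotspot runs must have length >= 3")
        if not (0 <= chrom_i < n_chromosomes):
            raise ValueError(f"chromosome index {chrom_i} out of range")
        if start < 0 or start + run > genes_per_chromosome:
            raise ValueError(
                f"hotspot [{start}, {start + run}) exceeds chromosome length "
                f"{genes_per_chromosome}")
        spec_by_chrom.setdefault(chrom_i, []).append((start, run, fam))
    for chrom_i, spans in spec_by_chrom.items():
        spans.sort()
        for (s1, r1, _), (s2, _, _) in zip(spans, spans[1:]):
            if s2 <= s1 + r1:
                raise ValueError("planted hotspots overlap or touch; runs must "
                                 "be separated by at least one gene")

    rng = np.random.default_rng(seed)
    bed: list[BedRecord] = []
    truths: list[LayoutTruth] = []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        n = genes_per_chromosome
        gene_ids = [f"{chrom}_g{i:05d}" for i in range(n)]
        families = [f"{chrom}_fam{i:05d}" for i in range(n)]
        responsive = np.zeros(n, dtype=bool)
        planted = []
        planted_mask = np.zeros(n, dtype=bool)
        for start, run, fam in spec_by_chrom.get(c, []):
            responsive[start:start + run] = True
            planted_mask[start:start + run] = True
            for i in range(start, start + run):
                families[i] = fam
            planted.append((start, start + run))
        background = ~planted_mask
        responsive[background] = rng.random(int(background.sum())) < background_responsive_rate

        # re-roll accidental runs >= 3 that are not exactly planted intervals
        planted_set = set(planted)
        while True:
            runs = _maximal_runs(responsive, min_run=3)
            bad = [r for r in runs if r not in planted_set]
            if not bad:
                break
            s, e = bad[0]
            bg_members = [i for i in range(s, e) if background[i]]
            responsive[int(rng.choice(bg_members))] = False

        for i, gid in enumerate(gene_ids):
            bed.append(BedRecord(chrom, i * gene_length, (i + 1) * gene_length,
                                 gid, 0, "+"))
        truths.append(LayoutTruth(chrom, gene_ids, families,
                                  responsive.tolist(), planted))
    return bed, truths


def truth_triplets(truths: Sequence[TripletTruth]):
    """Package simulated triplets as triplet-finder records for direct use."""
    from .triplets import GeneRecord, Triplet

    out = []
    for t in truths:
        members = {sg: GeneRecord(f"{t.triplet_id}_{sg}", sg, t.sequences[sg])
                   for sg in SUBGENOMES}
        out.append(Triplet(t.triplet_id, members))
    return out


def _maximal_runs(flags: Sequence[bool], min_run: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and len(flags) - start >= min_run:
        runs.append((start, len(flags)))
    return runs
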