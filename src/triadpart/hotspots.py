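"""Sliding-window scan and hotspot detection on ordered gene maps.

Stress-responsive genes in the hexaploid genome are not randomly placed:
tandemly duplicated family members often respond together, forming runs of
consecutive responsive genes along the gene order.  This module computes
per-window responsive percentages (default 10 genes per window, 5 genes per
step), calls hotspots as maximal runs of at least three consecutive
responsive genes, and annotates tandem duplication (two or more hotspot
members sharing a gene family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .triplets import score_pairwise, GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class ChromosomeLayout:
    """An ordered gene map with responsive flags and optional family labels."""

    chromosome: str
    gene_ids: list[str]
    responsive: list[bool]
    families: list[str] | None = None

    def __post_init__(self):
        if len(self.gene_ids) != len(self.responsive):
            raise ValueError("gene_ids and responsive flags differ in length")
        if self.families is not None and len(self.families) != len(self.gene_ids):
            raise ValueError("families differ in length from gene_ids")


@dataclass(frozen=True)
class WindowStat:
    chromosome: str
    start: int       # index in gene order
    window: int
    percent_responsive: float


@dataclass
class Hotspot:
    chromosome: str
    start: int       # gene-order index, half-open interval [start, end)
    end: int
    gene_ids: list[str]
    families: list[str] | None = None
    tandem: bool | None = None           # None = undetermined
    dominant_family: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def window_scan(layout: ChromosomeLayout, window: int = 10, step: int = 5
                ) -> list[WindowStat]:
    """Percentage of responsive genes in sliding windows along the map.

    Windows start at 0, step, 2*step, ... and a trailing window shorter
    than ``window`` is dropped, keeping percentages comparable.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    n = len(layout.gene_ids)
    stats = []
    for start in range(0, n - window + 1, step):
        hits = sum(layout.responsive[start:start + window])
        stats.append(WindowStat(layout.chromosome, start, window,
                                100.0 * hits / window))
    return stats


def find_hotspots(layout: ChromosomeLayout, min_run: int = 3) -> list[Hotspot]:
    """Maximal runs of >= ``min_run`` consecutive responsive genes."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    hotspots = []
    n = len(layout.responsive)
    i = 0
    while i < n:
        if layout.responsive[i]:
            j = i
            while j < n and layout.responsive[j]:
                j += 1
            if j - i >= min_run:
                fams = (layout.families[i:j] if layout.families is not None
                        else None)
                hotspots.append(Hotspot(layout.chromosome, i, j,
                                        layout.gene_ids[i:j], fams))
            i = j
        else:
            i += 1
    return hotspots


def _single_linkage_families(sequences: Mapping[str, str],
                             min_identity: float = 0.60) -> dict[str, str]:
    """Cluster genes into families by single-linkage at >= min_identity."""
    ids = sorted(sequences)
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, g1 in enumerate(ids):
        for g2 in ids[i + 1:]:
            hit = score_pairwise(GeneRecord(g1, "A", sequences[g1]),
                                 GeneRecord(g2, "A", sequences[g2]),
                                 band=64)
            if hit.identity >= min_identity:
                r1, r2 = find(g1), find(g2)
                if r1 != r2:
                    parent[max(r1, r2)] = min(r1, r2)
    return {g: f"fam_{find(g)}" for g in ids}


def annotate_tandem(hotspot: Hotspot,
                    families: Mapping[str, str] | None = None,
                    sequences: Mapping[str, str] | None = None,
                    min_identity: float = 0.60) -> Hotspot:
    """Set the tandem-duplication flag and dominant family of a hotspot.

    ``tandem`` is true iff at least two members share a family.  Family
    labels are taken from ``families`` (gene id -> label) when given;
    otherwise from single-linkage clustering of the member ``sequences`` at
    >= ``min_identity`` global identity.  With neither input the flag is
    left undetermined (logged).
    """
    if families is not None:
        labels = [families.get(g) for g in hotspot.gene_ids]
        if any(l is None for l in labels):
            missing = [g for g, l in zip(hotspot.gene_ids, labels) if l is None]
            raise ValueError(f"no family label for genes {missing}")
    elif sequences is not None:
        fam_map = _single_linkage_families(
            {g: sequences[g] for g in hotspot.gene_ids}, min_identity)
        labels = [fam_map[g] for g in hotspot.gene_ids]
    else:
        logger.warning("hotspot %s[%d,%d): no family labels or sequences; "
                       "tandem flag undetermined", hotspot.chromosome,
                       hotspot.start, hotspot.end)
        hotspot.tandem = None
        return hotspot

    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    best = max(sorted(counts), key=lambda l: counts[l])
    hotspot.families = labels
    hotspot.tandem = counts[best] >= 2
    hotspot.dominant_family = best if counts[best] >= 2 else None
    return hotspot


def scan_genome(layouts: Sequence[ChromosomeLayout], window: int = 10,
                step: int = 5, min_run: int = 3,
                families: Mapping[str, str] | None = None
                ) -> tuple[list[WindowStat], list[Hotspot]]:
    """Window scan and hotspot calls across a whole set of chromosomes."""
    windows: list[WindowStat] = []
    hotspots: list[Hotspot] = []
    for layout in layouts:
        windows.extend(window_scan(layout, window, step))
        found = find_hotspots(layout, min_run)
        if families is not None:
            found = [annotate_tandem(h, families=families) for h in found]
        elif layout.families is not None:
            fam = dict(zip(layout.gene_ids, layout.families))
            found = [annotate_tandem(h, families=fam) for h in found]
        hotspots.extend(found)
    return windows, hotspots
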