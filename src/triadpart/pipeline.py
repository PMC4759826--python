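"""End-to-end orchestration: simulate -> triplets -> quantify -> stats -> hotspots.

All stage thresholds default to the study's published criteria (90%
identity / 75% coverage for triplet calling, two mismatches for read
assignment, two-fold change with BH q < 0.01 for differential expression,
chi-square p < 0.01 with Expmax/Expmin >= 1.5 for homeolog bias, 10-gene
windows stepped by 5 and runs of >= 3 for hotspots), so a bare run applies
exactly those rules.  Every run writes the resolved configuration and a
manifest with input/output checksums; a re-run with matching checksums
reuses existing stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as tio
from . import simulate as sim
from . import stats as tstats
from .hotspots import ChromosomeLayout, scan_genome
from .quantify import quantify
from .triplets import (GeneRecord, SUBGENOMES, build_triplets,
                       call_diagnostic_sites)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "triplets", "quantify", "de", "bias", "partition",
          "hotspots", "enrich")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (exit code 2 in the CLI)."""


@dataclass
class PipelineConfig:
    """All pipeline paths, thresholds and the master seed.

    Threshold defaults equal the published criteria; simulation defaults
    are the generator defaults documented in :mod:`triadpart.simulate`.
    """

    outdir: str = "triadpart_run"
    seed: int = 0
    log_level: str = "INFO"

    # simulation stage (used when simulate = True)
    simulate: bool = True
    n_triplets: int = 50
    gene_length: int = 1000
    divergence: float = 0.02
    error_rate: float = 0.001
    depth: int = 20_000
    read_length: int = 125
    n_chromosomes: int = 3
    genes_per_chromosome: int = 200
    background_responsive_rate: float = 0.05
    hotspot_spec: list = field(default_factory=lambda: [
        [0, 20, 5, "HSP20-like"], [1, 50, 3, "Myb"], [2, 100, 4, "C2H2-ZnF"]])

    # external inputs (used when simulate = False)
    fasta_a: str | None = None
    fasta_b: str | None = None
    fasta_d: str | None = None
    positions: str | None = None        # BED or GFF3 gene positions
    reads_dir: str | None = None        # <library>.fastq per sample-sheet row
    sample_sheet: str | None = None     # library/genotype/condition/timepoint
    layout_bed: str | None = None
    responsive_tsv: str | None = None   # gene/responsive for the hotspot scan
    family_tsv: str | None = None       # gene/family
    term_map: str | None = None         # gene/term for enrichment

    # thresholds (defaults = published criteria)
    min_identity: float = 0.90
    min_coverage: float = 0.75
    max_mismatches: int = 2
    fold: float = 2.0
    q: float = 0.01
    bias_p: float = 0.01
    bias_ratio: float = 1.5
    window: int = 10
    step: int = 5
    min_run: int = 3
    enrich_p: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        for name in ("q", "bias_p", "enrich_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.fold < 1:
            raise ConfigError(f"fold must be >= 1, got {self.fold}")
        if self.bias_ratio < 1:
            raise ConfigError(f"bias_ratio must be >= 1, got {self.bias_ratio}")
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")
        if min(self.window, self.step, self.min_run) < 1:
            raise ConfigError("window, step and min_run must be >= 1")
        if not self.simulate:
            for name in ("fasta_a", "fasta_b", "fasta_d", "reads_dir",
                         "sample_sheet"):
                if getattr(self, name) is None:
                    raise ConfigError(
                        f"config field {name!r} is required when simulation "
                        "is disabled")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner over one output directory."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = {"version": __version__, "seed": config.seed,
                         "stages": {}}
        if self.manifest_path.exists():
            try:
                old = json.loads(self.manifest_path.read_text())
                if old.get("seed") == config.seed:
                    self.manifest["stages"] = old.get("stages", {})
            except json.JSONDecodeError:
                pass

    # -- helpers ----------------------------------------------------------

    def path(self, name: str) -> Path:
        return self.out / name

    def _record(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2,
                                                 sort_keys=True) + "\n")

    def _fresh(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        """True when the stage's recorded checksums still match on disk."""
        rec = self.manifest["stages"].get(stage)
        if rec is None:
            return False
        want = {str(p): p for p in inputs + outputs}
        for kind in ("inputs", "outputs"):
            for pstr, sha in rec[kind].items():
                p = Path(pstr)
                if not p.exists() or _sha256(p) != sha:
                    return False
        return all(p.exists() for p in outputs)

    def _sample_sheet(self) -> pd.DataFrame:
        if self.cfg.simulate:
            return tio.read_tsv(self.path("samples.tsv"))
        return tio.read_tsv(self.cfg.sample_sheet)

    # -- stages -----------------------------------------------------------

    def run_simulate(self) -> None:
        cfg = self.cfg
        design = sim.SimDesign(read_length=cfg.read_length,
                               error_rate=cfg.error_rate, depth=cfg.depth,
                               seed=cfg.seed)
        genes, truths = sim.simulate_triplets(cfg.n_triplets, cfg.gene_length,
                                              cfg.divergence, seed=cfg.seed)
        sim.simulate_expression(truths, design, seed=cfg.seed + 1)
        reads, origin = sim.simulate_reads(truths, design, seed=cfg.seed + 2)
        bed, layout_truths = sim.simulate_layout(
            cfg.n_chromosomes, cfg.genes_per_chromosome,
            [tuple(h) for h in cfg.hotspot_spec],
            cfg.background_responsive_rate, seed=cfg.seed + 3)

        outputs = []
        for sg in SUBGENOMES:
            p = self.path(f"genes_{sg}.fasta")
            tio.write_fasta(p, genes[sg])
            outputs.append(p)
        libs = design.libraries()
        samples = pd.DataFrame(
            [{"library": l.library_id, "genotype": l.genotype,
              "condition": l.condition, "timepoint": l.timepoint_h}
             for l in libs])
        tio.write_tsv(samples, self.path("samples.tsv"))
        outputs.append(self.path("samples.tsv"))
        for lib in libs:
            p = self.path(f"reads_{lib.library_id}.fastq")
            tio.write_fastq(p, reads[lib.library_id])
            outputs.append(p)
        tio.write_tsv(origin, self.path("origin.tsv"))
        truth_rows = []
        for t in truths:
            for lib in libs:
                pi = t.proportions(lib.library_id)
                truth_rows.append({"triplet": t.triplet_id,
                                   "library": lib.library_id,
                                   "total": t.total(lib.library_id),
                                   **{f"pi_{sg}": pi[sg] for sg in SUBGENOMES}})
        tio.write_tsv(pd.DataFrame(truth_rows), self.path("expression_truth.tsv"))
        tio.write_bed(self.path("layout.bed"), bed)
        flag_rows = []
        for lt in layout_truths:
            for gid, fam, resp in zip(lt.gene_ids, lt.families, lt.responsive):
                flag_rows.append({"gene": gid, "chromosome": lt.chromosome,
                                  "family": fam, "responsive": bool(resp)})
        tio.write_tsv(pd.DataFrame(flag_rows), self.path("layout_truth.tsv"))
        hs_rows = [{"chromosome": lt.chromosome, "start": s, "end": e}
                   for lt in layout_truths for s, e in lt.hotspots]
        tio.write_tsv(pd.DataFrame(hs_rows, columns=["chromosome", "start", "end"]),
                      self.path("planted_hotspots.tsv"))
        outputs += [self.path(n) for n in
                    ("origin.tsv", "expression_truth.tsv", "layout.bed",
                     "layout_truth.tsv", "planted_hotspots.tsv")]
        self._record("simulate", [], outputs)

    def _gene_inputs(self) -> dict[str, list[GeneRecord]]:
        cfg = self.cfg
        paths = {sg: (self.path(f"genes_{sg}.fasta") if cfg.simulate
                      else Path(getattr(cfg, f"fasta_{sg.lower()}")))
                 for sg in SUBGENOMES}
        positions = {}
        if not cfg.simulate and cfg.positions:
            ppath = Path(cfg.positions)
            recs = (tio.read_gff3_genes(ppath)
                    if ppath.suffix.lower() in {".gff", ".gff3"}
                    else tio.read_bed(ppath))
            positions = {r.name: r for r in recs}
        out = {}
        for sg in SUBGENOMES:
            genes = []
            for name, seq in tio.read_fasta(paths[sg]):
                pos = positions.get(name)
                genes.append(GeneRecord(
                    name, sg, seq,
                    chromosome=pos.chrom if pos else None,
                    start=pos.start if pos else None,
                    end=pos.end if pos else None,
                    strand=pos.strand if pos else "+"))
            out[sg] = genes
        return out

    def run_triplets(self) -> None:
        cfg = self.cfg
        genes = self._gene_inputs()
        triplets = build_triplets(genes["A"], genes["B"], genes["D"],
                                  cfg.min_identity, cfg.min_coverage)
        rows = []
        site_rows = []
        for t in triplets:
            hit_ab = t.pair_hits[("A", "B")]
            hit_ad = t.pair_hits[("A", "D")]
            hit_bd = t.pair_hits[("B", "D")]
            rows.append({
                "triplet": t.triplet_id,
                **{f"gene_{sg}": t.members[sg].gene_id for sg in SUBGENOMES},
                "identity_AB": hit_ab.identity, "identity_AD": hit_ad.identity,
                "identity_BD": hit_bd.identity,
                "coverage_AB": hit_ab.coverage, "coverage_AD": hit_ad.coverage,
                "coverage_BD": hit_bd.coverage})
            for s in call_diagnostic_sites(t):
                site_rows.append({"triplet": t.triplet_id, "position": s.position,
                                  "allele_A": s.alleles["A"],
                                  "allele_B": s.alleles["B"],
                                  "allele_D": s.alleles["D"],
                                  "class": s.site_class})
        cols = ["triplet", "gene_A", "gene_B", "gene_D", "identity_AB",
                "identity_AD", "identity_BD", "coverage_AB", "coverage_AD",
                "coverage_BD"]
        tio.write_tsv(pd.DataFrame(rows, columns=cols), self.path("triplets.tsv"))
        tio.write_tsv(pd.DataFrame(site_rows, columns=[
            "triplet", "position", "allele_A", "allele_B", "allele_D", "class"]),
            self.path("diagnostic_sites.tsv"))
        inputs = ([self.path(f"genes_{sg}.fasta") for sg in SUBGENOMES]
                  if cfg.simulate else
                  [Path(getattr(cfg, f"fasta_{sg.lower()}")) for sg in SUBGENOMES])
        self._record("triplets", inputs,
                     [self.path("triplets.tsv"), self.path("diagnostic_sites.tsv")])

    def _load_triplets(self) -> list:
        from .triplets import Triplet

        genes = self._gene_inputs()
        lookup = {g.gene_id: g for gl in genes.values() for g in gl}
        table = tio.read_tsv(self.path("triplets.tsv"))
        triplets = []
        for _, row in table.iterrows():
            members = {sg: lookup[row[f"gene_{sg}"]] for sg in SUBGENOMES}
            triplets.append(Triplet(row["triplet"], members))
        return triplets

    def run_quantify(self) -> None:
        cfg = self.cfg
        samples = self._sample_sheet()
        triplets = self._load_triplets()
        reads = {}
        fastq_paths = []
        for lib in samples["library"]:
            p = (self.path(f"reads_{lib}.fastq") if cfg.simulate
                 else Path(cfg.reads_dir) / f"{lib}.fastq")
            if not p.exists():
                raise ConfigError(f"FASTQ for library {lib!r} not found: {p}")
            reads[lib] = tio.read_fastq(p)
            fastq_paths.append(p)
        table = quantify(reads, triplets, max_mismatches=cfg.max_mismatches)
        tio.write_tsv(table, self.path("homeolog_counts.tsv"))
        self._record("quantify", [self.path("triplets.tsv")] + fastq_paths,
                     [self.path("homeolog_counts.tsv")])

    def _homeolog_count_matrix(self) -> pd.DataFrame:
        hc = tio.read_tsv(self.path("homeolog_counts.tsv"))
        long = []
        for _, row in hc.iterrows():
            for sg in SUBGENOMES:
                long.append({"feature": f"{row['triplet']}_{sg}",
                             "library": row["library"],
                             "count": int(round(row[f"c_{sg}"]))})
        return (pd.DataFrame(long)
                .pivot(index="feature", columns="library", values="count")
                .fillna(0).astype(int))

    def run_de(self) -> None:
        cfg = self.cfg
        counts = self._homeolog_count_matrix()
        samples = self._sample_sheet()
        de = tstats.de_table(counts, samples, cfg.fold, cfg.q)
        tio.write_tsv(de, self.path("de.tsv"))
        self._record("de", [self.path("homeolog_counts.tsv")],
                     [self.path("de.tsv")])

    def run_bias(self) -> None:
        cfg = self.cfg
        hc = tio.read_tsv(self.path("homeolog_counts.tsv"))
        bias = tstats.bias_table(hc, cfg.bias_p, cfg.bias_ratio)
        tio.write_tsv(bias, self.path("bias.tsv"))
        tio.write_tsv(tstats.summarize_bias(bias), self.path("bias_summary.tsv"))
        self._record("bias", [self.path("homeolog_counts.tsv")],
                     [self.path("bias.tsv"), self.path("bias_summary.tsv")])

    def run_partition(self) -> None:
        de = tio.read_tsv(self.path("de.tsv"))
        de = de.assign(
            triplet=de["feature"].str.rsplit("_", n=1).str[0],
            homeolog=de["feature"].str.rsplit("_", n=1).str[1])
        summary, tallies = tstats.summarize_partitioning(de)
        tio.write_tsv(summary, self.path("partition.tsv"))
        tio.write_tsv(tallies, self.path("tallies.tsv"))
        self._record("partition", [self.path("de.tsv")],
                     [self.path("partition.tsv"), self.path("tallies.tsv")])

    def run_hotspots(self) -> None:
        cfg = self.cfg
        bed_path = (self.path("layout.bed") if cfg.simulate
                    else Path(cfg.layout_bed) if cfg.layout_bed else None)
        if bed_path is None:
            raise ConfigError("config field 'layout_bed' is required for the "
                              "hotspots stage when simulation is disabled")
        flags_path = (self.path("layout_truth.tsv") if cfg.simulate
                      else Path(cfg.responsive_tsv) if cfg.responsive_tsv else None)
        if flags_path is None:
            raise ConfigError("config field 'responsive_tsv' is required for "
                              "the hotspots stage when simulation is disabled")
        bed = tio.read_bed(bed_path)
        flags = tio.read_tsv(flags_path)
        if not {"gene", "responsive"} <= set(flags.columns):
            raise ConfigError(f"{flags_path}: needs columns gene, responsive")
        resp = dict(zip(flags["gene"], flags["responsive"].astype(bool)))
        families = None
        if "family" in flags.columns:
            families = dict(zip(flags["gene"], flags["family"]))
        elif cfg.family_tsv:
            fam = tio.read_tsv(cfg.family_tsv)
            families = dict(zip(fam["gene"], fam["family"]))

        by_chrom: dict[str, list] = {}
        for rec in bed:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        layouts = []
        for chrom in sorted(by_chrom):
            recs = sorted(by_chrom[chrom], key=lambda r: r.start)
            gids = [r.name for r in recs]
            layouts.append(ChromosomeLayout(
                chrom, gids, [resp.get(g, False) for g in gids],
                [families[g] for g in gids] if families else None))
        windows, hotspots = scan_genome(layouts, cfg.window, cfg.step,
                                        cfg.min_run, families)
        wdf = pd.DataFrame([{"chromosome": w.chromosome, "start": w.start,
                             "window": w.window,
                             "percent_responsive": w.percent_responsive}
                            for w in windows],
                           columns=["chromosome", "start", "window",
                                    "percent_responsive"])
        hdf = pd.DataFrame([{"chromosome": h.chromosome, "start": h.start,
                             "end": h.end, "n_genes": h.length,
                             "genes": ",".join(h.gene_ids),
                             "tandem": h.tandem,
                             "dominant_family": h.dominant_family}
                            for h in hotspots],
                           columns=["chromosome", "start", "end", "n_genes",
                                    "genes", "tandem", "dominant_family"])
        tio.write_tsv(wdf, self.path("windows.tsv"))
        tio.write_tsv(hdf, self.path("hotspots.tsv"))
        self._record("hotspots", [bed_path, flags_path],
                     [self.path("windows.tsv"), self.path("hotspots.tsv")])

    def run_enrich(self) -> None:
        cfg = self.cfg
        if not cfg.term_map:
            logger.info("no term map configured; enrichment stage skipped")
            return
        terms = tio.read_tsv(cfg.term_map)
        if not {"gene", "term"} <= set(terms.columns):
            raise ConfigError(f"{cfg.term_map}: needs columns gene, term")
        term_to_genes = {t: set(g["gene"]) for t, g in terms.groupby("term")}
        de = tio.read_tsv(self.path("de.tsv"))
        population = sorted(de["feature"].unique())
        study = sorted(de.loc[de["call"] != "none", "feature"].unique())
        if not study:
            logger.warning("no differentially expressed features; "
                           "enrichment not computed")
            return
        result = tstats.enrich_terms(study, population, term_to_genes,
                                     cfg.enrich_p)
        tio.write_tsv(result, self.path("enrichment.tsv"))
        self._record("enrich", [self.path("de.tsv"), Path(cfg.term_map)],
                     [self.path("enrichment.tsv")])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; reuse fresh stage outputs.

    Returns the manifest dictionary.  Any stage failure propagates with the
    stage name logged.
    """
    pipe = Pipeline(config)
    config.to_yaml(pipe.path("config_resolved.yaml"))
    stage_fns = [("simulate", pipe.run_simulate) if config.simulate else None,
                 ("triplets", pipe.run_triplets),
                 ("quantify", pipe.run_quantify),
                 ("de", pipe.run_de),
                 ("bias", pipe.run_bias),
                 ("partition", pipe.run_partition),
                 ("hotspots", pipe.run_hotspots),
                 ("enrich", pipe.run_enrich)]
    for entry in stage_fns:
        if entry is None:
            continue
        stage, fn = entry
        rec = pipe.manifest["stages"].get(stage)
        if rec is not None and pipe._fresh(stage,
                                           [Path(p) for p in rec["inputs"]],
                                           [Path(p) for p in rec["outputs"]]):
            logger.info("stage %s: outputs up to date, skipped", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            fn()
        except Exception:
            logger.error("stage %s failed", stage)
            raise
    return pipe.manifest
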