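"""Tests for the synthetic allohexaploid data generator."""

import numpy as np
import pandas as pd
import pytest

import triadpart as tp
from triadpart.simulate import _maximal_runs, expected_pairwise_divergence

SEED = 0


class TestSimulateTriplets:
    def test_same_seed_is_byte_identical(self, tmp_path):
        out = []
        for rep in range(2):
            genes, _ = tp.simulate_triplets(4, 500, 0.03, seed=SEED)
            p = tmp_path / f"rep{rep}.fasta"
            tp.io.write_fasta(p, genes["A"] + genes["B"] + genes["D"])
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_record_counts(self):
        genes, truths = tp.simulate_triplets(5, 300, 0.02, seed=SEED)
        assert len(truths) == 5
        for sg in "ABD":
            assert len(genes[sg]) == 5
            assert all(len(seq) == 300 for _, seq in genes[sg])

    def test_pairwise_divergence_matches_model(self):
        """Observed substituted fraction stays within 3 binomial SD of the
        generator's process expectation for every homeolog pair."""
        n, L, d = 30, 1000, 0.02
        genes, _ = tp.simulate_triplets(n, L, d, seed=SEED)
        exp = expected_pairwise_divergence(d)
        sd = np.sqrt(exp * (1 - exp) / (n * L))
        for sg1, sg2 in (("A", "B"), ("A", "D"), ("B", "D")):
            diffs = sum(
                sum(c1 != c2 for c1, c2 in zip(s1, s2))
                for (_, s1), (_, s2) in zip(genes[sg1], genes[sg2]))
            assert abs(diffs / (n * L) - exp) < 3 * sd

    def test_snp_truth_columns_are_polymorphic(self, small_triplets):
        _, truths = small_triplets
        for t in truths:
            assert t.snp_sites  # 1 kb at 2% divergence: sites essentially certain
            for pos, alleles in t.snp_sites.items():
                assert len(set(alleles.values())) >= 2
                for sg in "ABD":
                    assert t.sequences[sg][pos] == alleles[sg]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="divergence"):
            tp.simulate_triplets(1, 300, 0.0, seed=SEED)
        with pytest.raises(ValueError):
            tp.simulate_triplets(0, 300, 0.02, seed=SEED)
        with pytest.raises(ValueError):
            tp.simulate_triplets(1, 100, 0.02, seed=SEED)


class TestSimulateExpression:
    def test_proportions_sum_to_one(self, expressed_truths):
        truths, design = expressed_truths
        for t in truths:
            for lib in design.libraries():
                pi = t.proportions(lib.library_id)
                assert sum(pi.values()) == pytest.approx(1.0)

    def test_degenerate_proportions(self):
        _, truths = tp.simulate_triplets(3, 300, 0.02, seed=SEED)
        design = tp.SimDesign(depth=100)
        tp.simulate_expression(truths, design,
                               fixed_proportions=(1 / 3, 1 / 3, 1 / 3),
                               de_fraction=0.0, seed=SEED)
        for t in truths:
            pi = t.proportions(design.libraries()[0].library_id)
            assert pi["A"] == pi["B"] == pi["D"]

    def test_null_model_has_no_stress_effect(self):
        _, truths = tp.simulate_triplets(3, 300, 0.02, seed=SEED)
        design = tp.SimDesign(depth=100)
        tp.simulate_expression(truths, design, de_fraction=0.0, seed=SEED)
        for t in truths:
            for geno in design.genotypes:
                for tp_h in design.timepoints_h:
                    a_c = t.abundance[f"{geno}_control_{tp_h}h"]
                    a_s = t.abundance[f"{geno}_stress_{tp_h}h"]
                    assert a_c == a_s

    def test_forced_fold_applies_exactly(self):
        _, truths = tp.simulate_triplets(4, 300, 0.02, seed=SEED)
        design = tp.SimDesign(depth=100)
        tp.simulate_expression(truths, design, de_fraction=1.0,
                               fold_range=(4.0, 4.0), de_direction="up",
                               seed=SEED)
        for t in truths:
            for geno in design.genotypes:
                for tp_h in design.timepoints_h:
                    a_c = t.abundance[f"{geno}_control_{tp_h}h"]
                    a_s = t.abundance[f"{geno}_stress_{tp_h}h"]
                    for sg in "ABD":
                        assert a_s[sg] / a_c[sg] == pytest.approx(4.0)


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, expressed_truths):
        truths, design = expressed_truths
        reads, origin = tp.simulate_reads(truths, design, seed=SEED)
        lookup = {t.triplet_id: t for t in truths}
        lib = design.libraries()[0].library_id
        by_id = dict(origin[origin.library == lib]
                     [["read_id", "triplet"]].values)
        starts = origin.set_index("read_id")
        for read_id, seq, qual in reads[lib][:200]:
            row = starts.loc[read_id]
            t = lookup[row["triplet"]]
            s = int(row["start"])
            assert t.sequences[row["homeolog"]][s:s + len(seq)] == seq
            assert qual == "I" * design.read_length

    def test_fixed_depth_is_exact_and_conserved(self, expressed_truths):
        truths, design = expressed_truths
        reads, origin = tp.simulate_reads(truths, design, seed=SEED)
        for lib in design.libraries():
            assert len(reads[lib.library_id]) == design.depth
            assert (origin.library == lib.library_id).sum() == design.depth

    def test_poisson_depth_within_three_sd(self):
        _, truths = tp.simulate_triplets(2, 500, 0.02, seed=SEED)
        design = tp.SimDesign(depth=10_000, depth_mode="poisson",
                              genotypes=("g",), timepoints_h=(6,))
        tp.simulate_expression(truths, design, seed=SEED)
        reads, _ = tp.simulate_reads(truths, design, seed=SEED)
        n = len(reads["g_control_6h"])
        assert abs(n - 10_000) <= 3 * np.sqrt(10_000)

    def test_degenerate_proportions_single_origin(self):
        _, truths = tp.simulate_triplets(1, 400, 0.02, seed=SEED)
        design = tp.SimDesign(depth=500, genotypes=("g",), timepoints_h=(6,))
        tp.simulate_expression(truths, design, fixed_proportions=(1, 0, 0),
                               seed=SEED)
        _, origin = tp.simulate_reads(truths, design, seed=SEED)
        assert set(origin.homeolog) == {"A"}

    def test_origin_fractions_converge_to_proportions(self):
        """Empirical origin fractions match pi within 3 standard errors."""
        _, truths = tp.simulate_triplets(2, 500, 0.02, seed=SEED)
        design = tp.SimDesign(depth=20_000, genotypes=("g",), timepoints_h=(6,),
                              error_rate=0.0)
        tp.simulate_expression(truths, design,
                               fixed_proportions=(0.5, 0.3, 0.2), seed=SEED)
        _, origin = tp.simulate_reads(truths, design, seed=SEED)
        counts = (origin[origin.library == "g_control_6h"]
                  .groupby(["triplet", "homeolog"]).size().unstack(fill_value=0))
        for tid, row in counts.iterrows():
            n = row.sum()
            for sg, p in zip("ABD", (0.5, 0.3, 0.2)):
                se = np.sqrt(p * (1 - p) / n)
                assert abs(row[sg] / n - p) < 3 * se

    def test_subseeding_is_per_library(self):
        """Adding libraries never perturbs the reads of earlier ones."""
        _, truths = tp.simulate_triplets(2, 400, 0.02, seed=SEED)
        d1 = tp.SimDesign(depth=300, genotypes=("g",), timepoints_h=(6,))
        d2 = tp.SimDesign(depth=300, genotypes=("g",), timepoints_h=(6, 12))
        tp.simulate_expression(truths, d2, seed=SEED)
        r1, _ = tp.simulate_reads(truths, d1, seed=SEED,
                                  libraries=d1.libraries())
        r2, _ = tp.simulate_reads(truths, d2, seed=SEED)
        assert r1["g_control_6h"] == r2["g_control_6h"]

    def test_read_longer_than_gene_rejected(self):
        _, truths = tp.simulate_triplets(1, 200, 0.02, seed=SEED)
        design = tp.SimDesign(depth=10, read_length=250)
        tp.simulate_expression(truths, design, seed=SEED)
        with pytest.raises(ValueError, match="length"):
            tp.simulate_reads(truths, design, seed=SEED)

    def test_paired_mode_draws_mates_from_one_fragment(self):
        _, truths = tp.simulate_triplets(1, 500, 0.02, seed=SEED)
        design = tp.SimDesign(depth=100, paired=True, error_rate=0.0,
                              genotypes=("g",), timepoints_h=(6,))
        tp.simulate_expression(truths, design, seed=SEED)
        reads, origin = tp.simulate_reads(truths, design, seed=SEED)
        lib = reads["g_control_6h"]
        assert len(lib) == 100  # 50 fragments x 2 mates
        mate1 = {r[0][:-2]: r[1] for r in lib if r[0].endswith("/1")}
        comp = str.maketrans("ACGT", "TGCA")
        starts = origin.set_index("read_id")
        t = truths[0]
        for rid2, seq2, _ in (r for r in lib if r[0].endswith("/2")):
            row = starts.loc[rid2]
            frag = t.sequences[row["homeolog"]][int(row["start"]):
                                                int(row["start"]) + 125]
            assert seq2 == frag.translate(comp)[::-1]
            assert rid2[:-2] in mate1


class TestSimulateLayout:
    def test_counts_and_planted_truth(self):
        spec = [(c, 10 + 15 * i, 3 + (i % 4), f"fam{i}")
                for c in range(2) for i in range(6)]
        bed, truths = tp.simulate_layout(2, 200, spec, 0.0, seed=SEED)
        assert len(bed) == 400
        assert sum(len(t.hotspots) for t in truths) == 12

    def test_null_layout(self):
        _, truths = tp.simulate_layout(1, 50, (), 0.0, seed=SEED)
        assert not any(truths[0].responsive)
        assert truths[0].hotspots == []

    def test_single_planted_run(self):
        _, truths = tp.simulate_layout(1, 50, [(0, 10, 5, "HSP20")], 0.0,
                                       seed=SEED)
        assert truths[0].hotspots == [(10, 15)]
        assert all(truths[0].responsive[10:15])
        assert sum(truths[0].responsive) == 5
        assert truths[0].families[10:15] == ["HSP20"] * 5

    @pytest.mark.parametrize("seed", range(5))
    def test_background_rerolls_keep_planted_runs_unique(self, seed):
        """With heavy background noise, the planted intervals are still the
        unique maximal runs of >= 3."""
        spec = [(0, 5, 4, "f1"), (0, 30, 3, "f2"), (1, 0, 6, "f3")]
        _, truths = tp.simulate_layout(2, 60, spec, 0.4, seed=seed)
        found = [(t.chromosome, s, e) for t in truths
                 for s, e in _maximal_runs(t.responsive, 3)]
        planted = [(t.chromosome, s, e) for t in truths
                   for s, e in t.hotspots]
        assert sorted(found) == sorted(planted)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="length >= 3"):
            tp.simulate_layout(1, 50, [(0, 0, 2, "f")], 0.0, seed=SEED)
        with pytest.raises(ValueError, match="exceeds"):
            tp.simulate_layout(1, 50, [(0, 48, 3, "f")], 0.0, seed=SEED)
        with pytest.raises(ValueError, match="overlap"):
            tp.simulate_layout(1, 50, [(0, 0, 3, "f"), (0, 3, 3, "g")], 0.0,
                               seed=SEED)
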