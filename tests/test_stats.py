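"""Tests for the DE, bias and enrichment statistics.

Fisher's exact p-values and hypergeometric enrichment are checked against
brute-force enumeration oracles written from the hypergeometric pmf; the
Benjamini–Hochberg step-up is checked against a direct O(m^2)
transcription of its definition.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import triadpart as tp
from triadpart.stats import (NotTestableError, bh_adjust, bias_table,
                             biased_percentage, call_bias, call_de,
                             chisq_bias, cpm_normalize, de_table,
                             enrich_terms, fisher_de, summarize_bias,
                             summarize_partitioning)

SEED = 0


# ---------------------------------------------------------------------------
# Oracles


def fisher_two_sided_oracle(a, ts, c, tc):
    """Two-sided Fisher exact p by enumerating the hypergeometric support:
    sum of P(k) over all tables (fixed margins) no more probable than the
    observed one."""
    n = a + c          # successes total
    N = ts + tc
    kmin, kmax = max(0, n - tc), min(n, ts)
    pmf = {k: sps.hypergeom.pmf(k, N, n, ts) for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def bh_oracle(pvalues):
    """Direct transcription of the step-up definition:
    q_i = min over p_(j) >= p_i of m * p_(j) / j, clipped at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {i: r + 1 for r, i in enumerate(order)}
    out = []
    for i in range(m):
        cands = [m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]]
        out.append(min(1.0, min(cands)))
    return out


def hypergeom_tail_oracle(hits, pop, pop_hits, study):
    return sum(sps.hypergeom.pmf(k, pop, pop_hits, study)
               for k in range(hits, min(study, pop_hits) + 1))


# ---------------------------------------------------------------------------


class TestCpm:
    def test_definition(self):
        counts = pd.DataFrame({"lib": [10, 999_990]}, index=["g1", "g2"])
        cpm = cpm_normalize(counts)
        assert cpm.at["g1", "lib"] == pytest.approx(10.0)

    def test_scale_invariance_and_total(self, rng):
        counts = pd.DataFrame({"l1": rng.integers(0, 500, 50) + 1})
        cpm1 = cpm_normalize(counts)
        cpm2 = cpm_normalize(counts * 2)
        assert np.allclose(cpm1, cpm2)
        assert cpm1["l1"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            cpm_normalize(pd.DataFrame({"l1": [0, 0]}))


class TestFisherDe:
    def test_null_table(self):
        p, fold = fisher_de(50, 1000, 50, 1000)
        assert p == 1.0
        assert fold == 1.0

    def test_empty_margins(self):
        p, fold = fisher_de(0, 1000, 0, 1000)
        assert p == 1.0
        assert fold == 1.0

    def test_against_enumeration_oracle(self):
        p, fold = fisher_de(40, 100_000, 10, 100_000)
        assert p == pytest.approx(fisher_two_sided_oracle(40, 100_000, 10,
                                                          100_000), rel=1e-6)
        # CPM 400 vs 100 with 0.5 pseudocount
        assert fold == pytest.approx(400.5 / 100.5)

    def test_exhaustive_small_tables(self):
        """All tables with both library totals <= 12 match the oracle."""
        for ts in range(1, 13):
            for tc in range(1, 13):
                for a in range(ts + 1):
                    for c in range(tc + 1):
                        p, _ = fisher_de(a, ts, c, tc)
                        assert p == pytest.approx(
                            fisher_two_sided_oracle(a, ts, c, tc),
                            rel=1e-9, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_de(5, 4, 0, 10)
        with pytest.raises(ValueError):
            fisher_de(0, 0, 0, 10)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_q_dominates_p_and_preserves_order(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDe:
    @pytest.mark.parametrize("fold,q,expected", [
        (2.0, 0.009, "up"),       # inclusive at exactly two-fold
        (1.99, 0.0001, "none"),   # below the fold gate
        (4.0, 0.011, "none"),     # fails the FDR gate
        (0.5, 0.005, "down"),
        (0.51, 0.005, "none"),
    ])
    def test_thresholds(self, fold, q, expected):
        assert call_de(fold, q) == expected


class TestChisqBias:
    def test_perfect_balance(self):
        stat, p = chisq_bias(100, 100, 100)
        assert stat == 0.0
        assert p == 1.0

    def test_forced_arithmetic(self):
        stat, p = chisq_bias(150, 75, 75)
        assert stat == pytest.approx(37.5)
        assert p == pytest.approx(np.exp(-37.5 / 2), rel=1e-12)

    def test_closed_form_survival(self, rng):
        """With df = 2 the chi-square survival function is exp(-x/2)."""
        for _ in range(50):
            obs = rng.integers(1, 500, 3)
            stat, p = chisq_bias(*obs)
            assert p == pytest.approx(np.exp(-stat / 2), rel=1e-12)

    def test_zero_total_not_testable(self):
        with pytest.raises(NotTestableError):
            chisq_bias(0, 0, 0)


class TestCallBias:
    def test_ratio_and_p_gates(self):
        stat, p = chisq_bias(150, 100, 100)
        assert stat == pytest.approx(100 / 7)  # E = 350/3
        assert p == pytest.approx(np.exp(-stat / 2), rel=1e-12)
        assert p < 0.01
        assert call_bias(p, (150, 100, 100)) is True     # ratio exactly 1.5
        assert call_bias(p, (140, 100, 100)) is False    # ratio 1.4

    def test_zero_minimum_is_infinite_ratio(self):
        assert call_bias(0.001, (100, 100, 0)) is True
        assert call_bias(0.5, (100, 100, 0)) is False


class TestBiasTables:
    def test_bias_table_rounds_allocated_counts(self):
        hc = pd.DataFrame([
            {"triplet": "T0", "library": "l1",
             "c_A": 150.4, "c_B": 74.8, "c_D": 74.8},
            {"triplet": "T1", "library": "l1",
             "c_A": 0.0, "c_B": 0.0, "c_D": 0.0},  # skipped
        ])
        out = bias_table(hc)
        assert len(out) == 1
        assert out.iloc[0]["statistic"] == pytest.approx(37.5)
        assert bool(out.iloc[0]["biased"]) is True

    def test_percentage_reporting(self):
        assert biased_percentage(1, 3) == 33.3
        with pytest.raises(ValueError):
            biased_percentage(5, 4)

    def test_summarize_bias_counts(self):
        bias = pd.DataFrame({
            "triplet": [f"T{i}" for i in range(4)],
            "library": ["l1"] * 4,
            "statistic": [0.0, 20.0, 30.0, 40.0],
            "p": [1.0, 1e-5, 1e-7, 1e-9],
            "ratio": [1.0, 1.2, 2.0, 3.0],
            "biased": [False, False, True, True],
        })
        out = summarize_bias(bias).iloc[0]
        assert out["n_tested"] == 4
        assert out["n_p_significant"] == 3
        assert out["pct_p_significant"] == 75.0
        assert out["n_biased"] == 2
        assert out["pct_biased"] == 50.0


class TestPartitioning:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["triplet", "homeolog", "genotype",
                                           "timepoint", "call"])

    def test_identical_calls_are_equal_contribution(self):
        rows = [("T0", sg, "g", 6, "up") for sg in "ABD"]
        summary, _ = summarize_partitioning(self._calls(rows))
        assert summary.iloc[0]["responsive"]
        assert not summary.iloc[0]["unequal"]

    def test_partial_response_is_unequal(self):
        rows = [("T0", "A", "g", 12, "up"), ("T0", "B", "g", 12, "none"),
                ("T0", "D", "g", 12, "none")]
        summary, _ = summarize_partitioning(self._calls(rows))
        assert summary.iloc[0]["responsive"]
        assert summary.iloc[0]["unequal"]

    def test_aggregates_match_exhaustive_recount(self, rng):
        """Aggregate tallies over a toy set of 10 triplets equal a direct
        recount of the hand-expanded call vectors."""
        calls = ["up", "down", "none"]
        rows = []
        for i in range(10):
            for sg in "ABD":
                for geno in ("cs", "qm"):
                    for tp_h in (6, 12):
                        rows.append((f"T{i}", sg, geno, tp_h,
                                     calls[rng.integers(0, 3)]))
        df = self._calls(rows)
        summary, tallies = summarize_partitioning(df)

        # brute-force recount
        resp = unequal = 0
        for tid, grp in df.groupby("triplet"):
            vecs = [tuple(sub.sort_values("homeolog")["call"])
                    for _, sub in grp.groupby(["genotype", "timepoint"])]
            r = any(any(c != "none" for c in v) for v in vecs)
            u = any(any(c != "none" for c in v) and len(set(v)) > 1
                    for v in vecs)
            resp += r
            unequal += u
        assert summary["responsive"].sum() == resp
        assert summary["unequal"].sum() == unequal
        for _, t in tallies.iterrows():
            n = ((df.genotype == t.genotype) & (df.timepoint == t.timepoint)
                 & (df.homeolog == t.homeolog) & (df.call == t.call)).sum()
            assert t.n_triplets == n

    def test_unequal_implies_responsive(self):
        rows = [("T0", sg, "g", 6, "none") for sg in "ABD"]
        summary, _ = summarize_partitioning(self._calls(rows))
        assert not summary.iloc[0]["responsive"]
        assert not summary.iloc[0]["unequal"]

    def test_incomplete_triplet_excluded(self):
        rows = [("T0", "A", "g", 6, "up")]
        summary, _ = summarize_partitioning(self._calls(rows))
        assert summary.empty


class TestEnrichment:
    def test_term_covering_population(self):
        pop = [f"g{i}" for i in range(100)]
        out = enrich_terms(pop[:10], pop, {"all": pop})
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        pop = [f"g{i}" for i in range(100)]
        study = pop[:10]
        term = pop[:5] + pop[50:55]  # 5 hits in study, 10 in population
        out = enrich_terms(study, pop, {"t": term})
        assert out.iloc[0]["study_hits"] == 5
        assert out.iloc[0]["p"] == pytest.approx(
            hypergeom_tail_oracle(5, 100, 10, 10), rel=1e-9)

    def test_rare_term_identical_to_study_is_significant(self):
        pop = [f"g{i}" for i in range(500)]
        study = pop[:5]
        out = enrich_terms(study, pop, {"t": study})
        assert out.iloc[0]["p"] == pytest.approx(
            hypergeom_tail_oracle(5, 500, 5, 5), rel=1e-9)
        assert out.iloc[0]["p"] <= 0.01
        assert bool(out.iloc[0]["significant"])

    def test_study_outside_population_rejected(self):
        with pytest.raises(ValueError):
            enrich_terms(["x"], ["a", "b"], {})
        with pytest.raises(ValueError, match="empty"):
            enrich_terms([], [], {})


class TestDeTable:
    def test_contrasts_and_families(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, (20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=["s6", "c6", "s12", "c12"])
        counts.iloc[0, 0] *= 8  # one strong up at 6 h
        samples = pd.DataFrame({
            "library": ["s6", "c6", "s12", "c12"],
            "genotype": ["g"] * 4,
            "condition": ["stress", "control", "stress", "control"],
            "timepoint": [6, 6, 12, 12]})
        de = de_table(counts, samples)
        assert set(de.timepoint) == {6, 12}
        assert len(de) == 40
        g0 = de[(de.feature == "g0") & (de.timepoint == 6)].iloc[0]
        assert g0.call == "up"
        # BH is per-contrast: each family's q values depend only on its ps
        fam = de[de.timepoint == 6]
        assert fam["q"].to_numpy() == pytest.approx(
            bh_adjust(fam["p"].to_numpy()))

    def test_unexpressed_features_excluded(self):
        counts = pd.DataFrame({"s": [0, 5], "c": [0, 5]},
                              index=["silent", "expressed"])
        samples = pd.DataFrame({
            "library": ["s", "c"], "genotype": ["g", "g"],
            "condition": ["stress", "control"], "timepoint": [6, 6]})
        de = de_table(counts, samples)
        assert set(de.feature) == {"expressed"}
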