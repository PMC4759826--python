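"""Differential expression, homeolog-bias and enrichment statistics.

The experimental design has one library per (genotype, condition,
timepoint) cell — no sequenced replicates — so differential expression per
contrast is tested with Fisher's exact test on raw counts against library
totals, with a two-fold change gate on CPM and Benjamini–Hochberg control
of the false discovery rate (call thresholds: fold >= 2 or <= 0.5 and
BH-adjusted q < 0.01).  Homeolog expression bias within a triplet is tested
against the balanced 1A:1B:1D expectation with a chi-square goodness-of-fit
test (df = 2), gated by the requirement that the most-expressed homeolog is
at least 1.5-fold the least-expressed one (Expmax/Expmin >= 1.5, flagged at
p < 0.01).  Term enrichment uses a one-sided hypergeometric (Fisher) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

SUBGENOMES = ("A", "B", "D")

#: CPM pseudocount used on both sides of the fold-change ratio.
FOLD_EPSILON_CPM = 0.5


# ---------------------------------------------------------------------------
# Normalisation and kernels


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per library (column). Zero-total libraries are rejected."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total libraries: {list(zero.index)}")
    return counts * 1e6 / totals


def fisher_de(count_stress: int, total_stress: int,
              count_control: int, total_control: int) -> tuple[float, float]:
    """Two-sided Fisher exact p and CPM fold change for one contrast.

    The 2x2 table is [[count_stress, rest_stress], [count_control,
    rest_control]].  The fold change is computed on CPM with a pseudocount
    of 0.5 CPM on both sides, so zero counts give finite folds.
    """
    if total_stress <= 0 or total_control <= 0:
        raise ValueError("library totals must be positive")
    if count_stress > total_stress or count_control > total_control:
        raise ValueError("count exceeds library total")
    table = [[count_stress, total_stress - count_stress],
             [count_control, total_control - count_control]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    cpm_s = count_stress * 1e6 / total_stress
    cpm_c = count_control * 1e6 / total_control
    fold = (cpm_s + FOLD_EPSILON_CPM) / (cpm_c + FOLD_EPSILON_CPM)
    return float(p), float(fold)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to 1, in the original
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(fold: float, q: float, fold_threshold: float = 2.0,
            q_threshold: float = 0.01) -> str:
    """'up' iff fold >= threshold and q < q_threshold; 'down' for the reciprocal."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    if q < q_threshold:
        if fold >= fold_threshold:
            return "up"
        if fold <= 1.0 / fold_threshold:
            return "down"
    return "none"


class NotTestableError(ValueError):
    """Raised when a triplet has zero total expression (bias test undefined)."""


def chisq_bias(c_A: float, c_B: float, c_D: float) -> tuple[float, float]:
    """Chi-square goodness-of-fit of (c_A, c_B, c_D) against 1:1:1 (df = 2)."""
    obs = np.array([c_A, c_B, c_D], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise NotTestableError("zero total: bias not testable")
    expected = total / 3.0
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=2))
    return stat, p


def call_bias(p: float, expressions: tuple[float, float, float],
              p_threshold: float = 0.01, ratio_threshold: float = 1.5) -> bool:
    """Biased iff p < 0.01 and Expmax/Expmin >= 1.5 (ratio = inf when min = 0)."""
    e = np.asarray(expressions, dtype=float)
    if (e < 0).any():
        raise ValueError("expressions must be non-negative")
    emin, emax = e.min(), e.max()
    ratio = np.inf if emin == 0 and emax > 0 else (emax / emin if emin > 0 else 1.0)
    return bool(p < p_threshold and ratio >= ratio_threshold)


# ---------------------------------------------------------------------------
# Tables


def expressed_features(counts: pd.DataFrame, min_count: int = 1) -> pd.Index:
    """Features with raw count >= min_count in at least one library."""
    return counts.index[(counts >= min_count).any(axis=1)]


def de_table(counts: pd.DataFrame, samples: pd.DataFrame,
             fold_threshold: float = 2.0, q_threshold: float = 0.01
             ) -> pd.DataFrame:
    """Per-feature stress-vs-control calls for every (genotype, timepoint).

    ``counts`` is features x libraries (raw); ``samples`` must carry
    columns library/genotype/condition/timepoint.  Only expressed features
    (count >= 1 in >= 1 library) are tested, and BH adjustment is applied
    within each contrast family.
    """
    required = {"library", "genotype", "condition", "timepoint"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    keep = expressed_features(counts)
    counts = counts.loc[keep]
    totals = counts.sum(axis=0)
    rows = []
    for (geno, tp), grp in samples.groupby(["genotype", "timepoint"], sort=True):
        by_cond = grp.set_index("condition")["library"]
        if "stress" not in by_cond.index or "control" not in by_cond.index:
            continue
        lib_s, lib_c = by_cond["stress"], by_cond["control"]
        ts, tc = int(totals[lib_s]), int(totals[lib_c])
        ps, folds = [], []
        for feat in counts.index:
            p, fold = fisher_de(int(counts.at[feat, lib_s]), ts,
                                int(counts.at[feat, lib_c]), tc)
            ps.append(p)
            folds.append(fold)
        qs = bh_adjust(ps)
        for feat, p, fold, q in zip(counts.index, ps, folds, qs):
            rows.append({"feature": feat, "genotype": geno, "timepoint": tp,
                         "fold": fold, "p": p, "q": q,
                         "call": call_de(fold, q, fold_threshold, q_threshold)})
    return pd.DataFrame(rows)


def bias_table(homeolog_counts: pd.DataFrame, p_threshold: float = 0.01,
               ratio_threshold: float = 1.5) -> pd.DataFrame:
    """Per-(triplet, library) homeolog bias test on allocated counts.

    The chi-square test consumes allocated counts rounded to the nearest
    integer (allocation conserves totals, so rounding error is bounded by
    one read per homeolog); the Expmax/Expmin ratio uses the unrounded
    values.  Zero-total triplets are skipped.
    """
    rows = []
    for _, rec in homeolog_counts.iterrows():
        alloc = np.array([rec["c_A"], rec["c_B"], rec["c_D"]], dtype=float)
        if alloc.sum() <= 0:
            continue
        rounded = np.rint(alloc)
        if rounded.sum() <= 0:
            continue
        stat, p = chisq_bias(*rounded)
        emin, emax = alloc.min(), alloc.max()
        ratio = np.inf if emin == 0 else emax / emin
        rows.append({"triplet": rec["triplet"], "library": rec["library"],
                     "statistic": stat, "p": p, "ratio": ratio,
                     "biased": call_bias(p, tuple(alloc), p_threshold,
                                         ratio_threshold)})
    return pd.DataFrame(rows,
                        columns=["triplet", "library", "statistic", "p",
                                 "ratio", "biased"])


def biased_percentage(n_biased: int, n_total: int) -> float:
    """Percentage of tested triplets flagged biased, to one decimal place."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= n_biased <= n_total):
        raise ValueError("biased count must lie in [0, total]")
    return round(100.0 * n_biased / n_total, 1)


def summarize_bias(bias: pd.DataFrame) -> pd.DataFrame:
    """Per-library bias summary with percentage reporting.

    For each library: number of testable triplets, number with chi-square
    p < 0.01 (and its percentage of tested), and number/percentage also
    passing the Expmax/Expmin >= 1.5 gate (the ``biased`` flag).
    """
    rows = []
    for lib, grp in bias.groupby("library", sort=True):
        n_tested = len(grp)
        n_sig = int((grp["p"] < 0.01).sum())
        n_biased = int(grp["biased"].sum())
        rows.append({
            "library": lib, "n_tested": n_tested,
            "n_p_significant": n_sig,
            "pct_p_significant": biased_percentage(n_sig, n_tested),
            "n_biased": n_biased,
            "pct_biased": biased_percentage(n_biased, n_tested)})
    return pd.DataFrame(rows)


def summarize_partitioning(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-triplet responsiveness and unequal-contribution flags.

    ``calls`` is a long table with columns triplet/homeolog/genotype/
    timepoint/call (one row per homeolog per stress contrast).  A triplet is
    responsive if at least one homeolog is called up or down in at least one
    contrast; its contribution is unequal if, in at least one contrast, the
    three homeolog calls are not all identical.  Triplets with missing
    homeolog calls in a contrast are excluded.  Also returns the aggregate
    per-(genotype, timepoint, homeolog) up/down tallies.
    """
    required = {"triplet", "homeolog", "genotype", "timepoint", "call"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls table must have columns {sorted(required)}")
    rows = []
    excluded = []
    for triplet, grp in calls.groupby("triplet", sort=True):
        complete = True
        responsive = False
        unequal = False
        per_contrast = {}
        for (geno, tp), sub in grp.groupby(["genotype", "timepoint"]):
            sub = sub.set_index("homeolog")["call"]
            if set(sub.index) != set(SUBGENOMES):
                complete = False
                break
            vec = tuple(sub[sg] for sg in SUBGENOMES)
            per_contrast[(geno, tp)] = vec
            if any(c != "none" for c in vec):
                responsive = True
                if len(set(vec)) > 1:
                    unequal = True
        if not complete:
            excluded.append(triplet)
            continue
        rows.append({"triplet": triplet, "responsive": responsive,
                     "unequal": unequal and responsive})
    if excluded:
        import logging
        logging.getLogger(__name__).warning(
            "%d triplets excluded for missing homeolog calls", len(excluded))
    summary = pd.DataFrame(rows, columns=["triplet", "responsive", "unequal"])

    tallies = (calls[calls["call"].isin(["up", "down"])]
               .groupby(["genotype", "timepoint", "homeolog", "call"])
               .size().rename("n_triplets").reset_index())
    return summary, tallies


def enrich_terms(study: Iterable[str], population: Iterable[str],
                 term_to_genes: Mapping[str, Iterable[str]],
                 p_threshold: float = 0.01) -> pd.DataFrame:
    """One-sided hypergeometric (Fisher) term enrichment.

    For each term, p = P(X >= study hits) with X hypergeometric over the
    population; terms with p <= ``p_threshold`` are flagged significant.
    """
    pop = set(population)
    if not pop:
        raise ValueError("population is empty")
    stu = set(study)
    if not stu <= pop:
        raise ValueError("study set must be a subset of the population")
    rows = []
    for term in sorted(term_to_genes):
        genes = set(term_to_genes[term]) & pop
        hits = len(genes & stu)
        p = float(sps.hypergeom.sf(hits - 1, len(pop), len(genes), len(stu)))
        rows.append({"term": term, "study_hits": hits, "study_size": len(stu),
                     "population_hits": len(genes), "population_size": len(pop),
                     "p": min(p, 1.0), "significant": p <= p_threshold})
    return pd.DataFrame(rows)
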