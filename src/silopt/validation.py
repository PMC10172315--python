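"""Self-validation routines: oracle checks and parameter-recovery studies.

These functions re-derive the package's key guarantees from scratch on
synthetic data — exact-test agreement with brute-force enumeration, BH
step-up correctness and false-discovery control, recovery of planted
timing/context/expression effects, and exact round-tripping of planted
codon changes through the MAF reader and scorer.  They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .candidates import run_candidate_screen
from .codon_usage import SENSE_CODONS, human_codon_usage, is_synonymous
from .context import context_score_association
from .evolution import TIMING_CLASSES, attach_timing, compare_scores_by_timing
from .io import read_maf, resolve_cohort
from .scoring import score_cohort, score_mutation
from .simulate import (
    SimulationConfig,
    build_substitution_pools,
    draw_silent_mutations,
    simulate_candidate_study,
    simulate_cds,
    simulate_cohort,
)
from .stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "score_antisymmetry_violations",
    "enumeration_rank_sum_p",
    "wilcoxon_oracle_agreement",
    "bh_step_up_reference",
    "bh_oracle_max_error",
    "bh_fdp_control",
    "timing_shift_recovery",
    "context_coupling_recovery",
    "candidate_screen_performance",
    "roundtrip_exact_fraction",
]


# --- score primitive -------------------------------------------------------


def score_antisymmetry_violations(table=None) -> int:
    """Violations of score(a,b) = -score(b,a) and score(a,a) = 0 over all
    synonymous sense-codon pairs (0 for a correct implementation)."""
    table = human_codon_usage() if table is None else table
    violations = 0
    for a in SENSE_CODONS:
        if score_mutation(a, a, table) != 0.0:
            violations += 1
        for b in SENSE_CODONS:
            if a < b and is_synonymous(a, b):
                fwd = score_mutation(a, b, table)
                rev = score_mutation(b, a, table)
                if abs(fwd + rev) > 1e-12:
                    violations += 1
    return violations


# --- Wilcoxon oracle -------------------------------------------------------


def enumeration_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)
    order = np.argsort(pooled)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    us = np.array(
        [ranks[list(idx)].sum() - n_x * (n_x + 1) / 2
         for idx in combinations(range(n), n_x)]
    )
    return float(min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())))


def wilcoxon_oracle_agreement(n_cases: int = 1000, seed: int = 0,
                              max_total: int = 8) -> float:
    """Fraction of random small untied samples where the exact Wilcoxon p
    equals the enumeration oracle (to 1e-12)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n_x = int(rng.integers(1, max_total - 1))
        n_y = int(rng.integers(1, max_total - n_x + 1))
        pooled = rng.permutation(np.arange(50, dtype=float))[: n_x + n_y]
        x, y = pooled[:n_x], pooled[n_x:]
        res = wilcoxon_rank_sum(x, y)
        if res.method == "exact" and abs(
            res.p_value - enumeration_rank_sum_p(x, y)
        ) < 1e-12:
            agree += 1
    return agree / n_cases


# --- BH oracle and FDP control --------------------------------------------


def bh_step_up_reference(p: np.ndarray) -> np.ndarray:
    """Closed-form BH step-up, written independently of the package path."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_oracle_max_error(n_reps: int = 100, m: int = 100, seed: int = 0) -> float:
    """Max |bh_adjust - closed form| over random p-vectors (with ties)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        p = np.round(rng.uniform(size=m), 3)
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - bh_step_up_reference(p)))))
    return worst


def bh_fdp_control(n_reps: int = 100, m: int = 10_000, n_true: int = 100,
                   alpha: float = 0.25, seed: int = 0) -> float:
    """Mean realized false-discovery proportion of BH at level ``alpha``.

    Each replicate mixes ``n_true`` strong signals (p near 0) into
    ``m - n_true`` null uniforms; the FDP is the fraction of rejections
    that are null.  BH guarantees the mean FDP is <= alpha (and <=
    alpha * (m - n_true) / m under this mixture)."""
    rng = np.random.default_rng(seed)
    fdp = []
    for _ in range(n_reps):
        p = np.concatenate(
            [rng.uniform(0, 1e-8, size=n_true), rng.uniform(size=m - n_true)]
        )
        rejected = bh_adjust(p) < alpha
        n_false = int(rejected[n_true:].sum())
        n_rej = int(rejected.sum())
        fdp.append(n_false / n_rej if n_rej else 0.0)
    return float(np.mean(fdp))


# --- parameter recovery ----------------------------------------------------


def _shared_pool(seed: int, n_genes: int = 60) -> pd.DataFrame:
    config = SimulationConfig(seed=seed, n_genes=n_genes)
    cds, genes = simulate_cds(config)
    silent, _ = build_substitution_pools(cds, genes)
    return silent


def timing_shift_recovery(
    n_replicates: int = 100,
    n_per_class: int = 500,
    shift: float = 5.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates where a planted subclonal score shift is
    recovered: subclonal median above every clonal class and BH-adjusted
    Wilcoxon p < alpha for all subclonal contrasts."""
    pool = _shared_pool(seed)
    rng = np.random.default_rng(seed + 1)
    n_by_class = {c: n_per_class for c in TIMING_CLASSES}
    successes = 0
    for _ in range(n_replicates):
        drawn = draw_silent_mutations(
            pool, n_by_class, {"subclonal": shift}, 0.0, rng
        )
        report = compare_scores_by_timing(drawn)
        summary = report["summary"]
        medians_ok = all(
            summary.loc["subclonal", "median"] > summary.loc[c, "median"]
            for c in TIMING_CLASSES
            if c != "subclonal"
        )
        contrasts = report["contrasts"]
        sub = contrasts[
            (contrasts["class_a"] == "subclonal")
            | (contrasts["class_b"] == "subclonal")
        ]
        if medians_ok and (sub["fdr"] < alpha).all():
            successes += 1
    return successes / n_replicates


def context_coupling_recovery(
    n_replicates: int = 100,
    n_mutations: int = 2000,
    coupling: float = -0.5,
    seed: int = 0,
) -> float:
    """Fraction of replicates where a planted negative score-context
    coupling is recovered as high-context-group median score below the
    low-context-group median (k = 10 analysis)."""
    pool = _shared_pool(seed)
    rng = np.random.default_rng(seed + 2)
    successes = 0
    for _ in range(n_replicates):
        drawn = draw_silent_mutations(
            pool, {"clonal_NA": n_mutations}, {}, coupling, rng
        )
        profiles = pd.DataFrame(
            {"k": 10, "mean_both": drawn["context_freq"], "score": drawn["score"]}
        )
        report = context_score_association(profiles, 10)
        summary = report["summary"]
        if summary.loc["high", "median"] < summary.loc["low", "median"]:
            successes += 1
    return successes / n_replicates


def candidate_screen_performance(
    n_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 1000,
    n_samples: int = 300,
    n_causal: int = 10,
    n_mut_samples: int = 20,
    expression_shift: float = 0.5,
    fdr_threshold: float = 0.25,
) -> dict:
    """Sensitivity and empirical false-discovery rate of the candidate
    screen on cohorts with planted causal genes, averaged over seeds."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    sens, fdp = [], []
    for s in sub_seeds:
        mutations, expr, types, truth = simulate_candidate_study(
            seed=int(s), n_genes=n_genes, n_samples=n_samples,
            n_causal=n_causal, n_mut_samples=n_mut_samples,
            expression_shift=expression_shift,
        )
        selected, _ = run_candidate_screen(
            mutations, expr, types, fdr_threshold=fdr_threshold
        )
        causal = set(truth.loc[truth["causal"], "gene"])
        passed = set(selected.loc[selected["passed"], "gene"])
        sens.append(len(passed & causal) / n_causal)
        fdp.append(len(passed - causal) / len(passed) if passed else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "empirical_fdr": float(np.mean(fdp)),
        "n_seeds": n_seeds,
    }


# --- round trip ------------------------------------------------------------


def roundtrip_exact_fraction(seed: int = 0, tmp_dir=None) -> dict:
    """Write a simulated cohort to MAF, read it back, resolve codons and
    score; return the fraction of planted silent mutations whose score is
    reproduced exactly, plus the number of mutations checked."""
    import tempfile
    from pathlib import Path

    config = SimulationConfig(
        seed=seed, n_genes=50, n_samples=60, mutations_per_sample=80
    )
    rng = config.rng()
    cds, genes = simulate_cds(config, rng=rng)
    maf, timing, truth = simulate_cohort(config, cds, genes, rng=rng)

    with tempfile.TemporaryDirectory(dir=tmp_dir) as tmp:
        path = Path(tmp) / "cohort.maf"
        maf.to_csv(path, sep="\t", index=False)
        read = read_maf(path)
    resolved = resolve_cohort(read, cds)
    scored = score_cohort(resolved, human_codon_usage())

    key = ["sample_id", "transcript_id", "cds_pos", "ref_base", "alt_base"]
    silent_truth = truth[truth["variant_class"] == "silent"]
    merged = scored.merge(
        silent_truth[key + ["ref_codon", "alt_codon", "score"]],
        on=key, suffixes=("", "_truth"),
    )
    exact = (
        (merged["ref_codon"] == merged["ref_codon_truth"])
        & (merged["alt_codon"] == merged["alt_codon_truth"])
        & (np.abs(merged["score"] - merged["score_truth"]) < 1e-12)
    )
    return {
        "fraction_exact": float(exact.mean()) if len(merged) else 0.0,
        "n_mutations": int(len(merged)),
        "n_planted": int(len(silent_truth)),
    }
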