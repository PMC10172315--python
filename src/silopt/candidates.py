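"""Recurrent-silent-mutation candidate screen.

The screen walks the funnel used to nominate pathogenic silent mutations:

1. pool silent mutations and keep variants recurring in >= 3 distinct
   samples (cancer types pooled);
2. keep variants with absolute codon optimality score >= 10;
3. flag (but do not remove) variants overlapping splicing elements;
4. within each cancer type where the variant again recurs in >= 3
   samples, test the gene's expression (log10 TPM) in mutated vs.
   non-mutated samples of that type with a two-sided Wilcoxon test and
   require the type's mean log10 TPM >= 1;
5. Benjamini-Hochberg across all tested (variant, cancer type) pairs and
   keep FDR < 0.25;
6. check co-occurrence of missense/nonsense mutations in the same gene.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANT_KEY",
    "find_recurrent",
    "filter_candidates",
    "flag_splicing_overlap",
    "test_expression_association",
    "adjust_and_select",
    "cooccurrence_check",
    "run_candidate_screen",
]

#: columns identifying one substitution
VARIANT_KEY = ["gene", "transcript_id", "cds_pos", "ref_base", "alt_base"]

DEFAULT_MIN_RECURRENCE = 3
DEFAULT_MIN_ABS_SCORE = 10.0
DEFAULT_FDR_THRESHOLD = 0.25
DEFAULT_MIN_MEAN_LOG_TPM = 1.0
DEFAULT_PSEUDOCOUNT = 0.01


def find_recurrent(
    mutations: pd.DataFrame,
    min_samples: int = DEFAULT_MIN_RECURRENCE,
    per_cancer_type: bool = False,
) -> pd.DataFrame:
    """Variants observed in >= ``min_samples`` distinct samples.

    Duplicate (sample, variant) rows are collapsed first.  With
    ``per_cancer_type=False`` (pooled) the result has one row per variant
    with ``n_samples_total``, a ``samples`` tuple, and a by-type count
    dict; with ``per_cancer_type=True`` it has one row per (variant,
    cancer type) whose within-type distinct-sample count reaches the
    threshold.
    """
    cols = VARIANT_KEY + ["sample_id", "cancer_type"]
    extra = [c for c in ("score", "score_group") if c in mutations.columns]
    dedup = mutations[cols + extra].drop_duplicates(subset=VARIANT_KEY + ["sample_id"])
    if per_cancer_type:
        grouped = dedup.groupby(VARIANT_KEY + ["cancer_type"], dropna=False, sort=True)
        out = grouped.agg(
            n_samples=("sample_id", "nunique"),
            samples=("sample_id", lambda s: tuple(sorted(s))),
            **{c: (c, "first") for c in extra},
        ).reset_index()
        return out[out["n_samples"] >= min_samples].reset_index(drop=True)
    grouped = dedup.groupby(VARIANT_KEY, dropna=False, sort=True)
    out = grouped.agg(
        n_samples_total=("sample_id", "nunique"),
        samples=("sample_id", lambda s: tuple(sorted(s))),
        n_samples_by_cancer_type=(
            "cancer_type",
            lambda s: dict(s.value_counts()),
        ),
        **{c: (c, "first") for c in extra},
    ).reset_index()
    return out[out["n_samples_total"] >= min_samples].reset_index(drop=True)


def filter_candidates(
    recurrent: pd.DataFrame, min_abs_score: float = DEFAULT_MIN_ABS_SCORE
) -> pd.DataFrame:
    """Keep variants with |score| >= ``min_abs_score`` (boundary included)."""
    return recurrent[recurrent["score"].abs() >= min_abs_score].reset_index(drop=True)


def flag_splicing_overlap(
    mutations: pd.DataFrame,
    intervals: pd.DataFrame,
    seq_column: str = "transcript_id",
    pos_column: str = "cds_pos",
) -> pd.Series:
    """Boolean flag per mutation: lies inside a splicing-element interval.

    ``intervals`` is BED-convention: columns ``seq_id``, ``start``,
    ``end`` with 0-based half-open coordinates.  A 1-based position ``p``
    overlaps an interval iff ``start <= p - 1 < end``; flagged mutations
    are reported, not removed.
    """
    flags = pd.Series(False, index=mutations.index)
    if intervals is None or len(intervals) == 0:
        return flags
    by_seq = {s: g[["start", "end"]].to_numpy() for s, g in intervals.groupby("seq_id")}
    for idx, row in mutations.iterrows():
        iv = by_seq.get(row[seq_column])
        if iv is None:
            continue
        p0 = int(row[pos_column]) - 1
        if np.any((iv[:, 0] <= p0) & (p0 < iv[:, 1])):
            flags.at[idx] = True
    return flags


def _log_tpm(values: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.log10(values + pseudocount)


def test_expression_association(
    gene: str,
    mutated_samples: Sequence[str],
    expression: pd.DataFrame,
    sample_types: Mapping[str, str],
    cancer_type: str,
    min_samples: int = DEFAULT_MIN_RECURRENCE,
    min_mean_log_tpm: float = DEFAULT_MIN_MEAN_LOG_TPM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Optional[dict]:
    """Wilcoxon test of a gene's expression, mutated vs. wild-type samples.

    Both groups are restricted to samples of ``cancer_type`` present in
    the expression matrix.  Expression is compared on the log10(TPM +
    pseudocount) scale; the mean-expression filter (mean log10 TPM >=
    ``min_mean_log_tpm``) is evaluated over all samples of the cancer
    type.  Returns ``None`` when the gene is absent from the matrix, the
    mutated group is smaller than ``min_samples``, or the wild-type group
    is empty.
    """
    if gene not in expression.index:
        warnings.warn(f"gene {gene} absent from expression matrix; skipped")
        return None
    type_samples = [
        s for s in expression.columns if sample_types.get(s) == cancer_type
    ]
    mut = sorted(set(mutated_samples) & set(type_samples))
    wt = [s for s in type_samples if s not in set(mut)]
    if len(mut) < min_samples or len(wt) == 0:
        return None
    row = expression.loc[gene]
    log_all = _log_tpm(row[type_samples].to_numpy(dtype=float), pseudocount)
    log_mut = _log_tpm(row[mut].to_numpy(dtype=float), pseudocount)
    log_wt = _log_tpm(row[wt].to_numpy(dtype=float), pseudocount)
    res = wilcoxon_rank_sum(log_mut, log_wt)
    return {
        "cancer_type": cancer_type,
        "n_mut": len(mut),
        "n_wt": len(wt),
        "mean_log_tpm": float(np.mean(log_all)),
        "p_value": res.p_value,
        "test_method": res.method,
        "direction": "up" if np.median(log_mut) >= np.median(log_wt) else "down",
        "expression_filter_passed": bool(np.mean(log_all) >= min_mean_log_tpm),
    }


def adjust_and_select(
    results: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    family: str = "global",
) -> pd.DataFrame:
    """BH-adjust candidate p-values and mark those passing the FDR cut.

    ``family="global"`` (default) adjusts over all tested candidates in
    one family; ``family="per_cancer_type"`` adjusts within each cancer
    type.  ``passed`` requires FDR < threshold and the mean-expression
    filter.  The result is sorted by FDR then p.
    """
    out = results.copy()
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        out["passed"] = pd.Series(dtype=bool)
        return out
    if family == "global":
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    elif family == "per_cancer_type":
        out["fdr"] = np.nan
        for _, idx in out.groupby("cancer_type").groups.items():
            out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    else:
        raise ValueError(f"unknown family {family!r}")
    filt = out["expression_filter_passed"] if "expression_filter_passed" in out else True
    out["passed"] = (out["fdr"] < fdr_threshold) & filt
    return out.sort_values(["fdr", "p_value"], kind="mergesort").reset_index(drop=True)


def cooccurrence_check(
    candidate_samples: Sequence[str],
    gene: str,
    all_mutations: pd.DataFrame,
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
) -> dict:
    """Co-occurring missense/nonsense mutations in the candidate's gene.

    ``all_cooccur``: every sample carrying the candidate silent mutation
    also carries a missense or nonsense mutation in the same gene.
    ``recurrent_cooccur``: at least one such co-occurring variant is
    itself recurrent (>= ``min_recurrence`` distinct samples cohort-wide).
    """
    samples = set(candidate_samples)
    other = all_mutations[
        (all_mutations["gene"] == gene)
        & all_mutations["variant_class"].isin(["missense", "nonsense"])
    ]
    with_other = set(other["sample_id"])
    all_cooccur = samples.issubset(with_other) and len(samples) > 0
    recurrent_cooccur = False
    if all_cooccur and len(other):
        inside = other[other["sample_id"].isin(samples)]
        counts = (
            other.drop_duplicates(subset=VARIANT_KEY + ["sample_id"])
            .groupby(VARIANT_KEY)["sample_id"]
            .nunique()
        )
        for key, _ in inside.groupby(VARIANT_KEY):
            if counts.get(key, 0) >= min_recurrence:
                recurrent_cooccur = True
                break
    return {"all_cooccur": all_cooccur, "recurrent_cooccur": recurrent_cooccur}


def run_candidate_screen(
    mutations: pd.DataFrame,
    expression: pd.DataFrame,
    sample_types: Mapping[str, str],
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    min_abs_score: float = DEFAULT_MIN_ABS_SCORE,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_mean_log_tpm: float = DEFAULT_MIN_MEAN_LOG_TPM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    splicing_intervals: Optional[pd.DataFrame] = None,
    family: str = "global",
) -> tuple[pd.DataFrame, dict]:
    """Run the whole screen; returns (result table, funnel counts).

    ``mutations`` is the scored cohort frame (silent + other classes; the
    screen uses the silent rows, co-occurrence uses the rest).
    """
    silent = mutations[
        (mutations["variant_class"] == "silent") & mutations["score"].notna()
    ]
    funnel = {"silent_scored": int(len(silent))}

    pooled = find_recurrent(silent, min_samples=min_recurrence)
    funnel["recurrent_pooled"] = int(len(pooled))

    strong = filter_candidates(pooled, min_abs_score=min_abs_score)
    funnel["abs_score_filtered"] = int(len(strong))

    if splicing_intervals is not None:
        flags = flag_splicing_overlap(strong, splicing_intervals)
        strong = strong.assign(splicing_flag=flags.to_numpy())
        funnel["splicing_flagged"] = int(flags.sum())
    else:
        strong = strong.assign(splicing_flag=False)

    per_type = find_recurrent(silent, min_samples=min_recurrence, per_cancer_type=True)
    strong_keys = set(map(tuple, strong[VARIANT_KEY].to_numpy()))
    per_type = per_type[
        per_type[VARIANT_KEY].apply(tuple, axis=1).isin(strong_keys)
    ].reset_index(drop=True)
    funnel["recurrent_per_type"] = int(len(per_type))

    splicing_by_key = dict(
        zip(map(tuple, strong[VARIANT_KEY].to_numpy()), strong["splicing_flag"])
    )
    rows = []
    for row in per_type.itertuples(index=False):
        d = row._asdict()
        res = test_expression_association(
            d["gene"],
            d["samples"],
            expression,
            sample_types,
            d["cancer_type"],
            min_samples=min_recurrence,
            min_mean_log_tpm=min_mean_log_tpm,
            pseudocount=pseudocount,
        )
        if res is None:
            continue
        key = tuple(d[c] for c in VARIANT_KEY)
        rows.append(
            {**{c: d[c] for c in VARIANT_KEY}, "score": d.get("score", np.nan),
             "samples": d["samples"], "splicing_flag": splicing_by_key.get(key, False),
             **res}
        )
    tested = pd.DataFrame(rows)
    funnel["expression_tested"] = int(len(tested))

    selected = adjust_and_select(tested, fdr_threshold=fdr_threshold, family=family)
    funnel["fdr_passed"] = int(selected["passed"].sum()) if len(selected) else 0

    if len(selected):
        flags = [
            cooccurrence_check(r["samples"], r["gene"], mutations,
                               min_recurrence=min_recurrence)
            if r["passed"]
            else {"all_cooccur": False, "recurrent_cooccur": False}
            for _, r in selected.iterrows()
        ]
        selected["all_cooccur"] = [f["all_cooccur"] for f in flags]
        selected["recurrent_cooccur"] = [f["recurrent_cooccur"] for f in flags]
    logger.info("candidate screen funnel: %s", funnel)
    return selected, funnel
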