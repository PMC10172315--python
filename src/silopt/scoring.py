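"""The codon optimality score and cohort-level summaries.

For a silent (synonymous) mutation that turns codon *ref* into codon
*alt*, the codon optimality score is

    score = frequency(alt) - frequency(ref)

with frequencies per 1,000 triplets from a codon usage table.  A positive
score means the mutation creates a more commonly used ("optimal") codon,
a negative score a rarer ("non-optimal") one.  Scores are binned into
three groups: low (< -10), mid (>= -10 and < 10) and high (>= 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .codon_usage import CodonUsageTable, is_stop, normalize_codon

__all__ = [
    "score_mutation",
    "assign_score_group",
    "score_cohort",
    "summarize_cohort",
    "CohortSummary",
]

SCORE_GROUP_LOW = -10.0
SCORE_GROUP_HIGH = 10.0


def score_mutation(
    ref_codon: str, alt_codon: str, table: CodonUsageTable
) -> Optional[float]:
    """Codon optimality score frequency(alt) - frequency(ref).

    Returns ``None`` (not scoreable) when either codon is a stop codon;
    the metric is defined over the 61 sense codons only.
    """
    ref = normalize_codon(ref_codon)
    alt = normalize_codon(alt_codon)
    if is_stop(ref) or is_stop(alt):
        return None
    return table.frequency(alt) - table.frequency(ref)


def assign_score_group(
    score: float, lo: float = SCORE_GROUP_LOW, hi: float = SCORE_GROUP_HIGH
) -> str:
    """Bin a score into ``low`` (< lo), ``mid`` ([lo, hi)) or ``high`` (>= hi)."""
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be below hi ({hi})")
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    if score < lo:
        return "low"
    if score >= hi:
        return "high"
    return "mid"


def score_cohort(
    mutations: pd.DataFrame,
    table: CodonUsageTable,
    lo: float = SCORE_GROUP_LOW,
    hi: float = SCORE_GROUP_HIGH,
) -> pd.DataFrame:
    """Attach ``score``, ``score_group`` and ``optimality_class`` columns.

    Only silent, scoreable rows receive a score; other rows get NaN.
    ``optimality_class`` is ``optimal`` (score > 0), ``non_optimal``
    (score < 0) or ``neutral`` (score == 0).
    """
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be below hi ({hi})")
    out = mutations.copy()
    freq = pd.Series(table.as_dict())
    scoreable = (out["variant_class"] == "silent") & ~out.get(
        "not_scoreable", pd.Series(False, index=out.index)
    ).astype(bool)
    ref_f = out["ref_codon"].map(freq)
    alt_f = out["alt_codon"].map(freq)
    score = (alt_f - ref_f).where(scoreable)
    out["score"] = score
    group = pd.Series(pd.NA, index=out.index, dtype="object")
    group[score.notna() & (score < lo)] = "low"
    group[score.notna() & (score >= lo) & (score < hi)] = "mid"
    group[score.notna() & (score >= hi)] = "high"
    out["score_group"] = group
    opt = pd.Series(pd.NA, index=out.index, dtype="object")
    opt[score.notna() & (score > 0)] = "optimal"
    opt[score.notna() & (score < 0)] = "non_optimal"
    opt[score.notna() & (score == 0)] = "neutral"
    out["optimality_class"] = opt
    return out


@dataclass
class CohortSummary:
    """Cohort-level descriptive tables for a scored mutation set."""

    per_sample: pd.DataFrame  # sample_id, cancer_type, n_silent, n_missense, ratio
    per_amino_acid: pd.DataFrame  # amino_acid, n_silent
    per_codon: pd.DataFrame  # ref_codon, n_silent
    median_score: float
    fraction_negative: float
    n_silent: int
    n_missense: int


def summarize_cohort(mutations: pd.DataFrame) -> CohortSummary:
    """Per-sample silent/missense counts and ratio, per-amino-acid and
    per-codon silent counts, and the score distribution summary.

    The silent/missense ratio is reported missing (NaN) for samples with
    zero missense mutations rather than infinite.
    """
    from .codon_usage import GENETIC_CODE

    silent = mutations[mutations["variant_class"] == "silent"]
    missense = mutations[mutations["variant_class"] == "missense"]

    counts = (
        mutations.groupby("sample_id")["variant_class"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for cls in ("silent", "missense"):
        if cls not in counts.columns:
            counts[cls] = 0
    per_sample = counts.rename(
        columns={"silent": "n_silent", "missense": "n_missense"}
    )[["n_silent", "n_missense"]].reset_index()
    if "cancer_type" in mutations.columns and len(mutations):
        types = mutations.groupby("sample_id")["cancer_type"].first()
        per_sample["cancer_type"] = per_sample["sample_id"].map(types)
    per_sample["ratio"] = np.where(
        per_sample["n_missense"] > 0,
        per_sample["n_silent"] / per_sample["n_missense"].replace(0, np.nan),
        np.nan,
    )

    if len(silent):
        per_codon = (
            silent["ref_codon"].value_counts().rename_axis("ref_codon")
            .reset_index(name="n_silent")
        )
        aa = silent["ref_codon"].map(GENETIC_CODE)
        per_aa = (
            aa.value_counts().rename_axis("amino_acid").reset_index(name="n_silent")
        )
    else:
        per_codon = pd.DataFrame(columns=["ref_codon", "n_silent"])
        per_aa = pd.DataFrame(columns=["amino_acid", "n_silent"])

    scores = silent["score"].dropna() if "score" in silent.columns else pd.Series(dtype=float)
    median_score = float(scores.median()) if len(scores) else float("nan")
    fraction_negative = float((scores < 0).mean()) if len(scores) else float("nan")

    return CohortSummary(
        per_sample=per_sample,
        per_amino_acid=per_aa,
        per_codon=per_codon,
        median_score=median_score,
        fraction_negative=fraction_negative,
        n_silent=int(len(silent)),
        n_missense=int(len(missense)),
    )
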