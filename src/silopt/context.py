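"""Codon context around silent mutations.

A mutation's context is the set of up to *k* codons on each side of the
mutated codon within the same CDS (k = 1, 5 or 10 codons, i.e. +/-3, 15 or
30 bases).  The mean usage frequency of those codons measures whether the
mutation sits in a region rich in common or rare codons; mutations are
binned into low (bottom 25%), mid, and high (top 25%) context groups and
the association between context and optimality score is tested.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_usage import CodonUsageTable, STOP_CODONS
from .stats import bh_adjust, spearman, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "extract_flanking_codons",
    "mean_context_frequency",
    "add_context_profiles",
    "assign_context_groups",
    "context_score_association",
]

DEFAULT_KS = (1, 5, 10)


def extract_flanking_codons(
    cds: str, codon_index: int, k: int
) -> tuple[list[str], list[str]]:
    """Up to ``k`` codons upstream and downstream of codon ``codon_index``.

    Both lists run 5'->3' and exclude the mutated codon; they are truncated
    at the CDS boundaries.  The terminal stop codon is never included in
    the downstream context (it encodes no amino acid).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    if not (1 <= codon_index <= n_codons):
        raise ValueError(f"codon_index {codon_index} outside 1..{n_codons}")
    if k < 0:
        raise ValueError("k must be non-negative")
    codons = [cds[i * 3 : i * 3 + 3] for i in range(n_codons)]
    i = codon_index - 1
    upstream = codons[max(0, i - k) : i]
    downstream = [c for c in codons[i + 1 : i + 1 + k] if c not in STOP_CODONS]
    return upstream, downstream


def mean_context_frequency(
    codons: Sequence[str], table: CodonUsageTable
) -> float:
    """Arithmetic mean of codon frequencies; NaN for an empty context."""
    if len(codons) == 0:
        return float("nan")
    return float(np.mean([table.frequency(c) for c in codons]))


def add_context_profiles(
    mutations: pd.DataFrame,
    cds_by_transcript: Mapping[str, str],
    table: CodonUsageTable,
    ks: Sequence[int] = DEFAULT_KS,
) -> pd.DataFrame:
    """Long-format context profiles: one row per (mutation, k).

    Columns ``mean_up``, ``mean_down``, ``mean_both`` hold the mean
    frequencies of the upstream codons, the downstream codons, and the
    concatenation of the two (not the mean of the two means, which would
    differ when the sides have unequal lengths).  Mutations whose context
    is empty at a given k carry NaN and are excluded from that k's
    analysis downstream.
    """
    freq = table.as_dict()
    rows = []
    for idx, row in mutations.iterrows():
        cds = cds_by_transcript.get(row["transcript_id"])
        if cds is None:
            continue
        for k in ks:
            up, down = extract_flanking_codons(cds, int(row["codon_index"]), k)
            both = up + down
            rows.append(
                {
                    "_idx": idx,
                    "k": k,
                    "n_up": len(up),
                    "n_down": len(down),
                    "mean_up": float(np.mean([freq[c] for c in up])) if up else np.nan,
                    "mean_down": float(np.mean([freq[c] for c in down]))
                    if down
                    else np.nan,
                    "mean_both": float(np.mean([freq[c] for c in both]))
                    if both
                    else np.nan,
                }
            )
    profile = pd.DataFrame.from_records(rows)
    keep = [c for c in ("sample_id", "gene", "transcript_id", "cds_pos", "score")
            if c in mutations.columns]
    out = profile.merge(
        mutations[keep], left_on="_idx", right_index=True, how="left"
    ).drop(columns="_idx")
    n_empty = int(out["mean_both"].isna().sum())
    if n_empty:
        logger.info("add_context_profiles: %d (mutation, k) rows have empty context", n_empty)
    return out


def assign_context_groups(values: Sequence[float]) -> np.ndarray:
    """Label each value ``low`` (< 25th pct), ``high`` (> 75th pct) or ``mid``.

    Percentiles are linear-interpolation empirical quantiles over the
    non-missing values; values tied with a cut go to ``mid``.  Missing
    values get the empty label ``""``.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 4:
        raise ValueError("need at least 4 non-missing values to form quartile groups")
    q25, q75 = np.quantile(v[ok], [0.25, 0.75])
    labels = np.full(v.shape, "", dtype=object)
    labels[ok] = "mid"
    if q25 == q75:
        warnings.warn("context values are (nearly) constant; all assigned to mid")
        return labels
    labels[ok & (v < q25)] = "low"
    labels[ok & (v > q75)] = "high"
    return labels


def context_score_association(
    profiles: pd.DataFrame,
    k: int,
    value_column: str = "mean_both",
    correlation: str = "spearman",
) -> dict:
    """Per-group score statistics and low-vs-high contrast at one k.

    ``profiles`` is the frame from :func:`add_context_profiles` (must carry
    ``score``).  Returns a dict with a per-group summary frame, the
    Wilcoxon p-values for the pairwise group contrasts (BH-adjusted), and
    the rank correlation between context frequency and score within the
    low and the high group.
    """
    sub = profiles[(profiles["k"] == k)].dropna(subset=[value_column, "score"]).copy()
    sub["context_group"] = assign_context_groups(sub[value_column].to_numpy())

    summary = (
        sub.groupby("context_group")["score"]
        .agg(n="size", median="median", mean="mean")
        .reindex(["low", "mid", "high"])
    )

    groups = {g: sub.loc[sub["context_group"] == g, "score"].to_numpy()
              for g in ("low", "mid", "high")}
    contrasts = []
    pairs = [("low", "high"), ("low", "mid"), ("mid", "high")]
    for a, b in pairs:
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            warnings.warn(f"context contrast {a} vs {b} skipped: degenerate group size")
            continue
        res = wilcoxon_rank_sum(groups[a], groups[b])
        contrasts.append({"group_a": a, "group_b": b, "p_value": res.p_value,
                          "method": res.method})
    contrast_df = pd.DataFrame(contrasts)
    if len(contrast_df):
        contrast_df["fdr"] = bh_adjust(contrast_df["p_value"].to_numpy())

    corr = {}
    for g in ("low", "high"):
        gsub = sub[sub["context_group"] == g]
        if len(gsub) >= 3:
            if correlation == "spearman":
                corr[g] = spearman(gsub[value_column], gsub["score"])
            else:
                corr[g] = float(np.corrcoef(gsub[value_column], gsub["score"])[0, 1])
        else:
            corr[g] = float("nan")

    return {
        "k": k,
        "summary": summary,
        "contrasts": contrast_df,
        "correlation": corr,
        "n": int(len(sub)),
    }
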