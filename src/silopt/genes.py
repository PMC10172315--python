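"""Per-gene optimality summaries and gene-set comparisons.

Each gene's silent mutations are collapsed to a central score (median by
default; mean available).  Genes in the extreme tails of the per-gene
central scores (top/bottom 5% by default) are extracted for downstream
functional analysis, and mutation scores within curated gene sets
(essential genes, oncogenes, tumor suppressors) are contrasted against
the whole cohort.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "gene_score_summary",
    "select_extreme_genes",
    "compare_gene_sets",
    "stratify_genes",
]

DEFAULT_TAIL_FRACTION = 0.05
DEFAULT_MIN_MUTATIONS = 1
#: minimum mutation count used for the functional (tail/GO-export) analysis
FUNCTIONAL_MIN_MUTATIONS = 5


def gene_score_summary(
    mutations: pd.DataFrame,
    center: str = "median",
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> pd.DataFrame:
    """One row per gene: mutation count and central optimality score.

    ``center`` is ``"median"`` (default, robust to single outliers) or
    ``"mean"``.  Genes with fewer than ``min_mutations`` scored silent
    mutations are dropped.
    """
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    silent = mutations[
        (mutations["variant_class"] == "silent") & mutations["score"].notna()
    ]
    agg = silent.groupby("gene")["score"].agg(
        n_mutations="size", center_score=center
    ).reset_index()
    return agg[agg["n_mutations"] >= min_mutations].reset_index(drop=True)


def select_extreme_genes(
    summaries: pd.DataFrame, tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> dict:
    """Genes in the top and bottom tails of the central scores.

    Cuts are the empirical ``tail_fraction`` and ``1 - tail_fraction``
    quantiles; genes tied with a cut are included in the tail (inclusive
    cut), so tails may exceed ceil(n * tail_fraction) under ties.
    Returns top/bottom gene lists, the cut values, and the input frame
    with a ``tail`` column in {top5, bottom5, none} (labels follow the
    configured fraction).
    """
    if not (0 < tail_fraction < 0.5):
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    centers = summaries["center_score"].to_numpy(dtype=float)
    cut_bottom = float(np.quantile(centers, tail_fraction))
    cut_top = float(np.quantile(centers, 1 - tail_fraction))
    pct = int(round(tail_fraction * 100))
    labeled = summaries.copy()
    labeled["tail"] = "none"
    labeled.loc[labeled["center_score"] <= cut_bottom, "tail"] = f"bottom{pct}"
    labeled.loc[labeled["center_score"] >= cut_top, "tail"] = f"top{pct}"
    top = labeled.loc[labeled["tail"] == f"top{pct}", "gene"].tolist()
    bottom = labeled.loc[labeled["tail"] == f"bottom{pct}", "gene"].tolist()
    return {
        "top": top,
        "bottom": bottom,
        "cut_top": cut_top,
        "cut_bottom": cut_bottom,
        "summaries": labeled,
    }


def compare_gene_sets(
    mutations: pd.DataFrame, gene_lists: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Mutation-score distributions in curated gene sets vs. all genes.

    ``gene_lists`` maps a set label (e.g. ESS/OG/TSG) to gene symbols
    (duplicates and ordering are irrelevant).  Each set's silent-mutation
    scores are compared against the full cohort ("ALL") with a two-sided
    Wilcoxon test; p-values are BH-adjusted across the sets.
    """
    silent = mutations[
        (mutations["variant_class"] == "silent") & mutations["score"].notna()
    ]
    all_scores = silent["score"].to_numpy(dtype=float)
    rows = [
        {"set_label": "ALL", "n_scores": len(all_scores),
         "median": float(np.median(all_scores)) if len(all_scores) else np.nan,
         "p_vs_all": np.nan}
    ]
    tested = []
    for label, symbols in gene_lists.items():
        members = set(symbols)
        scores = silent.loc[silent["gene"].isin(members), "score"].to_numpy(dtype=float)
        if scores.size == 0:
            warnings.warn(f"gene set {label} has no scored mutations; skipped")
            continue
        res = wilcoxon_rank_sum(scores, all_scores)
        rows.append(
            {"set_label": label, "n_scores": int(scores.size),
             "median": float(np.median(scores)), "p_vs_all": res.p_value}
        )
        tested.append(len(rows) - 1)
    out = pd.DataFrame(rows)
    if tested:
        out.loc[tested, "fdr_vs_all"] = bh_adjust(out.loc[tested, "p_vs_all"].to_numpy())
    return out


def stratify_genes(
    labeled_summaries: pd.DataFrame,
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    log_tpm_cut: float = 1.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Split tail genes by expression level and by mutation timing.

    Each gene in a tail is placed in a ``high_expr``/``low_expr`` stratum
    depending on whether its median log10(TPM + pseudocount) across all
    samples reaches ``log_tpm_cut`` (boundary inclusive), and in an
    ``early``/``late`` stratum by the majority of its silent mutations'
    coarse timing labels (ties go to late).  Genes absent from the
    expression matrix fall into an ``unknown`` expression stratum, genes
    without timing labels into an ``unknown`` timing stratum.
    """
    tails = labeled_summaries[labeled_summaries["tail"] != "none"].copy()

    expr_stratum = []
    for gene in tails["gene"]:
        if gene in expression.index:
            med = float(
                np.median(np.log10(expression.loc[gene].to_numpy(dtype=float) + pseudocount))
            )
            expr_stratum.append("high_expr" if med >= log_tpm_cut else "low_expr")
        else:
            expr_stratum.append("unknown")
    tails["expression_stratum"] = expr_stratum
    n_unknown = expr_stratum.count("unknown")
    if n_unknown:
        logger.info("stratify_genes: %d tail genes absent from expression", n_unknown)

    timing_stratum = []
    has_timing = "timing_coarse" in mutations.columns
    for gene in tails["gene"]:
        if not has_timing:
            timing_stratum.append("unknown")
            continue
        labels = mutations.loc[
            (mutations["gene"] == gene)
            & (mutations["variant_class"] == "silent")
            & mutations["timing_coarse"].notna(),
            "timing_coarse",
        ]
        if labels.empty:
            timing_stratum.append("unknown")
        else:
            n_early = int((labels == "early").sum())
            n_late = int((labels == "late").sum())
            timing_stratum.append("early" if n_early > n_late else "late")
    tails["timing_stratum"] = timing_stratum
    return tails
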