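"""End-to-end pipeline: score -> context -> timing -> conservation ->
candidates -> genes, with a filter-funnel log and TSV outputs.

The run configuration bundles every stage threshold (score-group cuts
-10/10, recurrence 3, |score| filter 10, FDR 0.25, tail fraction 0.05,
log10-TPM cut 1, control size 100,000, context windows 1/5/10) with the
input paths and the seed.  The resolved configuration is written next to
the outputs of every run, and each stage's row counts are logged so the
candidate funnel can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import candidates as cand
from . import context as ctx
from . import evolution as evo
from . import genes as gn
from . import io as mio
from . import scoring
from .codon_usage import human_codon_usage, load_codon_usage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """All stage parameters plus input paths; defaults are the reference
    thresholds of the analysis."""

    # inputs (TSV/FASTA paths); expression & timing & track are optional stages
    maf: str = ""
    cds_fasta: str = ""
    timing: Optional[str] = None
    expression: Optional[str] = None
    sample_annotation: Optional[str] = None
    conservation_track: Optional[str] = None
    splicing_bed: Optional[str] = None
    gene_lists: dict = field(default_factory=dict)  # label -> path
    codon_usage: Optional[str] = None  # None -> vendored human table
    codon_usage_dialect: str = "kazusa"

    # stage parameters
    score_group_lo: float = -10.0
    score_group_hi: float = 10.0
    min_recurrence: int = 3
    min_abs_score: float = 10.0
    fdr_threshold: float = 0.25
    fdr_family: str = "global"
    tail_fraction: float = 0.05
    gene_center: str = "median"
    min_gene_mutations: int = 5
    log_tpm_cut: float = 1.0
    pseudocount: float = 0.01
    control_n: int = 100_000
    context_ks: tuple = (1, 5, 10)

    seed: int = 0
    outdir: str = "silopt_run"

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["context_ks"] = list(self.context_ks)
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML key-value run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    if "context_ks" in raw:
        raw["context_ks"] = tuple(raw["context_ks"])
    return RunConfig(**raw)


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns a dict of result objects.

    Stages whose inputs are not configured are skipped.  All outputs are
    TSVs under ``config.outdir`` plus ``funnel.json`` (stage counts) and
    ``run_config.yaml`` (the resolved configuration).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(yaml.safe_dump(config.as_dict()))

    table = (
        human_codon_usage()
        if config.codon_usage is None
        else load_codon_usage(config.codon_usage, dialect=config.codon_usage_dialect)
    )

    sample_types = None
    if config.sample_annotation:
        annot = pd.read_csv(config.sample_annotation, sep="\t", dtype=str)
        sample_types = dict(zip(annot["sample_id"], annot["cancer_type"]))

    mutations = mio.read_maf(config.maf, sample_types=sample_types)
    cds = mio.read_cds_fasta(config.cds_fasta)
    mutations = mio.resolve_cohort(mutations, cds)
    mutations = scoring.score_cohort(
        mutations, table, lo=config.score_group_lo, hi=config.score_group_hi
    )
    funnel = {
        "mutations_read": int(len(mutations)),
        "silent_scored": int(
            ((mutations["variant_class"] == "silent") & mutations["score"].notna()).sum()
        ),
    }
    _write(mutations, out / "scored_mutations.tsv")

    summary = scoring.summarize_cohort(mutations)
    _write(summary.per_sample, out / "per_sample_counts.tsv")
    _write(summary.per_amino_acid, out / "per_amino_acid_counts.tsv")
    _write(summary.per_codon, out / "per_codon_counts.tsv")

    results: dict = {"mutations": mutations, "summary": summary, "funnel": funnel}

    silent = mutations[
        (mutations["variant_class"] == "silent") & mutations["score"].notna()
    ]

    profiles = ctx.add_context_profiles(silent, cds, table, ks=config.context_ks)
    _write(profiles, out / "context_profiles.tsv")
    context_reports = {}
    for k in config.context_ks:
        try:
            context_reports[k] = ctx.context_score_association(profiles, k)
        except ValueError as exc:
            logger.warning("context analysis skipped at k=%d: %s", k, exc)
    results["context"] = context_reports

    if config.timing:
        timing = evo.read_timing_table(config.timing)
        mutations = evo.attach_timing(mutations, timing)
        silent = mutations[
            (mutations["variant_class"] == "silent") & mutations["score"].notna()
        ]
        timing_report = evo.compare_scores_by_timing(silent)
        _write(timing_report["summary"].reset_index(), out / "timing_summary.tsv")
        _write(timing_report["contrasts"], out / "timing_contrasts.tsv")
        results["timing"] = timing_report
        results["mutations"] = mutations

    if config.conservation_track:
        track = evo.TsvTrack(config.conservation_track)
        control = evo.sample_cds_control(
            {tx: len(seq) for tx, seq in cds.items()},
            n=config.control_n,
            seed=config.seed,
        )
        conservation = evo.compare_conservation(silent, control, track)
        _write(conservation["summary"].reset_index(names="group"),
               out / "conservation_summary.tsv")
        _write(conservation["contrasts"], out / "conservation_contrasts.tsv")
        results["conservation"] = conservation

    if config.expression and sample_types is not None:
        expression = pd.read_csv(config.expression, sep="\t", index_col=0)
        splicing = None
        if config.splicing_bed:
            splicing = pd.read_csv(
                config.splicing_bed, sep="\t", header=None,
                names=["seq_id", "start", "end"],
            )
        selected, screen_funnel = cand.run_candidate_screen(
            mutations,
            expression,
            sample_types,
            min_recurrence=config.min_recurrence,
            min_abs_score=config.min_abs_score,
            fdr_threshold=config.fdr_threshold,
            min_mean_log_tpm=config.log_tpm_cut,
            pseudocount=config.pseudocount,
            splicing_intervals=splicing,
            family=config.fdr_family,
        )
        funnel.update(screen_funnel)
        export = selected.drop(columns=["samples"]) if "samples" in selected else selected
        _write(export, out / "candidates.tsv")
        results["candidates"] = selected

        summaries = gn.gene_score_summary(
            mutations, center=config.gene_center,
            min_mutations=config.min_gene_mutations,
        )
        if len(summaries) >= 20:
            tails = gn.select_extreme_genes(summaries, tail_fraction=config.tail_fraction)
            stratified = gn.stratify_genes(
                tails["summaries"], expression, mutations,
                log_tpm_cut=config.log_tpm_cut, pseudocount=config.pseudocount,
            )
            _write(tails["summaries"], out / "gene_summaries.tsv")
            _write(stratified, out / "gene_strata.tsv")
            results["gene_tails"] = tails
            results["gene_strata"] = stratified

        if config.gene_lists:
            lists = {
                label: mio.load_gene_list(path)
                for label, path in config.gene_lists.items()
            }
            comparison = gn.compare_gene_sets(mutations, lists)
            _write(comparison, out / "gene_set_comparison.tsv")
            results["gene_sets"] = comparison

    (out / "funnel.json").write_text(json.dumps(funnel, indent=2) + "\n")
    logger.info("pipeline funnel: %s", funnel)
    results["funnel"] = funnel
    return results
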