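"""Seed-reproducible synthetic cohorts with planted effects.

The generator emulates the statistical structure of the real inputs —
codon-biased coding sequences, a multi-sample multi-cancer-type somatic
mutation cohort (MAF), MutationTimeR-style timing labels, per-base
conservation tracks, and a TPM expression matrix — with known ("truth")
planted effects so every pipeline stage can be validated without any
download:

* per-timing-class shifts of the codon optimality score distribution,
  realized by exponential tilting of the discrete pool of available
  synonymous substitutions (the tilt is calibrated numerically so the
  pool's tilted mean moves by the configured amount; truth records the
  realized, not the target, scores);
* coupling between a substitution's score and the mean codon frequency
  of its +/-10-codon context;
* causal genes whose expression shifts in mutated samples (non-optimal
  mutations down, optimal mutations up).

All randomness flows through one ``numpy.random.Generator``; a fixed seed
gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .codon_usage import (
    CodonUsageTable,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    human_codon_usage,
)

__all__ = [
    "SimulationConfig",
    "simulate_cds",
    "build_substitution_pools",
    "draw_silent_mutations",
    "simulate_cohort",
    "simulate_expression",
    "simulate_conservation_track",
    "simulate_candidate_study",
    "make_gene_lists",
    "write_fasta",
]

_BASES = "ACGT"

#: curated gene-list sizes emulated by default (essential genes,
#: oncogenes, tumor suppressor genes)
GENE_LIST_SIZES = {"ESS": 331, "OG": 803, "TSG": 1217}

#: canonical timing class -> MutationTimeR output string
TIMING_STRINGS = {
    "early_clonal": "clonal [early]",
    "late_clonal": "clonal [late]",
    "clonal_NA": "clonal [NA]",
    "subclonal": "subclonal",
}


def _substitutions(codon: str) -> list[tuple[int, str, str]]:
    out = []
    for offset in range(3):
        for alt in _BASES:
            if alt == codon[offset]:
                continue
            alt_codon = codon[:offset] + alt + codon[offset + 1 :]
            out.append((offset + 1, alt, alt_codon))
    return out


#: codon -> synonymous single-base substitutions (sense -> same amino acid)
SYNONYMOUS_SUBS: dict[str, list[tuple[int, str, str]]] = {
    c: [
        s
        for s in _substitutions(c)
        if s[2] not in STOP_CODONS and GENETIC_CODE[s[2]] == GENETIC_CODE[c]
    ]
    for c in SENSE_CODONS
}

#: codon -> missense single-base substitutions (sense -> different amino acid)
MISSENSE_SUBS: dict[str, list[tuple[int, str, str]]] = {
    c: [
        s
        for s in _substitutions(c)
        if s[2] not in STOP_CODONS and GENETIC_CODE[s[2]] != GENETIC_CODE[c]
    ]
    for c in SENSE_CODONS
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Frequencies and thresholds mirror the real cohort where stated (the
    silent fraction of ~0.3 matches the observed silent:missense balance;
    score-group and screen thresholds live in their analysis modules) and
    are otherwise set to desk-scale values documented in the methods note.
    """

    seed: int = 0
    n_genes: int = 100
    n_samples: int = 100
    cancer_types: dict = field(default_factory=lambda: {"OV": 0.4, "BRCA": 0.35, "PCPG": 0.25})
    cds_length_range: tuple[int, int] = (100, 400)  # codons, incl. start/stop
    codon_temperature: float = 1.0  # 0 = uniform synonymous usage, 1 = table-proportional
    mutations_per_sample: float = 100.0
    silent_fraction: float = 0.3
    timing_class_probs: dict = field(
        default_factory=lambda: {
            "early_clonal": 0.25,
            "late_clonal": 0.15,
            "clonal_NA": 0.40,
            "subclonal": 0.20,
        }
    )
    score_shift_by_timing: dict = field(default_factory=dict)  # class -> per-1000 shift
    context_coupling: float = 0.0  # sign of the planted score-context correlation
    n_causal_genes: int = 10
    expression_shift: float = 0.5  # |log10 TPM| shift in mutated samples
    expression_noise_sd: float = 0.3
    expression_baseline_mean: float = 1.5
    expression_baseline_sd: float = 0.5
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name, probs in (
            ("cancer_types", self.cancer_types),
            ("timing_class_probs", self.timing_class_probs),
        ):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} proportions sum to {total}, expected 1")
        if self.cds_length_range[0] < 3 or self.cds_length_range[0] > self.cds_length_range[1]:
            raise ValueError(f"impossible cds_length_range {self.cds_length_range}")
        if self.mutations_per_sample < 0 or not (0 <= self.silent_fraction <= 1):
            raise ValueError("rates must be non-negative and fractions in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def as_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# coding sequences


def simulate_cds(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    table: Optional[CodonUsageTable] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate codon-biased CDSs, one transcript per gene.

    Every CDS starts with ATG, ends with a single stop codon, has length
    divisible by 3 and no internal stop.  Within each amino-acid family
    the codon is drawn with probability proportional to its table
    frequency raised to ``codon_temperature`` (0 = uniform synonymous
    usage, 1 = table-proportional).

    Returns (transcript_id -> sequence, gene annotation frame).
    """
    rng = config.rng() if rng is None else rng
    table = human_codon_usage() if table is None else table
    freq = table.as_dict()
    t = config.codon_temperature

    aa_to_codons: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        aa_to_codons.setdefault(GENETIC_CODE[c], []).append(c)
    aas = sorted(aa_to_codons)
    aa_weights = np.array([sum(freq[c] for c in aa_to_codons[aa]) for aa in aas])
    aa_probs = aa_weights / aa_weights.sum()
    codon_probs = {}
    for aa in aas:
        fam = aa_to_codons[aa]
        w = np.array([freq[c] for c in fam], dtype=float) ** t
        if w.sum() == 0:
            w = np.ones(len(fam))
        codon_probs[aa] = (fam, w / w.sum())
    stop_list = sorted(STOP_CODONS)
    stop_w = np.array([freq[c] for c in stop_list], dtype=float)
    stop_p = stop_w / stop_w.sum()

    lo, hi = config.cds_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    n_internal = lengths - 2  # minus start and stop
    total = int(n_internal.sum())
    aa_draws = rng.choice(len(aas), size=total, p=aa_probs)
    codons = np.empty(total, dtype=object)
    for ai, aa in enumerate(aas):
        mask = aa_draws == ai
        n = int(mask.sum())
        if n:
            fam, p = codon_probs[aa]
            codons[mask] = rng.choice(fam, size=n, p=p)
    stops = rng.choice(stop_list, size=config.n_genes, p=stop_p)

    cds: dict[str, str] = {}
    rows = []
    offset = 0
    for i in range(config.n_genes):
        gene = f"GENE{i + 1:04d}"
        tx = f"TX{i + 1:04d}"
        body = "".join(codons[offset : offset + n_internal[i]])
        offset += n_internal[i]
        cds[tx] = "ATG" + body + stops[i]
        rows.append({"gene": gene, "transcript_id": tx, "n_codons": int(lengths[i])})
    return cds, pd.DataFrame(rows)


def write_fasta(cds: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write CDSs as an uncompressed FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name in cds:
            fh.write(f">{name}\n")
            seq = cds[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# substitution pools and planted silent mutations


def build_substitution_pools(
    cds: Mapping[str, str],
    genes: pd.DataFrame,
    table: Optional[CodonUsageTable] = None,
    context_k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enumerate every available single-base substitution in the CDS set.

    Returns (silent pool, missense pool).  The silent pool carries the
    codon optimality score of each substitution and the mean codon
    frequency of its +/-``context_k``-codon context (mutated codon and
    terminal stop excluded), which drive the planted timing and context
    effects.
    """
    table = human_codon_usage() if table is None else table
    freq = table.as_dict()
    tx_to_gene = dict(zip(genes["transcript_id"], genes["gene"]))

    silent_rows: list[tuple] = []
    missense_rows: list[tuple] = []
    for tx, seq in cds.items():
        gene = tx_to_gene.get(tx, tx)
        n_codons = len(seq) // 3
        codon_list = [seq[i * 3 : (i + 1) * 3] for i in range(n_codons)]
        coding = codon_list[:-1] if codon_list[-1] in STOP_CODONS else codon_list
        f = np.array([freq[c] for c in coding], dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(f)])
        m = len(coding)
        for ci in range(m):
            codon = coding[ci]
            lo = max(0, ci - context_k)
            hi = min(m, ci + context_k + 1)
            s = csum[hi] - csum[lo] - f[ci]
            n_ctx = (hi - lo) - 1
            ctx = s / n_ctx if n_ctx else np.nan
            base = ci * 3
            for offset, alt, alt_codon in SYNONYMOUS_SUBS[codon]:
                pos = base + offset
                silent_rows.append(
                    (tx, gene, ci + 1, pos, codon[offset - 1], alt, codon, alt_codon,
                     freq[alt_codon] - freq[codon], ctx)
                )
            for offset, alt, alt_codon in MISSENSE_SUBS[codon]:
                pos = base + offset
                missense_rows.append(
                    (tx, gene, ci + 1, pos, codon[offset - 1], alt, codon, alt_codon)
                )
    cols = ["transcript_id", "gene", "codon_index", "cds_pos", "ref_base",
            "alt_base", "ref_codon", "alt_codon"]
    silent = pd.DataFrame(silent_rows, columns=cols + ["score", "context_freq"])
    missense = pd.DataFrame(missense_rows, columns=cols)
    return silent, missense


def _tilt_weights(
    scores: np.ndarray, context: np.ndarray, coupling: float
) -> np.ndarray:
    """Base sampling weights encoding the score-context coupling."""
    if coupling == 0.0:
        return np.ones_like(scores)
    zs = (scores - scores.mean()) / (scores.std() or 1.0)
    ctx = np.where(np.isnan(context), np.nanmean(context), context)
    zc = (ctx - ctx.mean()) / (ctx.std() or 1.0)
    w = np.exp(coupling * zs * zc)
    return w / w.mean()


def _calibrate_lambda(scores: np.ndarray, base_w: np.ndarray, shift: float) -> float:
    """Exponential-tilt parameter moving the weighted mean score by ``shift``."""
    if shift == 0.0:
        return 0.0
    target = float(np.average(scores, weights=base_w)) + shift
    smin, smax = scores.min(), scores.max()
    if not (smin < target < smax):
        raise ValueError(
            f"requested score shift {shift} is outside the attainable range "
            f"({smin:.1f}, {smax:.1f})"
        )
    s_shifted = scores - scores.mean()  # numerical stability of exp

    def tilted_mean(lam: float) -> float:
        w = base_w * np.exp(lam * s_shifted)
        return float(np.average(scores, weights=w)) - target

    lam = 1e-3
    while tilted_mean(-lam) * tilted_mean(lam) > 0:
        lam *= 2
        if lam > 64:
            raise RuntimeError("tilt calibration failed to bracket the target")
    return float(brentq(tilted_mean, -lam, lam, xtol=1e-10))


def draw_silent_mutations(
    pool: pd.DataFrame,
    n_by_class: Mapping[str, int],
    score_shift_by_timing: Mapping[str, float],
    context_coupling: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample silent mutations per timing class from the substitution pool.

    Classes with a configured score shift draw from an exponentially
    tilted version of the pool so the expected score moves by the
    configured per-1,000 amount relative to unshifted classes; the
    context coupling tilts the joint (score, context) distribution.
    """
    scores = pool["score"].to_numpy(dtype=float)
    context = pool["context_freq"].to_numpy(dtype=float)
    base_w = _tilt_weights(scores, context, context_coupling)
    out = []
    for cls, n in n_by_class.items():
        if n == 0:
            continue
        shift = float(score_shift_by_timing.get(cls, 0.0))
        lam = _calibrate_lambda(scores, base_w, shift)
        w = base_w * np.exp(lam * (scores - scores.mean()))
        p = w / w.sum()
        idx = rng.choice(len(pool), size=n, replace=True, p=p)
        drawn = pool.iloc[idx].copy()
        drawn["timing_raw"] = cls
        out.append(drawn)
    return pd.concat(out, ignore_index=True) if out else pool.iloc[:0].assign(timing_raw=[])


# --------------------------------------------------------------------------
# cohort


def simulate_cohort(
    config: SimulationConfig,
    cds: Mapping[str, str],
    genes: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    table: Optional[CodonUsageTable] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the somatic cohort: (MAF frame, timing frame, truth frame).

    Per-sample mutation counts are Poisson; each mutation is silent with
    probability ``silent_fraction`` and missense otherwise; every mutation
    gets one of the four timing classes.  Silent substitutions realize the
    configured per-class score shifts and score-context coupling.  The
    truth frame records the planted codon pair, score, context frequency
    and timing of every emitted mutation.
    """
    rng = config.rng() if rng is None else rng
    silent_pool, missense_pool = build_substitution_pools(cds, genes, table=table)

    type_names = sorted(config.cancer_types)
    type_p = np.array([config.cancer_types[t] for t in type_names])
    sample_ids = [f"SAMPLE{i + 1:04d}" for i in range(config.n_samples)]
    sample_types = rng.choice(type_names, size=config.n_samples, p=type_p)
    samples = pd.DataFrame({"sample_id": sample_ids, "cancer_type": sample_types})

    counts = rng.poisson(config.mutations_per_sample, size=config.n_samples)
    total = int(counts.sum())
    sample_of_event = np.repeat(np.arange(config.n_samples), counts)
    is_silent = rng.random(total) < config.silent_fraction

    classes = sorted(config.timing_class_probs)
    class_p = np.array([config.timing_class_probs[c] for c in classes])
    timing_of_event = rng.choice(classes, size=total, p=class_p)

    n_by_class = {
        c: int(((timing_of_event == c) & is_silent).sum()) for c in classes
    }
    silent_drawn = draw_silent_mutations(
        silent_pool, n_by_class, config.score_shift_by_timing,
        config.context_coupling, rng,
    )
    # order silent events to match their per-class sample assignment
    silent_events = np.flatnonzero(is_silent)
    order = np.concatenate(
        [silent_events[timing_of_event[silent_events] == c] for c in classes]
    )
    silent_drawn["_event"] = order
    silent_drawn["variant_class"] = "silent"

    n_missense = int((~is_silent).sum())
    mis_idx = rng.integers(0, len(missense_pool), size=n_missense)
    missense_drawn = missense_pool.iloc[mis_idx].copy()
    missense_drawn["_event"] = np.flatnonzero(~is_silent)
    missense_drawn["timing_raw"] = timing_of_event[~is_silent]
    missense_drawn["variant_class"] = "missense"
    missense_drawn["score"] = np.nan
    missense_drawn["context_freq"] = np.nan

    truth = pd.concat([silent_drawn, missense_drawn], ignore_index=True)
    truth = truth.sort_values("_event", kind="mergesort").reset_index(drop=True)
    truth["sample_id"] = np.array(sample_ids, dtype=object)[
        sample_of_event[truth["_event"].to_numpy()]
    ]
    truth["cancer_type"] = np.array(sample_types, dtype=object)[
        sample_of_event[truth["_event"].to_numpy()]
    ]
    truth = truth.drop(columns="_event")
    truth = truth.drop_duplicates(
        subset=["sample_id", "transcript_id", "cds_pos", "ref_base", "alt_base"]
    ).reset_index(drop=True)

    maf = pd.DataFrame(
        {
            "Hugo_Symbol": truth["gene"],
            "Tumor_Sample_Barcode": truth["sample_id"],
            "Cancer_Type": truth["cancer_type"],
            "Variant_Classification": truth["variant_class"].map(
                {"silent": "Silent", "missense": "Missense_Mutation",
                 "nonsense": "Nonsense_Mutation"}
            ),
            "Transcript_ID": truth["transcript_id"],
            "CDS_Position": truth["cds_pos"],
            "Reference_Allele": truth["ref_base"],
            "Tumor_Seq_Allele2": truth["alt_base"],
            "HGVSc": "c."
            + truth["cds_pos"].astype(str)
            + truth["ref_base"]
            + ">"
            + truth["alt_base"],
        }
    )
    timing = pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "transcript_id": truth["transcript_id"],
            "cds_pos": truth["cds_pos"],
            "ref_base": truth["ref_base"],
            "alt_base": truth["alt_base"],
            "timing": truth["timing_raw"].map(TIMING_STRINGS),
        }
    )
    truth.attrs["samples"] = samples
    return maf, timing, truth


# --------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix with expression shifts planted in causal genes.

    Baseline per-gene log10 TPM is normal; per-sample noise is normal.
    The ``n_causal_genes`` genes with the most silent-mutated samples are
    causal: their silent-mutated samples shift by ``expression_shift`` in
    the direction of the mutation score's sign (non-optimal down, optimal
    up).  Returns (TPM frame genes x samples, causal-gene truth frame).
    """
    rng = config.rng() if rng is None else rng
    gene_names = genes["gene"].tolist()
    sample_ids = samples["sample_id"].tolist()
    n_g, n_s = len(gene_names), len(sample_ids)

    baseline = rng.normal(
        config.expression_baseline_mean, config.expression_baseline_sd, size=n_g
    )
    log_tpm = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(n_g, n_s)
    )

    silent = truth[(truth["variant_class"] == "silent") & truth["score"].notna()]
    mut_samples = silent.groupby("gene")["sample_id"].agg(lambda s: sorted(set(s)))
    ranked = mut_samples.map(len).sort_values(ascending=False, kind="mergesort")
    causal = list(ranked.index[: config.n_causal_genes])

    gene_pos = {g: i for i, g in enumerate(gene_names)}
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    causal_rows = []
    for g in causal:
        med_score = float(silent.loc[silent["gene"] == g, "score"].median())
        direction = 1.0 if med_score > 0 else -1.0
        shift = config.expression_shift * direction
        for s in mut_samples[g]:
            if s in sample_pos:
                log_tpm[gene_pos[g], sample_pos[s]] += shift
        causal_rows.append(
            {"gene": g, "shift": shift, "direction": "up" if shift > 0 else "down",
             "n_mutated_samples": len(mut_samples[g])}
        )
    tpm = pd.DataFrame(10.0 ** log_tpm, index=gene_names, columns=sample_ids)
    tpm.index.name = "gene"
    return tpm, pd.DataFrame(causal_rows)


# --------------------------------------------------------------------------
# conservation


def simulate_conservation_track(
    cds: Mapping[str, str],
    truth: pd.DataFrame,
    rng: np.random.Generator,
    score_slope: float = 0.3,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Per-base [0, 1] conservation values over every CDS position.

    Background positions get mid-level noisy values; positions carrying a
    planted silent mutation get a value decreasing linearly with the
    mutation's standardized score (``score_slope`` per SD), emulating the
    negative score-conservation association.  Returns a TSV-ready frame
    (seq_id, pos, value).
    """
    frames = []
    for tx, seq in cds.items():
        n = len(seq)
        vals = np.clip(rng.normal(0.5, noise_sd + 0.15, size=n), 0.0, 1.0)
        frames.append(pd.DataFrame({"seq_id": tx, "pos": np.arange(1, n + 1), "value": vals}))
    track = pd.concat(frames, ignore_index=True)
    track = track.set_index(["seq_id", "pos"])

    silent = truth[(truth["variant_class"] == "silent") & truth["score"].notna()]
    if len(silent):
        scores = silent["score"].to_numpy(dtype=float)
        z = (scores - scores.mean()) / (scores.std() or 1.0)
        planted = np.clip(
            0.5 - score_slope * z + rng.normal(0.0, noise_sd, size=len(silent)),
            0.0,
            1.0,
        )
        idx = pd.MultiIndex.from_frame(
            silent[["transcript_id", "cds_pos"]].rename(
                columns={"transcript_id": "seq_id", "cds_pos": "pos"}
            )
        )
        vals = pd.Series(planted, index=idx)
        vals = vals[~vals.index.duplicated()]
        track.loc[vals.index, "value"] = vals
    return track.reset_index()


# --------------------------------------------------------------------------
# focused candidate-screen study


def simulate_candidate_study(
    seed: int,
    n_genes: int = 1000,
    n_samples: int = 300,
    n_causal: int = 10,
    n_mut_samples: int = 20,
    expression_shift: float = 0.5,
    n_null_recurrent: int = 190,
    null_mut_range: tuple[int, int] = (3, 20),
    expression_noise_sd: float = 0.3,
    expression_baseline_mean: float = 1.5,
    expression_baseline_sd: float = 0.5,
    cancer_type: str = "SYN",
) -> tuple[pd.DataFrame, pd.DataFrame, dict, pd.DataFrame]:
    """A cohort purpose-built for validating the candidate screen.

    ``n_causal`` genes carry a recurrent silent mutation (|score| >= 10)
    in ``n_mut_samples`` samples each, with the gene's expression shifted
    by ``expression_shift`` log10 units in mutated samples (sign follows
    the mutation score); ``n_null_recurrent`` genes carry equally strong
    recurrent mutations with no expression effect.  Returns (mutation
    frame, TPM matrix, sample->cancer-type map, causal truth frame).
    """
    rng = np.random.default_rng(seed)
    gene_names = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"SAMPLE{i + 1:04d}" for i in range(n_samples)]
    sample_types = {s: cancer_type for s in sample_ids}

    n_recurrent = n_causal + n_null_recurrent
    if n_recurrent > n_genes:
        raise ValueError("more recurrent genes requested than genes available")
    chosen = rng.choice(n_genes, size=n_recurrent, replace=False)
    causal_genes = [gene_names[i] for i in chosen[:n_causal]]
    null_genes = [gene_names[i] for i in chosen[n_causal:]]

    rows = []
    truth_rows = []
    for rank, gene in enumerate(causal_genes + null_genes):
        causal = rank < n_causal
        n_mut = (
            n_mut_samples
            if causal
            else int(rng.integers(null_mut_range[0], null_mut_range[1] + 1))
        )
        carriers = rng.choice(sample_ids, size=n_mut, replace=False)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        score = sign * rng.uniform(10.0, 25.0)
        pos = int(rng.integers(1, 900)) * 3  # arbitrary third-codon position
        for s in carriers:
            rows.append(
                {"gene": gene, "transcript_id": f"TX_{gene}", "cds_pos": pos,
                 "ref_base": "C", "alt_base": "T", "sample_id": s,
                 "cancer_type": cancer_type, "variant_class": "silent",
                 "score": score}
            )
        truth_rows.append(
            {"gene": gene, "causal": causal, "score": score,
             "shift": expression_shift * sign if causal else 0.0,
             "carriers": tuple(sorted(carriers))}
        )
    mutations = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    baseline = rng.normal(expression_baseline_mean, expression_baseline_sd, size=n_genes)
    log_tpm = baseline[:, None] + rng.normal(
        0.0, expression_noise_sd, size=(n_genes, n_samples)
    )
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    for row in truth[truth["causal"]].itertuples(index=False):
        for s in row.carriers:
            log_tpm[gene_pos[row.gene], sample_pos[s]] += row.shift
    expression = pd.DataFrame(10.0 ** log_tpm, index=gene_names, columns=sample_ids)
    expression.index.name = "gene"
    return mutations, expression, sample_types, truth


def make_gene_lists(
    gene_names: Sequence[str],
    rng: np.random.Generator,
    sizes: Mapping[str, int] = None,
) -> dict[str, set[str]]:
    """Sample curated-style gene lists (ESS/OG/TSG) from a gene universe.

    Default sizes mirror the curated lists the pipeline consumes (331
    essential genes, 803 oncogenes, 1217 tumor suppressors), clipped to
    the universe size; lists are drawn independently and may overlap,
    as real curated lists do.
    """
    sizes = dict(GENE_LIST_SIZES) if sizes is None else dict(sizes)
    names = list(gene_names)
    out = {}
    for label, n in sizes.items():
        n = min(n, len(names))
        out[label] = set(rng.choice(names, size=n, replace=False))
    return out
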