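"""Readers for cohort inputs and resolution of mutations to codon changes.

The cohort arrives as a MAF-dialect tab-delimited file (one somatic
single-nucleotide variant per row).  Each silent mutation is resolved to
its reference/alternate codon pair against the transcript's coding
sequence (CDS), which is the substrate for optimality scoring.

Coordinates are CDS-based and 1-based (HGVS ``c.`` convention): codon
index ``i`` covers CDS bases ``3(i-1)+1 .. 3i``, and the offset within the
codon is 1, 2 or 3.  A genomic-coordinate path (CDS intervals from a GTF
plus a genome FASTA) is supported as a secondary route for real data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .codon_usage import CodonUsageError, is_stop, is_synonymous, normalize_codon

logger = logging.getLogger(__name__)

__all__ = [
    "CodonChange",
    "DataIntegrityError",
    "MafFormatError",
    "read_maf",
    "read_cds_fasta",
    "load_gene_list",
    "resolve_codon_change",
    "resolve_cohort",
    "stratify_by_af",
    "genomic_to_cds_pos",
    "read_gtf_cds_intervals",
]

#: MAF Variant_Classification -> internal variant class
VARIANT_CLASS_MAP = {
    "Silent": "silent",
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
}

_MANDATORY_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Transcript_ID",
)

_HGVSC = re.compile(r"^c\.(\d+)([ACGTacgt])>([ACGTacgt])$")


class MafFormatError(ValueError):
    """Raised when a MAF file lacks mandatory structure."""


class DataIntegrityError(ValueError):
    """Raised when a mutation contradicts the provided CDS sequence."""


@dataclass(frozen=True)
class CodonChange:
    """A single-base substitution expressed at codon resolution."""

    ref_codon: str
    alt_codon: str
    codon_index: int  # 1-based codon within the CDS
    offset_in_codon: int  # 1, 2 or 3
    not_scoreable: bool = False  # True when a stop codon is involved


def read_maf(
    path: str | Path,
    keep_classes: Iterable[str] = ("silent", "missense", "nonsense"),
    sample_types: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read a MAF-dialect file into the package's cohort frame.

    Rows whose ``Variant_Classification`` does not map into
    ``keep_classes`` are dropped (counted in the log), as are rows with
    ambiguous (non-ACGT) alleles, rows lacking a transcript, and rows
    whose CDS coordinate cannot be parsed.  CDS coordinates are taken from
    an ``HGVSc`` column (``c.123C>T``) when present, otherwise from
    ``CDS_Position`` + ``Reference_Allele`` + ``Tumor_Seq_Allele2``.

    Returns a DataFrame with columns ``sample_id``, ``cancer_type``,
    ``gene``, ``transcript_id``, ``cds_pos``, ``ref_base``, ``alt_base``,
    ``variant_class``.
    """
    keep = set(keep_classes)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MafFormatError(f"MAF missing mandatory column(s): {', '.join(missing)}")
    has_hgvsc = "HGVSc" in df.columns
    has_explicit = {"CDS_Position", "Reference_Allele", "Tumor_Seq_Allele2"}.issubset(
        df.columns
    )
    if not has_hgvsc and not has_explicit:
        raise MafFormatError(
            "MAF needs either an HGVSc column or "
            "CDS_Position/Reference_Allele/Tumor_Seq_Allele2 columns"
        )

    n_total = len(df)
    df = df.copy()
    df["variant_class"] = df["Variant_Classification"].map(VARIANT_CLASS_MAP)
    df.loc[df["variant_class"].isna(), "variant_class"] = "other"
    n_class_dropped = int((~df["variant_class"].isin(keep)).sum())
    df = df[df["variant_class"].isin(keep)]

    n_no_transcript = int(df["Transcript_ID"].isna().sum())
    df = df[df["Transcript_ID"].notna()]

    records = []
    n_unparseable = 0
    n_ambiguous = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        pos = ref = alt = None
        if has_hgvsc and isinstance(d.get("HGVSc"), str):
            m = _HGVSC.match(d["HGVSc"].strip())
            if m:
                pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
        if pos is None and has_explicit:
            try:
                pos = int(float(d["CDS_Position"]))
                ref = str(d["Reference_Allele"]).strip().upper()
                alt = str(d["Tumor_Seq_Allele2"]).strip().upper()
            except (TypeError, ValueError):
                pos = None
        if pos is None or pos < 1 or ref is None or alt is None:
            n_unparseable += 1
            continue
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            n_unparseable += 1
            continue
        if ref not in "ACGT" or alt not in "ACGT":
            n_ambiguous += 1
            continue
        sample = d["Tumor_Sample_Barcode"]
        cancer_type = d.get("Cancer_Type")
        if cancer_type is None and sample_types is not None:
            cancer_type = sample_types.get(sample)
        records.append(
            {
                "sample_id": sample,
                "cancer_type": cancer_type,
                "gene": d["Hugo_Symbol"],
                "transcript_id": d["Transcript_ID"],
                "cds_pos": pos,
                "ref_base": ref,
                "alt_base": alt,
                "variant_class": d["variant_class"],
            }
        )
    out = pd.DataFrame.from_records(
        records,
        columns=[
            "sample_id",
            "cancer_type",
            "gene",
            "transcript_id",
            "cds_pos",
            "ref_base",
            "alt_base",
            "variant_class",
        ],
    )
    logger.info(
        "read_maf: %d rows -> %d kept (%d class-dropped, %d without transcript, "
        "%d unparseable, %d ambiguous-base)",
        n_total,
        len(out),
        n_class_dropped,
        n_no_transcript,
        n_unparseable,
        n_ambiguous,
    )
    return out


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read per-transcript CDS sequences; record IDs are transcript IDs."""
    fasta = Fasta(str(path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def load_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; blank lines/comments ignored."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line)
    return symbols


def resolve_codon_change(
    cds: str,
    cds_pos: int,
    ref_base: str,
    alt_base: str,
    gene: str = "?",
) -> CodonChange:
    """Resolve a single-base CDS substitution to its codon pair.

    ``cds_pos`` is 1-based.  Raises :class:`DataIntegrityError` when the
    reference base does not match the CDS; a substitution inside a stop
    codon (or one creating a stop) is returned flagged ``not_scoreable``
    rather than raised.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise DataIntegrityError(f"{gene}: CDS length {len(cds)} not divisible by 3")
    if not (1 <= cds_pos <= len(cds)):
        raise DataIntegrityError(
            f"{gene}: cds_pos {cds_pos} outside CDS of length {len(cds)}"
        )
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    if cds[cds_pos - 1] != ref_base:
        raise DataIntegrityError(
            f"{gene}: reference mismatch at cds_pos {cds_pos}: "
            f"CDS has {cds[cds_pos - 1]}, record says {ref_base}"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    offset = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start : start + 3]
    alt_codon = ref_codon[: offset - 1] + alt_base + ref_codon[offset:]
    not_scoreable = is_stop(ref_codon) or is_stop(alt_codon)
    return CodonChange(
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        codon_index=codon_index,
        offset_in_codon=offset,
        not_scoreable=not_scoreable,
    )


def resolve_cohort(
    mutations: pd.DataFrame,
    cds_by_transcript: Mapping[str, str],
    strict: bool = True,
) -> pd.DataFrame:
    """Attach codon-change columns to a cohort frame.

    Rows whose transcript has no CDS are dropped with a logged count.
    Reference mismatches raise :class:`DataIntegrityError` when ``strict``
    (the default) and are otherwise dropped and counted.
    """
    rows = []
    n_no_cds = 0
    n_mismatch = 0
    for idx, row in mutations.iterrows():
        cds = cds_by_transcript.get(row["transcript_id"])
        if cds is None:
            n_no_cds += 1
            continue
        try:
            change = resolve_codon_change(
                cds, int(row["cds_pos"]), row["ref_base"], row["alt_base"],
                gene=str(row["gene"]),
            )
        except DataIntegrityError:
            if strict:
                raise
            n_mismatch += 1
            continue
        rows.append(
            (
                idx,
                change.ref_codon,
                change.alt_codon,
                change.codon_index,
                change.offset_in_codon,
                change.not_scoreable,
            )
        )
    if n_no_cds or n_mismatch:
        logger.info(
            "resolve_cohort: dropped %d rows without CDS, %d reference mismatches",
            n_no_cds,
            n_mismatch,
        )
    resolved = pd.DataFrame(
        rows,
        columns=[
            "_idx",
            "ref_codon",
            "alt_codon",
            "codon_index",
            "offset_in_codon",
            "not_scoreable",
        ],
    ).set_index("_idx")
    out = mutations.join(resolved, how="inner")
    out.index.name = mutations.index.name
    # sanity: silent rows must be synonymous, missense must not be
    silent = out["variant_class"] == "silent"
    if silent.any():
        bad = [
            i
            for i in out.index[silent]
            if not out.at[i, "not_scoreable"]
            and is_synonymous(out.at[i, "ref_codon"], out.at[i, "alt_codon"]) is False
        ]
        if bad:
            raise DataIntegrityError(
                f"{len(bad)} records labeled silent are not synonymous "
                f"(first at index {bad[0]})"
            )
    return out


def stratify_by_af(
    variants: pd.DataFrame, af_column: str = "af", threshold: float = 0.01
) -> pd.DataFrame:
    """Label variants ``high_af`` (AF >= threshold) or ``low_af`` (< threshold).

    The boundary allele frequency goes to the high stratum.  Returns a copy
    with an ``af_stratum`` column.
    """
    af = pd.to_numeric(variants[af_column], errors="raise")
    if af.isna().any():
        raise ValueError("allele frequency must be defined for every variant")
    if ((af < 0) | (af > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    out = variants.copy()
    out["af_stratum"] = np.where(af >= threshold, "high_af", "low_af")
    return out


# --- secondary, genomic-coordinate path -----------------------------------


def read_gtf_cds_intervals(path: str | Path) -> pd.DataFrame:
    """CDS intervals per transcript from a GTF.

    Returns a frame with columns ``transcript_id``, ``chrom``, ``start``,
    ``end`` (1-based inclusive, as in GTF), ``strand``, sorted in
    translation order (ascending for '+', descending for '-').
    """
    cols = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    gtf = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype=str)
    cds = gtf[gtf["feature"] == "CDS"].copy()
    cds["transcript_id"] = cds["attributes"].str.extract(r'transcript_id "([^"]+)"')
    cds["start"] = cds["start"].astype(int)
    cds["end"] = cds["end"].astype(int)
    cds = cds[["transcript_id", "chrom", "start", "end", "strand"]]
    plus = cds[cds["strand"] == "+"].sort_values(["transcript_id", "start"])
    minus = cds[cds["strand"] == "-"].sort_values(
        ["transcript_id", "start"], ascending=[True, False]
    )
    return pd.concat([plus, minus], ignore_index=True)


def genomic_to_cds_pos(
    intervals: pd.DataFrame, transcript_id: str, genomic_pos: int
) -> int:
    """Map a genomic position to the 1-based CDS position of a transcript.

    ``intervals`` is the frame returned by :func:`read_gtf_cds_intervals`.
    For minus-strand transcripts the CDS runs 3'->5' on the genome and the
    caller must reverse-complement alleles separately.
    """
    tx = intervals[intervals["transcript_id"] == transcript_id]
    if tx.empty:
        raise KeyError(f"transcript {transcript_id} not in CDS intervals")
    offset = 0
    for row in tx.itertuples(index=False):
        length = row.end - row.start + 1
        if row.start <= genomic_pos <= row.end:
            if row.strand == "+":
                return offset + (genomic_pos - row.start) + 1
            return offset + (row.end - genomic_pos) + 1
        offset += length
    raise ValueError(
        f"position {genomic_pos} is not inside the CDS of {transcript_id}"
    )
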