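"""Codon usage tables and the genetic code.

The central quantity of the package is a codon's usage frequency per 1,000
triplets in human coding sequence.  A synonymous substitution changes a
codon without changing the encoded amino acid; the difference between the
usage frequencies of the mutant and the reference codon (the "codon
optimality score") is computed in :mod:`silopt.scoring` on top of the
lookups defined here.

A human codon usage table (per-1,000 frequencies in the layout published by
the Kazusa codon usage database) is vendored with the package so that no
analysis step requires a download.
"""

from __future__ import annotations

import math
import re
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

__all__ = [
    "CodonUsageTable",
    "CodonUsageError",
    "GENETIC_CODE",
    "STOP_CODONS",
    "SENSE_CODONS",
    "ALL_CODONS",
    "normalize_codon",
    "translate",
    "is_stop",
    "is_synonymous",
    "load_codon_usage",
    "human_codon_usage",
]

_BASES = "ACGT"

#: The 64 codons of the standard genetic code, DNA alphabet, sorted.
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: Stop codons of the standard code.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: codon -> one-letter amino acid ('*' for the three stop codons).
GENETIC_CODE: dict[str, str] = {
    **{c: aa for c, aa in _STANDARD.forward_table.items()},
    **{c: "*" for c in STOP_CODONS},
}

#: The 61 amino-acid-encoding codons.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


class CodonUsageError(ValueError):
    """Raised for malformed codon usage input or invalid codon lookups."""


def normalize_codon(codon: str) -> str:
    """Return ``codon`` upper-cased with RNA ``U`` mapped to DNA ``T``.

    Raises :class:`CodonUsageError` if the result is not one of the 64
    codons.  Normalization is idempotent.
    """
    if not isinstance(codon, str):
        raise CodonUsageError(f"codon must be a string, got {type(codon).__name__}")
    norm = codon.strip().upper().replace("U", "T")
    if len(norm) != 3 or any(b not in _BASES for b in norm):
        raise CodonUsageError(f"invalid codon {codon!r}")
    return norm


def translate(codon: str) -> str:
    """One-letter amino acid encoded by ``codon`` ('*' for stop)."""
    return GENETIC_CODE[normalize_codon(codon)]


def is_stop(codon: str) -> bool:
    return normalize_codon(codon) in STOP_CODONS


def is_synonymous(ref_codon: str, alt_codon: str) -> Optional[bool]:
    """Whether two codons encode the same amino acid.

    Returns ``True``/``False`` for sense-codon pairs.  Returns ``None`` when
    either codon is a stop codon: such a change is not scoreable under a
    translation-centric optimality metric, and callers flag rather than
    raise.
    """
    ref = normalize_codon(ref_codon)
    alt = normalize_codon(alt_codon)
    if ref in STOP_CODONS or alt in STOP_CODONS:
        return None
    return GENETIC_CODE[ref] == GENETIC_CODE[alt]


@dataclass(frozen=True)
class CodonUsageTable:
    """Usage frequency (per 1,000 triplets) for each of the 64 codons.

    Parameters
    ----------
    entries
        Mapping of DNA codon to its per-1,000 frequency.  Exactly the 64
        codons must be present with non-negative frequencies summing to
        1,000 within rounding tolerance (+/- 0.05 per codon, i.e. +/- 3.2).
    source_label
        Free-text provenance label carried into outputs.
    """

    entries: Mapping[str, float]
    source_label: str = ""
    _validate: bool = field(default=True, repr=False, compare=False)

    #: allowed deviation of the frequency sum from 1,000 (64 x 0.05)
    SUM_TOLERANCE = 3.2

    def __post_init__(self) -> None:
        if not self._validate:
            return
        entries = dict(self.entries)
        missing = [c for c in ALL_CODONS if c not in entries]
        if missing:
            raise CodonUsageError(f"missing codons: {', '.join(missing)}")
        extra = sorted(set(entries) - set(ALL_CODONS))
        if extra:
            raise CodonUsageError(f"unexpected codons: {', '.join(extra)}")
        negative = sorted(c for c, v in entries.items() if v < 0)
        if negative:
            raise CodonUsageError(f"negative frequency for: {', '.join(negative)}")
        total = sum(entries.values())
        if not math.isclose(total, 1000.0, abs_tol=self.SUM_TOLERANCE):
            raise CodonUsageError(
                f"frequencies sum to {total:.2f}, expected 1000 +/- {self.SUM_TOLERANCE}"
            )
        object.__setattr__(self, "entries", entries)

    def frequency(self, codon: str) -> float:
        """Per-1,000 usage frequency of ``codon`` (case/U-T insensitive)."""
        return self.entries[normalize_codon(codon)]

    def __getitem__(self, codon: str) -> float:
        return self.frequency(codon)

    def median_frequency(self, sense_only: bool = False) -> float:
        """Median usage frequency over the table's codons.

        By default the median is taken over all 64 codons, which reproduces
        the human table's reference median of 15.1; ``sense_only=True``
        restricts to the 61 amino-acid-encoding codons.
        """
        codons: Iterable[str] = SENSE_CODONS if sense_only else ALL_CODONS
        return float(statistics.median(self.entries[c] for c in codons))

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


_KAZUSA_FIELD = re.compile(
    r"([ACGTUacgtu]{3})\s+([0-9]+(?:\.[0-9]+)?)(?:\s*\(\s*[0-9]+\s*\))?"
)


def _parse_kazusa(text: str) -> dict[str, float]:
    entries: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for codon, freq in _KAZUSA_FIELD.findall(line):
            norm = normalize_codon(codon)
            if norm in entries:
                raise CodonUsageError(f"duplicate codon {norm}")
            entries[norm] = float(freq)
    return entries


def _parse_tsv(text: str) -> dict[str, float]:
    entries: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,\s]+", line)
        if len(parts) < 2:
            raise CodonUsageError(f"line {lineno}: expected 'codon<TAB>frequency'")
        codon, freq = parts[0], parts[1]
        if lineno == 1 and not re.fullmatch(r"[ACGTUacgtu]{3}", codon):
            continue  # header row
        norm = normalize_codon(codon)
        if norm in entries:
            raise CodonUsageError(f"duplicate codon {norm}")
        try:
            entries[norm] = float(freq)
        except ValueError as exc:
            raise CodonUsageError(f"line {lineno}: bad frequency {freq!r}") from exc
    return entries


def load_codon_usage(
    source: str | Path,
    dialect: str = "kazusa",
    source_label: str | None = None,
) -> CodonUsageTable:
    """Load a codon usage table from text or a file path.

    Parameters
    ----------
    source
        Either the table text itself or a path to a file containing it.
    dialect
        ``"kazusa"`` for the multi-column Kazusa layout (RNA alphabet,
        optional occurrence counts in parentheses) or ``"tsv"`` for a
        two-column codon/frequency file.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        path = Path(source)
        text = path.read_text()
        label = source_label or path.name
    else:
        text = str(source)
        label = source_label or f"<{dialect} text>"
    if dialect == "kazusa":
        entries = _parse_kazusa(text)
    elif dialect == "tsv":
        entries = _parse_tsv(text)
    else:
        raise CodonUsageError(f"unknown dialect {dialect!r}")
    return CodonUsageTable(entries=entries, source_label=label)


def human_codon_usage() -> CodonUsageTable:
    """The vendored human codon usage table (per-1,000 frequencies)."""
    text = (
        resources.files("silopt").joinpath("data/human_codon_usage.txt").read_text()
    )
    return CodonUsageTable(entries=_parse_kazusa(text), source_label="Homo sapiens")
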