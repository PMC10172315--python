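"""Clonal timing and evolutionary conservation of silent mutations.

Timing labels come from a MutationTimeR-style table that places each
somatic mutation into one of four classes relative to the tumor's
copy-number history: early clonal, late clonal, clonal (unassignable
within the clonal phase, "clonal [NA]"), and subclonal.  The coarse
early/late dichotomy maps early clonal and clonal to "early" and late
clonal and subclonal to "late".

Conservation comes from per-base tracks (PhastCons/PhyloP-style); mutated
positions are compared against a control of positions sampled uniformly
from the coding sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "TIMING_CLASSES",
    "COARSE_TIMING",
    "parse_timing_label",
    "read_timing_table",
    "attach_timing",
    "compare_scores_by_timing",
    "ControlSample",
    "sample_cds_control",
    "TsvTrack",
    "BigWigTrack",
    "compare_conservation",
]

#: canonical raw timing classes
TIMING_CLASSES = ("early_clonal", "late_clonal", "clonal_NA", "subclonal")

#: raw class -> coarse early/late dichotomy
COARSE_TIMING = {
    "early_clonal": "early",
    "clonal_NA": "early",
    "late_clonal": "late",
    "subclonal": "late",
}

_LABEL_ALIASES = {
    "clonal [early]": "early_clonal",
    "clonal [late]": "late_clonal",
    "clonal [na]": "clonal_NA",
    "subclonal": "subclonal",
    "early_clonal": "early_clonal",
    "late_clonal": "late_clonal",
    "clonal_na": "clonal_NA",
}


def parse_timing_label(label: str) -> str:
    """Normalize a MutationTimeR class string to a canonical raw label."""
    key = str(label).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown timing label {label!r}")
    return _LABEL_ALIASES[key]


def read_timing_table(path: str | Path) -> pd.DataFrame:
    """Read a timing TSV keyed by (sample, transcript, cds_pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "transcript_id": str})
    df["timing_raw"] = df["timing"].map(parse_timing_label)
    df["timing_coarse"] = df["timing_raw"].map(COARSE_TIMING)
    return df


_KEY = ["sample_id", "transcript_id", "cds_pos", "ref_base", "alt_base"]


def attach_timing(mutations: pd.DataFrame, timing: pd.DataFrame) -> pd.DataFrame:
    """Join timing labels onto the cohort frame.

    ``timing`` must carry the variant key columns and either a raw
    ``timing`` string column (parsed here) or pre-parsed ``timing_raw``.
    Unmatched mutations keep NaN labels and are counted in the log.
    """
    t = timing.copy()
    if "timing_raw" not in t.columns:
        t["timing_raw"] = t["timing"].map(parse_timing_label)
    else:
        t["timing_raw"] = t["timing_raw"].map(parse_timing_label)
    t["timing_coarse"] = t["timing_raw"].map(COARSE_TIMING)
    t = t.drop_duplicates(subset=_KEY)
    out = mutations.merge(
        t[_KEY + ["timing_raw", "timing_coarse"]], on=_KEY, how="left"
    )
    out.index = mutations.index
    n_unmatched = int(out["timing_raw"].isna().sum())
    if n_unmatched:
        logger.info("attach_timing: %d mutations without a timing label", n_unmatched)
    return out


def compare_scores_by_timing(mutations: pd.DataFrame) -> dict:
    """Score distributions per timing class with all pairwise contrasts.

    Returns per-class n/median/mean and a frame of pairwise two-sided
    Wilcoxon rank-sum p-values, BH-adjusted across the pairs.  Classes
    with fewer than 2 labeled scores are skipped with a warning.
    """
    sub = mutations.dropna(subset=["timing_raw", "score"])
    summary = (
        sub.groupby("timing_raw")["score"]
        .agg(n="size", median="median", mean="mean")
        .reindex([c for c in TIMING_CLASSES if c in set(sub["timing_raw"])])
    )
    present = [c for c in TIMING_CLASSES if (sub["timing_raw"] == c).sum() >= 1]
    if len(present) < 2:
        raise ValueError("need at least two non-empty timing classes")
    rows = []
    for a, b in combinations(present, 2):
        xa = sub.loc[sub["timing_raw"] == a, "score"].to_numpy()
        xb = sub.loc[sub["timing_raw"] == b, "score"].to_numpy()
        if len(xa) < 1 or len(xb) < 1:
            warnings.warn(f"timing contrast {a} vs {b} skipped: empty class")
            continue
        res = wilcoxon_rank_sum(xa, xb)
        rows.append({"class_a": a, "class_b": b, "p_value": res.p_value,
                     "method": res.method, "n_a": res.n_x, "n_b": res.n_y})
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["fdr"] = bh_adjust(contrasts["p_value"].to_numpy())
    return {"summary": summary, "contrasts": contrasts}


@dataclass(frozen=True)
class ControlSample:
    """Positions sampled uniformly from the coding sequence."""

    positions: pd.DataFrame  # columns: seq_id, pos (1-based within the sequence)
    n: int
    seed: int


def sample_cds_control(
    cds_lengths: Mapping[str, int], n: int = 100_000, seed: int = 0
) -> ControlSample:
    """Draw ``n`` CDS base positions uniformly with replacement.

    ``cds_lengths`` maps sequence ID to its CDS length in bases.  Sampling
    is uniform over all bases (long CDSs contribute proportionally) and
    reproducible under a fixed seed.
    """
    ids = list(cds_lengths)
    lengths = np.array([cds_lengths[i] for i in ids], dtype=np.int64)
    if len(ids) == 0 or lengths.sum() <= 0:
        raise ValueError("no CDS bases to sample from")
    rng = np.random.default_rng(seed)
    flat = rng.integers(0, lengths.sum(), size=n)
    bounds = np.cumsum(lengths)
    which = np.searchsorted(bounds, flat, side="right")
    offset = flat - (bounds[which] - lengths[which])
    positions = pd.DataFrame(
        {"seq_id": np.array(ids, dtype=object)[which], "pos": offset + 1}
    )
    return ControlSample(positions=positions, n=n, seed=seed)


class TsvTrack:
    """Per-position conservation scores from a 2/3-column TSV.

    Columns: ``seq_id``, ``pos`` (1-based), ``value``.  Positions absent
    from the file are missing (NaN), never zero.
    """

    def __init__(self, source: str | Path | pd.DataFrame, track_name: str = "other"):
        if isinstance(source, pd.DataFrame):
            df = source
        else:
            df = pd.read_csv(source, sep="\t")
        self.track_name = track_name
        self._values = df.set_index(["seq_id", "pos"])["value"]
        self._values = self._values[~self._values.index.duplicated()]

    def get(self, seq_id: str, pos: int) -> float:
        try:
            return float(self._values.loc[(seq_id, int(pos))])
        except KeyError:
            return float("nan")

    def get_many(self, positions: pd.DataFrame) -> np.ndarray:
        idx = pd.MultiIndex.from_frame(positions[["seq_id", "pos"]])
        return self._values.reindex(idx).to_numpy(dtype=float)


class BigWigTrack:
    """Per-position scores from a bigWig file (genomic coordinates).

    ``pos`` is 1-based; bigWig intervals are 0-based half-open.
    """

    def __init__(self, path: str | Path, track_name: str = "other"):
        import pyBigWig  # soft dependency; TSV tracks need no extra install

        self._bw = pyBigWig.open(str(path))
        self.track_name = track_name

    def get(self, seq_id: str, pos: int) -> float:
        vals = self._bw.values(seq_id, int(pos) - 1, int(pos))
        v = vals[0]
        return float("nan") if v is None else float(v)

    def get_many(self, positions: pd.DataFrame) -> np.ndarray:
        return np.array(
            [self.get(s, p) for s, p in positions[["seq_id", "pos"]].itertuples(index=False)]
        )


def compare_conservation(
    mutations: pd.DataFrame,
    control: ControlSample,
    track,
    seq_column: str = "transcript_id",
    pos_column: str = "cds_pos",
) -> dict:
    """Conservation of mutated positions by score group vs. the control.

    Looks up the track at every mutated position (grouped by the score
    group low/mid/high) and at the control positions, drops missing
    values with a count, and reports per-group summaries plus all
    pairwise two-sided Wilcoxon contrasts among {low, mid, high, control}
    (raw and BH-adjusted p-values).
    """
    values = {}
    n_missing = {}
    for grp in ("low", "mid", "high"):
        sub = mutations[mutations["score_group"] == grp]
        if sub.empty:
            continue
        pos = sub[[seq_column, pos_column]].rename(
            columns={seq_column: "seq_id", pos_column: "pos"}
        )
        v = track.get_many(pos)
        n_missing[grp] = int(np.isnan(v).sum())
        v = v[~np.isnan(v)]
        if v.size == 0:
            warnings.warn(f"conservation group {grp} has no covered positions; excluded")
            continue
        values[grp] = v
    vc = track.get_many(control.positions)
    n_missing["control"] = int(np.isnan(vc).sum())
    vc = vc[~np.isnan(vc)]
    if vc.size:
        values["control"] = vc

    if not values:
        warnings.warn("conservation track covers no queried positions")
        return {"summary": pd.DataFrame(), "contrasts": pd.DataFrame(),
                "n_missing": n_missing}

    summary = pd.DataFrame(
        {
            g: {"n": len(v), "median": float(np.median(v)), "mean": float(np.mean(v))}
            for g, v in values.items()
        }
    ).T
    rows = []
    for a, b in combinations(values, 2):
        res = wilcoxon_rank_sum(values[a], values[b])
        rows.append({"group_a": a, "group_b": b, "p_value": res.p_value,
                     "method": res.method})
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["fdr"] = bh_adjust(contrasts["p_value"].to_numpy())
    return {"summary": summary, "contrasts": contrasts, "n_missing": n_missing}
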