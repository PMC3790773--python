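"""Preprocessing: per-exon coverage summaries, exome-wide statistics and
raw heterozygosity candidates.

This stage is run once per sample pair; its outputs are persisted as plain
TSV intermediates (per-exon coverage, paired het candidates, stats) so the
calling stage can be re-run with new filters without re-reading alignments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import BASES, ExonRecord, PileupPosition

logger = logging.getLogger(__name__)

HET_MIN_COUNT = 5  # fixed candidate rule: >=2 bases each covered >=5

__all__ = [
    "ExonCoverage",
    "ExomeStats",
    "RawHetCandidate",
    "summarize_exons",
    "exome_stats",
    "collect_het_candidates",
    "pair_case_counts",
    "coverage_report",
    "write_exon_coverage",
    "read_exon_coverage",
    "write_stats",
    "read_stats",
    "write_het_table",
    "read_het_table",
]


@dataclass(frozen=True)
class ExonCoverage:
    """Mean and internal variability of per-base depth over one exon.

    ``cov_sd`` is the population standard deviation over all exon bases,
    uncovered bases counting as depth 0.
    """

    exon: ExonRecord
    mean_cov: float
    cov_sd: float
    n_bases: int


@dataclass(frozen=True)
class ExomeStats:
    """Whole-exome median and mean of the per-exon mean coverages."""

    median_cov: float
    mean_cov: float


@dataclass(frozen=True)
class RawHetCandidate:
    """Control position with >=2 bases covered >=5; only the top two kept."""

    chrom: str
    pos: int
    top2: Tuple[Tuple[str, int], Tuple[str, int]]


def _top_two(base_counts: Dict[str, int]) -> Tuple[Tuple[str, int],
                                                   Tuple[str, int]]:
    """Two most frequent bases, count ties broken by base order A<C<G<T."""
    items = sorted(base_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    items += [("N", 0), ("N", 0)]
    return items[0], items[1]


def summarize_exons(positions: Iterable[PileupPosition],
                    exons: List[ExonRecord]) -> List[ExonCoverage]:
    """Aggregate per-position counted depth into one summary per exon.

    Positions outside every exon are ignored (logged at debug level);
    positions missing from the input contribute depth 0.  The result is
    independent of input order.
    """
    by_chrom: Dict[str, List[Tuple[int, ExonRecord]]] = {}
    for i, ex in enumerate(exons):
        by_chrom.setdefault(ex.chrom, []).append((i, ex))

    starts = {c: np.array([e.start for _, e in lst])
              for c, lst in by_chrom.items()}
    # accumulate depth per (exon index) as dict pos->depth
    depths: Dict[int, Dict[int, int]] = {i: {} for i in range(len(exons))}
    for p in positions:
        lst = by_chrom.get(p.chrom)
        if lst is None:
            logger.debug("position %s:%d outside exonic space", p.chrom, p.pos)
            continue
        pos0 = p.pos - 1
        j = int(np.searchsorted(starts[p.chrom], pos0, side="right")) - 1
        hit = None
        if j >= 0:
            idx, ex = lst[j]
            if ex.start <= pos0 < ex.end:
                hit = idx
        if hit is None:
            logger.debug("position %s:%d outside exonic space", p.chrom, p.pos)
            continue
        depths[hit][pos0] = depths[hit].get(pos0, 0) + p.counted

    out: List[ExonCoverage] = []
    for i, ex in enumerate(exons):
        n = len(ex)
        vals = np.zeros(n)
        for pos0, d in depths[i].items():
            vals[pos0 - ex.start] = d
        out.append(ExonCoverage(ex, float(vals.mean()),
                                float(vals.std()), n))
    return out


def exome_stats(covs: Iterable[ExonCoverage]) -> ExomeStats:
    """Median and mean of the per-exon mean coverages.

    The median over an even number of exons is the mean of the two central
    values (numpy convention).
    """
    means = np.array([c.mean_cov for c in covs], dtype=float)
    if len(means) == 0:
        raise ValueError("cannot compute exome statistics of zero exons")
    return ExomeStats(float(np.median(means)), float(means.mean()))


def collect_het_candidates(control_positions: Iterable[PileupPosition]
                           ) -> List[RawHetCandidate]:
    """Raw heterozygosity candidates from the control sample.

    A position qualifies when at least two distinct bases each reach the
    fixed count of >= 5; the two most frequent bases are stored and the rest
    discarded.
    """
    out = []
    for p in control_positions:
        if sum(1 for b in BASES if p.base_counts.get(b, 0) >= HET_MIN_COUNT) >= 2:
            out.append(RawHetCandidate(p.chrom, p.pos,
                                       _top_two(p.base_counts)))
    return out


def pair_case_counts(candidates: Iterable[RawHetCandidate],
                     case_positions: Iterable[PileupPosition]) -> pd.DataFrame:
    """Attach the case's own two most frequent base counts to each candidate.

    Positions uncovered in the case get zero counts and an ``uncovered``
    flag.  The case's top-two pair may differ from the control's; it is
    recorded as-is and the discrepancy is resolved downstream.
    """
    case_idx = {(p.chrom, p.pos): p for p in case_positions}
    rows = []
    for c in candidates:
        p = case_idx.get((c.chrom, c.pos))
        if p is None or p.counted == 0:
            t1, t2 = ("N", 0), ("N", 0)
            flag = "case_uncovered"
        else:
            t1, t2 = _top_two(p.base_counts)
            flag = "."
        rows.append((c.chrom, c.pos,
                     c.top2[0][0], c.top2[0][1], c.top2[1][0], c.top2[1][1],
                     t1[0], t1[1], t2[0], t2[1], flag))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "control_a1", "control_c1", "control_a2",
        "control_c2", "case_a1", "case_c1", "case_a2", "case_c2", "flags"])


def coverage_report(case_stats: ExomeStats, control_stats: ExomeStats,
                    case_covs: Iterable[ExonCoverage],
                    control_covs: Iterable[ExonCoverage],
                    bins: int = 50,
                    warn_band: Tuple[float, float] = (0.5, 2.0)) -> dict:
    """Per-sample coverage histograms, medians and the case:control ratio.

    Emits an imbalance warning when the median ratio leaves ``warn_band``
    (a strongly imbalanced pair is analysable after normalization but the
    user should know).
    """
    case_means = np.array([c.mean_cov for c in case_covs])
    control_means = np.array([c.mean_cov for c in control_covs])
    hi = max(case_means.max(initial=0.0), control_means.max(initial=0.0), 1.0)
    edges = np.linspace(0.0, hi, bins + 1)
    if control_stats.median_cov == 0:
        raise ValueError("control median coverage is zero")
    ratio = case_stats.median_cov / control_stats.median_cov
    imbalance = not (warn_band[0] <= ratio <= warn_band[1])
    if imbalance:
        logger.warning(
            "case/control median coverage ratio %.2f outside %s: "
            "strong coverage imbalance", ratio, warn_band)
    return {
        "case": {"median": case_stats.median_cov,
                 "mean": case_stats.mean_cov,
                 "hist": np.histogram(case_means, bins=edges)[0],
                 "edges": edges},
        "control": {"median": control_stats.median_cov,
                    "mean": control_stats.mean_cov,
                    "hist": np.histogram(control_means, bins=edges)[0],
                    "edges": edges},
        "median_ratio": ratio,
        "imbalance_warning": imbalance,
    }


# ---------------------------------------------------------------------------
# intermediate TSV contract between preprocessing and calling


_COV_COLUMNS = ["exon_label", "chrom", "start", "end", "mean_cov", "cov_sd"]


def write_exon_coverage(covs: Iterable[ExonCoverage], path) -> None:
    df = pd.DataFrame(
        [(c.exon.exon_label, c.exon.chrom, c.exon.start, c.exon.end,
          c.mean_cov, c.cov_sd) for c in covs],
        columns=_COV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_exon_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_COV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_stats(stats: ExomeStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("stat\tvalue\n")
        fh.write(f"median_cov\t{stats.median_cov!r}\n")
        fh.write(f"mean_cov\t{stats.mean_cov!r}\n")


def read_stats(path) -> ExomeStats:
    df = pd.read_csv(path, sep="\t").set_index("stat")["value"]
    return ExomeStats(float(df["median_cov"]), float(df["mean_cov"]))


def write_het_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_het_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
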