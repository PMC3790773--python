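"""Scoring of calls against simulated truth, and the windowed Pearson
correlation module.

A truth event counts as detected when the union of same-direction called
exons overlapping it covers at least 80% of its exons; a call overlapping
no truth event at all is a false positive; a truth event satisfied only by
two or more disjoint calls is flagged as hypersegmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .cna import CNASegment
from .coverage import HET_MIN_COUNT
from .loh import AICall, LOHParams, call_control_het
from .simulate import TruthEvent

OVERLAP_FRACTION = 0.8

__all__ = ["EvalReport", "score_calls", "score_ai_calls",
           "windowed_pearson", "AIScore"]


@dataclass
class EvalReport:
    """CNA-call scoring summary."""

    n_truth: int
    n_called: int
    true_positives: int
    false_positives: int
    hypersegmented: int
    overlap_fractions: List[float] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.n_truth if self.n_truth else float("nan")

    @property
    def ppv(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")


def _segment_exon_range(seg: CNASegment, chrom_exons: pd.DataFrame
                        ) -> Tuple[int, int]:
    """Chromosome-local index range (inclusive) of exons inside a segment."""
    starts = chrom_exons["start"].to_numpy()
    ends = chrom_exons["end"].to_numpy()
    lo = int(np.searchsorted(ends, seg.start, side="right"))
    hi = int(np.searchsorted(starts, seg.end, side="right")) - 1
    return lo, hi


def score_calls(segments: Sequence[CNASegment],
                truth: Sequence[TruthEvent],
                exon_table: pd.DataFrame) -> EvalReport:
    """Score called segments against truth events on exon index space.

    ``exon_table`` is the ordered exon annotation (chrom, start, end) that
    defines chromosome-local exon indices for both sides.
    """
    by_chrom = {c: df.reset_index(drop=True)
                for c, df in exon_table.groupby("chrom", sort=False)}
    seg_ranges: List[Tuple[CNASegment, int, int]] = []
    for seg in segments:
        lo, hi = _segment_exon_range(seg, by_chrom[seg.chrom])
        seg_ranges.append((seg, lo, hi))

    tp = 0
    hyperseg = 0
    overlaps: List[float] = []
    matched_segments = set()
    for ev in truth:
        ev_len = ev.size
        covered = np.zeros(ev_len, dtype=bool)
        n_overlapping = 0
        best_single = 0
        for si, (seg, lo, hi) in enumerate(seg_ranges):
            if seg.chrom != ev.chrom or seg.direction != ev.direction:
                continue
            o_lo = max(lo, ev.first_exon)
            o_hi = min(hi, ev.last_exon)
            if o_lo > o_hi:
                continue
            covered[o_lo - ev.first_exon:o_hi - ev.first_exon + 1] = True
            n_overlapping += 1
            best_single = max(best_single, o_hi - o_lo + 1)
            matched_segments.add(si)
        frac = covered.sum() / ev_len
        overlaps.append(float(frac))
        if frac >= OVERLAP_FRACTION:
            tp += 1
            if n_overlapping >= 2 and best_single < OVERLAP_FRACTION * ev_len:
                hyperseg += 1

    fp = 0
    for si, (seg, lo, hi) in enumerate(seg_ranges):
        any_overlap = any(
            seg.chrom == ev.chrom and
            max(lo, ev.first_exon) <= min(hi, ev.last_exon)
            for ev in truth)
        if not any_overlap:
            fp += 1

    return EvalReport(n_truth=len(truth), n_called=len(segments),
                      true_positives=tp, false_positives=fp,
                      hypersegmented=hyperseg, overlap_fractions=overlaps)


@dataclass
class AIScore:
    """The three allelic-imbalance metrics plus false positives."""

    n_truth_het: int          # truth het positions inside CNA regions
    n_control_called: int     # of those, called heterozygous in the control
    n_ai_called: int          # of those, called non-conserved in the case
    n_correct_category: int   # of the AI calls, assigned the truth category
    false_positives: int      # truth-conserved positions called AI

    @property
    def het_sensitivity(self) -> Optional[float]:
        return (self.n_control_called / self.n_truth_het
                if self.n_truth_het else None)

    @property
    def ai_sensitivity(self) -> Optional[float]:
        return (self.n_ai_called / self.n_control_called
                if self.n_control_called else None)

    @property
    def category_accuracy(self) -> Optional[float]:
        return (self.n_correct_category / self.n_ai_called
                if self.n_ai_called else None)


def score_ai_calls(ai_calls: Sequence[AICall],
                   het_table: pd.DataFrame,
                   truth: Sequence[TruthEvent],
                   params: LOHParams = LOHParams()) -> AIScore:
    """Score the LOH/AI pipeline against simulated truth.

    The three metrics follow the detection chain: control het calling of
    truth positions inside CNA regions; AI detection (any non-conserved
    category) among those; and categorization among the detected.
    ``het_table`` is needed to recover which truth positions were even
    tested (calls exist only for control-accepted positions).
    """
    truth_pos: Dict[Tuple[str, int], str] = {}
    for ev in truth:
        for chrom, pos, category in ev.het_positions:
            truth_pos[(chrom, pos)] = category

    call_idx = {(c.chrom, c.pos): c for c in ai_calls}

    n_truth_het = len(truth_pos)
    n_control_called = 0
    n_ai_called = 0
    n_correct = 0
    fp = 0
    for row in het_table.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        expected = truth_pos.get(key)
        if expected is not None:
            if int(row.control_c2) < HET_MIN_COUNT:
                continue  # never became a candidate: a het-calling miss
            ok, _ = call_control_het(
                (row.control_a1, int(row.control_c1)),
                (row.control_a2, int(row.control_c2)), params.control_alpha)
            if not ok:
                continue
            n_control_called += 1
            call = call_idx.get(key)
            if call is not None and call.category != "conserved_het":
                n_ai_called += 1
                if call.category == expected:
                    n_correct += 1
        else:
            call = call_idx.get(key)
            if call is not None and call.category != "conserved_het":
                fp += 1
    return AIScore(n_truth_het, n_control_called, n_ai_called, n_correct, fp)


def windowed_pearson(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     value_col: str = "ratio") -> float:
    """Pearson r between two windowed case/control ratio tables.

    Both tables carry (chrom, window identifier, ratio) over identical
    window definitions; chromosome Y windows are removed and windows with a
    missing ratio in either table are dropped pairwise.
    """
    key_cols = [c for c in ("chrom", "window", "start") if c in table_a.columns
                and c in table_b.columns]
    if not key_cols:
        raise ValueError("tables share no window key columns")
    a = table_a[~table_a["chrom"].astype(str).isin(["Y", "chrY"])]
    b = table_b[~table_b["chrom"].astype(str).isin(["Y", "chrY"])]
    merged = a.merge(b, on=key_cols, suffixes=("_a", "_b"))
    x = merged[f"{value_col}_a"].astype(float)
    y = merged[f"{value_col}_b"].astype(float)
    keep = x.notna() & y.notna()
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >=3 complete window pairs, got {len(x)}")
    return float(pearsonr(x, y).statistic)
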