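"""LOH / allelic-imbalance calling.

Control positions passing the raw candidate rule (two bases each covered
>= 5) are tested for compatibility with perfect heterozygosity using an
exact two-sided binomial goodness-of-fit of the top-allele count against
proportion 0.5.  Accepted positions are re-tested in the case; positions
whose case allele counts reject heterozygosity are categorized by the
median-normalized case/control coverage fold at the position:

    fold <= 0.75          putative copy-number loss
    0.75 < fold <= 1.25   copy-neutral LOH
    1.25 < fold <= 1.75   +1 copy gain
    fold  > 1.75          +2-or-more copy gain
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .coverage import ExomeStats

__all__ = [
    "LOHParams",
    "SmoothingParams",
    "AICall",
    "CATEGORIES",
    "het_binomial_p",
    "call_control_het",
    "classify_fold",
    "call_case_status",
    "smooth_calls",
    "call_ai",
]

CATEGORIES = ("conserved_het", "copy_loss", "copy_neutral_loh",
              "gain_1", "gain_2plus")

LOSS_FOLD_MAX = 0.75
NEUTRAL_FOLD_MAX = 1.25
GAIN1_FOLD_MAX = 1.75


@dataclass(frozen=True)
class LOHParams:
    """Significance levels for the two goodness-of-fit tests and the
    allelic-ratio guard band.

    A case rejection whose allelic ratio still lies inside
    ``conserved_band`` is kept conserved: at very high depth the exact test
    rejects biologically meaningless deviations from exactly 50:50.
    """

    control_alpha: float = 0.01
    case_alpha: float = 0.01
    conserved_band: Tuple[float, float] = (0.4, 0.6)

    def __post_init__(self):
        for a in (self.control_alpha, self.case_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError(f"alpha must be in (0,1), got {a}")


@dataclass(frozen=True)
class SmoothingParams:
    """Modal sliding-window smoothing of the per-position categories."""

    enabled: bool = False
    window_size: int = 5

    def __post_init__(self):
        if self.enabled and (self.window_size < 3
                             or self.window_size % 2 == 0):
            raise ValueError("window_size must be odd and >= 3 when "
                             "smoothing is enabled")


@dataclass
class AICall:
    """Allelic status of one control-heterozygous position."""

    chrom: str
    pos: int
    control_a1: Tuple[str, int]
    control_a2: Tuple[str, int]
    case_a1: Tuple[str, int]
    case_a2: Tuple[str, int]
    control_p: float
    case_p: float
    case_allelic_ratio: float
    fold: float
    category: str
    smoothed_category: Optional[str] = None
    flags: Tuple[str, ...] = ()


def het_binomial_p(k1: int, k2: int) -> float:
    """Exact two-sided binomial p of counts (k1, k2) under proportion 0.5."""
    n = k1 + k2
    if n == 0:
        return 1.0
    return float(binomtest(k1, n, 0.5).pvalue)


def call_control_het(control_a1: Tuple[str, int], control_a2: Tuple[str, int],
                     alpha: float = 0.01) -> Tuple[bool, float]:
    """Accept a candidate as bona fide heterozygous iff the exact binomial
    goodness-of-fit p of its top-two counts vs 0.5 is >= alpha."""
    p = het_binomial_p(control_a1[1], control_a2[1])
    return p >= alpha, p


def classify_fold(fold: float) -> str:
    """Fixed-threshold categorization of a non-conserved position."""
    if fold <= LOSS_FOLD_MAX:
        return "copy_loss"
    if fold <= NEUTRAL_FOLD_MAX:
        return "copy_neutral_loh"
    if fold <= GAIN1_FOLD_MAX:
        return "gain_1"
    return "gain_2plus"


def call_case_status(chrom: str, pos: int,
                     control_a1: Tuple[str, int], control_a2: Tuple[str, int],
                     case_a1: Tuple[str, int], case_a2: Tuple[str, int],
                     control_p: float,
                     case_stats: ExomeStats, control_stats: ExomeStats,
                     params: LOHParams = LOHParams()) -> AICall:
    """Test conservation of heterozygosity in the case and categorize.

    The case's own two most frequent bases are tested; if its pair differs
    from the control's the position is flagged ``discordant_alleles``
    (possible somatic variant) and excluded from smoothing downstream.
    """
    flags: List[str] = []
    k1, k2 = case_a1[1], case_a2[1]
    total_case = k1 + k2
    total_control = control_a1[1] + control_a2[1]
    case_p = het_binomial_p(k1, k2)
    ratio = k1 / total_case if total_case else 0.0

    if {case_a1[0], case_a2[0]} - {"N"} and \
            {case_a1[0], case_a2[0]} - {"N"} != \
            {control_a1[0], control_a2[0]} - {"N"}:
        flags.append("discordant_alleles")

    fold = 0.0
    if total_control > 0 and case_stats.median_cov > 0 \
            and control_stats.median_cov > 0:
        fold = (total_case / case_stats.median_cov) \
            / (total_control / control_stats.median_cov)

    if total_case == 0:
        flags.append("low_confidence")
        category = "copy_loss"
        fold = 0.0
    elif case_p >= params.case_alpha:
        category = "conserved_het"
    elif params.conserved_band[0] <= ratio <= params.conserved_band[1]:
        # huge-depth guard: statistically non-50:50 but biologically het
        category = "conserved_het"
        flags.append("band_conserved")
    else:
        category = classify_fold(fold)

    return AICall(chrom, pos, control_a1, control_a2, case_a1, case_a2,
                  control_p, case_p, ratio, fold, category,
                  flags=tuple(flags))


def smooth_calls(calls: Sequence[AICall],
                 params: SmoothingParams) -> List[AICall]:
    """Replace each category by the modal category of its centred window.

    Windows are truncated at chromosome ends; positions flagged as
    allele-discordant keep their raw category and do not vote.  The raw
    category is retained in ``category``; the smoothed one in
    ``smoothed_category``.
    """
    calls = list(calls)
    if not params.enabled:
        for c in calls:
            c.smoothed_category = c.category
        return calls
    half = params.window_size // 2
    by_chrom: dict = {}
    for i, c in enumerate(calls):
        by_chrom.setdefault(c.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: calls[i].pos)
        voters = [i for i in idxs
                  if "discordant_alleles" not in calls[i].flags]
        for rank, i in enumerate(idxs):
            if "discordant_alleles" in calls[i].flags:
                calls[i].smoothed_category = calls[i].category
                continue
            vrank = voters.index(i)
            window = voters[max(0, vrank - half):vrank + half + 1]
            votes = Counter(calls[j].category for j in window)
            top = votes.most_common()
            best = max(c for c, n in top if n == top[0][1])
            # deterministic tie-break: highest lexicographic category,
            # preferring the centre's own category when tied
            if votes[calls[i].category] == top[0][1]:
                best = calls[i].category
            calls[i].smoothed_category = best
    return calls


def call_ai(het_table: pd.DataFrame, case_stats: ExomeStats,
            control_stats: ExomeStats,
            params: LOHParams = LOHParams(),
            smoothing: SmoothingParams = SmoothingParams()) -> List[AICall]:
    """Full LOH/AI pipeline over a paired het-candidate table.

    The table uses the intermediate schema written by the preprocessing
    stage (control/case top-two alleles and counts per position).  Only
    positions accepted as control-heterozygous yield calls.
    """
    calls: List[AICall] = []
    for row in het_table.itertuples(index=False):
        ok, control_p = call_control_het(
            (row.control_a1, row.control_c1), (row.control_a2, row.control_c2),
            params.control_alpha)
        if not ok:
            continue
        calls.append(call_case_status(
            row.chrom, int(row.pos),
            (row.control_a1, int(row.control_c1)),
            (row.control_a2, int(row.control_c2)),
            (row.case_a1, int(row.case_c1)),
            (row.case_a2, int(row.case_c2)),
            control_p, case_stats, control_stats, params))
    return smooth_calls(calls, smoothing)
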