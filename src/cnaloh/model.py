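"""Model/Results interface tying the pipeline together.

:class:`PairedExome` holds the preprocessed data of one case/control pair
(per-exon coverages, paired het candidates, exome statistics); ``fit()``
runs normalization, CNA segmentation and LOH/AI calling and returns a
:class:`PairedExomeResults` carrying the paired table, the segments, the
allelic calls and a text summary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import cna, coverage, io_formats, loh
from .cna import CNAParams, CNASegment
from .coverage import ExomeStats
from .loh import AICall, LOHParams, SmoothingParams

__all__ = ["PairedExome", "PairedExomeResults"]


class PairedExome:
    """Preprocessed case/control pair ready for (re-)calling.

    Construct with :meth:`from_tables` (in-memory per-exon coverage tables,
    e.g. from the simulator), :meth:`from_intermediates` (the TSV
    intermediates written by a previous preprocessing run) or
    :meth:`from_alignments` (raw pileup/SAM/BAM input; the slow path).
    """

    def __init__(self, paired_table: pd.DataFrame, het_table: pd.DataFrame,
                 case_stats: ExomeStats, control_stats: ExomeStats):
        self.paired_table = paired_table
        self.het_table = het_table
        self.case_stats = case_stats
        self.control_stats = control_stats

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tables(cls, case_table: pd.DataFrame,
                    control_table: pd.DataFrame,
                    het_table: Optional[pd.DataFrame] = None
                    ) -> "PairedExome":
        """Build from per-exon coverage tables in the intermediate schema."""
        merged = case_table.merge(
            control_table, on=["exon_label", "chrom", "start", "end"],
            suffixes=("_case", "_control"), validate="one_to_one")
        paired = pd.DataFrame({
            "exon_label": merged["exon_label"],
            "chrom": merged["chrom"].astype(str),
            "start": merged["start"],
            "end": merged["end"],
            "case_cov": merged["mean_cov_case"],
            "case_sd": merged["cov_sd_case"],
            "control_cov": merged["mean_cov_control"],
            "control_sd": merged["cov_sd_control"],
        })
        paired = paired.sort_values(["chrom", "start"],
                                    kind="mergesort").reset_index(drop=True)
        case_stats = ExomeStats(float(np.median(paired["case_cov"])),
                                float(paired["case_cov"].mean()))
        control_stats = ExomeStats(float(np.median(paired["control_cov"])),
                                   float(paired["control_cov"].mean()))
        if het_table is None:
            het_table = pd.DataFrame(columns=[
                "chrom", "pos", "control_a1", "control_c1", "control_a2",
                "control_c2", "case_a1", "case_c1", "case_a2", "case_c2",
                "flags"])
        return cls(paired, het_table, case_stats, control_stats)

    @classmethod
    def from_intermediates(cls, directory) -> "PairedExome":
        """Load the intermediates written by a preprocessing run."""
        def _need(name):
            path = os.path.join(directory, name)
            if not os.path.exists(path):
                raise FileNotFoundError(
                    f"missing intermediate file {path}; run the preprocess "
                    "stage first")
            return path

        case = coverage.read_exon_coverage(_need("case_exons.tsv"))
        control = coverage.read_exon_coverage(_need("control_exons.tsv"))
        het_path = os.path.join(directory, "het_candidates.tsv")
        het = coverage.read_het_table(het_path) if os.path.exists(het_path) \
            else None
        return cls.from_tables(case, control, het)

    @classmethod
    def from_alignments(cls, case_path, control_path, exon_db_path,
                        case_format: str = "pileup",
                        control_format: str = "pileup",
                        policy: Optional[io_formats.ReadQualityPolicy] = None
                        ) -> "PairedExome":
        """Preprocess raw alignment/pileup input (the static stage)."""
        exons = io_formats.read_exon_db(exon_db_path)

        def _positions(path, fmt):
            if fmt == "pileup":
                return list(io_formats.stream_pileup(path, policy))
            return list(io_formats.stream_alignments(path, fmt, policy,
                                                     exons))

        case_pos = _positions(case_path, case_format)
        control_pos = _positions(control_path, control_format)
        case_covs = coverage.summarize_exons(case_pos, exons)
        control_covs = coverage.summarize_exons(control_pos, exons)
        candidates = coverage.collect_het_candidates(control_pos)
        het = coverage.pair_case_counts(candidates, case_pos)

        def _table(covs):
            return pd.DataFrame(
                [(c.exon.exon_label, c.exon.chrom, c.exon.start, c.exon.end,
                  c.mean_cov, c.cov_sd) for c in covs],
                columns=["exon_label", "chrom", "start", "end", "mean_cov",
                         "cov_sd"])

        return cls.from_tables(_table(case_covs), _table(control_covs), het)

    # -- persistence of the preprocessing contract --------------------------

    def write_intermediates(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for sample in ("case", "control"):
            df = pd.DataFrame({
                "exon_label": self.paired_table["exon_label"],
                "chrom": self.paired_table["chrom"],
                "start": self.paired_table["start"],
                "end": self.paired_table["end"],
                "mean_cov": self.paired_table[f"{sample}_cov"],
                "cov_sd": self.paired_table[f"{sample}_sd"],
            })
            df.to_csv(os.path.join(directory, f"{sample}_exons.tsv"),
                      sep="\t", index=False)
        coverage.write_het_table(
            self.het_table, os.path.join(directory, "het_candidates.tsv"))
        coverage.write_stats(self.case_stats,
                             os.path.join(directory, "case_stats.tsv"))
        coverage.write_stats(self.control_stats,
                             os.path.join(directory, "control_stats.tsv"))

    def coverage_report(self) -> dict:
        covs_case = [coverage.ExonCoverage(
            io_formats.ExonRecord(r.chrom, int(r.start), int(r.end),
                                  exon_label=r.exon_label),
            float(r.case_cov), float(r.case_sd), int(r.end - r.start))
            for r in self.paired_table.itertuples(index=False)]
        covs_control = [coverage.ExonCoverage(
            io_formats.ExonRecord(r.chrom, int(r.start), int(r.end),
                                  exon_label=r.exon_label),
            float(r.control_cov), float(r.control_sd),
            int(r.end - r.start))
            for r in self.paired_table.itertuples(index=False)]
        return coverage.coverage_report(self.case_stats, self.control_stats,
                                        covs_case, covs_control)

    # -- fitting -------------------------------------------------------------

    def fit(self, cna_params: Optional[CNAParams] = None,
            loh_params: Optional[LOHParams] = None,
            smoothing: Optional[SmoothingParams] = None
            ) -> "PairedExomeResults":
        """Run the real-time stage: normalize, segment, call LOH/AI."""
        cna_params = cna_params or CNAParams()
        loh_params = loh_params or LOHParams()
        smoothing = smoothing or SmoothingParams()

        paired = cna.normalize(self.paired_table,
                               self.case_stats.median_cov,
                               self.control_stats.median_cov, cna_params)
        paired = cna.apply_exon_filters(paired, cna_params)
        segments = cna.call_cnas(paired, cna_params)
        ai_calls = loh.call_ai(self.het_table, self.case_stats,
                               self.control_stats, loh_params, smoothing)
        return PairedExomeResults(self, paired, segments, ai_calls,
                                  cna_params, loh_params, smoothing)


@dataclass
class PairedExomeResults:
    """Fitted results: paired table with ratios, segments and AI calls."""

    model: PairedExome
    paired_table: pd.DataFrame
    segments: List[CNASegment]
    ai_calls: List[AICall]
    cna_params: CNAParams
    loh_params: LOHParams
    smoothing: SmoothingParams

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, s.start, s.end, s.n_exons, s.direction, s.p_value,
              s.mean_log2) for s in self.segments],
            columns=["chrom", "start", "end", "n_exons", "direction",
                     "p_value", "mean_log2"])

    def summary(self) -> str:
        n_gain = sum(1 for s in self.segments if s.direction == "gain")
        n_loss = len(self.segments) - n_gain
        cats = pd.Series([c.category for c in self.ai_calls])
        lines = [
            "Paired-exome CNA / LOH-AI analysis",
            "=" * 42,
            f"exons analysed          "
            f"{int((~self.paired_table['excluded']).sum())}"
            f" / {len(self.paired_table)}",
            f"case median coverage    {self.model.case_stats.median_cov:.1f}",
            f"control median coverage "
            f"{self.model.control_stats.median_cov:.1f}",
            f"CNA preset              {self.cna_params.preset} "
            f"(window {self.cna_params.window_size}, "
            f"p<{self.cna_params.p_threshold:g})",
            f"CNA segments            {len(self.segments)} "
            f"({n_gain} gain / {n_loss} loss)",
            f"het positions called    {len(self.ai_calls)}",
        ]
        for cat in loh.CATEGORIES:
            n = int((cats == cat).sum()) if len(cats) else 0
            lines.append(f"  {cat:<22}{n}")
        for s in self.segments:
            lines.append(
                f"  {s.chrom}:{s.start}-{s.end}  {s.direction:<5} "
                f"n={s.n_exons:<6} mean_log2={s.mean_log2:+.3f} "
                f"p={s.p_value:.3g}")
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        return io_formats.write_results(
            self.segments, self.ai_calls, self.paired_table, out_dir,
            run_summary={
                "preset": self.cna_params.preset,
                "p_threshold": self.cna_params.p_threshold,
                "window_size": self.cna_params.window_size,
                "ccf": self.cna_params.ccf,
                "coverage_floor": self.cna_params.coverage_floor,
                "sdf": self.cna_params.sdf,
                "control_alpha": self.loh_params.control_alpha,
                "case_alpha": self.loh_params.case_alpha,
            })

    def to_circos(self, out_dir, chrom_prefix: str = "hs") -> dict:
        return io_formats.export_circos(self.segments, self.paired_table,
                                        out_dir, chrom_prefix)

    def plot_genome(self, path=None):
        from .plotting import plot_genome
        return plot_genome(self, path)

    def plot_chromosome(self, chrom: str, path=None):
        from .plotting import plot_chromosome
        return plot_chromosome(self, chrom, path)
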