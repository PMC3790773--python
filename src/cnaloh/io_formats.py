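"""Input dialects and tabular/Circos output.

Reads the three supported alignment/pileup dialects (samtools pileup, SAM,
BAM) plus the BED-like exon annotation database, and writes the analysis
result tables and the Circos bundle.

Coordinate conventions: the exon database is 0-based half-open (BED);
pileup positions are 1-based.  The conversion happens exactly once, at
ingestion: every :class:`PileupPosition` carries the 1-based coordinate of
its dialect, and exon membership tests subtract 1.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

__all__ = [
    "ExonRecord",
    "PileupPosition",
    "ReadQualityPolicy",
    "ParseError",
    "read_exon_db",
    "stream_pileup",
    "stream_alignments",
    "write_results",
    "export_circos",
    "normalize_chrom",
]


class ParseError(ValueError):
    """Malformed input line; carries the offending line number."""


@dataclass(frozen=True, order=True)
class ExonRecord:
    """One annotated exon: the unit of coverage quantification.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    """

    chrom: str
    start: int
    end: int
    gene: str = ""
    exon_label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.exon_label or self.gene}: start {self.start} "
                f">= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PileupPosition:
    """Per-position base counts (1-based coordinate, pileup convention)."""

    chrom: str
    pos: int
    base_counts: Dict[str, int]
    total_depth: int

    @property
    def counted(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class ReadQualityPolicy:
    """Phred-based quality filters.

    ``mean_read_quality_min`` and ``max_low_quality_bases`` apply to whole
    reads (SAM/BAM only); ``base_quality_min`` excludes individual base calls
    in both the read-centred and the pileup path.
    """

    mean_read_quality_min: Optional[float] = None
    base_quality_min: Optional[int] = None
    max_low_quality_bases: Optional[int] = None

    def __post_init__(self):
        for name in ("mean_read_quality_min", "base_quality_min",
                     "max_low_quality_bases"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


def normalize_chrom(chrom: str, like: str) -> str:
    """Rename ``chrom`` to the 'chr'-prefix convention of ``like``."""
    has = chrom.startswith("chr")
    want = like.startswith("chr")
    if has and not want:
        return chrom[3:]
    if want and not has:
        return "chr" + chrom
    return chrom


# ---------------------------------------------------------------------------
# exon database


def read_exon_db(path) -> List[ExonRecord]:
    """Read a tab-separated exon database (chrom, start, end, name[, ...]).

    The 4th column is parsed as ``GENE_label`` when it contains an
    underscore, otherwise it doubles as both gene and label.  Records are
    validated, sorted by (chrom, start) and duplicate labels rejected.
    """
    records: List[ExonRecord] = []
    seen: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            chrom, s, e, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            gene = name.rsplit("_", 1)[0] if "_" in name else name
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate exon label "
                                 f"{name!r}")
            seen.add(name)
            records.append(ExonRecord(chrom, start, end, gene, name))
    if not records:
        logger.warning("exon database %s is empty", path)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


# ---------------------------------------------------------------------------
# pileup dialect


def _decode_read_bases(bases: str, quals: str, ref: str,
                       base_quality_min: Optional[int], lineno: int):
    """Decode a samtools pileup read-bases string into base counts.

    Returns (counts, counted, excluded_low_qual, ignored_symbols) where the
    three tallies partition the declared depth.
    """
    counts = {b: 0 for b in BASES}
    excluded = 0
    ignored = 0
    qi = 0  # index into the quality string: one entry per read base
    i = 0
    n = len(bases)
    ref = ref.upper()
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # read start + mapping-quality char, no base consumed
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            try:
                run = int(bases[i + 1:j])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: malformed indel run at col {i}"
                ) from exc
            i = j + run
            continue
        # a real base call consumes one quality character
        if qi >= len(quals):
            raise ParseError(
                f"line {lineno}: more base calls than quality characters"
            )
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in ".,":
            call = ref
        elif c.upper() in BASES:
            call = c.upper()
        elif c in "*<>nN":
            ignored += 1
            continue
        else:
            raise ParseError(
                f"line {lineno}: unknown pileup symbol {c!r}"
            )
        if base_quality_min is not None and q < base_quality_min:
            excluded += 1
            continue
        if call in counts:
            counts[call] += 1
        else:
            ignored += 1
    counts = {b: c for b, c in counts.items() if c > 0}
    return counts, excluded, ignored


def stream_pileup(path, policy: Optional[ReadQualityPolicy] = None
                  ) -> Iterator[PileupPosition]:
    """Stream a classic samtools pileup file as :class:`PileupPosition`.

    Read-bases strings are decoded ('.'/',' reference matches, letters
    substitutions, '^X'/'$' and '+N'/'-N' runs consumed and ignored); base
    calls with Phred quality below ``policy.base_quality_min`` are excluded
    from the counts.  Positions absent from the file have depth 0.
    """
    policy = policy or ReadQualityPolicy()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 pileup columns, got "
                    f"{len(parts)}"
                )
            chrom, pos_s, ref, depth_s, bases, quals = parts[:6]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position/depth"
                                 ) from exc
            counts, excl, ign = _decode_read_bases(
                bases, quals, ref, policy.base_quality_min, lineno)
            counted = sum(counts.values())
            if counted + excl + ign != depth:
                raise ParseError(
                    f"{path}:{lineno}: decoded {counted + excl + ign} calls "
                    f"but declared depth is {depth}"
                )
            yield PileupPosition(chrom, pos, counts, depth)


# ---------------------------------------------------------------------------
# SAM/BAM


def _read_passes(read, policy: ReadQualityPolicy) -> bool:
    quals = read.query_qualities
    if policy.mean_read_quality_min is not None:
        if quals is None or len(quals) == 0:
            return False
        if float(np.mean(quals)) < policy.mean_read_quality_min:
            return False
    if (policy.max_low_quality_bases is not None
            and policy.base_quality_min is not None and quals is not None):
        low = int(np.sum(np.asarray(quals) < policy.base_quality_min))
        if low > policy.max_low_quality_bases:
            return False
    return True


def stream_alignments(path, fmt: str, policy: Optional[ReadQualityPolicy],
                      exons: Sequence[ExonRecord]
                      ) -> Iterator[PileupPosition]:
    """Pile up SAM/BAM reads into per-position base counts on exonic space.

    Reads failing the whole-read quality filters contribute nothing;
    surviving reads are converted to per-position counts restricted to the
    exon database.  Unmapped and secondary reads are skipped silently.
    """
    import pysam

    policy = policy or ReadQualityPolicy()
    fmt = fmt.upper()
    if fmt not in ("SAM", "BAM"):
        raise ValueError(f"format must be SAM or BAM, got {fmt!r}")

    if not exons:
        return
    exon_chrom_like = exons[0].chrom
    # exonic mask per chromosome (set of 0-based positions; fixtures are small)
    exonic: Dict[str, set] = {}
    for ex in exons:
        exonic.setdefault(ex.chrom, set()).update(range(ex.start, ex.end))

    counts: Dict[str, Dict[int, Dict[str, int]]] = {}
    mode = "rb" if fmt == "BAM" else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not _read_passes(read, policy):
                continue
            chrom = normalize_chrom(read.reference_name, exon_chrom_like)
            if chrom not in exonic:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            chrom_counts = counts.setdefault(chrom, {})
            chrom_exonic = exonic[chrom]
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos not in chrom_exonic:
                    continue
                base = seq[qpos].upper()
                if base not in BASES:
                    continue
                if (policy.base_quality_min is not None and quals is not None
                        and quals[qpos] < policy.base_quality_min):
                    continue
                pos_counts = chrom_counts.setdefault(rpos, {})
                pos_counts[base] = pos_counts.get(base, 0) + 1

    for chrom in sorted(counts):
        for rpos in sorted(counts[chrom]):
            bc = counts[chrom][rpos]
            yield PileupPosition(chrom, rpos + 1, bc, sum(bc.values()))


# ---------------------------------------------------------------------------
# result tables


_SEGMENT_COLUMNS = ["chrom", "start", "end", "n_exons", "direction",
                    "p_value", "mean_log2", "first_exon", "last_exon"]

_AI_COLUMNS = ["chrom", "pos", "control_a1", "control_c1", "control_a2",
               "control_c2", "case_a1", "case_c1", "case_a2", "case_c2",
               "control_p", "case_p", "case_allelic_ratio", "fold",
               "category", "smoothed_category", "flags"]


def _fmt_float(x) -> str:
    return repr(float(x))


def write_results(segments, ai_calls, paired_table: pd.DataFrame,
                  out_dir, run_summary: Optional[dict] = None) -> Dict[str, str]:
    """Write the per-exon table, CNA segments, AI calls and run summary.

    All four files are TSV with fixed, documented column orders; numeric
    fields use ``repr`` so a re-run on identical input is byte-identical and
    re-reading reproduces every value exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    seg_path = os.path.join(out_dir, "cna_segments.tsv")
    with open(seg_path, "w") as fh:
        fh.write("\t".join(_SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write("\t".join([
                s.chrom, str(s.start), str(s.end), str(s.n_exons),
                s.direction, _fmt_float(s.p_value), _fmt_float(s.mean_log2),
                str(s.first_exon), str(s.last_exon)]) + "\n")
    paths["segments"] = seg_path

    ai_path = os.path.join(out_dir, "ai_calls.tsv")
    with open(ai_path, "w") as fh:
        fh.write("\t".join(_AI_COLUMNS) + "\n")
        for c in ai_calls:
            fh.write("\t".join([
                c.chrom, str(c.pos),
                c.control_a1[0], str(c.control_a1[1]),
                c.control_a2[0], str(c.control_a2[1]),
                c.case_a1[0], str(c.case_a1[1]),
                c.case_a2[0], str(c.case_a2[1]),
                _fmt_float(c.control_p), _fmt_float(c.case_p),
                _fmt_float(c.case_allelic_ratio), _fmt_float(c.fold),
                c.category, c.smoothed_category or c.category,
                ",".join(c.flags) if c.flags else "."]) + "\n")
    paths["ai_calls"] = ai_path

    exon_path = os.path.join(out_dir, "paired_exons.tsv")
    paired_table.to_csv(exon_path, sep="\t", index=False,
                        float_format=None)
    paths["paired_exons"] = exon_path

    summary_path = os.path.join(out_dir, "run_summary.tsv")
    with open(summary_path, "w") as fh:
        fh.write("key\tvalue\n")
        items = dict(run_summary or {})
        items.setdefault("n_segments", len(list(segments)))
        items.setdefault("n_ai_calls", len(list(ai_calls)))
        for k in sorted(items):
            fh.write(f"{k}\t{items[k]}\n")
    paths["summary"] = summary_path
    return paths


_CIRCOS_CONF = """\
# auto-generated Circos configuration
karyotype = data/karyotype/karyotype.human.txt
chromosomes_units = 1000000

<ideogram>
<spacing>
default = 0.002r
</spacing>
radius    = 0.90r
thickness = 30p
fill      = yes
show_label = yes
label_radius = 1.05r
label_size = 30
</ideogram>

<plots>
<plot>
type = scatter
file = {data_file}
r0   = 0.60r
r1   = 0.95r
min  = -2
max  = 2
glyph = circle
glyph_size = 4
<axes>
<axis>
position = 0
color = lgrey
thickness = 2
</axis>
</axes>
</plot>

# Optional mutation track: uncomment and point `file` at a Circos-formatted
# list of point mutations / small indels to overlay them on the coverage ring.
#<plot>
#type = scatter
#file = mutations.txt
#r0   = 0.50r
#r1   = 0.58r
#glyph = triangle
#glyph_size = 8
#</plot>
</plots>

<image>
<<include etc/image.conf>>
</image>
<<include etc/colors_fonts_patterns.conf>>
<<include etc/housekeeping.conf>>
"""


def export_circos(segments, paired_table: pd.DataFrame, out_dir,
                  chrom_prefix: str = "hs") -> Dict[str, str]:
    """Write per-exon log2 ratios as a Circos 2D track plus a ready config.

    Chromosome labels follow the Circos human convention (``hs`` prefix by
    default); the configuration references the data file by relative path
    and contains one commented-out block for an optional mutation track.
    """
    os.makedirs(out_dir, exist_ok=True)
    data_name = "log2_ratio.circos.txt"
    data_path = os.path.join(out_dir, data_name)
    with open(data_path, "w") as fh:
        if len(paired_table):
            keep = paired_table[~paired_table["excluded"]]
            for row in keep.itertuples(index=False):
                label = chrom_prefix + str(row.chrom).removeprefix("chr")
                fh.write(f"{label} {row.start} {row.end} "
                         f"{row.log2_ratio:g}\n")
    conf_path = os.path.join(out_dir, "circos.conf")
    with open(conf_path, "w") as fh:
        fh.write(_CIRCOS_CONF.format(data_file=data_name))
    return {"data": data_path, "conf": conf_path}
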