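"""GC-normalized telomere content estimation from WGS alignments.

Telomeric reads are recognized by counting non-overlapping ("nonconsecutive")
instances of the four most common telomeric hexamer repeats — TTAGGG (t-type),
TCAGGG (c-type), TGAGGG (g-type) and TTGGGG (j-type) — on either strand. A read
qualifies as telomeric when it carries at least six such repeats per 100 bases
and is either unmapped or aligned with very low confidence (mapping quality
below 8). The telomere content of a sample is the number of telomeric reads
per million reads whose GC content lies in the 48-52% bin, which controls for
library GC bias between tumor and matched control. Tumor/control comparison is
expressed as log2(tumor content / control content).

TERRA (telomeric repeat-containing RNA) abundance is counted from RNA-seq
alignments with a read-length-dependent repeat threshold.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator

import pysam

__all__ = [
    "RepeatPatternSet",
    "TelomereContentResult",
    "ContentRatio",
    "ShortReadError",
    "SimRead",
    "reverse_complement",
    "count_repeat_instances",
    "classify_telomeric_read",
    "compute_telomere_content",
    "content_log2_ratio",
    "terra_repeat_threshold",
    "count_terra_reads",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Minimum usable read length; shorter reads are rejected outright.
MIN_READ_LENGTH = 30

#: Mapping-quality ceiling below which an aligned read still counts as telomeric.
DEFAULT_MAPQ_MAX = 8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ShortReadError(ValueError):
    """Raised for reads shorter than the minimum supported length (30 bp)."""


@dataclass(frozen=True)
class RepeatPatternSet:
    """The telomeric hexamer repertoire used for read classification.

    ``g_strand_patterns`` are the repeats as they appear on the G-rich strand;
    ``c_strand_patterns`` are their reverse complements and are derived, never
    set independently.
    """

    g_strand_patterns: tuple[str, ...] = ("TTAGGG", "TCAGGG", "TGAGGG", "TTGGGG")

    def __post_init__(self) -> None:
        for p in self.g_strand_patterns:
            if len(p) != 6:
                raise ValueError(f"telomere repeat patterns must be hexamers, got {p!r}")

    @property
    def c_strand_patterns(self) -> tuple[str, ...]:
        return tuple(reverse_complement(p) for p in self.g_strand_patterns)

    def regex(self, strand: str) -> re.Pattern:
        if strand == "G":
            pats = self.g_strand_patterns
        elif strand == "C":
            pats = self.c_strand_patterns
        else:
            raise ValueError(f"strand must be 'G' or 'C', got {strand!r}")
        return re.compile("|".join(pats))


@dataclass(frozen=True)
class TelomereContentResult:
    """Telomere content of one sample: telomeric reads per million GC-bin reads."""

    sample_id: str
    n_telomeric_reads: int
    n_gc_bin_reads: int

    def __post_init__(self) -> None:
        if self.n_gc_bin_reads <= 0:
            raise ValueError("telomere content undefined with zero GC-bin reads")

    @property
    def content(self) -> float:
        return self.n_telomeric_reads / self.n_gc_bin_reads * 1e6


@dataclass(frozen=True)
class ContentRatio:
    tumor_content: float
    control_content: float

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.tumor_content / self.control_content)


@dataclass(frozen=True)
class SimRead:
    """Lightweight alignment record for in-memory streams.

    Mirrors the fields of a SAM record that the read-level operations consume,
    so large simulations can bypass file I/O.
    """

    sequence: str
    mapping_quality: int = 0
    is_unmapped: bool = True
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    qualities: tuple[int, ...] | None = None


def _greedy_count(seq: str, pattern: re.Pattern) -> int:
    # Non-overlapping left-to-right regex scanning is exactly the greedy rule:
    # advance 6 bases on a match, 1 base otherwise.
    return len(pattern.findall(seq))


def count_repeat_instances(
    sequence: str,
    patterns: RepeatPatternSet | None = None,
    strand: str = "G",
) -> int:
    """Count non-overlapping telomere-repeat instances on one strand.

    The scan proceeds left to right, advancing six bases after a match and one
    base otherwise; matched instances need not be adjacent.
    """
    if not sequence:
        raise ValueError("empty sequence")
    patterns = patterns or RepeatPatternSet()
    return _greedy_count(sequence, patterns.regex(strand))


def repeat_threshold(read_length: int, per_100bp: float = 6, scale: bool = True) -> int:
    """Repeat-count threshold for a read: floor(per_100bp * L / 100) if scaled,
    else the flat per-100bp value (the behavior for 100-bp libraries either way)."""
    if scale:
        return math.floor(per_100bp * read_length / 100)
    return math.floor(per_100bp)


def classify_telomeric_read(
    read,
    patterns: RepeatPatternSet | None = None,
    threshold_per_100bp: float = 6,
    mapq_max: int = DEFAULT_MAPQ_MAX,
    scale_threshold: bool = True,
) -> bool:
    """Decide whether a read is telomeric.

    True iff max(G-strand count, C-strand count) meets the per-length repeat
    threshold AND the read is unmapped or mapped with quality < ``mapq_max``.

    Raises
    ------
    ShortReadError
        for reads shorter than 30 bp, which are outside the method's domain.
    """
    patterns = patterns or RepeatPatternSet()
    seq = read.sequence if hasattr(read, "sequence") else read.query_sequence
    if seq is None or len(seq) < MIN_READ_LENGTH:
        raise ShortReadError(f"read shorter than {MIN_READ_LENGTH} bp")
    seq = seq.upper()
    if not (read.is_unmapped or read.mapping_quality < mapq_max):
        return False
    thr = repeat_threshold(len(seq), threshold_per_100bp, scale_threshold)
    g = _greedy_count(seq, patterns.regex("G"))
    if g >= thr:
        return True
    c = _greedy_count(seq, patterns.regex("C"))
    return c >= thr


def gc_fraction(seq: str) -> float | None:
    """G+C fraction over non-N bases; None if the read is all N."""
    n_at = seq.count("A") + seq.count("T")
    n_gc = seq.count("G") + seq.count("C")
    denom = n_at + n_gc
    if denom == 0:
        return None
    return n_gc / denom


def _iter_alignment(alignment) -> Iterator:
    if isinstance(alignment, (str,)) or hasattr(alignment, "__fspath__"):
        with pysam.AlignmentFile(str(alignment), "r", check_sq=False) as fh:
            yield from fh
    elif isinstance(alignment, pysam.AlignmentFile):
        yield from alignment
    else:
        yield from alignment


def compute_telomere_content(
    alignment,
    patterns: RepeatPatternSet | None = None,
    sample_id: str = "sample",
    threshold_per_100bp: float = 6,
    mapq_max: int = DEFAULT_MAPQ_MAX,
    gc_bin: tuple[float, float] = (0.48, 0.52),
    scale_threshold: bool = True,
) -> TelomereContentResult:
    """Estimate telomere content from a SAM file path, AlignmentFile, or
    iterable of reads.

    Secondary, supplementary, and duplicate-flagged records are skipped for
    both the telomeric-read numerator and the GC-bin denominator. The GC bin
    is inclusive on both boundaries; N bases do not enter the GC fraction.
    """
    patterns = patterns or RepeatPatternSet()
    g_re = patterns.regex("G")
    c_re = patterns.regex("C")
    lo, hi = gc_bin
    n_tel = 0
    n_gc = 0
    for read in _iter_alignment(alignment):
        if getattr(read, "is_secondary", False) or getattr(read, "is_supplementary", False):
            continue
        if getattr(read, "is_duplicate", False):
            continue
        seq = read.sequence if hasattr(read, "sequence") else read.query_sequence
        if seq is None or len(seq) < MIN_READ_LENGTH:
            raise ShortReadError(f"read shorter than {MIN_READ_LENGTH} bp in {sample_id}")
        seq = seq.upper()
        frac = gc_fraction(seq)
        if frac is not None and lo <= frac <= hi:
            n_gc += 1
        if read.is_unmapped or read.mapping_quality < mapq_max:
            thr = repeat_threshold(len(seq), threshold_per_100bp, scale_threshold)
            if _greedy_count(seq, g_re) >= thr or _greedy_count(seq, c_re) >= thr:
                n_tel += 1
    if n_gc == 0:
        raise ValueError(f"no reads in GC bin {gc_bin} for sample {sample_id}; content undefined")
    return TelomereContentResult(sample_id=sample_id, n_telomeric_reads=n_tel, n_gc_bin_reads=n_gc)


def content_log2_ratio(tumor: TelomereContentResult, control: TelomereContentResult) -> ContentRatio:
    """Tumor/control telomere content log2 ratio."""
    if control.content <= 0:
        raise ValueError("control telomere content is zero; ratio undefined")
    if tumor.content <= 0:
        raise ValueError("tumor telomere content is zero; ratio undefined")
    return ContentRatio(tumor_content=tumor.content, control_content=control.content)


# Read-length anchors for the TERRA repeat threshold k. Within a listed range
# the printed k applies; between ranges, k is linearly interpolated on the
# upper anchors and rounded down (overridable via the k argument).
TERRA_K_TABLE: tuple[tuple[int, int, int], ...] = (
    (45, 50, 7),
    (75, 76, 10),
    (99, 101, 14),
)


def terra_repeat_threshold(read_length: int) -> int:
    for lo, hi, k in TERRA_K_TABLE:
        if lo <= read_length <= hi:
            return k
    anchors = [(hi, k) for lo, hi, k in TERRA_K_TABLE]
    xs = [a[0] for a in anchors]
    ys = [a[1] for a in anchors]
    if read_length < xs[0] or read_length > xs[-1]:
        raise ValueError(
            f"read length {read_length} outside supported TERRA range; pass k explicitly"
        )
    for (x0, y0), (x1, y1) in zip(anchors, anchors[1:]):
        if x0 <= read_length <= x1:
            return math.floor(y0 + (y1 - y0) * (read_length - x0) / (x1 - x0))
    raise AssertionError("unreachable")


def count_terra_reads(
    alignment,
    read_length: int | None = None,
    k: int | None = None,
    patterns: RepeatPatternSet | None = None,
) -> float:
    """TERRA reads per million total RNA-seq reads.

    A read counts when it contains at least ``k`` non-overlapping instances of
    the four telomeric repeats on either strand; ``k`` defaults to the
    read-length table (7 for 45-50 bp, 10 for 75-76 bp, 14 for 99-101 bp).
    """
    if k is None:
        if read_length is None:
            raise ValueError("either read_length or an explicit k is required")
        k = terra_repeat_threshold(read_length)
    patterns = patterns or RepeatPatternSet()
    g_re = patterns.regex("G")
    c_re = patterns.regex("C")
    n_total = 0
    n_terra = 0
    for read in _iter_alignment(alignment):
        if getattr(read, "is_secondary", False) or getattr(read, "is_supplementary", False):
            continue
        if getattr(read, "is_duplicate", False):
            continue
        seq = read.sequence if hasattr(read, "sequence") else read.query_sequence
        if seq is None:
            continue
        seq = seq.upper()
        n_total += 1
        if _greedy_count(seq, g_re) >= k or _greedy_count(seq, c_re) >= k:
            n_terra += 1
    if n_total == 0:
        raise ValueError("no reads in RNA alignment")
    return n_terra / n_total * 1e6
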