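"""Somatic telomere-insertion detection from tumor/control read pairs.

An insertion of telomeric sequence into a non-telomeric genomic position
leaves two read-level footprints: discordant pairs whose one mate is a
telomeric read and whose other mate maps uniquely near the junction, and
split (soft-clipped) reads whose clip point marks the junction base and whose
clipped tail is telomeric. Candidate 1-kb regions require at least three
tumor discordant pairs and none in the matched control; exact junctions
require at least three split reads whose clipped segment contains a TTAGGG
repeat (or its reverse complement — junctions are normalized to the forward
strand). Regions recurrent in 15 or more unmatched control samples (a panel
of normals) are excluded as artifacts.

Called insertions are classified one-/two-sided (a partner in opposite
orientation with the same forward-strand repeat within the downstream 10 kb),
and annotated with the copy-number change across the nearest segment boundary
within 50 kb, structural variants within 10 kb, chromothripsis-region
overlap, and junction microhomology.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
import pysam

from .telomere_content import (
    RepeatPatternSet,
    classify_telomeric_read,
    reverse_complement,
)

__all__ = [
    "DiscordantTelomerePair",
    "SplitRead",
    "CandidateRegion",
    "TelomereInsertion",
    "scan_alignment",
    "collect_discordant_pairs",
    "call_candidate_regions",
    "refine_junction",
    "filter_control_panel",
    "classify_sidedness",
    "annotate_cn_change",
    "annotate_nearby_sv",
    "detect_microhomology",
    "call_insertions",
    "insertions_to_frame",
]

ANCHOR_MAPQ_MIN = 30  # anchors must be uniquely mapped: MAPQ strictly greater
CLUSTER_GAP = 1000
MIN_DISCORDANT = 3
MIN_SPLIT = 3
MIN_CLIP_LEN = 12
MIN_CLIP_PURITY = 0.80
PANEL_MIN_CONTROLS = 15
SIDEDNESS_WINDOW = 10_000
CN_ASSIGN_WINDOW = 50_000
CN_MIN_SEGMENT = 10_000
CN_COMPLEX_DIFF = 4
SV_WINDOW = 10_000


@dataclass(frozen=True)
class DiscordantTelomerePair:
    chrom: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str
    mate_sequence: str
    qname: str


@dataclass(frozen=True)
class SplitRead:
    chrom: str
    clip_pos: int  # 0-based reference coordinate of the clip point
    side: str  # "right": clip follows the aligned block; "left": precedes it
    clipped_seq: str
    mapping_quality: int


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    pairs: list[DiscordantTelomerePair]

    @property
    def n_tumor(self) -> int:
        return len(self.pairs)


@dataclass
class TelomereInsertion:
    chrom: str
    position: int
    orientation: str  # "telomere-left" | "telomere-right"
    repeat_strand: str  # "G" | "C" (forward-strand repeat after normalization)
    n_discordant: int
    n_split: int
    clipped_seq: str = ""
    sidedness: str = "one_sided"
    partner: int | None = None
    cn_change: str = "neutral"
    nearby_sv: bool = False
    in_chromothripsis: bool = False
    microhomology_length: int = -1  # -1: not annotated (no reference)
    microhomology_ambiguous: bool = False


def _iter_records(alignment):
    if isinstance(alignment, (str,)) or hasattr(alignment, "__fspath__"):
        with pysam.AlignmentFile(str(alignment), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from alignment


def scan_alignment(
    alignment,
    patterns: RepeatPatternSet | None = None,
    anchor_mapq_min: int = ANCHOR_MAPQ_MIN,
) -> tuple[list[DiscordantTelomerePair], list[SplitRead], dict]:
    """Single pass over an alignment collecting both insertion footprints.

    Returns discordant telomere pairs (exactly one telomeric mate, the other
    uniquely mapped with MAPQ > ``anchor_mapq_min``), soft-clipped reads with
    their clip points, and a QC dictionary counting skipped orphan reads.
    """
    patterns = patterns or RepeatPatternSet()
    mates: dict[str, list] = defaultdict(list)
    splits: list[SplitRead] = []
    for rec in _iter_records(alignment):
        if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        if not rec.is_unmapped and rec.cigartuples:
            cig = rec.cigartuples
            if cig[-1][0] == 4:  # trailing soft clip
                splits.append(
                    SplitRead(
                        chrom=rec.reference_name,
                        clip_pos=rec.reference_end,
                        side="right",
                        clipped_seq=rec.query_sequence[len(rec.query_sequence) - cig[-1][1] :].upper(),
                        mapping_quality=rec.mapping_quality,
                    )
                )
            if cig[0][0] == 4:  # leading soft clip
                splits.append(
                    SplitRead(
                        chrom=rec.reference_name,
                        clip_pos=rec.reference_start,
                        side="left",
                        clipped_seq=rec.query_sequence[: cig[0][1]].upper(),
                        mapping_quality=rec.mapping_quality,
                    )
                )
        if rec.is_paired:
            mates[rec.query_name].append(rec)
    pairs: list[DiscordantTelomerePair] = []
    n_orphans = 0
    for qname, recs in mates.items():
        if len(recs) != 2:
            n_orphans += 1
            continue
        a, b = recs
        tel = [classify_telomeric_read(r, patterns) for r in (a, b)]
        if sum(tel) != 1:
            continue
        tel_read, anchor = (a, b) if tel[0] else (b, a)
        if anchor.is_unmapped or anchor.mapping_quality <= anchor_mapq_min:
            continue
        pairs.append(
            DiscordantTelomerePair(
                chrom=anchor.reference_name,
                anchor_start=anchor.reference_start,
                anchor_end=anchor.reference_end,
                anchor_strand="-" if anchor.is_reverse else "+",
                mate_sequence=(tel_read.query_sequence or "").upper(),
                qname=qname,
            )
        )
    return pairs, splits, {"n_orphans": n_orphans}


def collect_discordant_pairs(
    tumor_alignment,
    control_alignment,
    patterns: RepeatPatternSet | None = None,
) -> tuple[list[DiscordantTelomerePair], list[DiscordantTelomerePair]]:
    """Discordant telomere pairs of a tumor/control pair (see scan_alignment)."""
    tumor_pairs, _, _ = scan_alignment(tumor_alignment, patterns)
    control_pairs, _, _ = scan_alignment(control_alignment, patterns)
    return tumor_pairs, control_pairs


def call_candidate_regions(
    tumor_pairs: list[DiscordantTelomerePair],
    control_pairs: list[DiscordantTelomerePair],
    min_support: int = MIN_DISCORDANT,
    max_gap: int = CLUSTER_GAP,
) -> list[CandidateRegion]:
    """Cluster tumor anchors into candidate regions.

    Anchors are merged by single-linkage with an inter-anchor gap of at most
    ``max_gap`` (1 kb); a cluster is a candidate iff it holds at least
    ``min_support`` tumor pairs and no control discordant pair overlaps its
    span (the somatic contract).
    """
    by_chrom: dict[str, list[DiscordantTelomerePair]] = defaultdict(list)
    for p in tumor_pairs:
        by_chrom[p.chrom].append(p)
    ctrl_by_chrom: dict[str, list[DiscordantTelomerePair]] = defaultdict(list)
    for p in control_pairs:
        ctrl_by_chrom[p.chrom].append(p)
    regions: list[CandidateRegion] = []
    for chrom, plist in sorted(by_chrom.items()):
        plist.sort(key=lambda p: p.anchor_start)
        cluster: list[DiscordantTelomerePair] = []
        for p in plist:
            if cluster and p.anchor_start - cluster[-1].anchor_start > max_gap:
                regions.extend(_close_cluster(chrom, cluster, ctrl_by_chrom[chrom], min_support))
                cluster = []
            cluster.append(p)
        if cluster:
            regions.extend(_close_cluster(chrom, cluster, ctrl_by_chrom[chrom], min_support))
    return regions


def _close_cluster(chrom, cluster, control_pairs, min_support):
    if len(cluster) < min_support:
        return []
    start = min(p.anchor_start for p in cluster)
    end = max(p.anchor_end for p in cluster)
    for cp in control_pairs:
        if cp.anchor_start < end and cp.anchor_end > start:
            return []
    return [CandidateRegion(chrom=chrom, start=start, end=end, pairs=list(cluster))]


def _clip_is_telomeric(seq: str, patterns: RepeatPatternSet, min_purity: float) -> tuple[bool, str]:
    """Check the split-read clip: contains >= 1 TTAGGG (either strand) and
    enough telomeric purity. Returns (passes, repeat_strand)."""
    has_g = "TTAGGG" in seq
    has_c = "CCCTAA" in seq
    if not (has_g or has_c):
        return False, ""
    g = len(patterns.regex("G").findall(seq))
    c = len(patterns.regex("C").findall(seq))
    purity = max(g, c) * 6 / len(seq)
    if purity < min_purity:
        return False, ""
    return True, "G" if g >= c else "C"


def refine_junction(
    region: CandidateRegion,
    split_reads: list[SplitRead],
    patterns: RepeatPatternSet | None = None,
    min_split: int = MIN_SPLIT,
    min_clip_len: int = MIN_CLIP_LEN,
    min_purity: float = MIN_CLIP_PURITY,
    slack: int = CLUSTER_GAP,
) -> TelomereInsertion | None:
    """Resolve a candidate region to an exact junction from split reads.

    A split read supports position p when its clip point is p and its clipped
    segment contains at least one TTAGGG (or CCCTAA, normalized to forward
    strand), is at least ``min_clip_len`` long, and is at least
    ``min_purity`` telomeric. The position supported by at least ``min_split``
    reads wins; ties break toward most support, then smallest coordinate.
    Returns None (candidate dropped) if no position qualifies.
    """
    patterns = patterns or RepeatPatternSet()
    support: dict[tuple[int, str], list[SplitRead]] = defaultdict(list)
    strand_votes: dict[tuple[int, str], list[str]] = defaultdict(list)
    for sr in split_reads:
        if sr.chrom != region.chrom:
            continue
        if not (region.start - slack <= sr.clip_pos <= region.end + slack):
            continue
        if len(sr.clipped_seq) < min_clip_len:
            continue
        ok, strand = _clip_is_telomeric(sr.clipped_seq, patterns, min_purity)
        if not ok:
            continue
        key = (sr.clip_pos, sr.side)
        support[key].append(sr)
        strand_votes[key].append(strand)
    qualifying = [(len(v), key) for key, v in support.items() if len(v) >= min_split]
    if not qualifying:
        return None
    qualifying.sort(key=lambda t: (-t[0], t[1][0]))
    n_split, (pos, side) = qualifying[0]
    votes = strand_votes[(pos, side)]
    strand = "G" if votes.count("G") >= votes.count("C") else "C"
    reads = support[(pos, side)]
    longest = max(reads, key=lambda sr: len(sr.clipped_seq))
    return TelomereInsertion(
        chrom=region.chrom,
        position=pos,
        orientation="telomere-right" if side == "right" else "telomere-left",
        repeat_strand=strand,
        n_discordant=region.n_tumor,
        n_split=n_split,
        clipped_seq=longest.clipped_seq,
    )


def filter_control_panel(
    insertions: list[TelomereInsertion],
    panel: list[dict[str, list[tuple[int, int]]]] | None,
    min_controls: int = PANEL_MIN_CONTROLS,
    region_halfwidth: int = 500,
) -> list[TelomereInsertion]:
    """Drop insertions recurrent in at least ``min_controls`` panel controls.

    The panel is a list of per-control interval sets (chrom -> [(start, end)])
    of discordant telomere-pair regions. An empty panel passes everything
    through with a warning.
    """
    if not panel:
        warnings.warn("empty control panel: no recurrence filtering applied", stacklevel=2)
        return list(insertions)
    kept = []
    for ins in insertions:
        lo = ins.position - region_halfwidth
        hi = ins.position + region_halfwidth
        n_hit = 0
        for control in panel:
            for start, end in control.get(ins.chrom, ()):
                if start < hi and end > lo:
                    n_hit += 1
                    break
        if n_hit < min_controls:
            kept.append(ins)
    return kept


def classify_sidedness(
    insertions: list[TelomereInsertion], window: int = SIDEDNESS_WINDOW
) -> list[TelomereInsertion]:
    """Mark two-sided insertion pairs.

    An insertion is two-sided when another insertion in the opposite
    orientation with the same forward-strand repeat lies within the
    downstream (higher-coordinate) ``window``. Partners are cross-referenced
    by index into the returned list; pairing is symmetric.
    """
    order = sorted(range(len(insertions)), key=lambda i: (insertions[i].chrom, insertions[i].position))
    for i in order:
        insertions[i].sidedness = "one_sided"
        insertions[i].partner = None
    for a_idx in range(len(order)):
        i = order[a_idx]
        a = insertions[i]
        if a.partner is not None:
            continue
        for b_idx in range(a_idx + 1, len(order)):
            j = order[b_idx]
            b = insertions[j]
            if b.chrom != a.chrom or b.position - a.position > window:
                break
            if b.partner is not None:
                continue
            if b.orientation != a.orientation and b.repeat_strand == a.repeat_strand:
                a.sidedness = b.sidedness = "two_sided"
                a.partner, b.partner = j, i
                break
    return insertions


def annotate_cn_change(
    insertion: TelomereInsertion,
    cn_segments: pd.DataFrame,
    max_dist: int = CN_ASSIGN_WINDOW,
    min_segment: int = CN_MIN_SEGMENT,
    complex_diff: float = CN_COMPLEX_DIFF,
) -> str:
    """Copy-number change class at the insertion.

    Segments shorter than 10 kb are ignored (below the resolution of the
    consensus segmentation). The insertion is assigned to the closest segment
    boundary within 50 kb; without one, or with equal flanking copy numbers,
    the change is neutral. The loss/gain direction refers to the segment on
    the side of the junction where the telomere now sits — the fate of the
    broken distal fragment. Flanking differences of more than four copies are
    "complex".
    """
    seg = cn_segments[
        (cn_segments["chrom"] == insertion.chrom)
        & (cn_segments["end"] - cn_segments["start"] >= min_segment)
    ].sort_values("start")
    if seg.empty:
        insertion.cn_change = "neutral"
        return insertion.cn_change
    best = None  # (distance, cn_left, cn_right)
    rows = seg.to_dict("records")
    for left, right in zip(rows, rows[1:]):
        boundary = left["end"]
        dist = abs(insertion.position - boundary)
        if dist <= max_dist and (best is None or dist < best[0]):
            best = (dist, left["copy_number"], right["copy_number"])
    if best is None:
        insertion.cn_change = "neutral"
        return insertion.cn_change
    _, cn_left, cn_right = best
    if insertion.orientation == "telomere-right":
        cn_distal, cn_proximal = cn_right, cn_left
    else:
        cn_distal, cn_proximal = cn_left, cn_right
    diff = cn_distal - cn_proximal
    if diff == 0:
        insertion.cn_change = "neutral"
    elif abs(diff) > complex_diff:
        insertion.cn_change = "complex"
    elif diff < 0:
        insertion.cn_change = "loss"
    else:
        insertion.cn_change = "gain"
    return insertion.cn_change


def annotate_nearby_sv(
    insertion: TelomereInsertion,
    sv_table: pd.DataFrame | None,
    chromothripsis: pd.DataFrame | None = None,
    window: int = SV_WINDOW,
    other_insertions: list[TelomereInsertion] | None = None,
) -> TelomereInsertion:
    """Flag SV breakpoints within 10 kb and chromothripsis-region overlap.

    Other telomere insertions count as breakpoints too (small deletions next
    to a junction are invisible to the copy-number callers).
    """
    near = False
    if sv_table is not None and not sv_table.empty:
        for end in ("1", "2"):
            mask = (sv_table[f"chrom{end}"] == insertion.chrom) & (
                (sv_table[f"pos{end}"] - insertion.position).abs() <= window
            )
            if mask.any():
                near = True
                break
    if not near and other_insertions:
        for other in other_insertions:
            if other is insertion:
                continue
            if other.chrom == insertion.chrom and abs(other.position - insertion.position) <= window:
                near = True
                break
    insertion.nearby_sv = near
    insertion.in_chromothripsis = False
    if chromothripsis is not None and not chromothripsis.empty:
        mask = (
            (chromothripsis["chrom"] == insertion.chrom)
            & (chromothripsis["start"] <= insertion.position)
            & (insertion.position < chromothripsis["end"])
        )
        insertion.in_chromothripsis = bool(mask.any())
    return insertion


def _phase_of(inserted: str, unit: str) -> int | None:
    """Phase offset of the inserted repeat sequence within ``unit``'s cycle,
    or None if the insert does not start with a repeat in any phase."""
    probe = inserted[: min(len(inserted), 12)]
    stream = unit * (len(probe) // 6 + 3)
    for phi in range(6):
        if stream[phi : phi + len(probe)] == probe:
            return phi
    return None


def _mh_left_extension(flank: str, phi: int, unit: str) -> int:
    """Consecutive flank bases (walking left from the junction) that continue
    the repeat cycle leftward from phase ``phi`` — the number of bases the
    junction can be shifted left without breaking repeat continuity."""
    stream = unit * 20
    idx = 60 + phi  # a deep index with phase phi (stream has period 6)
    m = 0
    while m < len(flank) and stream[idx - m - 1] == flank[len(flank) - m - 1]:
        m += 1
    return m


def detect_microhomology(
    chrom_flank: str,
    inserted_seq: str,
    repeat: str = "TTAGGG",
) -> tuple[int, bool]:
    """Junction microhomology length between chromosomal flank and telomere.

    Defined as the number of bases the junction can slide left while the
    chromosomal sequence remains consistent with the telomere repeat phase of
    the inserted sequence (exhaustive base-by-base overlap extension). Both
    the G-rich repeat and its reverse complement are tried; the larger overlap
    is reported. The result is flagged ambiguous when the chromosomal flank
    itself ends in telomeric repeats (an interstitial repeat makes the
    junction assignment unreliable).
    """
    chrom_flank = chrom_flank.upper()
    inserted_seq = inserted_seq.upper()
    best = 0
    for unit in (repeat, reverse_complement(repeat)):
        phi = _phase_of(inserted_seq, unit)
        if phi is None:
            continue
        best = max(best, _mh_left_extension(chrom_flank, phi, unit))
    tail = chrom_flank[-18:]
    ambiguous = ("TTAGGG" in tail) or ("CCCTAA" in tail)
    return best, ambiguous


def _reference_flank(reference: dict[str, str], insertion: TelomereInsertion, width: int = 30) -> tuple[str, str]:
    """(chromosomal flank, inserted sequence) in junction-normalized
    orientation: flank runs into the junction, insert runs out of it."""
    seq = reference[insertion.chrom]
    p = insertion.position
    if insertion.orientation == "telomere-right":
        return seq[max(0, p - width) : p], insertion.clipped_seq
    flank = reverse_complement(seq[p : p + width])
    return flank, reverse_complement(insertion.clipped_seq)


def call_insertions(
    tumor_alignment,
    control_alignment,
    patterns: RepeatPatternSet | None = None,
    panel: list[dict] | None = None,
    reference: dict[str, str] | None = None,
    cn_segments: pd.DataFrame | None = None,
    sv_table: pd.DataFrame | None = None,
    chromothripsis: pd.DataFrame | None = None,
    min_discordant: int = MIN_DISCORDANT,
    min_split: int = MIN_SPLIT,
) -> list[TelomereInsertion]:
    """End-to-end somatic telomere-insertion calling on one tumor/control pair."""
    patterns = patterns or RepeatPatternSet()
    tumor_pairs, tumor_splits, _ = scan_alignment(tumor_alignment, patterns)
    control_pairs, _, _ = scan_alignment(control_alignment, patterns)
    regions = call_candidate_regions(tumor_pairs, control_pairs, min_support=min_discordant)
    insertions = []
    for region in regions:
        ins = refine_junction(region, tumor_splits, patterns, min_split=min_split)
        if ins is not None:
            insertions.append(ins)
    if panel is not None:
        insertions = filter_control_panel(insertions, panel)
    classify_sidedness(insertions)
    for ins in insertions:
        if cn_segments is not None:
            annotate_cn_change(ins, cn_segments)
        annotate_nearby_sv(ins, sv_table, chromothripsis, other_insertions=insertions)
        if reference is not None and ins.clipped_seq:
            flank, inserted = _reference_flank(reference, ins)
            ins.microhomology_length, ins.microhomology_ambiguous = detect_microhomology(
                flank, inserted
            )
    return insertions


def insertions_to_frame(insertions: list[TelomereInsertion]) -> pd.DataFrame:
    cols = [
        "chrom", "position", "orientation", "repeat_strand", "n_discordant",
        "n_split", "sidedness", "partner", "cn_change", "nearby_sv",
        "in_chromothripsis", "microhomology_length", "microhomology_ambiguous",
    ]
    rows = [{c: getattr(ins, c) for c in cols} for ins in insertions]
    return pd.DataFrame(rows, columns=cols)
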