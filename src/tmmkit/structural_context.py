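"""Genomic breakpoint counting and breakage-fusion-bridge (BFB) detection.

BFB cycles — repeated anaphase bridging of a chromosome that lost its
telomere — leave a characteristic signature of fold-back inversions: inverted
rearrangements whose two breakpoints lie close together, accompanied by a
copy-number step. A fold-back inversion qualifies when (1) its breakpoints
are less than 20 kb apart, (2) it has no reciprocal partner (no second
inversion interleaved as inv1_start < inv2_start < inv1_end < inv2_end, which
would indicate a balanced reciprocal inversion instead), and (3) a
copy-number change lies at the inversion site. Two or more qualifying
fold-backs on the same chromosome arm call a BFB event on that arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FoldBackInversion",
    "BFBCall",
    "count_breakpoints",
    "detect_fold_back_inversions",
    "detect_bfb",
]

FOLDBACK_MAX_SPAN = 20_000
CN_CHANGE_WINDOW = 50_000  # consensus CN breakpoints can be off by up to 50 kb


@dataclass
class FoldBackInversion:
    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str = ""
    spans_centromere: bool = False


@dataclass
class BFBCall:
    chrom: str
    arm: str
    fold_back_inversions: list[FoldBackInversion] = field(default_factory=list)

    @property
    def is_bfb(self) -> bool:
        return len(self.fold_back_inversions) >= 2


def count_breakpoints(sv_table: pd.DataFrame, sample_id: str | None = None) -> int:
    """Number of distinct breakpoints, de-duplicated by (chrom, pos).

    Both ends of each BEDPE-like record contribute one breakpoint.
    """
    if sv_table.empty:
        return 0
    if sample_id is not None and "sample_id" in sv_table.columns:
        sv_table = sv_table[sv_table["sample_id"] == sample_id]
    points = set()
    for end in ("1", "2"):
        for chrom, pos in zip(sv_table[f"chrom{end}"], sv_table[f"pos{end}"]):
            points.add((chrom, int(pos)))
    return len(points)


def _cn_breakpoints(cn_segments: pd.DataFrame) -> dict[str, list[int]]:
    """Internal segment boundaries per chromosome."""
    out: dict[str, list[int]] = {}
    for chrom, grp in cn_segments.groupby("chrom"):
        grp = grp.sort_values("start")
        rows = grp.to_dict("records")
        bps = []
        for left, right in zip(rows, rows[1:]):
            if left["copy_number"] != right["copy_number"]:
                bps.append(int(left["end"]))
        out[str(chrom)] = bps
    return out


def detect_fold_back_inversions(
    sv_table: pd.DataFrame,
    cn_segments: pd.DataFrame,
    max_span: int = FOLDBACK_MAX_SPAN,
    cn_window: int = CN_CHANGE_WINDOW,
) -> list[FoldBackInversion]:
    """Filter inversion-type SVs down to qualifying fold-back inversions.

    Inversions are records with both breakpoints on the same chromosome and
    the same strand orientation on both ends. The three criteria (span,
    reciprocal partner, copy-number change within ``cn_window`` of either
    breakpoint) are applied independently; the reciprocal-partner check tests
    the interleaving pattern against every other inversion in either order.
    """
    inv = sv_table[
        (sv_table["chrom1"] == sv_table["chrom2"])
        & (sv_table["strand1"] == sv_table["strand2"])
    ].copy()
    if inv.empty:
        return []
    inv["start"] = inv[["pos1", "pos2"]].min(axis=1)
    inv["end"] = inv[["pos1", "pos2"]].max(axis=1)
    cn_bps = _cn_breakpoints(cn_segments) if not cn_segments.empty else {}
    records = inv.to_dict("records")
    out: list[FoldBackInversion] = []
    for i, rec in enumerate(records):
        if rec["end"] - rec["start"] >= max_span:
            continue
        reciprocal = False
        for j, other in enumerate(records):
            if i == j or other["chrom1"] != rec["chrom1"]:
                continue
            if rec["start"] < other["start"] < rec["end"] < other["end"]:
                reciprocal = True
                break
            if other["start"] < rec["start"] < other["end"] < rec["end"]:
                reciprocal = True
                break
        if reciprocal:
            continue
        bps = cn_bps.get(str(rec["chrom1"]), [])
        has_cn_change = any(
            abs(bp - rec["start"]) <= cn_window or abs(bp - rec["end"]) <= cn_window
            for bp in bps
        )
        if not has_cn_change:
            continue
        out.append(
            FoldBackInversion(
                chrom=str(rec["chrom1"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                strand=str(rec["strand1"]),
                sample_id=str(rec.get("sample_id", "")),
            )
        )
    return out


def detect_bfb(
    inversions: list[FoldBackInversion],
    arm_boundaries: dict[str, int],
) -> list[BFBCall]:
    """Call BFB events per chromosome arm from qualifying fold-back inversions.

    ``arm_boundaries`` maps chromosome name to its centromere coordinate; an
    inversion goes to the arm containing its midpoint (inversions spanning
    the centromere are assigned by midpoint and flagged). At least two
    fold-backs on one arm make a BFB event.
    """
    by_arm: dict[tuple[str, str], list[FoldBackInversion]] = {}
    for inv in inversions:
        centro = arm_boundaries.get(inv.chrom)
        if centro is None:
            raise KeyError(f"no centromere coordinate for {inv.chrom}")
        mid = (inv.start + inv.end) // 2
        arm = "p" if mid < centro else "q"
        if inv.start < centro <= inv.end:
            inv.spans_centromere = True
        by_arm.setdefault((inv.chrom, arm), []).append(inv)
    return [
        BFBCall(chrom=chrom, arm=arm, fold_back_inversions=invs)
        for (chrom, arm), invs in sorted(by_arm.items())
    ]
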