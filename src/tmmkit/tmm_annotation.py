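"""Assignment of telomere-maintenance-mechanism (TMM) groups from mutations.

Samples are grouped by alterations in the two pathways that unlock unlimited
telomere maintenance: loss of ATRX or DAXX (associated with the recombination-
based ALT mechanism) and activation of TERT (telomerase). A truncating ATRX or
DAXX alteration — frameshift indel, stop-codon gain, or a structural-variant
breakpoint inside the gene body — defines ATRX/DAXX-trunc; other simple
nucleotide variants define ATRX/DAXX-nontrunc, and deletions confined to
introns are ignored. TERT modifications comprise promoter point mutations
(C228T/C250T, called with relaxed thresholds because promoter coverage is
poor), an upstream plus-strand SV breakpoint within 20 kb of the TSS, and
amplification to at least six copies above the sample's mean ploidy; two or
more of these make TERT-mult, and any of them plus an ATRX/DAXX alteration
makes "mixed". Everything else is wild type.

All genomic landmarks (gene bodies, TERT TSS, promoter hotspot positions) are
supplied as configuration so the logic is genome-build agnostic; hg19 defaults
are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "TMMGroup",
    "MutationEffect",
    "TMMAnnotation",
    "TERTConfig",
    "HG19_TERT",
    "classify_atrx_daxx",
    "detect_tertp_sv",
    "detect_tert_amplification",
    "call_tert_promoter_mutation",
    "assign_tmm_group",
    "enhancer_overlap",
    "annotate_cohort",
]


class TMMGroup(str, Enum):
    ATRX_DAXX_TRUNC = "ATRX_DAXX_trunc"
    ATRX_DAXX_NONTRUNC = "ATRX_DAXX_nontrunc"
    TERTP_MUT = "TERTp_mut"
    TERTP_SV = "TERTp_SV"
    TERT_AMP = "TERT_amp"
    TERT_MULT = "TERT_mult"
    MIXED = "mixed"
    WILD_TYPE = "wild_type"


class MutationEffect(str, Enum):
    FRAMESHIFT_INDEL = "frameshift_indel"
    STOP_GAIN = "stop_gain"
    MISSENSE = "missense"
    OTHER_SNV = "other_snv"
    SV_BREAKPOINT_IN_GENE = "sv_breakpoint_in_gene"
    INTRONIC_DELETION_ONLY = "intronic_deletion_only"


TRUNCATING_EFFECTS = {
    MutationEffect.FRAMESHIFT_INDEL.value,
    MutationEffect.STOP_GAIN.value,
    MutationEffect.SV_BREAKPOINT_IN_GENE.value,
}

NONTRUNC_EFFECTS = {MutationEffect.MISSENSE.value, MutationEffect.OTHER_SNV.value}


@dataclass(frozen=True)
class TERTConfig:
    """Genomic landmarks for the TERT locus (positions 0-based)."""

    chrom: str = "chr5"
    tss: int = 1_295_104
    gene_start: int = 1_253_287
    gene_end: int = 1_295_184
    promoter_positions: tuple[int, ...] = (1_295_228, 1_295_250)  # C228, C250
    upstream_window: int = 20_000
    # TERT is on the minus strand, so "upstream" runs toward higher coordinates
    upstream_sign: int = +1


HG19_TERT = TERTConfig()


@dataclass
class TMMAnnotation:
    sample_id: str
    group: TMMGroup
    evidence: list = field(default_factory=list)


def classify_atrx_daxx(records: pd.DataFrame) -> str | None:
    """Classify a sample's ATRX/DAXX status from its mutation records.

    ``records`` must carry ``gene`` and ``effect`` columns already filtered to
    one sample; only ATRX/DAXX rows are considered. Returns "trunc",
    "nontrunc", or None (wild type for this gene pair). Intronic-only
    deletions and a user-supplied blacklist of known false positives are
    ignored upstream.
    """
    if records.empty:
        return None
    sel = records[records["gene"].isin(["ATRX", "DAXX"])]
    effects = set(sel["effect"])
    effects.discard(MutationEffect.INTRONIC_DELETION_ONLY.value)
    if effects & TRUNCATING_EFFECTS:
        return "trunc"
    if effects & NONTRUNC_EFFECTS:
        return "nontrunc"
    return None


def detect_tertp_sv(
    sv_table: pd.DataFrame, tert: TERTConfig = HG19_TERT
) -> tuple[bool, pd.DataFrame]:
    """Plus-strand SV breakpoint within 20 kb upstream of the TERT TSS.

    Both breakpoint ends of each BEDPE-like record (chrom1/pos1/strand1,
    chrom2/pos2/strand2) are tested.
    """
    if sv_table.empty:
        return False, sv_table.iloc[0:0]
    hits = []
    for end in ("1", "2"):
        chrom = sv_table[f"chrom{end}"]
        pos = sv_table[f"pos{end}"]
        strand = sv_table[f"strand{end}"]
        dist = (pos - tert.tss) * tert.upstream_sign
        mask = (chrom == tert.chrom) & (strand == "+") & (dist >= 0) & (dist <= tert.upstream_window)
        hits.append(sv_table[mask])
    found = pd.concat(hits).drop_duplicates()
    return not found.empty, found


def detect_tert_amplification(
    cn_segments: pd.DataFrame,
    mean_ploidy: float,
    tert: TERTConfig = HG19_TERT,
    extra_copies: float = 6.0,
) -> bool:
    """True iff the copy number covering the TERT gene is >= mean ploidy + 6."""
    if cn_segments.empty:
        raise ValueError("TERT locus not covered by any copy-number segment")
    sel = cn_segments[
        (cn_segments["chrom"] == tert.chrom)
        & (cn_segments["start"] < tert.gene_end)
        & (cn_segments["end"] > tert.gene_start)
    ]
    if sel.empty:
        raise ValueError("TERT locus not covered by any copy-number segment")
    return bool((sel["copy_number"] >= mean_ploidy + extra_copies).any())


def call_tert_promoter_mutation(
    ref_reads: int, alt_reads: int, min_alt: int = 2, min_vaf: float = 0.20
) -> bool | None:
    """Relaxed TERT promoter (C228T/C250T) caller for low-coverage pileups.

    Returns True when at least ``min_alt`` mutated reads are present at a
    mutational frequency of at least ``min_vaf``; None when the site has no
    coverage (not callable, distinct from a negative call).
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        return None
    return alt_reads >= min_alt and alt_reads / total >= min_vaf


def assign_tmm_group(
    sample_id: str,
    atrx_daxx_status: str | None,
    tertp_mut: bool,
    tertp_sv: bool,
    tert_amp: bool,
) -> TMMAnnotation:
    """Combine the component calls into a single TMM group per sample.

    Any ATRX/DAXX alteration together with any TERT modification gives
    "mixed"; two or more TERT modification classes give TERT_mult; otherwise
    the single class present, else wild type.
    """
    tert_classes = []
    if tertp_mut:
        tert_classes.append(TMMGroup.TERTP_MUT)
    if tertp_sv:
        tert_classes.append(TMMGroup.TERTP_SV)
    if tert_amp:
        tert_classes.append(TMMGroup.TERT_AMP)
    if atrx_daxx_status is not None and tert_classes:
        group = TMMGroup.MIXED
    elif len(tert_classes) >= 2:
        group = TMMGroup.TERT_MULT
    elif len(tert_classes) == 1:
        group = tert_classes[0]
    elif atrx_daxx_status == "trunc":
        group = TMMGroup.ATRX_DAXX_TRUNC
    elif atrx_daxx_status == "nontrunc":
        group = TMMGroup.ATRX_DAXX_NONTRUNC
    else:
        group = TMMGroup.WILD_TYPE
    evidence = [c.value for c in tert_classes]
    if atrx_daxx_status:
        evidence.append(f"ATRX_DAXX_{atrx_daxx_status}")
    return TMMAnnotation(sample_id=sample_id, group=group, evidence=evidence)


def enhancer_overlap(
    sv_table: pd.DataFrame,
    enhancers: pd.DataFrame,
    tert: TERTConfig = HG19_TERT,
    indirect_window: int = 1_000_000,
) -> str | None:
    """Overlap class of a sample's TERT-juxtaposed position with enhancers.

    Considers only plus-strand SVs with a breakpoint within 1 Mb of the TERT
    TSS; of those, the closest breakpoint to the TSS defines the juxtaposed
    partner coordinate, which is classified as "direct" when it falls inside
    an enhancer interval, "indirect" when an enhancer lies within 1 Mb of it,
    else "none". Returns None when no eligible SV exists.

    ``enhancers`` is a BED-like frame with chrom/start/end columns.
    """
    if sv_table.empty:
        return None
    best = None  # (distance, juxtaposed chrom, juxtaposed pos)
    for end, other in (("1", "2"), ("2", "1")):
        for _, row in sv_table.iterrows():
            if row[f"strand{end}"] != "+":
                continue
            if row[f"chrom{end}"] != tert.chrom:
                continue
            dist = abs(row[f"pos{end}"] - tert.tss)
            if dist > indirect_window:
                continue
            cand = (dist, row[f"chrom{other}"], row[f"pos{other}"])
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return None
    _, jx_chrom, jx_pos = best
    sel = enhancers[enhancers["chrom"] == jx_chrom]
    inside = (sel["start"] <= jx_pos) & (jx_pos < sel["end"])
    if inside.any():
        return "direct"
    near = (sel["start"] - indirect_window <= jx_pos) & (jx_pos < sel["end"] + indirect_window)
    if near.any():
        return "indirect"
    return "none"


def annotate_cohort(
    mutations: pd.DataFrame,
    sv_tables: dict[str, pd.DataFrame] | None = None,
    cn_tables: dict[str, pd.DataFrame] | None = None,
    ploidies: dict[str, float] | None = None,
    promoter_pileups: dict[str, tuple[int, int]] | None = None,
    consensus_tertp_mut: set[str] | None = None,
    tert: TERTConfig = HG19_TERT,
    blacklist: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Annotate every sample in a cohort with its TMM group.

    ``mutations`` is a MAF-like frame (sample_id, gene, effect). Promoter
    pileups are (ref_reads, alt_reads) at C228/C250 combined; consensus SNV
    calls of the promoter hotspots are unioned in via ``consensus_tertp_mut``.
    ``blacklist`` removes known false-positive (sample_id, gene) records
    before classification.
    """
    sv_tables = sv_tables or {}
    cn_tables = cn_tables or {}
    ploidies = ploidies or {}
    promoter_pileups = promoter_pileups or {}
    consensus_tertp_mut = consensus_tertp_mut or set()
    samples = sorted(
        set(mutations["sample_id"])
        | set(sv_tables)
        | set(cn_tables)
        | set(promoter_pileups)
        | consensus_tertp_mut
    )
    rows = []
    for sid in samples:
        recs = mutations[mutations["sample_id"] == sid]
        if blacklist:
            keep = [
                (r["sample_id"], r["gene"]) not in blacklist for _, r in recs.iterrows()
            ]
            recs = recs[keep] if recs.shape[0] else recs
        status = classify_atrx_daxx(recs)
        sv = sv_tables.get(sid)
        tertp_sv = detect_tertp_sv(sv, tert)[0] if sv is not None else False
        cn = cn_tables.get(sid)
        tert_amp = (
            detect_tert_amplification(cn, ploidies.get(sid, 2.0), tert)
            if cn is not None
            else False
        )
        pile = promoter_pileups.get(sid)
        tertp_mut = sid in consensus_tertp_mut
        if pile is not None:
            call = call_tert_promoter_mutation(*pile)
            tertp_mut = tertp_mut or bool(call)
        ann = assign_tmm_group(sid, status, tertp_mut, tertp_sv, tert_amp)
        rows.append({"sample_id": sid, "group": ann.group.value, "evidence": ";".join(ann.evidence)})
    return pd.DataFrame(rows, columns=["sample_id", "group", "evidence"])
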