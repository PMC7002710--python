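"""Telomere variant repeat (TVR) scanning and singleton divergence.

Telomeres elongated by ALT versus telomerase acquire distinct non-canonical
hexamer repeats. This module scans extracted telomere reads for hexamers of
the form NNNGGG, distinguishing occurrences in *arbitrary* context from
*singletons* — an isolated variant flanked by exactly three canonical TTAGGG
repeats on each side, (TTAGGG)3-NNNGGG-(TTAGGG)3. Counts are normalized to
the total reads of the sample and compared tumor vs control as log2 ratios.

Because telomere content itself shifts all repeat counts, each singleton
pattern's tumor/control ratio is referenced against the value expected at the
sample's telomere-content ratio, taken from the regression line through
telomerase-driven (TERT-mod) samples. The residual ("divergence") is the
ALT-associated signal: positive for TTCGGG/TGAGGG/TCAGGG/TTGGGG and negative
for TTTGGG in ALT tumors. For TVRs in arbitrary context the expected log2
ratio is the telomere-content log2 ratio itself (identity line).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .telomere_content import reverse_complement

__all__ = [
    "TVROccurrence",
    "TVRProfile",
    "CLASSIFIER_PATTERNS",
    "scan_tvr",
    "build_profile",
    "fit_expected_regression",
    "singleton_divergence",
    "arbitrary_divergence",
    "cohort_divergences",
    "summarize_context_spectrum",
]

T_TYPE = "TTAGGG"
T_FLANK = T_TYPE * 3

#: Singleton patterns used as classifier features.
CLASSIFIER_PATTERNS: tuple[str, ...] = ("TGAGGG", "TCAGGG", "TTGGGG", "TTCGGG", "TTTGGG")

FLANK = 18
QUALITY_MIN = 20


@dataclass(frozen=True)
class TVROccurrence:
    pattern: str
    position: int  # offset within the (strand-normalized) read
    left_context: str
    right_context: str
    singleton: bool
    is_canonical: bool


def _normalize_strand(seq: str, quals) -> tuple[str, list[int] | None]:
    """Reverse-complement C-strand reads so all scanning is G-strand."""
    n_c = seq.count("CCCTAA")
    n_g = seq.count(T_TYPE)
    if n_c > n_g:
        seq = reverse_complement(seq)
        quals = list(quals)[::-1] if quals is not None else None
    return seq, quals


def scan_read(
    seq: str, quals=None, quality_threshold: int = QUALITY_MIN
) -> list[TVROccurrence]:
    """Scan one telomere read for NNNGGG hexamers.

    C-strand reads are first normalized to G-strand orientation. The scan is
    greedy left-to-right over all offsets: on a sequence match the cursor
    advances six bases (de-duplicating overlapping matches), otherwise one.
    A matched hexamer is recorded only when all six base qualities reach the
    threshold. Flanks are the neighboring 18 bp on each side; occurrences
    closer than 18 bp to a read end have truncated flanks and can never be
    singletons.
    """
    seq = seq.upper()
    seq, quals = _normalize_strand(seq, quals)
    out: list[TVROccurrence] = []
    i = 0
    n = len(seq)
    while i + 6 <= n:
        hexamer = seq[i : i + 6]
        if hexamer.endswith("GGG") and "N" not in hexamer:
            if quals is None or min(quals[i : i + 6]) >= quality_threshold:
                left = seq[max(0, i - FLANK) : i]
                right = seq[i + 6 : i + 6 + FLANK]
                out.append(
                    TVROccurrence(
                        pattern=hexamer,
                        position=i,
                        left_context=left,
                        right_context=right,
                        singleton=(left == T_FLANK and right == T_FLANK and hexamer != T_TYPE),
                        is_canonical=(hexamer == T_TYPE),
                    )
                )
            i += 6
        else:
            i += 1
    return out


def scan_tvr(reads, quality_threshold: int = QUALITY_MIN) -> pd.DataFrame:
    """Scan an iterable of telomere reads for TVR occurrences.

    ``reads`` yields sequences, (sequence, qualities) tuples, or objects with
    ``sequence``/``qualities`` attributes. Returns one row per recorded
    occurrence; canonical TTAGGG hits are flagged so variant statistics can
    exclude them.
    """
    rows = []
    for idx, read in enumerate(reads):
        if isinstance(read, str):
            seq, quals = read, None
        elif isinstance(read, tuple):
            seq, quals = read
        else:
            seq = read.sequence if hasattr(read, "sequence") else read.query_sequence
            quals = getattr(read, "qualities", None)
            if quals is None and hasattr(read, "query_qualities"):
                quals = read.query_qualities
        for occ in scan_read(seq, quals, quality_threshold):
            rows.append(
                {
                    "read_index": idx,
                    "pattern": occ.pattern,
                    "position": occ.position,
                    "left_context": occ.left_context,
                    "right_context": occ.right_context,
                    "singleton": occ.singleton,
                    "is_canonical": occ.is_canonical,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_index", "pattern", "position", "left_context",
            "right_context", "singleton", "is_canonical",
        ],
    )


@dataclass
class TVRProfile:
    """Per-sample-pair TVR count table with tumor/control log2 ratios.

    ``table`` is indexed by (pattern, context) with context "arbitrary" (all
    occurrences of the pattern) or "singleton" (t-type context only); columns
    are raw and normalized counts per side and the pseudocounted log2 ratio.
    """

    sample_id: str
    table: pd.DataFrame
    total_reads_tumor: int
    total_reads_control: int

    def log2_ratio(self, pattern: str, context: str = "singleton") -> float:
        return float(self.table.loc[(pattern, context), "log2_ratio"])


def _count_by_context(occurrences: pd.DataFrame) -> pd.Series:
    occ = occurrences[~occurrences["is_canonical"]]
    arbitrary = occ.groupby("pattern").size()
    singleton = occ[occ["singleton"]].groupby("pattern").size()
    out = {}
    for pat, cnt in arbitrary.items():
        out[(pat, "arbitrary")] = cnt
        out[(pat, "singleton")] = int(singleton.get(pat, 0))
    return pd.Series(out, dtype=int)


def build_profile(
    occurrences_tumor: pd.DataFrame,
    occurrences_control: pd.DataFrame,
    total_reads_tumor: int,
    total_reads_control: int,
    sample_id: str = "sample",
    pseudocount: float = 1.0,
    patterns: tuple[str, ...] | None = None,
) -> TVRProfile:
    """Aggregate occurrences into a per-pattern, per-context profile.

    Normalized counts are raw counts over total sample reads; log2 ratios use
    a symmetric pseudocount added to both raw counts so patterns absent from
    both samples get a ratio of exactly zero.
    """
    if total_reads_tumor <= 0 or total_reads_control <= 0:
        raise ValueError("total read counts must be positive")
    ct = _count_by_context(occurrences_tumor)
    cc = _count_by_context(occurrences_control)
    pats = set(p for p, _ in ct.index) | set(p for p, _ in cc.index)
    pats |= set(patterns or CLASSIFIER_PATTERNS)
    index = pd.MultiIndex.from_product(
        [sorted(pats), ["arbitrary", "singleton"]], names=["pattern", "context"]
    )
    table = pd.DataFrame(index=index)
    table["count_tumor"] = [int(ct.get(k, 0)) for k in index]
    table["count_control"] = [int(cc.get(k, 0)) for k in index]
    table["norm_tumor"] = table["count_tumor"] / total_reads_tumor
    table["norm_control"] = table["count_control"] / total_reads_control
    table["log2_ratio"] = np.log2(
        ((table["count_tumor"] + pseudocount) / total_reads_tumor)
        / ((table["count_control"] + pseudocount) / total_reads_control)
    )
    return TVRProfile(
        sample_id=sample_id,
        table=table,
        total_reads_tumor=total_reads_tumor,
        total_reads_control=total_reads_control,
    )


def fit_expected_regression(content_log2, pattern_log2) -> tuple[float, float]:
    """OLS of pattern-count log2 ratio on telomere-content log2 ratio.

    Fit through telomerase-driven (TERT-mod) samples only; this line defines
    the expected singleton abundance at a given telomere-content change.
    Returns (slope, intercept).
    """
    x = np.asarray(content_log2, dtype=float)
    y = np.asarray(pattern_log2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 samples with finite values to fit the regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in telomere-content ratios; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def singleton_divergence(
    observed_log2: float, content_log2: float, slope: float, intercept: float
) -> float:
    """Observed singleton log2 ratio minus its regression-expected value."""
    return observed_log2 - (intercept + slope * content_log2)


def arbitrary_divergence(observed_log2: float, content_log2: float) -> float:
    """Arbitrary-context divergence against the identity-line expectation:
    the expected pattern log2 ratio equals the telomere-content log2 ratio."""
    return observed_log2 - content_log2


def cohort_divergences(
    sample_table: pd.DataFrame,
    labels: pd.Series,
    patterns: tuple[str, ...] = CLASSIFIER_PATTERNS,
    reference_label: str = "TERT_mod",
) -> pd.DataFrame:
    """Per-sample singleton divergences for a cohort.

    ``sample_table`` must have a ``content_log2`` column plus one column per
    pattern holding singleton log2 ratios (named by pattern); the regression
    for each pattern is fitted on samples whose label equals
    ``reference_label`` and then applied to every sample.
    """
    ref = sample_table.loc[labels[labels == reference_label].index]
    out = pd.DataFrame(index=sample_table.index)
    for pat in patterns:
        slope, intercept = fit_expected_regression(ref["content_log2"], ref[pat])
        out[f"divergence_{pat}"] = sample_table[pat] - (
            intercept + slope * sample_table["content_log2"]
        )
    return out


def summarize_context_spectrum(occurrences: pd.DataFrame, pattern: str) -> pd.DataFrame:
    """Frequency-ranked 18+6+18 bp neighborhoods of one TVR pattern.

    Returns the full neighborhood strings with counts, each row flagged for
    pure t-type context; the ``t_type_fraction`` attribute of the frame gives
    the overall fraction of occurrences in t-type (singleton) context.
    """
    occ = occurrences[occurrences["pattern"] == pattern]
    if occ.empty:
        empty = pd.DataFrame(columns=["neighborhood", "count", "t_type_context"])
        empty.attrs["t_type_fraction"] = math.nan
        return empty
    neigh = occ["left_context"] + "|" + pattern + "|" + occ["right_context"]
    counts = (
        pd.DataFrame({"neighborhood": neigh, "t_type_context": occ["singleton"]})
        .groupby(["neighborhood", "t_type_context"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values("count", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )[["neighborhood", "count", "t_type_context"]]
    counts.attrs["t_type_fraction"] = float(occ["singleton"].mean())
    return counts
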