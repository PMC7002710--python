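"""Synthetic tumor/control WGS data with planted ground truth.

Every downstream stage of the pipeline is exercised on data from this module:
telomeric reads built from t-type repeats with controllable variant-repeat
(TVR) and singleton rates, background reads with controlled GC composition,
read pairs and split reads spanning planted telomere-insertion junctions,
copy-number segments, SV tables, and class-conditional classifier cohorts.

The generator emits standard formats (SAM with header, FASTA reference, TSV
truth tables) so the pipeline consumes synthetic and real data identically.
All randomness flows from a single integer seed; identical configuration gives
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .telomere_content import SimRead, reverse_complement

__all__ = [
    "SimulationConfig",
    "PlantedInsertion",
    "SamplePair",
    "generate_telomere_read",
    "simulate_content_reads",
    "generate_sample_pair",
    "build_control_panel",
    "generate_cohort_features",
    "paper_shaped_effects",
    "CLASSIFIER_FEATURES",
    "EFFECT_DIRECTIONS",
]

T_TYPE = "TTAGGG"

DEFAULT_CONTIGS: tuple[tuple[str, int], ...] = (("chr1", 400_000), ("chr2", 300_000))


@dataclass
class PlantedInsertion:
    """A planted junction between chromosomal sequence and telomere repeats.

    ``orientation`` says on which side of the junction the telomere repeats
    lie ("telomere-left" or "telomere-right"); ``repeat_strand`` is "G" when
    the G-rich repeat (TTAGGG) reads on the reference forward strand and "C"
    for its reverse complement. ``n_control_discordant`` plants matching
    discordant pairs in the control sample (a germline/artifact event), and
    ``panel_recurrence`` marks the region as recurrent in that many panel
    controls; both default to a clean somatic event.
    """

    chrom: str
    position: int
    orientation: str = "telomere-right"
    repeat_strand: str = "G"
    n_discordant_pairs: int = 5
    n_split_reads: int = 3
    n_control_discordant: int = 0
    panel_recurrence: int = 0
    partner: int | None = None  # index of the partner insertion, if two-sided

    def __post_init__(self) -> None:
        if self.orientation not in ("telomere-left", "telomere-right"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.repeat_strand not in ("G", "C"):
            raise ValueError(f"bad repeat_strand {self.repeat_strand!r}")
        if min(self.n_discordant_pairs, self.n_split_reads, self.n_control_discordant) < 0:
            raise ValueError("support counts must be non-negative")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    read_length: int = 100
    n_background_reads: int = 2000
    gc_bin_fraction: float = 0.3
    telomere_fraction_tumor: float = 0.002
    telomere_fraction_control: float = 0.001
    tvr_rates: dict[str, float] = field(default_factory=dict)
    singleton_rates: dict[str, float] = field(default_factory=dict)
    planted_insertions: list[PlantedInsertion] = field(default_factory=list)
    cn_segments: list[tuple] = field(default_factory=list)
    sv_records: list[tuple] = field(default_factory=list)
    mutations: list[dict] = field(default_factory=list)
    contigs: tuple[tuple[str, int], ...] = DEFAULT_CONTIGS

    def __post_init__(self) -> None:
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        for name, v in [
            ("gc_bin_fraction", self.gc_bin_fraction),
            ("telomere_fraction_tumor", self.telomere_fraction_tumor),
            ("telomere_fraction_control", self.telomere_fraction_control),
            *[(f"tvr_rates[{p}]", r) for p, r in self.tvr_rates.items()],
            *[(f"singleton_rates[{p}]", r) for p, r in self.singleton_rates.items()],
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        contig_len = dict(self.contigs)
        by_chrom: dict[str, list[int]] = {}
        for ins in self.planted_insertions:
            if ins.chrom not in contig_len:
                raise ValueError(f"insertion on unknown contig {ins.chrom}")
            if not 0 <= ins.position < contig_len[ins.chrom]:
                raise ValueError(f"insertion position {ins.position} outside {ins.chrom}")
            by_chrom.setdefault(ins.chrom, []).append(ins.position)
        for chrom, positions in by_chrom.items():
            positions.sort()
            for a, b in zip(positions, positions[1:]):
                if b - a < 1000:
                    raise ValueError(
                        f"planted insertions on {chrom} at {a} and {b} are closer than "
                        "1 kb and would merge ambiguously"
                    )


@dataclass
class SamplePair:
    tumor_sam: Path
    control_sam: Path
    reference_fasta: Path
    truth: pd.DataFrame


def generate_telomere_read(
    length: int,
    tvr_rates: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    singleton: str | None = None,
    c_strand: bool = False,
    base_quality: int = 30,
    low_quality_positions: Sequence[int] = (),
) -> tuple[str, list[int]]:
    """Build one telomeric read as a concatenation of hexamer repeats.

    Each hexamer is the canonical TTAGGG unless substituted by a variant
    pattern with the per-hexamer probabilities in ``tvr_rates``. When a
    ``singleton`` pattern is requested, exactly one isolated variant is placed
    with at least three untouched t-type hexamers on each side. With
    ``c_strand`` the finished read is reverse-complemented, emulating a read
    from the C-rich strand.
    """
    if length < 6:
        raise ValueError("telomere read length must be >= 6")
    rng = rng or np.random.default_rng()
    tvr_rates = tvr_rates or {}
    n_hex = length // 6
    hexamers = [T_TYPE] * n_hex
    protected: set[int] = set()
    if singleton is not None:
        if n_hex < 7:
            raise ValueError("singleton placement needs at least 7 hexamers (42 bp)")
        pos = int(rng.integers(3, n_hex - 3))
        hexamers[pos] = singleton
        protected = set(range(pos - 3, pos + 4))
    if tvr_rates:
        pats = list(tvr_rates)
        probs = np.array([tvr_rates[p] for p in pats])
        if probs.sum() > 1.0:
            raise ValueError("tvr_rates sum to more than 1")
        for i in range(n_hex):
            if i in protected:
                continue
            u = rng.random()
            acc = 0.0
            for p, pr in zip(pats, probs):
                acc += pr
                if u < acc:
                    hexamers[i] = p
                    break
    seq = "".join(hexamers)
    # pad a trailing partial hexamer so the read reaches the requested length
    if len(seq) < length:
        seq += T_TYPE[: length - len(seq)]
    if c_strand:
        seq = reverse_complement(seq)
    quals = [base_quality] * length
    for i in low_quality_positions:
        if 0 <= i < length:
            quals[i] = 10
    return seq, quals


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background_sequences(
    n: int, length: int, gc_target: float, rng: np.random.Generator
) -> list[str]:
    """Random reads with an exact per-read GC count of round(gc_target*length)."""
    if n == 0:
        return []
    n_gc = int(round(gc_target * length))
    template = np.empty(length, dtype=np.uint8)
    half_gc = n_gc // 2
    half_at = (length - n_gc) // 2
    template[:half_gc] = ord("G")
    template[half_gc:n_gc] = ord("C")
    template[n_gc : n_gc + half_at] = ord("A")
    template[n_gc + half_at :] = ord("T")
    order = rng.random((n, length)).argsort(axis=1)
    mat = template[order]
    raw = mat.tobytes()
    return [raw[i * length : (i + 1) * length].decode("ascii") for i in range(n)]


def _pick_singleton(singleton_rates: dict[str, float], rng: np.random.Generator) -> str | None:
    if not singleton_rates:
        return None
    u = rng.random()
    acc = 0.0
    for pat, rate in singleton_rates.items():
        acc += rate
        if u < acc:
            return pat
    return None


def simulate_content_reads(
    n_reads: int,
    telomere_fraction: float,
    gc_bin_fraction: float,
    read_length: int,
    rng: np.random.Generator,
    tvr_rates: dict[str, float] | None = None,
    singleton_rates: dict[str, float] | None = None,
    chunk: int = 50_000,
) -> Iterator[SimRead]:
    """Stream an in-memory read set with the configured telomeric fraction.

    Each of the ``n_reads`` reads is telomeric with probability
    ``telomere_fraction`` (unmapped, repeat-composed); the rest are background
    reads mapped with quality 60, landing in the 48-52% GC normalization bin
    with probability ``gc_bin_fraction`` (GC 0.5 inside, 0.3 outside the bin).
    Generated in chunks so multi-million-read simulations stay in bounded
    memory.
    """
    singleton_rates = singleton_rates or {}
    n_tel = int(rng.binomial(n_reads, telomere_fraction)) if telomere_fraction > 0 else 0
    n_bg = n_reads - n_tel
    for _ in range(n_tel):
        c_strand = bool(rng.random() < 0.5)
        seq, _ = generate_telomere_read(
            read_length,
            tvr_rates=tvr_rates,
            rng=rng,
            singleton=_pick_singleton(singleton_rates, rng),
            c_strand=c_strand,
        )
        yield SimRead(sequence=seq, is_unmapped=True, mapping_quality=0)
    done = 0
    while done < n_bg:
        m = min(chunk, n_bg - done)
        in_bin = rng.random(m) < gc_bin_fraction
        n_in = int(in_bin.sum())
        seqs_in = iter(_background_sequences(n_in, read_length, 0.5, rng))
        seqs_out = iter(_background_sequences(m - n_in, read_length, 0.3, rng))
        for flag in in_bin:
            seq = next(seqs_in) if flag else next(seqs_out)
            yield SimRead(sequence=seq, is_unmapped=False, mapping_quality=60)
        done += m


def _write_reference(path: Path, contigs, rng: np.random.Generator) -> dict[str, str]:
    seqs = {}
    with open(path, "w") as fh:
        for name, length in contigs:
            arr = _BASES[rng.integers(0, 4, size=length)]
            seq = arr.tobytes().decode("ascii")
            seqs[name] = seq
            fh.write(f">{name}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    return seqs


def _telomere_run(n_bases: int, repeat_strand: str, side: str) -> str:
    """Telomere sequence abutting a junction.

    For G-rich forward repeats the run is phased so TTAGGG starts right at the
    junction (side "right") or ends flush against it (side "left"); C-rich
    runs are the reverse complement.
    """
    n_units = n_bases // 6 + 2
    run = T_TYPE * n_units
    g_forward = run[:n_bases] if side == "right" else run[-n_bases:]
    if repeat_strand == "G":
        return g_forward
    return reverse_complement(g_forward)


class _SamWriter:
    def __init__(self, path: Path, contigs) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs],
        }
        self.fh = pysam.AlignmentFile(str(path), "w", header=header)
        self.header = self.fh.header

    def close(self) -> None:
        self.fh.close()

    def _new(self, name: str, seq: str, quals: Sequence[int] | None = None):
        a = pysam.AlignedSegment(self.header)
        a.query_name = name
        a.query_sequence = seq
        a.query_qualities = list(quals) if quals is not None else [30] * len(seq)
        return a

    def write_mapped_pair(self, name, chrom, pos1, seq1, pos2, seq2, mapq=60):
        L1, L2 = len(seq1), len(seq2)
        a = self._new(name, seq1)
        a.reference_name = chrom
        a.reference_start = pos1
        a.mapping_quality = mapq
        a.cigarstring = f"{L1}M"
        a.is_paired = True
        a.is_read1 = True
        a.is_proper_pair = True
        a.mate_is_reverse = True
        a.next_reference_name = chrom
        a.next_reference_start = pos2
        b = self._new(name, seq2)
        b.reference_name = chrom
        b.reference_start = pos2
        b.mapping_quality = mapq
        b.cigarstring = f"{L2}M"
        b.is_paired = True
        b.is_read2 = True
        b.is_proper_pair = True
        b.is_reverse = True
        b.next_reference_name = chrom
        b.next_reference_start = pos1
        self.fh.write(a)
        self.fh.write(b)

    def write_unmapped_pair(self, name, seq1, seq2, quals1=None, quals2=None):
        a = self._new(name, seq1, quals1)
        a.is_unmapped = True
        a.is_paired = True
        a.is_read1 = True
        a.mate_is_unmapped = True
        b = self._new(name, seq2, quals2)
        b.is_unmapped = True
        b.is_paired = True
        b.is_read2 = True
        b.mate_is_unmapped = True
        self.fh.write(a)
        self.fh.write(b)

    def write_discordant_pair(self, name, chrom, anchor_pos, anchor_seq, tel_seq, anchor_reverse=False):
        a = self._new(name, anchor_seq)
        a.reference_name = chrom
        a.reference_start = anchor_pos
        a.mapping_quality = 60
        a.cigarstring = f"{len(anchor_seq)}M"
        a.is_paired = True
        a.is_read1 = True
        a.is_reverse = anchor_reverse
        a.mate_is_unmapped = True
        b = self._new(name, tel_seq)
        b.is_unmapped = True
        b.is_paired = True
        b.is_read2 = True
        # unmapped mate is placed at the anchor position per SAM convention
        b.reference_name = chrom
        b.reference_start = anchor_pos
        b.next_reference_name = chrom
        b.next_reference_start = anchor_pos
        self.fh.write(a)
        self.fh.write(b)

    def write_split_read(self, name, chrom, junction, aligned_seq, clipped_seq, clip_side):
        """A junction-spanning read encoded as a soft-clipped alignment.

        ``clip_side`` "right": alignment ends at the junction, clip follows;
        "left": alignment starts at the junction, clip precedes it.
        """
        m, s = len(aligned_seq), len(clipped_seq)
        a = self._new(name, aligned_seq + clipped_seq if clip_side == "right" else clipped_seq + aligned_seq)
        a.reference_name = chrom
        a.mapping_quality = 60
        if clip_side == "right":
            a.reference_start = junction - m
            a.cigarstring = f"{m}M{s}S"
        else:
            a.reference_start = junction
            a.cigarstring = f"{s}S{m}M"
        a.is_paired = True
        a.is_read1 = True
        a.mate_is_unmapped = True
        self.fh.write(a)


def _emit_insertion_evidence(
    writer: _SamWriter,
    ins: PlantedInsertion,
    idx: int,
    ref: dict[str, str],
    read_length: int,
    rng: np.random.Generator,
    n_pairs: int,
    n_splits: int,
    prefix: str,
) -> None:
    L = read_length
    chrom_seq = ref[ins.chrom]
    tel_side = "right" if ins.orientation == "telomere-right" else "left"
    for k in range(n_pairs):
        gap = 50 + int(rng.integers(0, 350))
        if tel_side == "right":
            start = max(0, ins.position - L - gap)
            anchor_reverse = False
        else:
            start = min(len(chrom_seq) - L, ins.position + gap)
            anchor_reverse = True
        anchor_seq = chrom_seq[start : start + L]
        tel_seq = _telomere_run(L, ins.repeat_strand, tel_side)
        writer.write_discordant_pair(
            f"{prefix}ins{idx}_dp{k}", ins.chrom, start, anchor_seq, tel_seq, anchor_reverse
        )
    clip_len = L // 2
    m = L - clip_len
    for k in range(n_splits):
        clipped = _telomere_run(clip_len, ins.repeat_strand, tel_side)
        if tel_side == "right":
            aligned = chrom_seq[ins.position - m : ins.position]
            writer.write_split_read(f"{prefix}ins{idx}_sp{k}", ins.chrom, ins.position, aligned, clipped, "right")
        else:
            aligned = chrom_seq[ins.position : ins.position + m]
            writer.write_split_read(f"{prefix}ins{idx}_sp{k}", ins.chrom, ins.position, aligned, clipped, "left")


def _emit_sample(
    writer: _SamWriter,
    config: SimulationConfig,
    ref: dict[str, str],
    rng: np.random.Generator,
    telomere_fraction: float,
    is_tumor: bool,
    prefix: str,
) -> None:
    L = config.read_length
    contigs = list(config.contigs)
    names = [c[0] for c in contigs]
    lengths = np.array([c[1] for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    n_pairs = config.n_background_reads // 2
    n_tel_pairs = int(rng.binomial(n_pairs, telomere_fraction)) if telomere_fraction > 0 else 0
    n_bg_pairs = n_pairs - n_tel_pairs
    for i in range(n_bg_pairs):
        ci = int(rng.choice(len(contigs), p=weights))
        chrom, clen = contigs[ci]
        pos1 = int(rng.integers(0, max(1, clen - 2 * L - 400)))
        pos2 = pos1 + L + int(rng.integers(50, 350))
        gc = 0.5 if rng.random() < config.gc_bin_fraction else 0.3
        seq1 = _background_sequences(1, L, gc, rng)[0]
        gc2 = 0.5 if rng.random() < config.gc_bin_fraction else 0.3
        seq2 = _background_sequences(1, L, gc2, rng)[0]
        writer.write_mapped_pair(f"{prefix}bg{i:07d}", chrom, pos1, seq1, pos2, seq2)
    for i in range(n_tel_pairs):
        seqs = []
        for _ in range(2):
            seq, _q = generate_telomere_read(
                L,
                tvr_rates=config.tvr_rates,
                rng=rng,
                singleton=_pick_singleton(config.singleton_rates, rng),
                c_strand=bool(rng.random() < 0.5),
            )
            seqs.append(seq)
        writer.write_unmapped_pair(f"{prefix}tel{i:07d}", seqs[0], seqs[1])
    for idx, ins in enumerate(config.planted_insertions):
        if is_tumor:
            _emit_insertion_evidence(
                writer, ins, idx, ref, L, rng, ins.n_discordant_pairs, ins.n_split_reads, prefix
            )
        elif ins.n_control_discordant > 0:
            _emit_insertion_evidence(
                writer, ins, idx, ref, L, rng, ins.n_control_discordant, 0, prefix
            )


def generate_sample_pair(config: SimulationConfig, outdir: str | Path) -> SamplePair:
    """Write a tumor/control SAM pair, FASTA reference, and truth table.

    The truth table has one row per planted insertion with its coordinates,
    support counts, and whether the caller's printed thresholds (>=3 discordant
    pairs, >=3 split reads, no control support, recurrent in <15 panel
    controls) should recover it (column ``expected_called``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref_path = outdir / "reference.fa"
    ref = _write_reference(ref_path, config.contigs, rng)
    tumor_path = outdir / "tumor.sam"
    control_path = outdir / "control.sam"
    # independent child streams keep tumor and control draws decoupled
    rng_t, rng_c = rng.spawn(2)
    wt = _SamWriter(tumor_path, config.contigs)
    _emit_sample(wt, config, ref, rng_t, config.telomere_fraction_tumor, True, "t_")
    wt.close()
    wc = _SamWriter(control_path, config.contigs)
    _emit_sample(wc, config, ref, rng_c, config.telomere_fraction_control, False, "c_")
    wc.close()
    rows = []
    for idx, ins in enumerate(config.planted_insertions):
        rows.append(
            {
                "insertion_id": idx,
                "chrom": ins.chrom,
                "position": ins.position,
                "orientation": ins.orientation,
                "repeat_strand": ins.repeat_strand,
                "n_discordant_pairs": ins.n_discordant_pairs,
                "n_split_reads": ins.n_split_reads,
                "n_control_discordant": ins.n_control_discordant,
                "panel_recurrence": ins.panel_recurrence,
                "partner": -1 if ins.partner is None else ins.partner,
                "expected_called": (
                    ins.n_discordant_pairs >= 3
                    and ins.n_split_reads >= 3
                    and ins.n_control_discordant == 0
                    and ins.panel_recurrence < 15
                ),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "insertion_id", "chrom", "position", "orientation", "repeat_strand",
            "n_discordant_pairs", "n_split_reads", "n_control_discordant",
            "panel_recurrence", "partner", "expected_called",
        ],
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return SamplePair(tumor_sam=tumor_path, control_sam=control_path, reference_fasta=ref_path, truth=truth)


def build_control_panel(
    config: SimulationConfig, n_panel: int = 20
) -> list[dict[str, list[tuple[int, int]]]]:
    """Per-control discordant-anchor interval sets for the recurrence filter.

    Each planted insertion with ``panel_recurrence`` r appears as a 1-kb
    discordant region in the first r of the ``n_panel`` controls.
    """
    panel: list[dict[str, list[tuple[int, int]]]] = [dict() for _ in range(n_panel)]
    for ins in config.planted_insertions:
        span = (max(0, ins.position - 500), ins.position + 500)
        for i in range(min(ins.panel_recurrence, n_panel)):
            panel[i].setdefault(ins.chrom, []).append(span)
    return panel


# --- classifier cohort -------------------------------------------------------

CLASSIFIER_FEATURES: tuple[str, ...] = (
    "content_log2_ratio",
    "n_telomere_insertions",
    "n_breakpoints",
    "divergence_TGAGGG",
    "divergence_TCAGGG",
    "divergence_TTGGGG",
    "divergence_TTCGGG",
    "divergence_TTTGGG",
)

#: Sign of the ALT-minus-telomerase mean shift for each feature: ALT samples
#: have higher content ratios, more insertions and breakpoints, positive
#: divergence of TTCGGG/TGAGGG/TCAGGG/TTGGGG singletons and negative TTTGGG
#: divergence.
EFFECT_DIRECTIONS: dict[str, float] = {
    "content_log2_ratio": +1.0,
    "n_telomere_insertions": +1.0,
    "n_breakpoints": +1.0,
    "divergence_TGAGGG": +1.0,
    "divergence_TCAGGG": +1.0,
    "divergence_TTGGGG": +1.0,
    "divergence_TTCGGG": +1.0,
    "divergence_TTTGGG": -1.0,
}


def paper_shaped_effects(scale: float) -> dict[str, float]:
    """Effect-size map with the observed ALT-vs-telomerase directions scaled
    by ``scale`` (in units of the within-class standard deviation)."""
    return {f: scale * d for f, d in EFFECT_DIRECTIONS.items()}


def generate_cohort_features(
    n_alt: int,
    n_tert: int,
    effect_sizes: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the 8 classifier features from two class-conditional Gaussians.

    The telomerase (TERT_mod) class is centered at zero with unit variance per
    feature; the ALT (ATRX_DAXX_trunc) class mean is shifted by
    ``effect_sizes`` (zero map makes the classes exchangeable). Returns the
    feature matrix indexed by sample_id and the label series.
    """
    if n_alt < 2 or n_tert < 2:
        raise ValueError("need at least two samples per class")
    effect_sizes = effect_sizes or {}
    rng = np.random.default_rng(seed)
    shift = np.array([effect_sizes.get(f, 0.0) for f in CLASSIFIER_FEATURES])
    x_tert = rng.standard_normal((n_tert, len(CLASSIFIER_FEATURES)))
    x_alt = rng.standard_normal((n_alt, len(CLASSIFIER_FEATURES))) + shift
    X = pd.DataFrame(
        np.vstack([x_alt, x_tert]),
        columns=list(CLASSIFIER_FEATURES),
        index=[f"ALT{i:04d}" for i in range(n_alt)] + [f"TERT{i:04d}" for i in range(n_tert)],
    )
    X.index.name = "sample_id"
    y = pd.Series(
        ["ATRX_DAXX_trunc"] * n_alt + ["TERT_mod"] * n_tert, index=X.index, name="label"
    )
    return X, y
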