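"""REF/ALT flanking-sequence construction and motif scanning for variants.

For each credible-set variant (SNV or indel) the ±30 bp flanking
sequences are built for both alleles; by construction the two sequences
share their flanks exactly and differ only in the allele itself. Each
sequence is scanned against every discovered motif with log-odds (base
2) scores and *exact* null p-values obtained by dynamic-programming
convolution of the discretized per-position score distributions under an
order-0 background — the FIMO role. The best hit over all windows and
both strands gives the per-allele (score, p) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import io as tio
from .intervals import GenomicInterval
from .motifs import BackgroundModel, Pwm, significance_threshold
from .sequences import N_CODE, encode

logger = logging.getLogger(__name__)

_COMP = np.array([3, 2, 1, 0, 4])
_VALID_BASES = frozenset("ACGT")


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """A normalized variant: minimal alleles, 0-based first affected base.

    After normalization an insertion has an empty ``ref_allele`` and a
    deletion an empty ``alt_allele`` (the dash-notation convention,
    e.g. rs138300818 ``-/G``).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        if not self.ref_allele and not self.alt_allele:
            raise VariantError(f"{self.id}: both alleles empty (null variant)")
        for allele in (self.ref_allele, self.alt_allele):
            if allele and not set(allele) <= _VALID_BASES:
                raise VariantError(f"{self.id}: non-ACGT allele {allele!r}")
        if self.pos < 0:
            raise VariantError(f"{self.id}: negative position")

    @property
    def dash_ref(self) -> str:
        return self.ref_allele or "-"

    @property
    def dash_alt(self) -> str:
        return self.alt_allele or "-"


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str, id: str = "."
) -> Variant:
    """Trim shared leading/trailing bases to the minimal representation.

    ``pos`` is the 0-based position of the first REF base (or, for a
    dash-notation insertion, the insertion point). ``"-"`` or ``""``
    denotes an empty allele.
    """
    ref = "" if ref in ("-", "") else ref.upper()
    alt = "" if alt in ("-", "") else alt.upper()
    if ref == alt:
        raise VariantError(f"{id}: REF and ALT alleles are identical")
    for allele in (ref, alt):
        if allele and not set(allele) <= _VALID_BASES:
            raise VariantError(f"{id}: non-ACGT allele {allele!r}")
    # trim shared suffix first, then prefix (advancing pos)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(chrom, pos, ref, alt, id)


@dataclass(frozen=True)
class AllelePair:
    """REF and ALT flanking sequences for one variant.

    The flanks of the two sequences are identical strings; the sequences
    differ only by the substituted allele.
    """

    variant: Variant
    seq_ref: str
    seq_alt: str
    flank: int = 30

    def __post_init__(self) -> None:
        v = self.variant
        if len(self.seq_ref) != 2 * self.flank + len(v.ref_allele):
            raise VariantError(f"{v.id}: REF sequence length mismatch")
        if len(self.seq_alt) != 2 * self.flank + len(v.alt_allele):
            raise VariantError(f"{v.id}: ALT sequence length mismatch")
        up_r, down_r = self.seq_ref[: self.flank], self.seq_ref[len(self.seq_ref) - self.flank :]
        up_a, down_a = self.seq_alt[: self.flank], self.seq_alt[len(self.seq_alt) - self.flank :]
        if up_r != up_a or down_r != down_a:
            raise VariantError(f"{v.id}: allele pair flanks differ")


def extract_allele_sequences(
    variant: Variant, genome, flank: int = 30
) -> AllelePair:
    """Build the ±``flank`` bp REF and ALT sequences around a variant.

    Errors if the genome does not carry the REF allele at the variant
    position.
    """
    v = variant
    ref_len = len(v.ref_allele)
    if v.pos - flank < 0:
        raise VariantError(f"{v.id}: variant closer than {flank} bp to contig start")
    upstream = tio.fetch_sequence(
        genome, GenomicInterval(v.chrom, v.pos - flank, v.pos)
    )
    downstream = tio.fetch_sequence(
        genome, GenomicInterval(v.chrom, v.pos + ref_len, v.pos + ref_len + flank)
    )
    if ref_len:
        observed = tio.fetch_sequence(
            genome, GenomicInterval(v.chrom, v.pos, v.pos + ref_len)
        )
        if observed != v.ref_allele:
            raise VariantError(
                f"{v.id}: genome has {observed!r} at {v.chrom}:{v.pos}, "
                f"expected REF {v.ref_allele!r}"
            )
    return AllelePair(
        v,
        upstream + v.ref_allele + downstream,
        upstream + v.alt_allele + downstream,
        flank,
    )


# ---------------------------------------------------------------------------
# log-odds scoring with exact null p-values


def log_odds(pwm: Pwm, bg: BackgroundModel) -> np.ndarray:
    """Base-2 log-odds matrix ``entry[b, i] = log2(probs[b, i] / bg[b])``."""
    if bg.order != 0:
        raise ValueError("scanning background must be order 0")
    if np.any(bg.freq0 <= 0):
        raise ValueError("background frequencies must be positive")
    return np.log2(pwm.probs / bg.freq0[:, None])


class ScoreTable:
    """Discretized log-odds matrix with its exact null tail distribution.

    The log-odds matrix is rounded onto an integer grid with
    ``resolution`` steps spanning the [min, max] achievable score range;
    the distribution of the integer window score under the order-0
    background is then obtained exactly by per-position convolution, so
    ``p(score ≥ s)`` is exact on the grid (the classic PWM p-value DP).
    """

    def __init__(self, pwm: Pwm, bg: BackgroundModel, resolution: int = 1000):
        if resolution < 100:
            raise ValueError("resolution must be ≥ 100")
        self.pwm = pwm
        self.bg = bg
        lo = log_odds(pwm, bg)
        self.lo = lo
        col_min = lo.min(axis=0)
        span = float(lo.max(axis=0).sum() - col_min.sum())
        self.step = span / resolution if span > 0 else 1.0
        self.offset = float(col_min.sum())
        self.int_matrix = np.rint((lo - col_min[None, :]) / self.step).astype(np.int64)
        tmax = int(self.int_matrix.max(axis=0).sum())
        dist = np.zeros(tmax + 1)
        dist[0] = 1.0
        for i in range(pwm.width):
            nxt = np.zeros_like(dist)
            for b in range(4):
                s = self.int_matrix[b, i]
                nxt[s:] += bg.freq0[b] * dist[: len(dist) - s if s else None]
            dist = nxt
        self.tail = np.cumsum(dist[::-1])[::-1]  # P(int score >= t)
        self.tail = np.minimum(self.tail, 1.0)

    def p_for_int(self, t: int) -> float:
        t = max(0, min(int(t), len(self.tail) - 1))
        return float(self.tail[t])

    def p_for_score(self, score: float) -> float:
        """Tail p-value for a real-valued score (mapped onto the grid)."""
        t = int(np.rint((score - self.offset) / self.step))
        return self.p_for_int(t)


def score_pvalue_table(
    pwm: Pwm, bg: BackgroundModel, resolution: int = 1000
) -> ScoreTable:
    """Exact null score→p mapping for one motif (see :class:`ScoreTable`)."""
    return ScoreTable(pwm, bg, resolution)


@dataclass
class BestHit:
    score: float
    p_value: float
    strand: str
    offset: int


def best_hit(
    pwm: Pwm,
    seq: str,
    bg: BackgroundModel,
    both_strands: bool = True,
    table: ScoreTable | None = None,
) -> BestHit:
    """Maximal log-odds hit of a motif in a sequence, with its exact p.

    Windows containing N are skipped. Ties prefer the forward strand,
    then the smallest offset. A sequence shorter than the motif (or with
    no N-free window) yields the sentinel (−inf, p=1).
    """
    if table is None:
        table = ScoreTable(pwm, bg)
    w = pwm.width
    codes = encode(seq)
    if len(codes) < w:
        logger.warning("sequence shorter than motif width %d; no hit", w)
        return BestHit(float("-inf"), 1.0, "+", -1)
    Xw = sliding_window_view(codes, w)
    valid = ~np.any(Xw == N_CODE, axis=-1)
    if not valid.any():
        return BestHit(float("-inf"), 1.0, "+", -1)
    im = np.zeros((5, w), dtype=np.int64)
    im[:4] = table.int_matrix
    ints_f = im[Xw, np.arange(w)].sum(axis=-1)
    ints_f = np.where(valid, ints_f, -1)
    best_t = int(ints_f.max())
    strand, offset = "+", int(np.argmax(ints_f))
    if both_strands:
        im_rc = np.zeros((5, w), dtype=np.int64)
        im_rc[:4] = table.int_matrix[::-1, ::-1]
        ints_r = im_rc[Xw, np.arange(w)].sum(axis=-1)
        ints_r = np.where(valid, ints_r, -1)
        if int(ints_r.max()) > best_t:
            best_t = int(ints_r.max())
            strand, offset = "-", int(np.argmax(ints_r))
    # exact float score at the chosen window
    lo = np.zeros((5, w))
    lo[:4] = table.lo if strand == "+" else table.lo[::-1, ::-1]
    score = float(lo[Xw[offset], np.arange(w)].sum())
    return BestHit(score, table.p_for_int(best_t), strand, offset)


@dataclass
class ScanResult:
    """Best-hit comparison of one variant's alleles against one motif."""

    variant_id: str
    motif_id: str
    dataset_id: str
    p_ref: float
    p_alt: float
    sc_ref: float
    sc_alt: float
    strand_ref: str
    strand_alt: str
    offset_ref: int
    offset_alt: int
    significant_overlap: bool = False


def scan_variants(
    pairs: Sequence[AllelePair],
    motifs_by_dataset: Mapping[str, Sequence[Pwm]],
    bg_by_dataset: Mapping[str, BackgroundModel],
    alpha: float = 0.01,
    resolution: int = 1000,
) -> list[ScanResult]:
    """Scan every allele pair against every dataset's motifs.

    One :class:`ScanResult` per (variant × motif × dataset). A pair is
    flagged as significant overlap when ``min(p_ref, p_alt)`` beats the
    Bonferroni bound ``alpha / n_motifs / n_variants`` (n_motifs summed
    over datasets, as all motifs are tested against all variants).
    """
    n_motifs_total = sum(len(m) for m in motifs_by_dataset.values())
    n_variants = len(pairs)
    if n_motifs_total and n_variants:
        bound = significance_threshold(alpha, [n_motifs_total, n_variants])
    else:
        bound = 0.0
    results = []
    for dataset_id, motifs in motifs_by_dataset.items():
        bg = bg_by_dataset[dataset_id]
        for pwm in motifs:
            table = ScoreTable(pwm, bg, resolution)
            for pair in pairs:
                hr = best_hit(pwm, pair.seq_ref, bg, table=table)
                ha = best_hit(pwm, pair.seq_alt, bg, table=table)
                results.append(
                    ScanResult(
                        pair.variant.id,
                        pwm.name,
                        dataset_id,
                        hr.p_value,
                        ha.p_value,
                        hr.score,
                        ha.score,
                        hr.strand,
                        ha.strand,
                        hr.offset,
                        ha.offset,
                        min(hr.p_value, ha.p_value) < bound,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# variant file interfaces


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a VCF 4.x subset (CHROM POS ID REF ALT); positions 1-based."""
    variants = []
    with tio._open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise VariantError(f"{path}:{lineno}: fewer than 5 VCF columns")
            chrom, pos1, vid, ref, alts = fields[:5]
            for alt in alts.split(","):
                variants.append(
                    normalize_variant(chrom, int(pos1) - 1, ref, alt, vid)
                )
    return variants


def read_dash_table(path: str | Path) -> list[Variant]:
    """Read a dash-notation variant table: id, chrom, pos (0-based), ref, alt."""
    variants = []
    with tio._open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("id", "chrom", "pos", "ref", "alt"):
            if name not in idx:
                raise VariantError(f"{path}: missing column {name!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            variants.append(
                normalize_variant(
                    f[idx["chrom"]],
                    int(f[idx["pos"]]),
                    f[idx["ref"]],
                    f[idx["alt"]],
                    f[idx["id"]],
                )
            )
    return variants


SCAN_COLUMNS = [
    "variant_id",
    "motif_id",
    "dataset_id",
    "p_ref",
    "p_alt",
    "sc_ref",
    "sc_alt",
    "strand_ref",
    "strand_alt",
    "offset_ref",
    "offset_alt",
    "significant_overlap",
]


def write_scan_table(path: str | Path, results: Sequence[ScanResult]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SCAN_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.motif_id,
                        r.dataset_id,
                        f"{r.p_ref:.3e}",
                        f"{r.p_alt:.3e}",
                        f"{r.sc_ref:.3f}",
                        f"{r.sc_alt:.3f}",
                        r.strand_ref,
                        r.strand_alt,
                        str(r.offset_ref),
                        str(r.offset_alt),
                        str(int(r.significant_overlap)),
                    ]
                )
                + "\n"
            )


def read_scan_table(path: str | Path) -> list[ScanResult]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == SCAN_COLUMNS, f"unexpected scan table header in {path}"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ScanResult(
                    f[0], f[1], f[2],
                    float(f[3]), float(f[4]), float(f[5]), float(f[6]),
                    f[7], f[8], int(f[9]), int(f[10]), bool(int(f[11])),
                )
            )
    return out
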