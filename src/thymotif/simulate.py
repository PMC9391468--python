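"""Synthetic input bundle with known ground truth.

Generates everything the pipeline consumes — genome FASTA, exon GFF3,
per-sample histone peak calls with fold changes and q-values, an RNA
coverage bedGraph, and a credible-set VCF — with planted motif instances
and variants of known allelic effect, so every stage is testable with no
download. The bundle emulates the statistical structure of thymocyte
ChIP-seq data: enhancer-scale peaks (hundreds of bp) with
gamma-distributed fold changes, RNA coverage elevated in active regions,
PWM instances planted in a fraction of enhancers, and variants that
destroy planted sites (SNV at a high-information column, deletions) or
create one on the ALT allele (the 1 bp creator-insertion pattern of
rs138300818). A machine-readable truth table labels every variant.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from . import io as tio
from .intervals import CoverageTrack, GenomicInterval, IntervalSet
from .motifs import Pwm
from .peaks import PeakCall
from .scan import Variant
from .sequences import decode, encode


@dataclass
class SimConfig:
    """The stated synthetic world. Defaults give 2 × 200 kb chromosomes,
    200 enhancers, one planted 12 bp motif at ~1.5 bits/column, 100
    variants of which 10% are disruptive."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    gc_content: float = 0.41
    exon_fraction: float = 0.10
    exon_length: int = 200
    n_enhancers: int = 200
    enhancer_min_len: int = 200
    enhancer_max_len: int = 600
    pwm_width: int = 12
    pwm_ic_per_column: float = 1.5
    n_planted_pwms: int = 1
    plant_rate: float = 0.7
    cell_type: str = "thymoDP"
    hist_mods: tuple[str, ...] = ("H3K27ac",)
    n_samples: int = 2
    peak_jitter: int = 20
    fc_gamma_shape: float = 2.0
    fc_gamma_scale: float = 3.0
    fraction_failing: float = 0.1
    fraction_silent: float = 0.05
    coverage_in: float = 5.0
    coverage_out: float = 0.0
    n_variants: int = 100
    fraction_disruptive: float = 0.10
    #: disruptive variant types, cycled: "ins" (creator insertion, the
    #: rs138300818 pattern), "del" (site-destroying deletion), "snv"
    #: (substitution at the highest-information column — included on
    #: request only, since a one-column dent leaves the match intact
    #: and the score statistic is documented to be insensitive to it)
    disruptive_kinds: tuple[str, ...] = ("ins", "del")
    indel_min_len: int = 1
    indel_max_len: int = 12
    neutral_indel_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("gc_content", "exon_fraction", "plant_rate",
                     "fraction_failing", "fraction_silent",
                     "fraction_disruptive", "neutral_indel_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("chrom_length", "n_enhancers", "enhancer_min_len",
                     "pwm_width", "n_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Ground-truth label for one simulated variant."""

    variant_id: str
    is_disruptive: bool
    affected_motif: str = ""
    direction: str = ""  # "REF" or "ALT": which allele carries the intact site

    def __post_init__(self) -> None:
        if self.is_disruptive and not self.affected_motif:
            raise ValueError(f"{self.variant_id}: disruptive but no affected motif")


@dataclass
class PlantedSite:
    chrom: str
    start: int
    pwm_name: str
    strand: str


def make_planted_pwm(
    width: int,
    ic_per_column: float,
    rng: np.random.Generator,
    name: str = "planted_1",
) -> Pwm:
    """A PWM with one dominant base per column at the requested
    per-column information content (bits, relative to uniform)."""

    def ic_of(p: float) -> float:
        q = (1 - p) / 3
        return 2 + p * np.log2(p) + 3 * q * np.log2(q)

    p = brentq(lambda x: ic_of(x) - ic_per_column, 0.2501, 1 - 1e-9)
    probs = np.full((4, width), (1 - p) / 3)
    consensus = rng.integers(0, 4, size=width)
    probs[consensus, np.arange(width)] = p
    return Pwm(probs, name=name)


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], IntervalSet]:
    """I.i.d. background genome at the stated GC plus non-overlapping
    exon features covering roughly ``exon_fraction`` of each chromosome."""
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    exons = []
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        genome[chrom] = rng.choice(4, size=config.chrom_length, p=base_p).astype(
            np.int8
        )
        n_exons = int(config.exon_fraction * config.chrom_length / config.exon_length)
        # regular grid with random offsets keeps exons non-overlapping
        stride = config.chrom_length // max(n_exons, 1)
        for k in range(n_exons):
            lo = k * stride
            start = int(rng.integers(lo, lo + stride - config.exon_length))
            exons.append(GenomicInterval(chrom, start, start + config.exon_length))
    return genome, IntervalSet(exons)


def _overlaps(occupied: list[tuple[str, int, int]], chrom: str, s: int, e: int) -> bool:
    return any(c == chrom and s < oe and os_ < e for c, os_, oe in occupied)


def _place(
    rng: np.random.Generator,
    config: SimConfig,
    occupied: list[tuple[str, int, int]],
    span: int,
    margin: int,
    max_tries: int = 2000,
) -> tuple[str, int]:
    for _ in range(max_tries):
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        start = int(rng.integers(margin, config.chrom_length - span - margin))
        if not _overlaps(occupied, chrom, start - margin, start + span + margin):
            occupied.append((chrom, start, start + span))
            return chrom, start
    raise RuntimeError("insufficient free genome space for placement")


@dataclass
class PlantResult:
    enhancers: IntervalSet
    active: list[bool]  # RNA-active flag per enhancer
    sites: list[PlantedSite]
    pwms: list[Pwm]
    sample_peaks: dict[tuple[str, str, str], list[PeakCall]]
    coverage: CoverageTrack
    expected_n_peaks: dict[str, int]  # dataset id -> truth peak count


def plant_and_peak(
    config: SimConfig,
    genome: dict[str, np.ndarray],
    exons: IntervalSet,
    rng: np.random.Generator,
) -> PlantResult:
    """Place enhancers, plant motif sites, and emit per-sample peak calls
    plus RNA coverage.

    Enhancers avoid exons (with margin for the downstream 20 bp peak
    flank); each receives a planted PWM instance with probability
    ``plant_rate``. Per-sample peaks are the enhancer intervals with
    edge jitter, gamma fold changes and q-values drawn so that about
    ``fraction_failing`` of calls fail the fold-change/q filter.
    ``fraction_silent`` of enhancers get no RNA coverage, so their peaks
    fail the RNA-activity gate when ``coverage_out < 0.001``.
    """
    occupied = [(iv.chrom, iv.start, iv.end) for iv in exons]
    # neighbours must stay apart even after both are jittered outward and
    # padded by the 20 bp peak flank, or pooling would fuse them and break
    # the per-enhancer peak-count bookkeeping
    margin = 2 * (config.peak_jitter + 20) + 10
    enhancers: list[GenomicInterval] = []
    for _ in range(config.n_enhancers):
        length = int(
            rng.integers(config.enhancer_min_len, config.enhancer_max_len + 1)
        )
        chrom, start = _place(rng, config, occupied, length, margin)
        enhancers.append(GenomicInterval(chrom, start, start + length))

    pwms = [
        make_planted_pwm(
            config.pwm_width, config.pwm_ic_per_column, rng, name=f"planted_{k + 1}"
        )
        for k in range(config.n_planted_pwms)
    ]
    sites: list[PlantedSite] = []
    for iv in enhancers:
        if rng.random() >= config.plant_rate:
            continue
        pwm = pwms[int(rng.integers(len(pwms)))]
        w = pwm.width
        pos = int(rng.integers(iv.start + 5, iv.end - w - 5))
        site = np.array(
            [rng.choice(4, p=pwm.probs[:, i]) for i in range(w)], dtype=np.int8
        )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = np.array([3, 2, 1, 0], dtype=np.int8)[site][::-1]
        genome[iv.chrom][pos : pos + w] = site
        sites.append(PlantedSite(iv.chrom, pos, pwm.name, strand))

    active = [rng.random() >= config.fraction_silent for _ in enhancers]
    # coverage: elevated over active enhancers, baseline elsewhere
    cov_records: list[tuple[str, int, int, float]] = []
    if config.coverage_out > 0:
        boundaries: dict[str, list[tuple[int, int]]] = {}
        for iv, act in zip(enhancers, active):
            if act:
                boundaries.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom in genome:
            pos = 0
            for s, e in sorted(boundaries.get(chrom, [])):
                if s > pos:
                    cov_records.append((chrom, pos, s, config.coverage_out))
                cov_records.append((chrom, s, e, config.coverage_in))
                pos = e
            if pos < config.chrom_length:
                cov_records.append((chrom, pos, config.chrom_length, config.coverage_out))
    else:
        for iv, act in zip(enhancers, active):
            if act:
                cov_records.append((iv.chrom, iv.start, iv.end, config.coverage_in))
    coverage = CoverageTrack.from_records(cov_records)

    sample_peaks: dict[tuple[str, str, str], list[PeakCall]] = {}
    surviving: dict[str, set[int]] = {}
    for mod in config.hist_mods:
        dataset_id = f"{config.cell_type}.{mod}"
        surviving[dataset_id] = set()
        for s in range(config.n_samples):
            sample_id = f"{config.cell_type}_{mod}_rep{s + 1}"
            calls = []
            for ei, iv in enumerate(enhancers):
                jl = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                jr = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                start = max(0, iv.start + jl)
                end = min(config.chrom_length, iv.end + jr)
                fc = float(rng.gamma(config.fc_gamma_shape, config.fc_gamma_scale))
                fails = rng.random() < config.fraction_failing
                if fails:
                    # fail via the q-value arm of the filter
                    q = float(rng.uniform(1.01e-4, 1.0))
                else:
                    fc = max(fc, 3.0)
                    q = float(10.0 ** -rng.uniform(4.1, 12.0))
                calls.append(
                    PeakCall(
                        GenomicInterval(iv.chrom, start, end),
                        fc,
                        q,
                        sample_id,
                        config.cell_type,
                        mod,
                    )
                )
                if not fails and fc >= 3.0 and q < 1e-4 and active[ei]:
                    surviving[dataset_id].add(ei)
            sample_peaks[(config.cell_type, mod, sample_id)] = calls
    expected = {ds: len(idx) for ds, idx in surviving.items()}
    return PlantResult(
        IntervalSet(enhancers), active, sites, pwms, sample_peaks, coverage, expected
    )


_COMP4 = np.array([3, 2, 1, 0], dtype=np.int8)


def simulate_variants(
    config: SimConfig,
    genome: dict[str, np.ndarray],
    sites: Sequence[PlantedSite],
    pwms: Sequence[Pwm],
    rng: np.random.Generator,
) -> tuple[list[Variant], list[TruthRecord]]:
    """Place labeled variants: disruptive ones at planted sites (or as
    creator insertions in background), the rest neutral in background.

    Disruptive types cycle through ``config.disruptive_kinds``:
    ``"ins"`` — a 1 bp creator insertion whose ALT allele completes an
    otherwise-broken consensus (ALT intact, the rs138300818 pattern);
    ``"del"`` — a deletion destroying a planted site's alignment (REF
    intact); ``"snv"`` — a substitution at the site's highest-
    information column (REF intact; note this dents rather than
    destroys the match and is excluded from the default mix).
    """
    pwm_by_name = {p.name: p for p in pwms}
    n_disruptive = round(config.fraction_disruptive * config.n_variants)
    if n_disruptive > len(sites) + config.n_variants:
        raise ValueError("not enough planted sites for disruptive variants")
    occupied = [(s.chrom, s.start - 40, s.start + 40) for s in sites]
    site_pool = list(rng.permutation(len(sites)))
    variants: list[Variant] = []
    truth: list[TruthRecord] = []
    kinds = list(config.disruptive_kinds)
    if not set(kinds) <= {"ins", "del", "snv"}:
        raise ValueError(f"unknown disruptive kind in {kinds}")
    for k in range(n_disruptive):
        vid = f"var{k + 1:04d}"
        kind = kinds[k % len(kinds)]
        if kind != "ins" and not site_pool:
            kind = "ins"
        if kind == "ins":
            pwm = pwms[int(rng.integers(len(pwms)))]
            w = pwm.width
            consensus = encode(pwm.consensus)
            chrom, start = _place(rng, config, occupied, w, margin=60)
            # drop a central base so both REF half-sites are short and
            # the REF partial is a genuinely broken match
            drop = int(rng.integers((w - 1) // 2, w // 2 + 2))
            partial = np.delete(consensus, drop)
            genome[chrom][start : start + w - 1] = partial
            pos = start + drop
            alt = decode(consensus[drop : drop + 1])
            variants.append(Variant(chrom, pos, "", alt, vid))
            truth.append(TruthRecord(vid, True, pwm.name, "ALT"))
            continue
        si = site_pool.pop()
        site = sites[si]
        pwm = pwm_by_name[site.pwm_name]
        w = pwm.width
        ic = pwm.information_content()
        if kind == "snv":
            # destroy at the most informative column where the sampled
            # site actually carries the consensus base (sampling noise
            # can have pre-dented the top column, in which case any
            # substitution there could improve the match)
            consensus = np.argmax(pwm.probs, axis=0)
            col = int(np.argmax(ic))
            for c in np.argsort(-ic):
                gp = site.start + (c if site.strand == "+" else w - 1 - c)
                expect = (
                    consensus[c]
                    if site.strand == "+"
                    else int(_COMP4[consensus[c]])
                )
                if int(genome[site.chrom][gp]) == expect:
                    col = int(c)
                    break
            # genome position of motif column `col`; minus-strand sites
            # are stored reverse-complemented
            gpos = (
                site.start + col
                if site.strand == "+"
                else site.start + w - 1 - col
            )
            ref_code = int(genome[site.chrom][gpos])
            worst = int(np.argmin(pwm.probs[:, col]))
            alt_code = worst if site.strand == "+" else int(_COMP4[worst])
            if alt_code == ref_code:
                alt_code = (ref_code + 2) % 4
            variants.append(
                Variant(
                    site.chrom,
                    gpos,
                    decode(np.array([ref_code], dtype=np.int8)),
                    decode(np.array([alt_code], dtype=np.int8)),
                    vid,
                )
            )
        else:  # deletion removing at least half the site
            d = int(
                rng.integers(
                    max(config.indel_min_len, w // 2),
                    min(config.indel_max_len, w) + 1,
                )
            )
            gpos = site.start + (w - d) // 2
            ref = decode(genome[site.chrom][gpos : gpos + d])
            variants.append(Variant(site.chrom, gpos, ref, "", vid))
        truth.append(TruthRecord(vid, True, pwm.name, "REF"))

    for k in range(n_disruptive, config.n_variants):
        vid = f"var{k + 1:04d}"
        if rng.random() < config.neutral_indel_rate:
            d = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                chrom, start = _place(rng, config, occupied, d, margin=60)
                ref = decode(genome[chrom][start : start + d])
                variants.append(Variant(chrom, start, ref, "", vid))
            else:
                chrom, start = _place(rng, config, occupied, 1, margin=60)
                ins = decode(rng.integers(0, 4, size=d).astype(np.int8))
                variants.append(Variant(chrom, start, "", ins, vid))
        else:
            chrom, start = _place(rng, config, occupied, 1, margin=60)
            ref_code = int(genome[chrom][start])
            alt_code = int((ref_code + rng.integers(1, 4)) % 4)
            variants.append(
                Variant(
                    chrom,
                    start,
                    decode(np.array([ref_code], dtype=np.int8)),
                    decode(np.array([alt_code], dtype=np.int8)),
                    vid,
                )
            )
        truth.append(TruthRecord(vid, False))
    return variants, truth


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict[str, np.ndarray]
    exons: IntervalSet
    plant: PlantResult
    variants: list[Variant]
    truth: list[TruthRecord]

    @property
    def genome_str(self) -> dict[str, str]:
        return {c: decode(codes) for c, codes in self.genome.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full plain-text bundle; returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}
        files["genome"] = outdir / "genome.fa"
        tio.write_fasta(files["genome"], self.genome_str)
        files["chrom_sizes"] = outdir / "genome.chrom.sizes"
        tio.write_chrom_sizes(
            files["chrom_sizes"], {c: len(s) for c, s in self.genome.items()}
        )
        files["exons"] = outdir / "exons.gff3"
        tio.write_gff_exons(files["exons"], self.exons)
        files["coverage"] = outdir / "rna_coverage.bedGraph"
        tio.write_bedgraph(files["coverage"], self.plant.coverage)
        peak_files = []
        for (cell, mod, sample), calls in self.plant.sample_peaks.items():
            p = outdir / f"peaks_{sample}.narrowPeak"
            with open(p, "w") as fh:
                for i, c in enumerate(calls):
                    neglog_q = -np.log10(max(c.q_value, 1e-300))
                    fh.write(
                        f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                        f"{sample}_peak{i + 1}\t0\t.\t{c.fold_change:.4f}\t"
                        f"0\t{neglog_q:.4f}\t-1\n"
                    )
            peak_files.append({"path": p.name, "sample": sample, "cell_type": cell,
                               "hist_mod": mod})
        files["variants"] = outdir / "variants.vcf"
        self._write_vcf(files["variants"])
        files["truth"] = outdir / "truth.tsv"
        with open(files["truth"], "w") as fh:
            fh.write("variant_id\tis_disruptive\taffected_motif\tdirection\n")
            for t in self.truth:
                fh.write(
                    f"{t.variant_id}\t{int(t.is_disruptive)}\t"
                    f"{t.affected_motif}\t{t.direction}\n"
                )
        files["planted_pwms"] = outdir / "planted_pwms.meme"
        from .motifs import write_meme

        write_meme(files["planted_pwms"], self.plant.pwms)
        files["manifest"] = outdir / "sim_config.yaml"
        cfg = asdict(self.config)
        cfg["hist_mods"] = list(cfg["hist_mods"])
        cfg["peak_files"] = peak_files
        cfg["expected_n_peaks"] = self.plant.expected_n_peaks
        with open(files["manifest"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
        return files

    def _write_vcf(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c, codes in self.genome.items():
                fh.write(f"##contig=<ID={c},length={len(codes)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in sorted(self.variants, key=lambda v: (v.chrom, v.pos)):
                if v.ref_allele and v.alt_allele:  # SNV / MNV
                    pos1, ref, alt = v.pos + 1, v.ref_allele, v.alt_allele
                else:  # indel: anchor on the preceding base
                    anchor = decode(self.genome[v.chrom][v.pos - 1 : v.pos])
                    pos1 = v.pos  # 1-based position of anchor = v.pos
                    ref = anchor + v.ref_allele
                    alt = anchor + v.alt_allele
                fh.write(f"{v.chrom}\t{pos1}\t{v.id}\t{ref}\t{alt}\t.\tPASS\t.\n")


def simulate_bundle(config: SimConfig | None = None) -> SimBundle:
    """Generate the complete synthetic bundle for a configuration.

    Fully deterministic for a fixed ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genome, exons = simulate_genome(config, rng)
    plant = plant_and_peak(config, genome, exons, rng)
    variants, truth = simulate_variants(config, genome, plant.sites, plant.pwms, rng)
    return SimBundle(config, genome, exons, plant, variants, truth)


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            vid, dis, motif, direction = line.rstrip("\n").split("\t")
            out.append(TruthRecord(vid, bool(int(dis)), motif, direction))
    return out
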