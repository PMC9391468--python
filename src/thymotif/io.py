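"""Readers and writers for the plain-text positional formats.

BED (3+ columns, extras preserved), bedGraph, GFF3 (exon features),
two-column chrom-sizes and FASTA. All tab-separated text, transparently
gzipped. GFF3 coordinates (1-based inclusive) are converted to the
package's internal 0-based half-open convention on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from pyfaidx import Fasta

from .intervals import CoverageTrack, GenomicInterval, IntervalError, IntervalSet


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path) -> tuple[IntervalSet, list[list[str]]]:
    """Read a BED file; returns the intervals and any extra columns.

    ``extras[i]`` holds columns 4+ of record ``i`` (empty list if absent).
    """
    ivs: list[GenomicInterval] = []
    extras: list[list[str]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise IntervalError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except (ValueError, IntervalError) as err:
            raise IntervalError(f"{path}:{lineno}: {err}") from err
        ivs.append(iv)
        extras.append(fields[3:])
    return IntervalSet(ivs), extras


def write_bed(
    path: str | Path,
    intervals: IntervalSet,
    extras: Iterable[Iterable[str]] | None = None,
) -> None:
    rows = list(intervals)
    ex = [list(e) for e in extras] if extras is not None else [[]] * len(rows)
    with _open_text(path, "wt") as fh:
        for iv, cols in zip(rows, ex):
            fields = [iv.chrom, str(iv.start), str(iv.end), *cols]
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise IntervalError(f"{path}:{lineno}: bedGraph needs 4 columns")
        records.append(
            (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
        )
    return CoverageTrack.from_records(records)


def write_bedgraph(path: str | Path, track: CoverageTrack) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in sorted(track.runs):
            for s, e, d in track.runs[chrom]:
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{d:g}\n")


def read_gff_exons(path: str | Path) -> IntervalSet:
    """Exon features from a GFF3 file, converted to 0-based half-open."""
    ivs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise IntervalError(f"{path}:{lineno}: fewer than 5 GFF columns")
        if fields[2].lower() != "exon":
            continue
        start_1based, end_inclusive = int(fields[3]), int(fields[4])
        ivs.append(GenomicInterval(fields[0], start_1based - 1, end_inclusive))
    return IntervalSet(ivs)


def write_gff_exons(path: str | Path, exons: IntervalSet, source: str = "thymotif") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for iv in exons:
            fh.write(
                f"{iv.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID=exon_{iv.chrom}_{iv.start}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise IntervalError(f"{path}:{lineno}: chrom-sizes needs 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(path: str | Path, sizes: Mapping[str, int]) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_genome(path: str | Path) -> Fasta:
    """Open a FASTA genome with a pyfaidx random-access handle."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_sequence(genome: Fasta, iv: GenomicInterval) -> str:
    """Uppercase sequence of ``iv``; errors if beyond the chromosome end."""
    if iv.chrom not in genome:
        raise IntervalError(f"chromosome {iv.chrom!r} absent from genome")
    chrom_len = len(genome[iv.chrom])
    if iv.end > chrom_len:
        raise IntervalError(
            f"interval {iv.name} extends beyond chromosome end ({chrom_len})"
        )
    return str(genome[iv.chrom][iv.start : iv.end]).upper()
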