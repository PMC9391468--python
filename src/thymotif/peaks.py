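"""Histone-modification peak processing into active-region datasets.

A *dataset* is one (cell type × histone modification) combination, built
from per-sample peak calls by: enrichment filtering (fold change ≥ 3,
q < 1e-4), an RNA-activity gate (mean RNA-seq depth ≥ 0.001 over the
peak), pooling of biological replicates, removal of calls shorter than
6 bp, 20 bp border flanks, and exon exclusion. Chromatin *pseudostates*
are interval intersections of several pooled histone-mark sets, mimicking
the Ernst–Kellis state definitions (state 7 = H3K4me1 ∩ H3K36me3, …,
state 12 = H3K4me3 ∩ H3K27ac).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import (
    CoverageTrack,
    GenomicInterval,
    IntervalError,
    IntervalSet,
    intersect_sets,
    mean_depth,
    merge_intervals,
    pad_intervals,
    subtract_intervals,
)
from . import io as tio

logger = logging.getLogger(__name__)

#: Ernst–Kellis-style pseudostate membership by histone mark.
PSEUDOSTATE_MEMBERS: dict[int, tuple[str, ...]] = {
    7: ("H3K4me1", "H3K36me3"),
    9: ("H3K4me1", "H3K27ac"),
    10: ("H3K4me3", "H3K27ac", "H3K4me1"),
    11: ("H3K4me3", "H3K4me1"),
    12: ("H3K4me3", "H3K27ac"),
}


@dataclass(frozen=True)
class PeakCall:
    """One called peak with its enrichment statistics."""

    interval: GenomicInterval
    fold_change: float
    q_value: float
    sample_id: str
    cell_type: str
    hist_mod: str

    def __post_init__(self) -> None:
        if self.fold_change < 0:
            raise ValueError(f"negative fold change for {self.interval.name}")
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"q-value outside [0,1] for {self.interval.name}")


@dataclass
class Dataset:
    """Pooled, cleaned active regions for one cell type × mark (or state)."""

    cell_type: str
    hist_mod: str
    peaks: IntervalSet
    n_samples: int

    @property
    def dataset_id(self) -> str:
        return f"{self.cell_type}.{self.hist_mod}"


@dataclass(frozen=True)
class PseudostateDefinition:
    state_id: int
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state_id not in PSEUDOSTATE_MEMBERS:
            raise ValueError(f"unknown pseudostate id {self.state_id}")
        if not self.members:
            object.__setattr__(
                self, "members", PSEUDOSTATE_MEMBERS[self.state_id]
            )
        if len(self.members) < 2:
            raise ValueError("pseudostate needs at least 2 member marks")

    @property
    def label(self) -> str:
        return f"pseudostate{self.state_id}"


def filter_peaks(
    peaks: Iterable[PeakCall], min_fc: float = 3.0, max_q: float = 1e-4
) -> list[PeakCall]:
    """Retain peaks with fold change ≥ ``min_fc`` and q-value < ``max_q``.

    The fold-change bound is inclusive, the q-value bound strict.
    """
    return [p for p in peaks if p.fold_change >= min_fc and p.q_value < max_q]


def rna_active_filter(
    peaks: Iterable[PeakCall],
    track: CoverageTrack,
    min_mean: float = 0.001,
    uncovered: str = "zero",
) -> list[PeakCall]:
    """Retain peaks whose mean RNA-seq depth over the peak is ≥ ``min_mean``.

    Peaks on chromosomes absent from the track are treated as depth 0 and
    dropped (logged).
    """
    kept = []
    for p in peaks:
        if p.interval.chrom not in track.runs:
            logger.warning(
                "peak %s: chromosome absent from coverage track, depth 0",
                p.interval.name,
            )
            depth = 0.0
        else:
            depth = mean_depth(track, p.interval, uncovered=uncovered)
        if not math.isnan(depth) and depth >= min_mean:
            kept.append(p)
    return kept


def pool_and_clean(
    peaks: Sequence[PeakCall],
    exons: IntervalSet,
    chrom_sizes: Mapping[str, int],
    min_len: int = 6,
    flank: int = 20,
    merge: bool = True,
) -> Dataset:
    """Pool per-sample peak calls of one dataset into its active regions.

    Order of operations follows the processing protocol: concatenate all
    samples' calls and merge, drop intervals shorter than ``min_len``,
    pad by ``flank``, re-merge, then subtract exons. The length filter is
    applied once, before flanking; fragments produced by the exon
    subtraction are kept regardless of length.
    """
    if not peaks:
        raise ValueError("pool_and_clean needs at least one peak call")
    keys = {(p.cell_type, p.hist_mod) for p in peaks}
    if len(keys) > 1:
        raise ValueError(f"peaks span multiple datasets: {sorted(keys)}")
    cell_type, hist_mod = keys.pop()
    n_samples = len({p.sample_id for p in peaks})

    pooled = IntervalSet([p.interval for p in peaks])
    if merge:
        pooled = merge_intervals(pooled)
    pooled = IntervalSet([iv for iv in pooled if len(iv) >= min_len])
    if len(pooled):
        pooled = pad_intervals(pooled, flank, chrom_sizes)
        pooled = subtract_intervals(pooled, exons)
    if not len(pooled):
        logger.warning("dataset %s.%s: empty after cleaning", cell_type, hist_mod)
    return Dataset(cell_type, hist_mod, pooled, n_samples)


def build_pseudostates(
    datasets: Sequence[Dataset],
    definitions: Sequence[PseudostateDefinition] | None = None,
) -> list[Dataset]:
    """Intersect pooled histone-mark sets into per-cell-type pseudostates.

    A pseudostate is produced for a cell type only when every member mark
    has a dataset there; otherwise it is skipped (logged).
    """
    if definitions is None:
        definitions = [PseudostateDefinition(s) for s in sorted(PSEUDOSTATE_MEMBERS)]
    by_key = {(d.cell_type, d.hist_mod): d for d in datasets}
    cell_types = sorted({d.cell_type for d in datasets})
    out = []
    for cell_type in cell_types:
        for defn in definitions:
            members = [by_key.get((cell_type, m)) for m in defn.members]
            if any(m is None for m in members):
                logger.info(
                    "cell type %s: pseudostate %d skipped (missing marks)",
                    cell_type,
                    defn.state_id,
                )
                continue
            state_set = intersect_sets([m.peaks for m in members])
            out.append(
                Dataset(
                    cell_type,
                    defn.label,
                    state_set,
                    min(m.n_samples for m in members),
                )
            )
    return out


def extract_sequences(dataset: Dataset, genome) -> dict[str, str]:
    """One uppercase DNA sequence per peak interval, named chrom:start-end."""
    return {iv.name: tio.fetch_sequence(genome, iv) for iv in dataset.peaks}


# ---------------------------------------------------------------------------
# file-level interfaces


@dataclass(frozen=True)
class PeakColumns:
    """Column layout of a peak BED file (0-based indices past chrom/start/end).

    The default matches MACS2 narrowPeak: column 7 is fold change and
    column 9 holds −log10(q); ``q_is_neglog10`` converts on read.
    """

    fold_change: int = 6
    q_value: int = 8
    q_is_neglog10: bool = True


def read_peak_bed(
    path: str | Path,
    sample_id: str,
    cell_type: str,
    hist_mod: str,
    columns: PeakColumns = PeakColumns(),
) -> list[PeakCall]:
    ivs, extras = tio.read_bed(path)
    peaks = []
    for iv, cols in zip(ivs, extras):
        fields = [iv.chrom, str(iv.start), str(iv.end), *cols]
        try:
            fc = float(fields[columns.fold_change])
            q = float(fields[columns.q_value])
        except (IndexError, ValueError) as err:
            raise IntervalError(f"{path}: bad peak columns at {iv.name}") from err
        if columns.q_is_neglog10:
            q = 10.0 ** (-q)
        peaks.append(PeakCall(iv, fc, q, sample_id, cell_type, hist_mod))
    return peaks


def write_dataset_bed(path: str | Path, dataset: Dataset) -> None:
    tio.write_bed(path, dataset.peaks)


def summary_table(datasets: Sequence[Dataset]) -> list[dict]:
    """Table-1-style rows: dataset, n_samples, n_peaks."""
    return [
        {
            "dataset": d.dataset_id,
            "cell_type": d.cell_type,
            "hist_mod": d.hist_mod,
            "n_samples": d.n_samples,
            "n_peaks": len(d.peaks),
        }
        for d in datasets
    ]
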