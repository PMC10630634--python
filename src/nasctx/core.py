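"""Core domain types for strand-specific nascent transcriptomics.

All coordinates are 0-based half-open (BED convention) on named
chromosomes.  Strandedness is mandatory: every interval, transcript and
coverage track carries an explicit ``+`` or ``-`` strand, because the
analyses built on top (antisense pairing, promoter-proximal pausing,
strand-specific quantification) are meaningless without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded span: ``[start, end)`` on ``chrom``.

    ``start`` is 0-based inclusive, ``end`` exclusive; length is
    ``end - start`` and must be at least 1.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware).

        For a minus-strand interval the TSS is the last covered base,
        i.e. ``end - 1``.
        """
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination position (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared base pairs with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    """A transcript: interval plus exon structure.

    ``source`` distinguishes reference annotation (``annotated``) from de
    novo transcription units (``denovo``).  An unspliced transcript has
    exactly one exon spanning its interval.
    """

    id: str
    interval: GenomicInterval
    exons: List[GenomicInterval] = field(default_factory=list)
    biotype: str = "novel"
    source: str = "annotated"

    BIOTYPES = ("coding", "lncRNA", "antisense", "novel")
    SOURCES = ("annotated", "denovo")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        if self.biotype not in self.BIOTYPES:
            raise ValidationError(f"unknown biotype {self.biotype!r}")
        if self.source not in self.SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if not self.exons:
            self.exons = [self.interval]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValidationError(
                    f"{self.id}: exon {e} not on transcript chrom/strand"
                )
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValidationError(f"{self.id}: exon {e} outside interval")
            if prev_end is not None and e.start < prev_end:
                raise ValidationError(f"{self.id}: overlapping exons")
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> List[GenomicInterval]:
        """Intronic intervals: the interval minus its exons."""
        out = []
        pos = self.interval.start
        for e in self.exons:
            if e.start > pos:
                out.append(GenomicInterval(self.chrom, pos, e.start, self.strand))
            pos = e.end
        if pos < self.interval.end:
            out.append(
                GenomicInterval(self.chrom, pos, self.interval.end, self.strand)
            )
        return out

    @property
    def spliced(self) -> bool:
        return len(self.exons) > 1


class CoverageTrack:
    """Run-length encoded per-base coverage on one strand.

    Runs are stored per chromosome as parallel ``starts``/``ends``/``depths``
    arrays, sorted and non-overlapping.  Positions outside any run have
    depth 0.  Depth is in reads per base pair and must be non-negative.
    """

    def __init__(self, strand: str):
        if strand not in STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
        self.strand = strand
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def add_runs(
        self,
        chrom: str,
        starts: Iterable[int],
        ends: Iterable[int],
        depths: Iterable[float],
    ) -> None:
        starts = np.asarray(list(starts), dtype=np.int64)
        ends = np.asarray(list(ends), dtype=np.int64)
        depths = np.asarray(list(depths), dtype=float)
        if not (len(starts) == len(ends) == len(depths)):
            raise ValidationError("runs arrays must have equal length")
        order = np.argsort(starts, kind="stable")
        starts, ends, depths = starts[order], ends[order], depths[order]
        if np.any(ends <= starts):
            raise ValidationError(f"empty or inverted run on {chrom}")
        if np.any(depths < 0):
            raise ValidationError(f"negative depth on {chrom}")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"overlapping runs on {chrom}")
        if chrom in self._runs:
            raise ValidationError(f"runs for {chrom} already present")
        self._runs[chrom] = (starts, ends, depths)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._runs:
            z = np.empty(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._runs[chrom]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total signal (depth x bp) over ``[start, end)``."""
        if start >= end:
            return 0.0
        starts, ends, depths = self.runs(chrom)
        if len(starts) == 0:
            return 0.0
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * depths[lo:hi]))

    def total_signal(self) -> float:
        return sum(
            float(np.sum((e - s) * d)) for s, e, d in self._runs.values()
        )

    def covered_span(self) -> int:
        return int(sum(np.sum(e - s) for s, e, _ in self._runs.values()))

    def max_end(self, chrom: str) -> int:
        starts, ends, _ = self.runs(chrom)
        return int(ends[-1]) if len(ends) else 0

    def to_dense(self, chrom: str, length: int) -> np.ndarray:
        """Per-base depth array; intended for small test genomes."""
        arr = np.zeros(length, dtype=float)
        for s, e, d in zip(*self.runs(chrom)):
            arr[s:e] = d
        return arr

    @classmethod
    def from_dense(cls, strand: str, per_chrom: Mapping[str, np.ndarray]) -> "CoverageTrack":
        """Build a track by run-length encoding dense per-base arrays."""
        track = cls(strand)
        for chrom, arr in per_chrom.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            depths = arr[starts]
            nz = depths != 0
            if np.any(nz):
                track.add_runs(chrom, starts[nz], ends[nz], depths[nz])
            else:
                track._runs.setdefault(chrom, (
                    np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)))
        return track


class CountMatrix:
    """Integer feature x sample count table with a sample->group design."""

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, str]):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        vals = counts.to_numpy()
        if vals.size and (np.any(vals < 0) or not np.allclose(vals, np.round(vals))):
            raise ValidationError("counts must be non-negative integers")
        missing = [s for s in counts.columns if s not in groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        self.counts = counts.astype(np.int64)
        self.groups = {s: groups[s] for s in counts.columns}

    @property
    def features(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_samples(self, group: str) -> List[str]:
        return [s for s, g in self.groups.items() if g == group]

    def group_labels(self) -> List[str]:
        seen: List[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def subset_features(self, ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)], self.groups)

    def __repr__(self) -> str:
        return (
            f"CountMatrix({len(self.features)} features x "
            f"{len(self.samples)} samples, groups={sorted(set(self.groups.values()))})"
        )
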