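"""De novo transcription-unit calling from strand-specific nascent coverage.

Nascent run-on coverage marks actively transcribed regions directly, so
transcription units can be called by thresholding depth and bridging
short sub-threshold gaps (polymerase pausing, mappability dropouts).
Called units are unspliced single-exon transcripts: nascent signal
covers introns and does not resolve splicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .core import CoverageTrack, GenomicInterval, Transcript, ValidationError


@dataclass
class CallerParams:
    """Parameters of the threshold-and-bridge transcription-unit caller.

    min_depth
        Depth (reads/bp) a base must reach to count as transcribed.
    max_gap
        Longest run of sub-threshold bases bridged inside one unit (bp).
    min_length
        Units shorter than this are discarded; 200 bp by default, the
        conventional lower bound for a long noncoding RNA.
    flank_trim
        After gap bridging, sub-threshold bases are trimmed back from
        the unit ends so reported boundaries sit on signal.
    """

    min_depth: float
    max_gap: int = 500
    min_length: int = 200
    flank_trim: bool = True

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValidationError("min_depth must be > 0")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")

    @classmethod
    def from_track(cls, track: CoverageTrack, depth_factor: float = 4.0, **kw) -> "CallerParams":
        """Default threshold: ``depth_factor`` x genome-wide mean depth.

        The mean is taken over the covered span (bases inside runs).
        """
        span = track.covered_span()
        if span == 0:
            raise ValidationError("cannot derive min_depth from an empty track")
        mean_depth = track.total_signal() / span
        return cls(min_depth=depth_factor * mean_depth, **kw)


def call_transcription_units(track: CoverageTrack, params: CallerParams) -> List[Transcript]:
    """Call maximal above-threshold runs as single-exon transcription units.

    A unit is a maximal stretch of bases with depth >= ``min_depth``
    where internal sub-threshold gaps of at most ``max_gap`` bp are
    bridged.  Units shorter than ``min_length`` are dropped.  Ids are
    deterministic: ``TU_<chrom>_<start>_<strand>``.
    """
    units: List[Transcript] = []
    strand = track.strand
    for chrom in track.chroms:
        starts, ends, depths = track.runs(chrom)
        above = depths >= params.min_depth
        if not np.any(above):
            continue
        seg_starts = starts[above]
        seg_ends = ends[above]
        # merge adjacent/contiguous above-threshold runs
        merged: List[List[int]] = []
        for s, e in zip(seg_starts, seg_ends):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        # bridge gaps <= max_gap
        bridged: List[List[int]] = [merged[0]]
        for s, e in merged[1:]:
            if s - bridged[-1][1] <= params.max_gap:
                bridged[-1][1] = e
            else:
                bridged.append([s, e])
        for s, e in bridged:
            if e - s >= params.min_length:
                units.append(
                    Transcript(
                        id=f"TU_{chrom}_{s}_{strand}",
                        interval=GenomicInterval(chrom, s, e, strand),
                        biotype="novel",
                        source="denovo",
                    )
                )
    units.sort(key=lambda t: (t.chrom, t.interval.start, t.id))
    return units


def merge_with_annotation(
    novel: List[Transcript],
    annotated: List[Transcript],
    dedup_overlap: float = 0.5,
) -> List[Transcript]:
    """Concatenate de novo units with an annotation, dropping duplicates.

    A novel unit is dropped iff some same-strand annotated transcript
    covers at least ``dedup_overlap`` of the novel unit's length.
    Annotated entries are never modified.
    """
    if not (0 < dedup_overlap <= 1):
        raise ValidationError("dedup_overlap must be in (0, 1]")
    ids = [t.id for t in annotated] + [t.id for t in novel]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate ids across union: {dupes}")

    by_loc: dict = {}
    for a in annotated:
        by_loc.setdefault((a.chrom, a.strand), []).append(a)
    survivors = []
    for n in novel:
        covered = 0
        for a in by_loc.get((n.chrom, n.strand), []):
            ov = n.interval.overlap_bp(a.interval)
            covered = max(covered, ov)
        if covered / n.length < dedup_overlap:
            survivors.append(n)
    return list(annotated) + survivors
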