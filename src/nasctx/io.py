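"""Readers and writers for GTF, BED, bedGraph and count/design tables.

Internally everything is 0-based half-open; GTF I/O converts at the
boundary (GTF is 1-based inclusive).  Chromosome names are matched as
exact strings; an optional chr-alias mapping can be applied explicitly
by the caller, never silently.
"""

from __future__ import annotations

import re
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core import CountMatrix, CoverageTrack, GenomicInterval, Transcript, ValidationError


class ParseError(ValueError):
    """Raised on malformed input lines; names the offending line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# GTF/GENCODE biotype vocabulary folded onto the four internal classes.
_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "antisense": "antisense",
    "antisense_RNA": "antisense",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "novel": "novel",
}


def _parse_attributes(text: str) -> Dict[str, str]:
    return {k: v for k, v in _ATTR_RE.findall(text)}


def read_gtf(path: str) -> List[Transcript]:
    """Read a GTF file (Ensembl/GENCODE attribute dialect) into transcripts.

    Exon records sharing a ``transcript_id`` are aggregated into one
    :class:`Transcript`; 1-based inclusive GTF coordinates are converted
    to 0-based half-open.  Comment lines (``#``) are ignored.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, Dict[str, str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end < start after conversion")
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}:{lineno}: unstranded records are not supported"
                )
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            exons.setdefault(tid, []).append(GenomicInterval(chrom, start, end, strand))
            if tid not in meta:
                meta[tid] = attrs
                order.append(tid)

    out = []
    for tid in order:
        ex = sorted(exons[tid], key=lambda e: e.start)
        attrs = meta[tid]
        raw_bt = (
            attrs.get("transcript_biotype")
            or attrs.get("transcript_type")
            or attrs.get("gene_biotype")
            or attrs.get("gene_type")
            or "novel"
        )
        biotype = _BIOTYPE_MAP.get(raw_bt, "novel")
        source = attrs.get("source", "annotated")
        if source not in Transcript.SOURCES:
            source = "annotated"
        interval = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        out.append(Transcript(id=tid, interval=interval, exons=ex, biotype=biotype, source=source))
    return out


_INV_BIOTYPE = {"coding": "protein_coding", "lncRNA": "lncRNA",
                "antisense": "antisense", "novel": "novel"}


def write_gtf(transcripts: List[Transcript], path: str) -> None:
    """Write transcripts as GTF exon records (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)):
            attrs = (
                f'gene_id "{t.id}"; transcript_id "{t.id}"; '
                f'transcript_biotype "{_INV_BIOTYPE[t.biotype]}"; source "{t.source}";'
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, "nasctx", "exon", str(e.start + 1), str(e.end),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_bed(path: str) -> List[Transcript]:
    """Read BED6/BED12 into (unspliced or spliced) transcripts."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: BED needs >= 6 columns")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: unstranded BED record")
            if len(f) >= 12:
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                if not (len(sizes) == len(offsets) == n_blocks):
                    raise ParseError(f"{path}:{lineno}: inconsistent block columns")
                exons = [
                    GenomicInterval(chrom, start + o, start + o + s, strand)
                    for o, s in zip(offsets, sizes)
                ]
            else:
                exons = [GenomicInterval(chrom, start, end, strand)]
            interval = GenomicInterval(chrom, start, end, strand)
            out.append(Transcript(id=name, interval=interval, exons=exons))
    return out


def write_bed(transcripts: List[Transcript], path: str) -> None:
    """Write BED6 (single-exon) / BED12 (multi-exon), deterministically ordered."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)):
            base = [t.chrom, str(t.interval.start), str(t.interval.end), t.id, ".", t.strand]
            if t.spliced:
                sizes = ",".join(str(e.length) for e in t.exons)
                offsets = ",".join(str(e.start - t.interval.start) for e in t.exons)
                base += [str(t.interval.start), str(t.interval.end), "0",
                         str(len(t.exons)), sizes, offsets]
            fh.write("\t".join(base) + "\n")


def read_bedgraph(path: str, strand: str) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) as one strand's coverage.

    Overlapping runs or negative depths are validation errors; runs need
    not be depth-merged.
    """
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
            chrom = f[0]
            try:
                start, end, depth = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed values") from exc
            if depth < 0:
                raise ValidationError(f"{path}:{lineno}: negative depth")
            per_chrom.setdefault(chrom, []).append((start, end, depth))
    track = CoverageTrack(strand)
    for chrom, rows in per_chrom.items():
        rows.sort()
        track.add_runs(
            chrom,
            [r[0] for r in rows],
            [r[1] for r in rows],
            [r[2] for r in rows],
        )
    return track


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for s, e, d in zip(*track.runs(chrom)):
                fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


def read_counts(path: str, design: Optional[Mapping[str, str]] = None) -> CountMatrix:
    """Read a feature x sample TSV count matrix.

    First column holds feature ids, header row holds sample ids.  If
    ``design`` is omitted every sample is placed in a single group
    ``"all"`` (sufficient for quantification-only uses).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if design is None:
        design = {s: "all" for s in df.columns}
    return CountMatrix(df, design)


def write_counts(cm: CountMatrix, path: str) -> None:
    df = cm.counts.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def read_design(path: str) -> Dict[str, str]:
    """Read a two-column (sample, group) TSV design file."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: design file needs 'sample' and 'group' columns")
    sample_col, group_col = df.columns[:2]
    return dict(zip(df[sample_col].astype(str), df[group_col].astype(str)))


def write_design(groups: Mapping[str, str], path: str) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def apply_chr_alias(name: str) -> str:
    """Map 'chr1' <-> '1'.  Only used when the caller opts in."""
    return name[3:] if name.startswith("chr") else "chr" + name
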