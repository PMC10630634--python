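"""Sense-antisense pairing, inverse-regulation classification, HRE scanning.

A natural antisense transcript (NAT) is a transcript on the strand
opposite a coding gene with (partial) genomic overlap.  Pairs are formed
on gene-body intervals (TSS to TTS): nascent transcription covers
introns, so locus-level overlap is the relevant quantity.  Retained
pairs overlap by at least 10% of the antisense transcript's length
(inclusive).  Given differential-expression calls, pairs are classified
as ASRG (antisense-regulated: both members differential with opposite
signs), NARG (both differential, same sign) or not regulated.

``scan_hre`` finds the hypoxia response element core consensus RCGTG
(R = A/G) on both strands of a promoter sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import Transcript, ValidationError

MIN_OVERLAP_FRACTION = 0.10

TOPOLOGIES = ("convergent", "divergent", "nested", "other")
REGULATION_CLASSES = ("ASRG", "NARG", "not_regulated")


@dataclass
class SenseAntisensePair:
    """A coding gene paired with an overlapping opposite-strand transcript."""

    sense_id: str
    antisense_id: str
    overlap_bp: int
    overlap_fraction: float  # of the antisense transcript's length
    topology: str
    regulation_class: str = "not_regulated"

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"unknown topology {self.topology!r}")
        if not (0 < self.overlap_fraction <= 1):
            raise ValidationError("overlap_fraction must be in (0, 1]")


@dataclass
class PairCorrelation:
    n_pairs: int
    pearson_r: float
    p_value: float


def _topology(gene: Transcript, antisense: Transcript) -> str:
    gi, ai = gene.interval, antisense.interval
    if gi.contains(ai) or ai.contains(gi):
        return "nested"
    # orientations point toward each other (3' ends in the overlap) or away
    left, right = (gi, ai) if gi.start <= ai.start else (ai, gi)
    if left.strand == "+" and right.strand == "-":
        return "convergent"
    if left.strand == "-" and right.strand == "+":
        return "divergent"
    return "other"


def find_antisense_pairs(
    transcripts: Sequence[Transcript],
    coding_genes: Sequence[Transcript],
    min_fraction: float = MIN_OVERLAP_FRACTION,
) -> List[SenseAntisensePair]:
    """All (coding gene, opposite-strand transcript) overlapping pairs.

    Overlap is computed on gene-body intervals and a pair is retained
    iff overlap_bp / antisense_length >= ``min_fraction`` (inclusive).
    A gene may appear in several pairs and vice versa.
    """
    trees: dict = {}
    genes_by_id = {}
    for g in coding_genes:
        if g.id in genes_by_id:
            raise ValidationError(f"duplicate coding gene id {g.id}")
        genes_by_id[g.id] = g
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    pairs: List[SenseAntisensePair] = []
    for t in transcripts:
        if t.chrom not in trees:
            continue
        for hit in trees[t.chrom].overlap(t.interval.start, t.interval.end):
            gene: Transcript = hit.data
            if gene.strand == t.strand or gene.id == t.id:
                continue
            ov = gene.interval.overlap_bp(t.interval)
            if ov <= 0:
                continue
            frac = ov / t.length
            if frac >= min_fraction:
                pairs.append(
                    SenseAntisensePair(
                        sense_id=gene.id,
                        antisense_id=t.id,
                        overlap_bp=ov,
                        overlap_fraction=frac,
                        topology=_topology(gene, t),
                    )
                )
    pairs.sort(key=lambda p: (p.sense_id, p.antisense_id))
    return pairs


def correlate_pairs(
    pairs: Sequence[SenseAntisensePair],
    de_table: pd.DataFrame,
) -> PairCorrelation:
    """Pearson correlation of sense vs antisense log2 fold changes."""
    if len(pairs) < 3:
        raise ValidationError("need >= 3 pairs for a defined correlation")
    sense = np.array([de_table.loc[p.sense_id, "log2_fc"] for p in pairs])
    anti = np.array([de_table.loc[p.antisense_id, "log2_fc"] for p in pairs])
    if not (np.all(np.isfinite(sense)) and np.all(np.isfinite(anti))):
        raise ValidationError("non-finite log2_fc among pair members")
    r, p = stats.pearsonr(sense, anti)
    return PairCorrelation(n_pairs=len(pairs), pearson_r=float(r), p_value=float(p))


def classify_regulation(
    pairs: Sequence[SenseAntisensePair],
    de_table: pd.DataFrame,
    require_both_de: bool = True,
) -> List[SenseAntisensePair]:
    """Attach a regulation class to each pair from DE statuses.

    ASRG: both members differentially expressed with opposite-sign fold
    changes (the archetype: antisense induced, sense repressed).
    NARG: both differential with the same sign (coregulated).
    Anything else: not_regulated.

    With ``require_both_de=False`` only the antisense member must be
    differential and the class is assigned from the fold-change signs (a
    looser, directional definition).
    """
    out: List[SenseAntisensePair] = []
    for p in pairs:
        for member in (p.sense_id, p.antisense_id):
            if member not in de_table.index:
                raise ValidationError(
                    f"pair ({p.sense_id}, {p.antisense_id}): {member} missing from DE table"
                )
        s = de_table.loc[p.sense_id]
        a = de_table.loc[p.antisense_id]
        s_de = s["status"] in ("up", "down")
        a_de = a["status"] in ("up", "down")
        qualifying = (s_de and a_de) if require_both_de else a_de
        if qualifying:
            opposite = s["log2_fc"] * a["log2_fc"] < 0
            cls = "ASRG" if opposite else "NARG"
        else:
            cls = "not_regulated"
        out.append(
            SenseAntisensePair(
                sense_id=p.sense_id,
                antisense_id=p.antisense_id,
                overlap_bp=p.overlap_bp,
                overlap_fraction=p.overlap_fraction,
                topology=p.topology,
                regulation_class=cls,
            )
        )
    return out


def pairs_to_frame(pairs: Sequence[SenseAntisensePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sense_id": p.sense_id,
                "antisense_id": p.antisense_id,
                "overlap_bp": p.overlap_bp,
                "overlap_fraction": p.overlap_fraction,
                "topology": p.topology,
                "regulation_class": p.regulation_class,
            }
            for p in pairs
        ]
    )


# ---------------------------------------------------------------------------
# HRE consensus scanning
# ---------------------------------------------------------------------------

_HRE_FWD = re.compile(r"(?=([AG]CGTG))")
_HRE_REV = re.compile(r"(?=(CACG[TC]))")  # reverse complement of RCGTG
_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifHit:
    position: int  # 0-based offset of the 5-mer start, promoter coordinates
    strand: str
    matched: str  # the RCGTG-matching 5-mer (reverse-complemented for '-')


def scan_hre(sequence: str, offset: int = 0) -> List[MotifHit]:
    """Find all HRE core consensus (RCGTG) matches on both strands.

    Minus-strand hits are occurrences whose reverse complement matches
    the consensus; positions are reported on the forward sequence,
    0-based relative to ``offset`` (e.g. a promoter interval start).
    ``N`` never matches.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    hits: List[MotifHit] = []
    for m in _HRE_FWD.finditer(seq):
        hits.append(MotifHit(position=offset + m.start(), strand="+", matched=m.group(1)))
    for m in _HRE_REV.finditer(seq):
        rc = m.group(1).translate(_COMP)[::-1]
        hits.append(MotifHit(position=offset + m.start(), strand="-", matched=rc))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
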