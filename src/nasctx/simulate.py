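"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is seeded and bit-reproducible, and returns (or fills) a
:class:`TruthManifest` recording the planted ground truth, so recovery
can be checked end to end:

* a toy genome of non-overlapping plus-strand coding genes, a fraction
  of which carry one convergent opposite-strand antisense unit with a
  controlled overlap fraction;
* strand-specific coverage with promoter-proximal pausing enrichment
  (first 300 bp scaled by the pausing ratio) and Poisson per-base noise;
* negative-binomial replicate counts with condition-dependent fold
  changes, including planted inversely regulated sense-antisense pairs
  (antisense induced, sense repressed);
* approach-to-equilibrium labeling series linear in time;
* qPCR CT tables under perfect amplification efficiency.

What this emulates - and what it does not (mappability, GC bias,
splicing, fragment-level sampling) - is discussed in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .antisense import find_antisense_pairs
from .core import CountMatrix, CoverageTrack, GenomicInterval, Transcript, ValidationError
from .kinetics import LabelingSeries

PAUSING_WINDOW = 300


@dataclass
class TruthManifest:
    """Machine-readable record of everything a generator planted."""

    seed: int
    params: Dict = field(default_factory=dict)
    features: Dict[str, Dict] = field(default_factory=dict)  # id -> truth
    pairs: List[Dict] = field(default_factory=list)
    pausing: Dict[str, float] = field(default_factory=dict)
    slopes: Dict[str, float] = field(default_factory=dict)
    qpcr_folds: Dict[str, float] = field(default_factory=dict)

    def planted_class(self, cls: str) -> List[Tuple[str, str]]:
        return [
            (p["sense_id"], p["antisense_id"])
            for p in self.pairs
            if p["regulation_class"] == cls
        ]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "params": self.params,
                    "features": self.features,
                    "pairs": self.pairs,
                    "pausing": self.pausing,
                    "slopes": self.slopes,
                    "qpcr_folds": self.qpcr_folds,
                },
                fh,
                indent=1,
                default=float,
            )

    @classmethod
    def from_json(cls, path: str) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def make_toy_genome(
    n_genes: int,
    antisense_fraction: float = 0.10,
    overlap_range: Tuple[float, float] = (0.10, 0.90),
    seed: int = 0,
    gene_length_range: Tuple[int, int] = (2_000, 60_000),
    gap_range: Tuple[int, int] = (2_000, 8_000),
    genes_per_chrom: int = 500,
) -> Tuple[List[Transcript], Dict[str, int]]:
    """Toy genome: plus-strand coding genes, some with a convergent NAT.

    Gene lengths are log-uniform over ``gene_length_range``.  A fraction
    ``antisense_fraction`` of genes receive one minus-strand antisense
    unit whose overlap fraction (of the antisense unit's own length) is
    drawn uniformly from ``overlap_range``; the unit's 3' overlap is
    anchored at the host gene's termination end, the convergent
    geometry.  Ids and coordinates are deterministic in ``seed``.
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    if not (0 <= antisense_fraction <= 1):
        raise ValidationError("antisense_fraction must be in [0, 1]")
    lo_f, hi_f = overlap_range
    if not (0 < lo_f <= hi_f <= 1):
        raise ValidationError("overlap_range must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    transcripts: List[Transcript] = []
    chrom_sizes: Dict[str, int] = {}
    log_lo, log_hi = np.log(gene_length_range[0]), np.log(gene_length_range[1])
    n_chroms = max(1, int(np.ceil(n_genes / genes_per_chrom))) if n_genes else 0

    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(gap_range[0], gap_range[1] + 1))
        for _ in range(min(genes_per_chrom, n_genes - gi)):
            length = int(np.exp(rng.uniform(log_lo, log_hi)))
            gene_id = f"gene_{gi + 1:05d}"
            gene_iv = GenomicInterval(chrom, cursor, cursor + length, "+")
            transcripts.append(
                Transcript(id=gene_id, interval=gene_iv, biotype="coding")
            )
            right_edge = gene_iv.end
            if rng.random() < antisense_fraction:
                frac = rng.uniform(lo_f, hi_f)
                as_len = int(np.exp(rng.uniform(np.log(1_000), np.log(40_000))))
                max_ov = max(200, length - 100)
                if frac * as_len > max_ov:
                    as_len = max(200, int(max_ov / frac))
                overlap = max(1, int(round(frac * as_len)))
                a_start = gene_iv.end - overlap
                a_end = a_start + as_len
                as_iv = GenomicInterval(chrom, a_start, a_end, "-")
                transcripts.append(
                    Transcript(
                        id=f"as_{gene_id}", interval=as_iv, biotype="antisense"
                    )
                )
                right_edge = max(right_edge, a_end)
            cursor = right_edge + int(rng.integers(gap_range[0], gap_range[1] + 1))
            gi += 1
        chrom_sizes[chrom] = cursor + 10_000
    return transcripts, chrom_sizes


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def simulate_coverage(
    transcripts: Sequence[Transcript],
    chrom_sizes: Mapping[str, int],
    expression: Mapping[str, float],
    pausing_ratio: Mapping[str, float] | float = 1.0,
    noise_depth: float = 0.0,
    seed: int = 0,
    pausing_window: int = PAUSING_WINDOW,
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Strand-specific coverage: per-base Poisson around planted means.

    Each transcript contributes ``expression[id]`` mean depth over its
    interval on its own strand, with the first ``pausing_window`` bp
    downstream of the TSS multiplied by its pausing ratio.  A uniform
    background of ``noise_depth`` mean depth is added genome-wide on
    both strands, then every base is Poisson-sampled.
    """
    if noise_depth < 0:
        raise ValidationError("noise_depth must be >= 0")
    rng = np.random.default_rng(seed)
    dense = {
        "+": {c: np.full(int(n), float(noise_depth)) for c, n in chrom_sizes.items()},
        "-": {c: np.full(int(n), float(noise_depth)) for c, n in chrom_sizes.items()},
    }
    for t in transcripts:
        level = float(expression.get(t.id, 0.0))
        if level < 0:
            raise ValidationError(f"{t.id}: negative expression level")
        if level == 0:
            continue
        ratio = (
            float(pausing_ratio.get(t.id, 1.0))
            if isinstance(pausing_ratio, Mapping)
            else float(pausing_ratio)
        )
        if ratio < 1:
            raise ValidationError(f"{t.id}: pausing ratio must be >= 1")
        arr = dense[t.strand][t.chrom]
        iv = t.interval
        arr[iv.start : iv.end] += level
        win = min(pausing_window, iv.length)
        if t.strand == "+":
            arr[iv.start : iv.start + win] += level * (ratio - 1.0)
        else:
            arr[iv.end - win : iv.end] += level * (ratio - 1.0)
    tracks = {}
    for strand in ("+", "-"):
        sampled = {
            c: rng.poisson(m).astype(float) for c, m in sorted(dense[strand].items())
        }
        tracks[strand] = CoverageTrack.from_dense(strand, sampled)
    return tracks["+"], tracks["-"]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    transcripts: Sequence[Transcript],
    n_per_group: Mapping[str, int],
    condition: str,
    baseline_means: Mapping[str, float],
    planted_log2fc: Optional[Mapping[str, float]] = None,
    n_inverse_pairs: int = 0,
    phi: float = 0.05,
    lib_sizes: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    antisense_lfc_range: Tuple[float, float] = (2.0, 4.0),
    sense_lfc_range: Tuple[float, float] = (-2.0, -0.7),
    pair_min_fraction: float = 0.10,
) -> Tuple[CountMatrix, TruthManifest]:
    """NB replicate counts with planted condition effects.

    ``counts ~ NB(mean = baseline * 2**(log2fc * [sample in condition])
    * libsize factor, dispersion phi)`` with variance ``mu + phi*mu**2``.
    ``n_inverse_pairs`` sense-antisense pairs (found on the provided
    annotation) are planted inversely regulated: the antisense member
    up by a log2 fold change drawn from ``antisense_lfc_range``, the
    sense member down by one drawn from ``sense_lfc_range``.  Explicit
    ``planted_log2fc`` entries are applied first and never overwritten
    by pair planting.
    """
    if phi < 0:
        raise ValidationError("phi must be >= 0")
    groups = list(n_per_group)
    if condition not in groups:
        raise ValidationError(f"condition {condition!r} not among groups {groups}")
    rng = np.random.default_rng(seed)
    ids = [t.id for t in transcripts]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate transcript ids")

    lfc = {i: 0.0 for i in ids}
    if planted_log2fc:
        unknown = set(planted_log2fc) - set(ids)
        if unknown:
            raise ValidationError(f"planted_log2fc for unknown features: {sorted(unknown)}")
        lfc.update({k: float(v) for k, v in planted_log2fc.items()})

    pair_records: List[Dict] = []
    if n_inverse_pairs:
        coding = [t for t in transcripts if t.biotype == "coding"]
        others = [t for t in transcripts if t.biotype != "coding"]
        pairs = find_antisense_pairs(others, coding, min_fraction=pair_min_fraction)
        free = [
            p
            for p in pairs
            if not (planted_log2fc and (p.sense_id in planted_log2fc or p.antisense_id in planted_log2fc))
        ]
        if n_inverse_pairs > len(free):
            raise ValidationError(
                f"requested {n_inverse_pairs} inverse pairs, only {len(free)} available"
            )
        chosen_idx = rng.choice(len(free), size=n_inverse_pairs, replace=False)
        for idx in sorted(chosen_idx):
            p = free[idx]
            up = rng.uniform(*antisense_lfc_range)
            down = rng.uniform(*sense_lfc_range)
            lfc[p.antisense_id] = float(up)
            lfc[p.sense_id] = float(down)
            pair_records.append(
                {
                    "sense_id": p.sense_id,
                    "antisense_id": p.antisense_id,
                    "regulation_class": "ASRG",
                    "sense_log2fc": float(down),
                    "antisense_log2fc": float(up),
                }
            )

    samples = []
    sample_groups = {}
    for g in groups:
        for r in range(int(n_per_group[g])):
            s = f"{g}_{r + 1}"
            samples.append(s)
            sample_groups[s] = g
    if lib_sizes is None:
        lib = {s: float(rng.uniform(0.8e6, 1.2e6)) for s in samples}
    else:
        lib = {s: float(lib_sizes[s]) for s in samples}
    lib_factor = np.array([lib[s] for s in samples])
    lib_factor = lib_factor / lib_factor.mean()

    base = np.array([float(baseline_means[i]) for i in ids])
    if np.any(base < 0):
        raise ValidationError("baseline means must be >= 0")
    lfc_vec = np.array([lfc[i] for i in ids])
    in_cond = np.array([sample_groups[s] == condition for s in samples])
    mu = base[:, None] * (2.0 ** (lfc_vec[:, None] * in_cond[None, :])) * lib_factor[None, :]
    if phi < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=samples), sample_groups)
    truth = TruthManifest(
        seed=int(seed),
        params={
            "n_per_group": dict(n_per_group),
            "condition": condition,
            "phi": phi,
            "antisense_lfc_range": list(antisense_lfc_range),
            "sense_lfc_range": list(sense_lfc_range),
            "n_inverse_pairs": n_inverse_pairs,
        },
        features={
            i: {"baseline": float(b), "log2fc": float(f), "de": bool(f != 0.0)}
            for i, b, f in zip(ids, base, lfc_vec)
        },
        pairs=pair_records,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# labeling and qPCR
# ---------------------------------------------------------------------------

def simulate_labeling(
    true_slope: float,
    condition: str = "untreated",
    gene_id: str = "gene",
    times: Sequence[float] = (15.0, 30.0, 45.0, 60.0),
    sigma_frac: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> LabelingSeries:
    """Linear-in-time labeled abundance with multiplicative Gaussian noise.

    abundance = true_slope * time * (1 + N(0, sigma_frac)), floored at 0.
    """
    if sigma_frac < 0:
        raise ValidationError("sigma_frac must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.tile(np.asarray(times, dtype=float), replicates)
    rep = np.repeat(np.arange(replicates), len(times))
    noise = rng.normal(0.0, sigma_frac, size=t.shape) if sigma_frac > 0 else 0.0
    y = np.maximum(true_slope * t * (1.0 + noise), 0.0)
    return LabelingSeries(
        gene_id=gene_id, condition=condition, times=t, abundances=y, replicates=rep
    )


def simulate_qpcr(
    fold_changes: Mapping[str, float],
    calibrator_group: str,
    target: str = "target",
    reference: str = "REF",
    base_ct: float = 24.0,
    base_ct_ref: float = 18.0,
    sigma_ct: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> Tuple[pd.DataFrame, TruthManifest]:
    """CT table under perfect doubling: CT drops one cycle per 2x RNA.

    ``fold_changes`` maps group -> true expression fold relative to the
    calibrator group (whose fold is forced to 1).
    """
    if sigma_ct < 0:
        raise ValidationError("sigma_ct must be >= 0")
    folds = dict(fold_changes)
    folds[calibrator_group] = 1.0
    rng = np.random.default_rng(seed)
    rows = []
    for group in folds:
        for r in range(replicates):
            ct_t = base_ct - np.log2(folds[group]) + rng.normal(0.0, sigma_ct)
            ct_r = base_ct_ref + rng.normal(0.0, sigma_ct)
            rows.append(
                {
                    "sample": f"{group}_{r + 1}",
                    "group": group,
                    "target": target,
                    "reference": reference,
                    "ct_target": float(ct_t),
                    "ct_reference": float(ct_r),
                    "replicate": r,
                }
            )
    truth = TruthManifest(seed=int(seed), params={"sigma_ct": sigma_ct},
                          qpcr_folds={g: float(f) for g, f in folds.items()})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# the default scene
# ---------------------------------------------------------------------------

SCENE_DEFAULTS = dict(
    n_genes=3000,
    antisense_fraction=0.10,
    overlap_range=(0.10, 0.90),
    n_per_group={"normoxia": 4, "hypoxia": 4},
    condition="hypoxia",
    phi=0.05,
    n_inverse_pairs=25,
    antisense_lfc_range=(2.0, 4.0),
    sense_lfc_range=(-2.5, -1.5),
    background_sd=0.35,
    background_corr=0.35,
    n_background_de=150,
    background_lfc_range=(0.8, 2.5),
)


def default_scene(seed: int = 42, params: Optional[Dict] = None) -> Dict:
    """The canonical integration fixture: 3000 genes, ~300 antisense
    units, 25 planted inverse sense-antisense pairs with large effects.

    Non-pair coding genes receive a sprinkling of background fold
    changes; sense-antisense pairs not planted inverse get small,
    positively correlated fold changes (loose coregulation).  Returns a
    dict with the annotation, chromosome sizes, count matrix, planted
    pairs and the truth manifest.
    """
    p = dict(SCENE_DEFAULTS)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    transcripts, chrom_sizes = make_toy_genome(
        n_genes=p["n_genes"],
        antisense_fraction=p["antisense_fraction"],
        overlap_range=tuple(p["overlap_range"]),
        seed=seed,
    )
    coding = [t for t in transcripts if t.biotype == "coding"]
    anti = [t for t in transcripts if t.biotype == "antisense"]
    all_pairs = find_antisense_pairs(anti, coding)

    # baselines: coding log-uniform 30..600, antisense 15..150
    baselines: Dict[str, float] = {}
    for t in coding:
        baselines[t.id] = float(np.exp(rng.uniform(np.log(30), np.log(600))))
    for t in anti:
        baselines[t.id] = float(np.exp(rng.uniform(np.log(15), np.log(150))))

    # choose the inverse pairs up-front so their members get comfortable
    # baselines and are excluded from background planting
    idx = rng.choice(len(all_pairs), size=p["n_inverse_pairs"], replace=False)
    inverse_pairs = [all_pairs[i] for i in sorted(idx)]
    planted: Dict[str, float] = {}
    pair_records: List[Dict] = []
    for pr in inverse_pairs:
        up = float(rng.uniform(*p["antisense_lfc_range"]))
        down = float(rng.uniform(*p["sense_lfc_range"]))
        planted[pr.antisense_id] = up
        planted[pr.sense_id] = down
        baselines[pr.sense_id] = float(rng.uniform(200, 500))
        baselines[pr.antisense_id] = float(rng.uniform(100, 300))
        pair_records.append(
            {
                "sense_id": pr.sense_id,
                "antisense_id": pr.antisense_id,
                "regulation_class": "ASRG",
                "sense_log2fc": down,
                "antisense_log2fc": up,
            }
        )
    taken = set(planted)

    # loose coregulation for the remaining pairs: small correlated effects
    sd, corr = p["background_sd"], p["background_corr"]
    cov = sd * sd * np.array([[1.0, corr], [corr, 1.0]])
    for pr in all_pairs:
        if pr.sense_id in taken or pr.antisense_id in taken:
            continue
        s_lfc, a_lfc = rng.multivariate_normal([0.0, 0.0], cov)
        planted[pr.sense_id] = float(s_lfc)
        planted[pr.antisense_id] = float(a_lfc)
        taken.update((pr.sense_id, pr.antisense_id))

    # background DE among unpaired coding genes
    free_coding = [t.id for t in coding if t.id not in taken]
    n_bg = min(p["n_background_de"], len(free_coding))
    bg_ids = rng.choice(len(free_coding), size=n_bg, replace=False)
    for i in sorted(bg_ids):
        mag = float(rng.uniform(*p["background_lfc_range"]))
        planted[free_coding[i]] = mag if rng.random() < 0.5 else -mag

    cm, truth = simulate_counts(
        transcripts,
        n_per_group=p["n_per_group"],
        condition=p["condition"],
        baseline_means=baselines,
        planted_log2fc=planted,
        n_inverse_pairs=0,
        phi=p["phi"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth.seed = int(seed)
    truth.params.update({k: v for k, v in p.items() if k != "n_per_group"})
    truth.pairs = pair_records
    return {
        "transcripts": transcripts,
        "chrom_sizes": chrom_sizes,
        "counts": cm,
        "pairs": all_pairs,
        "inverse_pairs": inverse_pairs,
        "truth": truth,
    }
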