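# nasctx

Strand-specific nascent transcriptomics at desk scale: de novo
transcription-unit discovery, natural-antisense-transcript (NAT) pairing
and inverse-regulation classification, negative-binomial differential
expression, promoter-proximal pausing, metabolic-labeling kinetics and
comparative-CT qPCR quantification — all driven by seeded synthetic-data
generators with ground-truth manifests.

## Who this is for

Nascent-RNA assays (GRO-seq and relatives) resolve *where* and *how
strongly* RNA polymerase is transcribing, strand by strand and
independently of transcript stability. That makes them the tool of
choice for studying convergent antisense transcription: a long noncoding
RNA transcribed from the strand opposite a coding gene can repress its
host in *cis*, and the signature is inverse regulation of the pair under
stimulus. `nasctx` packages every analysis step of that workflow as a
tested, reusable library with a thin CLI, so the statistics can be
exercised, calibrated and validated on synthetic data with known truth.

## What it computes

* **Transcription units** from strand-separated coverage: maximal runs of
  depth ≥ *d*, bridging sub-threshold gaps ≤ *g* bp, discarding units
  shorter than 200 bp (the conventional lncRNA lower bound), then merged
  with a reference annotation with overlap-based de-duplication.
* **Sense–antisense pairs**: a coding gene and an opposite-strand
  transcript whose gene-body overlap covers at least 10% of the antisense
  transcript's length (inclusive), labeled convergent / divergent /
  nested.
* **Differential expression**: features with >10 counts in ≥70% of some
  group's samples are kept; TMM (trimmed mean of M-values) scaling
  factors; NB dispersion φ (variance μ + φμ²) by Cox–Reid adjusted
  profile likelihood with tagwise shrinkage; per-feature log-linear NB
  GLM likelihood-ratio test (χ², 1 df); Benjamini–Hochberg FDR; calls at
  |log₂FC| ≥ 0.7 and FDR < 0.01.
* **Regulation classes**: ASRG (both pair members differential, opposite
  signs — the antisense-regulated archetype), NARG (both differential,
  same sign), or not regulated; plus the Pearson correlation of paired
  fold changes.
* **Pausing**: signal density over the first 300 bp downstream of the
  TSS versus the rest of the gene body, compared between conditions with
  Welch t tests.
* **Kinetics**: the OLS slope of labeled-RNA abundance on labeling time
  (approach-to-equilibrium design) as a synthesis-rate proxy, with a
  condition×time interaction t test for slope equality.
* **qPCR**: ΔΔCT relative expression (2^−ΔΔCT), with replicate statistics
  on the ΔCT scale and Bonferroni-adjusted Welch t tests.
* **HRE scanning**: all matches of the hypoxia response element core
  consensus RCGTG on both strands of a promoter sequence.

## Worked example

The default scene plants 3000 coding genes, ~300 convergent antisense
units, and 25 inversely regulated sense–antisense pairs (antisense up
2–4 log₂ units, sense down 1.5–2.5) in NB counts for 4+4 replicates:

```python
import nasctx as nx

scene = nx.default_scene(seed=42)
res = nx.run_de(scene["counts"], ("hypoxia", "normoxia"))

expressed = [p for p in scene["pairs"]
             if p.sense_id in res.index and p.antisense_id in res.index]
classified = nx.classify_regulation(expressed, res)
n_asrg = sum(p.regulation_class == "ASRG" for p in classified)
corr = nx.correlate_pairs(expressed, res)

untreated = nx.simulate_labeling(1.91, condition="untreated", seed=1)
inhibited = nx.simulate_labeling(0.34, condition="inhibited", seed=2)
fu, fi = nx.fit_synthesis_rate(untreated), nx.fit_synthesis_rate(inhibited)
diff, t, p = nx.compare_slopes(inhibited, untreated)
```

prints (via the obvious `print` statements):

```
features tested : 3310
differential    : 206
antisense pairs : 310
ASRG            : 25 (planted: 25)
pair correlation: r=-0.64, p=6.4e-37
slopes          : 1.88 vs 0.32 (p = 7.1e-18)
```

All 25 planted inverse pairs — and only those — are classified ASRG.
The pair-level fold-change correlation is negative here because the 25
large inverse effects dominate the smaller, positively correlated
background effects. The two labeling series (true slopes 1.91 and 0.34
units/min, 5% noise) are recovered and cleanly separated by the
interaction test.

The same pipeline runs from the shell on files:

```sh
nasctx sim scene --seed 42 --outdir scene/
nasctx de --counts scene/counts.tsv --design scene/design.tsv \
          --contrast hypoxia:normoxia --out de.tsv
nasctx pairs --genes scene/toy.gtf --transcripts scene/toy.gtf \
             --de de.tsv --out pairs.tsv
nasctx discover --plus scene/coverage.plus.bedgraph \
                --minus scene/coverage.minus.bedgraph --min-depth 8 --out units.bed
nasctx kinetics --series scene/labeling.tsv --compare untreated:inhibited \
                --out slopes.tsv
```

## Layout

```
src/nasctx/core.py       intervals, transcripts, coverage tracks, count matrices
src/nasctx/io.py         GTF / BED / bedGraph / TSV readers and writers
src/nasctx/discovery.py  transcription-unit caller, annotation merging
src/nasctx/quantify.py   signal quantification, RPKM, pausing
src/nasctx/diffexpr.py   filter, TMM, NB dispersion, GLM-LRT, BH calls
src/nasctx/antisense.py  pairing, regulation classes, HRE scanning
src/nasctx/kinetics.py   ddCT, labeling slopes, slope comparison
src/nasctx/simulate.py   seeded generators + truth manifests
src/nasctx/cli.py        `nasctx` command-line interface
```

See `docs/methods.md` for the statistical models, default parameters and
known limitations.
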