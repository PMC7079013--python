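# endemix

Categorize DNA-barcoded arthropod species as **likely native** or **likely
nonnative** from nucleotide-diversity signatures alone — no complete
reference library required.

## The problem

Community barcoding projects (COI barcodes from bulk arthropod sampling)
routinely sequence far more specimens than taxonomists can identify, and
most tropical endemics have no match in public reference databases. Yet
two population-genetic signatures distinguish recently introduced species
from members of an endemic radiation:

* introduced species pass through bottlenecks, so their **within-species
  diversity** (mean pairwise distance among conspecific barcodes, `sim`)
  tends to be low;
* introduced species arrive without close relatives, so their
  **nearest-neighbor distance** (mean-linkage distance to the closest
  other species in the community, `dist`) tends to be large, while members
  of an endemic radiation sit close to their sister species.

`endemix` turns those signatures into a classifier. The pipeline:

1. **QC** — drop barcodes under 300 bp, drop order-level contaminants
   (specimens whose best reference-library hit belongs to a different
   order than their morphological ID), and drop sequences without >100 bp
   of pairwise overlap with every other sequence in their order alignment.
2. **Species delimitation** — barcode-gap partitioning per order
   (ABGD-style recursive gap detection over a log grid of prior maximum
   intraspecific divergences P; the working prior is chosen where the
   initial and recursive species-count curves meet).
3. **Distances** — Kimura two-parameter (or p-) distances with pairwise
   deletion; per-species `sim` and `dist` statistics.
4. **Identification update** — morphological species names propagate
   through each species-group; unnamed groups take names from reference
   matches (≥97% → species, 90–97% → genus, 80–90% → family, else
   "*Order* sp."); species-rank names are looked up in a biogeographic
   checklist to build the training labels.
5. **Model** — four candidate binomial GLMMs with logit link,
   status (endemic = 1, introduced = 0) as response, `sim` and/or `dist`
   as fixed effects and a random intercept per order:

   `status ~ sim + dist + (1 | order)` (and the `sim × dist`, `dist`,
   `sim` variants), fitted by Laplace-approximated maximum likelihood and
   compared by AICc; the best model scores every species on [0, 1].
6. **Categorization** — a species is `GLMM-Native` if its score reaches
   the lower 95% confidence bound (mean − 1.96 SE) of the endemic
   training scores, `GLMM-Nonnative` if it does not exceed the upper
   bound of the introduced training scores, `GLMM-Undet` in between, and
   `NA` if it is a singleton with no within-species statistic. Directional
   error rates (endemic called nonnative and vice versa) are reported per
   order and overall.

A seeded synthetic-community generator (`endemix.simulate`) emulates the
statistical structure of an island arthropod survey — endemic radiations
with nearest-neighbor distances around 0.05, isolated introduced lineages
around 0.18, within-species diversity near 0.008, a partial checklist,
contaminants and short sequences — so the whole pipeline is testable
offline.

## Worked example

```python
import tempfile
import endemix as em
from endemix.pipeline import PipelineConfig, run_pipeline

com = em.simulate_community(em.SimConfig(rng_seed=7))
indir = tempfile.mkdtemp(); com.write(indir)
res = run_pipeline(PipelineConfig(input_dir=indir, out_dir=tempfile.mkdtemp()))

print(res.model_comparison.round(2).to_string(index=False))
print(res.species["category"].value_counts().to_string())
```

prints

```
formula_id     LL  K   AICc  dAICc  weight
      dist  -9.11  3  24.50   0.00    0.66
  sim+dist  -9.08  4  26.63   2.13    0.23
  sim*dist  -8.64  5  28.01   3.51    0.11
       sim -54.74  3 115.77  91.27    0.00

GLMM-Nonnative    98
GLMM-Native       86
NA                39
GLMM-Undet        17
```

The nearest-neighbor distance dominates model selection (the `sim`-only
model is ~90 AICc units worse), exactly the signature the method relies
on. 184 of 240 species get a confident call; the 39 `NA` species are
singletons. On this community the directional error rates are 1.6%
(introduced) and 0.0% (endemic), i.e. 99.2% accuracy against the
simulated truth.

The same pipeline runs from the shell:

```bash
endemix simulate --seed 7 --out-dir data/
endemix run --input-dir data/ --out-dir results/
```

writing `species_summary.csv`, `model_comparison.csv`, `partitions.csv`,
`curves.csv`, `identities.csv`, `thresholds.json`, `error_report.csv` and
a reproducibility manifest.

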