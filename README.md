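# nirclda

Geographical-origin classification of food samples from near-infrared (NIR)
spectra, built around **common-vectors linear discriminant analysis (CLDA)**
and its boosted ensemble, **AdaBoost-CLDA**.

## The problem

A portable NIR spectrometer measures an absorbance spectrum per sample —
here 228 channels spanning 900–1700 nm (5894.5–11111 cm⁻¹) — and the task
is to assign each sample to one of C origin classes from a small labelled
training set (tens of samples per class).  With d = 228 channels and
M = 160 training samples over C = 4 classes, the within-class scatter

    S_W = Σᵢ Σₘ (xₘⁱ − μᵢ)(xₘⁱ − μᵢ)ᵀ

has rank at most M − C = 156 < d, so classical Fisher LDA is undefined:
this is the *small-sample-size* problem.

## The methods

**CLDA** discriminates in the null space of S_W.  An orthonormal basis Q of
range(S_W) is computed from the M×M Gram matrix of the class-centered
training samples (the 228×228 scatter is never formed).  Projecting any one
sample of a class onto null(S_W),

    x_comⁱ = x − QQᵀx,

gives the class's *common vector* — identical for every sample of the class.
The scatter of the C common vectors is eigendecomposed, its C − 1 non-null
eigenvectors form the projection W, and the *discriminative common vectors*
Ωᵢ = Wᵀxₘⁱ act as class templates; a test spectrum is assigned to the
nearest Ωᵢ in Euclidean distance.  On the training set this classifier is
exact (every training sample projects exactly onto its own Ωᵢ).

**AdaBoost-CLDA** wraps CLDA in an AdaBoost.M1 loop: each round resamples
the training set from the current weight distribution, fits CLDA on the
subset, and uses nearest-Ω in that round's subspace as the weak classifier.
The weighted error εₜ on the full training set sets the round's voting
weight αₜ = ½ln[(1−εₜ)/εₜ], misclassified samples are up-weighted to carry
half the next distribution, and the ensemble predicts by α-weighted
plurality vote.  Exact training separability of each individual round would
make boosting vacuous; resampling restores a meaningful εₜ.

Also included: Savitzky–Golay / MSC / SNV preprocessing, the PCA+LDA
baseline, KNN and Gaussian naive-Bayes back-end classifiers, a synthetic
spectra generator, and a CLI.

## Data format

Delimited text (CSV/TSV by extension).  Header row: `sample_id`, `label`,
then the numeric channel axis; one spectrum per row:

```
sample_id,label,5894.5,5917.5,5940.4
s0001,gansu,0.412,0.418,0.425
s0002,gansu,0.398,0.404,0.410
s0003,henan,0.441,0.446,0.452
```

A long-format reader (`sample_id,wavelength,absorbance,label`) is also
provided.  The axis is metadata only — no algorithm reads it.

## Worked example

```python
from dataclasses import replace
from nirclda import RunConfig, PreprocessSpec, run_experiment
from nirclda.synthetic import generate, preset

data = generate(replace(preset("overlapping"), seed=0))
for extractor in ("pca_lda", "clda", "adaboost_clda"):
    cfg = RunConfig(preprocess=PreprocessSpec([("SG", {})]),
                    extractor=extractor, classifier="knn", knn_k=7,
                    boost_T=10, seed=0)
    print(extractor, run_experiment(data, cfg).accuracy)
```

prints (SG preprocessing, KNN with K = 7, seed 0):

```
pca_lda 0.2125
clda 0.65
adaboost_clda 0.9375
```

The `overlapping` preset generates four origin classes whose band
amplitudes differ too little for a single discriminant subspace: plain
CLDA reaches 65% on the held-out third, while ten boosted CLDA rounds
reach 93.75% (the staged vote climbs 0.66 → 0.93 over the iterations).
PCA+LDA collapses on this seed because smoothing concentrates the retained
variance on scatter directions.  Averaged over 20 seeds the ordering is
CLDA 0.80 < PCA+LDA 0.84 < AdaBoost-CLDA 0.92 (see the test suite).

The same pipeline from the shell:

```bash
nirclda simulate --preset overlapping --seed 0 --out data.csv
nirclda split --in data.csv --out-train train.csv --out-test test.csv --ratio 2:1 --seed 0
nirclda train --in train.csv --method adaboost_clda --boost-rounds 10 --seed 0 --out model.npz
nirclda predict --model model.npz --in test.csv --out pred.csv
nirclda evaluate --data test.csv --pred pred.csv
nirclda grid --in data.csv --classifier knn --out grid.csv   # 6 recipes x 3 extractors
nirclda ksweep --in data.csv --kmax 15                       # accuracy vs K
```

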