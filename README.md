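# glmsarray

Analysis pipeline for massively parallel, real-time measurements of
**glmS ribozyme self-cleavage kinetics** on an RNA array.  The glmS
riboswitch performs a ligand-dependent self-cleavage reaction: its observed
first-order rate follows Michaelis–Menten kinetics in the cofactor
glucosamine-6-phosphate (GlcN6P),

```
k_obs(C) = k_cat · C / (K_M + C),          C = [GlcN6P]
```

so measuring the fluorescence decay of thousands of barcoded sequence-variant
clusters at several ligand concentrations yields `k_cat` and apparent `K_M`
for every variant, and from those, maps of mutational interactions
(double-mutant rescue) and of the link between catalysis and evolutionary
conservation.

The package is written for RNA biochemists and quantitative-biology groups
who want to analyse (or prototype against a simulation of) such array
experiments.  It covers:

* **synthetic data** — a forward model of the whole experiment: doped-synthesis
  mutant libraries (1.3% per non-consensus base over a 54-nt region, point
  deletions and double-incorporation insertions, bottlenecking to a fixed
  molecule count), 16-nt random barcodes, sequencing errors, and per-cluster
  decay traces over a two-phase ~14-h imaging schedule with tile-level
  photobleaching/drift and additive noise;
* **barcode consensus** — per-barcode modal consensus with the 66%-match and
  binomial (p < 0.05 against a uniform null) filters, and cluster assignment
  at Hamming distance < 3;
* **normalization** — per-cluster baseline division (two pre-ligand images),
  then per-tile correction by ten non-cleaving reference single mutants
  (G1C, G1U, C2G, C2A, G3C, A27G, C28G, G56C, G56U, G57C), then per-variant
  per-tile medians;
* **kinetic fitting** — single- vs double-exponential fits (Levenberg–
  Marquardt, box constraints), model choice by ΔBIC ≥ 10, fast-rate
  extraction with the 10% amplitude rule, quality filtering by a maximum
  BIC, and the gel-based fraction-cleaved model for bulk cross-checks;
* **Michaelis–Menten fitting** — inverse-variance weighted fits across the
  five assayed concentrations (0.04, 0.16, 0.64, 2.5, 10 mM) with the
  σ(k_cat) < k_cat and σ(K_M) < K_M acceptance rules;
* **variant interactions** — rescue ratios k_obs(i,j)/k_obs(j) with the
  ≥ 1σ significance rule, heatmap matrices with background 1, and automatic
  duplex (secondary-structure) inference from anti-diagonal rescue bands;
* **conservation** — Needleman–Wunsch alignment of homolog sets to the
  consensus, per-base mutation frequencies, and Spearman correlation (with
  the two-tailed t-transform p-value) against kinetic parameters.

The two fitting cores follow the model/results idiom: build a model object
from data, call `fit()`, get a results object with estimates, errors,
diagnostics and a `summary()`.

## Worked example

Simulate consensus-ribozyme clusters at each GlcN6P concentration, run the
normalization, fit the decay at 10 mM, then fit the Michaelis–Menten curve:

```python
import warnings
from glmsarray import DecayModel, MichaelisMentenModel, ConcentrationSeries
from glmsarray.simulate import (build_ground_truth, clusters_to_frame,
                                default_schedule, simulate_clusters)
from glmsarray.normalize import normalize_experiment
from glmsarray.construct import REFERENCE_NONCLEAVER_LABELS
from glmsarray.variants import Variant

schedule = default_schedule()
labels = ["consensus", "G7C"] + list(REFERENCE_NONCLEAVER_LABELS)
variants = [Variant.from_label(l) for l in labels]
truth = build_ground_truth(variants, schedule, seed=0, n_tiles=2, noise_sd=0.02)

concs, k_obs, sigma = [0.04, 0.16, 0.64, 2.5, 10.0], [], []
for c in concs:
    clusters = simulate_clusters([(v, 1) for v in variants], truth, c, 4, seed=1)
    table = clusters_to_frame(clusters)
    table["variant"] = table["true_variant"]
    series, _ = normalize_experiment(table, schedule)
    fit = DecayModel.from_series(series[series["variant"] == "consensus"]).fit()
    k_obs.append(fit.k_obs); sigma.append(fit.sigma_k_obs)

print(fit.summary())
mm = MichaelisMentenModel(
    ConcentrationSeries(tuple(concs), tuple(k_obs), tuple(sigma))).fit()
print(mm.summary())
```

which prints

```
Exponential decay fit
==========================================
points                104
model                 single
k_obs (1/s)           0.06565
sigma k_obs (1/s)     0.0007202
BIC single / double   -979.2 / -970.0
quality pass          True
below detection floor False

Michaelis-Menten fit
==========================================
points                5
k_cat (1/s)           0.07887 +/- 0.00089   accepted: True
K_M (mM)              2.019 +/- 0.03   accepted: True
k_cat/K_M (1/s/mM)    0.03906
chi-square            0.2992
```

The 10 mM decay fit returns the consensus saturating rate (≈ 6.4 × 10⁻² s⁻¹
generated, 6.6 × 10⁻² recovered after normalization through the reference
mutants), the single-exponential model is kept because the double fit does
not improve the BIC by 10 units, and the weighted Michaelis–Menten fit
recovers the apparent K_M of ≈ 2.0 mM with both parameters passing the
σ-based acceptance rule.

## Command-line pipeline

The full pipeline (simulate → consensus → normalize → fit → mm → rescue →
conserve) runs from a shell, with YAML configuration and per-stage
subcommands:

```bash
glmsarray all --outdir results/ --seed 1 --bottleneck-size 2000 --max-variants 200
glmsarray fit --outdir results/        # re-run a single stage
```

All outputs are tidy tab-separated tables with units in the column headers
(`k_obs_per_s`, `K_M_mM`, …) plus a `manifest.json` recording the config
hash and seed.

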