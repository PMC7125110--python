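# Methods

This note documents the models, defaults and numerical choices in
`glmsarray`, and what the synthetic data do and do not emulate.

## The measurement being modelled

On an RNA array, each cluster carries clonal copies of one ribozyme variant,
transcribed in situ and scored by a fluorescent probe hybridised 5' of the
cleavage site.  Self-cleavage releases the probe, so the cluster's
fluorescence decays with the variant's observed cleavage rate.  Imaging a
chip at a ligand concentration C for ~14 h yields, per cluster, an intensity
time series; repeating at several C values traces out the Michaelis–Menten
curve k_obs(C) = k_cat·C/(K_M + C).  Apparent K_M refers to the assay's
buffer context (physiological Mg²⁺); no Mg dependence is modelled.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the test-suite and the acceptance script.

**Library.** Doped solid-phase synthesis over a 54-nt region: each doped
position independently receives each of the three non-consensus bases with
probability 0.013 (the value that, with ~0.039 total per-position mutation
probability over 54 positions, maximises two-mismatch molecules — the grid
optimum is d* ≈ 0.0123), a point deletion with probability 0.002 and a
double incorporation (duplicate of the expected base) with probability
0.002.  The synthesis indel rates are not experimentally constrained;
0.002/position is a typical solid-phase error scale and is configurable.
The pool is bottlenecked to 700,000 molecules by default (binomial draw of
per-position events for each molecule, then collapse to canonical genotypes
with abundances).  Barcodes are 16-nt uniform random.

**Default construct.** The packaged 66-nt core consensus is synthetic: it is
not a natural glmS sequence but realises the architecture the analysis
expects — duplexes P1, P2, P2.1, P2.2 of the double pseudoknot, the bulged
A6, and the catalytically essential residues around the A(−1)G1 cleavage
dinucleotide — so that every named quantity (reference mutants, duplex
rescue diagonals) is well defined.  Numbering: cleavage-site G = 1, upstream
A = −1, no position 0; a 5-nt linker (AUAAA) precedes the core.

**Genotype canonicalisation.** Deletions and double-incorporation insertions
inside homopolymer runs are normalised to the leftmost position of the run.
Because a substitution adjacent to an indel can make two distinct genotype
descriptions sequence-identical, the sequence-based caller is the canonical
authority for indel-containing variants: the genotype is re-called from the
mutated sequence (global alignment, gap-placement search, minimal-mutation
tie-break, and a hard check that the call reproduces the sequence).  Rare
indel+substitution combinations that admit no in-model minimal call keep
their event-based genotype; clusters carrying them are reported unassigned
by the caller rather than mislabelled.

**Kinetics ground truth.** A structure-aware effect model maps genotypes to
k_cat multiplicatively: disrupting a designed basepair costs ×0.02 (once per
pair, mismatch-on-mismatch doubles included), a compensatory double that
restores Watson–Crick pairing costs only ×0.5, any mutation at a
catalytic/binding position (1, 2, 3, 26, 27, 28, 45, 52, 56, 57) costs
×10⁻⁵, other substitutions ×0.7, deletions ×0.05 and insertions ×0.5 extra,
floored at 10⁻⁸ s⁻¹.  Consensus k_cat = 7.68 × 10⁻² s⁻¹ (so that k_obs at
10 mM is 6.4 × 10⁻² s⁻¹ with K_M = 2.0 mM); per-variant K_M scatters
lognormally (σ = 0.2 in log space) around 2.0 mM, independently of k_cat.
An `independent=True` mode disables pairing logic so double-mutant rates are
exactly the product of single-mutant reductions (used to test the
independence expectation).  Setting `catalytic_positions=frozenset()` gives
a library whose rates depend solely on pairing status (used for planted
secondary-structure recovery).

**Traces.** intensity(t) = baseline × gain_tile(t) × exp(−k_obs·t_post) +
ε, ε ~ N(0, noise_sd × baseline) truncated at 0, with noise_sd = 0.02 by
default.  The imaging schedule holds two t = 0 baseline images, 10-s
sampling for the first 5 min, then geometric spacing (factor 1.3) to
50,400 s; it spans rates 10⁻¹–10⁻⁶ s⁻¹.  Tile gains decay monotonically to
a uniform-random fraction (0.5–0.9) of their initial value, emulating
photobleaching, degradation and focus drift.  Clusters are spread
round-robin over tiles from a random offset — on a real chip every
well-represented variant appears on every tile, and the ten reference
mutants must be present per tile for normalization.

**What is not emulated.** Optics and image registration, transcription
kinetics, probe-hybridisation thermodynamics, the Cy5 registration channel,
spatial within-tile structure, cross-chip pooling, and real sequencing
error profiles (errors are iid substitutions).  Passing tests therefore
demonstrate the statistical machinery — normalization cancelling
multiplicative systematics, model selection, weighted fitting, rescue
logic — not robustness to image-level artefacts.

## Normalization

Each cluster is divided by the mean of its two pre-ligand baseline images
(nonpositive baselines discard the cluster, with the id logged).  Then, per
tile and timepoint, the correction factor is the mean over the ten
reference non-cleaving single mutants of the per-variant median cluster
intensity; every cluster value is divided by it, cancelling any tile-wide
multiplicative systematic exactly in the noiseless case.  Aggregation is
median over clusters within (variant, tile, timepoint).  Variants observed
in multiple tiles contribute their per-tile median series as independent
observations to the fit (points tagged by tile, concatenated); this
preserves the per-tile error structure rather than averaging tiles.

## Exponential fitting and model selection

Surviving-signal models with an additive offset b (incompletely cleaved or
non-releasing fraction):

* single: y = a·exp(−k t) + b
* double: y = a·[f·exp(−k_f t) + (1−f)·exp(−k_s t)] + b

Fits use Levenberg–Marquardt (lmfit) with box constraints k ∈ [10⁻⁷, 1] s⁻¹,
a ∈ [0, 2], b ∈ [0, 0.2], f ∈ [0, 1].  The single fit multistarts over one
decade around a half-decay initial guess, ties resolved toward the slower
rate; the double fit initialises from the single fit and enforces
k_fast ≥ k_slow by relabelling after the fit (identical optimum to a
reparameterisation, but keeps each rate's covariance-derived error attached
to the right parameter).  BIC = n·ln(RSS/n) + p·ln(n) with p = 3 (single)
or 5 (double); the single model is adopted unless ΔBIC ≥ 10.  The
characteristic rate is the faster rate when it carries ≥ 10% of the decay
amplitude, else the slower.  Rates at or below 10⁻⁶ s⁻¹ are flagged
`below_floor`: over a 50,400-s schedule a 10⁻⁶ s⁻¹ decay loses only ~5% of
signal, and 10⁻⁷ s⁻¹ is indistinguishable from a non-cleaver.  Constant
series land at the k lower bound with `below_floor` set.

The quality filter excludes fits with BIC above a configurable maximum,
default −200: for a ~52-point series this requires rms residuals below
~0.15, which structured decay fits at the default noise easily meet and
pure-noise series fail.  It scales with n only logarithmically, so runs
with very different schedule lengths should revisit it.

The gel-based fraction-cleaved model
F(t) = F0 + (Fmax − F0)·{1 − [f·exp(−k_f t) + (1−f)·exp(−k_s t)]} is fit
with 0 ≤ F0 ≤ Fmax ≤ 1 enforced via a nonnegative span parameter.

## Michaelis–Menten fitting

Weighted least squares, χ² = Σ[(k_obs − k_cat·C/(K_M+C))/σ(k_obs)]², over
the concentrations with quality-passing decay fits (≥ 3 required).
"Weighted" is read as inverse-variance in the measured σ(k_obs).
Initialisation k_cat₀ = max k_obs, K_M₀ = 1 mM; bounds K_M ∈ [10⁻³, 10³] mM
prevent runaway on flat series.  Parameter errors come from the fit
covariance without reduced-χ² rescaling, because the weights are real
measurement errors; the acceptance rules σ(k_cat) < k_cat and
σ(K_M) < K_M are applied independently per parameter.  A point with an
unusable σ receives the median weight rather than being dropped.

## Rescue analysis

For each double mutant (i, j) with both constituent singles measured, the
rescue ratio is k_obs(i,j)/k_obs(j), evaluated against both singles as
reference.  Heatmap matrices store max(ratio, 1) (background 1), ordered by
position then mutant base (A<C<G<U), deletions then insertions after
substitutions.  Significance requires |k_obs(i,j) − k_obs(j)| ≥ 1σ using
the single mutant's rate error; when that error is unavailable or the
single's rate is at/below the 10⁻⁶ s⁻¹ floor, the double's error is used.
Significance is judged in rate space (not log-rate), as literally worded by
the rule.  Duplex inference scans for position pairs (p, q) supported by a
WC-restoring substitution double that significantly rescues both singles
with ratio > 2, and calls maximal anti-diagonal runs (p, q), (p+1, q−1), …
of length ≥ 3; bulged or catalytically constrained pairs shorten runs and
are reported only as part of a qualifying run.

## Conservation

Homologs are aligned to the core consensus with Biopython's global
PairwiseAligner under EMBOSS-Needle-like affine scores (match 5, mismatch
−4, gap open 10, extend 0.5; the tool's named defaults, since no parameters
are fixed by the protocol).  Internal gaps count as deletions at the
aligned positions; terminal gap runs count as missing data (truncated
records contribute no information at the positions they lack).  Per-base
mutation frequency is the count of each non-consensus base (or deletion)
over sequences with data at that position.  Correlation against kinetic
parameters pairs by exact mutation identity (position + base change) and
uses Spearman's ρ with the two-tailed p from t = ρ√((n−2)/(1−ρ²));
constant inputs yield an undefined ρ, reported as such.  The synthetic
homolog generator draws per-position substitution probabilities as an
increasing function of the single-mutant k_cat (scale 0.12, power 0.35,
plus optional terminal truncations), so conservation tracks catalysis by
construction while K_M is uninformative — the pipeline should, and does,
find ρ(k_cat) strongly positive and ρ(K_M) near zero.

## Pipeline, sizes and reproducibility

One global seed fans out to per-stage generators through SHA-256-derived
SeedSequence keys.  Stages communicate through tidy TSV tables with units
in the headers; a manifest records the config hash and seed.  The default
test-suite problem sizes are chosen for desk-scale runs: end-to-end
recovery uses a 200-variant library (bottleneck 600, 3 tiles, 3
clusters/variant) over the five assayed concentrations; model-selection
operating characteristics use 200 + 40 seeded replicates; full-scale
defaults (700,000 molecules, 19 tiles) remain available through the config.

Reproducibility contract: simulation-side tables (library, ground truth,
schedule, reads, consensus map) are byte-identical for identical config and
seed.  Tables produced by iterative fitting reproduce numerically (relative
differences well below 10⁻⁶ in practice) but not always bitwise: vectorized
libm kernels round prologue/epilogue lanes differently depending on heap
alignment, and on ill-conditioned series the optimizer amplifies that
last-ulp jitter into visible digits of diagnostic quantities.  Scientific
results are unaffected.

## Known limitations

* Insertions are modelled only as double incorporations; arbitrary-base
  insertions are outside the genotype model and are reported unassigned.
* The detection floor and quality threshold assume the default ~14-h
  schedule; shorter schedules shift both.
* Equal-length reads carrying a compensating deletion+insertion pair are
  genotyped positionally when ≤ 3 mismatches result, which can mask the
  indel pair (matching how Hamming-based assignment treats them).
* The conservation module recomputes frequencies from supplied alignments
  only; no phylogenetic weighting or covariation analysis is attempted.
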