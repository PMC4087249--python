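# Methods

## Problem and model

The package scores single amino acid variants (SAVs) for
disease association. The unit of prediction is one substitution
(protein, 1-based position, wild-type residue, mutant residue); the
output is a calibrated probability of disease association scaled to
0–100, with scores above 50 called disease. The classifier is a
radial-basis-function SVM over per-variant feature vectors; features
describe both the position (conservation, annotations, predicted
solvent accessibility) and the protein's context in interaction
networks, reflecting the premise that variants in centrally placed,
disease-susceptible proteins are more likely to be pathogenic
regardless of the exact position hit.

## Features

**Conservation.** PSSM features read the wild-type score, the mutant
score and their difference from a PSI-BLAST ASCII matrix (or from a
log2-odds matrix computed internally from an alignment with a
pseudocount against the BLOSUM62 background — a stand-in so synthetic
tests need no PSI-BLAST run). Jensen–Shannon divergence of an
alignment column P against background Q is
λ·KL(P‖M) + (1−λ)·KL(Q‖M), M = λP + (1−λ)Q, base-2 logs, hence bounded
in [0, 1]; columns with ≥ 99.9 % gaps are excluded. Defaults: λ = 0.5,
BLOSUM62 marginal background, uniform row weights — the divergence
reference leaves these open, and uniform weights keep the oracle tests
exact. E-value-ordered divergence features scan homologues by
ascending E-value for the first row differing from the wild type and
the first carrying the mutant; when none exists the E-value falls back
to 10 (the usual PSI-BLAST inclusion ceiling) and the identity to 0,
both configurable. Percent identity is computed over columns where
both query and subject are non-gap (identity over query length is an
option). Domain-HMM emission differences e(wt) − e(mut) are missing
outside any domain.

**Networks.** Graphs are undirected and simple, at protein
(interactome), domain (domain–domain and domain-bigram) and residue
scales; residue contact graphs join residues whose minimum heavy-atom
distance is below 5 Å (Cβ-only is an option). Degree, betweenness,
closeness and coreness are computed per node. Betweenness is
normalised by (n−1)(n−2)/2 (raw counts optional). Closeness follows
the inverse-sum-of-distances definition, evaluated within the node's
connected component; harmonic closeness is available when
cross-component comparability matters. Coreness is the classical
k-core index; isolated nodes get 0. networkx supplies the graph
machinery; closeness is computed directly from BFS distances because
the library default rescales by component size.

**Amino-acid properties.** BLOSUM62 (from biopython), side-chain
charge change (D/E −1, K/R +1, His neutral by default, configurable),
to/from glycine and proline flags, Atchley five-factor deltas
(vendored table), GRAVY (mean Kyte–Doolittle hydropathy) and the
aliphatic index X_A + 2.9·X_V + 3.9·(X_I + X_L). A genetic-code check
flags substitutions unreachable by a single nucleotide change.
Predicted solvent accessibility, disorder and annotation counts enter
as per-position TSV tracks; their upstream predictors are deliberately
not re-implemented.

## Feature selection

Stability selection over mRMR. Each of 100 subsets draws half the
variants without replacement; mRMR greedily picks 30 features per
subset, scoring a candidate f given the picked set S as
I(f; y) − α·mean_{s∈S} I(f; s) with α = 0.5 and ties broken by feature
name. Mutual information is the plug-in estimate on 10 equal-frequency
bins (missing values form their own bin; binary labels are used as
is) — the estimator is a design choice here, made for determinism and
speed. Features picked in every subset (keep threshold 1.0, exposed)
form the chosen set. All subsampling derives child seeds
deterministically from the run seed.

## Classifier

Features are min-max scaled to [0, 1] on the training set (constant
columns map to 0; prediction-time values clip into range). Missing
entries are imputed with the training-set feature mean — the original
protocol falls back to sequence-only prediction when structure is
unavailable but states no imputation rule, so the mean rule is this
package's choice, recorded per feature in the missingness mask. The
SVM uses an RBF kernel with C = 128 and γ = 0.01 and Platt-style
probability calibration (scikit-learn's `SVC(probability=True)`);
score = 100 × P(disease). A call at exactly the cutoff is neutral —
the published rule names the cutoff but not the boundary side. A
data-driven (C, γ) search is provided: γ from the
quantile-of-pairwise-squared-distances heuristic (inverse of the
midpoint of the 0.1/0.9 quantiles), C by stratified 10-fold CV
maximising balanced accuracy, ties to the smaller C (the original CV
objective is unstated). No class weighting by default; an option
exists.

## Evaluation

The six confusion metrics use the standard printed formulas; zero
denominators yield 0 (MCC and precision conventions are documented
design choices). AUC is the tie-aware Mann–Whitney statistic; its
variance and the paired AUC comparison use DeLong's placement-value
estimator with a two-sided normal p (sidedness is a package choice).
Zero variance of an AUC difference returns p = 1 with a logged note.

## Synthetic data

Generators plant known ground truth: (i) feature matrices with k
informative columns N(d, 1) vs N(0, 1) and pure-noise columns, so the
Bayes-optimal AUC is Φ(d√k/√2) in closed form; (ii) alignments with
designated conserved columns (query residue repeated with probability
0.95), i.i.d. gaps and strict rank-based E-values (1e−50·10^rank);
(iii) Barabási–Albert or Erdős–Rényi graphs whose node disease
propensity is logistic in the z-scored degree. The standard study uses
9 informative of 77 features, d = 1.5, 1000 variants per class —
mirroring the published design's scale (nine selected of 77 candidate
features) at a desk-scale sample size. Gaussian class-conditionals
were chosen over copying real feature marginals precisely because they
admit the closed-form Bayes AUC used in quantitative tests. What
passing tests show is therefore recovery of planted structure and
internal correctness; they do not certify performance on real variant
compendia, whose features are correlated, heavy-tailed and
missingness-structured in ways the generator does not emulate.

## Numerical and interface choices

Positions are 1-based at every public boundary. Non-canonical residues
are kept in sequences but rejected in variants, since the 20-letter
feature tables are undefined for them. Variant labels other than
disease/neutral map to unknown and are excluded from training. The
PSSM reader accepts the PSI-BLAST ASCII dialect (40 or 42 numeric
fields per row) and reorders columns to the package's canonical
alphabet. Stochastic components (subsampling, CV folds, calibration)
all derive child seeds from one run seed, making the pipeline
end-to-end reproducible; the model file is a JSON header plus a binary
payload and validates its format version on load.

## Problem sizes

Tests and the acceptance script run the standard synthetic study
(2000 variants, 77 features, 100 stability subsets), brute-force
centrality oracles on ~10³ graphs of ≤ 8 nodes, 10⁴ random confusion
tables against an independent implementation, and a 1000-replicate
null simulation for DeLong's test — sizes chosen so the full pipeline,
including the published 100-subset selection rule, runs in minutes on
one core.

## Known limitations

Structure-derived features beyond residue networks (secondary
structure, pockets, catalytic-site flags) are consumed only as generic
tracks. The mRMR α convention (relevance minus α·mean redundancy) is
the common reading of an underspecified parameter. Real-data
performance claims require real training data; nothing here retrains
or re-benchmarks against external variant databases.
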