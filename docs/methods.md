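# Methods

## Problem and model

`ppamut` predicts ΔΔG, the change in binding free energy of a
protein–protein complex upon single-point mutation, in kcal/mol. The sign
convention is ΔΔG = ΔG_mut − ΔG_wild with ΔG = −RT ln(1/K_d); since more
negative ΔG means tighter binding, positive ΔΔG means the mutation
reduces affinity. R is fixed at 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ so that all
energies are in kcal/mol; when a record carries a K_d pair but no
temperature, 298.15 K is assumed.

The predictor is a two-stage ensemble trained separately per functional
class of the complex (antigen–antibody, enzyme–inhibitor, G-protein,
receptor, other-enzyme, miscellaneous — binding-energy distributions
differ systematically between these categories, and class-wise models
outperform a pooled one):

1. a feed-forward encoder — input layer, one hidden ReLU layer (default
   width 64), and a 12-unit ReLU output layer — trained as a regressor on
   standardized features with a temporary linear head minimising mean
   squared error (Adam, learning rate 10⁻³, batch 32, 200 epochs, no
   early stopping so runs are bit-reproducible). The head is discarded;
   the 12-D activation is the embedding. Training the encoder
   supervised, rather than as an autoencoder, follows from treating the
   network as a single prediction model whose bottleneck regularises the
   feature space.
2. a random-forest regressor (100 trees, unlimited depth, seed-pinned,
   single-threaded) fitted on the embedding.

The embedding width of 12 is the model's defining bottleneck and is kept
fixed unless explicitly overridden.

## Features

- **Property deltas.** ΔP = P_mut − P_wild for every property in the
  active table. The shipped default table carries ten widely used
  literature scales (Kyte–Doolittle hydrophobicity, Zamyatnin volume,
  Bhaskaran–Ponnuswamy flexibility, normalized-B-factor fluctuation,
  Grantham polarity, isoelectric point, Chou–Fasman α/β propensities,
  Zimmerman bulkiness, and a generic interface-propensity column). Any
  user table in the same CSV layout (20 residues × properties) replaces
  it; results are table-relative by design.
- **Mutation descriptors.** Net volume, hydrophobicity, flexibility and
  fluctuation change — ΔP over the four designated scales.
- **Profile features.** Wild and mutant log-odds, their difference, and
  the per-site information content from a PSI-BLAST ASCII PSSM.
  Conservation scores are ingested from a two-column TSV (position,
  score) as produced by standard conservation scorers; they are never
  recomputed internally.
- **Structure features.** Computed on the wild-type structure at the
  mutation site (the mutant side chain is not modelled):
  - SASA by the dot-sphere (Shrake–Rupley) construction, 960
    quasi-uniform golden-spiral dots per atom, probe 1.4 Å, vdW radii
    C 1.70 / N 1.55 / O 1.52 / S 1.80 Å (1.80 Å for anything else).
    Relative SASA divides by theoretical Gly-X-Gly maxima, so termini
    can slightly exceed 1.
  - Interface region from monomer-vs-complex relative SASA at the 25%
    burial threshold with a 10⁻⁶ change tolerance: residues that lose
    area upon complexation are support (buried already in the monomer),
    core (exposed → buried) or rim (stays exposed); the rest are
    interior or surface. The monomer is the residue's chain extracted
    alone.
  - Hydrogen bonds by a hydrogen-free geometric rule: a donor heavy atom
    within 3.5 Å of a chemically eligible acceptor heavy atom of another
    residue (per-residue donor/acceptor dictionaries; backbone N donates
    except proline, backbone O accepts). Chosen because predicted models
    usually lack hydrogens.
  - Residue depth: mean distance of the residue's heavy atoms to the
    nearest solvent-accessible surface dot of the whole structure. A
    single-atom structure degenerates to r + probe.
  - Contact-network centralities on the residue graph with edges at
    representative-point distance strictly < 8 Å (Cβ, Cα for glycine,
    centroid fallback; minimum-heavy-atom distance available behind a
    flag). Degree is normalized by n−1, betweenness by (n−1)(n−2)/2,
    closeness uses the within-component convention, and eigenvector
    centrality is the per-component principal adjacency eigenvector
    (unit norm, nonnegative). Isolated nodes score 0 on all four.
    Centralities default to the whole complex; computing them per chain
    is a caller choice (pass the extracted monomer).
  - The region label enters the matrix as five indicator columns.

Missing structures or profiles are median-imputed with a
`structure_missing` indicator column, keeping sequence-only prediction
possible.

## Dataset curation

Mutation tables (CSV/TSV with header `complex_id,chain,position,wild,
mutant,class[,ddg,kd_wild,kd_mut,temp_K]`) are validated against
multi-FASTA sequences (`complexid_chainid` record ids); rows with unknown
residues, unknown classes, unresolvable positions, or a stated wild type
disagreeing with the sequence are rejected with per-row reasons rather
than aborting the parse. Author numbering offsets are reconciled through
an explicit per-chain offset map.

Redundancy filtering collapses exact duplicate mutations (conflicting
measured ΔΔG values are averaged — a deliberate tie-break, since no
single measurement is privileged) and then greedily removes complexes
whose best chain-pair global-alignment identity (BLOSUM62, gap open 10 /
extend 0.5, identity = identical columns / alignment length) to an
already-retained complex exceeds 25%. Keep-first order follows input
order for determinism; the filter acts per complex using the best
chain-pair identity, a choice made because interface redundancy is a
complex-level property.

## Feature selection

Two stages, run per functional class: (i) greedy correlation filter —
scanning columns in canonical order, drop a column iff |Pearson r| with
an already-retained column is strictly above 0.85 (zero-variance columns
are dropped first); the retained set provably has no pair above the
cutoff and this is asserted post-hoc. (ii) recursive feature elimination
with a seed-pinned random-forest importance, one column per iteration,
down to k features (default 20 per class, with k = 50 available for
pooled-mode selection). Which member of a correlated pair survives is the
scan order — documented, deterministic, and recorded in the
FeatureSpec's provenance along with the full RFE ranking.

## Evaluation

Metrics are Pearson's product-moment correlation, MAE and RMSE, all in
kcal/mol. Three split regimes: shuffled 10-fold over mutations;
leave-one-complex-out (one fold per complex, probing transfer to unseen
complexes); and site-grouped folds where all substitutions at one
(complex, chain, position) stay together (mode `variation` relaxes this
to a plain row shuffle). Per-fold cells with fewer than two evaluable
rows, or zero variance, report errors without a correlation. Reports
carry per-fold, pooled (mutation-weighted) and per-class tables plus an
`overall` row that is the unweighted mean across classes — both
aggregations are reported because they answer different questions.
Headline train/test numbers use a stratified-by-class 80/20 split.

Feature importance is permutation-based: the mean drop in PCC when one
column is shuffled, repeated (default 5×) with dispersion. It is
model-agnostic and needs no extra dependencies; permuting a constant
column gives exactly zero.

## Synthetic data generator

The generator emulates the full input surface: two-chain toy complexes
(chain A snakes through a compact lattice at 3.8 Å Cα spacing so buried,
exposed and interface residues all exist; chain B packs against one face
at a controllable gap), valid PDB/FASTA serializations, PSSMs whose
self-residue log-odds is maximal per row, conservation TSVs, and mutation
tables whose ΔΔG obeys a linear-Gaussian law ΔΔG = Σ w_j x_ij + ε with
recorded weights. Defaults — 20 features of which 3 carry signal with
weights (1.5, −1.0, 0.8) kcal/mol, noise σ = 0.3 kcal/mol — produce ΔΔG
spanning roughly −6 to +8 kcal/mol, the range seen in curated mutation
collections. The default toy complex exercises all five interface
regions.

What the generator does *not* emulate: realistic evolutionary profiles,
physically packed side chains, heteroscedastic experimental noise, or
class-dependent effect sizes. Passing tests therefore demonstrate that
the machinery is correct and can recover a planted signal at realistic
noise — not that the shipped defaults reach any particular accuracy on
real curated data, which requires externally curated inputs.

## Numerical choices and degenerate inputs

- Strict inequality at the 8 Å contact cutoff; hydrogen-bond distance is
  ≤ 3.5 Å.
- Dot-sphere SASA at 960 points has < 1% single-atom error against
  4π(r+probe)²; the dot density is the accuracy/time dial.
- Encoder determinism requires single-threaded training with a fixed
  seed and disabled early stopping; forests are seed-pinned with
  `n_jobs=1`.
- Classes with fewer than 10 records cannot train the encoder
  (its stated minimum) and are skipped with a low-n warning rather than
  silently fitted.
- PCC on zero-variance vectors is NaN by convention; such folds still
  report MAE/RMSE and are excluded from fold means but counted in pooled
  metrics.
- Model artifacts are single-file, carry a mandatory format-version
  field, the training-data hash and fit date; loading an incompatible or
  corrupted file raises rather than mispredicting.

## Problem sizes

The test suite and `scripts/acceptance.py` run the study at desk scale:
n = 500 mutations (80/20 holdout, 10 seeds in the tests), n = 600 across
12 complexes for the 10-fold/LOOC/site-grouped comparisons, 100 seeded
runs for the feature-selection recovery rate, and 50 random ≤12-node
graphs for the centrality oracle. These sizes give stable metrics for a
linear-Gaussian law while keeping a full run in minutes on one CPU.

## Known limitations

- Accuracy on real data is bounded by the property table and the
  ingested profiles; the shipped table is a sensible default, not the
  definitive feature inventory.
- Structural features come from the wild-type structure only; mutations
  that repack the interface are seen only through sequence-side deltas.
- The 25% identity filter uses global pairwise alignment, which can
  overestimate relatedness for multi-domain chains.
- Grid-search hyperparameter optimisation is deliberately not the
  default path; the pinned defaults favour reproducibility.
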