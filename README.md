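# ppamut

Predicting the change in binding affinity of protein–protein complexes
upon single-point mutation.

Mutations at or near a protein–protein interface shift the binding free
energy of the complex. `ppamut` implements a per-functional-class deep
ensemble that predicts this shift, ΔΔG = ΔG_mut − ΔG_wild (kcal/mol,
positive = reduced affinity), from sequence- and structure-derived
features of the mutation site. It is aimed at structural bioinformaticians
who curate mutation/affinity datasets (SKEMPI-style tables plus FASTA,
PDB/mmCIF models, PSI-BLAST PSSMs and conservation scores) and want a
reproducible, fully scriptable training/evaluation pipeline.

## The model

For data reported as dissociation constants, free energies come from

    ΔG = −RT ln(1/K_d),   R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹

and the target is ΔΔG = ΔG_mut − ΔG_wild.

Each mutation is described by four feature families:

- **property deltas** ΔP = P_mut − P_wild over a configurable amino-acid
  property table (hydrophobicity, volume, flexibility, polarity, …);
- **mutation descriptors**: net volume, hydrophobicity, flexibility and
  fluctuation change;
- **evolutionary profile**: wild/mutant log-odds, their difference and the
  information content from a PSI-BLAST ASCII PSSM, plus an ingested
  per-position conservation score;
- **structure features** at the mutation site: dot-sphere SASA and
  relative SASA, interface region (core/support/rim/interior/surface from
  monomer-vs-complex burial), hydrogen-bond donor/acceptor counts,
  residue depth, and four centralities (degree, betweenness, closeness,
  eigenvector) of the residue contact network (edges between residues
  < 8 Å apart).

Features are selected per functional class (correlation filter at
|r| > 0.85, then recursive feature elimination), standardized, and passed
through a three-layer feed-forward encoder (ReLU) whose 12-dimensional
output layer feeds a random-forest regressor. One ensemble is trained per
functional class (antigen–antibody, enzyme–inhibitor, G-protein,
receptor, other-enzyme, miscellaneous). Evaluation supports 10-fold,
leave-one-complex-out (LOOC), and site-grouped/variation-level
cross-validation with Pearson r, MAE and RMSE.

## Worked example

The package ships a synthetic-data generator that emulates every input
format at toy scale with a known linear feature→ΔΔG law, so the whole
workflow runs with no downloads:

```bash
ppamut simulate  --out-dir sim --n-mutations 300 --n-complexes 6 --seed 1
ppamut featurize --mutations sim/mutations.csv --fasta sim/sequences.fasta \
                 --structures sim/structures --pssm-dir sim \
                 --conservation-dir sim --out-dir feats
ppamut train     --features feats/features.tsv --targets feats/targets.tsv \
                 --out-dir models --regime kfold --regime looc --seed 1
ppamut predict   --model models/model_receptor.joblib \
                 --features feats/features.tsv --out preds.tsv
```

The same pipeline from Python, on the generator's features directly:

```python
import numpy as np
from ppamut import AffinityModel, EncoderSpec, metrics
from ppamut.synthetic import SyntheticConfig, make_synthetic_mutation_dataset

synth = make_synthetic_mutation_dataset(
    SyntheticConfig(n_mutations=500, noise_sigma=0.3, seed=1))
idx = np.random.default_rng(1).permutation(500)
train, test = idx[:400], idx[400:]
res = AffinityModel(synth.ddg_true[train], synth.features.data.iloc[train],
                    n_features=10).fit(seed=1)
print(res.summary())
print(metrics(synth.ddg_true[test], res.predict(synth.features.data.iloc[test])))
```

prints (abridged):

```
Affinity-change ensemble (encoder -> 12-D -> random forest)
...
features selected: 10
embedding dim    : 12
in-sample PCC    : 0.997
in-sample MAE    : 0.121 kcal/mol
...
{'pcc': 0.972, 'mae': 0.369, 'rmse': 0.478}
```

The holdout Pearson r of 0.97 and MAE of 0.37 kcal/mol sit close to the
generator's noise floor (σ = 0.3 kcal/mol), i.e. the pipeline recovers
the planted feature→ΔΔG law almost perfectly; predictions above zero are
labelled "decreases affinity", below zero "increases affinity".

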