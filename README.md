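# synergnet

Drug-synergy prediction on attributed protein–protein interaction graphs.
The package implements a complete, desk-scale pipeline:

1. **Featured graphs** (`synergnet.features`) — every protein in a shared
   PPI topology receives a 218-dimensional feature vector for a specific
   (drug pair, cell line) instance: trinary differential expression (1),
   CNV one-hot (3), thirteen mutation-type indicators (13), a combined
   drug–protein association score (1), and a 200-dimensional GO-term
   embedding.
2. **Graph reduction** (`synergnet.reduce`) — knowledge-based edge
   contraction: edges joining druggable to non-druggable nodes, edges
   incident to either drug's target nodes, and edges joining nodes with
   different expression values are pruned; the connected components of the
   persisting edges are merged into super-nodes; features are combined per
   block; all removed edges are restored as quotient-graph edges.
3. **Data augmentation** (`synergnet.augment`) — new labeled instances are
   created by substituting one drug of a pair with library drugs passing a
   combined similarity filter (fingerprint Tanimoto ≤ 0.95 and a combined
   structural/target-profile score ≥ 0.53); labels are transferred from
   the parent instance and provenance is recorded.
4. **Graph classifier** (`synergnet.gnn`) — two graph convolutional
   modules (generalized softmax-aggregation convolution → batch norm →
   ReLU), jumping-knowledge concatenation, max+mean global pooling, and a
   two-layer MLP head. Implemented on a small numpy reverse-mode autodiff
   engine (no GPU framework required); trained with Adam and
   class-weighted cross-entropy.
5. **Baseline** (`synergnet.baseline`) — degree-sorted node ordering,
   feature standardization, 32-component PCA, row-major flattening to
   fixed-size vectors, and a random-forest classifier.
6. **Evaluation** (`synergnet.evalcv`) — AUC/BAC/PPV/FPR/MCC/ΔBAC,
   stratified 5-fold cross-validation in which augmented instances whose
   parent lies in the held-out fold are excluded from training, and test
   folds contain original instances only.
7. **Synthetic data** (`synergnet.synthdata`) — deterministic generator
   for all pipeline inputs with a planted, learnable label rule (joint
   target coverage of a per-cell-line dysregulated gene module), so the
   whole stack is testable offline.

## CLI

```bash
synergnet simulate --config synth.yaml --seed 17 --out data/
synergnet stats --network data/edges.tsv --nodes data/nodes.tsv --min-confidence 0.7
synergnet reduce --data data/ --out reduced/
synergnet augment --data data/ --tc-max 0.95 --dacs-min 0.53 --out aug.tsv
synergnet evaluate --data data/ --classifier gnn --augmented aug.tsv --seed 17
```

`synth.yaml` may override any generator field (e.g. `n_proteins`,
`n_drugs`, `n_pairs`, `label_noise`).

## Notes

- File formats are plain TSV/JSON throughout; see the `simulate` output
  for the expected layout.
- The GNN is intentionally dependency-light: the autodiff engine in
  `synergnet/gnn/autodiff.py` supports exactly the operator set the model
  needs and is verified against finite differences in the test suite.
- `rdkit` is optional and only needed for SMILES-backed fingerprints
  (`synergnet.augment.fingerprint_from_smiles`); synthetic datasets ship
  precomputed fingerprints instead.
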