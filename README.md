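# extendscore

Rank-based estimation of telomerase enzymatic activity from gene expression.

A 13-gene signature is split into a **constituent component** (TERT, TERC) and
an 11-gene **marker component**. Per sample *i*, with `r_gi` the within-sample
midrank of gene *g*:

```
V_const,i  = max(r_tert,i , r_terc,i)
V_marker,i = sum over markers m of r_m,i
ES_i       = (delta * V_const,i + V_marker,i) / (N_g * N_m)
delta      = 1 / (1 - rho),  rho = Spearman(V_const, V_marker)
```

`N_g` is the total gene count of the input, `N_m` the number of signature
genes detected in it, and `delta` is computed once per dataset (clamped to
[0.5, 20] for numerical stability). Scores are min-max scaled to [0, 1].
Because everything is rank-derived, scores are invariant to expression units
(counts, TPM, RPKM, RSEM) and to any monotone normalization — but they are
**dataset-relative**: comparing scores across datasets requires scoring the
datasets jointly. When neither constituent gene is detected (e.g. single-cell
dropout), scoring falls back to the marker component alone.

The package also ships:

- **signature derivation** (`extendscore.signature`): one-sided Welch
  upregulation filter (p <= 0.05, log2 FC > 1.5 on group means with a
  pseudo-count), an anchor-gene Pearson co-expression scan over 11 cutoffs
  (0.20–0.70, step 0.05), elbow selection via the percentage difference of
  consecutive gene counts, set intersection, and constituent augmentation;
- **downstream analyses** (`extendscore.downstream`): per-sample stemness
  scores (Spearman of a gene-weight vector vs the expression vector),
  gene-label permutation tests with empirical p-values, k-means cell-cycle
  phase grouping (G1-S / G2-M / non-cycling / ambiguous), and pairwise
  two-sided t-tests with Bonferroni correction;
- **synthetic cohorts** (`extendscore.simulate`): bulk cohorts with a planted
  upregulated, mutually co-expressed signature module driven by a latent
  per-sample activity, and sparse single-cell cohorts with Bernoulli dropout,
  planted cycling phases, and optional constituent-gene dropout.

## Default signature

Only TERT, TERC, LIN9, HELLS, and POLE2 of the published 13-gene signature
are named in the publication's main text; the remaining eight marker genes
appear in supplementary material that is not redistributed here. The shipped
`default_signature.yaml` therefore carries explicit `MARKERxx` placeholders —
replace them with the published identifiers before scoring real data. The
engine is signature-agnostic: any YAML/JSON file with `constituent` (2 ids)
and `markers` (list) works, and `extend derive` produces one from your own
two-group cohort.

## CLI

All commands write a `<output>.provenance.json` record (parameters, version,
input checksums). Parameter precedence: CLI flag > `--config` YAML > default.

```sh
# score a genes-x-samples TSV (first column gene ids, header sample ids)
extend score --expr matrix.tsv --signature sig.yaml --out scores.tsv

# sparse single-cell input: MatrixMarket plus one-per-line label files
extend score --expr matrix.mtx --genes genes.txt --samples cells.txt --out scores.tsv

# derive a signature from a two-group cohort
extend derive --expr matrix.tsv --group-a a.txt --group-b b.txt \
    --anchor TERT --terc TERC --out sig.yaml --audit audit.tsv

# stemness, permutation test, cell-cycle phases
extend stemness --expr matrix.tsv --weights weights.tsv --out stem.tsv
extend permtest --expr matrix.tsv --weights weights.tsv --n-perm 1000 --seed 17 --out perm.tsv
extend cellcycle --expr matrix.tsv --g1s g1s.txt --g2m g2m.txt --out phases.tsv

# synthetic cohorts (deterministic given --seed)
extend simulate bulk --seed 7 --out sim/
extend simulate sc --seed 7 --dropout-rate 0.6 --out sim_sc/
```

`extend score` output columns: `sample_id`, `raw_score`, `scaled_score`,
`n_m_present`, `const_fraction`.

## Python API sketch

```python
from extendscore import read_expression, extend_score, default_signature

expr = read_expression("matrix.tsv")
result = extend_score(expr, default_signature())
result.to_frame()          # per-sample scores
result.contributions       # additive per-gene score decomposition
```
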