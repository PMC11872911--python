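# wcsgnet

Cell-type annotation for scRNA-seq data from **weighted cell-specific gene
association networks** (WCSNs) and a graph neural network classifier.

Most supervised annotators classify each cell from its expression vector
alone.  This package additionally builds one weighted gene-association graph
*per cell*: for cell *k* and gene pair *(u, v)*, windows of the
0.1·*n* cells nearest to *k*'s expression of each gene are compared, and the
standardized deviation of the joint window occupancy from independence

&nbsp;&nbsp;&nbsp;&nbsp;ρ′ₖ(u,v) = √(n−1) · (n·n_uv − n_u·n_v) / √(n_u·n_v·(n−n_u)·(n−n_v))

is tested one-sided against the standard normal at α = 0.01.  Significant
pairs become edges weighted by ρ′ (optionally ln(ρ′+1) or 1).  A graph
convolution h′(v) = A₁h(v) + A₂·Σ_{j∈N(v)} w_v(j)·h(j) over this network,
with the cell's log-CPM expression as node features, followed by two 1×1
convolution stages and an MLP, predicts the cell type.  Training uses a
class-weighted loss with per-class weights clamp(max_t n(t)/n(j), 1, 50),
so rare cell types stay visible.  Evaluation is a leak-free stratified
5-fold protocol: each test cell is inserted into the training pool
individually to build its own network, and training networks never see any
test cell.

Intended for computational biologists benchmarking annotation methods or
exploring per-cell network structure (hub genes, high-weight edges, their
cross-fold stability and type specificity).

## Worked example

```python
import wcsgnet as w

# A labeled synthetic benchmark: 3 cell types x 200 cells, 200 genes,
# one 20-gene co-expression block per type (fold change 4, dependence 0.8).
ds = w.simulate_dataset(w.SimulationConfig(seed=7))

# Full leak-free 5-fold protocol: per-fold HVG selection, per-cell network
# construction, training with class-weighted loss, per-test-cell networks.
res = w.run_crossval(ds, k=5, seed=0)
print(f"pooled accuracy {res.pooled.accuracy:.3f}")
print(f"pooled mean F1  {res.pooled.mean_f1:.3f}")
```

Output:

```
pooled accuracy 0.912
pooled mean F1  0.912
```

Pooled accuracy is the fraction of the 600 cells (each held out exactly
once) whose predicted type matches the truth; mean F1 is the unweighted
average of per-type F1 scores.  Values near 0.9 mean the planted block
structure — detectable through both expression shifts and per-cell network
edges — is recovered; an expression-only linear baseline reaches ~0.65 on
the same data.

The scikit-learn style estimator is available directly:

```python
clf = w.WCSGNetClassifier(weight_mode="log1p", random_state=0)
clf.fit(X_train_cpm, y_train)      # X: CPM expression over the HVG panel
proba = clf.predict_proba(X_test_cpm)
```

A command-line interface mirrors the pipeline
(`wcsgnet simulate | preprocess | build-wcsn | crossval | analyze-networks |
train | predict | verify`), reading MTX triplets, dense CSV/TSV or h5ad.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.

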