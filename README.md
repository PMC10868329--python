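# ngmda — microbe–drug association prediction on heterogeneous graphs

The human microbiome modulates drug activity and toxicity, and screening
which microbes a drug interacts with is expensive; computational ranking
of candidate microbes per drug narrows the search. `ngmda` implements a
heterogeneous-graph neural link-prediction model for this task, aimed at
computational biologists who have a binary drug–microbe association
matrix `B ∈ {0,1}^{N_d×N_m}`, a drug similarity matrix `K^drug ∈ [0,1]`
and either a microbe similarity matrix `K^micr` or microbe attribute
profiles (from which cosine similarities `K_ij = (cos(x_i,x_j)+1)/2` are
computed).

## Model

Drugs and microbes form one graph: within-type edges keep similarity
values ≥ β (default 0.9), cross-type edges are the known associations.
Each node carries four feature families — its similarity row, its
multi-modal row `[[K^drug, B],[B^T, K^micr]]`, its position (adjacency
row), and a multi-scale topology vector of t-step random-walk return
probabilities `[RW¹_ii … RWᵗ_ii]` with `RW = (B^hete D^{-1})` (t = 2).
The network then

1. compresses similarity and multi-modal rows with node-type-specific
   **supervised autoencoders** (reconstruction + node-type
   classification losses sharpen the drug/microbe embedding separation);
2. fuses **neighbor features** with position/topology-sensitive
   heterogeneous graph attention: weights are a softmax over the
   neighbor set of `r_ψ · s_ij · c_ij`, where `s` is a semantic
   attention score, `c = [τ·cos(position) + (1−τ)·cos(topology) + 1]/2`
   (τ = 0.4), and `r_ψ` is a learned importance per relation type
   ψ ∈ {drug←drug, microbe←drug, drug←microbe, microbe←microbe};
3. fuses **whole-graph features** with a relation-aware graph
   transformer: dense attention over all node pairs whose
   query/key/value projections see a learned relation-type embedding;
4. scores each (drug, microbe) pair with a softmax head on the
   concatenation of original features and every layer's representations,
   trained jointly on `γ = ε·γ_proc + (1−ε)·γ_pred` (ε = 0.2) with Adam.

Evaluation follows a per-drug 5-fold protocol: balanced negative
sampling for training, **all** remaining unobserved pairs as test
negatives, test positives masked out of the training graph, and
per-drug AUC / average precision / top-k recall averaged over evaluable
drugs and folds. A paired Wilcoxon signed-rank test (exact for n ≤ 25)
compares per-drug metric vectors of two methods.

No GPU or deep-learning framework is required: the model runs on a
compact numpy reverse-mode autodiff engine (`ngmda.autodiff`), sized for
desk-scale graphs (hundreds of nodes, minutes per cross-validated run).

## Worked example

```python
from ngmda import NGMDAModel, SyntheticConfig

# synthetic dataset with planted low-rank structure (60 drugs x 30 microbes)
model = NGMDAModel.from_synthetic(SyntheticConfig())
results = model.fit(seed=1)
print(results.summary())
```

```
Microbe-drug association prediction: 5-fold cross-validation
==============================================================
drugs: 60   microbes: 30   known associations: 151
seed: 1   epochs/fold: 80   embed dim: 64
--------------------------------------------------------------
fold   mean AUC  mean AUPR  drugs eval.  skipped
   1     0.8671     0.6171           19       41
   2     0.9318     0.6582           19       41
   3     0.7591     0.4203           20       40
   4     0.8270     0.5214           20       40
   5     0.9031     0.6466           22       38
--------------------------------------------------------------
 all     0.8576     0.5727
recall  top-3: 0.608   top-6: 0.796   top-9: 0.854   top-12: 0.910
```

Per fold, `mean AUC` / `mean AUPR` average the per-drug ranking metrics
over the drugs that have at least one held-out positive (`drugs eval.`;
the rest are `skipped` — with ~2.5 associations per drug most drugs have
no test positive in any single fold). The bottom row averages the five
fold means; `top-k` is the mean fraction of a drug's held-out true
microbes ranked in its top k candidates. An AUC of ~0.86 against ~1500
test negatives per fold means the planted drug–microbe structure is
recovered well above the 0.5 chance level of the matched null dataset.

Real data in the same TSV dialect can be fitted with
`NGMDAModel.from_dataframes(...)`, and the CLI mirrors the library:

```sh
ngmda simulate --out-dir data/            # synthetic dataset
ngmda train --data-dir data/ --seed 1 --out-dir run/
ngmda predict --data-dir data/ --out-dir pred/   # ranked candidates per drug
ngmda compare --metrics-a run/per_drug_metrics.tsv --metrics-b other/per_drug_metrics.tsv
```

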