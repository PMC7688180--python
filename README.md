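# ppifunc

Protein function prediction from protein–protein interaction (PPI)
networks, for computational biologists studying how network sparsity and
predicted interactions affect automatic Gene Ontology (GO) annotation.

Experimentally measured interactomes are incomplete, and the damage this
does to network-based function prediction is uneven: well-studied hub
proteins keep their edges while poorly studied proteins lose theirs first.
`ppifunc` provides the full analysis loop for studying this: network
construction from experimental and predicted association data,
guilt-by-association and embedding-based classifiers, CAFA-style
evaluation, a data-source combination sweep, and an edge-downsampling
robustness study — all runnable end-to-end on synthetic data with planted
functional signal.

## The methods in brief

**Guilt-by-association (GBA).** With training proteins `V_train`, annotation
sets `T(p)` closed under the GO is_a hierarchy, and neighbourhood
`N(p_i) = {p ∈ V_train : A[p, p_i] = 1}`, the posterior for term `t` is

    P(p_i, t) = Σ_{p ∈ N(p_i)} I(t ∈ T(p)) / |N(p_i)|

(the weighted variant votes with edge weights and normalises by their sum).
An empty neighbourhood yields `P = 0` for every term.

**Baselines.** The *naive* classifier assigns every term its training
frequency (identical for all test proteins); *similarity transfer* assigns
the maximum sequence identity over annotated hits, BLAST-style.

**node2vec.** Second-order biased random walks (return parameter `p`,
in-out parameter `q`) feed a skip-gram-with-negative-sampling model; the
resulting node vectors are classified with kNN or multi-output ridge,
`W* = (XᵀX + λI)⁻¹XᵀY` with labels `Y ∈ {−1, 1}^{N×L}`, squashed by a
sigmoid.

**Fusion.** Two classifiers combine by the noisy-OR
`P = 1 − (1 − P₁)(1 − P₂)`.

**Evaluation.** Protein-centric `Fmax` and `Smin` over the threshold grid
0.01…1.00, coverage (fraction of test proteins with any non-zero
posterior), and Prediction Advantage `PA = 1 − L_c / L_naive` with
`L = 1 − Fmax`, under 5-fold cross-validation with per-fold term filtering
and an inner 80/20 split for hyperparameter tuning.

**Network recipes.** Experimental edges (physical interactions only);
STRING-style evidence channels thresholded at the median or top half of
non-zero scores, probabilistically integrated across channels with a prior
correction; binary networks combined by element-wise logical OR; weighted
networks that keep association scores as edge weights; fixed-threshold
graphs for externally produced sequence-based interaction scores.

## Worked example

```python
from ppifunc.simulate import SimConfig, simulate
from ppifunc.pipeline import run_experiment

sim = simulate(SimConfig(seed=1))      # 150 proteins, planted GBA signal
report = run_experiment(
    sim.network, sim.annotations, sim.ontology,
    classifiers=("naive", "gba"), seed=1,
)
print(report.groupby("classifier")[["fmax", "smin", "coverage", "pa"]]
      .mean().round(3))
```

prints

```
              fmax    smin  coverage     pa
classifier
gba          0.771   6.422       1.0  0.428
naive        0.601  10.922       1.0  0.000
```

On this synthetic interactome — where edges are planted with probability
increasing in the Jaccard similarity of two proteins' specific GO terms —
GBA reaches a mean cross-validated Fmax of 0.77 against the naive
baseline's 0.60, a Prediction Advantage of 0.43 (it removes 43% of the
baseline's loss), and loses ~4.5 bits less information per protein (Smin).
Both methods cover every test protein because the network is dense enough
that every protein keeps a training neighbour.

The same experiments run from the shell:

```sh
ppifunc simulate --seed 1 --outdir data/
ppifunc evaluate --config config.yaml --seed 1 --outdir results/
ppifunc sweep     --config config.yaml --seed 1 --out results/sweep.tsv
ppifunc downsample --config config.yaml --seed 1 --out results/downsample.tsv
```

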