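# graincast

Forecasting and grading of stored-grain quality.

Post-harvest wheat degrades in storage: germination rate (physiological
viability) falls, the fatty acid value (lipid oxidation, mg KOH/100 g)
rises, and bulk density (g/L, a milling-quality proxy) declines — all
faster at higher storage temperature and grain moisture. `graincast` is a
dual-model toolkit for storage managers and food-quality researchers who
monitor such trials: a multivariate time-series **forecaster** predicts
how the quality indicators will evolve under each storage condition, and
a temporally weighted **clustering grader** turns joint history + forecast
trajectories into ordered, interpretable quality grades. A synthetic
full-factorial storage-experiment generator makes the entire chain
runnable and testable without laboratory data.

## The models

**SGCNiFormer forecaster.** For a lookback window `X ∈ R^{T×N}` (T time
steps, N = 5 variables: temperature, moisture, germination, fatty acid,
bulk density), each variable's full series is embedded as one token,
`H = Embedding(X) ∈ R^{N×D}` — the *inverted* arrangement, so attention
operates across variables:

    Attention(H) = softmax(Q Kᵀ / √d_k) V,   Q = H W_Q, K = H W_K, V = H W_V
    FFN(h) = max(0, h W₁ + b₁) W₂ + b₂

with residual connections and layer normalization around both sublayers.
In parallel, a **graph branch** treats each variable as a node of a fully
connected graph whose edge weights are Pearson correlations fitted on the
training split, `e_ij = Cov(x_i, x_j)/(σ_i σ_j)`, plus one *association
node* pooled from the environmental (temperature, moisture) tokens. Each
GCN layer propagates

    h^{(l+1)} = ReLU(Â h^{(l)} W^{(l)} + b^{(l)}) ‖ h^{(0)}

where `Â` is the symmetrically degree-normalized adjacency with self-loops
and `‖ h^{(0)}` is a jump connection that carries the original token
through the stack; per-layer outputs are concatenated column-wise and
mixed by `W_g`, giving graph features `S`. A **dynamic gate** fuses the
branches per dimension:

    Γ = σ(W_γ (H ⊕ S) + b_γ),   K = Γ ⊙ H + (1 − Γ) ⊙ S

so `Γ → 1` recovers the pure transformer and `Γ → 0` the pure GCN. A
shared per-variable linear head maps `K` to the forecast horizon.
Ablation switches reproduce the reduced models: attention-only
(Model 1) and ungated branch mean (Model 2).

**K-Smeans grader.** Each sample to grade is the spatiotemporal feature

    G_t = [x_{t−P}, …, x_t, x̂_{t+1}, …, x̂_{t+F}] ∈ R^{(P+F+1)×3}

stacking P past standardized observations of the three indicators, the
current one, and F forecaster outputs. Rows are scaled by the sigmoid
time-decay weight `w(τ) = 2/(1 + e^{λ|τ−t|})` (1 at the anchor, decaying
with lag), then clustered by Lloyd's algorithm with deterministic
maximin (farthest-point) seeding. The number of grades is chosen by
majority vote of three validity indices (silhouette ↑, Davies–Bouldin ↓,
Dunn ↑); clusters are ordered into grades by descending germination and
summarized as per-indicator min/max ranges.

## Worked example

```bash
python examples/02_forecasting.py
```

```
panel: 3904 records, 64 condition series
training loss: 0.5363 (epoch 1) -> 0.0007 (epoch 20)
test MAE (standardized, pooled quality indicators): model 0.0261 vs persistence 0.0487
       germination_pct: MAE 0.0229
     fatty_acid_mg100g: MAE 0.0312
       bulk_density_gL: MAE 0.0241
```

The model's standardized test MAE (0.026) roughly halves the persistence
baseline's (0.049): it has learned the temperature/moisture-dependent
degradation rates rather than merely repeating the last observation.
`examples/03_grading.py` runs the full chain on the 560-record factorial
design and prints the per-k validity table, the per-grade indicator
ranges in original units, and the sample count per grade; the grade
counts always sum to the number of clustered samples. The command-line
interface exposes the same stages (`graincast simulate | preprocess |
train | predict | evaluate | features | cluster | pipeline ...`).

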