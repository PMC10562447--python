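# seedflank

Expert-seeded promoter design: fix the motifs you trust, learn the flanks.

A promoter's strength and inducibility are set not only by its
transcription-factor binding sites (the −35/−10 elements, lacO/tetO
operators, a minimal core promoter) but also by the flanking sequence
around them, which is usually chosen arbitrarily.  seedflank keeps the
expert-chosen motifs — the *seed* m\*, pinned at exact positions in a
fixed-length window — and optimizes everything else.  Writing a sequence as
s = (m, f), the design objective factorizes as

    max_f  P(f | m*, T)  ∝  P(f | m*) · P(T | f, m*)

with T the target property (expression level).  P(f | m\*) is modelled by a
conditional Wasserstein adversarial generator G(m\*, z) (attention + conv
residual blocks, gradient penalty, L1 flank reconstruction) that fills
flanking sequence compatible with the seed; P(T | f, m\*) by a
conv→BiLSTM→DenseNet activity predictor F.  Design maximizes F(G(m\*, z))
over the latent z with a genetic algorithm, so candidates never leave the
generator's manifold of promoter-like sequences.  An analysis suite checks
the results: k-mer spectra, DNA-shape tracks and embeddings, edit-distance
diversity, PWM scanning with exact p-values, second-promoter detection, and
saliency-map clustering.

The neural models run on a small built-in reverse-mode autodiff engine
(numpy, float64, exact second-order gradients for the gradient penalty) —
no deep-learning framework required.

## Worked example

Simulate a training corpus with a known activity oracle, train both models
at a small scale, and design promoters for a sigma-70 seed:

```python
from seedflank.benchmarks import parameter_recovery, design_benefit

rec = parameter_recovery(seed=1)          # n=2000 simulated 50-bp promoters
print(f"held-out Spearman vs oracle: {rec['spearman_vs_oracle']:.3f}")
print(f"shuffled-label control:      {rec['shuffled_control_spearman']:.3f}")

db = design_benefit(seed=1, predictor=rec["model"],
                    corpus=rec["corpus"], sim_config=rec["sim_config"])
print(f"designed mean oracle activity: {db['designed_mean_oracle']:.2f}")
print(f"random-flank control mean:     {db['control_mean_oracle']:.2f}")
print(f"Cohen's d:                     {db['cohen_d']:.1f}")
```

Output from this exact run:

```
held-out Spearman vs oracle: 0.966
shuffled-label control:      0.047
designed mean oracle activity: 19.69
random-flank control mean:     17.83
Cohen's d:                     8.3
```

The predictor ranks unseen promoters almost exactly as the hidden activity
formula does (Spearman 0.97), learns nothing from permuted labels (|ρ| ≈
0.05, consistent with chance), and GA-designed flanks raise true (oracle)
activity far above random flanks carrying the same seed motifs — every
emitted sequence still contains the seed motifs at their exact positions,
because the generator overwrites seed rows structurally.

The same workflow is available from the shell:

```sh
seedflank simulate --n 1000 --window 165 --seed 0 --out corpus.tsv
seedflank train-predictor --data corpus.tsv --out pred.npz
seedflank train-generator --data corpus.tsv --seed-spec spec.yaml --out gen.npz
seedflank design --generator gen.npz --predictor pred.npz \
    --seed-spec spec.yaml --n-out 16 --out designs.fasta --report report.json
seedflank analyze kmer --fasta designs.fasta --against corpus.fasta -k 4
```

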