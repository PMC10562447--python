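"""Synthetic-benchmark experiments exercising the whole pipeline.

These are the package's standard scaled-down study conditions: each function
simulates data with a known activity oracle, runs the relevant stage
(predictor training, adversarial training, GA design), and returns the
summary numbers.  Problem sizes are chosen to run on a single CPU core in
minutes; docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .actpred import PredictorConfig, train_predictor, predict_activity
from .flankgan import (CGANTrainConfig, CriticModel, GeneratorModel,
                       generate_sequences, train_cgan)
from .flankstats import kmer_correlation
from .gadesign import GAConfig, ga_optimize
from .seqcore import PromoterRecord, SeedSpec, random_flank_rows
from .synthdata import (PromoterDataset, activity_oracle, default_config,
                        simulate_dataset)

#: window length used by the predictor/GA benchmarks
BENCH_WINDOW = 50


def bench_sim_config(seed: int, n: int = 2000, noise_sd: float = 0.1):
    return default_config(n=n, window_length=BENCH_WINDOW, noise_sd=noise_sd,
                          rng_seed=seed)


def bench_predictor_config(seed: int, **overrides) -> PredictorConfig:
    """Scaled-down predictor: same architecture family, smaller widths."""
    base = dict(window_length=BENCH_WINDOW, conv1_channels=16, conv1_kernel=5,
                lstm_hidden=12, dense_blocks=(1, 1, 2, 1), growth_rate=8,
                batch_size=64, learning_rate=2e-3, max_epochs=25, patience=6,
                rng_seed=seed)
    base.update(overrides)
    return PredictorConfig(**base)


def parameter_recovery(seed: int, n: int = 2000):
    """Train the predictor on simulated promoters; score it against the
    noise-free activity oracle on the held-out split.

    Also runs the shuffled-label negative control (labels permuted before
    training, 400 held-out pairs).
    """
    cfg = bench_sim_config(seed, n=n)
    corpus = simulate_dataset(cfg)
    model, report = train_predictor(corpus, bench_predictor_config(seed))
    # held-out Spearman vs the oracle, recomputed from sequences
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(int(n * 0.2), 1)
    val_seqs = [corpus.records[i].seq for i in perm[:n_val]]
    oracle = np.array([activity_oracle(s, cfg) for s in val_seqs])
    pred = predict_activity(model, val_seqs)
    spearman = float(stats.spearmanr(pred, oracle)[0])

    # negative control: permuted labels destroy the sequence-activity link
    shuffle_rng = np.random.default_rng(seed + 1)
    shuffled = shuffle_rng.permutation(corpus.activities())
    shuffled_ds = PromoterDataset(
        [PromoterRecord(r.seq, float(a)) for r, a in zip(corpus.records, shuffled)],
        corpus.window_length, "shuffled-label control")
    _, ctrl_report = train_predictor(
        shuffled_ds, bench_predictor_config(seed, max_epochs=6, patience=3,
                                            val_fraction=0.2))
    return {
        "spearman_vs_oracle": spearman,
        "heldout_spearman_vs_labels": float(report.spearman),
        "shuffled_control_spearman": float(ctrl_report.spearman),
        "model": model,
        "corpus": corpus,
        "sim_config": cfg,
    }


def bench_generator_config(seed: int) -> CGANTrainConfig:
    return CGANTrainConfig(batch_size=16, total_batches=60,
                           critic_steps_per_gen_step=3, rng_seed=seed)


def design_benefit(seed: int, predictor=None, corpus=None, sim_config=None,
                   population: int = 256, generations: int = 30,
                   n_designs: int = 16, gan_steps: int = 60):
    """Computational design-vs-random comparison on the synthetic landscape.

    Trains the generator briefly on the corpus, GA-optimizes the latent
    input against the predictor, then compares the *oracle* activity of the
    top designs with random-flank controls carrying the same seed motifs.
    Returns means, Cohen's d, and the fitness traces.
    """
    if predictor is None or corpus is None or sim_config is None:
        rec = parameter_recovery(seed)
        predictor, corpus, sim_config = rec["model"], rec["corpus"], rec["sim_config"]
    spec = sim_config.planted_specs[0]
    gen = GeneratorModel(BENCH_WINDOW, d_k=32, heads=2, rng_seed=seed)
    critic = CriticModel(BENCH_WINDOW, d_k=32, heads=2, rng_seed=seed + 1)
    gan_cfg = bench_generator_config(seed)
    gan_cfg.total_batches = gan_steps
    gen, _, _ = train_cgan(corpus, spec, gan_cfg, gen, critic)
    ga_cfg = GAConfig(population=population, generations=generations,
                      rng_seed=seed, eval_batch=64)
    result = ga_optimize(gen, predictor, spec, ga_cfg)
    designs = list(dict.fromkeys(d[0] for d in result.designs))[:n_designs]
    designed_oracle = np.array([activity_oracle(s, sim_config, spec)
                                for s in designs])
    # random-flank controls with the same seed motifs
    rng = np.random.default_rng(seed + 2)
    controls = []
    for _ in range(64):
        flat = np.argmax(random_flank_rows(BENCH_WINDOW, rng), axis=1)
        seq = spec.apply_to("".join("ACGT"[i] for i in flat))
        controls.append(seq)
    control_oracle = np.array([activity_oracle(s, sim_config, spec)
                               for s in controls])
    pooled = np.sqrt((designed_oracle.var(ddof=1) + control_oracle.var(ddof=1)) / 2)
    d = float((designed_oracle.mean() - control_oracle.mean()) / pooled)
    return {
        "designed_mean_oracle": float(designed_oracle.mean()),
        "control_mean_oracle": float(control_oracle.mean()),
        "cohen_d": d,
        "designs": designs,
        "controls": controls,
        "best_trace": result.best_trace,
        "spec": spec,
    }


def distribution_matching(seed: int, n_seqs: int = 200, window: int = 32,
                          batches: int = 300, k: int = 4):
    """Scaled-down adversarial training and 4-mer spectrum comparison.

    The training corpus uses an AT-biased background so its flank k-mer
    spectrum has structure to learn.  Spectra are compared on the flanking
    regions (the quantity the generator models; the shared planted motif
    would otherwise dominate both correlations): after training, the
    generated flanks should correlate better with the training flanks than
    uniform-random flanks do.
    """
    spec = SeedSpec(window, (("TATAAT", 13),), "toy")
    cfg = default_config(n=n_seqs, window_length=window, noise_sd=0.0,
                         rng_seed=seed, spec=spec)
    cfg.background = (0.35, 0.15, 0.15, 0.35)
    corpus = simulate_dataset(cfg)
    gan_cfg = CGANTrainConfig(batch_size=32, total_batches=batches,
                              critic_steps_per_gen_step=5, rng_seed=seed)
    gen = GeneratorModel(window, d_k=32, heads=2, rng_seed=seed)
    critic = CriticModel(window, d_k=32, heads=2, rng_seed=seed + 1)
    gen, _, log = train_cgan(corpus, spec, gan_cfg, gen, critic)
    generated = generate_sequences(gen, spec, n_seqs, rng_seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    random_seqs = [spec.apply_to("".join(
        "ACGT"[i] for i in rng.integers(4, size=window)))
        for _ in range(n_seqs)]
    mask = spec.seed_mask

    def flanks(seqs):
        return ["".join(c for c, m in zip(s, mask) if not m) for s in seqs]

    train_fl = flanks(corpus.sequences())
    return {
        "r_generated_vs_train": kmer_correlation(flanks(generated), train_fl, k),
        "r_random_vs_train": kmer_correlation(flanks(random_seqs), train_fl, k),
        "r_generated_fullseq": kmer_correlation(generated, corpus.sequences(), k),
        "l1_start": log[0]["l1"],
        "l1_end": log[-1]["l1"],
        "generated": generated,
        "spec": spec,
        "log": log,
    }
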