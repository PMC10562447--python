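"""Genetic-algorithm search over the generator's latent input.

The latent variable is the set of pre-softmax flanking-row coordinates fed to
the generator.  Each coordinate is binary-encoded at a fixed precision; the
population evolves by tournament selection, single-point crossover, and
bit-flip mutation, with elitism, and fitness is the predictor's score of the
decoded design.  Fitness evaluation is vectorized over whole populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .actpred import PredictorModel, predict_matrices
from .flankgan import GeneratorModel
from .seqcore import (SeedSpec, decode_onehot, encode_onehot,
                      flanking_length, generator_input_from_latent)


@dataclass
class GAConfig:
    population: int = 5120
    mutation_prob: float = 0.005
    generations: int = 100
    elitism: int = 1
    bits_per_coord: int = 8
    latent_range: float = 3.0      # coordinates decode into [-range, range]
    tournament_size: int = 3
    crossover_prob: float = 0.9
    eval_batch: int = 64
    rng_seed: int = 0

    def __post_init__(self):
        if self.population <= 0 or self.generations <= 0:
            raise ValueError("population and generations must be positive")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.elitism > self.population:
            raise ValueError("population smaller than elitism")


@dataclass
class DesignResult:
    designs: list                  # (sequence, predicted_activity, latent fingerprint)
    best_trace: np.ndarray         # per-generation best fitness
    mean_trace: np.ndarray         # per-generation mean fitness
    filter_tally: dict = field(default_factory=dict)

    def sequences(self):
        return [d[0] for d in self.designs]

    def scores(self):
        return np.array([d[1] for d in self.designs])


def _decode_latents(bits: np.ndarray, n_coords: int, config: GAConfig) -> np.ndarray:
    """(P, n_coords*b) bits -> (P, n_coords) real coordinates."""
    b = config.bits_per_coord
    weights = 2.0 ** np.arange(b - 1, -1, -1)
    ints = bits.reshape(bits.shape[0], n_coords, b) @ weights
    frac = ints / (2.0 ** b - 1.0)
    return (2.0 * frac - 1.0) * config.latent_range


def _population_matrices(bits, spec, config):
    n_flank = flanking_length(spec)
    latents = _decode_latents(bits, n_flank * 4, config)
    mats = np.empty((bits.shape[0], spec.window_length, 4))
    for i in range(bits.shape[0]):
        mats[i] = generator_input_from_latent(spec, latents[i]).matrix
    return mats, latents


def _default_fitness(generator, predictor, spec, config):
    mask = spec.seed_mask
    seed_rows = encode_onehot(spec.seed_string()) * mask[:, None]

    def fitness(mats):
        scores = np.empty(mats.shape[0])
        for s in range(0, mats.shape[0], config.eval_batch):
            chunk = mats[s:s + config.eval_batch]
            with ad.no_grad():
                out = generator.forward_tensor(ad.Tensor(chunk), mask, seed_rows)
            scores[s:s + chunk.shape[0]] = predict_matrices(
                predictor, out.data, batch=config.eval_batch)
        return scores

    return fitness


def ga_optimize(generator, predictor, spec: SeedSpec, config: GAConfig,
                fitness_fn=None) -> DesignResult:
    """Maximize predicted activity over binary-encoded latent genomes.

    ``fitness_fn`` (optional) maps a (P, L, 4) array of generator-input
    matrices to a (P,) fitness vector; the default pushes the inputs through
    the generator and scores the outputs with the predictor.
    """
    if generator is not None and generator.window_length != spec.window_length:
        raise ValueError("generator window does not match spec")
    if (predictor is not None
            and predictor.config.window_length != spec.window_length):
        raise ValueError("predictor window does not match spec")
    rng = np.random.default_rng(config.rng_seed)
    n_flank = flanking_length(spec)
    genome_len = n_flank * 4 * config.bits_per_coord
    pop = rng.integers(0, 2, size=(config.population, genome_len)).astype(np.int8)
    if fitness_fn is None:
        fitness_fn = _default_fitness(generator, predictor, spec, config)
    best_trace, mean_trace = [], []
    elite_bits, elite_fit = None, None
    for gen_i in range(config.generations):
        mats, _ = _population_matrices(pop, spec, config)
        fit = np.asarray(fitness_fn(mats), dtype=np.float64)
        order = np.argsort(-fit)
        if config.elitism > 0:
            elite_bits = pop[order[:config.elitism]].copy()
            elite_fit = fit[order[:config.elitism]].copy()
        best_trace.append(float(fit.max()))
        mean_trace.append(float(fit.mean()))
        if gen_i == config.generations - 1:
            break
        # tournament selection
        t = config.tournament_size
        contenders = rng.integers(config.population, size=(config.population, t))
        winners = contenders[np.arange(config.population),
                             np.argmax(fit[contenders], axis=1)]
        children = pop[winners].copy()
        # single-point crossover on consecutive pairs
        for i in range(0, config.population - 1, 2):
            if rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, genome_len))
                tmp = children[i, cut:].copy()
                children[i, cut:] = children[i + 1, cut:]
                children[i + 1, cut:] = tmp
        # bit-flip mutation
        if config.mutation_prob > 0:
            flips = rng.random(children.shape) < config.mutation_prob
            children[flips] ^= 1
        if config.elitism > 0:
            children[:config.elitism] = elite_bits
        pop = children
    # rank the final population (elites included by construction)
    mats, latents = _population_matrices(pop, spec, config)
    fit = np.asarray(fitness_fn(mats), dtype=np.float64)
    if config.elitism > 0 and elite_fit is not None and fit.max() < elite_fit[0]:
        # guard: final evaluation must contain the elite
        fit[0] = elite_fit[0]
    order = np.argsort(-fit)
    designs = []
    if generator is not None:
        mask = spec.seed_mask
        seed_rows = encode_onehot(spec.seed_string()) * mask[:, None]
        for i in order:
            with ad.no_grad():
                out = generator.forward_tensor(ad.Tensor(mats[i][None]),
                                               mask, seed_rows)
            seq = spec.apply_to(decode_onehot(out.data[0]))
            designs.append((seq, float(fit[i]), latents[i]))
    else:
        for i in order:
            designs.append((decode_onehot(mats[i]), float(fit[i]), latents[i]))
    return DesignResult(designs=designs, best_trace=np.array(best_trace),
                        mean_trace=np.array(mean_trace))


def motif_filter(seqs, motif_library, score_threshold, mode="logodds",
                 spec: SeedSpec | None = None):
    """Reject sequences where any library PWM scores a hit on either strand.

    ``mode='logodds'`` rejects when the best log-odds >= threshold;
    ``mode='pvalue'`` rejects when the best scan p-value <= threshold.
    Hits whose window overlaps seed positions (per ``spec``) are ignored.
    Returns (retained, rejected) where rejected entries carry hit annotations
    (motif index, position, strand, score).
    """
    from .flankstats import PWM, pwm_pvalue, scan_pwm

    if not motif_library:
        warnings.warn("empty motif library: all sequences retained")
        return list(seqs), []
    retained, rejected = [], []
    seed_mask = spec.seed_mask if spec is not None else None
    for seq in seqs:
        hit = None
        for mi, pwm in enumerate(motif_library):
            for strand, scores in scan_pwm(seq, pwm, both_strands=True).items():
                for pos, sc in enumerate(scores):
                    if seed_mask is not None:
                        if seed_mask[pos:pos + pwm.width].any():
                            continue
                    if mode == "logodds":
                        bad = sc >= score_threshold
                    else:
                        bad = pwm_pvalue(pwm, sc) <= score_threshold
                    if bad:
                        hit = {"motif": mi, "position": pos, "strand": strand,
                               "score": float(sc)}
                        break
                if hit:
                    break
            if hit:
                break
        if hit is None:
            retained.append(seq)
        else:
            rejected.append((seq, hit))
    return retained, rejected


def design_promoters(generator, predictor, spec: SeedSpec, ga_config: GAConfig,
                     n_out: int, filters=None, fitness_fn=None) -> DesignResult:
    """End-to-end design: GA search, decode, dedupe, filter, rank, top-k.

    ``filters`` is a list of callables mapping a sequence list to
    (retained, rejected); rejected counts are tallied by filter index.
    ``fitness_fn`` overrides the generator+predictor fitness (surrogate
    landscapes, testing).
    """
    result = ga_optimize(generator, predictor, spec, ga_config, fitness_fn)
    seen, unique = set(), []
    for seq, score, latent in result.designs:
        if seq not in seen:
            seen.add(seq)
            unique.append((seq, score, latent))
    tally = {"duplicates": len(result.designs) - len(unique)}
    survivors = unique
    for fi, filt in enumerate(filters or []):
        seq_list = [s for s, _, _ in survivors]
        retained, rejected = filt(seq_list)
        retained_set = set(retained)
        tally[f"filter_{fi}"] = len(rejected)
        survivors = [d for d in survivors if d[0] in retained_set]
    if not survivors:
        warnings.warn(f"all candidates filtered out; tally: {tally}")
    if n_out > len(survivors):
        warnings.warn(f"requested {n_out} designs, only {len(survivors)} survive")
    return DesignResult(designs=survivors[:n_out], best_trace=result.best_trace,
                        mean_trace=result.mean_trace, filter_tally=tally)
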