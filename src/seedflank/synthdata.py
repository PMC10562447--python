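"""Promoter datasets: real-table loading, geometry filtering, and simulation.

The simulator is the testing ground for the whole pipeline: it plants sigma-70
style motifs into random backgrounds and assigns each sequence an activity by
a *known* formula (motif log-odds strength plus a flanking-composition term
plus Gaussian noise), so that every downstream model can be checked against an
exact oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .seqcore import (ALPHABET, PromoterRecord, SeedSpec, encode_onehot,
                      read_fasta, write_fasta)


class SchemaError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


@dataclass
class PromoterDataset:
    records: list
    window_length: int
    provenance: str = ""

    def __post_init__(self):
        for r in self.records:
            if len(r.seq) != self.window_length:
                raise ValueError(
                    f"record length {len(r.seq)} != window_length {self.window_length}")

    def __len__(self):
        return len(self.records)

    def sequences(self):
        return [r.seq for r in self.records]

    def activities(self):
        return np.array([r.activity for r in self.records])

    def standardized(self) -> "PromoterDataset":
        """Z-score the activities (predictor training default)."""
        a = self.activities()
        sd = a.std()
        if sd == 0:
            raise ValueError("degenerate activities: zero variance")
        z = (a - a.mean()) / sd
        recs = [PromoterRecord(r.seq, float(v), dict(r.meta))
                for r, v in zip(self.records, z)]
        return PromoterDataset(recs, self.window_length, self.provenance + "|zscored")


def load_activity_table(path, seq_column="sequence", activity_column="activity",
                        sep="\t", dedupe=False):
    """Load a delimited table of sequences and activities.

    Malformed rows (non-finite activity, non-ACGTN sequence, inconsistent
    length) are excluded; the exclusion count is stored in the dataset
    provenance and returned alongside.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (seq_column, activity_column):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}; have {list(df.columns)}")
    if len(df) == 0:
        raise EmptyDatasetError(f"{path} has a header but no rows")
    records, excluded = [], 0
    lengths = df[seq_column].astype(str).str.len()
    window = int(lengths.mode().iloc[0])
    seen = set()
    for seq, act in zip(df[seq_column], df[activity_column]):
        seq = str(seq).upper()
        act = pd.to_numeric(act, errors="coerce")
        if (len(seq) != window or not np.isfinite(act)
                or any(c not in "ACGTN" for c in seq)):
            excluded += 1
            continue
        if dedupe:
            if seq in seen:
                excluded += 1
                continue
            seen.add(seq)
        records.append(PromoterRecord(seq, float(act)))
    if not records:
        raise EmptyDatasetError(f"no valid rows in {path}")
    ds = PromoterDataset(records, window, provenance=f"{path}|excluded={excluded}")
    return ds, excluded


def write_activity_table(path, dataset: PromoterDataset, sep="\t"):
    pd.DataFrame({"sequence": dataset.sequences(),
                  "activity": dataset.activities()}).to_csv(path, sep=sep, index=False)


def load_fasta_with_activities(path) -> PromoterDataset:
    """FASTA whose headers carry ``id|activity=<float>``."""
    records = []
    for name, seq in read_fasta(path):
        if "activity=" not in name:
            raise SchemaError(f"header {name!r} lacks an activity= field")
        act = float(name.split("activity=")[1])
        records.append(PromoterRecord(seq, act, {"id": name.split("|")[0]}))
    if not records:
        raise EmptyDatasetError(f"no records in {path}")
    return PromoterDataset(records, len(records[0].seq), provenance=str(path))


def write_fasta_with_activities(path, dataset: PromoterDataset):
    write_fasta(path, [(f"seq{i}|activity={r.activity:.6g}", r.seq)
                       for i, r in enumerate(dataset.records)])


# ---------------------------------------------------------------------------
# promoter geometry filtering

#: sigma-70 consensus count-derived probability columns used to locate
#: unannotated -10/-35 elements (TATAAT / TTGACA with soft off-consensus mass)
def _soft_pwm(consensus: str, major=0.7):
    minor = (1.0 - major) / 3.0
    mat = np.full((len(consensus), 4), minor)
    for i, c in enumerate(consensus):
        mat[i, ALPHABET.index(c)] = major
    return mat


MINUS10_PWM = _soft_pwm("TATAAT")
MINUS35_PWM = _soft_pwm("TTGACA")


def _best_pwm_hit(seq, pwm, lo, hi):
    """Maximal log-odds placement of ``pwm`` with start in [lo, hi]."""
    w = pwm.shape[0]
    best, best_pos = -np.inf, None
    logm = np.log2(pwm / 0.25)
    for s in range(max(0, lo), min(len(seq) - w, hi) + 1):
        sc = sum(logm[i, ALPHABET.index(seq[s + i])] for i in range(w))
        if sc > best:
            best, best_pos = sc, s
    return best_pos, best


def annotate_elements(record: PromoterRecord, tss_index: int,
                      pwm10=None, pwm35=None) -> PromoterRecord:
    """Locate -10/-35 elements by maximal PWM log-odds in the allowed windows
    (ends 1-21 bp and 25-45 bp upstream of the TSS) unless already annotated."""
    if "minus10_start" in record.meta and "minus35_start" in record.meta:
        return record
    pwm10 = MINUS10_PWM if pwm10 is None else pwm10
    pwm35 = MINUS35_PWM if pwm35 is None else pwm35
    w10, w35 = pwm10.shape[0], pwm35.shape[0]
    # element end e (inclusive, 0-based) at distance d upstream means
    # tss_index - 1 - e == d - 1, i.e. e = tss_index - d; start = e - w + 1
    p10, _ = _best_pwm_hit(record.seq, pwm10, tss_index - 21 - w10 + 1,
                           tss_index - 1 - w10 + 1)
    p35, _ = _best_pwm_hit(record.seq, pwm35, tss_index - 45 - w35 + 1,
                           tss_index - 25 - w35 + 1)
    meta = dict(record.meta)
    if p10 is not None:
        meta["minus10_start"] = p10
        meta["minus10_len"] = w10
    if p35 is not None:
        meta["minus35_start"] = p35
        meta["minus35_len"] = w35
    return PromoterRecord(record.seq, record.activity, meta)


def filter_promoters(dataset: PromoterDataset, tss_index: int,
                     pwm10=None, pwm35=None):
    """Keep promoters with canonical sigma-70 geometry around the TSS.

    Rules (distances in bp upstream of the TSS, strict as stated):
      (a) the window extends more than 75 bp distal of the TSS;
      (b) the -10 element ends 1-21 bp upstream;
      (c) the -35 element ends 25-45 bp upstream;
      (d) the spacer between the elements is 10-24 bp.
    Each rejection is tagged with the first failed rule.
    """
    if not (0 <= tss_index < dataset.window_length):
        raise ValueError(f"tss_index {tss_index} outside window "
                         f"[0, {dataset.window_length})")
    kept, rejections = [], []
    for rec in dataset.records:
        rec = annotate_elements(rec, tss_index, pwm10, pwm35)
        rule = _first_failed_rule(rec, tss_index)
        if rule is None:
            kept.append(rec)
        else:
            rejections.append((rec, rule))
    out = PromoterDataset(kept, dataset.window_length,
                          dataset.provenance + f"|filtered(tss={tss_index})")
    return out, rejections


def _first_failed_rule(rec: PromoterRecord, tss_index: int):
    if tss_index <= 75:  # rule (a): > 75 bp between window start and TSS
        return "a"
    m = rec.meta
    if "minus10_start" not in m or "minus35_start" not in m:
        return "b"
    e10 = m["minus10_start"] + m["minus10_len"] - 1
    e35 = m["minus35_start"] + m["minus35_len"] - 1
    d10 = tss_index - e10  # bp upstream of TSS of the -10 3' end
    if not (1 <= d10 <= 21):
        return "b"
    d35 = tss_index - e35
    if not (25 <= d35 <= 45):
        return "c"
    spacer = m["minus10_start"] - e35 - 1
    if not (10 <= spacer <= 24):
        return "d"
    return None


# ---------------------------------------------------------------------------
# simulation

@dataclass
class SimulationConfig:
    """Synthetic promoter corpus with a known activity formula.

    activity = w_motif * (sum of per-motif PWM log-odds)
             + w_flank * (gc_fraction(flank) - 0.5 + kmer_bonus * count(bonus_kmer)/n_windows)
             + Normal(0, noise_sd)
    """

    n: int
    window_length: int = 165
    planted_specs: tuple = ()
    motif_pwms: dict = field(default_factory=dict)  # motif string -> width x 4
    w_motif: float = 1.0
    w_flank: float = 4.0
    noise_sd: float = 0.1
    bonus_kmer: str = "TGAC"
    kmer_bonus: float = 2.0
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    sample_motifs_from_pwm: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for spec in self.planted_specs:
            if spec.window_length != self.window_length:
                raise ValueError("planted spec window does not match config")

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        d["planted_specs"] = [s.to_dict() for s in self.planted_specs]
        d["motif_pwms"] = {k: np.asarray(v).tolist() for k, v in self.motif_pwms.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["planted_specs"] = tuple(SeedSpec.from_dict(s) for s in d["planted_specs"])
        d["motif_pwms"] = {k: np.asarray(v) for k, v in d["motif_pwms"].items()}
        d["background"] = tuple(d["background"])
        return cls(**d)


def default_sigma70_spec(window_length=165, label="sigma70") -> SeedSpec:
    """J23119-style seed: -35 TTGACA and -10 TATAAT with a 17 bp spacer and
    the -10 element ending 8 bp upstream of the TSS.

    The TSS sits 20 bp before the window end when the window allows it, and
    is pushed just far enough downstream to fit the elements otherwise
    (windows shorter than 37 bp cannot hold this geometry).
    """
    tss = max(36, window_length - 20)
    if tss > window_length - 1:
        raise ValueError("window too short for the sigma-70 seed geometry")
    s10 = tss - 8 - 6 + 1  # -10 end 8 bp upstream of TSS
    s35 = s10 - 17 - 6     # 17 bp spacer
    return SeedSpec(window_length=window_length,
                    motifs=(("TTGACA", s35), ("TATAAT", s10)), label=label)


def default_config(n=2000, window_length=165, noise_sd=0.1, rng_seed=0,
                   spec: SeedSpec | None = None) -> SimulationConfig:
    spec = default_sigma70_spec(window_length) if spec is None else spec
    pwms = {m: _soft_pwm(m) for m, _ in spec.motifs}
    return SimulationConfig(n=n, window_length=window_length,
                            planted_specs=(spec,), motif_pwms=pwms,
                            noise_sd=noise_sd, rng_seed=rng_seed)


def _motif_logodds(seq, spec: SeedSpec, config: SimulationConfig) -> float:
    bg = np.asarray(config.background)
    total = 0.0
    for m, s in spec.motifs:
        pwm = config.motif_pwms.get(m)
        if pwm is None:
            pwm = _soft_pwm(m)
        sub = seq[s:s + len(m)]
        for i, c in enumerate(sub):
            j = ALPHABET.index(c)
            total += np.log2(pwm[i, j] / bg[j])
    return total


def _flank_statistic(seq, spec: SeedSpec, config: SimulationConfig) -> float:
    mask = spec.seed_mask
    flank = "".join(c for c, m in zip(seq, mask) if not m)
    if not flank:
        return 0.0
    gc = sum(c in "GC" for c in flank) / len(flank)
    k = len(config.bonus_kmer)
    nwin = max(len(flank) - k + 1, 1)
    hits = sum(flank[i:i + k] == config.bonus_kmer for i in range(len(flank) - k + 1))
    return (gc - 0.5) + config.kmer_bonus * hits / nwin


def activity_oracle(seq: str, config: SimulationConfig,
                    spec: SeedSpec | None = None) -> float:
    """Deterministic noise-free activity of ``seq`` under the simulator."""
    if len(seq) != config.window_length:
        raise ValueError(f"sequence length {len(seq)} != window "
                         f"{config.window_length}")
    spec = config.planted_specs[0] if spec is None else spec
    return float(config.w_motif * _motif_logodds(seq, spec, config)
                 + config.w_flank * _flank_statistic(seq, spec, config))


def simulate_dataset(config: SimulationConfig) -> PromoterDataset:
    """Draw ``config.n`` promoters with planted motifs and oracle activities."""
    rng = np.random.default_rng(config.rng_seed)
    bg = np.asarray(config.background)
    specs = config.planted_specs or (SeedSpec(config.window_length),)
    records = []
    for i in range(config.n):
        spec = specs[i % len(specs)]
        letters = rng.choice(4, size=config.window_length, p=bg)
        seq = list("".join(ALPHABET[j] for j in letters))
        for m, s in spec.motifs:
            if config.sample_motifs_from_pwm:
                pwm = config.motif_pwms.get(m, _soft_pwm(m))
                draw = [ALPHABET[rng.choice(4, p=pwm[t] / pwm[t].sum())]
                        for t in range(len(m))]
                seq[s:s + len(m)] = draw
            else:
                seq[s:s + len(m)] = list(m)
        seq = "".join(seq)
        act = activity_oracle(seq, config, spec)
        if config.noise_sd > 0:
            act += rng.normal(0.0, config.noise_sd)
        records.append(PromoterRecord(seq, float(act), {"spec": spec.label}))
    return PromoterDataset(records, config.window_length,
                           provenance=f"simulated(seed={config.rng_seed})")
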