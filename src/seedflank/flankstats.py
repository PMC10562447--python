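"""Sequence analysis battery for designed promoters.

k-mer spectra and their correlations, Levenshtein diversity profiles,
template difference scores (edit distance normalized by flanking length),
pentamer-derived DNA shape tracks and 2-D embeddings, PWM scanning with exact
p-values, and detection of unintended second promoter structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import edlib
import numpy as np
from Bio import motifs as bio_motifs

from .seqcore import ALPHABET, SeedSpec, flanking_length, reverse_complement

# ---------------------------------------------------------------------------
# PWMs


@dataclass
class PWM:
    """Probability matrix over A,C,G,T columns with background and pseudocount."""

    matrix: np.ndarray                  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-4
    name: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(p / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, counts, background=None, pseudocount=0.5, name=""):
        counts = np.asarray(counts, dtype=np.float64) + pseudocount
        mat = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(mat, bg, name=name)

    @classmethod
    def from_consensus(cls, consensus: str, major=0.85, name=""):
        minor = (1 - major) / 3
        mat = np.full((len(consensus), 4), minor)
        for i, c in enumerate(consensus.upper()):
            mat[i, ALPHABET.index(c)] = major
        return cls(mat, name=name or consensus)


def read_jaspar(path) -> list:
    """Read JASPAR-format PFMs (via Bio.motifs), pseudocount-normalized."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in ALPHABET]).T
            out.append(PWM.from_counts(counts, name=m.name or m.matrix_id))
    return out


def read_meme_minimal(path) -> list:
    """Read MEME minimal motif format (letter-probability matrix blocks)."""
    pwms, name, rows, in_matrix = [], None, [], False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix, rows = True, []
            elif in_matrix:
                vals = line.split()
                if len(vals) == 4:
                    rows.append([float(v) for v in vals])
                else:
                    if rows:
                        mat = np.array(rows)
                        mat = mat / mat.sum(axis=1, keepdims=True)
                        pwms.append(PWM(mat, name=name or ""))
                    in_matrix = False
    if in_matrix and rows:
        mat = np.array(rows)
        pwms.append(PWM(mat / mat.sum(axis=1, keepdims=True), name=name or ""))
    return pwms


def read_probability_table(path, name="") -> PWM:
    """Plain 4-column (A C G T) probability text, one row per position."""
    mat = np.loadtxt(path, ndmin=2)
    return PWM(mat / mat.sum(axis=1, keepdims=True), name=name)


def pwm_log_odds(seq_window: str, pwm: PWM) -> float:
    """log2 odds of a window of exactly the PWM's width vs background."""
    if len(seq_window) != pwm.width:
        raise ValueError(f"window length {len(seq_window)} != width {pwm.width}")
    lo = pwm.log_odds
    return float(sum(lo[i, ALPHABET.index(c)] for i, c in enumerate(seq_window.upper())))


def scan_pwm(seq: str, pwm: PWM, both_strands=False) -> dict:
    """Per-offset log-odds scores; keys '+' and (optionally) '-'.

    A '-' hit at offset i scores the reverse complement of seq[i:i+w].
    """
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w:
        return {"+": np.empty(0)} | ({"-": np.empty(0)} if both_strands else {})
    lo = pwm.log_odds
    idx = np.array([ALPHABET.index(c) for c in seq])
    n = len(seq) - w + 1
    windows = idx[np.arange(n)[:, None] + np.arange(w)[None, :]]
    plus = lo[np.arange(w)[None, :], windows].sum(axis=1)
    out = {"+": plus}
    if both_strands:
        # rc window: complement (3 - base) read right-to-left
        rc_windows = 3 - windows[:, ::-1]
        out["-"] = lo[np.arange(w)[None, :], rc_windows].sum(axis=1)
    return out


#: score-grid granularity (log2-odds units) for the exact p-value DP
PVALUE_GRANULARITY = 1e-3


def pwm_pvalue(pwm: PWM, score: float) -> float:
    """P(log-odds of a background-drawn width-mer >= score), exact DP.

    Column scores are binned at :data:`PVALUE_GRANULARITY` with rounding
    toward -inf, which makes the reported p conservative (never smaller than
    the continuous-score value by more than the bin width allows).
    """
    if not np.isfinite(score):
        if score == -np.inf:
            return 1.0
        raise ValueError("score must be finite or -inf")
    if pwm.width > 30:
        raise ValueError("exact DP limited to width <= 30")
    offset, dist = _score_distribution(pwm)
    target = int(np.floor(score / PVALUE_GRANULARITY))
    if target > offset + dist.size - 1:
        return 0.0
    if target <= offset:
        return 1.0
    return float(dist[target - offset:].sum())


def _score_distribution(pwm: PWM):
    """Exact distribution of the binned log-odds score under the background.

    Returns (offset, dist) with dist[i] = P(integer score == offset + i);
    cached on the PWM instance (scans query it at every offset).
    """
    cached = getattr(pwm, "_score_dist", None)
    if cached is not None:
        return cached
    iscores = np.floor(pwm.log_odds / PVALUE_GRANULARITY).astype(np.int64)
    dist = np.array([1.0])
    offset = 0  # dist[i] = P(partial sum == offset + i)
    for c in range(pwm.width):
        col = iscores[c]
        new_lo = offset + int(col.min())
        new_hi = offset + dist.size - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            sh = offset + int(col[b]) - new_lo
            new[sh:sh + dist.size] += pwm.background[b] * dist
        dist, offset = new, new_lo
    pwm._score_dist = (offset, dist)
    return pwm._score_dist


def combined_promoter_pwm(pwm_minus35: PWM, pwm_minus10: PWM,
                          spacer_bp: int = 17) -> PWM:
    """-35 block, uniform spacer columns, -10 block, as one PWM.

    Uniform spacer columns are information-free and contribute zero log-odds
    under a uniform background.
    """
    if spacer_bp < 0:
        raise ValueError("spacer_bp must be >= 0")
    spacer = np.full((spacer_bp, 4), 0.25)
    mat = np.vstack([pwm_minus35.matrix, spacer, pwm_minus10.matrix])
    return PWM(mat, pwm_minus35.background,
               name=f"{pwm_minus35.name}+{spacer_bp}bp+{pwm_minus10.name}")


def second_promoter_scan(seq: str, pwm_minus10: PWM, pwm_minus35: PWM,
                         spacer_bp: int = 17, significance: float = 1e-4,
                         exclude=None, both_strands=False):
    """Scan for unintended sigma-70 'promoter structure' in a design.

    Returns (offsets, p-value track, flagged) where ``flagged`` is True when
    any offset outside the ``exclude`` interval (start, end half-open; e.g.
    the intended promoter's own location) reaches the significance level.
    """
    combined = combined_promoter_pwm(pwm_minus35, pwm_minus10, spacer_bp)
    if combined.width > len(seq):
        raise ValueError("combined motif wider than sequence")
    scans = scan_pwm(seq, combined, both_strands=both_strands)
    n = len(seq) - combined.width + 1
    pvals = np.ones(n)
    for strand_scores in scans.values():
        for i, sc in enumerate(strand_scores):
            pvals[i] = min(pvals[i], pwm_pvalue(combined, sc))
    flag_mask = pvals <= significance
    if exclude is not None:
        s, e = exclude
        for i in range(n):
            if i < e and i + combined.width > s:  # overlap with original region
                flag_mask[i] = False
    return np.arange(n), pvals, bool(flag_mask.any())


# ---------------------------------------------------------------------------
# k-mer spectra


def _kmer_index(seq: str, k: int):
    idx = 0
    for c in seq[:k]:
        idx = idx * 4 + ALPHABET.index(c)
    yield idx
    mask = 4 ** (k - 1)
    for c in seq[k:]:
        idx = (idx % mask) * 4 + ALPHABET.index(c)
        yield idx


def _restrict(seq: str, region: str, split: int | None):
    if region == "entire":
        return seq
    cut = len(seq) // 2 if split is None else split
    return seq[:cut] if region == "distal" else seq[cut:]


def kmer_frequencies(seqs, k: int, region="entire", split=None) -> np.ndarray:
    """Pooled overlapping k-mer frequencies (length 4**k, sums to 1).

    ``region`` restricts counting to the distal (first) or proximal (second)
    part of each window, split at ``split`` (default: midpoint).
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    if region not in ("entire", "distal", "proximal"):
        raise ValueError(f"unknown region {region!r}")
    counts = np.zeros(4 ** k)
    skipped = 0
    for seq in seqs:
        seq = _restrict(seq.upper(), region, split)
        if len(seq) < k:
            skipped += 1
            continue
        for idx in _kmer_index(seq, k):
            counts[idx] += 1
    if skipped:
        warnings.warn(f"{skipped} sequences shorter than k={k} skipped")
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable k-mers")
    return counts / total


def kmer_correlation(setA, setB, k: int, region="entire", split=None) -> float:
    """Pearson r between the two k-mer frequency spectra."""
    fa = kmer_frequencies(setA, k, region, split)
    fb = kmer_frequencies(setB, k, region, split)
    if fa.std() == 0 or fb.std() == 0:
        raise ValueError("zero-variance k-mer spectrum: correlation undefined")
    return float(np.corrcoef(fa, fb)[0, 1])


# ---------------------------------------------------------------------------
# edit distance and diversity


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitution/insertion/deletion)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class DiversityProfile:
    distances: dict                     # group label -> (nA*nB,) distances
    quantiles: dict                     # group label -> (q25, q50, q75)


def diversity_profile(groupA, groups: dict) -> DiversityProfile:
    """All pairwise cross-group edit distances from groupA to each group.

    ``groups`` maps a label ('g' generated, 'n' natural, ...) to a sequence
    list; the profile holds |groupA| x |group| distances per label.
    """
    distances, quantiles = {}, {}
    for label, groupB in groups.items():
        d = np.array([edit_distance(a, b) for a in groupA for b in groupB])
        distances[label] = d
        quantiles[label] = tuple(np.percentile(d, [25, 50, 75]))
    return DiversityProfile(distances=distances, quantiles=quantiles)


@dataclass
class TemplateDifference:
    scores: np.ndarray                  # per-sequence s = ed / flanking_length
    mean: float
    sd: float
    mode: str


def template_difference(designed_seqs, template_seq: str, spec: SeedSpec,
                        mode="full") -> TemplateDifference:
    """Difference score s = edit_distance / flanking_length per design.

    ``mode='full'`` computes the edit distance on whole sequences (seed
    regions are identical so only flanks contribute substitutions, but indels
    may couple regions); ``mode='flanking'`` computes it on the concatenated
    flanking positions only.  Both normalize by the flanking length.
    """
    if mode not in ("full", "flanking"):
        raise ValueError("mode must be 'full' or 'flanking'")
    n_flank = flanking_length(spec)
    if n_flank == 0:
        raise ValueError("spec has no flanking positions")
    mask = spec.seed_mask

    def flank_of(seq):
        return "".join(c for c, m in zip(seq, mask) if not m)

    tem = template_seq.upper()
    if len(tem) != spec.window_length:
        raise ValueError("template length does not match spec window")
    tem_fl = flank_of(tem)
    scores = []
    for seq in designed_seqs:
        seq = seq.upper()
        if len(seq) != spec.window_length:
            raise ValueError("designed sequence length does not match spec window")
        if mode == "full":
            d = edit_distance(seq, tem)
        else:
            d = edit_distance(flank_of(seq), tem_fl)
        scores.append(d / n_flank)
    scores = np.array(scores)
    return TemplateDifference(scores=scores, mean=float(scores.mean()),
                              sd=float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
                              mode=mode)


# ---------------------------------------------------------------------------
# DNA shape

SHAPE_FIELDS = ("mgw", "prot", "roll1", "roll2", "helt1", "helt2")


@dataclass
class ShapeTracks:
    """Per-position MGW/ProT (Å, degrees) and per-step Roll/HelT (degrees).

    Undefined boundary entries are NaN; ``defined`` masks mark valid spans
    (L-4 positions for MGW/ProT, L-4 steps for Roll/HelT: steps 2..L-3,
    averaging the two overlapping central-step pentamer values where both
    exist).
    """

    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray

    def defined(self, track: str) -> np.ndarray:
        return ~np.isnan(getattr(self, track))


def _pentamer_code(p: str) -> int:
    code = 0
    for c in p:
        code = code * 4 + ALPHABET.index(c)
    return code


def synthetic_shape_table() -> dict:
    """Deterministic reverse-complement-consistent pentamer shape table.

    This is a synthetic stand-in for a published query table: values are
    drawn from a seeded generator per canonical pentamer, with minor-groove
    width biased narrower for AT-rich pentamers so composition structure is
    visible in embeddings.  Ranges are plausible (MGW in Å, angles in
    degrees) but the numbers are not experimental predictions.
    """
    table = {}
    for code in range(1024):
        p = ""
        c = code
        for _ in range(5):
            p = ALPHABET[c % 4] + p
            c //= 4
        rc = reverse_complement(p)
        canon = min(p, rc)
        rng = np.random.default_rng(98_000 + _pentamer_code(canon))
        n_at = sum(ch in "AT" for ch in canon)
        mgw = 5.1 - 0.22 * (n_at - 2.5) + 0.35 * (rng.random() - 0.5)
        prot = -8.0 - 1.4 * (n_at - 2.5) + 2.0 * (rng.random() - 0.5)
        r_a = -2.0 + 1.1 * (2.5 - n_at) + 3.0 * (rng.random() - 0.5)
        r_b = -2.0 + 1.1 * (2.5 - n_at) + 3.0 * (rng.random() - 0.5)
        h_a = 34.5 + 0.6 * (n_at - 2.5) + 1.5 * (rng.random() - 0.5)
        h_b = 34.5 + 0.6 * (n_at - 2.5) + 1.5 * (rng.random() - 0.5)
        if p == canon:
            vals = (mgw, prot, r_a, r_b, h_a, h_b)
        else:
            vals = (mgw, prot, r_b, r_a, h_b, h_a)  # swap central-step pairs
        table[p] = tuple(round(float(v), 3) for v in vals)
    return table


def load_shape_table(path) -> dict:
    """TSV keyed by pentamer: MGW, ProT, Roll1, Roll2, HelT1, HelT2."""
    table = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed shape-table row: {line!r}")
            table[parts[0].upper()] = tuple(float(v) for v in parts[1:])
    return table


def packaged_shape_table() -> dict:
    """The synthetic fixture table shipped with the package."""
    ref = resources.files("seedflank").joinpath("data/pentamer_shape_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_shape_table(path)


def dna_shape(seq: str, table: dict) -> ShapeTracks:
    """Sliding-pentamer shape tracks.

    MGW/ProT are assigned to the pentamer's center base (positions 2..L-3).
    Roll/HelT: step i (between bases i and i+1) for i in 2..L-3 averages the
    second central-step value of the pentamer centered at i with the first
    central-step value of the pentamer centered at i+1 (single-sided at the
    last step), giving exactly L-4 defined steps.
    """
    seq = seq.upper()
    L = len(seq)
    if L < 5:
        raise ValueError("sequence must be at least 5 bp")
    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    roll_sum = np.zeros(L)
    roll_n = np.zeros(L)
    helt_sum = np.zeros(L)
    helt_n = np.zeros(L)
    for c in range(2, L - 2):
        p = seq[c - 2:c + 3]
        row = table.get(p)
        if row is None:
            raise KeyError(f"pentamer {p} missing from shape table")
        m, pr, r1, r2, h1, h2 = row
        mgw[c] = m
        prot[c] = pr
        # central steps of this pentamer: (c-1, c) -> r1/h1 and (c, c+1) -> r2/h2
        if c - 1 >= 2:
            roll_sum[c - 1] += r1
            roll_n[c - 1] += 1
            helt_sum[c - 1] += h1
            helt_n[c - 1] += 1
        roll_sum[c] += r2
        roll_n[c] += 1
        helt_sum[c] += h2
        helt_n[c] += 1
    roll = np.full(L, np.nan)
    helt = np.full(L, np.nan)
    steps = (roll_n > 0) & (np.arange(L) >= 2) & (np.arange(L) <= L - 3)
    roll[steps] = roll_sum[steps] / roll_n[steps]
    helt[steps] = helt_sum[steps] / helt_n[steps]
    return ShapeTracks(mgw=mgw, prot=prot, roll=roll, helt=helt)


def shape_feature_vector(seq: str, table: dict) -> np.ndarray:
    """Concatenation of the four defined shape tracks of one sequence."""
    t = dna_shape(seq, table)
    return np.concatenate([t.mgw[t.defined("mgw")], t.prot[t.defined("prot")],
                           t.roll[t.defined("roll")], t.helt[t.defined("helt")]])


def shape_embedding(seqs, table: dict, reduction_seed=0, method="tsne"):
    """2-D embedding of standardized per-sequence shape feature vectors."""
    if len(seqs) < 10:
        raise ValueError("need at least 10 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    X = np.stack([shape_feature_vector(s, table) for s in seqs])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (len(seqs) - 1) / 3.0)
        emb = TSNE(n_components=2, random_state=reduction_seed, init="pca",
                   perplexity=perplexity).fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=reduction_seed).fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.asarray(emb, dtype=np.float64)


def write_shape_table(path, table: dict) -> None:
    with open(path, "w") as fh:
        fh.write("pentamer\tMGW\tProT\tRoll1\tRoll2\tHelT1\tHelT2\n")
        for p in sorted(table):
            vals = "\t".join(f"{v:g}" for v in table[p])
            fh.write(f"{p}\t{vals}\n")
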