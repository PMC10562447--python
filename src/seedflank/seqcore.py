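"""Sequence alphabets, one-hot encodings, and seed specifications.

A *seed* is the expert-knowledge part of a promoter design: motif substrings
(e.g. the -35/-10 sigma-70 elements, lacO or tetO operators) pinned at fixed
positions inside a fixed-length design window.  Everything outside the seed is
flanking sequence, which the generative model is free to fill in.

Conventions used throughout the package: channel order A, C, G, T; 0-based
coordinates; half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Sequence contains a character outside A/C/G/T/N."""


class SeedSpecError(ValueError):
    """Invalid seed specification (overlap or out-of-window motif)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSpec:
    """Fixed motifs at fixed positions inside a design window.

    ``motifs`` is a tuple of ``(motif_seq, start)`` pairs with 0-based starts;
    motifs must be non-overlapping, fit inside the window, and use only ACGT.
    """

    window_length: int
    motifs: tuple = ()
    label: str = ""

    def __post_init__(self):
        if self.window_length <= 0:
            raise SeedSpecError("window_length must be positive")
        motifs = tuple((str(m).upper(), int(s)) for m, s in self.motifs)
        object.__setattr__(self, "motifs", motifs)
        occupied = np.zeros(self.window_length, dtype=bool)
        for m, s in motifs:
            if any(c not in _BASE_INDEX for c in m):
                raise SeedSpecError(f"motif {m!r} contains non-ACGT characters")
            if s < 0 or s + len(m) > self.window_length:
                raise SeedSpecError(
                    f"motif {m!r} at {s} does not fit in window [0, {self.window_length})")
            if occupied[s:s + len(m)].any():
                lo = s
                hi = s + len(m)
                raise SeedSpecError(f"overlapping motifs in interval [{lo}, {hi})")
            occupied[s:s + len(m)] = True

    @property
    def seed_mask(self) -> np.ndarray:
        """Boolean vector, True at seed positions."""
        mask = np.zeros(self.window_length, dtype=bool)
        for m, s in self.motifs:
            mask[s:s + len(m)] = True
        return mask

    def seed_string(self, fill: str = "N") -> str:
        """The window with motifs written in and flanks as ``fill``."""
        out = [fill] * self.window_length
        for m, s in self.motifs:
            out[s:s + len(m)] = list(m)
        return "".join(out)

    def apply_to(self, seq: str) -> str:
        """Overwrite seed positions of ``seq`` with the motifs."""
        if len(seq) != self.window_length:
            raise SeedSpecError("sequence length does not match window_length")
        out = list(seq)
        for m, s in self.motifs:
            out[s:s + len(m)] = list(m)
        return "".join(out)

    def contains_motifs(self, seq: str) -> bool:
        return all(seq[s:s + len(m)] == m for m, s in self.motifs)

    # serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {"window_length": self.window_length,
                "motifs": [{"seq": m, "start": s} for m, s in self.motifs],
                "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "SeedSpec":
        return cls(window_length=int(d["window_length"]),
                   motifs=tuple((e["seq"], int(e["start"])) for e in d.get("motifs", [])),
                   label=d.get("label", ""))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "SeedSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SeedSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PromoterRecord:
    """A fixed-length promoter sequence with a scalar activity label."""

    seq: str
    activity: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not np.isfinite(self.activity):
            raise ValueError("activity must be finite")


@dataclass
class GeneratorInput:
    """Relaxed one-hot matrix fed to the generator: hard rows at seed
    positions, random row-stochastic vectors elsewhere (the latent draw)."""

    matrix: np.ndarray  # L x 4
    seed_mask: np.ndarray  # L bool


def flanking_length(spec: SeedSpec) -> int:
    """Number of non-seed positions in the design window."""
    return int(spec.window_length - int(spec.seed_mask.sum()))


def encode_onehot(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix (A,C,G,T); 'N' becomes the uniform row."""
    if not seq:
        raise AlphabetError("empty sequence")
    seq = seq.upper()
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, c in enumerate(seq):
        if c == "N":
            out[i] = 0.25
        else:
            j = _BASE_INDEX.get(c)
            if j is None:
                raise AlphabetError(f"illegal character {c!r} at position {i}")
            out[i, j] = 1.0
    return out


def decode_onehot(matrix: np.ndarray) -> str:
    """Per-row argmax letter; ties break lexicographically (A<C<G<T)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError(f"expected an Lx4 matrix, got shape {matrix.shape}")
    if not np.isfinite(matrix).all():
        raise ValueError("matrix contains non-finite entries")
    idx = matrix.argmax(axis=1)  # argmax returns the first maximal index: A<C<G<T
    return "".join(ALPHABET[i] for i in idx)


def random_flank_rows(n: int, rng: np.random.Generator) -> np.ndarray:
    """Latent rows for flanking positions: softmax of 4 standard normals."""
    z = rng.standard_normal((n, 4))
    z = np.exp(z - z.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


def build_generator_input(spec: SeedSpec, rng_seed: int) -> GeneratorInput:
    """Seed rows hard one-hot; non-seed rows i.i.d. softmax-normal draws."""
    rng = np.random.default_rng(rng_seed)
    mask = spec.seed_mask
    mat = np.empty((spec.window_length, 4), dtype=np.float64)
    n_flank = int((~mask).sum())
    mat[~mask] = random_flank_rows(n_flank, rng)
    for m, s in spec.motifs:
        mat[s:s + len(m)] = encode_onehot(m)
    return GeneratorInput(matrix=mat, seed_mask=mask)


def generator_input_from_latent(spec: SeedSpec, latent: np.ndarray) -> GeneratorInput:
    """Build a generator input from explicit pre-softmax latent coordinates.

    ``latent`` has shape (flanking_length, 4); used by the GA, which searches
    over these coordinates directly.
    """
    mask = spec.seed_mask
    n_flank = int((~mask).sum())
    latent = np.asarray(latent, dtype=np.float64).reshape(n_flank, 4)
    z = np.exp(latent - latent.max(axis=1, keepdims=True))
    z = z / z.sum(axis=1, keepdims=True)
    mat = np.empty((spec.window_length, 4), dtype=np.float64)
    mat[~mask] = z
    for m, s in spec.motifs:
        mat[s:s + len(m)] = encode_onehot(m)
    return GeneratorInput(matrix=mat, seed_mask=mask)


# ---------------------------------------------------------------------------
# FASTA plumbing

def read_fasta(path) -> list:
    """Read a FASTA file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs to FASTA."""
    seqs = [SeqRecord(Seq(s), id=str(i), description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")
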