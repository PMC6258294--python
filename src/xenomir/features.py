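"""Sequence feature encodings for mature miRNAs.

Two encodings are provided:

* a 129-feature named vector per sequence — length, the nucleotide
  identity at each of the first 24 positions, 1-3-mer frequencies over the
  full sequence (4 + 16 + 64 features) and 1-2-mer frequencies over the
  seed region, nucleotides 2-8 (4 + 16 features).  The 105 numeric
  features (everything except the 24 categorical position features) form
  the model subset used by the statistical screen, the LDA and the random
  forest;
* a one-of-K binary encoding of the first 18 nucleotides (A=0001, C=0010,
  G=0100, U=1000; all-zero padding blocks) flattened to 72 bits, the input
  of the convolutional classifier.

k-mer frequencies are window counts divided by the number of windows
(L - k + 1), so each k-mer family sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import MiRNARecord, RNA_ALPHABET

NUCLEOTIDES = ("A", "C", "G", "U")
GAP = "-"

#: positional window of the identity features
N_POSITIONS = 24

#: seed region = 1-based positions 2..8 (7 nt)
SEED_START, SEED_END = 2, 8

#: CNN input: first 18 nt, 4 bits each
ENCODING_LENGTH = 18
ENCODING_BITS = ENCODING_LENGTH * 4


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(NUCLEOTIDES, repeat=k)]


FULL_KMER_NAMES: list[str] = _kmers(1) + _kmers(2) + _kmers(3)
SEED_KMER_NAMES: list[str] = [f"{m} (seed)" for m in _kmers(1) + _kmers(2)]
POSITION_NAMES: list[str] = [f"pos_{i}" for i in range(1, N_POSITIONS + 1)]

#: the 105 numeric features used by models and hypothesis tests
MODEL_FEATURE_NAMES: list[str] = ["length"] + FULL_KMER_NAMES + SEED_KMER_NAMES

#: all 129 named features, stable order
ALL_FEATURE_NAMES: list[str] = ["length"] + POSITION_NAMES + \
    FULL_KMER_NAMES + SEED_KMER_NAMES

# one-of-K codes, position-major; bit order follows the A=0001 convention
_ONE_HOT = {
    "A": (0.0, 0.0, 0.0, 1.0),
    "C": (0.0, 0.0, 1.0, 0.0),
    "G": (0.0, 1.0, 0.0, 0.0),
    "U": (1.0, 0.0, 0.0, 0.0),
}


def seed_region(sequence: str) -> str:
    """Return the 7-nt seed region (1-based positions 2-8)."""
    if len(sequence) < SEED_END:
        raise ValueError(
            f"sequence of length {len(sequence)} has no complete seed region"
        )
    return sequence[SEED_START - 1:SEED_END]


def kmer_frequencies(sequence: str, k: int) -> dict[str, float]:
    """Sliding-window k-mer frequencies with all 4^k keys present.

    frequency(m) = count(m) / (len - k + 1); values sum to 1.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    n_windows = len(sequence) - k + 1
    counts = dict.fromkeys(_kmers(k), 0)
    for i in range(n_windows):
        counts[sequence[i:i + k]] += 1
    return {m: c / n_windows for m, c in counts.items()}


@dataclass(frozen=True)
class FeatureVector:
    """The named 129-feature encoding of one sequence."""

    length: int
    position_identity: str          # 24 symbols over {A,C,G,U,-}
    full_kmer_freq: Mapping[str, float]   # 84 values, keys FULL_KMER_NAMES
    seed_kmer_freq: Mapping[str, float]   # 20 values, keys SEED_KMER_NAMES

    def model_values(self) -> np.ndarray:
        """The 105 numeric model features, in MODEL_FEATURE_NAMES order."""
        vals = [float(self.length)]
        vals += [self.full_kmer_freq[m] for m in FULL_KMER_NAMES]
        vals += [self.seed_kmer_freq[m] for m in SEED_KMER_NAMES]
        return np.asarray(vals)

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {"length": self.length}
        for i, name in enumerate(POSITION_NAMES):
            out[name] = self.position_identity[i]
        out.update(self.full_kmer_freq)
        out.update(self.seed_kmer_freq)
        return out


def extract_features(record: MiRNARecord | str) -> FeatureVector:
    """Compute the full 129-feature vector for one miRNA.

    ``length`` is the untruncated sequence length; only the positional
    identity features honor the 24-nt window (shorter sequences padded
    with the gap symbol, longer ones truncated for positions only).
    """
    seq = record.sequence if isinstance(record, MiRNARecord) else record
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)}")
    seed = seed_region(seq)
    positions = (seq[:N_POSITIONS] + GAP * N_POSITIONS)[:N_POSITIONS]
    full = {}
    for k in (1, 2, 3):
        full.update(kmer_frequencies(seq, k))
    seed_f = {}
    for k in (1, 2):
        seed_f.update({f"{m} (seed)": v
                       for m, v in kmer_frequencies(seed, k).items()})
    return FeatureVector(len(seq), positions, full, seed_f)


def feature_matrix(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    """105-column numeric model-feature matrix, indexed by record id."""
    rows = [extract_features(r).model_values() for r in records]
    return pd.DataFrame(rows, index=[r.id for r in records],
                        columns=MODEL_FEATURE_NAMES)


def feature_table(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    """Full 129-column table (position features as symbols), for export."""
    rows = [extract_features(r).as_dict() for r in records]
    return pd.DataFrame(rows, index=[r.id for r in records],
                        columns=ALL_FEATURE_NAMES)


def one_hot_encode(sequence: str, length: int = ENCODING_LENGTH) -> np.ndarray:
    """One-of-K encode the first ``length`` nucleotides into 4*length bits.

    Shorter sequences are padded with all-zero blocks at the end; longer
    sequences are truncated.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)}")
    bits = np.zeros(length * 4)
    for i, nt in enumerate(sequence[:length]):
        bits[4 * i:4 * i + 4] = _ONE_HOT[nt]
    return bits


def one_hot_decode(bits: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`, dropping trailing padding blocks."""
    blocks = np.asarray(bits).reshape(-1, 4)
    rev = {v: k for k, v in _ONE_HOT.items()}
    out = []
    for block in blocks:
        if not block.any():
            break
        out.append(rev[tuple(block)])
    return "".join(out)


def encode_records(records: Iterable[MiRNARecord]) -> np.ndarray:
    """Stack one-hot encodings into an (n, 72) float matrix."""
    return np.vstack([one_hot_encode(r.sequence) for r in records])
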