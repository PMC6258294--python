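"""Reading, validation and curation of mature miRNA sequence sets.

Sequences are stored as uppercase RNA (``ACGU``); DNA input (``T``) is
normalized transparently.  The curation rules implemented here mirror the
collection protocol of the xenomiR / non-xenomiR study design: per-sample
removal of the lowest-abundance 30% of reads, removal of sequences that
overlap the positive set, and strict per-set sequence uniqueness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

LABELS = ("positive", "negative", "unlabeled")

#: minimum mature-miRNA length accepted anywhere in the package
MIN_LENGTH = 15

#: minimum length for members of the unlabeled prediction pool
MIN_POOL_LENGTH = 18


class SequenceError(ValueError):
    """Raised for records that violate the sequence contract."""


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: identifier, RNA sequence and class label.

    ``species``, ``family`` and ``abundance`` (read count or RPM) are
    optional annotations used by curation and family summaries.
    """

    id: str
    sequence: str
    label: str = "unlabeled"
    species: str | None = None
    family: str | None = None
    abundance: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if self.label not in LABELS:
            raise SequenceError(f"unknown label {self.label!r}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-RNA characters {sorted(bad)}"
            )
        if len(self.sequence) < MIN_LENGTH:
            raise SequenceError(
                f"record {self.id!r}: length {len(self.sequence)} < {MIN_LENGTH}"
            )
        if self.abundance is not None and self.abundance < 0:
            raise SequenceError(f"record {self.id!r}: negative abundance")

    def relabel(self, label: str) -> "MiRNARecord":
        return MiRNARecord(self.id, self.sequence, label,
                           self.species, self.family, self.abundance)


@dataclass
class LabeledDataset:
    """Positive (xenomiR) and negative (non-xenomiR) record sets.

    Invariants: sequences are unique within each set and the two sets are
    disjoint by sequence.
    """

    positives: list[MiRNARecord] = field(default_factory=list)
    negatives: list[MiRNARecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos_seqs = [r.sequence for r in self.positives]
        neg_seqs = [r.sequence for r in self.negatives]
        if len(set(pos_seqs)) != len(pos_seqs):
            raise SequenceError("duplicate sequences in positive set")
        if len(set(neg_seqs)) != len(neg_seqs):
            raise SequenceError("duplicate sequences in negative set")
        overlap = set(pos_seqs) & set(neg_seqs)
        if overlap:
            raise SequenceError(
                f"{len(overlap)} sequences occur in both classes"
            )

    @property
    def all_records(self) -> list[MiRNARecord]:
        return list(self.positives) + list(self.negatives)

    def sequences(self) -> set[str]:
        return {r.sequence for r in self.all_records}


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA T to RNA U; raise on any other symbol."""
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"non-nucleotide characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path, label: str = "unlabeled"):
    """Read a miRBase-style mature FASTA file.

    The header token before the first whitespace becomes the record id.
    Records containing characters outside ``ACGUTacgut`` (or shorter than
    the package minimum length) are rejected rather than failing the whole
    file.

    Returns
    -------
    (records, rejected_ids) : tuple[list[MiRNARecord], list[str]]
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MiRNARecord] = []
    rejected: list[str] = []
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        try:
            seq = normalize_sequence(str(entry.seq))
            records.append(MiRNARecord(entry.id, seq, label))
        except SequenceError:
            rejected.append(entry.id)
    if n_entries == 0:
        raise SequenceError(f"{path}: empty or not FASTA")
    return records, rejected


def write_fasta(records: Iterable[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_sequence_table(path: str | Path, label: str,
                        sep: str | None = None) -> list[MiRNARecord]:
    """Read a delimited table with columns id, sequence[, species, family, abundance].

    The delimiter is sniffed from the extension (``.csv`` vs tab) unless
    given.  Sequences are normalized exactly as in :func:`read_fasta`, but
    here an invalid sequence is an error: tables are curated inputs.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise SequenceError(f"{path}: missing mandatory column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for opt in ("species", "family"):
            if opt in df.columns and pd.notna(getattr(row, opt)):
                kwargs[opt] = str(getattr(row, opt))
        if "abundance" in df.columns and pd.notna(row.abundance):
            kwargs["abundance"] = float(row.abundance)
        records.append(
            MiRNARecord(str(row.id), normalize_sequence(str(row.sequence)),
                        label, **kwargs)
        )
    return records


def deduplicate(records: Sequence[MiRNARecord]) -> list[MiRNARecord]:
    """Keep the first occurrence of each sequence, preserving input order."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def filter_unlabeled_pool(candidates: Sequence[MiRNARecord],
                          labeled: LabeledDataset) -> list[MiRNARecord]:
    """Build the unlabeled prediction pool.

    Removes candidates whose sequence is already labeled, keeps only
    sequences of length >= 18 nt, deduplicates and relabels ``unlabeled``.
    """
    known = labeled.sequences()
    kept = [
        rec.relabel("unlabeled")
        for rec in candidates
        if rec.sequence not in known and len(rec.sequence) >= MIN_POOL_LENGTH
    ]
    return deduplicate(kept)


def curate_negatives(samples: Sequence[Sequence[MiRNARecord]],
                     positives: Sequence[MiRNARecord]) -> list[MiRNARecord]:
    """Curate a non-xenomiR (negative) set from per-sample abundance profiles.

    Per sample, records are ranked by abundance (descending) and the
    lowest ``floor(0.3 * n)`` removed — low-abundance miRNAs are probable
    false negatives.  Survivors from all samples are pooled (union), any
    sequence present in the positive set removed, and the result
    deduplicated and labeled ``negative``.

    Abundance ties are broken by lexicographic sequence order so the cut is
    deterministic.
    """
    pos_seqs = {r.sequence for r in positives}
    pooled: list[MiRNARecord] = []
    for sample in samples:
        missing = [r.id for r in sample if r.abundance is None]
        if missing:
            raise SequenceError(
                f"records without abundance in sample: {missing[:5]}"
            )
        n_drop = math.floor(0.3 * len(sample))
        ranked = sorted(sample, key=lambda r: (-r.abundance, r.sequence))
        pooled.extend(ranked[: len(sample) - n_drop] if n_drop else ranked)
    survivors = [r.relabel("negative") for r in pooled
                 if r.sequence not in pos_seqs]
    return deduplicate(survivors)
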