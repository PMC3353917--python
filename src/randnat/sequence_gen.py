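"""Completely random amino-acid sequence generation.

Each position is drawn i.i.d. uniformly over the 20 standard amino acids
(integer 0–19 mapped to one-letter codes in alphabetical order).  The
default length of 70 residues matches the short natural chains the
classifier is compared against.

A library generator applies a pluggable *novelty filter*: in the original
RandomBlast design the filter is a BLAST search against NR that rejects any
sequence with detectable similarity to a natural protein.  Running BLAST is
out of scope here; the default filter accepts everything, and an offline
k-mer-overlap screen against a user-supplied FASTA is provided as a cheap
stand-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Residue <-> integer mapping: index i is the i-th letter in alphabetical
#: one-letter order (A=0, C=1, ..., Y=19).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_LENGTH = 70


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def generate_random_sequence(
    length: int = DEFAULT_LENGTH,
    rng: np.random.Generator | None = None,
    seq_id: str = "rnd-0",
) -> SequenceRecord:
    """Draw one uniform random sequence of the given length."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, len(AA_ALPHABET), size=length)
    return SequenceRecord(id=seq_id, sequence="".join(AA_ALPHABET[i] for i in idx))


def accept_all(sequence: str) -> bool:
    """Default novelty filter: every draw is accepted."""
    return True


def kmer_overlap_filter(reference_fasta, k: int = 8) -> Callable[[str], bool]:
    """Reject sequences sharing any k-mer with a reference FASTA.

    A crude offline surrogate for a similarity search: a candidate is
    novel only if none of its length-k words occurs in any reference
    sequence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref_kmers: set[str] = set()
    for rec in SeqIO.parse(reference_fasta, "fasta"):
        s = str(rec.seq).upper()
        ref_kmers.update(s[i : i + k] for i in range(len(s) - k + 1))

    def _filter(sequence: str) -> bool:
        s = sequence.upper()
        return not any(s[i : i + k] in ref_kmers for i in range(len(s) - k + 1))

    return _filter


def generate_library(
    n: int,
    length: int = DEFAULT_LENGTH,
    novelty_filter: Callable[[str], bool] | None = None,
    max_attempts: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "rnd",
) -> list[SequenceRecord]:
    """Generate exactly ``n`` accepted random sequences.

    Draws are made one at a time; a draw failing the novelty filter is
    discarded (and logged).  Raises ``RuntimeError`` if ``n`` acceptances
    are not reached within ``max_attempts`` draws (default ``100 * n``).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    novelty_filter = accept_all if novelty_filter is None else novelty_filter
    max_attempts = 100 * n if max_attempts is None else max_attempts
    rng = np.random.default_rng() if rng is None else rng

    records: list[SequenceRecord] = []
    attempts = rejected = 0
    while len(records) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"novelty filter accepted only {len(records)}/{n} sequences "
                f"after {attempts} attempts"
            )
        attempts += 1
        rec = generate_random_sequence(
            length, rng, seq_id=f"{id_prefix}-{len(records):05d}"
        )
        if novelty_filter(rec.sequence):
            records.append(rec)
        else:
            rejected += 1
    if rejected:
        logger.info("novelty filter rejected %d of %d draws", rejected, attempts)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
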