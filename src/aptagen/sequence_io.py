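"""Sequence containers, one-hot encoding and batched character streams.

The generator is a character-level model: training data is a set of
fixed-length nucleotide sequences that are concatenated (in file order,
with no separator) into one long character stream.  The stream is cut
into ``B`` parallel sub-streams and those into chunks of ``S`` characters,
the unit over which truncated backpropagation is run.

Nucleotides map to class indices ``A=1, C=2, G=3, T/U=4``; T and U are
distinct on input but share class 4, so DNA and RNA models share one
4-symbol alphabet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence as TypingSequence, Tuple, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "Sequence",
    "OneHotVector",
    "StreamChunks",
    "read_sequences",
    "write_sequences",
    "encode_indices",
    "decode_indices",
    "encode_one_hot",
    "decode_one_hot",
    "build_streams",
]


class Alphabet(enum.Enum):
    DNA = "DNA"
    RNA = "RNA"

    @property
    def letters(self) -> str:
        return "ACGT" if self is Alphabet.DNA else "ACGU"


# class-index order A, C, G, T/U (1-based classes 1..4; arrays use 0..3)
_DNA_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_RNA_TO_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class Sequence:
    """A fixed-alphabet nucleotide sequence with an identifier."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        table = _DNA_TO_IDX if self.alphabet is Alphabet.DNA else _RNA_TO_IDX
        for pos, ch in enumerate(self.residues):
            if ch not in table:
                raise ValueError(
                    f"sequence {self.id!r}: invalid character {ch!r} at "
                    f"position {pos + 1} for alphabet {self.alphabet.value}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OneHotVector:
    """One observed nucleotide as a 4-element indicator vector.

    ``class_index`` is 1-based (A=1, C=2, G=3, T/U=4); ``values`` has a
    single 1 at ``class_index - 1``.
    """

    values: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4,):
            raise ValueError("one-hot vector must have exactly 4 elements")
        if self.class_index not in (1, 2, 3, 4):
            raise ValueError("class_index must be in {1,2,3,4}")


def read_sequences(
    path: Union[str, Path],
    fmt: str = "plain",
    alphabet: Alphabet = Alphabet.DNA,
) -> List[Sequence]:
    """Read sequences from a plain-text (one per line) or FASTA file.

    Residues are uppercased.  Plain-format identifiers are 1-based line
    numbers.  A character outside the alphabet raises ``ValueError``
    naming the offending line/position; an empty file raises too.
    """
    path = Path(path)
    seqs: List[Sequence] = []
    if fmt == "plain":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                residues = line.strip().upper()
                if not residues:
                    continue
                try:
                    seqs.append(Sequence(str(lineno), residues, alphabet))
                except ValueError as exc:
                    raise ValueError(f"{path}, line {lineno}: {exc}") from None
    elif fmt == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            seqs.append(Sequence(record.id, str(record.seq).upper(), alphabet))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'plain' or 'fasta'")
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_sequences(
    seqs: Iterable[Sequence], path: Union[str, Path], fmt: str = "plain"
) -> None:
    """Write sequences as plain text (one per line) or FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            if fmt == "plain":
                fh.write(s.residues + "\n")
            elif fmt == "fasta":
                fh.write(f">{s.id}\n{s.residues}\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")


def encode_indices(seq: Union[Sequence, str], alphabet: Alphabet = Alphabet.DNA) -> np.ndarray:
    """Encode residues as 0-based class indices (A=0, C=1, G=2, T/U=3)."""
    if isinstance(seq, Sequence):
        residues, alphabet = seq.residues, seq.alphabet
    else:
        residues = seq
    table = _DNA_TO_IDX if alphabet is Alphabet.DNA else _RNA_TO_IDX
    try:
        return np.array([table[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} for {alphabet.value}") from None


def decode_indices(idx: np.ndarray, alphabet: Alphabet = Alphabet.DNA) -> str:
    letters = alphabet.letters
    return "".join(letters[i] for i in np.asarray(idx).ravel())


def encode_one_hot(seq: Sequence) -> List[OneHotVector]:
    """One-hot encode every position of *seq* in class order A,C,G,T/U."""
    out = []
    for i in encode_indices(seq):
        v = np.zeros(4)
        v[i] = 1.0
        out.append(OneHotVector(values=v, class_index=int(i) + 1))
    return out


def decode_one_hot(vectors: TypingSequence[OneHotVector], alphabet: Alphabet = Alphabet.DNA) -> str:
    """Inverse of :func:`encode_one_hot`."""
    return decode_indices(np.array([v.class_index - 1 for v in vectors]), alphabet)


@dataclass
class StreamChunks:
    """Batched input/target chunks for truncated-BPTT training.

    Each chunk is a pair of ``(B, S)`` integer matrices: inputs and their
    next-character targets within the concatenated stream.  The last
    ``max(1, floor(val_frac * n_chunks))`` chunks (when at least two
    chunks exist) are held out for validation.
    """

    train_chunks: List[Tuple[np.ndarray, np.ndarray]]
    val_chunks: List[Tuple[np.ndarray, np.ndarray]]
    batch_size: int
    seq_len: int
    total_chars: int
    dropped_chars: int = 0
    alphabet: Alphabet = Alphabet.DNA

    @property
    def n_chunks(self) -> int:
        return len(self.train_chunks) + len(self.val_chunks)


def build_streams(
    seqs: TypingSequence[Sequence],
    batch_size: int = 50,
    seq_len: int = 20,
    val_frac: float = 0.05,
) -> StreamChunks:
    """Concatenate *seqs* into ``batch_size`` parallel streams of chunks.

    All sequences must share length ``seq_len``.  The concatenation (no
    separator characters) is cut into ``B`` contiguous streams; each
    stream into chunks of ``S`` characters.  Targets are the next
    character within the concatenation; the final character's target
    wraps to the stream's first character.  Characters that do not fill
    a whole ``B x S`` chunk are dropped.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if not 0.0 < val_frac < 1.0:
        raise ValueError("val_frac must lie in (0, 1)")
    if not seqs:
        raise ValueError("no input sequences")
    alphabet = seqs[0].alphabet
    for s in seqs:
        if len(s) != seq_len:
            raise ValueError(
                f"sequence {s.id!r} has length {len(s)}, expected {seq_len}"
            )
    data = np.concatenate([encode_indices(s) for s in seqs])
    n_total = data.size
    chunk_chars = batch_size * seq_len
    n_chunks = n_total // chunk_chars
    if n_chunks == 0:
        raise ValueError(
            f"{n_total} characters cannot fill one {batch_size}x{seq_len} chunk"
        )
    used = n_chunks * chunk_chars
    # stream b is the contiguous slice data[b*L:(b+1)*L]
    streams = data[:used].reshape(batch_size, n_chunks * seq_len)
    targets = np.empty_like(streams)
    targets[:, :-1] = streams[:, 1:]
    for b in range(batch_size):
        nxt = (b + 1) * (n_chunks * seq_len)
        # wrap to start of concatenation when no successor exists
        targets[b, -1] = data[nxt] if nxt < n_total else data[0]
    chunks = [
        (
            streams[:, c * seq_len : (c + 1) * seq_len].copy(),
            targets[:, c * seq_len : (c + 1) * seq_len].copy(),
        )
        for c in range(n_chunks)
    ]
    n_val = max(1, int(np.floor(val_frac * n_chunks))) if n_chunks >= 2 else 0
    return StreamChunks(
        train_chunks=chunks[: n_chunks - n_val],
        val_chunks=chunks[n_chunks - n_val :],
        batch_size=batch_size,
        seq_len=seq_len,
        total_chars=n_total,
        dropped_chars=n_total - used,
        alphabet=alphabet,
    )
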