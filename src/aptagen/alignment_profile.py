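"""Global alignment of candidates to known aptamers and specificity profiles.

Candidate sequences (short, e.g. 20-mers) are aligned to full-length
reference aptamers — the randomized selection region plus its constant
primer-derived flanks — with a Needleman–Wunsch / Gotoh affine-gap
aligner.  Defaults emulate the EMBOSS needle nucleotide setup: match +5,
mismatch −4, gap open 10, gap extend 0.5, and free (unpenalized) end
gaps, which is what makes a 20-mer align locally along a ~90-nt
reference.

For a ranked candidate set, the per-position **cumulative specificity
profile** adds each candidate's SP to every reference position where its
alignment places a non-gap query character; peaks in the profile mark
where high-specificity candidates concentrate along the aptamer.

Also provided: IUPAC degenerate-motif occurrence scanning (e.g. the
pyrimidine-rich YGCY motif of MBNL1-binding RNAs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import IUPACData

from .sequence_io import Sequence

__all__ = [
    "AlignParams",
    "GlobalAlignment",
    "AptamerReference",
    "AlignmentProfile",
    "global_align",
    "build_profile",
    "find_motif_occurrences",
    "NFATC1_APTAMER_TEMPLATE",
    "MBNL1_APTAMER_TEMPLATE",
]

_NEG_INF = -1e30


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring; a gap of length L costs ``gap_open + L * gap_extend``."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    free_end_gaps: bool = True
    ambiguous_score: float = -2.0  # any pair involving a non-ACGT code


@dataclass
class GlobalAlignment:
    aligned_query: str
    aligned_reference: str
    score: float
    params: AlignParams

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned strings must have equal length")

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference(self) -> str:
        return self.aligned_reference.replace("-", "")


def _as_string(seq: Union[Sequence, str]) -> str:
    s = seq.residues if isinstance(seq, Sequence) else str(seq)
    return s.upper()


def _pair_score(a: str, b: str, params: AlignParams) -> float:
    # T and U are the same symbol for alignment purposes
    a = "T" if a == "U" else a
    b = "T" if b == "U" else b
    if a not in "ACGT" or b not in "ACGT":
        return params.ambiguous_score
    return params.match if a == b else params.mismatch


def global_align(
    query: Union[Sequence, str],
    reference: Union[Sequence, str],
    params: AlignParams = AlignParams(),
) -> GlobalAlignment:
    """Optimal global (Gotoh affine-gap) alignment with deterministic traceback.

    Ties in the main matrix prefer diagonal over up (gap in reference)
    over left (gap in query).  With ``free_end_gaps`` (default), leading
    and trailing gaps in either sequence are unpenalized and the end
    cell is the best cell on the last row/column (ties resolved toward
    the bottom-right corner).
    """
    q = _as_string(query)
    r = _as_string(reference)
    if not q or not r:
        raise ValueError("cannot align an empty sequence")
    m, n = len(q), len(r)
    open_cost = params.gap_open + params.gap_extend
    ext = params.gap_extend

    H = np.full((m + 1, n + 1), _NEG_INF)
    E = np.full((m + 1, n + 1), _NEG_INF)  # gap in query (left moves)
    F = np.full((m + 1, n + 1), _NEG_INF)  # gap in reference (up moves)
    hptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up(F), 2 left(E)
    eptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 opened from H, 1 extended
    fptr = np.zeros((m + 1, n + 1), dtype=np.int8)

    H[0, 0] = 0.0
    for j in range(1, n + 1):
        if params.free_end_gaps:
            H[0, j] = 0.0
        else:
            E[0, j] = -(params.gap_open + j * ext)
            eptr[0, j] = 0 if j == 1 else 1
            H[0, j] = E[0, j]
            hptr[0, j] = 2
    for i in range(1, m + 1):
        if params.free_end_gaps:
            H[i, 0] = 0.0
        else:
            F[i, 0] = -(params.gap_open + i * ext)
            fptr[i, 0] = 0 if i == 1 else 1
            H[i, 0] = F[i, 0]
            hptr[i, 0] = 1

    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - open_cost
            e_ext = E[i, j - 1] - ext
            if e_open >= e_ext:
                E[i, j], eptr[i, j] = e_open, 0
            else:
                E[i, j], eptr[i, j] = e_ext, 1
            f_open = H[i - 1, j] - open_cost
            f_ext = F[i - 1, j] - ext
            if f_open >= f_ext:
                F[i, j], fptr[i, j] = f_open, 0
            else:
                F[i, j], fptr[i, j] = f_ext, 1
            diag = H[i - 1, j - 1] + _pair_score(qi, r[j - 1], params)
            # tie preference: diagonal > up > left
            best, ptr = diag, 0
            if F[i, j] > best:
                best, ptr = F[i, j], 1
            if E[i, j] > best:
                best, ptr = E[i, j], 2
            H[i, j], hptr[i, j] = best, ptr

    if params.free_end_gaps:
        end_i, end_j, best = m, n, H[m, n]
        for j in range(n + 1):
            if H[m, j] > best or (H[m, j] == best and (m + j, m) > (end_i + end_j, end_i)):
                end_i, end_j, best = m, j, H[m, j]
        for i in range(m + 1):
            if H[i, n] > best or (H[i, n] == best and (i + n, i) > (end_i + end_j, end_i)):
                end_i, end_j, best = i, n, H[i, n]
        score = float(best)
    else:
        end_i, end_j = m, n
        score = float(H[m, n])

    aq: List[str] = []
    ar: List[str] = []
    # trailing free end gaps
    for i in range(m, end_i, -1):
        aq.append(q[i - 1])
        ar.append("-")
    for j in range(n, end_j, -1):
        aq.append("-")
        ar.append(r[j - 1])
    i, j, state = end_i, end_j, "H"
    while i > 0 or j > 0:
        if state == "H":
            if params.free_end_gaps and (i == 0 or j == 0):
                break  # leading free end gaps handled below
            if i == 0:
                state = "E"
                continue
            if j == 0:
                state = "F"
                continue
            p = hptr[i, j]
            if p == 0:
                aq.append(q[i - 1])
                ar.append(r[j - 1])
                i -= 1
                j -= 1
            elif p == 1:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            p = fptr[i, j]
            aq.append(q[i - 1])
            ar.append("-")
            i -= 1
            state = "H" if p == 0 else "F"
        else:  # E
            p = eptr[i, j]
            aq.append("-")
            ar.append(r[j - 1])
            j -= 1
            state = "H" if p == 0 else "E"
    # leading free end gaps
    while i > 0:
        aq.append(q[i - 1])
        ar.append("-")
        i -= 1
    while j > 0:
        aq.append("-")
        ar.append(r[j - 1])
        j -= 1
    return GlobalAlignment("".join(reversed(aq)), "".join(reversed(ar)), score, params)


# ----------------------------------------------------------------------
# reference aptamers


@dataclass(frozen=True)
class AptamerReference:
    """A known aptamer: constant flanks plus the selected variable region.

    ``region`` is the 0-based half-open span of the variable (randomized
    library) segment within ``residues``.  Templates below keep the
    variable region as N's; real references carry the selected bases.
    """

    id: str
    residues: str
    region: Tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.region
        if not (0 <= start <= end <= len(self.residues)):
            raise ValueError("variable-region span must lie within the sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> List["AptamerReference"]:
        """Read references whose descriptions carry ``region=<start>-<end>``
        (1-based inclusive)."""
        refs = []
        for record in SeqIO.parse(str(path), "fasta"):
            mobj = re.search(r"region=(\d+)-(\d+)", record.description)
            seq = str(record.seq).upper()
            if mobj:
                region = (int(mobj.group(1)) - 1, int(mobj.group(2)))
            else:
                region = (0, len(seq))
            refs.append(cls(record.id, seq, region))
        if not refs:
            raise ValueError(f"no reference aptamers in {path}")
        return refs


#: Selection-library template for the NFATC1 aptamer: constant flanks
#: around a 40-nt randomized region.
NFATC1_APTAMER_TEMPLATE = AptamerReference(
    "NFATC1_template",
    "GGGAGAGCGGAAGCGUGCUGGGCC" + "N" * 40 + "CAUAACCCAGAGGUCGAUGGAUCCCCCC",
    (24, 64),
)

#: Selection-library template for the MBNL1 aptamers: 32-nt randomized region.
MBNL1_APTAMER_TEMPLATE = AptamerReference(
    "MBNL1_template",
    "GGGAAUGGAUCCACAUCUACGAAUUC" + "N" * 32 + "AAGACUCGAUACGUGACGAACCU",
    (26, 58),
)


@dataclass
class AlignmentProfile:
    """Per-position cumulative specificity over a reference aptamer."""

    reference_id: str
    cumulative_sp: np.ndarray
    coverage: np.ndarray
    region: Tuple[int, int]

    @property
    def argmax(self) -> int:
        """0-based reference position with the highest cumulative SP."""
        return int(np.argmax(self.cumulative_sp))

    @property
    def argmax_in_region(self) -> bool:
        return self.region[0] <= self.argmax < self.region[1]

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: 1-based position, cumulative SP, coverage,
        in_variable_region flag."""
        n = self.cumulative_sp.size
        pos = np.arange(1, n + 1)
        return pd.DataFrame(
            {
                "position": pos,
                "cumulative_sp": self.cumulative_sp,
                "coverage": self.coverage,
                "in_variable_region": [
                    self.region[0] <= p < self.region[1] for p in range(n)
                ],
            }
        )


def build_profile(
    candidates: Union[pd.DataFrame, Iterable[Tuple[Union[Sequence, str], float]]],
    reference: AptamerReference,
    params: AlignParams = AlignParams(),
) -> AlignmentProfile:
    """Align every candidate to *reference* and accumulate SP per position.

    A candidate's SP is added once at every ungapped reference position
    where its alignment places a non-gap query character.  Accepts a
    scored table (columns ``sequence`` and ``SP``) or ``(sequence, sp)``
    pairs.
    """
    if isinstance(candidates, pd.DataFrame):
        pairs = list(zip(candidates["sequence"], candidates["SP"]))
    else:
        pairs = [( _as_string(s), float(sp)) for s, sp in candidates]
    if not pairs:
        raise ValueError("no candidates to profile")
    n = len(reference)
    cumulative = np.zeros(n)
    coverage = np.zeros(n, dtype=np.int64)
    for seq, sp in pairs:
        aln = global_align(seq, reference.residues, params)
        ref_pos = 0
        for qc, rc in zip(aln.aligned_query, aln.aligned_reference):
            if rc != "-":
                if qc != "-":
                    cumulative[ref_pos] += sp
                    coverage[ref_pos] += 1
                ref_pos += 1
    return AlignmentProfile(reference.id, cumulative, coverage, reference.region)


# ----------------------------------------------------------------------
# IUPAC motif scanning

_IUPAC_SETS = {
    code: set(letters)
    for code, letters in IUPACData.ambiguous_dna_values.items()
}


def find_motif_occurrences(
    seq: Union[Sequence, str], pattern: str
) -> List[Tuple[int, int]]:
    """All (possibly overlapping) occurrences of an IUPAC *pattern*.

    Returns 0-based half-open spans.  T and U are interchangeable on
    both sides (the YGCY pyrimidine motif matches DNA and RNA alike).
    """
    s = _as_string(seq).replace("U", "T")
    pat = pattern.upper().replace("U", "T")
    sets = []
    for code in pat:
        if code not in _IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        sets.append(_IUPAC_SETS[code])
    hits = []
    m = len(pat)
    for start in range(len(s) - m + 1):
        if all(s[start + k] in sets[k] for k in range(m)):
            hits.append((start, start + m))
    return hits
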