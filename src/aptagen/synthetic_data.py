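"""Synthetic motif-planted training data and matched ground-truth scorers.

Emulates a selection experiment's positive pool: fixed-length sequences
over a uniform background in which a binding motif is planted, with a
configurable rate, at a uniform-random offset.  Motif instances are
sampled from a per-position probability matrix (not pasted as a fixed
consensus string) so that a generator trained on the output has to learn
a distribution.  The matching ground-truth scorer is the log-odds PWM of
the same matrix, which makes every downstream stage testable without
any external model or download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence as TypingSequence, Union

import numpy as np
from Bio.Data import IUPACData

from .binding_score import EnsembleMember, PWMScorer, ScorerEnsemble, build_background
from .sequence_io import Alphabet, Sequence, decode_indices

__all__ = [
    "SyntheticSpec",
    "iupac_probability_matrix",
    "dirichlet_motif_matrix",
    "consensus_of",
    "sample_training_set",
    "sample_cross_reactive_set",
    "random_pool",
    "ground_truth_scorer",
    "make_ensemble_fixture",
]


def _iupac_letters(code: str) -> str:
    """Concrete DNA letters an IUPAC code stands for (U handled as T)."""
    code = code.upper().replace("U", "T")
    try:
        return IUPACData.ambiguous_dna_values[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def iupac_probability_matrix(motif: str, consensus_prob: float = 0.85) -> np.ndarray:
    """Per-position probability matrix for an IUPAC motif string.

    The letters allowed by each code share ``consensus_prob``; the
    remaining mass is spread over the other letters, so a planted
    instance matches the consensus at a position with probability
    ``consensus_prob`` but is not a constant substring.
    """
    if not 0.0 < consensus_prob <= 1.0:
        raise ValueError("consensus_prob must lie in (0, 1]")
    order = "ACGT"
    rows = []
    for code in motif:
        allowed = _iupac_letters(code)
        row = np.empty(4)
        for j, base in enumerate(order):
            if base in allowed:
                row[j] = consensus_prob / len(allowed)
            else:
                row[j] = (1.0 - consensus_prob) / (4 - len(allowed))
        rows.append(row)
    return np.array(rows)


def dirichlet_motif_matrix(
    consensus: str,
    concentration: float = 20.0,
    off_mass: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Probability matrix perturbed around a consensus with Dirichlet noise.

    Yields heterogeneous columns (as real transcription-factor PWMs
    have), so window log-odds sums are generically distinct and the
    affinity percentiles of random sequences are finely resolved.
    """
    base = iupac_probability_matrix(consensus, consensus_prob=1.0 - off_mass)
    rng = np.random.default_rng(seed)
    return np.stack([rng.dirichlet(row * concentration) for row in base])


def consensus_of(matrix: np.ndarray, alphabet: Alphabet = Alphabet.DNA) -> str:
    """Argmax consensus string of a probability (or log-odds) matrix."""
    return decode_indices(np.argmax(np.asarray(matrix), axis=1), alphabet)


@dataclass
class SyntheticSpec:
    """Recipe for one motif-planted training set and its true scorer."""

    n_sequences: int
    seq_len: int = 20
    motif: Union[str, np.ndarray] = "TTTCCA"
    plant_rate: float = 0.9
    consensus_prob: float = 0.85
    alphabet: Alphabet = Alphabet.DNA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must lie in [0, 1]")
        if self.motif_matrix.shape[0] > self.seq_len:
            raise ValueError("motif length exceeds seq_len")

    @property
    def motif_matrix(self) -> np.ndarray:
        if isinstance(self.motif, str):
            return iupac_probability_matrix(self.motif, self.consensus_prob)
        return np.asarray(self.motif, dtype=float)

    @property
    def consensus(self) -> str:
        if isinstance(self.motif, str):
            return self.motif.upper().replace("U", "T")
        return consensus_of(self.motif)


def sample_training_set(spec: SyntheticSpec) -> List[Sequence]:
    """Draw the training set: uniform background, motif planted with
    probability ``plant_rate`` at a uniform-random valid offset."""
    rng = np.random.default_rng(spec.seed)
    matrix = spec.motif_matrix
    m = matrix.shape[0]
    L = spec.seq_len
    idx = rng.integers(0, 4, size=(spec.n_sequences, L))
    plant = rng.random(spec.n_sequences) < spec.plant_rate
    offsets = rng.integers(0, L - m + 1, size=spec.n_sequences)
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0
    for i in np.flatnonzero(plant):
        u = rng.random(m)
        inst = (u[:, None] < cum).argmax(axis=1)
        idx[i, offsets[i] : offsets[i] + m] = inst
    return [
        Sequence(f"syn_{i}", decode_indices(row, spec.alphabet), spec.alphabet)
        for i, row in enumerate(idx)
    ]


def random_pool(
    n: int, length: int = 20, alphabet: Alphabet = Alphabet.DNA, seed: int = 0
) -> List[Sequence]:
    """n uniform-random sequences (the plant_rate = 0 special case)."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=(n, length))
    return [
        Sequence(f"rand_{i}", decode_indices(row, alphabet), alphabet)
        for i, row in enumerate(idx)
    ]


def sample_cross_reactive_set(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    n_sequences: int,
    p_both: float = 0.4,
    p_a_only: float = 0.5,
    seed: int = 0,
) -> List[Sequence]:
    """Training set emulating a cross-reactive selection pool.

    Each sequence gets, over uniform background: both motifs at
    non-overlapping random offsets (probability ``p_both``), motif A
    alone (``p_a_only``), or no motif (the rest).  Such a pool is what
    makes specificity ranking differ from affinity ranking: affinity to
    A alone cannot see the off-target motif B, specificity can.
    """
    if p_both + p_a_only > 1.0 + 1e-12:
        raise ValueError("p_both + p_a_only must be <= 1")
    if spec_a.seq_len != spec_b.seq_len:
        raise ValueError("specs must share seq_len")
    L = spec_a.seq_len
    mat_a, mat_b = spec_a.motif_matrix, spec_b.motif_matrix
    ma, mb = mat_a.shape[0], mat_b.shape[0]
    if ma + mb > L:
        raise ValueError("motifs do not fit together in one sequence")
    # all non-overlapping offset pairs, either order
    pairs = [
        (oa, ob)
        for oa in range(L - ma + 1)
        for ob in range(L - mb + 1)
        if oa + ma <= ob or ob + mb <= oa
    ]
    rng = np.random.default_rng(seed)

    def _instance(matrix: np.ndarray) -> np.ndarray:
        cum = np.cumsum(matrix, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(matrix.shape[0])
        return (u[:, None] < cum).argmax(axis=1)

    idx = rng.integers(0, 4, size=(n_sequences, L))
    kinds = rng.choice(3, size=n_sequences, p=[p_both, p_a_only, 1.0 - p_both - p_a_only])
    for i in range(n_sequences):
        if kinds[i] == 0:
            oa, ob = pairs[rng.integers(0, len(pairs))]
            idx[i, oa : oa + ma] = _instance(mat_a)
            idx[i, ob : ob + mb] = _instance(mat_b)
        elif kinds[i] == 1:
            oa = rng.integers(0, L - ma + 1)
            idx[i, oa : oa + ma] = _instance(mat_a)
    return [
        Sequence(f"mix_{i}", decode_indices(row, spec_a.alphabet), spec_a.alphabet)
        for i, row in enumerate(idx)
    ]


def ground_truth_scorer(
    spec: SyntheticSpec,
    name: Optional[str] = None,
    experiment_type: str = "SELEX",
    auc: Optional[float] = None,
    pseudocount: float = 0.5,
) -> PWMScorer:
    """Log-odds PWM of the spec's motif matrix (uniform 0.25 background)."""
    return PWMScorer.from_probabilities(
        name or f"pwm_{spec.consensus}",
        spec.motif_matrix,
        pseudocount=pseudocount,
        experiment_type=experiment_type,
        auc=auc,
    )


def make_ensemble_fixture(
    specs: TypingSequence[SyntheticSpec],
    aucs: TypingSequence[float] = (),
    experiment_types: Optional[TypingSequence[str]] = None,
    background_n: int = 20_000,
    seed: int = 0,
) -> ScorerEnsemble:
    """Ensemble of ground-truth scorers with per-member backgrounds.

    Empty ``aucs`` means every member is weighted 1.  Motif consensi
    must be distinct.  All specs must share ``seq_len`` (the background
    length).
    """
    if aucs and len(aucs) != len(specs):
        raise ValueError("aucs must be empty or match the number of specs")
    consensi = [s.consensus for s in specs]
    if len(set(consensi)) != len(consensi):
        raise ValueError(f"duplicate motif consensus in specs: {consensi}")
    lengths = {s.seq_len for s in specs}
    if len(lengths) != 1:
        raise ValueError("all specs must share seq_len")
    length = lengths.pop()
    exp = experiment_types or ["SELEX"] * len(specs)
    members = []
    bg_seeds = np.random.SeedSequence(seed).generate_state(len(specs))
    for i, spec in enumerate(specs):
        scorer = ground_truth_scorer(
            spec,
            experiment_type=exp[i],
            auc=aucs[i] if aucs else None,
        )
        bg = build_background(scorer, n=background_n, length=length, seed=int(bg_seeds[i] % (2**31)))
        members.append(EnsembleMember(scorer, bg))
    return ScorerEnsemble(members)
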