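"""Binding-affinity and binding-specificity scoring.

Raw scores from different protein-binding predictors live on arbitrary,
mutually incomparable scales.  They are calibrated here through an
empirical background: score ``n`` uniform-random sequences (200,000 by
default) with one scorer, sort the scores, and define the **binding
affinity** AF of a query sequence as the fraction of background scores
its own score equals or exceeds — an empirical-CDF percentile in [0, 1].

The **binding specificity** SP of a sequence for a target scorer m is
the AUC-weighted affinity under m minus the mean AUC-weighted affinity
under all *other* scorers trained on the same experiment type:

    SP(s) = AF_m(s) * AUC_m - (1/|Mc|) * sum_{k in Mc} AF_k(s) * AUC_k

where Mc is the set of same-experiment scorers other than m.  A scorer
with no AUC annotation is weighted 1.

Any deterministic ``Sequence -> float`` scorer honours the contract; the
shipped implementation is a log-odds position weight matrix (PWM) with
max-over-windows aggregation on the forward strand (the candidate
molecules are single-stranded).
"""

from __future__ import annotations

import abc
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence as TypingSequence, Union

import numpy as np
import pandas as pd

from .sequence_io import Sequence, encode_indices

__all__ = [
    "Scorer",
    "PWMScorer",
    "EmpiricalBackground",
    "EnsembleMember",
    "ScorerEnsemble",
    "build_background",
    "affinity",
    "specificity",
    "score_pool",
    "REFERENCE_MODEL_AUCS",
]

#: Published test-set AUCs of reference protein-binding models (per
#: protein: experiment type, AUC; ``None`` = not available, weighted 1).
REFERENCE_MODEL_AUCS: Dict[str, tuple] = {
    "TEAD4": ("ChIP-seq", 0.990),
    "NFATC1": ("SELEX", 0.909),
    "DRGX": ("SELEX", 0.897),
    "GCM1": ("SELEX", 0.841),
    "NFKB1": ("SELEX", 0.771),
    "OLIG1": ("SELEX", 0.733),
    "RXRB": ("SELEX", 0.720),
    "SOX2": ("SELEX", 0.605),
    "BHLHE23": ("SELEX", 0.557),
    "MTF1": ("SELEX", 0.538),
    "FOXP3": ("SELEX", 0.499),
    "MBNL1": ("RNAcompete", None),
}


class Scorer(abc.ABC):
    """Deterministic sequence scorer with optional reliability metadata."""

    def __init__(self, name: str, experiment_type: str = "SELEX", auc: Optional[float] = None):
        if auc is not None and not 0.0 < auc <= 1.0:
            raise ValueError("auc must lie in (0, 1]")
        self.name = name
        self.experiment_type = experiment_type
        self.auc = auc

    @property
    def weight(self) -> float:
        """AUC weight; 1 exactly when no AUC is available."""
        return 1.0 if self.auc is None else float(self.auc)

    @abc.abstractmethod
    def score_indices(self, idx: np.ndarray) -> np.ndarray:
        """Score encoded sequences ``(n, L)`` of class indices 0..3."""

    def score(self, seq: Union[Sequence, str]) -> float:
        idx = encode_indices(seq) if not isinstance(seq, np.ndarray) else seq
        return float(self.score_indices(idx.reshape(1, -1))[0])

    def __repr__(self) -> str:
        return f"{type(self).__name__}(name={self.name!r}, experiment={self.experiment_type!r}, auc={self.auc})"


class PWMScorer(Scorer):
    """Log-odds position weight matrix scorer.

    ``log_odds`` has shape (motif_length, 4) in A, C, G, T/U column
    order.  A sequence's score is the maximum over all contiguous
    windows (forward strand only) of the summed log-odds.
    """

    def __init__(
        self,
        name: str,
        log_odds: np.ndarray,
        experiment_type: str = "SELEX",
        auc: Optional[float] = None,
    ):
        super().__init__(name, experiment_type, auc)
        log_odds = np.asarray(log_odds, dtype=float)
        if log_odds.ndim != 2 or log_odds.shape[1] != 4:
            raise ValueError("log_odds must have shape (motif_length, 4)")
        self.log_odds = log_odds

    @property
    def motif_length(self) -> int:
        return self.log_odds.shape[0]

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: float = 0.25,
        **kwargs,
    ) -> "PWMScorer":
        """Build from a (motif_length, 4) count matrix.

        Log-odds: ln((count + pseudocount) / (column_total + 4 *
        pseudocount) / background), with uniform background 0.25.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (motif_length, 4)")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)
        return cls(name, np.log(probs / background), **kwargs)

    @classmethod
    def from_probabilities(cls, name: str, probs: np.ndarray, pseudo_obs: float = 100.0, **kwargs) -> "PWMScorer":
        """Build from a per-position probability matrix via pseudo-counts."""
        probs = np.asarray(probs, dtype=float)
        return cls.from_counts(name, probs * pseudo_obs, **kwargs)

    @classmethod
    def from_jaspar(cls, path: Union[str, Path, io.TextIOBase], **kwargs) -> "PWMScorer":
        """Read a JASPAR-style plain-text count matrix (4 rows, A C G T)."""
        from Bio import motifs

        handle = open(path) if isinstance(path, (str, Path)) else path
        try:
            motif = motifs.read(handle, "jaspar")
        finally:
            if isinstance(path, (str, Path)):
                handle.close()
        counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float).T
        name = kwargs.pop("name", motif.matrix_id or motif.name or "pwm")
        return cls.from_counts(name, counts, **kwargs)

    def to_jaspar(self, path: Union[str, Path], counts_scale: float = 100.0) -> None:
        """Write as a JASPAR-style count matrix (probabilities x scale)."""
        probs = np.exp(self.log_odds) * 0.25
        probs = probs / probs.sum(axis=1, keepdims=True)
        counts = probs * counts_scale
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for row, base in zip(counts.T, "ACGT"):
                fh.write(f"{base} [ " + " ".join(f"{v:.2f}" for v in row) + " ]\n")

    def score_indices(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        if idx.ndim == 1:
            idx = idx.reshape(1, -1)
        n, L = idx.shape
        m = self.motif_length
        if m > L:
            raise ValueError(f"motif length {m} exceeds sequence length {L}")
        n_windows = L - m + 1
        best = np.full(n, -np.inf)
        for off in range(n_windows):
            window = np.zeros(n)
            for j in range(m):
                window += self.log_odds[j, idx[:, off + j]]
            np.maximum(best, window, out=best)
        return best


@dataclass
class EmpiricalBackground:
    """Sorted scores of n uniform-random sequences under one scorer.

    Defines the affinity percentile function for that scorer.
    """

    scorer_name: str
    sorted_scores: np.ndarray
    length: int
    seed: int

    def __post_init__(self) -> None:
        self.sorted_scores = np.asarray(self.sorted_scores, dtype=float)
        if self.sorted_scores.ndim != 1 or self.sorted_scores.size < 1:
            raise ValueError("sorted_scores must be a nonempty 1-D array")
        if np.any(np.diff(self.sorted_scores) < 0):
            raise ValueError("sorted_scores must be nondecreasing")

    @property
    def n(self) -> int:
        return int(self.sorted_scores.size)


def build_background(
    scorer: Scorer,
    n: int = 200_000,
    length: int = 20,
    seed: int = 0,
) -> EmpiricalBackground:
    """Score *n* i.i.d. uniform-random sequences of *length* and sort."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=(n, length))
    scores = scorer.score_indices(idx)
    return EmpiricalBackground(
        scorer_name=scorer.name, sorted_scores=np.sort(scores), length=length, seed=seed
    )


def affinity(
    bg: EmpiricalBackground,
    scorer: Scorer,
    seq: Union[Sequence, str, float],
) -> float:
    """Binding affinity: fraction of background scores <= the query score.

    Ties count as satisfied (the >= in the percentile definition), so
    the value is the right-continuous empirical CDF at the query score,
    located by binary search over the sorted background.
    """
    if isinstance(seq, (int, float, np.floating)):
        s = float(seq)
    else:
        if isinstance(seq, Sequence) and len(seq) != bg.length:
            raise ValueError(
                f"sequence length {len(seq)} does not match background length {bg.length}"
            )
        s = scorer.score(seq)
    count = int(np.searchsorted(bg.sorted_scores, s, side="right"))
    return count / bg.n


def _affinity_vector(bg: EmpiricalBackground, scores: np.ndarray) -> np.ndarray:
    return np.searchsorted(bg.sorted_scores, scores, side="right") / bg.n


@dataclass
class EnsembleMember:
    scorer: Scorer
    background: EmpiricalBackground


class ScorerEnsemble:
    """Named scorers with backgrounds; defines the specificity statistic."""

    def __init__(self, members: TypingSequence[EnsembleMember]):
        if not members:
            raise ValueError("ensemble must have at least one member")
        lengths = {m.background.length for m in members}
        if len(lengths) != 1:
            raise ValueError(f"members have mixed background lengths: {sorted(lengths)}")
        names = [m.scorer.name for m in members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scorer names in ensemble")
        self.members = list(members)

    @classmethod
    def build(
        cls,
        scorers: TypingSequence[Scorer],
        background_n: int = 200_000,
        length: int = 20,
        seed: int = 0,
    ) -> "ScorerEnsemble":
        """Construct per-member backgrounds with seeds spawned from *seed*."""
        children = np.random.SeedSequence(seed).generate_state(len(scorers))
        return cls(
            [
                EnsembleMember(s, build_background(s, background_n, length, int(cs % (2**31))))
                for s, cs in zip(scorers, children)
            ]
        )

    def __len__(self) -> int:
        return len(self.members)

    def member(self, name: str) -> EnsembleMember:
        for m in self.members:
            if m.scorer.name == name:
                return m
        raise KeyError(f"no ensemble member named {name!r}")

    def competitors(self, target: Union[str, Scorer]) -> List[EnsembleMember]:
        """Same-experiment members other than the target (the set Mc)."""
        t = self.member(target if isinstance(target, str) else target.name)
        return [
            m
            for m in self.members
            if m.scorer.name != t.scorer.name
            and m.scorer.experiment_type == t.scorer.experiment_type
        ]


def specificity(
    ensemble: ScorerEnsemble,
    target: Union[str, Scorer],
    seq: Union[Sequence, str],
) -> float:
    """AUC-weighted affinity to the target minus the mean AUC-weighted
    affinity to all other same-experiment members.

    Raises ``ValueError`` when the target has no same-experiment
    competitor (the mean over an empty set is undefined).
    """
    t = ensemble.member(target if isinstance(target, str) else target.name)
    comp = ensemble.competitors(t.scorer)
    if not comp:
        raise ValueError(
            f"specificity undefined: no other member shares experiment type "
            f"{t.scorer.experiment_type!r} with {t.scorer.name!r}"
        )
    af_t = affinity(t.background, t.scorer, seq)
    off = [affinity(m.background, m.scorer, seq) * m.scorer.weight for m in comp]
    return af_t * t.scorer.weight - float(np.mean(off))


def score_pool(
    ensemble: ScorerEnsemble,
    target: Union[str, Scorer],
    pool: TypingSequence[Sequence],
) -> pd.DataFrame:
    """Score every pool sequence under every member; add SP for *target*.

    Returns one row per sequence with columns ``id``, ``sequence``, one
    ``AF_<member>`` column per member (deterministic member order), and
    ``SP``.
    """
    if not pool:
        raise ValueError("empty pool")
    t = ensemble.member(target if isinstance(target, str) else target.name)
    comp = ensemble.competitors(t.scorer)
    if not comp:
        raise ValueError(
            f"specificity undefined: no other member shares experiment type "
            f"{t.scorer.experiment_type!r} with {t.scorer.name!r}"
        )
    idx = np.stack([encode_indices(s) for s in pool])
    if idx.shape[1] != t.background.length:
        raise ValueError(
            f"pool sequence length {idx.shape[1]} does not match background "
            f"length {t.background.length}"
        )
    af = {}
    for m in ensemble.members:
        raw = m.scorer.score_indices(idx)
        af[m.scorer.name] = _affinity_vector(m.background, raw)
    comp_names = [m.scorer.name for m in comp]
    comp_weights = np.array([m.scorer.weight for m in comp])
    off = np.stack([af[name] for name in comp_names], axis=1) * comp_weights
    sp = af[t.scorer.name] * t.scorer.weight - off.mean(axis=1)
    data = {"id": [s.id for s in pool], "sequence": [s.residues for s in pool]}
    for m in ensemble.members:
        data[f"AF_{m.scorer.name}"] = af[m.scorer.name]
    data["SP"] = sp
    return pd.DataFrame(data)
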