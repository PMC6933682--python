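"""End-to-end candidate construction: train, select, generate, score, rank.

The pipeline trains the character-level generator on protein-binding
sequences for a fixed number of epochs, keeps the checkpoint with the
lowest validation loss, samples a large pool of sequences from it,
removes duplicates, scores the pool under every ensemble member
(affinity percentiles plus the specificity statistic for the chosen
target), and returns the top-k candidates by specificity.

All randomness derives from one master seed; two runs with the same
configuration produce byte-identical artifact files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence as TypingSequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .binding_score import PWMScorer, Scorer, ScorerEnsemble, score_pool
from .generator_lstm import (
    GeneratorModel,
    TrainConfig,
    TrainingTrace,
    generate_pool,
    select_checkpoint,
    train,
)
from .sequence_io import Alphabet, Sequence, build_streams, read_sequences, write_sequences

__all__ = [
    "PipelineConfig",
    "CandidateSet",
    "load_config",
    "run_pipeline",
    "select_top_k",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    training_path: Union[str, Path]
    target: str
    training_format: str = "plain"
    alphabet: Alphabet = Alphabet.DNA
    seq_len: int = 20
    batch_size: int = 50
    val_frac: float = 0.05
    layers: int = 2
    hidden_size: int = 128
    epochs: int = 50
    pool_size: int = 200_000
    top_k: int = 100
    temperature: float = 1.0
    seed: int = 0
    out_dir: Optional[Union[str, Path]] = None
    train_config: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class CandidateSet:
    """Ranked candidates: descending SP, tie-broken by target AF then
    lexicographic residue order; duplicate residue strings removed."""

    table: pd.DataFrame
    target: str
    k: int

    @property
    def af_column(self) -> str:
        return f"AF_{self.target}"

    @property
    def sequences(self) -> List[str]:
        return list(self.table["sequence"])

    def __len__(self) -> int:
        return len(self.table)


def select_top_k(scored: pd.DataFrame, k: int, target: str) -> CandidateSet:
    """Top-k rows by specificity with a fully deterministic order.

    Duplicate residue strings are collapsed (first occurrence kept —
    scoring is deterministic, so duplicates carry identical scores);
    ties in SP break by higher target AF, then lexicographic sequence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if scored.empty:
        raise ValueError("empty score table")
    af_col = f"AF_{target}"
    if af_col not in scored.columns or "SP" not in scored.columns:
        raise ValueError(f"score table lacks {af_col!r} or 'SP' columns")
    dedup = scored.drop_duplicates(subset="sequence", keep="first")
    ranked = dedup.sort_values(
        by=["SP", af_col, "sequence"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if len(ranked) < k:
        logger.warning(
            "only %d distinct sequences available for top_k=%d", len(ranked), k
        )
    return CandidateSet(table=ranked.head(k).copy(), target=target, k=k)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    ensemble: ScorerEnsemble,
    training_seqs: Optional[TypingSequence[Sequence]] = None,
) -> CandidateSet:
    """Execute the full pipeline; every stage failure names its stage.

    ``training_seqs`` bypasses file reading (for programmatic use); the
    target scorer must be an ensemble member.  Artifacts written to
    ``config.out_dir`` (trace, checkpoint, pool, score table,
    candidates) are sufficient to re-score and reproduce the candidate
    set.
    """
    ensemble.member(config.target)  # raises KeyError if absent

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    if training_seqs is None:
        training_seqs = stage("read")(
            read_sequences, config.training_path, config.training_format, config.alphabet
        )
    chunks = stage("stream")(
        build_streams, training_seqs, config.batch_size, config.seq_len, config.val_frac
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    model_seed, train_seed, pool_seed = (int(s) for s in seeds)
    model = GeneratorModel(
        layers=config.layers,
        hidden_size=config.hidden_size,
        alphabet=config.alphabet,
        seq_len=config.seq_len,
        seed=model_seed,
    )
    trace = stage("train")(
        train,
        model,
        chunks,
        config.epochs,
        config.train_config,
        training_seqs,
        train_seed,
    )
    best = stage("select_checkpoint")(select_checkpoint, trace)
    pool = stage("generate")(
        generate_pool,
        best,
        config.pool_size,
        pool_seed,
        config.seq_len,
        config.temperature,
    )
    seen = set()
    unique_pool = []
    for s in pool:
        if s.residues not in seen:
            seen.add(s.residues)
            unique_pool.append(s)
    if not unique_pool:
        raise RuntimeError("pipeline stage 'dedupe' failed: empty post-dedup pool")
    logger.info(
        "pool: %d generated, %d distinct (%.1f%% duplicated)",
        len(pool),
        len(unique_pool),
        100.0 * (1 - len(unique_pool) / len(pool)),
    )
    scored = stage("score")(score_pool, ensemble, config.target, unique_pool)
    candidates = stage("rank")(select_top_k, scored, config.top_k, config.target)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(trace.to_frame(), out / "trace.tsv")
        best.save(out / "checkpoint_best.npz")
        write_sequences(pool, out / "pool.txt", fmt="plain")
        _write_tsv(scored, out / "scores.tsv")
        _write_tsv(candidates.table, out / "candidates.tsv")
        write_sequences(
            [
                Sequence(f"cand_{i}_SP={row.SP:.6g}", row.sequence, config.alphabet)
                for i, row in enumerate(candidates.table.itertuples(), start=1)
            ],
            out / "candidates.fasta",
            fmt="fasta",
        )
    return candidates


# ----------------------------------------------------------------------
# YAML configuration (CLI entry)


def load_config(path: Union[str, Path]) -> Tuple[PipelineConfig, ScorerEnsemble]:
    """Load a pipeline config plus scorer ensemble from one YAML file.

    Scorer PWMs are JASPAR-style count files resolved relative to the
    YAML file's directory; ``background_n`` controls the size of each
    member's empirical background.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    scorers: List[Scorer] = []
    for entry in raw.get("scorers", []):
        pwm = PWMScorer.from_jaspar(
            base / entry["pwm"],
            name=entry.get("name"),
            experiment_type=entry.get("experiment_type", "SELEX"),
            auc=entry.get("auc"),
        )
        scorers.append(pwm)
    if not scorers:
        raise ValueError(f"{path}: no scorers defined")
    seed = int(raw.get("seed", 0))
    ensemble = ScorerEnsemble.build(
        scorers,
        background_n=int(raw.get("background_n", 200_000)),
        length=int(raw.get("seq_len", 20)),
        seed=seed,
    )
    tc_kwargs = {
        k: raw[k]
        for k in ("learning_rate", "decay", "epsilon", "clip_norm", "iu_probe_size")
        if k in raw
    }
    config = PipelineConfig(
        training_path=base / raw["training"],
        target=raw["target"],
        training_format=raw.get("format", "plain"),
        alphabet=Alphabet(raw.get("alphabet", "DNA")),
        seq_len=int(raw.get("seq_len", 20)),
        batch_size=int(raw.get("batch_size", 50)),
        val_frac=float(raw.get("val_frac", 0.05)),
        layers=int(raw.get("layers", 2)),
        hidden_size=int(raw.get("hidden_size", 128)),
        epochs=int(raw.get("epochs", 50)),
        pool_size=int(raw.get("pool_size", 200_000)),
        top_k=int(raw.get("top_k", 100)),
        temperature=float(raw.get("temperature", 1.0)),
        seed=seed,
        out_dir=raw.get("out_dir"),
        train_config=TrainConfig(**tc_kwargs),
    )
    return config, ensemble
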