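"""Synthetic labelled sequence datasets with controllable class separation.

The generator emulates the compositional contrast between an
aromatase-like positive family and a background negative family: positives
are drawn residue-i.i.d. from a weight profile enriched in leucine (x2) and
in F, P, S, V (x1.5) and depleted in C and W (x0.3), negatives from a
uniform background. Matching position-specific scoring matrix fixtures can
be written so the PSSM pipeline is testable without running any profile
search. Sequences have no positional structure - this exercises
composition-based encoders, not real protein grammar.

All randomness flows from a single integer seed; each operation uses its
own documented generator stream so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import PSSMProfile, write_pssm
from .io_seq import STANDARD_RESIDUES, Dataset, ProteinRecord

#: PSI-BLAST's ASCII PSSM column order
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: default positive-class weight multipliers (background weight 1.0)
DEFAULT_POS_BIAS = {
    "L": 2.0, "F": 1.5, "P": 1.5, "S": 1.5, "V": 1.5, "C": 0.3, "W": 0.3,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic two-class dataset."""

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (150, 500)
    pos_bias: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_POS_BIAS))
    neg_bias: Mapping[str, float] = field(default_factory=dict)
    mutation_rate: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("n_pos and n_neg must be positive")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        for bias in (self.pos_bias, self.neg_bias):
            for aa, w in bias.items():
                if aa not in STANDARD_RESIDUES:
                    raise ValueError(f"bias on non-standard residue {aa!r}")
                if w <= 0:
                    raise ValueError(f"bias weight for {aa!r} must be > 0")
        if not 0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5)")


def _profile(bias: Mapping[str, float]) -> np.ndarray:
    weights = np.array([bias.get(aa, 1.0) for aa in STANDARD_RESIDUES])
    return weights / weights.sum()


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(STANDARD_RESIDUES[i] for i in idx)


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, pd.DataFrame]:
    """Draw a labelled two-class dataset and a truth log.

    Positives get ids ``pos0001``..., label +1; negatives ``neg0001``...,
    label -1. Lengths are uniform over ``length_range``. The truth log
    records the exact per-residue generating probabilities of each class.
    """
    rng = np.random.default_rng([config.seed, 0])
    pos_probs = _profile(config.pos_bias)
    neg_probs = _profile(config.neg_bias)
    records = []
    lo, hi = config.length_range
    for i in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        records.append(ProteinRecord(
            id=f"pos{i + 1:04d}",
            description="synthetic positive (aromatase-like composition)",
            sequence=_draw_sequence(rng, length, pos_probs),
            label=1,
        ))
    for i in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        records.append(ProteinRecord(
            id=f"neg{i + 1:04d}",
            description="synthetic negative (background composition)",
            sequence=_draw_sequence(rng, length, neg_probs),
            label=-1,
        ))
    truth = pd.DataFrame({
        "residue": list(STANDARD_RESIDUES),
        "positive_prob": pos_probs,
        "negative_prob": neg_probs,
    })
    dataset = Dataset(
        records=records,
        provenance=(
            f"synthetic seed={config.seed} n_pos={config.n_pos} "
            f"n_neg={config.n_neg} lengths={config.length_range}"
        ),
    )
    return dataset, truth


def generate_redundant_pairs(
    dataset: Dataset,
    n_pairs: int,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> Dataset:
    """Append near-duplicate copies of randomly chosen records.

    Each copy substitutes residues independently with probability
    ``mutation_rate`` (substitutions drawn uniformly from the other 19
    residues) and carries the source id suffixed ``_dup``. At rates <= 0.05
    the expected identity to the source exceeds 90%, so the copies are
    exactly what redundancy reduction at 0.90 should remove.
    """
    if not 0 <= mutation_rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5)")
    if n_pairs > len(dataset):
        raise ValueError(f"n_pairs={n_pairs} exceeds dataset size {len(dataset)}")
    rng = np.random.default_rng([seed, 1])
    chosen = rng.choice(len(dataset), size=n_pairs, replace=False)
    new_records = list(dataset.records)
    for i in sorted(int(c) for c in chosen):
        src = dataset[i]
        seq = list(src.sequence)
        for p in range(len(seq)):
            if rng.random() < mutation_rate:
                alternatives = STANDARD_RESIDUES.replace(seq[p], "")
                seq[p] = alternatives[int(rng.integers(len(alternatives)))]
        new_records.append(replace(src, id=f"{src.id}_dup", sequence="".join(seq)))
    return Dataset(records=new_records, provenance=f"{dataset.provenance}; +{n_pairs} dups")


def generate_pssm_fixtures(
    dataset: Dataset,
    out_dir: str | Path,
    seed: int = 0,
) -> Path:
    """Write one synthetic ASCII-PSSM file per record into ``out_dir``.

    At each position the column of the actual sequence residue receives a
    high integer score (4..9) and every other column a low one (-4..2), so
    the profile carries the same class-correlated compositional signal as
    the sequence itself. Files are named ``<record id>.pssm`` and parse
    with the package's PSSM reader.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 2])
    col_of = {aa: i for i, aa in enumerate(PSIBLAST_COLUMN_ORDER)}
    for rec in dataset:
        L = len(rec.sequence)
        matrix = rng.integers(-4, 3, size=(L, 20)).astype(float)
        high = rng.integers(4, 10, size=L)
        for p, aa in enumerate(rec.sequence):
            matrix[p, col_of[aa]] = high[p]
        profile = PSSMProfile(rec.sequence, matrix, PSIBLAST_COLUMN_ORDER)
        write_pssm(profile, out_dir / f"{rec.id}.pssm")
    return out_dir
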