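"""Fixed-length feature encodings of protein sequences.

Four schemes:

* AAC — amino-acid composition, 20 residue frequencies.
* DPC — dipeptide composition, 400 overlapping-pair frequencies.
* HYBRID — AAC concatenated with DPC, 420 values.
* PSSM — 400-dimensional composition of a normalized position-specific
  scoring matrix, aggregated over (sequence residue, profile column) pairs.

AAC values are counts / L (so they sum to 1); DPC values are counts / (L-1).
PSSM profiles are min-max normalized per matrix to [0, 1] before
composition. Residue order everywhere is alphabetical one-letter
(A, C, D, ..., Y); PSSM file column order is preserved on parse and mapped
to the canonical order at composition time.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_seq import STANDARD_RESIDUES, Dataset, ProteinRecord

#: canonical residue -> index 0..19
RESIDUE_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}

#: all 400 dipeptides in canonical (first, second) order
DIPEPTIDES = [a + b for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES]


class Scheme(str, Enum):
    AAC = "aac"
    DPC = "dpc"
    HYBRID = "hybrid"
    PSSM = "pssm"

    @property
    def dimension(self) -> int:
        return {"aac": 20, "dpc": 400, "hybrid": 420, "pssm": 400}[self.value]


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length numeric encoding of one sequence under one scheme."""

    scheme: Scheme
    values: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.shape[0] != self.scheme.dimension:
            raise ValueError(
                f"{self.scheme.value} vector must have length "
                f"{self.scheme.dimension}, got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PSSMProfile:
    """Per-sequence position-specific scoring matrix (L x 20 log-odds scores).

    ``residue_order`` is the 20-letter column order as read from the source
    file (PSI-BLAST writes A R N D C Q E G H I L K M F P S T W Y V).
    """

    sequence: str
    matrix: np.ndarray
    residue_order: str

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape != (len(self.sequence), 20):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"(sequence length {len(self.sequence)}, 20)"
            )
        if len(self.residue_order) != 20 or len(set(self.residue_order)) != 20:
            raise ValueError("residue_order must contain 20 distinct letters")
        if set(self.residue_order) != set(STANDARD_RESIDUES):
            raise ValueError("residue_order must cover the 20 standard residues")
        object.__setattr__(self, "matrix", matrix)

    @property
    def length(self) -> int:
        return len(self.sequence)


def aac(record: ProteinRecord) -> FeatureVector:
    """Amino-acid composition: 20 residue frequencies, summing to 1."""
    seq = record.sequence
    if not seq:
        raise ValueError(f"record {record.id!r}: empty sequence")
    counts = np.zeros(20)
    for ch in seq:
        counts[RESIDUE_INDEX[ch]] += 1
    return FeatureVector(Scheme.AAC, counts / len(seq), record.id)


def dpc(record: ProteinRecord) -> FeatureVector:
    """Dipeptide composition: 400 overlapping-pair frequencies, summing to 1.

    The denominator is the number of overlapping dipeptides in the
    sequence (L - 1), making the vector a frequency distribution.
    """
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(f"record {record.id!r}: need length >= 2 for dipeptides")
    counts = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        counts[RESIDUE_INDEX[a] * 20 + RESIDUE_INDEX[b]] += 1
    return FeatureVector(Scheme.DPC, counts / (len(seq) - 1), record.id)


def hybrid(record: ProteinRecord) -> FeatureVector:
    """AAC followed by DPC: a 420-dimensional vector."""
    values = np.concatenate([aac(record).values, dpc(record).values])
    return FeatureVector(Scheme.HYBRID, values, record.id)


def parse_pssm(path: str | Path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` dialect).

    Only the first 20-column log-odds block is read; the weighted-percentage
    block, information content and trailing statistics are ignored.
    """
    path = Path(path)
    residue_order: str | None = None
    sequence: list[str] = []
    rows: list[list[int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if residue_order is None:
                # the column header line: at least 20 single-letter tokens
                letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
                if len(letters) >= 20:
                    residue_order = "".join(letters[:20])
                continue
            if len(tokens) < 2 or not tokens[0].isdigit():
                if rows:
                    break  # footer reached
                continue
            if len(tokens) < 22:
                raise ValueError(
                    f"{path}:{lineno}: truncated row ({len(tokens) - 2} scores, need 20)"
                )
            residue = tokens[1]
            try:
                scores = [int(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer score cell") from exc
            sequence.append(residue)
            rows.append(scores)
    if residue_order is None:
        raise ValueError(f"{path}: no PSSM column header found")
    if not rows:
        raise ValueError(f"{path}: no score rows found")
    return PSSMProfile("".join(sequence), np.array(rows, dtype=float), residue_order)


def write_pssm(profile: PSSMProfile, path: str | Path) -> Path:
    """Write a PSSMProfile in the ASCII PSSM dialect that :func:`parse_pssm` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(profile.residue_order) + "\n")
        for i, (res, row) in enumerate(zip(profile.sequence, profile.matrix), start=1):
            cells = " ".join(f"{int(v):4d}" for v in row)
            fh.write(f"{i:5d} {res} {cells}\n")
        fh.write("\n")
    return path


def normalize_pssm(profile: PSSMProfile) -> PSSMProfile:
    """Min-max normalize all cells of a profile to [0, 1].

    min and max are taken over the whole L x 20 matrix; a constant matrix
    maps to all zeros.
    """
    m = profile.matrix
    lo, hi = m.min(), m.max()
    if hi == lo:
        scaled = np.zeros_like(m)
    else:
        scaled = (m - lo) / (hi - lo)
    return PSSMProfile(profile.sequence, scaled, profile.residue_order)


def pssm_composition(profile: PSSMProfile) -> FeatureVector:
    """400-dimensional composition of a normalized PSSM.

    Component (i, j) sums the normalized score in column j over all
    positions whose sequence residue is i, divided by the sequence length L.
    Residues absent from the sequence contribute zero rows. Requires a
    profile already normalized to [0, 1].
    """
    m = profile.matrix
    if m.min() < 0 or m.max() > 1:
        raise ValueError("profile must be normalized to [0, 1] first")
    L = profile.length
    # map file column order -> canonical column order
    col_map = np.array([RESIDUE_INDEX[aa] for aa in profile.residue_order])
    out = np.zeros((20, 20))
    for res, row in zip(profile.sequence, m):
        canonical = np.zeros(20)
        canonical[col_map] = row
        out[RESIDUE_INDEX[res]] += canonical
    return FeatureVector(Scheme.PSSM, out.ravel() / L, "")


def pssm_vector(profile: PSSMProfile, source_id: str) -> FeatureVector:
    """pssm_composition with an explicit source id attached."""
    vec = pssm_composition(profile)
    return FeatureVector(Scheme.PSSM, vec.values, source_id)


def encode_dataset(
    dataset: Dataset,
    scheme: Scheme | str,
    pssm_dir: str | Path | None = None,
) -> list[FeatureVector]:
    """Encode every record of a dataset under one scheme, order preserved.

    For the PSSM scheme, ``pssm_dir`` must contain ``<record id>.pssm``
    files; a missing file raises with all missing ids listed.
    """
    scheme = Scheme(scheme)
    if scheme is not Scheme.PSSM:
        encoder = {Scheme.AAC: aac, Scheme.DPC: dpc, Scheme.HYBRID: hybrid}[scheme]
        return [encoder(rec) for rec in dataset]
    if pssm_dir is None:
        raise ValueError("scheme=pssm requires pssm_dir")
    pssm_dir = Path(pssm_dir)
    missing = [rec.id for rec in dataset if not (pssm_dir / f"{rec.id}.pssm").exists()]
    if missing:
        raise FileNotFoundError(f"missing PSSM files for ids: {', '.join(missing)}")
    out = []
    for rec in dataset:
        profile = normalize_pssm(parse_pssm(pssm_dir / f"{rec.id}.pssm"))
        out.append(pssm_vector(profile, rec.id))
    return out


def feature_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Stack FeatureVectors into an (n, d) array, checking scheme consistency."""
    if not vectors:
        raise ValueError("no vectors to stack")
    scheme = vectors[0].scheme
    if any(v.scheme is not scheme for v in vectors):
        raise ValueError("vectors mix feature schemes")
    return np.vstack([v.values for v in vectors])
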