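"""Sequence I/O, dataset curation and SVM-light interchange.

Curation mirrors the construction of a high-quality positive set for a
binary protein classifier: drop entries whose descriptions carry
unreliable-annotation keywords (fragment, isoform, potential, similarity,
probable), then remove redundancy by greedy clustering at a pairwise
global-identity threshold (a deterministic stand-in for CD-HIT at 90%).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Annotation keywords whose presence marks a record as unreliable.
DEFAULT_FILTER_KEYWORDS = ("fragment", "isoform", "potential", "similarity", "probable")

_NONSTANDARD = re.compile(f"[^{STANDARD_RESIDUES}]")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty file, sequence-less header, duplicate id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    The sequence is uppercase and restricted to the 20 standard residues;
    anything else (B, J, O, U, X, Z, gaps) is stripped at construction with
    a logged warning, so composition denominators always refer to standard
    residues only.
    """

    id: str
    description: str = ""
    sequence: str = ""
    label: int | None = None  # +1 / -1 for labelled data

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.label not in (None, 1, -1):
            raise ValueError(f"label must be +1/-1/None, got {self.label!r}")
        seq = self.sequence.upper()
        cleaned = _NONSTANDARD.sub("", seq)
        if cleaned != seq:
            logger.warning(
                "record %s: removed %d non-standard residue(s)",
                self.id,
                len(seq) - len(cleaned),
            )
        object.__setattr__(self, "sequence", cleaned)
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence after validation")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """Ordered collection of ProteinRecords with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[int]:
        """Labels of all records; raises if any record is unlabelled."""
        out = []
        for r in self.records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} has no label")
            out.append(r.label)
        return out


def read_fasta(path: str | Path) -> Dataset:
    """Read a multi-record FASTA file into a Dataset.

    The header token before the first whitespace becomes the id, the
    remainder the description. Sequences are uppercased and cleaned of
    non-standard residues. Wrapped and unwrapped sequence lines are both
    accepted.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise FastaParseError(f"{path}: record {entry.id!r} has no sequence")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        desc = entry.description
        # SeqIO keeps the full header in .description; strip the leading id token
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(ProteinRecord(id=entry.id, description=desc, sequence=seq))
    if not records:
        raise FastaParseError(f"{path}: no records found")
    return Dataset(records=records, provenance=f"read_fasta({path})")


def write_fasta(dataset: Dataset, path: str | Path, width: int = 60) -> Path:
    """Write a Dataset as FASTA with 60-column sequence wrapping.

    Round-trips through :func:`read_fasta` (ids, descriptions, sequences).
    """
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    path = Path(path)
    with path.open("w") as fh:
        for rec in dataset:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
    return path


def filter_annotations(
    dataset: Dataset,
    keywords: Sequence[str] = DEFAULT_FILTER_KEYWORDS,
) -> Dataset:
    """Drop records whose description contains any filter keyword.

    Matching is case-insensitive substring on the description only, so the
    singular keywords also catch plural forms ("fragments", "isoforms").
    Input order is preserved; an empty result is legal.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    lowered = [k.lower() for k in keywords]
    kept = [
        rec for rec in dataset
        if not any(k in rec.description.lower() for k in lowered)
    ]
    return Dataset(
        records=kept,
        provenance=f"{dataset.provenance}; filter_annotations({list(keywords)})",
    )


def _global_aligner() -> PairwiseAligner:
    # match +1, mismatch 0, gaps ~0: the score is the number of identical
    # aligned positions; the infinitesimal gap penalty only breaks ties so
    # that, among max-match alignments, the one with fewest gap columns is
    # returned and the alignment length is well defined
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1e-6
    aligner.extend_gap_score = -1e-6
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity between two sequences.

    Identity = identical aligned positions / alignment length, under a
    match-maximising global alignment (match +1, mismatch 0, gap 0).
    """
    aligner = _global_aligner()
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    matches = best.counts().identities
    aln_len = best.length
    return matches / aln_len if aln_len else 0.0


def reduce_redundancy(dataset: Dataset, identity_threshold: float = 0.90) -> Dataset:
    """Greedy longest-first redundancy reduction (CD-HIT stand-in).

    Records are visited longest first (ties broken by id); a record is kept
    iff its global identity to every already-kept record is at or below the
    threshold. Output preserves the original dataset order.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    order = sorted(dataset, key=lambda r: (-len(r.sequence), r.id))
    kept: list[ProteinRecord] = []
    for rec in order:
        if all(pairwise_identity(rec.sequence, k.sequence) <= identity_threshold for k in kept):
            kept.append(rec)
    kept_ids = {r.id for r in kept}
    return Dataset(
        records=[r for r in dataset if r.id in kept_ids],
        provenance=f"{dataset.provenance}; reduce_redundancy({identity_threshold})",
    )


def write_svmlight(
    vectors: Iterable,
    labels: Sequence[int],
    path: str | Path,
) -> Path:
    """Write labelled feature vectors in SVM-light sparse format.

    One line per vector: ``<label> <index>:<value> ...`` with 1-based
    ascending indices, zero components omitted, values at 6 significant
    digits. ``vectors`` may be FeatureVectors or plain numeric sequences.
    """
    vectors = list(vectors)
    labels = list(labels)
    if len(vectors) != len(labels):
        raise ValueError(f"{len(vectors)} vectors but {len(labels)} labels")
    rows = [getattr(v, "values", v) for v in vectors]
    if rows:
        dim = len(rows[0])
        for i, row in enumerate(rows):
            if len(row) != dim:
                raise ValueError(f"vector {i} has dimension {len(row)}, expected {dim}")
    path = Path(path)
    with path.open("w") as fh:
        for label, row in zip(labels, rows):
            parts = [f"{label:+d}"]
            for j, v in enumerate(row, start=1):
                if v != 0:
                    parts.append(f"{j}:{v:.6g}")
            fh.write(" ".join(parts) + "\n")
    return path


def read_svmlight(path: str | Path, dimension: int) -> tuple[list[list[float]], list[int]]:
    """Read an SVM-light file back into dense rows and labels (inverse of the writer)."""
    rows: list[list[float]] = []
    labels: list[int] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                label = int(tokens[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad label {tokens[0]!r}") from exc
            row = [0.0] * dimension
            for tok in tokens[1:]:
                idx_s, _, val_s = tok.partition(":")
                idx = int(idx_s)
                if not 1 <= idx <= dimension:
                    raise ValueError(f"{path}:{lineno}: index {idx} out of range 1..{dimension}")
                row[idx - 1] = float(val_s)
            labels.append(label)
            rows.append(row)
    return rows, labels


def to_seqrecords(dataset: Dataset) -> list[SeqRecord]:
    """Convert a Dataset to Biopython SeqRecords (interop helper)."""
    return [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in dataset
    ]


def with_labels(dataset: Dataset, label: int) -> Dataset:
    """Return a copy of the dataset with every record assigned one class label."""
    return Dataset(
        records=[replace(r, label=label) for r in dataset],
        provenance=dataset.provenance,
    )
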