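"""Peptide dataset I/O, validation, merging, fold assignment and length strata.

Datasets are ordered collections of :class:`PeptideRecord` held in a
:class:`DatasetManifest`.  Sequences are restricted to the 20 standard
one-letter amino-acid codes and lengths 2-50 (the model's fixed context);
anything else is rejected at validation time with the offending record ids,
never silently dropped.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
MIN_LENGTH = 2
MAX_LENGTH = 50


class PeptideValidationError(ValueError):
    """Raised when one or more records fail sequence validation."""

    def __init__(self, message: str, bad_ids: Sequence[str] = ()):
        super().__init__(message)
        self.bad_ids = list(bad_ids)


class FastaParseError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: id, validated sequence, optional binary label and source."""

    id: str
    sequence: str
    label: int | None = None
    source: str | None = None


@dataclass
class DatasetManifest:
    """Ordered peptide collection with positive/negative bookkeeping."""

    records: list[PeptideRecord]
    name: str = "dataset"

    @property
    def counts(self) -> tuple[int, int]:
        n_pos = sum(1 for r in self.records if r.label == 1)
        n_neg = sum(1 for r in self.records if r.label == 0)
        return n_pos, n_neg

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def subset(self, indices: Iterable[int], name: str | None = None) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices],
                               name=name or self.name)


@dataclass
class FoldSplit:
    """Stratified fold assignment: ``assignments[i]`` is record i's fold."""

    k: int
    assignments: np.ndarray

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_sequence(seq: str, truncate: bool = False) -> str:
    """Upper-case, check alphabet and length; returns the validated sequence."""
    seq = seq.strip().upper()
    bad = sorted(set(seq) - _AA_SET)
    if bad:
        raise PeptideValidationError(
            f"non-standard residue(s) {''.join(bad)!r} in sequence {seq!r}")
    if len(seq) > MAX_LENGTH:
        if truncate:
            warnings.warn(f"sequence of length {len(seq)} truncated to {MAX_LENGTH}")
            seq = seq[:MAX_LENGTH]
        else:
            raise PeptideValidationError(
                f"sequence of length {len(seq)} exceeds maximum {MAX_LENGTH}")
    if len(seq) < MIN_LENGTH:
        raise PeptideValidationError(
            f"sequence {seq!r} shorter than minimum length {MIN_LENGTH}")
    return seq


def validate_records(records: Sequence[PeptideRecord],
                     truncate: bool = False) -> list[PeptideRecord]:
    """Validate every record; raises one error listing all offending ids."""
    ok: list[PeptideRecord] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            ok.append(replace(rec, sequence=validate_sequence(rec.sequence,
                                                              truncate=truncate)))
        except PeptideValidationError as err:
            failures.append((rec.id, str(err)))
    if failures:
        detail = "; ".join(f"{rid}: {msg}" for rid, msg in failures)
        raise PeptideValidationError(
            f"{len(failures)} record(s) failed validation: {detail}",
            bad_ids=[rid for rid, _ in failures])
    return ok


def _parse_label(raw: str) -> int:
    if raw not in ("0", "1"):
        raise PeptideValidationError(f"labels must be 0 or 1, got {raw!r}")
    return int(raw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path, label_field: str | None = "label",
               truncate: bool = False, name: str | None = None) -> DatasetManifest:
    """Read a FASTA file; labels come from a ``label=0|1`` token in the header."""
    path = Path(path)
    records: list[PeptideRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip() and not line.startswith(">"):
                raise FastaParseError(
                    f"malformed FASTA {path}: line {lineno} is not a header")
            break
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as err:
        raise FastaParseError(f"malformed FASTA {path}: {err}") from err
    for entry in entries:
        label = None
        if label_field:
            for token in entry.description.split():
                if token.startswith(f"{label_field}="):
                    label = _parse_label(token.split("=", 1)[1])
        records.append(PeptideRecord(id=entry.id, sequence=str(entry.seq),
                                     label=label, source=name or path.stem))
    return DatasetManifest(validate_records(records, truncate=truncate),
                           name=name or path.stem)


def read_table(path, seq_col: str = "sequence", label_col: str | None = "label",
               id_col: str | None = "id", truncate: bool = False,
               name: str | None = None) -> DatasetManifest:
    """Read a delimited table (delimiter sniffed from the header row)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return DatasetManifest([], name=name or path.stem)
    header_line = text.splitlines()[0]
    try:
        dialect = csv.Sniffer().sniff(header_line, delimiters=",;\t")
        delim = dialect.delimiter
    except csv.Error:
        delim = ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    cols = reader.fieldnames or []
    if seq_col not in cols:
        raise ConfigurationError(f"column {seq_col!r} not in {path} (has {cols})")
    if label_col is not None and label_col not in cols:
        raise ConfigurationError(f"column {label_col!r} not in {path} (has {cols})")
    use_id = id_col if id_col in cols else None
    records = []
    for i, row in enumerate(reader):
        label = _parse_label(row[label_col]) if label_col else None
        rid = row[use_id] if use_id else str(i)
        src = row.get("source") or name or path.stem
        records.append(PeptideRecord(id=rid, sequence=row[seq_col],
                                     label=label, source=src))
    return DatasetManifest(validate_records(records, truncate=truncate),
                           name=name or path.stem)


def write_csv(manifest: DatasetManifest, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "sequence", "label", "source"])
        for rec in manifest.records:
            writer.writerow([rec.id, rec.sequence,
                             "" if rec.label is None else rec.label,
                             rec.source or ""])


def write_fasta(manifest: DatasetManifest, path) -> None:
    with open(path, "w") as handle:
        for rec in manifest.records:
            label = "" if rec.label is None else f" label={rec.label}"
            handle.write(f">{rec.id}{label}\n{rec.sequence}\n")


def read_manifest_csv(path, name: str | None = None) -> DatasetManifest:
    """Read a manifest previously written by :func:`write_csv`."""
    path = Path(path)
    records = []
    with open(path) as handle:
        for row in csv.DictReader(handle):
            label = _parse_label(row["label"]) if row.get("label") else None
            records.append(PeptideRecord(id=row["id"], sequence=row["sequence"],
                                         label=label,
                                         source=row.get("source") or None))
    return DatasetManifest(validate_records(records), name=name or path.stem)


# ---------------------------------------------------------------------------
# merging, folds, strata
# ---------------------------------------------------------------------------

def merge_datasets(manifests: Sequence[DatasetManifest], deduplicate: bool = False,
                   drop_conflicts: bool = False,
                   name: str = "merged") -> DatasetManifest:
    """Concatenate datasets; optionally collapse duplicate sequences.

    Under deduplication the first occurrence of a sequence wins; duplicates
    carrying a different label trigger a warning (and are dropped entirely
    when ``drop_conflicts`` is set).
    """
    if not manifests:
        raise ConfigurationError("merge_datasets requires at least one manifest")
    merged: list[PeptideRecord] = []
    seen: dict[str, int] = {}
    conflicts: set[str] = set()
    counter = 0
    for man in manifests:
        for rec in man.records:
            counter += 1
            rec = replace(rec, id=f"{man.name}:{rec.id}",
                          source=rec.source or man.name)
            if not deduplicate:
                merged.append(rec)
                continue
            if rec.sequence in seen:
                first = merged[seen[rec.sequence]]
                if first is not None and first.label != rec.label:
                    conflicts.add(rec.sequence)
                continue
            seen[rec.sequence] = len(merged)
            merged.append(rec)
    if conflicts:
        warnings.warn("conflicting labels for duplicated sequence(s): "
                      + ", ".join(sorted(conflicts)))
        if drop_conflicts:
            merged = [r for r in merged if r.sequence not in conflicts]
    return DatasetManifest(merged, name=name)


def make_folds(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k-fold assignment: shuffle within each class, deal round-robin.

    Guarantees fold sizes within 1 of each other and per-fold class balance
    within 1 record of the global fraction, deterministically for a seed.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    n = len(manifest)
    if k > n:
        raise ConfigurationError(f"k={k} exceeds number of records ({n})")
    labels = manifest.labels()
    if any(lab is None for lab in labels):
        raise ConfigurationError("make_folds requires a fully labeled manifest")
    rng = np.random.Generator(np.random.PCG64(seed))
    assignments = np.empty(n, dtype=int)
    offset = 0
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, record_index in enumerate(idx):
            assignments[record_index] = (j + offset) % k
        offset += len(idx)  # continue dealing where the previous class stopped
    return FoldSplit(k=k, assignments=assignments)


def split_by_length(manifest: DatasetManifest,
                    threshold: int = 15) -> tuple[DatasetManifest, DatasetManifest]:
    """Short stratum: length < threshold; long stratum: length >= threshold."""
    if threshold < 1:
        raise ConfigurationError("threshold must be >= 1")
    short = [i for i, r in enumerate(manifest.records) if len(r.sequence) < threshold]
    long_ = [i for i, r in enumerate(manifest.records) if len(r.sequence) >= threshold]
    return (manifest.subset(short, name=f"{manifest.name}_short"),
            manifest.subset(long_, name=f"{manifest.name}_long"))


# ---------------------------------------------------------------------------
# sequence identity
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(a: str, b: str) -> float:
    """Percent identity over the columns of the best-scoring global alignment."""
    aligner = _aligner()
    alignment = next(iter(aligner.align(a, b)))
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def pairwise_identity(query: DatasetManifest,
                      reference: DatasetManifest) -> tuple[np.ndarray, float]:
    """Per-query maximum identity (%) against a reference set, plus the mean."""
    if not len(query) or not len(reference):
        raise ConfigurationError("pairwise_identity requires non-empty manifests")
    ref_seqs = reference.sequences()
    best = np.array([max(alignment_identity(q, r) for r in ref_seqs)
                     for q in query.sequences()])
    return best, float(best.mean())
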