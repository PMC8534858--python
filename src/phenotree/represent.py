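"""Bag-of-words patient representation and stratified data splits.

Each patient is treated as a document over clinical codes: the order and
timing of events is discarded and only per-code occurrence counts are kept.
The result is a sparse patients-by-codes count matrix with an aligned binary
label vector. Cohorts are divided into train/validation/test parts with
per-class (stratified) proportions, since positive prevalence in these
cohorts is typically a few percent.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import (
    ConfigurationError,
    EmptyInputError,
    IntegrityError,
    StratificationError,
    UnknownCodeError,
)
from .io import EventTable, LabelTable

PARTS = ("train", "validation", "test")


@dataclasses.dataclass
class Vocabulary:
    """Ordered set of distinct clinical codes defining matrix columns."""

    codes: list[str]
    index: dict[str, int] = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.index = {c: j for j, c in enumerate(self.codes)}
        if len(self.index) != len(self.codes):
            raise IntegrityError("vocabulary codes are not unique")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.index


def build_vocabulary(events: EventTable) -> Vocabulary:
    """Collect the distinct codes of an event table, lexicographically ordered.

    Lexicographic order makes the matrix layout (and every downstream
    tie-break) independent of event-row order.
    """
    if len(events) == 0:
        raise EmptyInputError("cannot build a vocabulary from an empty event table")
    return Vocabulary(sorted(set(events.codes)))


@dataclasses.dataclass
class PatientTermMatrix:
    """Sparse patients x codes count matrix with aligned binary labels.

    ``counts[i, j]`` is the number of event rows for patient ``i`` carrying
    code ``j``. Patients with a label but no events are legitimate all-zero
    rows (no recorded code).
    """

    patients: list[str]
    counts: sp.csr_matrix
    vocab: Vocabulary
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n, k = self.counts.shape
        if len(self.patients) != n or len(self.labels) != n:
            raise IntegrityError("patients, counts and labels are misaligned")
        if k != len(self.vocab):
            raise IntegrityError("matrix width does not match vocabulary size")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_patients(self) -> int:
        return self.counts.shape[0]

    def row_of(self, patient_id: str) -> int:
        try:
            return self.patients.index(patient_id)
        except ValueError:
            raise KeyError(patient_id)

    def subset(self, patient_ids: Iterable[str]) -> "PatientTermMatrix":
        """Row-restricted view for a set of patients (matrix order kept)."""
        wanted = set(patient_ids)
        rows = [i for i, p in enumerate(self.patients) if p in wanted]
        return PatientTermMatrix(
            patients=[self.patients[i] for i in rows],
            counts=self.counts[rows],
            vocab=self.vocab,
            labels=self.labels[rows],
        )

    def dense_columns(self, codes: Sequence[str]) -> np.ndarray:
        """Dense (n_patients, len(codes)) count array; unknown codes raise."""
        cols = []
        for c in codes:
            if c not in self.vocab:
                raise UnknownCodeError(c)
            cols.append(self.vocab.index[c])
        if not cols:
            return np.zeros((self.n_patients, 0))
        return np.asarray(self.counts[:, cols].todense())


def build_matrix(
    events: EventTable,
    labels: LabelTable,
    vocab: Vocabulary,
    on_unknown_code: str = "drop",
    dedup_same_day: bool = False,
) -> PatientTermMatrix:
    """Assemble the bag-of-words count matrix.

    Rows are ordered by first appearance of each patient in the event table,
    followed by labelled patients with no events (all-zero rows, in label
    order). Every event patient must have a label. Codes outside the
    vocabulary are dropped with a warning by default (``on_unknown_code=
    "error"`` raises instead). ``dedup_same_day`` collapses repeated
    identical (patient, code, date) rows before counting.
    """
    if on_unknown_code not in ("drop", "error"):
        raise ConfigurationError(f"on_unknown_code={on_unknown_code!r}")
    df = events.frame
    if dedup_same_day:
        df = df.drop_duplicates(subset=["patient_id", "code", "date"])

    unlabeled = set(df["patient_id"]) - set(labels.entries)
    if unlabeled:
        raise IntegrityError(
            f"{len(unlabeled)} event patient(s) without a label, e.g. "
            f"{sorted(unlabeled)[:3]}"
        )
    known = df["code"].map(vocab.index.__contains__)
    if not known.all():
        dropped = sorted(set(df.loc[~known, "code"]))
        if on_unknown_code == "error":
            raise UnknownCodeError(dropped[0])
        warnings.warn(
            f"dropping {int((~known).sum())} event row(s) with "
            f"{len(dropped)} code(s) outside the vocabulary",
            stacklevel=2,
        )
        df = df[known]

    patients: list[str] = list(dict.fromkeys(df["patient_id"]))
    seen = set(patients)
    patients.extend(pid for pid in labels.entries if pid not in seen)
    row_of = {p: i for i, p in enumerate(patients)}

    rows = df["patient_id"].map(row_of).to_numpy()
    cols = df["code"].map(vocab.index).to_numpy()
    counts = sp.coo_matrix(
        (np.ones(len(df), dtype=np.int64), (rows, cols)),
        shape=(len(patients), len(vocab)),
    ).tocsr()
    y = np.array([labels[p] for p in patients], dtype=np.int8)
    return PatientTermMatrix(patients=patients, counts=counts, vocab=vocab, labels=y)


@dataclasses.dataclass
class SplitPlan:
    """Assignment of every patient to train/validation/test."""

    fractions: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]

    def part(self, name: str) -> list[str]:
        if name not in PARTS:
            raise ConfigurationError(f"unknown part {name!r}")
        return [p for p, a in self.assignment.items() if a == name]


def split_patients(
    matrix: PatientTermMatrix,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/validation/test split of the cohort.

    Within each outcome class, part sizes follow `fractions` by the
    largest-remainder rule, so every part's class count is within one
    patient of the exact proportion. Reproducible for a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ConfigurationError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions {fractions} do not sum to 1")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    y = matrix.labels
    for cls in (0, 1):
        members = [p for p, lab in zip(matrix.patients, y) if lab == cls]
        if len(members) < 3:
            raise StratificationError(
                f"class {cls} has {len(members)} member(s); need at least 3"
            )
        targets = [f * len(members) for f in fractions]
        sizes = [int(np.floor(t)) for t in targets]
        remainders = sorted(
            range(3), key=lambda i: (-(targets[i] - sizes[i]), i)
        )
        for i in remainders[: len(members) - sum(sizes)]:
            sizes[i] += 1
        order = rng.permutation(len(members))
        cursor = 0
        for part, size in zip(PARTS, sizes):
            for idx in order[cursor : cursor + size]:
                assignment[members[idx]] = part
            cursor += size
    return SplitPlan(fractions=fractions, seed=seed, assignment=assignment)


def save_matrix(matrix: PatientTermMatrix, prefix: str | Path) -> None:
    """Persist as MatrixMarket plus sidecar text files.

    Writes ``<prefix>.mtx`` (counts), ``<prefix>.patients.txt``,
    ``<prefix>.codes.txt`` and ``<prefix>.labels.txt``.
    """
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), matrix.counts)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.patients.txt").write_text("\n".join(matrix.patients) + "\n")
    Path(f"{prefix}.codes.txt").write_text("\n".join(matrix.vocab.codes) + "\n")
    Path(f"{prefix}.labels.txt").write_text(
        "\n".join(str(int(v)) for v in matrix.labels) + "\n"
    )


def load_matrix(prefix: str | Path) -> PatientTermMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    patients = Path(f"{prefix}.patients.txt").read_text().splitlines()
    codes = Path(f"{prefix}.codes.txt").read_text().splitlines()
    labels = np.array(
        [int(v) for v in Path(f"{prefix}.labels.txt").read_text().split()],
        dtype=np.int8,
    )
    return PatientTermMatrix(
        patients=patients, counts=counts, vocab=Vocabulary(codes), labels=labels
    )
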