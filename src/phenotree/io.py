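"""Reading and writing the on-disk artifacts.

Long-format coded event tables and per-patient label tables come in as
CSV/TSV with a header row; code dictionaries map clinical codes to free-text
descriptions. Performance reports and fitted tree models are serialized as
JSON, decision rules as plain text, and patient-term matrices as MatrixMarket
with sidecar text files (see :mod:`phenotree.represent`).

Column names default to ``patient_id, code, date, source`` for events and
``patient_id, outcome`` for labels but can be remapped, since real EHR
exports rarely agree on headers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import EmptyInputError, FormatError, IntegrityError

EVENT_COLUMNS = ("patient_id", "code", "date", "source")
_SOURCES = {"primary", "secondary"}


@dataclasses.dataclass
class EventTable:
    """Long-format coded clinical events, one row per recorded code.

    Duplicate (patient, code) rows are meaningful: the bag-of-words
    representation turns them into occurrence counts. ``date`` and
    ``source`` are optional provenance columns ignored by the core
    pipeline.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("patient_id", "code"):
            if col not in df.columns:
                raise FormatError(f"event table lacks mandatory column {col!r}")
        for col in ("date", "source"):
            if col not in df.columns:
                df[col] = pd.Series([None] * len(df), dtype=object)
        df["patient_id"] = df["patient_id"].astype(str)
        df["code"] = df["code"].astype(str)
        if (df["patient_id"].str.len() == 0).any() or (df["code"].str.len() == 0).any():
            raise FormatError("patient_id and code must be non-empty strings")
        bad = df["source"].dropna()
        bad = bad[~bad.isin(_SOURCES)]
        if len(bad):
            raise FormatError(f"unknown event source values: {sorted(set(bad))[:5]}")
        self.frame = df[list(EVENT_COLUMNS)]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> pd.Series:
        return self.frame["patient_id"]

    @property
    def codes(self) -> pd.Series:
        return self.frame["code"]


@dataclasses.dataclass
class LabelTable:
    """Gold-standard binary outcome per patient (1 = has the condition)."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        for pid, y in self.entries.items():
            if y not in (0, 1):
                raise FormatError(f"outcome for {pid!r} is {y!r}, expected 0/1")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, patient_id: str) -> int:
        return self.entries[patient_id]

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self.entries


@dataclasses.dataclass
class CodeDictionary:
    """Optional mapping from clinical code to a human-readable description."""

    entries: dict[str, str]

    def get(self, code: str, default: str | None = None) -> str | None:
        return self.entries.get(code, default)

    def __len__(self) -> int:
        return len(self.entries)


def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    if dialect not in ("csv", "tsv"):
        raise FormatError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="," if dialect == "csv" else "\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    return df


def read_events(
    path: str | Path,
    dialect: str = "csv",
    columns: Mapping[str, str] | None = None,
) -> EventTable:
    """Read a long-format coded event table.

    Parameters
    ----------
    path : file path to a delimited text file with a header row.
    dialect : ``"csv"`` or ``"tsv"``.
    columns : optional mapping from canonical names (``patient_id``, ``code``,
        ``date``, ``source``) to the headers actually present in the file.

    Row order and duplicate rows are preserved.
    """
    df = _read_table(path, dialect)
    rename = {v: k for k, v in (columns or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in ("patient_id", "code") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return EventTable(df)


def write_events(events: EventTable, path: str | Path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    events.frame.to_csv(path, sep=sep, index=False)


def read_labels(
    path: str | Path,
    dialect: str = "csv",
    columns: Mapping[str, str] | None = None,
) -> LabelTable:
    """Read a per-patient label table (columns patient_id, outcome).

    Consistent duplicate rows are tolerated; conflicting duplicates raise
    :class:`~phenotree.errors.IntegrityError`.
    """
    df = _read_table(path, dialect)
    rename = {v: k for k, v in (columns or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in ("patient_id", "outcome") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    entries: dict[str, int] = {}
    for pid, raw in zip(df["patient_id"].astype(str), df["outcome"]):
        try:
            y = int(raw)
        except (TypeError, ValueError):
            raise FormatError(f"outcome {raw!r} for patient {pid!r} is not 0/1")
        if y not in (0, 1):
            raise FormatError(f"outcome {raw!r} for patient {pid!r} is not 0/1")
        if pid in entries and entries[pid] != y:
            raise IntegrityError(f"conflicting outcomes for patient {pid!r}")
        entries[pid] = y
    return LabelTable(entries)


def write_labels(labels: LabelTable, path: str | Path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    pd.DataFrame(
        {"patient_id": list(labels.entries), "outcome": list(labels.entries.values())}
    ).to_csv(path, sep=sep, index=False)


def read_dictionary(path: str | Path, dialect: str = "csv") -> CodeDictionary:
    """Read a code dictionary (columns code, description)."""
    df = _read_table(path, dialect)
    missing = [c for c in ("code", "description") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    codes = df["code"].astype(str)
    if codes.duplicated().any():
        raise IntegrityError("duplicate codes in dictionary")
    return CodeDictionary(dict(zip(codes, df["description"].astype(str))))


def write_report(report, path: str | Path) -> None:
    """Serialize a :class:`~phenotree.metrics.PerformanceReport` as JSON.

    Undefined metrics (zero denominators) are stored as JSON ``null`` and
    round-trip back to NaN.
    """
    payload = report.to_dict()
    out = {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in payload.items()}
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def read_report(path: str | Path):
    from .metrics import PerformanceReport

    raw = json.loads(Path(path).read_text())
    return PerformanceReport.from_dict(
        {k: (math.nan if v is None else v) for k, v in raw.items()}
    )


def save_ranked(ranked, path: str | Path) -> None:
    """Persist a ranked feature list as TSV: rank, code, score, method.

    Scores are written with ``repr`` so reload is bit-exact.
    """
    lines = ["rank\tcode\tscore\tmethod"]
    for i, (code, score) in enumerate(ranked.entries, start=1):
        lines.append(f"{i}\t{code}\t{float(score)!r}\t{ranked.method}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_ranked(path: str | Path):
    from .ranking import RankedFeatureList

    df = pd.read_csv(path, sep="\t", dtype={"code": str})
    if len(df) == 0:
        raise EmptyInputError(f"{path} has no entries")
    methods = set(df["method"])
    if len(methods) != 1:
        raise FormatError(f"{path}: mixed methods {methods}")
    entries = [(c, float(s)) for c, s in zip(df["code"], df["score"])]
    return RankedFeatureList(method=methods.pop(), entries=entries)


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted tree (nodes, splits, counts, params) as JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def load_model(path: str | Path):
    from .tree import PhenotypeDecisionTree

    return PhenotypeDecisionTree.from_dict(json.loads(Path(path).read_text()))


def save_rules(ruleset, path: str | Path) -> None:
    """Write decision rules as plain text, one rule per line."""
    Path(path).write_text("\n".join(ruleset.to_lines()) + "\n")


def save_trace(trace, path: str | Path) -> None:
    """Persist a forward-selection trace as TSV (i, accuracy_val, f1_val)."""
    lines = ["i\taccuracy_val\tf1_val"]
    for i, acc, f1 in trace.steps:
        lines.append(f"{i}\t{acc!r}\t{f1!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _sanitize(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def save_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_sanitize(obj), indent=2) + "\n")
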