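"""Synthetic imbalanced coded-EHR cohorts with planted informative codes.

The generator emulates the structure of linked primary-care data: a few
thousand patients, a heavy-tailed (Zipf-like) background distribution over
hundreds to thousands of clinical codes, low positive prevalence, and a
small set of codes whose per-event selection probability is multiplied by
a rate ratio in positive patients. Because enrichment acts on per-event
weights (not per-patient presence), positives accumulate *higher counts*
of the planted codes, which exercises the count thresholds in the trees
and not just presence/absence.

Generation order is fixed — labels first, then per-patient event counts,
then codes — from a single seeded stream, so a configuration and seed
reproduce a cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import EventTable, LabelTable


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``informative`` lists (code index, rate_ratio, base_rate): the code's
    per-event probability is ``base_rate`` in negatives and ``base_rate *
    rate_ratio`` (before renormalisation) in positives. Remaining
    probability mass follows a Zipf law over the other codes.
    """

    n_patients: int
    prevalence: float
    n_codes: int
    zipf_exponent: float = 1.2
    mean_events: float = 50.0
    informative: tuple[tuple[int, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_codes < 1:
            raise ConfigurationError("n_patients and n_codes must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.zipf_exponent <= 0 or self.mean_events <= 0:
            raise ConfigurationError("zipf_exponent and mean_events must be > 0")
        idx = [i for i, _, _ in self.informative]
        if len(set(idx)) != len(idx):
            raise ConfigurationError("informative code indices must be distinct")
        total_base = 0.0
        for i, rr, base in self.informative:
            if not 0 <= i < self.n_codes:
                raise ConfigurationError(f"informative index {i} out of range")
            if rr < 1:
                raise ConfigurationError("rate_ratio must be >= 1")
            if not 0 < base < 1:
                raise ConfigurationError("base_rate must lie in (0, 1)")
            total_base += base
        if total_base >= 1:
            raise ConfigurationError("informative base rates must sum below 1")


def default_code_names(n_codes: int) -> list[str]:
    """Read-style 5-character code tokens (letter + 3 digits + '.')."""
    names = []
    for i in range(n_codes):
        letter = chr(ord("a") + (i // 1000) % 26)
        names.append(f"{letter}{i % 1000:03d}.")
    return names


def _code_weights(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(negative-class, positive-class) per-event code probabilities."""
    ranks = np.arange(1, cfg.n_codes + 1, dtype=float)
    zipf = ranks ** (-cfg.zipf_exponent)
    informative_idx = np.array([i for i, _, _ in cfg.informative], dtype=int)
    base_rates = np.array([b for _, _, b in cfg.informative], dtype=float)
    ratios = np.array([r for _, r, _ in cfg.informative], dtype=float)

    neg = zipf.copy()
    if len(informative_idx):
        neg[informative_idx] = 0.0
        neg *= (1.0 - base_rates.sum()) / neg.sum()
        neg[informative_idx] = base_rates
    else:
        neg /= neg.sum()
    pos = neg.copy()
    if len(informative_idx):
        pos[informative_idx] = base_rates * ratios
        pos /= pos.sum()
    return neg, pos


def generate_cohort(
    cfg: CohortConfig, code_names: Sequence[str] | None = None
) -> tuple[EventTable, LabelTable]:
    """Draw one cohort: labels, per-patient Poisson event counts, codes.

    Patients are ``P000001``... in order; every patient gets a label even
    when the Poisson draw leaves them with no events (a legitimate
    no-recorded-code control).
    """
    names = list(code_names) if code_names is not None else default_code_names(cfg.n_codes)
    if len(names) != cfg.n_codes or len(set(names)) != cfg.n_codes:
        raise ConfigurationError("code_names must be n_codes unique strings")
    rng = np.random.default_rng(cfg.seed)
    pad = max(6, len(str(cfg.n_patients)))
    patients = [f"P{i:0{pad}d}" for i in range(1, cfg.n_patients + 1)]
    labels = (rng.random(cfg.n_patients) < cfg.prevalence).astype(int)
    n_events = rng.poisson(cfg.mean_events, size=cfg.n_patients)
    neg_w, pos_w = _code_weights(cfg)

    name_arr = np.array(names)
    pids: list[str] = []
    codes: list[np.ndarray] = []
    for pid, lab, k in zip(patients, labels, n_events):
        if k == 0:
            continue
        drawn = rng.choice(cfg.n_codes, size=k, p=pos_w if lab == 1 else neg_w)
        pids.extend([pid] * k)
        codes.append(name_arr[drawn])
    frame = pd.DataFrame(
        {
            "patient_id": pids,
            "code": np.concatenate(codes) if codes else np.array([], dtype=str),
        }
    )
    events = EventTable(frame)
    label_table = LabelTable(dict(zip(patients, (int(v) for v in labels))))
    return events, label_table


# -- deterministic fixtures -------------------------------------------------

FIXTURES = ("tiny_separable", "tiny_imbalanced", "as_like", "ra_like")


def _tiny_separable() -> tuple[EventTable, LabelTable]:
    # 12 patients, 6 positive; code "AAA01" present iff positive; two noise
    # codes shared by everyone
    rows = []
    labels = {}
    for i in range(12):
        pid = f"S{i + 1:03d}"
        lab = 1 if i < 6 else 0
        labels[pid] = lab
        if lab:
            rows += [(pid, "AAA01")] * (1 + i % 2)
        rows.append((pid, "ZZZ01"))
        if i % 3 == 0:
            rows.append((pid, "ZZZ02"))
    frame = pd.DataFrame(rows, columns=["patient_id", "code"])
    return EventTable(frame), LabelTable(labels)


def _tiny_imbalanced() -> tuple[EventTable, LabelTable]:
    # 50 patients, 2 positives; the positives carry extra "RARE1" events but
    # a handful of negatives carry one too, so the code is informative yet
    # imperfect and leaf labels respond to the false-negative cost
    rows = []
    labels = {}
    for i in range(50):
        pid = f"T{i + 1:03d}"
        lab = 1 if i < 2 else 0
        labels[pid] = lab
        rows.append((pid, "COMM1"))
        if i % 2 == 0:
            rows.append((pid, "COMM2"))
        if lab:
            rows += [(pid, "RARE1")] * 2
        elif i in (10, 20, 30):
            rows.append((pid, "RARE1"))
    frame = pd.DataFrame(rows, columns=["patient_id", "code"])
    return EventTable(frame), LabelTable(labels)


def _as_like() -> tuple[EventTable, LabelTable]:
    # low-prevalence cohort in the ankylosing-spondylitis regime: 2%
    # positives, two strongly enriched codes named after the classic
    # spondylitis/uveitis pair
    # mean_events is high enough that count thresholds separate the
    # Poisson(~1) background from the ~8x enriched positives; a single
    # code is then a mediocre predictor but the pair is near-decisive,
    # so forward selection genuinely needs both
    cfg = CohortConfig(
        n_patients=2000,
        prevalence=0.02,
        n_codes=300,
        zipf_exponent=1.2,
        mean_events=100.0,
        informative=((0, 8.0, 0.010), (1, 8.0, 0.008)),
        seed=20211015,
    )
    names = default_code_names(cfg.n_codes)
    names[0], names[1] = "N100.", "F440."
    return generate_cohort(cfg, code_names=names)


def _ra_like() -> tuple[EventTable, LabelTable]:
    # higher-prevalence cohort in the rheumatoid-arthritis regime: 14%
    # positives, ten moderately enriched codes
    cfg = CohortConfig(
        n_patients=2000,
        prevalence=0.14,
        n_codes=500,
        zipf_exponent=1.2,
        mean_events=30.0,
        informative=tuple((i, 4.0, 0.008) for i in range(10)),
        seed=19481204,
    )
    return generate_cohort(cfg)


_FIXTURE_BUILDERS = {
    "tiny_separable": _tiny_separable,
    "tiny_imbalanced": _tiny_imbalanced,
    "as_like": _as_like,
    "ra_like": _ra_like,
}


def golden_fixture(name: str) -> tuple[EventTable, LabelTable]:
    """Deterministic reference cohorts used across the test suite.

    ``tiny_separable``: 12 patients, one code perfectly separating the
    classes. ``tiny_imbalanced``: 50 patients, 2 positives, one imperfect
    informative code. ``as_like``: 2000 patients at 2% prevalence with two
    planted codes ("N100.", "F440."). ``ra_like``: 2000 patients at 14%
    prevalence with ten planted codes.
    """
    if name not in _FIXTURE_BUILDERS:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    return _FIXTURE_BUILDERS[name]()
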