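"""End-to-end phenotyping runs driven by a validated YAML config.

A run chains the three phases: bag-of-words representation with a
stratified 60/20/20 split, per-index feature ranking plus forward
selection against the validation part, and cross-validated grid search
over the tree profiles with final selection on validation and a single
report on the test part. Every artifact lands in the output directory and
is stamped with the config hash and seed; a failed stage renames the
artifacts written so far to ``*.partial`` so a rerun starts clean.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import io as pio
from .errors import ConfigurationError, PhenotreeError
from .ranking import METHODS, rank_features
from .represent import build_matrix, build_vocabulary, save_matrix, split_patients
from .search import ParamGrid, cross_validated_grid_search, select_final_model
from .selection import feature_subsets_for_phase3, forward_select
from .tree import export_rules

log = logging.getLogger("phenotree")


class PipelineError(PhenotreeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_SCHEMA: dict[str, set[str]] = {
    "": {"events", "labels", "dictionary", "output_dir", "split", "ranking",
         "selection", "profiles", "grids", "folds", "seed", "report"},
    "split": {"fractions", "seed"},
    "ranking": {"methods"},
    "selection": {"i_max", "tolerance", "step"},
    "report": {"dialect"},
}


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    events: str
    labels: str
    output_dir: str
    dictionary: str | None = None
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    methods: tuple[str, ...] = ("chi2", "info_gain", "dkm", "binomial")
    i_max: int = 400
    tolerance: float = 0.0
    step: int = 1
    profiles: tuple[str, ...] = ("c50", "cart", "ci")
    grids: dict[str, dict] = dataclasses.field(default_factory=dict)
    folds: int = 10
    seed: int = 0
    dialect: str = "csv"

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        def check_keys(section: str, mapping: Mapping[str, Any]):
            unknown = set(mapping) - _SCHEMA[section]
            if unknown:
                where = section or "top level"
                raise ConfigurationError(f"unknown config key(s) {sorted(unknown)} at {where}")

        check_keys("", raw)
        for section in ("split", "ranking", "selection", "report"):
            if section in raw:
                if not isinstance(raw[section], Mapping):
                    raise ConfigurationError(f"config section {section!r} must be a mapping")
                check_keys(section, raw[section])
        for key in ("events", "labels", "output_dir"):
            if key not in raw:
                raise ConfigurationError(f"config lacks required key {key!r}")
        split = raw.get("split", {})
        ranking = raw.get("ranking", {})
        selection = raw.get("selection", {})
        report = raw.get("report", {})
        cfg = cls(
            events=str(raw["events"]),
            labels=str(raw["labels"]),
            output_dir=str(raw["output_dir"]),
            dictionary=raw.get("dictionary"),
            fractions=tuple(split.get("fractions", (0.6, 0.2, 0.2))),
            split_seed=int(split.get("seed", 0)),
            methods=tuple(ranking.get("methods", ("chi2", "info_gain", "dkm", "binomial"))),
            i_max=int(selection.get("i_max", 400)),
            tolerance=float(selection.get("tolerance", 0.0)),
            step=int(selection.get("step", 1)),
            profiles=tuple(raw.get("profiles", ("c50", "cart", "ci"))),
            grids={k: dict(v) for k, v in raw.get("grids", {}).items()},
            folds=int(raw.get("folds", 10)),
            seed=int(raw.get("seed", 0)),
            dialect=str(report.get("dialect", "csv")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if len(self.fractions) != 3 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions {self.fractions} must sum to 1")
        for m in self.methods:
            if m not in METHODS:
                raise ConfigurationError(f"unknown ranking method {m!r}")
        for p in self.profiles:
            ParamGrid.default(p)  # raises on unknown profile
        for p in self.grids:
            if p not in self.profiles:
                raise ConfigurationError(f"grid given for unlisted profile {p!r}")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.i_max < 1:
            raise ConfigurationError("i_max must be >= 1")

    def grid_for(self, profile: str) -> ParamGrid:
        if profile in self.grids:
            return ParamGrid(profile, {k: list(v) for k, v in self.grids[profile].items()})
        return ParamGrid.default(profile)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config file must contain a mapping")
    return RunConfig.from_mapping(raw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute phases 1-3 and write all artifacts.

    Returns a summary dict (also written as ``run.json``) with the selected
    model's provenance and test performance.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stamp = {"config_sha256": cfg.digest(), "seed": cfg.seed}

    def emit(path: Path):
        written.append(path)
        return path

    stage = "load"
    try:
        events = pio.read_events(cfg.events, dialect=cfg.dialect)
        labels = pio.read_labels(cfg.labels, dialect=cfg.dialect)
        dictionary = pio.read_dictionary(cfg.dictionary) if cfg.dictionary else None

        stage = "represent"
        vocab = build_vocabulary(events)
        matrix = build_matrix(events, labels, vocab)
        plan = split_patients(matrix, cfg.fractions, cfg.split_seed)
        train = matrix.subset(plan.part("train"))
        val = matrix.subset(plan.part("validation"))
        test = matrix.subset(plan.part("test"))
        save_matrix(matrix, out / "matrix")
        for suffix in ("mtx", "patients.txt", "codes.txt", "labels.txt"):
            emit(out / f"matrix.{suffix}")
        log.info(
            "represent: %d patients x %d codes, split %s",
            matrix.n_patients, len(vocab), {p: len(plan.part(p)) for p in ("train", "validation", "test")},
        )

        stage = "rank+select"
        candidates = []
        selections = {}
        for method in cfg.methods:
            ranked = rank_features(train, method=method)
            pio.save_ranked(ranked, emit(out / f"ranked_{method}.tsv"))
            trace = forward_select(
                ranked, train, val, i_max=cfg.i_max,
                tolerance=cfg.tolerance, step=cfg.step,
            )
            pio.save_trace(trace, emit(out / f"trace_{method}.tsv"))
            if trace.second_cutoff is None:
                subsets = [ranked.top(trace.best_cutoff)]
            else:
                subsets = list(feature_subsets_for_phase3(trace, ranked))
            pio.save_json(
                {**stamp, "method": method, "best_cutoff": trace.best_cutoff,
                 "second_cutoff": trace.second_cutoff, "tolerance": trace.tolerance,
                 "n_fits": trace.n_fits},
                emit(out / f"selection_{method}.json"),
            )
            selections[method] = subsets
            log.info("select[%s]: cut-offs best=%s second=%s (%d fits)",
                     method, trace.best_cutoff, trace.second_cutoff, trace.n_fits)

        stage = "gridsearch"
        for method, subsets in selections.items():
            for rank_pos, features in enumerate(subsets, start=1):
                for profile in cfg.profiles:
                    grid = cfg.grid_for(profile)
                    result = cross_validated_grid_search(
                        train, features, grid, folds=cfg.folds, seed=cfg.seed
                    )
                    path = emit(out / f"grid_{profile}_{method}_{rank_pos}.tsv")
                    lines = ["\t".join(list(grid.axes) + ["cv_agreement"])]
                    for params, score in result.results:
                        lines.append("\t".join(
                            [str(params[a]) for a in grid.axes] + [f"{score:.6f}"]
                        ))
                    path.write_text("\n".join(lines) + "\n")
                    candidates.append((features, profile, result.best,
                                       f"{method}-{rank_pos}"))
                    log.info("gridsearch[%s %s-%d]: best %s (agreement %.4f)",
                             profile, method, rank_pos, result.best, result.best_score)

        stage = "final"
        model, report, summaries = select_final_model(
            [(f, p, b) for f, p, b, _ in candidates], train, val, test
        )
        for s, (_, _, _, tag) in zip(summaries, candidates):
            s["candidate"] = tag
        pio.save_model(model, emit(out / "model.json"))
        pio.save_rules(export_rules(model, dictionary), emit(out / "rules.txt"))
        pio.write_report(report, emit(out / "report.json"))
        summary = {
            **stamp,
            "selected": next(s for s in summaries if s["selected"]),
            "candidates": summaries,
            "test_report": report.to_dict(),
        }
        pio.save_json(summary, emit(out / "run.json"))
        log.info("final: %s test accuracy %.4f", summary["selected"]["candidate"],
                 report.accuracy)
        return summary
    except Exception as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        raise PipelineError(stage, exc) from exc
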