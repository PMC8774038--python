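"""Configuration-driven grid runner: cleaning arm x band x channel strategy
x classifier x task pair, with tabulated metrics.

For the a-priori strategies (C3C4, CP3CP4, ROI_C3C4, ROI_CP3CP4) the
feature matrix is restricted to the group's channels before
classification; for ``optimal`` the ReliefF + nested-subset wrapper runs
on all channels and both the selection-maximised accuracy and a nested
outer-CV estimate are reported.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from mi_erd import cleaning, data_io, features, synthetic
from mi_erd.channel_selection import optimise_selection, outer_cv_selection_accuracy
from mi_erd.classification import (
    ClassifierSpec,
    compute_metrics,
    cross_validated_predictions,
    resolve_params,
)
from mi_erd.data_io import ConfigurationError, InputError

logger = logging.getLogger(__name__)

CLEANING_ARMS = ("filter", "filter+ica")
CHANNEL_STRATEGIES = ("C3C4", "CP3CP4", "ROI_C3C4", "ROI_CP3CP4", "optimal")
CLASSIFIERS = ("SVM", "KNN", "TREE")


@dataclass
class GridConfig:
    """Axes and data source of one grid run."""

    task_pairs: tuple[str, ...] = data_io.TASK_PAIR_NAMES
    cleaning_arms: tuple[str, ...] = ("filter",)
    bands: tuple[str, ...] = ("ERD_A", "ERD_B", "ERD_AB")
    channel_strategies: tuple[str, ...] = CHANNEL_STRATEGIES
    classifiers: tuple[str, ...] = ("SVM", "KNN", "TREE")
    cv_folds: int = 5
    seed: int = 0
    tuning_budget: int = 30
    tuning_strategy: str = "bayesian"
    tune: bool = True
    outer_cv: bool = False
    per_subject: bool = False
    sim: synthetic.SimConfig | None = None
    data_dir: str | None = None
    excluded_subjects: tuple[int, ...] = data_io.DEFAULT_EXCLUDED_SUBJECTS
    out_dir: str | None = None

    def validate(self) -> None:
        for pair in self.task_pairs:
            if pair not in data_io.TASK_PAIR_NAMES:
                raise ConfigurationError(f"unknown task pair {pair!r}")
        for arm in self.cleaning_arms:
            if arm not in CLEANING_ARMS:
                raise ConfigurationError(f"unknown cleaning arm {arm!r}")
        for band in self.bands:
            if band not in features.BANDS:
                raise ConfigurationError(f"unknown band {band!r}")
        for strat in self.channel_strategies:
            if strat not in CHANNEL_STRATEGIES:
                raise ConfigurationError(f"unknown channel strategy {strat!r}")
        for clf in self.classifiers:
            if clf not in CLASSIFIERS:
                raise ConfigurationError(f"unknown classifier {clf!r}")
        if self.sim is None and self.data_dir is None:
            raise ConfigurationError("either a synthetic SimConfig or a data_dir is required")
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise ConfigurationError(f"data directory {self.data_dir} does not exist")


def _clean(rec: data_io.Recording, arm: str, seed: int) -> data_io.Recording:
    filtered = cleaning.bandpass_filter(rec)
    if arm == "filter":
        return filtered
    cleaned, _ = cleaning.ica_artifact_removal(filtered, seed=seed)
    return cleaned


def _synthetic_epochs(config: GridConfig, pair: data_io.TaskPair, arm: str,
                      ) -> data_io.EpochSet:
    sim = replace(config.sim, class_labels=(pair.label_a, pair.label_b))
    rec = synthetic.generate_recording(sim)
    if sim.blink_rate_per_min > 0 or sim.line_noise_amplitude > 0:
        rec = synthetic.inject_artifacts(rec, sim)
    return data_io.epoch_events(_clean(rec, arm, config.seed))


def _physionet_epochs_by_subject(config: GridConfig, pair: data_io.TaskPair,
                                 arm: str) -> dict[int, data_io.EpochSet]:
    by_subject = data_io.subject_run_files(config.data_dir, pair,
                                           excluded=config.excluded_subjects)
    if not by_subject:
        raise InputError(f"no runs for task pair {pair.name} under {config.data_dir}")
    out = {}
    for subject, paths in sorted(by_subject.items()):
        recs = [data_io.read_edf_run(p, pair) for p in paths]
        rec = data_io.concatenate_runs(recs)
        out[subject] = data_io.epoch_events(_clean(rec, arm, config.seed))
    return out


def _physionet_epochs(config: GridConfig, pair: data_io.TaskPair, arm: str,
                      ) -> data_io.EpochSet:
    """Pool all subjects' trials into one epoch set (group-level framing)."""
    epoch_sets = list(_physionet_epochs_by_subject(config, pair, arm).values())
    data = np.concatenate([e.data for e in epoch_sets], axis=0)
    labels = [l for e in epoch_sets for l in e.labels]
    first = epoch_sets[0]
    return data_io.EpochSet(data=data, labels=labels, fs=first.fs,
                            n_pre=first.n_pre, n_post=first.n_post,
                            channels=first.channels)


def _fold_hash(y: np.ndarray, folds: int, seed: int) -> str:
    from sklearn.model_selection import StratifiedKFold

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for k, (_, test) in enumerate(cv.split(np.zeros((len(y), 1)), y)):
        assignment[test] = k
    return hashlib.sha1(assignment.tobytes()).hexdigest()[:10]


def run_grid(config: GridConfig) -> pd.DataFrame:
    """Run every grid cell; one result row per cell.

    Deterministic given the seed.  When ``out_dir`` is set, writes
    ``grid_results.csv`` (full precision) and ``summary.md`` (rounded
    percentages in the comparison-table layout).
    """
    config.validate()
    rows = []
    for pair_name in config.task_pairs:
        pair = data_io.task_pair(pair_name)
        for arm in config.cleaning_arms:
            if config.sim is not None:
                epoch_sets = {None: _synthetic_epochs(config, pair, arm)}
            elif config.per_subject:
                epoch_sets = _physionet_epochs_by_subject(config, pair, arm)
            else:
                epoch_sets = {None: _physionet_epochs(config, pair, arm)}
            for band_name in config.bands:
                mats = {subj: features.build_feature_matrix(e, features.BANDS[band_name])
                        for subj, e in epoch_sets.items()}
                for strategy in config.channel_strategies:
                    for clf in config.classifiers:
                        if config.per_subject and config.sim is None:
                            accs = []
                            for subj, fm in mats.items():
                                cell = _run_cell(config, pair, arm, band_name,
                                                 fm, strategy, clf)
                                accs.append(cell["accuracy"])
                            rows.append({"task_pair": pair.name, "cleaning": arm,
                                         "band": band_name, "channels": strategy,
                                         "classifier": clf, "seed": config.seed,
                                         "n_subjects": len(accs),
                                         "accuracy": float(np.mean(accs)),
                                         "accuracy_sd": float(np.std(accs, ddof=1))
                                         if len(accs) > 1 else 0.0})
                        else:
                            fm = mats[None]
                            rows.append(_run_cell(config, pair, arm, band_name,
                                                  fm, strategy, clf))
    result = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "grid_results.csv", index=False)
        (out / "summary.md").write_text(summarise(result))
    return result


def _run_cell(config: GridConfig, pair: data_io.TaskPair, arm: str,
              band_name: str, fm: features.FeatureMatrix, strategy: str,
              clf: str) -> dict:
    t0 = time.perf_counter()
    spec = ClassifierSpec(kind=clf, tuning_budget=config.tuning_budget,
                          tuning_strategy=config.tuning_strategy,
                          seed=config.seed, tune=config.tune)
    y = np.asarray(fm.labels)
    row: dict = {"task_pair": pair.name, "cleaning": arm, "band": band_name,
                 "channels": strategy, "classifier": clf, "seed": config.seed,
                 "n_trials": len(y),
                 "fold_hash": _fold_hash(y, config.cv_folds, config.seed)}
    if strategy == "optimal":
        sel = optimise_selection(fm.values, y, spec, cv_folds=config.cv_folds,
                                 seed=config.seed, descriptors=fm.descriptors)
        cols = sel.ranking.order[: sel.best_size]
        sub = fm.values[:, cols]
        spec_fixed = spec.with_params(sel.tuned_params)
        y_pred, scores = cross_validated_predictions(sub, y, spec_fixed,
                                                     folds=config.cv_folds,
                                                     seed=config.seed,
                                                     positive_label=pair.label_a)
        row["selected_channels"] = " ".join(ch for ch, _ in sel.selected_features)
        row["n_selected"] = sel.best_size
        row["selection_accuracy"] = sel.selection_accuracy
        row["tuned_params"] = repr(sel.tuned_params)
        if config.outer_cv:
            row["outer_cv_accuracy"] = outer_cv_selection_accuracy(
                fm.values, y, spec, cv_folds=config.cv_folds, seed=config.seed)
    else:
        sub_fm = fm.select_channels(data_io.channel_group(strategy))
        params = resolve_params(sub_fm.values, y, spec, folds=config.cv_folds)
        spec_fixed = spec.with_params(params)
        row["tuned_params"] = repr(params)
        y_pred, scores = cross_validated_predictions(sub_fm.values, y, spec_fixed,
                                                     folds=config.cv_folds,
                                                     seed=config.seed,
                                                     positive_label=pair.label_a)
    report = compute_metrics(y, y_pred, scores, positive_label=pair.label_a)
    row.update(report.as_dict())
    row["runtime_s"] = round(time.perf_counter() - t0, 3)
    logger.info("cell %s/%s/%s/%s/%s: accuracy %.3f", pair.name, arm, band_name,
                strategy, clf, report.accuracy)
    return row


def summarise(result: pd.DataFrame) -> str:
    """Markdown summary with percentages rounded to integers."""
    lines = ["# Grid results (CV accuracy, %)", ""]
    for (pair, arm), chunk in result.groupby(["task_pair", "cleaning"]):
        lines.append(f"## {pair} — cleaning: {arm}")
        lines.append("")
        table = chunk.pivot_table(index=["channels", "band"], columns="classifier",
                                  values="accuracy", aggfunc="first") * 100
        lines.append(table.round(0).astype("Int64").to_markdown())
        lines.append("")
    return "\n".join(lines)
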