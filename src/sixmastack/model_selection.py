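"""Selection protocols: repeated hold-out, greedy feature and learner search.

Evaluation backbone is the repeated stratified hold-out: split the training
set 8:2, fit, score on the 20% validation part, repeat five times with
shifted seeds, and report mean ACC/AUC with a Student-t 95% confidence
interval over the repeats.

Three greedy protocols are built on it:

* :func:`forward_feature_search` — screen each encoder alone with a single
  screening learner, drop encoders below an ACC cutoff (0.81 by default),
  then grow the combination greedily while additions strictly improve ACC.
* :func:`backward_classifier_search` — start from the full first layer and
  repeatedly drop the base learner whose removal does not hurt ACC.
* :func:`second_layer_sweep` — try each candidate final classifier above a
  fixed first layer.

Mean ACC is the selection criterion throughout; AUC is recorded but never
used to select.  Every evaluated candidate lands in a :class:`SearchTrace`,
which is sufficient to replay the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .encoders import EncoderSpec, encode_dataset
from .errors import ConfigurationError, EmptyInputError
from .evaluation import MetricsReport, report_from_scores
from .sequence_io import LabeledDataset
from .stacking import (
    BaseLearnerSpec,
    fit_stacking_matrix,
    make_learner,
    positive_proba,
    predict_proba_matrix,
)


def confidence_interval(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, float]:
    """Student-t interval for the mean of ``values`` (needs >= 2 values).

    mean ± t_{df=m-1, (1+confidence)/2} · sd / sqrt(m).
    """
    if not 0.0 < confidence < 1.0:
        raise ConfigurationError(f"confidence {confidence} outside (0, 1)")
    v = np.asarray(values, dtype=float)
    m = v.size
    if m < 2:
        raise ConfigurationError("confidence interval needs at least 2 values")
    mean = v.mean()
    sd = v.std(ddof=1)
    half = stats.t.ppf((1.0 + confidence) / 2.0, df=m - 1) * sd / np.sqrt(m)
    return float(mean - half), float(mean + half)


@dataclass(frozen=True)
class StackingConfig:
    """A full two-layer model configuration for hold-out evaluation."""

    base_specs: tuple
    final_spec: BaseLearnerSpec
    K: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_specs", tuple(self.base_specs))


@dataclass
class HoldOutResult:
    """Aggregate of one repeated hold-out evaluation."""

    per_repeat: list[MetricsReport]
    mean_acc: float
    mean_auc: float
    ci_acc: tuple[float, float] | None
    ci_auc: tuple[float, float] | None
    split_ratio: float
    repeats: int
    seeds: list[int]


def _fit_score(config, X_train, y_train, X_test, seed: int) -> np.ndarray:
    """Fit one configuration and return validation probabilities."""
    if isinstance(config, BaseLearnerSpec):
        model = make_learner(config)
        model.fit(X_train, y_train)
        return positive_proba(model, X_test)
    if isinstance(config, StackingConfig):
        model = fit_stacking_matrix(
            X_train, y_train, list(config.base_specs), config.final_spec,
            K=config.K, seed=seed,
        )
        return predict_proba_matrix(model, X_test)
    raise ConfigurationError(
        f"model_config must be a BaseLearnerSpec or StackingConfig, "
        f"got {type(config).__name__}"
    )


def holdout_eval(
    dataset: LabeledDataset,
    encoder_specs: Sequence[EncoderSpec],
    model_config,
    ratio: float = 0.8,
    repeats: int = 5,
    base_seed: int = 0,
    confidence: float = 0.95,
    threshold: float = 0.5,
) -> HoldOutResult:
    """Repeated stratified hold-out evaluation of one configuration.

    Repeat r uses a stratified split seeded ``base_seed + r``; the model is
    trained on the ``ratio`` fraction and scored on the remainder.  With a
    single repeat the confidence intervals are ``None`` (undefined).
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError(f"split ratio {ratio} outside (0, 1)")
    if repeats < 1:
        raise ConfigurationError(f"repeats {repeats} must be >= 1")
    X = encode_dataset(dataset, encoder_specs).values
    y = dataset.labels
    if np.unique(y).size < 2:
        raise ConfigurationError("hold-out evaluation needs both classes")
    reports: list[MetricsReport] = []
    seeds = [base_seed + r for r in range(repeats)]
    for seed in seeds:
        train_idx, test_idx = train_test_split(
            np.arange(y.shape[0]), train_size=ratio, stratify=y, random_state=seed
        )
        scores = _fit_score(model_config, X[train_idx], y[train_idx], X[test_idx], seed)
        reports.append(report_from_scores(y[test_idx], scores, threshold=threshold))
    accs = [r.ACC for r in reports]
    aucs = [r.AUC for r in reports]
    ci_acc = ci_auc = None
    if repeats >= 2:
        ci_acc = confidence_interval(accs, confidence)
        ci_auc = confidence_interval(aucs, confidence)
    return HoldOutResult(
        per_repeat=reports,
        mean_acc=float(np.mean(accs)),
        mean_auc=float(np.mean(aucs)),
        ci_acc=ci_acc,
        ci_auc=ci_auc,
        split_ratio=ratio,
        repeats=repeats,
        seeds=seeds,
    )


@dataclass(frozen=True)
class SearchStep:
    """One evaluated candidate with its hold-out score."""

    description: str
    result: HoldOutResult


@dataclass
class SearchTrace:
    """Ordered record of every candidate evaluated by a greedy search."""

    direction: str
    steps: list[SearchStep] = field(default_factory=list)
    selected: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for step in self.steps:
            r = step.result
            rows.append(
                {
                    "candidate": step.description,
                    "mean_ACC": r.mean_acc,
                    "ACC_CI_low": r.ci_acc[0] if r.ci_acc else None,
                    "ACC_CI_high": r.ci_acc[1] if r.ci_acc else None,
                    "mean_AUC": r.mean_auc,
                    "AUC_CI_low": r.ci_auc[0] if r.ci_auc else None,
                    "AUC_CI_high": r.ci_auc[1] if r.ci_auc else None,
                    "selected": step.description == self.selected,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _encoder_desc(specs: Sequence[EncoderSpec]) -> str:
    return "+".join(s.name for s in specs)


def forward_feature_search(
    dataset: LabeledDataset,
    candidates: Sequence[EncoderSpec],
    screening_learner: BaseLearnerSpec,
    min_single_acc: float = 0.81,
    **holdout_kwargs,
) -> SearchTrace:
    """Greedy forward selection over encoders.

    1. Evaluate each candidate encoder alone with the screening learner and
       discard any with mean ACC below ``min_single_acc``.
    2. Seed the combination with the best surviving single encoder.
    3. Repeatedly try adding each remaining encoder; accept the best
       addition only if it *strictly* improves mean ACC, else stop.
    """
    if len(candidates) < 2:
        raise ConfigurationError("forward search needs at least 2 candidates")
    trace = SearchTrace(direction="forward_features")
    singles: list[tuple[EncoderSpec, HoldOutResult]] = []
    for spec in candidates:
        result = holdout_eval(dataset, [spec], screening_learner, **holdout_kwargs)
        trace.steps.append(SearchStep(_encoder_desc([spec]), result))
        singles.append((spec, result))
    retained = [(s, r) for s, r in singles if r.mean_acc >= min_single_acc]
    if not retained:
        raise EmptyInputError(
            f"every candidate fell below the {min_single_acc} single-feature "
            f"ACC cutoff"
        )
    retained.sort(key=lambda sr: sr[1].mean_acc, reverse=True)
    current = [retained[0][0]]
    current_acc = retained[0][1].mean_acc
    remaining = [s for s, _ in retained[1:]]
    while remaining:
        best_idx, best_acc = None, current_acc
        for i, spec in enumerate(remaining):
            result = holdout_eval(
                dataset, current + [spec], screening_learner, **holdout_kwargs
            )
            trace.steps.append(SearchStep(_encoder_desc(current + [spec]), result))
            if result.mean_acc > best_acc:
                best_idx, best_acc = i, result.mean_acc
        if best_idx is None:
            break
        current.append(remaining.pop(best_idx))
        current_acc = best_acc
    trace.selected = _encoder_desc(current)
    return trace


def _learner_desc(specs: Sequence[BaseLearnerSpec]) -> str:
    return "+".join(s.algorithm for s in specs)


def backward_classifier_search(
    dataset: LabeledDataset,
    initial_base_specs: Sequence[BaseLearnerSpec],
    fixed_final_spec: BaseLearnerSpec,
    encoder_specs: Sequence[EncoderSpec],
    K: int = 5,
    **holdout_kwargs,
) -> SearchTrace:
    """Greedy backward elimination over the first-layer classifiers.

    Each round evaluates every single-learner removal from the current set;
    the best removal is accepted when its mean ACC is >= the current set's
    (a learner whose removal does not hurt contributed nothing).  Exact
    ties between removals are broken toward removing the later learner in
    list order.  Stops when no removal qualifies or one learner remains.
    """
    current = list(initial_base_specs)
    trace = SearchTrace(direction="backward_classifiers")
    result = holdout_eval(
        dataset,
        encoder_specs,
        StackingConfig(tuple(current), fixed_final_spec, K=K),
        **holdout_kwargs,
    )
    trace.steps.append(SearchStep(_learner_desc(current), result))
    current_acc = result.mean_acc
    while len(current) > 1:
        best_idx, best_acc = None, -np.inf
        for i in range(len(current)):
            subset = current[:i] + current[i + 1 :]
            result = holdout_eval(
                dataset,
                encoder_specs,
                StackingConfig(tuple(subset), fixed_final_spec, K=K),
                **holdout_kwargs,
            )
            trace.steps.append(SearchStep(_learner_desc(subset), result))
            if result.mean_acc >= best_acc:  # later index wins exact ties
                best_idx, best_acc = i, result.mean_acc
        if best_acc >= current_acc:
            current.pop(best_idx)
            current_acc = best_acc
        else:
            break
    trace.selected = _learner_desc(current)
    return trace


def second_layer_sweep(
    dataset: LabeledDataset,
    fixed_base_specs: Sequence[BaseLearnerSpec],
    candidate_final_specs: Sequence[BaseLearnerSpec],
    encoder_specs: Sequence[EncoderSpec],
    K: int = 5,
    **holdout_kwargs,
) -> SearchTrace:
    """Evaluate each candidate final classifier above a fixed first layer."""
    if not candidate_final_specs:
        raise ConfigurationError("second-layer sweep needs >= 1 candidate")
    trace = SearchTrace(direction="second_layer_sweep")
    best_desc, best_acc = None, -np.inf
    for spec in candidate_final_specs:
        result = holdout_eval(
            dataset,
            encoder_specs,
            StackingConfig(tuple(fixed_base_specs), spec, K=K),
            **holdout_kwargs,
        )
        trace.steps.append(SearchStep(spec.algorithm, result))
        if result.mean_acc > best_acc:
            best_desc, best_acc = spec.algorithm, result.mean_acc
    trace.selected = best_desc
    return trace
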