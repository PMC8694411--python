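"""Scoring layer: confidence-binned outcome summaries, accuracies, model
filters, the full settings grid, per-compound confusion and subset retraining.

Every test-window classification falls into one of five outcome bins:
Correct-Identified, Correct-Unclear, Incorrect-Identified, Incorrect-Unclear
and Unknown ("Unclear" is the Uncertain confidence bin).  Two accuracies are
derived:

* **General Accuracy** = 100 * (CI + CU) / (CI + CU + II + IU) — percent
  correct among all classifications that produced a label (Unknowns are
  excluded from the denominator).
* **Identified Accuracy** = 100 * CI / (CI + II) — percent correct among
  Identified-confidence classifications only.

Models with more than 50% Unknowns, or with less than a 25% Identified
share, are flagged as excluded: the former are poor classifiers, the latter
lack confidence.  The default settings grid crosses window lengths {4,5,6}
x standardizations {raw, all, per_compound, control} x ten method variants
(five RBF interpreters and five KNN k values), 120 configurations in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .rce import (
    Classification,
    classify_dataset,
    default_rce_config,
    train_knn,
    train_rbf,
)
from .stability import DEFAULT_WINDOW, ObservationWindow
from .standardize import SCHEMES, apply_standardizer, fit_standardizer
from .synthetic import ExperimentData
from .windows import build_dataset, split

__all__ = [
    "ConfusionSummary",
    "GridSetting",
    "ModelResult",
    "summarize",
    "general_accuracy",
    "identified_accuracy",
    "filter_models",
    "default_grid",
    "run_grid",
    "results_table",
    "confusion_by_class",
    "subset_experiment",
]

logger = logging.getLogger(__name__)

UNKNOWN_LIMIT_PCT = 50.0  # strict: > 50% Unknown excludes a model
MIN_IDENTIFIED_PCT = 25.0  # strict: < 25% Identified share excludes a model


@dataclass
class ConfusionSummary:
    """Five-bin outcome percentages for one model's test set.

    Percentages refer to all ``n_test`` test windows and sum to 100 (within
    rounding when built from printed, rounded cells).  ``counts`` holds the
    matching integers when the summary was tallied from classifications.
    """

    pct_correct_identified: float
    pct_correct_unclear: float
    pct_incorrect_identified: float
    pct_incorrect_unclear: float
    pct_unknown: float
    n_test: int = 0
    counts: tuple[int, int, int, int, int] | None = None

    def __post_init__(self) -> None:
        total = (
            self.pct_correct_identified
            + self.pct_correct_unclear
            + self.pct_incorrect_identified
            + self.pct_incorrect_unclear
            + self.pct_unknown
        )
        if abs(total - 100.0) > 0.15:
            raise ValueError(f"outcome percentages sum to {total}, expected 100")
        if self.counts is not None and sum(self.counts) != self.n_test:
            raise ValueError("outcome counts do not sum to n_test")

    @classmethod
    def from_percentages(
        cls, ci: float, cu: float, ii: float, iu: float, unknown: float
    ) -> "ConfusionSummary":
        """Build a summary from (possibly rounded) printed percentages."""
        return cls(ci, cu, ii, iu, unknown)

    @property
    def pct_identified(self) -> float:
        return self.pct_correct_identified + self.pct_incorrect_identified


def summarize(predictions: list[Classification], truths: list[str]) -> ConfusionSummary:
    """Tally predictions into the five outcome bins."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truths)} truths"
        )
    if not predictions:
        raise ValueError("no predictions to summarize")
    ci = cu = ii = iu = unk = 0
    for pred, truth in zip(predictions, truths):
        if pred.confidence == "Unknown":
            unk += 1
        elif pred.confidence == "Identified":
            if pred.label == truth:
                ci += 1
            else:
                ii += 1
        else:  # Uncertain -> "Unclear"
            if pred.label == truth:
                cu += 1
            else:
                iu += 1
    n = len(predictions)
    return ConfusionSummary(
        100 * ci / n, 100 * cu / n, 100 * ii / n, 100 * iu / n, 100 * unk / n,
        n_test=n, counts=(ci, cu, ii, iu, unk),
    )


def general_accuracy(summary: ConfusionSummary) -> float:
    """Percent correct among classifications that produced a label."""
    denom = (
        summary.pct_correct_identified
        + summary.pct_correct_unclear
        + summary.pct_incorrect_identified
        + summary.pct_incorrect_unclear
    )
    if denom <= 0:
        raise ValueError("general accuracy undefined: every output was Unknown")
    return 100 * (summary.pct_correct_identified + summary.pct_correct_unclear) / denom


def identified_accuracy(summary: ConfusionSummary) -> float:
    """Percent correct among Identified-confidence classifications."""
    denom = summary.pct_correct_identified + summary.pct_incorrect_identified
    if denom <= 0:
        raise ValueError("identified accuracy undefined: no Identified outputs")
    return 100 * summary.pct_correct_identified / denom


@dataclass(frozen=True)
class GridSetting:
    """One model configuration of the settings grid."""

    w: int
    scheme: str
    method: str  # "RBF" or "KNN"
    interpreter: str  # dominant | best_match | unanimous | min_consensus
    k: int | None = None  # KNN neighbours
    min_consensus: int | None = None  # quorum m for min_consensus

    def label(self) -> str:
        scheme_names = {"raw": "Raw", "all": "All", "per_compound": "AC", "control": "Control"}
        interp = {"dominant": "D", "best_match": "BM", "unanimous": "U"}
        if self.method == "KNN":
            return f"{self.w}pt-{scheme_names[self.scheme]}-KNN-{self.k}-D"
        tag = f"MC-{self.min_consensus}" if self.interpreter == "min_consensus" else interp[self.interpreter]
        return f"{self.w}pt-{scheme_names[self.scheme]}-RBF-{tag}"


@dataclass
class ModelResult:
    setting: GridSetting
    summary: ConfusionSummary | None
    general_accuracy: float | None
    identified_accuracy: float | None
    excluded: bool = False
    reason: str | None = None
    #: Identified share (%) per true class, for the per-class filter variant.
    identified_share_by_class: dict[str, float] | None = None


def default_grid() -> list[GridSetting]:
    """The full 120-configuration grid: 3 window lengths x 4 standardizations
    x (5 RBF interpreter variants + 5 KNN k values)."""
    settings: list[GridSetting] = []
    for w in (4, 5, 6):
        for scheme in SCHEMES:
            for interpreter in ("dominant", "best_match", "unanimous"):
                settings.append(GridSetting(w, scheme, "RBF", interpreter))
            for m in (2, 3):
                settings.append(GridSetting(w, scheme, "RBF", "min_consensus", min_consensus=m))
            for k in (3, 4, 5, 10, 15):
                settings.append(GridSetting(w, scheme, "KNN", "dominant", k=k))
    return settings


def run_grid(
    experiment: ExperimentData,
    settings: list[GridSetting] | None = None,
    seed: int = 0,
    window: ObservationWindow | None = DEFAULT_WINDOW,
    test_fraction: float = 0.2,
    split_mode: str = "window",
) -> list[ModelResult]:
    """Train and score every grid configuration.

    For each window length, the dataset is built and split once; for each
    standardization, the scaler is fitted on the training partition; each
    method is trained once and scored under every applicable interpreter /
    k.  Deterministic for a fixed seed.  Per-model failures are recorded on
    the result and the grid continues.
    """
    if settings is None:
        settings = default_grid()
    results: dict[GridSetting, ModelResult] = {}

    for w in sorted({s.w for s in settings}):
        w_settings = [s for s in settings if s.w == w]
        dataset = build_dataset(experiment, w, window)
        train, test = split(dataset, test_fraction, mode=split_mode, seed=seed)
        truths = test.labels()
        for scheme in dict.fromkeys(s.scheme for s in w_settings):
            group = [s for s in w_settings if s.scheme == scheme]
            try:
                std = fit_standardizer(train, scheme)
                train_s = apply_standardizer(train, std)
                test_s = apply_standardizer(test, std)
            except Exception as exc:
                for s in group:
                    results[s] = ModelResult(s, None, None, None, True, f"standardization failed: {exc}")
                continue
            models = {}
            for method in dict.fromkeys(s.method for s in group):
                try:
                    if method == "RBF":
                        cfg = default_rce_config(train_s, seed=seed)
                        models[method] = train_rbf(train_s, cfg, shuffle_seed=seed)
                    else:
                        models[method] = train_knn(train_s)
                except Exception as exc:
                    models[method] = exc
            for s in group:
                model = models[s.method]
                if isinstance(model, Exception):
                    results[s] = ModelResult(s, None, None, None, True, f"training failed: {model}")
                    continue
                try:
                    preds = classify_dataset(
                        model, test_s, interpreter=s.interpreter,
                        min_consensus=s.min_consensus, k=s.k,
                    )
                    summary = summarize(preds, truths)
                    try:
                        ga = general_accuracy(summary)
                    except ValueError:
                        ga = None
                    try:
                        ia = identified_accuracy(summary)
                    except ValueError:
                        ia = None
                    shares: dict[str, float] = {}
                    for lab in dict.fromkeys(truths):
                        ids = [p for p, t in zip(preds, truths) if t == lab]
                        n_id = sum(p.confidence == "Identified" for p in ids)
                        shares[lab] = 100 * n_id / len(ids)
                    results[s] = ModelResult(
                        s, summary, ga, ia, identified_share_by_class=shares
                    )
                except Exception as exc:
                    results[s] = ModelResult(s, None, None, None, True, f"classification failed: {exc}")
        logger.info("grid: finished window length %d", w)

    return filter_models([results[s] for s in settings])


def filter_models(results: list[ModelResult], per_class: bool = False) -> list[ModelResult]:
    """Apply the exclusion rules and rank the survivors.

    A model is marked excluded (never deleted — its summary is untouched)
    when more than 50% of its outputs are Unknown or when its Identified
    share is below 25%.  ``per_class`` applies the 25% rule to each true
    class instead of the model as a whole (a stricter reading).  Survivors
    are ranked by General Accuracy, then Identified Accuracy.
    """
    out: list[ModelResult] = []
    for r in results:
        r = replace(r)
        if r.summary is not None and not r.excluded:
            if r.summary.pct_unknown > UNKNOWN_LIMIT_PCT:
                r.excluded = True
                r.reason = f"Unknown share {r.summary.pct_unknown:.1f}% > {UNKNOWN_LIMIT_PCT:.0f}%"
            elif per_class and r.identified_share_by_class is not None:
                low = {c: s for c, s in r.identified_share_by_class.items() if s < MIN_IDENTIFIED_PCT}
                if low:
                    r.excluded = True
                    r.reason = f"per-class Identified share < {MIN_IDENTIFIED_PCT:.0f}% for {sorted(low)}"
            elif r.summary.pct_identified < MIN_IDENTIFIED_PCT:
                r.excluded = True
                r.reason = f"Identified share {r.summary.pct_identified:.1f}% < {MIN_IDENTIFIED_PCT:.0f}%"
        out.append(r)

    def sort_key(r: ModelResult):
        ga = r.general_accuracy if r.general_accuracy is not None else -1.0
        ia = r.identified_accuracy if r.identified_accuracy is not None else -1.0
        return (-ga, -ia)

    kept = sorted([r for r in out if not r.excluded], key=sort_key)
    return kept + [r for r in out if r.excluded]


def results_table(results: list[ModelResult]) -> pd.DataFrame:
    """Ranked table mirroring the published layout."""
    interp_tags = {"dominant": "D", "best_match": "BM", "unanimous": "U"}
    rows = []
    for r in results:
        s = r.summary
        if r.setting.method == "KNN":
            method, interp = f"KNN-{r.setting.k}", "D"
        else:
            method = "RBF"
            interp = (
                f"MC-{r.setting.min_consensus}"
                if r.setting.interpreter == "min_consensus"
                else interp_tags[r.setting.interpreter]
            )
        rows.append(
            {
                "#pts": r.setting.w,
                "Standard.": r.setting.scheme,
                "Method": method,
                "Interpreter": interp,
                "CorrectID": None if s is None else round(s.pct_correct_identified, 1),
                "CorrectUnclear": None if s is None else round(s.pct_correct_unclear, 1),
                "IncorrectID": None if s is None else round(s.pct_incorrect_identified, 1),
                "IncorrectUnclear": None if s is None else round(s.pct_incorrect_unclear, 1),
                "Unknown": None if s is None else round(s.pct_unknown, 1),
                "AccAll": None if r.general_accuracy is None else round(r.general_accuracy, 1),
                "AccID": None if r.identified_accuracy is None else round(r.identified_accuracy, 1),
                "Excluded": r.excluded,
                "Reason": r.reason or "",
            }
        )
    return pd.DataFrame(rows)


def confusion_by_class(
    predictions: list[Classification], truths: list[str]
) -> pd.DataFrame:
    """Per-true-label outcome percentages with misclassification destinations.

    One row per true label; columns: ``correct`` (labelled with the truth,
    any confidence), ``unknown``, and ``to_<label>`` for each wrong
    destination.  Values are percentages of that true label's windows.
    """
    if not predictions:
        raise ValueError("no predictions")
    labels = list(dict.fromkeys(truths))
    rows = {}
    for true_label in labels:
        idx = [i for i, t in enumerate(truths) if t == true_label]
        n = len(idx)
        row = {"correct": 0.0, "unknown": 0.0}
        row.update({f"to_{lab}": 0.0 for lab in labels if lab != true_label})
        for i in idx:
            pred = predictions[i]
            if pred.confidence == "Unknown" or pred.label is None:
                row["unknown"] += 100 / n
            elif pred.label == true_label:
                row["correct"] += 100 / n
            else:
                row.setdefault(f"to_{pred.label}", 0.0)
                row[f"to_{pred.label}"] += 100 / n
        rows[true_label] = row
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def subset_experiment(experiment: ExperimentData, drop_labels: set[str]) -> ExperimentData:
    """Remove whole treatments (e.g. drop DNT and petroleum to retrain the
    classifier on the four well-separated classes)."""
    remaining = [t for t in experiment.treatments if t not in drop_labels]
    if len(remaining) < 2:
        raise ValueError(
            f"dropping {sorted(drop_labels)} leaves {len(remaining)} treatment(s); need >= 2"
        )
    return experiment.subset(remaining)
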