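"""Input-scaling schemes for the classifier.

Four schemes are compared: ``raw`` (no scaling), ``all`` (one z-score over
every voltage value), ``per_compound`` (a z-score per treatment label), and
``control`` (every value scaled by the control group's mean and SD).  The
control-referenced scheme deliberately does not yield overall mean 0 / SD 1:
treated groups are expressed in units of control variability, which can make
compound effects more distinct to the classifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .windows import Window, WindowedDataset

__all__ = ["SCHEMES", "Standardizer", "fit_standardizer", "apply_standardizer"]

SCHEMES = ("raw", "all", "per_compound", "control")

_POOLED = "__all__"  # parameter key for schemes with a single group


def _fingerprint(dataset: WindowedDataset) -> str:
    h = hashlib.sha1()
    h.update(dataset.matrix().tobytes())
    h.update("|".join(dataset.labels()).encode())
    return h.hexdigest()[:12]


@dataclass
class Standardizer:
    """Fitted affine value transform v -> (v - mean_g) / sd_g.

    ``parameters`` maps the grouping key (treatment label, or a pooled key
    for the ``all``/``control`` schemes) to (mean, sd) in mV.  ``raw`` stores
    nothing and is the identity.
    """

    scheme: str
    parameters: dict[str, tuple[float, float]] = field(default_factory=dict)
    fitted_on: str = ""
    ddof: int = 1

    def _params_for(self, label: str) -> tuple[float, float]:
        if self.scheme in ("all", "control"):
            return self.parameters[_POOLED]
        if label not in self.parameters:
            raise KeyError(
                f"no standardization parameters for label {label!r} "
                f"(scheme={self.scheme}); fitted labels: {sorted(self.parameters)}"
            )
        return self.parameters[label]

    def transform(self, values: np.ndarray, label: str) -> np.ndarray:
        if self.scheme == "raw":
            return np.asarray(values, dtype=float)
        mean, sd = self._params_for(label)
        return (np.asarray(values, dtype=float) - mean) / sd

    def inverse(self, values: np.ndarray, label: str) -> np.ndarray:
        if self.scheme == "raw":
            return np.asarray(values, dtype=float)
        mean, sd = self._params_for(label)
        return np.asarray(values, dtype=float) * sd + mean

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "parameters": {k: list(v) for k, v in self.parameters.items()},
                "fitted_on": self.fitted_on,
                "ddof": self.ddof,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Standardizer":
        d = json.loads(text)
        return cls(
            scheme=d["scheme"],
            parameters={k: (float(v[0]), float(v[1])) for k, v in d["parameters"].items()},
            fitted_on=d.get("fitted_on", ""),
            ddof=int(d.get("ddof", 1)),
        )


def _mean_sd(values: np.ndarray, ddof: int, group: str) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=ddof))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(f"zero variance in standardization group {group!r}")
    return mean, sd


def fit_standardizer(
    train: WindowedDataset,
    scheme: str,
    ddof: int = 1,
    control_label: str = "control",
) -> Standardizer:
    """Fit scaling parameters on the training windows.

    ``all``: pooled mean/SD over every value.  ``per_compound``: mean/SD per
    treatment label.  ``control``: mean/SD of control-labelled windows only,
    applied to every label.  ``raw``: identity.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if len(train) == 0:
        raise ValueError("cannot fit a standardizer on an empty dataset")

    params: dict[str, tuple[float, float]] = {}
    if scheme == "all":
        params[_POOLED] = _mean_sd(train.matrix().ravel(), ddof, "all")
    elif scheme == "per_compound":
        mat, labels = train.matrix(), np.asarray(train.labels())
        for label in train.label_set:
            params[label] = _mean_sd(mat[labels == label].ravel(), ddof, label)
    elif scheme == "control":
        mat, labels = train.matrix(), np.asarray(train.labels())
        values = mat[labels == control_label]
        if values.size == 0:
            raise ValueError(
                f"scheme 'control' requires windows labelled {control_label!r}"
            )
        params[_POOLED] = _mean_sd(values.ravel(), ddof, control_label)

    return Standardizer(scheme, params, fitted_on=_fingerprint(train), ddof=ddof)


def apply_standardizer(dataset: WindowedDataset, std: Standardizer) -> WindowedDataset:
    """Transform every window's values; the dataset's scheme tag is updated."""
    if std.scheme == "per_compound":
        missing = set(dataset.label_set) - set(std.parameters)
        if missing:
            raise KeyError(
                f"per_compound standardizer has no parameters for labels {sorted(missing)}"
            )
    windows = [
        Window(std.transform(win.values, win.label), win.label, win.source_id, win.start_index)
        for win in dataset.windows
    ]
    return WindowedDataset(
        windows, dataset.w, standardization=std.scheme,
        observation_window=dataset.observation_window,
    )
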