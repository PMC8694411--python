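"""Software emulation of the NM500 neuromorphic classifier.

The NM500 chip classifies a fixed-length input vector with a bank of
prototype neurons.  Each neuron stores a prototype vector, a category and an
active influence field (AIF) radius; a neuron *fires* when the distance
between the input and its prototype is below its AIF.  Two methods are
emulated:

* **RBF** — the restricted-Coulomb-energy (RCE) network.  Training commits a
  new neuron whenever no correct-category neuron fires for an input, and
  shrinks the field of any wrong-category neuron that fires.  At recognition
  time the fired set determines both a label and a confidence: *Identified*
  (all fired neurons agree), *Uncertain* (disagreement) or *Unknown*
  (nothing fired — no classification is given).
* **KNN** — every training vector becomes a neuron, every neuron fires, and
  the k nearest neighbours vote; *Unknown* is impossible by construction.

Four interpreters turn the fired set into a single label: Dominant
(plurality), Best Match (nearest fired neuron), Unanimous (Uncertain
re-binned to Unknown) and Minimum Consensus (plurality must have at least m
agreeing neurons).

Distances default to the chip's L1 norm; an L-infinity option and an 8-bit
component quantization mode (hardware fidelity) are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .windows import WindowedDataset

__all__ = [
    "CONFIDENCES",
    "INTERPRETERS",
    "Neuron",
    "RCEConfig",
    "Classification",
    "RCEModel",
    "distance",
    "default_rce_config",
    "train_rbf",
    "classify_rbf",
    "train_knn",
    "classify_knn",
    "classify_dataset",
    "model_to_json",
    "model_from_json",
]

CONFIDENCES = ("Identified", "Uncertain", "Unknown")
INTERPRETERS = ("dominant", "best_match", "unanimous", "min_consensus")


@dataclass
class RCEConfig:
    """Distance and influence-field configuration.

    ``max_if`` is both the initial field of an unopposed neuron and the
    ceiling for any field; ``min_if`` is the floor (> 0, so a committed
    prototype always fires on itself).  ``quant_range`` gives the (lo, hi)
    value range mapped onto integers 0-255 when ``quantize_8bit`` is set;
    training fills it from the data if left unset.
    """

    distance: str = "L1"  # "L1" or "Linf"
    max_if: float = 1.0
    min_if: float = 1e-3
    max_epochs: int = 20
    max_neurons: int = 4096
    quantize_8bit: bool = False
    quant_range: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.distance not in ("L1", "Linf"):
            raise ValueError(f"distance must be 'L1' or 'Linf', got {self.distance!r}")
        if not 0 < self.min_if <= self.max_if:
            raise ValueError(
                f"need 0 < min_if <= max_if, got min_if={self.min_if}, max_if={self.max_if}"
            )
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class Neuron:
    prototype: np.ndarray
    category: str
    aif: float
    committed_at: int  # training step at which the neuron was committed

    def __post_init__(self) -> None:
        self.prototype = np.asarray(self.prototype, dtype=float)


@dataclass
class Classification:
    """Outcome for one input: label (None when Unknown), confidence bin,
    the fired neurons as (index, distance) sorted by ascending distance,
    and the interpreter that produced the label."""

    label: str | None
    confidence: str
    fired: list[tuple[int, float]]
    interpreter: str


@dataclass
class RCEModel:
    neurons: list[Neuron]
    config: RCEConfig
    method: str  # "RBF" or "KNN"
    w: int
    label_set: tuple[str, ...]

    def prototype_matrix(self) -> np.ndarray:
        if not self.neurons:
            return np.empty((0, self.w))
        return np.vstack([n.prototype for n in self.neurons])

    def aif_vector(self) -> np.ndarray:
        return np.array([n.aif for n in self.neurons])

    def categories(self) -> list[str]:
        return [n.category for n in self.neurons]


def _quantize(x: np.ndarray, quant_range: tuple[float, float]) -> np.ndarray:
    lo, hi = quant_range
    if hi <= lo:
        raise ValueError("quant_range must satisfy lo < hi")
    scaled = np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return np.rint(scaled * 255.0)


def _prepare(x: np.ndarray, config: RCEConfig) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if config.quantize_8bit:
        if config.quant_range is None:
            raise ValueError("quantize_8bit requires quant_range to be set")
        x = _quantize(x, config.quant_range)
    return x


def distance(a: np.ndarray, b: np.ndarray, config: RCEConfig | None = None) -> float:
    """L1 (default) or L-infinity distance, with optional 8-bit quantization."""
    if config is None:
        config = RCEConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a, b = _prepare(a, config), _prepare(b, config)
    diff = np.abs(a - b)
    return float(diff.max()) if config.distance == "Linf" else float(diff.sum())


def _row_distances(protos: np.ndarray, x: np.ndarray, config: RCEConfig) -> np.ndarray:
    diff = np.abs(protos - x)
    return diff.max(axis=1) if config.distance == "Linf" else diff.sum(axis=1)


def default_rce_config(train: WindowedDataset, seed: int = 0, **overrides) -> RCEConfig:
    """Scale-adaptive defaults: ``max_if`` is the 95th percentile of pairwise
    training-window distances (estimated from a sample when the set is
    large); ``min_if`` is 1e-3 of that."""
    cfg = RCEConfig(**{k: v for k, v in overrides.items() if k not in ("max_if", "min_if")})
    mat = train.matrix()
    n = len(mat)
    if n < 2:
        raise ValueError("need at least two training windows to scale the influence field")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(n, 400), replace=False)
    sample = mat[idx]
    if cfg.quantize_8bit and cfg.quant_range is None:
        cfg.quant_range = (float(mat.min()), float(mat.max()))
    if cfg.quantize_8bit:
        sample = _quantize(sample, cfg.quant_range)
    diffs = np.abs(sample[:, None, :] - sample[None, :, :])
    d = diffs.max(axis=2) if cfg.distance == "Linf" else diffs.sum(axis=2)
    tri = d[np.triu_indices(len(sample), k=1)]
    max_if = float(np.percentile(tri, 95))
    if max_if <= 0:
        max_if = 1.0
    cfg.max_if = overrides.get("max_if", max_if)
    cfg.min_if = overrides.get("min_if", 1e-3 * cfg.max_if)
    cfg.validate()
    return cfg


def train_rbf(
    train: WindowedDataset,
    config: RCEConfig | None = None,
    shuffle_seed: int = 0,
) -> RCEModel:
    """Train a restricted-Coulomb-energy prototype network.

    Training vectors are presented in a seeded random order, repeatedly:
    for each input (i) every currently firing wrong-category neuron shrinks
    its field to max(min_if, distance-to-input); (ii) if no correct-category
    neuron fires, a new neuron is committed at the input, its field clamped
    to the distance of the nearest different-category prototype.  Epochs
    repeat until one passes with no commitment and no field reduction, or
    ``max_epochs`` is reached.  Fields never grow.
    """
    if len(train) == 0:
        raise ValueError("cannot train on an empty dataset")
    if config is None:
        config = default_rce_config(train, seed=shuffle_seed)
    config.validate()
    if config.quantize_8bit and config.quant_range is None:
        mat = train.matrix()
        config = replace(config, quant_range=(float(mat.min()), float(mat.max())))

    X = np.vstack([_prepare(w.values, config) for w in train.windows])
    labels = train.labels()
    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(len(X))

    protos: list[np.ndarray] = []
    aifs: list[float] = []
    cats: list[str] = []
    committed_at: list[int] = []
    step = 0

    for epoch in range(config.max_epochs):
        changed = False
        for i in order:
            x, c = X[i], labels[i]
            step += 1
            if protos:
                P = np.vstack(protos)
                d = _row_distances(P, x, config)
                a = np.asarray(aifs)
                fired = d < a
                cat_arr = np.asarray(cats)
                wrong_fired = fired & (cat_arr != c)
                if wrong_fired.any():
                    for j in np.flatnonzero(wrong_fired):
                        new_aif = min(aifs[j], max(config.min_if, float(d[j])))
                        if new_aif < aifs[j]:
                            aifs[j] = new_aif
                            changed = True
                correct_fired = fired & (cat_arr == c)
                if correct_fired.any():
                    continue
                other = cat_arr != c
                if other.any():
                    aif = float(np.clip(d[other].min(), config.min_if, config.max_if))
                else:
                    aif = config.max_if
            else:
                aif = config.max_if
            if len(protos) >= config.max_neurons:
                raise RuntimeError(
                    f"neuron capacity exceeded ({config.max_neurons}); "
                    f"{len(protos)} neurons committed"
                )
            protos.append(x.copy())
            aifs.append(aif)
            cats.append(c)
            committed_at.append(step)
            changed = True
        if not changed:
            break

    neurons = [
        Neuron(p, c, a, s) for p, c, a, s in zip(protos, cats, aifs, committed_at)
    ]
    return RCEModel(neurons, config, "RBF", train.w, train.label_set)


def _interpret_fired(
    fired_idx: np.ndarray,
    dists: np.ndarray,
    cats: Sequence[str],
    interpreter: str,
    min_consensus: int | None,
) -> Classification:
    """Shared fired-set -> (label, confidence) logic for the RBF method."""
    order = np.argsort(dists[fired_idx], kind="stable")
    fired_sorted = fired_idx[order]
    fired_pairs = [(int(j), float(dists[j])) for j in fired_sorted]

    if len(fired_sorted) == 0:
        return Classification(None, "Unknown", [], interpreter)

    fired_cats = [cats[j] for j in fired_sorted]
    unique = list(dict.fromkeys(fired_cats))
    confidence = "Identified" if len(unique) == 1 else "Uncertain"

    # Dominant label: plurality; ties broken toward the nearest tied neuron.
    counts = {u: fired_cats.count(u) for u in unique}
    top = max(counts.values())
    tied = [u for u in unique if counts[u] == top]
    if len(tied) == 1:
        dominant = tied[0]
    else:
        dominant = next(c for c in fired_cats if c in tied)  # fired_cats is distance-sorted

    if interpreter == "dominant":
        return Classification(dominant, confidence, fired_pairs, interpreter)
    if interpreter == "best_match":
        return Classification(fired_cats[0], confidence, fired_pairs, interpreter)
    if interpreter == "unanimous":
        if confidence == "Identified":
            return Classification(dominant, confidence, fired_pairs, interpreter)
        return Classification(None, "Unknown", fired_pairs, interpreter)
    if interpreter == "min_consensus":
        if min_consensus is None:
            raise ValueError("min_consensus interpreter requires the quorum m")
        if counts[dominant] >= min_consensus:
            return Classification(dominant, confidence, fired_pairs, interpreter)
        return Classification(None, "Unknown", fired_pairs, interpreter)
    raise ValueError(f"unknown interpreter {interpreter!r}; choose from {INTERPRETERS}")


def classify_rbf(
    model: RCEModel,
    x: np.ndarray,
    interpreter: str = "dominant",
    min_consensus: int | None = None,
) -> Classification:
    """Classify one input with the RBF (RCE) method.

    The fired set contains every neuron whose prototype lies within its
    influence field of the input (strict inequality).  Confidence is
    Identified / Uncertain / Unknown depending on agreement within the fired
    set; the interpreter chooses the label.
    """
    if not model.neurons:
        raise ValueError("model has no neurons")
    x = _prepare(np.asarray(x, dtype=float), model.config)
    if len(x) != model.w:
        raise ValueError(f"input length {len(x)} != model window length {model.w}")
    d = _row_distances(model.prototype_matrix(), x, model.config)
    fired_idx = np.flatnonzero(d < model.aif_vector())
    return _interpret_fired(fired_idx, d, model.categories(), interpreter, min_consensus)


def train_knn(train: WindowedDataset, config: RCEConfig | None = None) -> RCEModel:
    """KNN 'training': one neuron per training window; influence fields unused."""
    if len(train) == 0:
        raise ValueError("cannot train on an empty dataset")
    if config is None:
        config = RCEConfig(max_if=np.inf, min_if=1.0)
    if config.quantize_8bit and config.quant_range is None:
        mat = train.matrix()
        config = replace(config, quant_range=(float(mat.min()), float(mat.max())))
    neurons = [
        Neuron(_prepare(w.values, config), w.label, float("inf"), i + 1)
        for i, w in enumerate(train.windows)
    ]
    return RCEModel(neurons, config, "KNN", train.w, train.label_set)


def classify_knn(model: RCEModel, x: np.ndarray, k: int) -> Classification:
    """Classify one input by its k nearest training neurons.

    All neurons fire, so the confidence is Identified when all k neighbours
    agree and Uncertain otherwise — never Unknown.  Ties at the k-th distance
    are broken by training order; a tied plurality goes to the category of
    the nearest neuron among the tied categories.
    """
    if not model.neurons:
        raise ValueError("model has no neurons")
    if not 1 <= k <= len(model.neurons):
        raise ValueError(f"k={k} out of range for {len(model.neurons)} neurons")
    x = _prepare(np.asarray(x, dtype=float), model.config)
    if len(x) != model.w:
        raise ValueError(f"input length {len(x)} != model window length {model.w}")
    d = _row_distances(model.prototype_matrix(), x, model.config)
    order = np.argsort(d, kind="stable")  # stable sort = training-order tie break
    top = order[:k]
    cats = model.categories()
    top_cats = [cats[j] for j in top]
    unique = list(dict.fromkeys(top_cats))
    counts = {u: top_cats.count(u) for u in unique}
    best = max(counts.values())
    tied = [u for u in unique if counts[u] == best]
    label = tied[0] if len(tied) == 1 else next(c for c in top_cats if c in tied)
    confidence = "Identified" if len(unique) == 1 else "Uncertain"
    fired = [(int(j), float(d[j])) for j in top]
    return Classification(label, confidence, fired, "dominant")


def classify_dataset(
    model: RCEModel,
    dataset: WindowedDataset,
    interpreter: str = "dominant",
    min_consensus: int | None = None,
    k: int | None = None,
) -> list[Classification]:
    """Classify every window in a dataset (vectorised distance computation)."""
    if model.method == "KNN":
        if k is None:
            raise ValueError("KNN classification requires k")
        return [classify_knn(model, w.values, k) for w in dataset.windows]

    X = np.vstack([_prepare(w.values, model.config) for w in dataset.windows])
    P = model.prototype_matrix()
    aifs = model.aif_vector()
    cats = model.categories()
    diff = np.abs(X[:, None, :] - P[None, :, :])
    D = diff.max(axis=2) if model.config.distance == "Linf" else diff.sum(axis=2)
    out = []
    for row in range(len(X)):
        fired_idx = np.flatnonzero(D[row] < aifs)
        out.append(_interpret_fired(fired_idx, D[row], cats, interpreter, min_consensus))
    return out


def model_to_json(model: RCEModel) -> str:
    """Serialize a trained model (bit-exact float round trip via repr)."""
    return json.dumps(
        {
            "method": model.method,
            "w": model.w,
            "label_set": list(model.label_set),
            "config": {
                "distance": model.config.distance,
                "max_if": model.config.max_if,
                "min_if": model.config.min_if,
                "max_epochs": model.config.max_epochs,
                "max_neurons": model.config.max_neurons,
                "quantize_8bit": model.config.quantize_8bit,
                "quant_range": list(model.config.quant_range)
                if model.config.quant_range
                else None,
            },
            "neurons": [
                {
                    "prototype": n.prototype.tolist(),
                    "category": n.category,
                    "aif": n.aif if np.isfinite(n.aif) else "inf",
                    "committed_at": n.committed_at,
                }
                for n in model.neurons
            ],
        }
    )


def model_from_json(text: str) -> RCEModel:
    d = json.loads(text)
    cfg = d["config"]
    config = RCEConfig(
        distance=cfg["distance"],
        max_if=cfg["max_if"],
        min_if=cfg["min_if"],
        max_epochs=cfg["max_epochs"],
        max_neurons=cfg["max_neurons"],
        quantize_8bit=cfg["quantize_8bit"],
        quant_range=tuple(cfg["quant_range"]) if cfg["quant_range"] else None,
    )
    neurons = [
        Neuron(
            np.array(n["prototype"], dtype=float),
            n["category"],
            float("inf") if n["aif"] == "inf" else float(n["aif"]),
            int(n["committed_at"]),
        )
        for n in d["neurons"]
    ]
    return RCEModel(neurons, config, d["method"], int(d["w"]), tuple(d["label_set"]))
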