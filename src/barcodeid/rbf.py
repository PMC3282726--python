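"""Exact-interpolation radial-basis-function network for species assignment.

One Gaussian hidden unit is placed on every (deduplicated) training vector,
so the linear output layer can reproduce the one-hot species targets with
zero error on the training set.  Classification of a query is competitive:
the species with the largest output score wins.

Hidden unit j responds as ``exp(-(b * ||x - c_j||)^2)`` with
``b = sqrt(ln 2) / spread``, so the activation falls to 0.5 exactly at
distance ``spread`` from the center — ``spread`` is the radius of the input
region each unit responds to.  Features are standardized with training-set
statistics before anything else, so the default ``spread`` = 1.0 is on the
scale of one feature standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InterpolationError


def one_hot_targets(labels: list[str], index: list[str]) -> np.ndarray:
    """One-hot target rows: row i has a single 1 at index.index(labels[i])."""
    pos = {s: k for k, s in enumerate(index)}
    try:
        cols = [pos[lab] for lab in labels]
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in species index") from None
    t = np.zeros((len(labels), len(index)))
    t[np.arange(len(labels)), cols] = 1.0
    return t


@dataclass
class RbfModel:
    """A trained exact-interpolation RBF network."""

    centers: np.ndarray          # (m, d) standardized training vectors
    spread: float
    output_weights: np.ndarray   # (n_species, m)
    output_biases: np.ndarray    # (n_species,)
    species_index: list[str]     # canonical (sorted) species order
    feature_center: np.ndarray   # (d,) training-set mean
    feature_scale: np.ndarray    # (d,) training-set std (zeros -> 1)

    @property
    def hidden_bias(self) -> float:
        return math.sqrt(math.log(2.0)) / self.spread

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.feature_center) / self.feature_scale

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "spread": self.spread,
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
            "species_index": self.species_index,
            "feature_center": self.feature_center.tolist(),
            "feature_scale": self.feature_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RbfModel":
        return cls(
            centers=np.array(d["centers"]),
            spread=float(d["spread"]),
            output_weights=np.array(d["output_weights"]),
            output_biases=np.array(d["output_biases"]),
            species_index=list(d["species_index"]),
            feature_center=np.array(d["feature_center"]),
            feature_scale=np.array(d["feature_scale"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RbfModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def hidden_activations(model: RbfModel, x: np.ndarray) -> np.ndarray:
    """Gaussian hidden-layer response to raw feature vector(s) ``x``.

    Accepts a single vector or a stack of rows; standardization is applied
    internally with the model's training statistics.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[1]}")
    z = model.standardize(x)
    diff = z[:, None, :] - model.centers[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    act = np.exp(-((model.hidden_bias * dist) ** 2))
    return act[0] if single else act


def _deduplicate(features: np.ndarray, labels: list[str]):
    """Collapse identical feature rows with identical labels; error if two
    identical rows carry different labels (exact interpolation impossible)."""
    seen: dict[bytes, tuple[int, str]] = {}
    keep: list[int] = []
    for i, row in enumerate(features):
        key = row.tobytes()
        if key in seen:
            j, lab = seen[key]
            if lab != labels[i]:
                raise InterpolationError(
                    f"training vectors {j} and {i} are identical but labeled "
                    f"{lab!r} vs {labels[i]!r}"
                )
        else:
            seen[key] = (i, labels[i])
            keep.append(i)
    return features[keep], [labels[i] for i in keep]


def train_rbf(
    features: np.ndarray,
    labels: list[str],
    spread: float = 1.0,
    ridge: float = 0.0,
) -> RbfModel:
    """Train the network: one center per training vector, least-squares output.

    The output layer solves ``[activations | 1] @ [W b]^T = targets`` by
    minimum-norm least squares, which reproduces the one-hot targets exactly
    (the Gaussian interpolation matrix on distinct centers is nonsingular).

    ``ridge`` adds Tikhonov damping to the output-layer solve.  The default 0
    keeps exact interpolation; a small positive value tames the large
    canceling weights that near-duplicate centers induce (their far-field
    lobes can overrule genuine activations) at the cost of no-longer-exact
    target reproduction.  Training-set *classification* stays at 100% for
    small ridge values either way.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        raise ValueError("need at least one training vector")
    if features.shape[0] != len(labels):
        raise ValueError("features and labels disagree in length")
    features, labels = _deduplicate(features, labels)
    center = features.mean(axis=0)
    scale = features.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    species_index = sorted(set(labels))
    model = RbfModel(
        centers=(features - center) / scale,
        spread=float(spread),
        output_weights=np.zeros((len(species_index), features.shape[0])),
        output_biases=np.zeros(len(species_index)),
        species_index=species_index,
        feature_center=center,
        feature_scale=scale,
    )
    phi = hidden_activations(model, features)  # (n, m) with n == m
    design = np.column_stack((phi, np.ones(phi.shape[0])))
    targets = one_hot_targets(labels, species_index)
    if ridge > 0:
        design = np.vstack((design, math.sqrt(ridge) * np.eye(design.shape[1])))
        targets = np.vstack((targets, np.zeros((design.shape[1], targets.shape[1]))))
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)  # (m+1, n_species)
    model.output_weights = coef[:-1].T
    model.output_biases = coef[-1]
    return model


def output_scores(model: RbfModel, x: np.ndarray) -> np.ndarray:
    """Output-layer scores W @ h(x) + b for vector(s) ``x``."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    act = np.atleast_2d(hidden_activations(model, np.atleast_2d(x)))
    scores = act @ model.output_weights.T + model.output_biases
    return scores[0] if single else scores


def predict(model: RbfModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one feature vector: (species, score vector).

    Ties in the competitive argmax go to the earliest species in the
    canonical species index.
    """
    scores = output_scores(model, np.asarray(x, dtype=float))
    return model.species_index[int(np.argmax(scores))], scores


def predict_batch(model: RbfModel, x: np.ndarray) -> list[str]:
    """Classify a stack of feature vectors."""
    scores = output_scores(model, np.atleast_2d(np.asarray(x, dtype=float)))
    return [model.species_index[int(k)] for k in np.argmax(scores, axis=1)]


def training_accuracy(model: RbfModel, features: np.ndarray, labels: list[str]) -> float:
    """Fraction of training vectors the model assigns to their own species."""
    pred = predict_batch(model, features)
    return float(np.mean([p == t for p, t in zip(pred, labels)]))
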