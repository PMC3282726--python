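"""High-level model interface: build an identifier from a reference library,
fit it, inspect it, classify queries.

`SpeciesIdentificationModel` holds the reference dataset and the pipeline
configuration (encoder, RBF spread, PCA threshold); `fit()` encodes the
library, fits the PCA reduction where applicable, trains the RBF network and
returns a `SpeciesIdentificationResults` carrying the fitted components, the
training diagnostics and prediction methods.  The whole fitted pipeline
round-trips through a single JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import fj, rbf
from .evaluate import ENCODERS, encode_features
from .io import Dataset, read_fasta


class SpeciesIdentificationModel:
    """Alignment-free species identifier built from a labeled reference library.

    Parameters
    ----------
    dataset
        Labeled reference records (every record needs a species label).
    encoder
        "dv" for the 24-component dual-vector characterization, "fj" for the
        5-component tetrahedral chaos-game characterization (PCA-reduced).
    spread
        Radius, in standardized-feature units, at which a hidden unit's
        Gaussian response falls to one half.
    pca_threshold
        Minimum explained-variance ratio for a principal component to be
        retained (FJ encoder only).
    """

    def __init__(
        self,
        dataset: Dataset,
        encoder: str = "dv",
        spread: float = 1.0,
        pca_threshold: float = 0.01,
        ridge: float = 0.0,
    ):
        if encoder not in ENCODERS:
            raise ValueError(f"encoder must be one of {ENCODERS}")
        labels = [rec.species for rec in dataset]
        if any(lab is None for lab in labels):
            raise ValueError("every reference record needs a species label")
        if len(dataset) == 0:
            raise ValueError("reference dataset is empty")
        self.dataset = dataset
        self.encoder = encoder
        self.spread = float(spread)
        self.pca_threshold = float(pca_threshold)
        self.ridge = float(ridge)

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "SpeciesIdentificationModel":
        return cls(read_fasta(path, require_labels=True), **kwargs)

    def fit(self) -> "SpeciesIdentificationResults":
        raw = encode_features([rec.sequence for rec in self.dataset], self.encoder)
        pca = None
        feats = raw
        if self.encoder == "fj" and raw.shape[0] >= 2:
            pca = fj.fit_pca(raw, threshold=self.pca_threshold)
            feats = pca.transform(raw)
        labels = [rec.species for rec in self.dataset]
        network = rbf.train_rbf(feats, labels, spread=self.spread, ridge=self.ridge)
        train_acc = rbf.training_accuracy(network, feats, labels)
        return SpeciesIdentificationResults(self, network, pca, train_acc)


class SpeciesIdentificationResults:
    """A fitted identification pipeline."""

    def __init__(
        self,
        model: SpeciesIdentificationModel | None,
        network: rbf.RbfModel,
        pca: fj.PcaTransform | None,
        training_accuracy: float,
        encoder: str | None = None,
        spread: float | None = None,
        pca_threshold: float | None = None,
    ):
        self.model = model
        self.network = network
        self.pca = pca
        self.training_accuracy = training_accuracy
        self.encoder = encoder if encoder is not None else model.encoder
        self.spread = spread if spread is not None else model.spread
        self.pca_threshold = (
            pca_threshold if pca_threshold is not None else model.pca_threshold
        )

    @property
    def species_index(self) -> list[str]:
        return self.network.species_index

    def _features(self, sequences: list[str]) -> np.ndarray:
        feats = encode_features(sequences, self.encoder)
        if self.pca is not None:
            feats = self.pca.transform(feats)
        return feats

    def predict(self, sequences: str | list[str]) -> str | list[str]:
        """Assign sequence(s) to species by the competitive output."""
        single = isinstance(sequences, str)
        feats = self._features([sequences] if single else list(sequences))
        pred = rbf.predict_batch(self.network, feats)
        return pred[0] if single else pred

    def predict_scores(self, sequences: list[str]) -> np.ndarray:
        """Raw output-layer scores, one row per sequence, columns in
        ``species_index`` order."""
        return rbf.output_scores(self.network, self._features(list(sequences)))

    def summary(self) -> str:
        n_ref = self.network.centers.shape[0]
        lines = [
            "Species identification model",
            "=" * 46,
            f"encoder:               {self.encoder}",
            f"hidden units:          {n_ref}",
            f"feature dimension:     {self.network.n_features}",
            f"species:               {len(self.species_index)}",
            f"spread:                {self.spread:g}",
            f"training accuracy:     {self.training_accuracy:.2%}",
        ]
        if self.pca is not None:
            ratios = ", ".join(f"{r:.3f}" for r in self.pca.explained_variance_ratio)
            lines.append(f"PCA components kept:   {self.pca.n_components}")
            lines.append(f"explained var ratios:  {ratios}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        doc = {
            "encoder": self.encoder,
            "spread": self.spread,
            "pca_threshold": self.pca_threshold,
            "training_accuracy": self.training_accuracy,
            "network": self.network.to_dict(),
            "pca": None if self.pca is None else self.pca.to_dict(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "SpeciesIdentificationResults":
        doc = json.loads(Path(path).read_text())
        return cls(
            model=None,
            network=rbf.RbfModel.from_dict(doc["network"]),
            pca=None if doc["pca"] is None else fj.PcaTransform.from_dict(doc["pca"]),
            training_accuracy=doc["training_accuracy"],
            encoder=doc["encoder"],
            spread=doc["spread"],
            pca_threshold=doc["pca_threshold"],
        )
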