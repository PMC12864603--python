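"""Scikit-learn style estimators for antioxidant-peptide classification.

:class:`AntioxidantPeptideClassifier` wraps the full fused model (or a
single-view ablation) behind ``fit`` / ``predict`` / ``predict_proba`` so it
composes with scikit-learn pipelines, cloning and model selection.  ``X`` is
a sequence of peptide strings (or a :class:`~aopfusion.data.DatasetManifest`).

:class:`CompositionLogisticClassifier` is a cheap linear baseline on amino
acid composition, useful wherever a fast reference model is needed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .chem import GraphCache
from .data import AMINO_ACIDS, DatasetManifest, PeptideRecord, validate_records
from .model import (FusionConfig, FusionModel, TrainConfig, predict as
                    model_predict, train as model_train)

#: Reduced optimization settings for desk-scale experiments on synthetic
#: data (the full-scale defaults, lr 1e-5 over up to 300 epochs, are sized
#: for the real benchmark corpora).
DESK_TRAINING = dict(learning_rate=1e-3, max_epochs=20, patience=4)


def _as_manifest(X, y=None, name="data") -> DatasetManifest:
    if isinstance(X, DatasetManifest):
        return X
    records = [PeptideRecord(id=str(i), sequence=s,
                             label=None if y is None else int(y[i]))
               for i, s in enumerate(X)]
    return DatasetManifest(validate_records(records), name=name)


class AntioxidantPeptideClassifier(ClassifierMixin, BaseEstimator):
    """Binary antioxidant-activity classifier over peptide sequences.

    Parameters mirror the tuned training configuration; ``view`` selects the
    fused model or a single-view ablation, ``fusion`` the integration
    strategy.  After ``fit`` the trained weights live in ``model_`` and the
    per-epoch log in ``history_``.
    """

    def __init__(self, view: str = "fused", fusion: str = "hierarchical",
                 learning_rate: float = 1e-5, weight_decay: float = 3e-3,
                 dropout: float = 0.2, batch_size: int = 64,
                 max_epochs: int = 300, patience: int = 30,
                 validation_fraction: float = 0.1, seed: int = 0,
                 dtype: str = "float32"):
        self.view = view
        self.fusion = fusion
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.dtype = dtype

    # -- internal ------------------------------------------------------
    def _split_validation(self, manifest: DatasetManifest):
        if not self.validation_fraction:
            return manifest, None
        rng = np.random.Generator(np.random.PCG64(self.seed + 1))
        labels = manifest.labels()
        valid_idx: list[int] = []
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            take = int(round(len(idx) * self.validation_fraction))
            valid_idx.extend(idx[:take])
        valid_set = set(valid_idx)
        train_idx = [i for i in range(len(manifest)) if i not in valid_set]
        return (manifest.subset(train_idx, name="fit_train"),
                manifest.subset(sorted(valid_set), name="fit_valid"))

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y=None):
        manifest = _as_manifest(X, y, name="fit")
        if any(r.label is None for r in manifest.records):
            raise ValueError("fit requires labels for every record")
        self.classes_ = np.array([0, 1])
        train_man, valid_man = self._split_validation(manifest)
        model = FusionModel(view=self.view,
                            fusion=FusionConfig(strategy=self.fusion,
                                                dropout=self.dropout),
                            seed=self.seed, dtype=self.dtype)
        config = TrainConfig(learning_rate=self.learning_rate,
                             weight_decay=self.weight_decay,
                             dropout=self.dropout, batch_size=self.batch_size,
                             max_epochs=self.max_epochs, patience=self.patience,
                             seed=self.seed)
        self.cache_ = GraphCache()
        self.model_, self.history_ = model_train(model, config, train_man,
                                                 valid_man, cache=self.cache_)
        self.n_parameters_ = sum(t.data.size for t in self.model_.params.values())
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        manifest = _as_manifest(X, name="predict")
        preds = model_predict(self.model_, manifest, cache=self.cache_)
        p1 = np.array([p.probability for p in preds])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predictions(self, manifest: DatasetManifest):
        """Full :class:`~aopfusion.model.Prediction` objects for a manifest."""
        check_is_fitted(self, "model_")
        return model_predict(self.model_, manifest, cache=self.cache_)


def composition_features(sequences) -> np.ndarray:
    """Amino-acid composition (20 fractions) per sequence."""
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    out = np.zeros((len(sequences), 20))
    for i, seq in enumerate(sequences):
        for a in seq:
            out[i, index[a]] += 1.0
        out[i] /= max(len(seq), 1)
    return out


class CompositionLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Logistic regression on amino-acid composition; a fast linear baseline."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(self, X, y=None):
        manifest = _as_manifest(X, y)
        self.classes_ = np.array([0, 1])
        self._lr = LogisticRegression(C=self.C, max_iter=1000,
                                      random_state=self.seed)
        feats = composition_features(manifest.sequences())
        # sequence length carries signal too when compositions are close
        lengths = np.array([len(s) for s in manifest.sequences()])[:, None]
        self._lr.fit(np.hstack([feats, lengths / 50.0]), manifest.labels())
        self.fitted_ = True
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "fitted_")
        manifest = _as_manifest(X)
        feats = composition_features(manifest.sequences())
        lengths = np.array([len(s) for s in manifest.sequences()])[:, None]
        return self._lr.predict_proba(np.hstack([feats, lengths / 50.0]))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
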