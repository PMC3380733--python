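"""scikit-learn style estimators wrapping the feature → consensus pipeline.

:class:`QualityFeaturizer` turns a list of spectra into the n x 10 feature
matrix; :class:`ConsensusQualityClassifier` binarizes each feature column at
a percentile, builds the bipartite ensemble graph and solves the consensus
optimization. The classifier is transductive (like a clusterer): call
``fit`` or ``fit_predict`` on the full batch of spectra to be assessed —
the percentile split is defined relative to that batch, so there is no
out-of-batch ``predict``.

    >>> pipe = make_quality_pipeline()
    >>> labels = pipe.fit_predict(spectra)        # 1 = high quality, 0 = poor

Fitted attributes follow sklearn conventions (trailing underscore), and both
estimators support ``get_params`` / ``set_params`` / ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_array, check_is_fitted

from . import consensus as _consensus
from . import ensemble as _ensemble
from .features import MassConstants, compute_feature_matrix
from .spectra import Spectrum


class QualityFeaturizer(TransformerMixin, BaseEstimator):
    """Transform a sequence of :class:`Spectrum` into the 10-feature matrix.

    Parameters
    ----------
    constants : MassConstants, optional
        Mass table, tolerance and pair-sum convention; defaults to the
        monoisotopic table with 0.5 Da tolerance.
    """

    def __init__(self, constants: MassConstants | None = None):
        self.constants = constants

    def fit(self, X, y=None):
        self.n_features_out_ = 10
        return self

    def transform(self, X) -> np.ndarray:
        if not all(isinstance(s, Spectrum) for s in X):
            raise TypeError("QualityFeaturizer expects a sequence of Spectrum")
        c = self.constants if self.constants is not None else MassConstants()
        return compute_feature_matrix(list(X), c).to_numpy()

    def get_feature_names_out(self, input_features=None):
        from .features import FEATURE_NAMES
        return np.asarray(FEATURE_NAMES, dtype=object)


class ConsensusQualityClassifier(BaseEstimator):
    """Unsupervised spectrum-quality classifier via bipartite-graph consensus.

    Each feature column is binarized (top ``percentile`` percent of values
    → high-quality vote), the votes form the bipartite spectrum-group graph,
    and the consensus probabilities are obtained by alternating quadratic
    minimization anchored to the initial group labels with confidence
    ``alpha``.

    Parameters
    ----------
    percentile : float, default 50.0
        Per-feature fraction of spectra voted high quality.
    alpha : float, default 90.0
        Confidence weight on the initial group labels.
    epsilon : float, default 1e-6
        Frobenius-norm stopping tolerance on successive U iterates.
    max_iter : int, default 1000
        Iteration cap (non-convergence is flagged, not raised).
    threshold : float, default 0.5
        Probability cut for the hard high/poor call.

    Attributes
    ----------
    p_high_ : ndarray of shape (n,)
        Probability that each spectrum is high quality.
    labels_ : ndarray of shape (n,)
        Hard calls, 1 = high quality, 0 = poor quality.
    graph_ : EnsembleGraph
        The fitted bipartite graph (A, Y).
    result_ : ConsensusResult
        Full solver output (U, Q, cost trajectory).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, percentile: float = 50.0, alpha: float = 90.0,
                 epsilon: float = 1e-6, max_iter: int = 1000,
                 threshold: float = 0.5):
        self.percentile = percentile
        self.alpha = alpha
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.threshold = threshold

    def fit(self, X, y=None):
        """Run binarization + consensus on the n x m feature matrix X."""
        X = check_array(X, ensure_min_samples=2, ensure_min_features=1)
        assignments = _ensemble.binarize_features(X, self.percentile)
        self.graph_ = _ensemble.build_graph(assignments)
        params = _consensus.ConsensusParams(
            alpha=self.alpha, epsilon=self.epsilon, max_iter=self.max_iter)
        self.result_ = _consensus.solve(self.graph_, params)
        self.p_high_ = self.result_.p_high.copy()
        self.labels_ = (self.p_high_ >= self.threshold).astype(int)
        self.n_iter_ = self.result_.iterations
        self.converged_ = self.result_.converged
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit on X and return the hard calls (1 = high quality)."""
        return self.fit(X).labels_

    def score_samples(self, X=None) -> np.ndarray:
        """Fitted per-spectrum probability of high quality."""
        check_is_fitted(self, "p_high_")
        return self.p_high_


def make_quality_pipeline(constants: MassConstants | None = None,
                          **classifier_params) -> Pipeline:
    """Featurizer + consensus classifier as a single sklearn pipeline."""
    return Pipeline([
        ("features", QualityFeaturizer(constants=constants)),
        ("consensus", ConsensusQualityClassifier(**classifier_params)),
    ])
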