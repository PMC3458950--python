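"""One-class SVM abnormality scoring of coherence features.

A nu-parameterized one-class SVM with an RBF kernel is trained on the
*pooled* feature matrix of two groups treated as a single population
(the mixed-group protocol).  The trained decision function is

    f(v) = sum_i alpha_i k(x_i, v) - rho,     k(u, v) = exp(-gamma ||u-v||^2)

with dual coefficients satisfying sum alpha_i = 1 and
0 <= alpha_i <= 1/(nu n).  The abnormality index of a subject is the
negated decision score, -f(v): high values mean the subject's coherence
spectrum is atypical relative to the pooled sample.  nu upper-bounds the
fraction of training subjects flagged abnormal (negative score) and
lower-bounds the support-vector fraction.

Training in-sample on the mixture of both groups — rather than on one
group — is deliberate: it is symmetric in the groups and so cannot bias
the index toward either of them.

The convex dual program is solved by scikit-learn's ``OneClassSVM``
(libsvm); coefficients are rescaled from libsvm's sum alpha = nu n
convention to sum alpha = 1, and scoring uses this module's own kernel
arithmetic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.svm import OneClassSVM

__all__ = [
    "AnomalyModel",
    "AbnormalityResult",
    "rbf_kernel",
    "default_gamma",
    "train_ocsvm",
    "abnormality_index",
    "mixed_group_protocol",
]

#: Training quantile parameter used by the default pipeline: with two
#: equal-size groups pooled, at most half the sample may be flagged.
DEFAULT_NU = 0.5

#: Solver tolerance; training is deterministic given input order.
SOLVER_TOL = 1e-6


@dataclasses.dataclass
class AnomalyModel:
    """Trained one-class boundary: support vectors, dual weights, offset."""

    support_vectors: np.ndarray  # (n_sv, d)
    alphas: np.ndarray  # (n_sv,), sum to 1, each <= 1/(nu n)
    rho: float
    gamma: float
    nu: float
    n_train: int

    @property
    def dim(self) -> int:
        return self.support_vectors.shape[1]

    def decision_score(self, v: np.ndarray) -> float:
        """sum_i alpha_i k(x_i, v) - rho; negative for abnormal points."""
        v = np.asarray(v, dtype=float).ravel()
        if v.size != self.dim:
            raise ValueError(f"feature dimension {v.size} != model dimension {self.dim}")
        k = np.exp(-self.gamma * np.sum((self.support_vectors - v) ** 2, axis=1))
        return float(self.alphas @ k - self.rho)


@dataclasses.dataclass
class AbnormalityResult:
    """Per-subject abnormality index with its group label attached."""

    subject_id: str
    group: str
    index: float


def rbf_kernel(u, v, gamma: float) -> float:
    """Radial basis function kernel exp(-gamma ||u - v||^2), in (0, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"dimension mismatch: {u.size} vs {v.size}")
    return float(np.exp(-gamma * np.sum((u - v) ** 2)))


def default_gamma(d: int) -> float:
    """Kernel-width heuristic gamma = 1/d for feature dimension d.

    For the default 125-frequency coherence vector this is 1/125.  The
    heuristic is re-applied to the current dimension, so dropping a
    frequency column (relevance analysis) yields 1/124; pass an explicit
    gamma downstream to freeze it instead.
    """
    if d < 1:
        raise ValueError("feature dimension must be >= 1")
    return 1.0 / d


def train_ocsvm(features: np.ndarray, nu: float = DEFAULT_NU, gamma: float | None = None) -> AnomalyModel:
    """Train the nu-one-class SVM on an (n, d) feature matrix.

    Solves the standard dual — minimize (1/2) alpha' K alpha subject to
    0 <= alpha_i <= 1/(nu n), sum alpha_i = 1 — deterministically (no
    random initialization).  ``gamma=None`` applies the 1/d heuristic.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be an (n >= 2, d) matrix")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if not 0.0 < nu < 1.0:
        raise ValueError(f"nu must be in (0, 1), got {nu}")
    if gamma is None:
        gamma = default_gamma(X.shape[1])
    if gamma <= 0:
        raise ValueError("gamma must be > 0")

    n = X.shape[0]
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma, tol=SOLVER_TOL)
    svm.fit(X)
    # libsvm scaling: 0 <= alpha <= 1, sum alpha = nu n, f = K alpha - offset.
    scale = nu * n
    return AnomalyModel(
        support_vectors=svm.support_vectors_.copy(),
        alphas=svm.dual_coef_[0] / scale,
        rho=float(svm.offset_[0]) / scale,
        gamma=gamma,
        nu=nu,
        n_train=n,
    )


def abnormality_index(model: AnomalyModel, v: np.ndarray) -> float:
    """Negated decision score: rho - sum_i alpha_i k(x_i, v).

    Higher values indicate observations that are atypical relative to
    the training population; positive values correspond to points
    outside the learned boundary.
    """
    return -model.decision_score(v)


def mixed_group_protocol(
    features_g1: np.ndarray,
    features_g2: np.ndarray,
    nu: float = DEFAULT_NU,
    gamma: float | None = None,
    *,
    ids_g1=None,
    ids_g2=None,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> tuple[list[AbnormalityResult], AnomalyModel]:
    """Train on the pooled groups and score every subject in-sample.

    Both groups are concatenated into one training sample; the
    abnormality index of each subject is computed from the resulting
    model, and returned with the original group labels attached.  The
    symmetry of this protocol is the bias control: neither group is
    privileged as the "normal" reference.
    """
    A = np.asarray(features_g1, dtype=float)
    B = np.asarray(features_g2, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be nonempty 2-D feature matrices")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimension mismatch between groups: {A.shape[1]} vs {B.shape[1]}"
        )
    ids_g1 = list(ids_g1) if ids_g1 is not None else [f"{group_names[0]}_{i:02d}" for i in range(A.shape[0])]
    ids_g2 = list(ids_g2) if ids_g2 is not None else [f"{group_names[1]}_{i:02d}" for i in range(B.shape[0])]

    X = np.vstack([A, B])
    model = train_ocsvm(X, nu=nu, gamma=gamma)
    labels = [group_names[0]] * A.shape[0] + [group_names[1]] * B.shape[0]
    ids = ids_g1 + ids_g2
    results = [
        AbnormalityResult(subject_id=s, group=g, index=abnormality_index(model, row))
        for s, g, row in zip(ids, labels, X)
    ]
    return results, model
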