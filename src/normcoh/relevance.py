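"""Leave-one-frequency-out relevance of each coherence feature.

The abnormality index is produced by an unsupervised model, so no
feature weighting is available from training itself.  Discriminative
relevance of each frequency is instead measured by ablation: retrain
the mixed-group one-class SVM with that frequency's coherence column
removed and record how the between-group median separation of the
abnormality indices changes.

With Delta = median(case indices) - median(control indices), the default
("drop") convention defines

    relevance_j = Delta_full - Delta_(-j),

the drop in separation caused by excluding frequency j: large positive
values mark frequencies whose presence in training drives the group
difference.  The raw excluded-column separations Delta_(-j) are also
reported (and selectable as the convention), since either reading is
defensible for an ablation measure.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .anomaly import DEFAULT_NU, default_gamma, mixed_group_protocol

__all__ = [
    "RelevanceCurve",
    "median_separation",
    "leave_one_frequency_out",
    "leave_one_out_indices",
]


@dataclasses.dataclass
class RelevanceCurve:
    """Per-frequency discriminative relevance for a two-group contrast."""

    frequencies: np.ndarray
    relevance: np.ndarray  # drop in separation, Delta_full - Delta_(-j)
    excluded_separation: np.ndarray  # raw Delta_(-j)
    baseline_separation: float  # Delta_full

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.relevance = np.asarray(self.relevance, dtype=float)
        self.excluded_separation = np.asarray(self.excluded_separation, dtype=float)
        if not (len(self.frequencies) == len(self.relevance) == len(self.excluded_separation)):
            raise ValueError("frequency and relevance sequences must have equal length")
        if not np.isfinite(self.relevance).all():
            raise ValueError("relevance values must be finite")

    @property
    def peak_frequency(self) -> float:
        """Frequency at which the relevance curve is maximal."""
        return float(self.frequencies[int(np.argmax(self.relevance))])


def median_separation(results) -> float:
    """median(case-group indices) - median(control-group indices).

    ``results`` is a list of :class:`~normcoh.anomaly.AbnormalityResult`;
    the case group is the group of the *first* result (manifest order:
    case group first).
    """
    groups: dict[str, list[float]] = {}
    order: list[str] = []
    for r in results:
        if r.group not in groups:
            groups[r.group] = []
            order.append(r.group)
        groups[r.group].append(r.index)
    if len(order) < 2:
        raise ValueError(f"need two groups for a separation, found {order}")
    g1, g2 = order[0], order[1]
    return float(np.median(groups[g1]) - np.median(groups[g2]))


def leave_one_out_indices(
    features_g1: np.ndarray,
    features_g2: np.ndarray,
    nu: float = DEFAULT_NU,
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Abnormality indices for the full model and each one-column ablation.

    Returns ``(full, ablated)`` where ``full`` has shape (n,) and
    ``ablated`` shape (d, n): row j holds every subject's index when
    frequency column j is excluded from training.  Because mixed-group
    training ignores group labels, these index sets are sufficient to
    evaluate the relevance curve under any relabelling of subjects —
    used by permutation-null tests.

    ``gamma=None`` re-applies the 1/d heuristic at the reduced dimension
    d-1; pass a number to freeze the kernel width instead.
    """
    A = np.asarray(features_g1, dtype=float)
    B = np.asarray(features_g2, dtype=float)
    d = A.shape[1]
    if d < 2:
        raise ValueError("need at least 2 feature columns for leave-one-out")

    res_full, _ = mixed_group_protocol(A, B, nu=nu, gamma=gamma)
    full = np.array([r.index for r in res_full])

    ablated = np.empty((d, full.size))
    keep = np.ones(d, dtype=bool)
    for j in range(d):
        keep[j] = False
        try:
            res_j, _ = mixed_group_protocol(A[:, keep], B[:, keep], nu=nu, gamma=gamma)
        except Exception as exc:
            raise RuntimeError(f"retraining failed with feature column {j} excluded") from exc
        keep[j] = True
        ablated[j] = [r.index for r in res_j]
    return full, ablated


def leave_one_frequency_out(
    features_g1: np.ndarray,
    features_g2: np.ndarray,
    frequencies: np.ndarray,
    nu: float = DEFAULT_NU,
    gamma: float | None = None,
) -> RelevanceCurve:
    """Relevance curve over all frequencies for a two-group contrast.

    Group 1 is the case group (its median enters the separation with a
    plus sign).  Retrains the mixed-group model d + 1 times.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    n1 = np.asarray(features_g1).shape[0]
    if frequencies.size != np.asarray(features_g1).shape[1]:
        raise ValueError("frequency grid length must match the feature dimension")

    full, ablated = leave_one_out_indices(features_g1, features_g2, nu=nu, gamma=gamma)
    delta_full = float(np.median(full[:n1]) - np.median(full[n1:]))
    delta_excl = np.median(ablated[:, :n1], axis=1) - np.median(ablated[:, n1:], axis=1)
    return RelevanceCurve(
        frequencies=frequencies,
        relevance=delta_full - delta_excl,
        excluded_separation=delta_excl,
        baseline_separation=delta_full,
    )
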