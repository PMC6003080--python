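"""Supervised multi-interval discretization (Fayyad-Irani MDL) and information gain.

A continuous feature is recursively split on the cut point that minimizes
the class-entropy of the induced partition; a split is accepted only when
its information gain clears the minimum-description-length penalty

    gain > ( log2(N - 1) + log2(3^k - 2) - [k H(S) - k1 H(S1) - k2 H(S2)] ) / N

with k the number of classes present in the current subset and k1, k2 those
present in each side.  Accepted cuts recurse into both halves.  The
procedure is deterministic: candidate cuts are midpoints between adjacent
distinct sorted values, and ties in entropy are broken toward the lowest
cut value.

Information gain of a feature is then the label-entropy reduction achieved
by binning samples at the accepted cut points; a feature with no accepted
cut has a single bin and exactly zero gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationScheme", "mdlp_discretize", "information_gain", "entropy"]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Accepted cut points for one feature; empty tuple means a single bin."""

    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cut_points, self.cut_points[1:])):
            raise ValueError("cut points must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value: the number of cut points strictly below it."""
        return np.searchsorted(np.asarray(self.cut_points), values, side="left")


def entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, int]:
    classes, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    return codes, len(classes)


def _split_recursive(
    values: np.ndarray, codes: np.ndarray, n_classes: int, cuts: list[float]
) -> None:
    # values sorted ascending; codes aligned
    n = values.shape[0]
    if n < 2:
        return
    # cumulative class counts above each candidate boundary
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), codes] = 1.0
    cum = onehot.cumsum(axis=0)
    total = cum[-1]
    boundary = np.nonzero(values[1:] > values[:-1])[0]  # cut after index i
    if boundary.size == 0:
        return
    left = cum[boundary]
    right = total - left
    n_left = boundary + 1.0
    n_right = n - n_left

    def _ent(rows: np.ndarray, sizes: np.ndarray) -> np.ndarray:
        p = rows / sizes[:, None]
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
        return -(p * logp).sum(axis=1)

    ent_s = entropy(total)
    weighted = (n_left * _ent(left, n_left) + n_right * _ent(right, n_right)) / n
    # ties (within fp noise) break toward the lowest cut value
    best = int(np.argmax(weighted <= weighted.min() + 1e-12))
    gain = ent_s - weighted[best]
    i = boundary[best]
    k = int((total > 0).sum())
    k1 = int((left[best] > 0).sum())
    k2 = int((right[best] > 0).sum())
    ent_s1 = entropy(left[best])
    ent_s2 = entropy(right[best])
    delta = np.log2(3.0**k - 2.0) - (k * ent_s - k1 * ent_s1 - k2 * ent_s2)
    if gain <= (np.log2(n - 1.0) + delta) / n:
        return
    cut = (values[i] + values[i + 1]) / 2.0
    cuts.append(float(cut))
    _split_recursive(values[: i + 1], codes[: i + 1], n_classes, cuts)
    _split_recursive(values[i + 1 :], codes[i + 1 :], n_classes, cuts)


def mdlp_discretize(values: np.ndarray, labels: np.ndarray) -> DiscretizationScheme:
    """Fit the MDL discretization of one feature against categorical labels.

    Returns the accepted cut points (possibly none).  Constant features or
    features whose best split fails the MDL test yield an empty scheme.
    """
    values = np.asarray(values, dtype=float)
    codes, n_classes = _encode_labels(np.asarray(labels))
    if values.shape != codes.shape:
        raise ValueError("values and labels must have equal length")
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _split_recursive(values[order], codes[order], n_classes, cuts)
    return DiscretizationScheme(tuple(sorted(cuts)))


def information_gain(
    scheme: DiscretizationScheme, values: np.ndarray, labels: np.ndarray
) -> float:
    """Label-entropy reduction (bits) from binning ``values`` at the scheme's cuts.

    IG = H(L) - sum_b (n_b / n) H(L | bin b).  A single-bin scheme returns
    exactly 0.0.
    """
    if not scheme.cut_points:
        return 0.0
    values = np.asarray(values, dtype=float)
    codes, n_classes = _encode_labels(np.asarray(labels))
    bins = scheme.assign(values)
    n = values.shape[0]
    table = np.zeros((scheme.n_bins, n_classes))
    np.add.at(table, (bins, codes), 1.0)
    h_total = entropy(table.sum(axis=0))
    sizes = table.sum(axis=1)
    h_cond = sum(
        (sizes[b] / n) * entropy(table[b]) for b in range(scheme.n_bins) if sizes[b] > 0
    )
    return max(0.0, float(h_total - h_cond))
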