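"""Kennard-Stone representative train/test splitting, applied per class.

The Kennard-Stone algorithm greedily picks training samples that cover the
sample domain: start from the two most distant points, then repeatedly add
the candidate whose minimum Euclidean distance to the already-selected set
is largest.  Run within each class and merged, it yields a training set
spanning every class's own distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
from scipy.spatial.distance import cdist

from .io import SpectraSet


@dataclass
class SplitResult:
    train_ids: np.ndarray
    test_ids: np.ndarray
    per_class: dict          # class -> (n_train, n_test)

    def __post_init__(self):
        overlap = set(self.train_ids.tolist()) & set(self.test_ids.tolist())
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)!r}")


def kennard_stone(X: np.ndarray, m: int) -> tuple[list[int], list[int]]:
    """Deterministic greedy max-min selection of ``m`` rows of X.

    Returns (selected, remaining) row indices; ``selected`` is in pick
    order.  Ties are broken by the lowest index.  Duplicate rows are
    allowed — at distance zero a duplicate can only be picked after all
    distinct points.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    if not 2 <= m <= n:
        raise ValueError(f"m must lie in [2, {n}], got {m}")
    D = cdist(X, X)
    # initial pair: maximum distance; np.argmax on the flat matrix breaks
    # ties at the lexicographically smallest (i, j)
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    chosen = np.zeros(n, bool)
    chosen[selected] = True
    while len(selected) < m:
        cand = np.where(chosen, -np.inf, min_dist)
        nxt = int(np.argmax(cand))          # first index wins ties
        selected.append(nxt)
        chosen[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
    remaining = [i for i in range(n) if not chosen[i]]
    return selected, remaining


def split_per_class(data: SpectraSet,
                    m_per_class: Union[int, Mapping[str, int]] = 25) -> SplitResult:
    """Kennard-Stone split within each class, merged into one result.

    ``m_per_class`` is either one training count for every class (default
    25) or a class -> count mapping.  Distances are computed in the feature
    space of ``data`` as given — pass the representation the classifier
    will see so that 'coverage' matches the model's geometry.
    """
    classes = list(dict.fromkeys(data.labels.tolist()))  # stable order
    train_ids: list = []
    test_ids: list = []
    per_class = {}
    for cls in classes:
        m = m_per_class if isinstance(m_per_class, int) else m_per_class[cls]
        sub = data.class_subset(cls)
        if sub.n_samples < m:
            raise ValueError(f"class {cls!r} has {sub.n_samples} samples, "
                             f"fewer than the requested {m} training samples")
        sel, rem = kennard_stone(sub.absorbance, m)
        train_ids.extend(sub.sample_ids[sel].tolist())
        test_ids.extend(sub.sample_ids[rem].tolist())
        per_class[cls] = (len(sel), len(rem))
    if not test_ids:
        warnings.warn("every sample was assigned to the training set; "
                      "the test set is empty")
    return SplitResult(np.array(train_ids), np.array(test_ids), per_class)
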