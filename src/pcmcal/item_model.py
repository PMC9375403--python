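"""Partial Credit Model item banks and category-response probabilities.

The Partial Credit Model (PCM) is the polytomous Rasch model: a person with
latent trait ``theta`` responds to item ``j`` in one of ``M`` ordered
categories ``k = 0..M-1``, with

    P(X_j = k | theta) = exp(k*theta - sum_{l<=k} delta_jl) / normalizer,

where ``delta_jl`` are the item's ``M-1`` category thresholds (the trait level
at which categories ``l-1`` and ``l`` are equally likely).  An item's
*location* ``delta_j`` is the mean of its thresholds.

This module provides the :class:`ItemBank` container (an instrument's
calibration: the full threshold matrix), two archetype bank constructors that
mimic instruments commonly met in practice, and numerically stable
probability / expected-score evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ItemBank",
    "make_archetype_bank",
    "category_probabilities",
    "expected_score",
]

_ALLOWED_J = (4, 7, 10)
_ALLOWED_M = (3, 5)

#: item-location range and within-item threshold spread (SD of the normal
#: whose percentiles place the thresholds) for the two instrument archetypes
_ARCHETYPES = {
    1: {"loc_lo": -0.25, "loc_hi": 0.25, "spread": 2.5},
    2: {"loc_lo": -1.0, "loc_hi": 1.0, "spread": 1.5},
}


@dataclass(frozen=True)
class ItemBank:
    """Calibration of a polytomous instrument: J x (M-1) threshold matrix."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        thr = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if thr.ndim != 2 or thr.shape[1] < 1:
            raise ValueError("thresholds must be a J x (M-1) matrix")
        if not np.all(np.isfinite(thr)):
            raise ValueError("thresholds must be finite")
        object.__setattr__(self, "thresholds", thr)

    @property
    def J(self) -> int:
        return self.thresholds.shape[0]

    @property
    def M(self) -> int:
        return self.thresholds.shape[1] + 1

    @property
    def locations(self) -> np.ndarray:
        """Item locations delta_j: row means of the threshold matrix."""
        return self.thresholds.mean(axis=1)

    # -- plain tabular serialization (calibration hand-off format) ---------

    def to_frame(self) -> pd.DataFrame:
        cols = {"item": np.arange(1, self.J + 1), "location": self.locations}
        for l in range(1, self.M):
            cols[f"delta_{l}"] = self.thresholds[:, l - 1]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ItemBank":
        cols = [c for c in frame.columns if c.startswith("delta_")]
        cols.sort(key=lambda c: int(c.split("_")[1]))
        if not cols:
            raise ValueError("no delta_<l> columns found")
        return cls(frame[cols].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path))


def make_archetype_bank(
    J: int, M: int, archetype: int, *, literal_percentiles: bool = False
) -> ItemBank:
    """Build one of the two archetype item banks.

    Archetype 1: item locations tightly packed (regularly spaced on
    [-0.25, 0.25]) with widely spread thresholds (normal percentiles,
    SD 2.5) -- the "parallel items" pattern of classical-test-theory
    instruments.  Archetype 2: locations spread over [-1, 1] with tight
    thresholds (SD 1.5) -- the "item hierarchy" pattern of Rasch-built
    instruments.

    Thresholds sit at the tercile (M=3) or quintile (M=5) points of a
    normal centered on the item location; the whole bank is then shifted so
    the grand mean of all thresholds is 0.  ``literal_percentiles`` uses the
    rounded 33rd/66th percentiles instead of exact thirds for M=3.
    """
    if J not in _ALLOWED_J:
        raise ValueError(f"J must be one of {_ALLOWED_J}, got {J!r}")
    if M not in _ALLOWED_M:
        raise ValueError(f"M must be one of {_ALLOWED_M}, got {M!r}")
    if archetype not in _ARCHETYPES:
        raise ValueError(f"archetype must be 1 or 2, got {archetype!r}")

    spec = _ARCHETYPES[archetype]
    locations = np.linspace(spec["loc_lo"], spec["loc_hi"], J)
    if M == 3:
        q = np.array([0.33, 0.66]) if literal_percentiles else np.array([1, 2]) / 3
    else:
        q = np.array([0.2, 0.4, 0.6, 0.8])
    offsets = spec["spread"] * stats.norm.ppf(q)
    thresholds = locations[:, None] + offsets[None, :]
    thresholds -= thresholds.mean()  # grand-mean centering of the bank
    return ItemBank(thresholds)


def _logits(theta, thresholds_row: np.ndarray) -> np.ndarray:
    """log numerators k*theta - cumsum(delta)_k, with empty sum at k=0."""
    cum = np.concatenate([[0.0], np.cumsum(thresholds_row)])
    k = np.arange(cum.size)
    return np.multiply.outer(np.asarray(theta, dtype=float), k) - cum


def category_probabilities(theta, item_thresholds) -> np.ndarray:
    """PCM category probabilities P(X = k | theta) for one item.

    ``theta`` may be a scalar or an array; the category axis is last.
    Evaluated in log space with max-subtraction, so it is overflow-safe for
    any |theta| a simulation will produce.
    """
    thr = np.asarray(item_thresholds, dtype=float).ravel()
    if thr.size < 1 or not np.all(np.isfinite(thr)):
        raise ValueError("item thresholds must be a non-empty finite vector")
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    probs = special.softmax(_logits(th, thr), axis=-1)
    return probs if th.ndim else probs.reshape(-1)


def expected_score(theta, bank: ItemBank) -> np.ndarray:
    """Expected total score sum_j E[X_j | theta]; monotone in theta.

    Ranges over (0, J*(M-1)); useful as a scale-level summary of where an
    instrument is informative.
    """
    th = np.asarray(theta, dtype=float)
    k = np.arange(bank.M)
    total = np.zeros(th.shape)
    for row in bank.thresholds:
        total = total + category_probabilities(th, row) @ k
    return total if th.ndim else float(total)
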