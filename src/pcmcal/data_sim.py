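"""Simulation of polytomous PRO response data.

Two kinds of samples are generated, matching the design of a calibration
study followed by a two-arm randomized trial:

* a *calibration sample*: latent traits N(0, variance), used only to
  estimate item thresholds;
* a *trial sample*: two equal arms, placebo traits N(mu0, 1) and treated
  traits N(mu0 + gamma, 1), where gamma is the treatment effect on the logit
  scale (a standardized mean difference, the within-arm SD being 1) and mu0
  measures (mis)targeting of the instrument to the trial population.

Responses are drawn item-wise from the PCM category probabilities of a given
:class:`~pcmcal.item_model.ItemBank`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .item_model import ItemBank, category_probabilities

__all__ = [
    "PopulationSpec",
    "TrialSpec",
    "ResponseDataset",
    "draw_latent",
    "simulate_responses",
    "simulate_trial",
]


@dataclass(frozen=True)
class PopulationSpec:
    """A single normal latent population (calibration-sample style)."""

    mean: float
    variance: float
    N: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass(frozen=True)
class TrialSpec:
    """Two-arm cross-sectional trial: theta ~ N(mu0 + g*gamma, variance)."""

    n_per_group: int
    mu0: float
    gamma: float
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.variance <= 0:
            raise ValueError("variance must be > 0")


@dataclass
class ResponseDataset:
    """N x J integer response matrix with optional simulation truth.

    ``theta_true`` and ``group`` are carried for diagnostics and group
    comparison respectively; estimation never reads ``theta_true``.
    ``M`` records the number of response categories the generating (or
    assumed) instrument has, since rare categories may be unobserved.
    """

    responses: np.ndarray
    M: int
    theta_true: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.responses)
        if X.ndim != 2:
            raise ValueError("responses must be an N x J matrix")
        if X.size and (X.min() < 0 or X.max() > self.M - 1):
            raise ValueError("responses must lie in 0..M-1")
        self.responses = X.astype(np.int64)
        if self.group is not None:
            g = np.asarray(self.group, dtype=np.int64)
            if g.shape != (X.shape[0],) or not np.isin(g, (0, 1)).all():
                raise ValueError("group must be a length-N 0/1 vector")
            self.group = g
        if self.theta_true is not None:
            self.theta_true = np.asarray(self.theta_true, dtype=float)

    @property
    def N(self) -> int:
        return self.responses.shape[0]

    @property
    def J(self) -> int:
        return self.responses.shape[1]

    # -- wide-CSV round trip (one row per patient) --------------------------

    def to_frame(self) -> pd.DataFrame:
        out = {"id": np.arange(1, self.N + 1)}
        if self.group is not None:
            out["group"] = self.group
        for j in range(self.J):
            out[f"item{j + 1}"] = self.responses[:, j]
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, M: int) -> "ResponseDataset":
        items = [c for c in frame.columns if c.startswith("item")]
        items.sort(key=lambda c: int(c[4:]))
        if not items:
            raise ValueError("no item<j> columns found")
        group = frame["group"].to_numpy() if "group" in frame.columns else None
        return cls(frame[items].to_numpy(), M=M, group=group)

    @classmethod
    def from_csv(cls, path, M: int) -> "ResponseDataset":
        return cls.from_frame(pd.read_csv(path), M=M)


def draw_latent(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw N latent traits from N(mean, variance)."""
    return spec.mean + np.sqrt(spec.variance) * rng.standard_normal(spec.N)


def simulate_responses(
    bank: ItemBank, theta: np.ndarray, rng: np.random.Generator
) -> ResponseDataset:
    """Draw PCM responses to every item of ``bank`` for each latent trait."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    N = theta.size
    X = np.empty((N, bank.J), dtype=np.int64)
    for j, row in enumerate(bank.thresholds):
        cdf = np.cumsum(category_probabilities(theta, row), axis=1)
        X[:, j] = (rng.random(N)[:, None] > cdf[:, :-1]).sum(axis=1)
    return ResponseDataset(X, M=bank.M, theta_true=theta)


def simulate_trial(
    bank: ItemBank, spec: TrialSpec, rng: np.random.Generator
) -> ResponseDataset:
    """Simulate a balanced two-arm trial (placebo first, then treated)."""
    n = spec.n_per_group
    group = np.repeat([0, 1], n)
    means = spec.mu0 + group * spec.gamma
    theta = means + np.sqrt(spec.variance) * rng.standard_normal(2 * n)
    data = simulate_responses(bank, theta, rng)
    data.group = group
    return data
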