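import numpy as np
import pytest

from pcmcal import make_archetype_bank
from pcmcal.item_model import category_probabilities

ALL_BANK_PARAMS = [
    (J, M, a) for J in (4, 7, 10) for M in (3, 5) for a in (1, 2)
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bank_4_3_2():
    """The base archetype-2 instrument: 4 items, 3 categories."""
    return make_archetype_bank(4, 3, 2)


def grid_marginal_loglik(responses, thresholds, mu0, sigma2, group=None, gamma=0.0,
                         n_points=2001, half_width=10.0):
    """Trapezoid-rule oracle for the marginal log-likelihood (per dataset).

    Independent of the package's Gauss-Hermite path: integrates the PCM
    likelihood times the normal density on a fine theta grid.
    """
    sig = np.sqrt(sigma2)
    total = 0.0
    g = np.zeros(len(responses), dtype=int) if group is None else np.asarray(group)
    for row, gi in zip(np.asarray(responses), g):
        m = mu0 + gamma * gi
        grid = np.linspace(m - half_width * sig, m + half_width * sig, n_points)
        dens = np.exp(-0.5 * ((grid - m) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        L = dens.copy()
        for j, trow in enumerate(thresholds):
            L *= category_probabilities(grid, trow)[:, row[j]]
        total += np.log(np.trapezoid(L, grid))
    return total


def grid_eap(responses, thresholds, prior_mean, prior_var, n_points=2001):
    """Grid-integration oracle for EAP posterior means."""
    sig = np.sqrt(prior_var)
    grid = np.linspace(prior_mean - 10 * sig, prior_mean + 10 * sig, n_points)
    dens = np.exp(-0.5 * ((grid - prior_mean) / sig) ** 2)
    out = []
    for row in np.asarray(responses):
        L = dens.copy()
        for j, trow in enumerate(thresholds):
            L *= category_probabilities(grid, trow)[:, row[j]]
        out.append(np.trapezoid(grid * L, grid) / np.trapezoid(L, grid))
    return np.array(out)
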