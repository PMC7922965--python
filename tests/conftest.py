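import numpy as np
import pytest
from scipy import stats

import dichodiff as dd


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def exp_equal():
    """Equal-means exponential model: D+=10, D-=0, <tau>=1 both states."""
    return dd.ModelParams(10.0, 0.0, dd.Exponential(1.0), dd.Exponential(1.0))


@pytest.fixture
def exp_unequal():
    """Unequal-means exponential model: <tau>+=1, <tau>-=5."""
    return dd.ModelParams(10.0, 0.0, dd.Exponential(1.0), dd.Exponential(5.0))


@pytest.fixture
def uniform_model():
    """Uniform-sojourn model behind the short-time tent comparison."""
    return dd.ModelParams(10.0, 0.0, dd.Uniform(0.0, 5.0), dd.Uniform(0.0, 10.0))


def mixed_displacement_gof(x, pdf, n_bins=25, x_max=None):
    """Chi-square goodness of fit of endpoint draws against a DisplacementPDF.

    The point mass at the origin is tested through the exactly-zero samples;
    the continuous part is binned symmetrically with expected masses from
    quadrature of the density.  Returns the chi-square p-value (the atom
    count is folded in as one extra category).
    """
    x = np.asarray(x)
    n = x.size
    zeros = int(np.sum(x == 0.0))
    movers = x[x != 0.0]
    if x_max is None:
        x_max = np.quantile(np.abs(movers), 0.999)
    edges = np.linspace(-x_max, x_max, n_bins + 1)
    counts, _ = np.histogram(movers, bins=edges)
    expected = np.array(
        [pdf.interval_probability(a, b) - (pdf.atom_at_zero if a < 0 < b else 0.0)
         for a, b in zip(edges[:-1], edges[1:])]
    ) * n
    # overflow category keeps the total expected count at n
    counts = np.append(counts, [movers.size - counts.sum(), zeros])
    expected = np.append(expected, [(1 - pdf.atom_at_zero) * n - expected.sum(),
                                    pdf.atom_at_zero * n])
    keep = expected > 5
    stat = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
    dof = keep.sum() - 1
    return stats.chi2.sf(stat, dof)


def occupation_fraction_gof(p_plus, g, n_bins=30):
    """Chi-square p-value of occupation-fraction draws against a mixed law."""
    p_plus = np.asarray(p_plus)
    n = p_plus.size
    at0 = int(np.sum(p_plus == 0.0))
    at1 = int(np.sum(p_plus == 1.0))
    interior = p_plus[(p_plus > 0) & (p_plus < 1)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(interior, bins=edges)
    from scipy.integrate import quad
    expected = np.array(
        [quad(lambda p: float(g.density(np.array(p))), a, b, limit=100)[0]
         for a, b in zip(edges[:-1], edges[1:])]
    ) * n
    counts = np.append(counts, [at0, at1])
    expected = np.append(expected, [g.atom0 * n, g.atom1 * n])
    keep = expected > 5
    stat = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
    dof = keep.sum() - 1
    return stats.chi2.sf(stat, dof)
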