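import numpy as np
import pytest

from acuityfit import GratingSpec, make_study_fixture


@pytest.fixture(scope="session")
def card_spec() -> GratingSpec:
    """The study's physical card: 20 cm, 81% Michelson, Gaussian SD 0.22."""
    return GratingSpec(
        side_length=0.20, n_cycles=10.0, peak_contrast=0.81,
        envelope_sd=0.22, resolution=512,
    )


@pytest.fixture(scope="session")
def dog_bright_fixture():
    """One simulated bright-light dog with a 12 cpd true threshold."""
    return make_study_fixture("dog_bright", 12.0, seed=11)


def exact_binomial_tail_oracle(k: int, n: int) -> float:
    """P(X >= k | n, 1/2) by full enumeration of all 2^n equally likely outcomes.

    Independent of the implementation under test: counts, via binomial
    coefficients built up by Pascal's rule, how many of the 2^n outcome
    sequences contain at least k successes.
    """
    row = [1]
    for _ in range(n):
        row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
    favourable = sum(row[j] for j in range(k, n + 1))
    return favourable / 2**n


def grid_oracle_min_nll(freqs, ks, ns, origin, n_a=200, n_b=200, n_lam=21):
    """Brute-force minimum negative log-likelihood over a dense (a, b, lapse) grid.

    Written from the model definition (independently of the fitting code):
    psi = 1/2 + (1/2 - lam) * (1 - exp(-(x/a)^b)) on x = origin - frequency.
    """
    x = origin - np.asarray(freqs, dtype=float)
    k = np.asarray(ks, dtype=float)
    n = np.asarray(ns, dtype=float)
    span = max(x.max(), 1e-6)
    a = np.geomspace(0.01 * span, 3.0 * span, n_a)
    b = np.geomspace(0.1, 30.0, n_b)
    lam = np.linspace(0.0, 0.2, n_lam)
    A, B, L = np.meshgrid(a, b, lam, indexing="ij")
    xx = x.reshape(-1, 1, 1, 1)
    p = 0.5 + (0.5 - L) * (1.0 - np.exp(-((xx / A) ** B)))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    nll = -(k.reshape(-1, 1, 1, 1) * np.log(p)
            + (n - k).reshape(-1, 1, 1, 1) * np.log(1 - p)).sum(axis=0)
    return float(nll.min())
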