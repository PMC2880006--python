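"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they check: chain statistics
are recomputed by exhaustive sequence enumeration, and Viterbi results by
scoring every possible sequence with plain loops/broadcasting.
"""
import itertools

import numpy as np
import pytest

import pepdesign as pkg
from pepdesign.chain_model import EnergyTables, Thermo
from pepdesign.decoder import emission_log_matrices
from pepdesign.ramachandran import RegionSet


@pytest.fixture(scope="session")
def regions():
    return RegionSet.default()


@pytest.fixture(scope="session")
def thermo():
    return Thermo()


def random_energy_tables(rng, alphabet, n, scale=1.0):
    a = len(alphabet)
    return EnergyTables(
        first_grid=rng.normal(0.0, scale, a),
        pair_grids=[rng.normal(0.0, scale, (a, a)) for _ in range(n - 1)],
        alphabet=alphabet,
    )


def enumerate_chain(tables, thermo, include_first=False):
    """Brute-force partition function and pair marginals over all sequences."""
    a = len(tables.alphabet)
    n = tables.n
    beta = thermo.beta
    Z = 0.0
    pair_sums = [np.zeros((a, a)) for _ in range(n - 1)]
    for seq in itertools.product(range(a), repeat=n):
        w = np.exp(-beta * tables.first_grid[seq[0]]) if include_first else 1.0
        for t in range(n - 1):
            w *= np.exp(-beta * tables.pair_grids[t][seq[t], seq[t + 1]])
        Z += w
        for t in range(n - 1):
            pair_sums[t][seq[t], seq[t + 1]] += w
    return Z, [p / Z for p in pair_sums]


def model_log_terms(tables, thermo, observations, singlet, pair, config=None):
    """The per-term log quantities the decoder maximizes over, recomputed."""
    config = config or pkg.DecodeConfig()
    chain = pkg.build_weights(tables, thermo)
    marg = pkg.pair_marginals(chain, include_first=config.include_first)
    with np.errstate(divide="ignore"):
        if config.transition_mode == "conditional":
            log_trans = [np.log(m) for m in marg.transitions]
        else:
            log_trans = [np.log(m) for m in marg.pair_probs]
        log_p1 = np.log(pkg.first_grid_probs(chain))
    log_e1, log_B = emission_log_matrices(
        observations, singlet, pair,
        floor=config.floor, singlet_index=config.singlet_index,
    )
    return log_p1, log_e1, log_trans, log_B


def brute_force_decode(tables, thermo, observations, singlet, pair, config=None):
    """Exhaustive maximum over all |alphabet|^n sequences (broadcast sum)."""
    log_p1, log_e1, log_trans, log_B = model_log_terms(
        tables, thermo, observations, singlet, pair, config
    )
    a = len(tables.alphabet)
    n = tables.n
    total = (log_p1 + log_e1).reshape((a,) + (1,) * (n - 1))
    for t in range(n - 1):
        shape = [1] * n
        shape[t], shape[t + 1] = a, a
        total = total + (log_trans[t] + log_B[t]).reshape(shape)
    flat = int(np.argmax(total))
    idx = np.unravel_index(flat, total.shape)
    seq = "".join(tables.alphabet[i] for i in idx)
    return seq, float(total.max()), total
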