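"""Rotational-isomeric-state (RIS) chain statistics from binding energies.

Docking binding energies (kcal/mol) for the 20 single amino acids at the
first grid box and for the 400 dipeptides at each consecutive grid pair are
converted into Boltzmann statistical weights u = exp(−E / kT).  The chain
partition function is the transfer-matrix product

    Z = J* · U(1) · U(2) · … · U(n−1) · J,

with J* a row of ones (every amino acid admitted as the first residue) and J
a column of ones.  Pairwise position marginals p_ij(t) follow from the same
product with all elements of U(t) zeroed except (i, j); they are computed
here by prefix/suffix vector products, which is algebraically identical.
Conditional transitions a(j | i) at each grid pair are the row-normalized
pair marginals and drive the Viterbi decoder.

All products are carried in the log domain: with pair energies of order
−13 kcal/mol a single weight is ≈ exp(22), so linear-domain products
overflow within a few grids.

By default the first-grid single-residue weights do **not** enter Z or the
pair marginals; they enter the design solely through the initial
distribution :func:`first_grid_probs`.  ``include_first=True`` folds them in
as a diagonal prefactor for sensitivity checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alphabet import AA_ORDER, validate_alphabet
from .errors import InputError, PepDesignError

#: Boltzmann (gas) constant in kcal/(mol·K), matching kcal/mol energies.
KB_KCAL_PER_MOL_K: float = 0.0019872

#: Default absolute temperature in kelvin.
DEFAULT_TEMPERATURE_K: float = 298.15


@dataclass(frozen=True)
class Thermo:
    """Thermodynamic context: temperature and Boltzmann constant."""

    temperature_K: float = DEFAULT_TEMPERATURE_K
    kB: float = KB_KCAL_PER_MOL_K

    def __post_init__(self):
        if not (self.temperature_K > 0):
            raise InputError(f"temperature must be positive, got {self.temperature_K}")
        if not (self.kB > 0):
            raise InputError(f"kB must be positive, got {self.kB}")

    @property
    def beta(self) -> float:
        """1 / (kB·T) in mol/kcal."""
        return 1.0 / (self.kB * self.temperature_K)


@dataclass
class EnergyTables:
    """Binding energies: 20 for grid 1, and one 20×20 matrix per grid pair.

    ``alphabet`` may be a reduced subset of the canonical 20 letters (used to
    make enumeration oracles cheap); arrays are indexed in alphabet order.
    """

    first_grid: np.ndarray
    pair_grids: list
    alphabet: str = AA_ORDER

    def __post_init__(self):
        self.alphabet = validate_alphabet(self.alphabet)
        a = len(self.alphabet)
        self.first_grid = np.asarray(self.first_grid, dtype=float)
        self.pair_grids = [np.asarray(m, dtype=float) for m in self.pair_grids]
        if self.first_grid.shape != (a,):
            raise InputError(
                f"first grid expects {a} energies, got shape {self.first_grid.shape}"
            )
        if not np.all(np.isfinite(self.first_grid)):
            raise InputError("non-finite energy in first grid")
        if len(self.pair_grids) < 1:
            raise InputError("need at least one grid pair (peptide length >= 2)")
        for t, m in enumerate(self.pair_grids, start=1):
            if m.shape != (a, a):
                raise InputError(
                    f"grid pair {t}: expected shape ({a}, {a}), got {m.shape}"
                )
            if not np.all(np.isfinite(m)):
                raise InputError(f"non-finite energy in grid pair {t}")

    @property
    def n(self) -> int:
        """Designed peptide length."""
        return len(self.pair_grids) + 1


@dataclass
class WeightChain:
    """Statistical weights in the log domain: log u = −E / (kB·T)."""

    alphabet: str
    log_u1: np.ndarray
    log_U: list

    @property
    def n(self) -> int:
        return len(self.log_U) + 1


@dataclass
class ChainMarginals:
    """Partition function and the chain's pairwise/singlet/transition laws."""

    log_Z: float
    pair_probs: list      # n−1 matrices p_ij(t), each summing to 1
    singlet_probs: list   # n vectors of per-position residue marginals
    transitions: list     # n−1 row-stochastic conditional matrices a(j|i)


def build_weights(tables: EnergyTables, thermo: Thermo = Thermo()) -> WeightChain:
    """Convert binding energies to Boltzmann statistical weights (log domain)."""
    beta = thermo.beta
    return WeightChain(
        alphabet=tables.alphabet,
        log_u1=-beta * tables.first_grid,
        log_U=[-beta * m for m in tables.pair_grids],
    )


def partition_function(chain: WeightChain, include_first: bool = False) -> float:
    """log Z via the transfer-matrix product J* · U(1) … U(n−1) · J."""
    if chain.n < 2:
        raise InputError("partition function needs peptide length >= 2")
    a = len(chain.alphabet)
    v = chain.log_u1.copy() if include_first else np.zeros(a)
    for logU in chain.log_U:
        v = logsumexp(v[:, None] + logU, axis=0)
    return float(logsumexp(v))


def pair_marginals(chain: WeightChain, include_first: bool = False) -> ChainMarginals:
    """Pairwise marginals p_ij(t), singlet marginals and conditional transitions.

    p_ij(t) equals the literal zeroed-matrix transfer product Z⁻¹ · J* ·
    U(1) … U′(t) … U(n−1) · J with U′(t) keeping only element (i, j);
    computed with prefix/suffix log-vector products.
    """
    a = len(chain.alphabet)
    n = chain.n
    prefix = [np.zeros(a)]
    if include_first:
        prefix[0] = chain.log_u1.copy()
    for logU in chain.log_U:
        prefix.append(logsumexp(prefix[-1][:, None] + logU, axis=0))
    suffix = [np.zeros(a) for _ in range(n)]
    for t in range(n - 2, -1, -1):
        suffix[t] = logsumexp(chain.log_U[t] + suffix[t + 1][None, :], axis=1)
    log_Z = float(logsumexp(prefix[0] + suffix[0]))

    pair_probs = []
    transitions = []
    for t in range(n - 1):
        logp = prefix[t][:, None] + chain.log_U[t] + suffix[t + 1][None, :] - log_Z
        p = np.exp(logp)
        row = p.sum(axis=1, keepdims=True)
        if np.any(row <= 0):
            raise PepDesignError(
                f"internal consistency error: zero row marginal at grid pair {t + 1}"
            )
        pair_probs.append(p)
        transitions.append(p / row)
    singlet_probs = [p.sum(axis=1) for p in pair_probs]
    singlet_probs.append(pair_probs[-1].sum(axis=0))
    return ChainMarginals(
        log_Z=log_Z,
        pair_probs=pair_probs,
        singlet_probs=singlet_probs,
        transitions=transitions,
    )


def first_grid_probs(chain: WeightChain) -> np.ndarray:
    """Binding probabilities of the 20 amino acids at the first grid box.

    The softmax of the first-grid log-weights: p1_i = u1_i / Σ_k u1_k.
    """
    v = chain.log_u1 - np.max(chain.log_u1)
    w = np.exp(v)
    return w / w.sum()
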