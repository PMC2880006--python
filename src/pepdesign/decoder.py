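"""Viterbi decoding of the designed peptide sequence.

The hidden states at each grid are the 20 amino-acid identities; the
observations are the torsion states of the docked candidates.  With p1 the
first-grid binding distribution, a(t)(j|i) the conditional transitions from
the RIS chain and b(t)(i, j) the coil-library emission of the observed
torsion states, the dynamic program is (all in log domain):

    δ_1(i)   = log π_i + log p1_i + log s_i(m_i)          (π_i = 1)
    δ_t+1(j) = max_i [ δ_t(i) + log a(t)(j|i) + log b(t)(i, j) ]

with backpointers stored during the induction; backtracking from
argmax δ_n yields the designed sequence.  Ties are broken toward the lowest
index in the canonical alphabet order, so runs are reproducible.

Memory is O(m·n) (the stored δ and backpointer arrays) and time O(n·m²)
with m = 20 states and n the peptide length.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .alphabet import AA_ORDER, ONE_TO_THREE, validate_alphabet
from .chain_model import (
    EnergyTables,
    Thermo,
    build_weights,
    first_grid_probs,
    pair_marginals,
)
from .errors import DegenerateModelError, InputError
from .ramachandran import (
    N_STATES,
    UNCLASSIFIED,
    PairTable,
    RegionSet,
    SingletTable,
    classify_states,
)


@dataclass
class ObservationSet:
    """Torsion-state observations of every docked candidate.

    ``first_states``: state of (φ_1, ψ_1) for each of the single amino acids
    docked at grid 1.  ``pair_states[t]``: an (A, A, 2) int array with the
    (φ_t, ψ_t) state (index 0) and (ψ_t, φ_{t+1}) state (index 1) of each
    docked dipeptide candidate at grid pair t.  Raw torsion angles are kept
    when available so observation files can be round-tripped.
    """

    alphabet: str
    first_states: np.ndarray
    pair_states: list
    first_torsions: Optional[np.ndarray] = None   # (A, 2): phi, psi
    pair_torsions: Optional[list] = None          # (A, A, 3): phi_t, psi_t, phi_next

    def __post_init__(self):
        self.alphabet = validate_alphabet(self.alphabet)
        a = len(self.alphabet)
        self.first_states = np.asarray(self.first_states, dtype=int)
        self.pair_states = [np.asarray(m, dtype=int) for m in self.pair_states]
        if self.first_states.shape != (a,):
            raise InputError(
                f"first-grid observations: expected {a} states, got shape "
                f"{self.first_states.shape}"
            )
        for t, m in enumerate(self.pair_states, start=1):
            if m.shape != (a, a, 2):
                raise InputError(
                    f"grid pair {t}: expected observation shape ({a}, {a}, 2), "
                    f"got {m.shape}"
                )
        all_states = np.concatenate(
            [self.first_states.ravel()] + [m.ravel() for m in self.pair_states]
        )
        if all_states.min() < 0 or all_states.max() > N_STATES:
            raise InputError("observation states must lie in 0..11 (0 = unclassified)")

    @property
    def n(self) -> int:
        return len(self.pair_states) + 1

    @classmethod
    def from_torsions(
        cls,
        alphabet: str,
        first_torsions: np.ndarray,
        pair_torsions: list,
        regions: RegionSet,
    ) -> "ObservationSet":
        """Classify raw docked torsion angles into states.

        ``first_torsions``: (A, 2) array of (φ_1, ψ_1) per single candidate;
        ``pair_torsions``: list of (A, A, 3) arrays of (φ_t, ψ_t, φ_{t+1})
        per dipeptide candidate.
        """
        first_torsions = np.asarray(first_torsions, dtype=float)
        pair_torsions = [np.asarray(m, dtype=float) for m in pair_torsions]
        first_states = classify_states(
            first_torsions[:, 0], first_torsions[:, 1], regions
        )
        pair_states = []
        for m in pair_torsions:
            m1 = classify_states(m[..., 0], m[..., 1], regions)
            m2 = classify_states(m[..., 1], m[..., 2], regions)
            pair_states.append(np.stack([m1, m2], axis=-1))
        return cls(
            alphabet=alphabet,
            first_states=first_states,
            pair_states=pair_states,
            first_torsions=first_torsions,
            pair_torsions=pair_torsions,
        )


@dataclass(frozen=True)
class DecodeConfig:
    """Tunable decoding switches.

    ``floor``: probability substituted for an UNCLASSIFIED torsion state
    (default 1e-4, so one strained pose cannot veto a sequence).
    ``transition_mode``: "conditional" uses a(j|i) (default); "joint" uses
    the pair marginal p_ij directly.  ``singlet_index``: whether the singlet
    emission factor is indexed by the residue at grid t ("i", default) or by
    the following residue ("j").  ``include_first``: fold first-grid weights
    into the chain partition function (sensitivity mode).
    """

    floor: float = 1e-4
    transition_mode: str = "conditional"
    singlet_index: str = "i"
    include_first: bool = False

    def __post_init__(self):
        if self.floor < 0:
            raise InputError("floor must be >= 0")
        if self.transition_mode not in ("conditional", "joint"):
            raise InputError(f"unknown transition_mode: {self.transition_mode!r}")
        if self.singlet_index not in ("i", "j"):
            raise InputError(f"singlet_index must be 'i' or 'j'")


@dataclass
class DecodeResult:
    """Decoded peptide, its log-score and the per-step score breakdown."""

    sequence: str
    log_score: float
    delta: list
    backpointers: list
    breakdown: dict
    tie_break: str = "canonical-alphabet-order"
    op_count: int = 0

    @property
    def sequence3(self) -> list[str]:
        return [ONE_TO_THREE[a] for a in self.sequence]

    def to_fasta(self, header: str = "designed_peptide") -> str:
        return f">{header}\n{self.sequence}\n"

    def to_json_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "sequence3": self.sequence3,
            "log_score": self.log_score,
            "breakdown": {k: list(map(float, v)) for k, v in self.breakdown.items()},
            "tie_break": self.tie_break,
            "op_count": self.op_count,
        }


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def emission_log_matrices(
    observations: ObservationSet,
    singlet: SingletTable,
    pair: PairTable,
    floor: float = 1e-4,
    singlet_index: str = "i",
) -> tuple[np.ndarray, list]:
    """Per-grid emission log-probabilities from the observed torsion states.

    Returns ``(log_e1, log_B)``: ``log_e1[i]`` is the first-grid singlet
    emission; ``log_B[t][i, j]`` is the dipeptide emission
    s(m1) · p(i, j, m2) with the floor substituted for unclassified states.
    """
    rows = np.array([AA_ORDER.index(a) for a in observations.alphabet])
    a = len(rows)

    m = observations.first_states
    e1 = np.where(
        m == UNCLASSIFIED,
        floor,
        singlet.values[rows, np.maximum(m, 1) - 1],
    )
    log_B = []
    for ps in observations.pair_states:
        m1, m2 = ps[..., 0], ps[..., 1]
        srow = rows[:, None] if singlet_index == "i" else rows[None, :]
        s = np.where(
            m1 == UNCLASSIFIED,
            floor,
            singlet.values[np.broadcast_to(srow, (a, a)), np.maximum(m1, 1) - 1],
        )
        p = np.where(
            m2 == UNCLASSIFIED,
            floor,
            pair.values[rows[:, None], rows[None, :], np.maximum(m2, 1) - 1],
        )
        log_B.append(_log(s) + _log(p))
    return _log(e1), log_B


def initialize(
    p1: np.ndarray,
    obs1: np.ndarray,
    singlet: SingletTable,
    floor: float = 1e-4,
    alphabet: str = AA_ORDER,
) -> np.ndarray:
    """δ_1(i) = log π_i + log p1_i + log s_i(m_i), with π_i = 1."""
    alphabet = validate_alphabet(alphabet)
    p1 = np.asarray(p1, dtype=float)
    obs1 = np.asarray(obs1, dtype=int)
    if obs1.shape != (len(alphabet),):
        raise InputError(
            f"missing first-grid observations: expected one state per residue "
            f"({len(alphabet)}), got shape {obs1.shape}"
        )
    rows = np.array([AA_ORDER.index(a) for a in alphabet])
    e1 = np.where(
        obs1 == UNCLASSIFIED, floor, singlet.values[rows, np.maximum(obs1, 1) - 1]
    )
    return _log(p1) + _log(e1)


def induct(
    delta_t: np.ndarray,
    log_trans_t: np.ndarray,
    log_emit_t: np.ndarray,
    grid: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One induction step: δ_{t+1}(j) = max_i [δ_t(i) + log a(j|i) + log b(i,j)].

    Returns the new δ row and the backpointer row (the maximizing i per j;
    ties resolve to the lowest canonical index via first-argmax).
    """
    scores = delta_t[:, None] + log_trans_t + log_emit_t
    delta_next = scores.max(axis=0)
    backptr = scores.argmax(axis=0)
    if np.all(np.isneginf(delta_next)):
        where = f" at grid {grid}" if grid is not None else ""
        raise DegenerateModelError(
            f"no viable residue{where}: all candidate scores are -inf"
        )
    return delta_next, backptr


def backtrack(delta: list, backpointers: list, alphabet: str) -> tuple[str, float]:
    """Recover q_n = argmax δ_n and q_t = backptr_t(q_{t+1})."""
    q = int(np.argmax(delta[-1]))
    log_score = float(delta[-1][q])
    idx = [q]
    for bp in reversed(backpointers):
        q = int(bp[q])
        idx.append(q)
    idx.reverse()
    return "".join(alphabet[i] for i in idx), log_score


def score_sequence(
    seq: str,
    log_p1: np.ndarray,
    log_e1: np.ndarray,
    log_trans: list,
    log_B: list,
    alphabet: str,
) -> tuple[float, dict]:
    """Independent single-sequence score: Σ of the same log-terms the DP sums.

    Returns the total and a per-term breakdown (init and per-step
    transition/emission contributions).
    """
    idx = [alphabet.index(a) for a in seq]
    init_p1 = float(log_p1[idx[0]])
    init_em = float(log_e1[idx[0]])
    trans_terms, emit_terms = [], []
    for t in range(len(seq) - 1):
        trans_terms.append(float(log_trans[t][idx[t], idx[t + 1]]))
        emit_terms.append(float(log_B[t][idx[t], idx[t + 1]]))
    total = init_p1 + init_em + sum(trans_terms) + sum(emit_terms)
    breakdown = {
        "init_binding": [init_p1],
        "init_emission": [init_em],
        "transition": trans_terms,
        "emission": emit_terms,
    }
    return total, breakdown


def decode(
    tables: EnergyTables,
    thermo: Thermo,
    observations: ObservationSet,
    singlet: SingletTable,
    pair: PairTable,
    config: DecodeConfig = DecodeConfig(),
) -> DecodeResult:
    """Full design pipeline: weights → chain marginals → Viterbi → sequence."""
    if observations.alphabet != tables.alphabet:
        raise InputError(
            "observation alphabet does not match energy-table alphabet: "
            f"{observations.alphabet!r} vs {tables.alphabet!r}"
        )
    if observations.n != tables.n:
        raise InputError(
            f"observation length {observations.n} does not match peptide "
            f"length {tables.n}"
        )
    chain = build_weights(tables, thermo)
    marg = pair_marginals(chain, include_first=config.include_first)
    if config.transition_mode == "conditional":
        log_trans = [_log(a) for a in marg.transitions]
    else:
        log_trans = [_log(p) for p in marg.pair_probs]
    p1 = first_grid_probs(chain)
    log_e1, log_B = emission_log_matrices(
        observations, singlet, pair, floor=config.floor,
        singlet_index=config.singlet_index,
    )
    delta = [initialize(p1, observations.first_states, singlet,
                        floor=config.floor, alphabet=tables.alphabet)]
    backpointers = []
    op_count = 0
    a = len(tables.alphabet)
    for t in range(tables.n - 1):
        d, bp = induct(delta[-1], log_trans[t], log_B[t], grid=t + 2)
        op_count += a * a
        delta.append(d)
        backpointers.append(bp)
    seq, log_score = backtrack(delta, backpointers, tables.alphabet)
    total, breakdown = score_sequence(
        seq, _log(p1), log_e1, log_trans, log_B, tables.alphabet
    )
    # the DP maximum must be reproduced exactly by re-scoring the argmax path
    assert abs(total - log_score) < 1e-9 or (
        np.isneginf(total) and np.isneginf(log_score)
    )
    return DecodeResult(
        sequence=seq,
        log_score=log_score,
        delta=delta,
        backpointers=backpointers,
        breakdown=breakdown,
        op_count=op_count,
    )
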