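"""Ramachandran torsion-state classification and coil-library emission tables.

Backbone dihedral pairs are classified into eleven labelled regions of the
(φ, ψ) map — the torsion "states" of the design model: ε′, ε, α_R, γ, δ_R,
δ_L, ζ, γ′, α_L, β_s and β_p.  The same region geometry is reused for the
(ψ_t, φ_{t+1}) plane that couples consecutive residues.  From a coil library
(dihedral observations of non-regular protein fragments, a proxy for
unfolded-state propensities) two emission tables are built:

* a singlet table  P(state m | residue i)        — 20 × 11,
* a neighbor table P(state m | residues i, j)    — 20 × 20 × 11,

whose product is the emission probability of a candidate dipeptide's docked
conformation in the Viterbi decoder.

Region geometry is configurable: it is loaded from an editable YAML file
(see :func:`RegionSet.from_yaml`); the shipped default reproduces the
eleven-state taxonomy with axis-aligned rectangles.  Observations falling in
no region ("strained" conformations) are tallied and excluded when building
tables; at decode time they receive a configurable floor probability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .alphabet import AA_ORDER, aa_index
from .errors import InputError

#: Sentinel state index for points outside all eleven regions.
UNCLASSIFIED: int = 0

#: Canonical names of the eleven torsion states, in frozen state order 1-11.
STATE_NAMES: tuple[str, ...] = (
    "ε′", "ε", "α_R", "γ", "δ_R", "δ_L", "ζ", "γ′", "α_L", "β_s", "β_p",
)

N_STATES: int = 11

_ASCII_NAMES = {
    "eps_prime": "ε′", "epsilon_prime": "ε′",
    "eps": "ε", "epsilon": "ε",
    "alpha_R": "α_R",
    "gamma": "γ",
    "delta_R": "δ_R",
    "delta_L": "δ_L",
    "zeta": "ζ",
    "gamma_prime": "γ′",
    "alpha_L": "α_L",
    "beta_s": "β_s",
    "beta_p": "β_p",
}

_STATE_OF_NAME = {name: i + 1 for i, name in enumerate(STATE_NAMES)}


def canonical_state_name(name: str) -> str:
    """Map an ASCII alias (or canonical name) onto the canonical state name."""
    name = str(name).strip()
    if name in _STATE_OF_NAME:
        return name
    if name in _ASCII_NAMES:
        return _ASCII_NAMES[name]
    raise InputError(f"unknown torsion-state name: {name!r}")


def wrap_angle(x):
    """Wrap an angle in degrees into the half-open interval (-180, 180]."""
    return -((180.0 - np.asarray(x, dtype=float)) % 360.0) + 180.0


@dataclass(frozen=True)
class Region:
    """One axis-aligned rectangle [phi_lo, phi_hi) × [psi_lo, psi_hi) of a state."""

    name: str
    state: int
    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float

    def __post_init__(self):
        if not (self.phi_lo < self.phi_hi and self.psi_lo < self.psi_hi):
            raise InputError(f"region {self.name}: empty interval")


def _in_interval(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # membership on the wrapped axis: the point, or its ±360 image, in [lo, hi)
    return (
        ((v >= lo) & (v < hi))
        | ((v - 360.0 >= lo) & (v - 360.0 < hi))
        | ((v + 360.0 >= lo) & (v + 360.0 < hi))
    )


@dataclass(frozen=True)
class RegionSet:
    """The eleven torsion-angle regions; possibly several rectangles per state."""

    rects: tuple[Region, ...]

    def __post_init__(self):
        names = {r.name for r in self.rects}
        if names != set(STATE_NAMES):
            missing = set(STATE_NAMES) - names
            extra = names - set(STATE_NAMES)
            raise InputError(
                f"region set must cover exactly the 11 canonical states; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    @classmethod
    def from_entries(cls, entries: Iterable[dict]) -> "RegionSet":
        rects = []
        for e in entries:
            name = canonical_state_name(e["name"])
            rects.append(
                Region(
                    name=name,
                    state=_STATE_OF_NAME[name],
                    phi_lo=float(e["phi_lo"]),
                    phi_hi=float(e["phi_hi"]),
                    psi_lo=float(e["psi_lo"]),
                    psi_hi=float(e["psi_hi"]),
                )
            )
        return cls(tuple(rects))

    @classmethod
    def from_yaml(cls, path) -> "RegionSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "regions" not in doc:
            raise InputError(f"region file {path}: expected a top-level 'regions' list")
        return cls.from_entries(doc["regions"])

    @classmethod
    def default(cls) -> "RegionSet":
        """The shipped default region table."""
        text = resources.files("pepdesign").joinpath("data/regions.yaml").read_text()
        return cls.from_entries(yaml.safe_load(text)["regions"])

    def rects_for_state(self, state: int) -> list[Region]:
        return [r for r in self.rects if r.state == state]


def classify_states(phi, psi, regions: RegionSet) -> np.ndarray:
    """Vectorized torsion-state classification.

    Returns an int array of state indices 1-11, with :data:`UNCLASSIFIED` (0)
    where no region contains the wrapped point.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(psi))):
        bad = "phi" if not np.all(np.isfinite(phi)) else "psi"
        raise InputError(f"non-finite angle in field {bad!r}")
    phi_w = wrap_angle(phi)
    psi_w = wrap_angle(psi)
    out = np.zeros(np.broadcast(phi_w, psi_w).shape, dtype=int)
    for rect in regions.rects:
        mask = _in_interval(phi_w, rect.phi_lo, rect.phi_hi) & _in_interval(
            psi_w, rect.psi_lo, rect.psi_hi
        )
        out = np.where(mask & (out == 0), rect.state, out)
    return out


def classify_state(phi: float, psi: float, regions: RegionSet) -> int:
    """Classify a single (φ, ψ) pair; returns 1-11 or UNCLASSIFIED (0)."""
    for name, v in (("phi", phi), ("psi", psi)):
        if not math.isfinite(float(v)):
            raise InputError(f"non-finite angle in field {name!r}: {v!r}")
    return int(classify_states(phi, psi, regions))


# --------------------------------------------------------------------------
# Emission tables
# --------------------------------------------------------------------------

@dataclass
class SingletTable:
    """P(torsion state m | residue type i) over the (φ_t, ψ_t) plane: 20 × 11."""

    values: np.ndarray
    pseudocount: float
    n_unclassified: int

    @classmethod
    def uniform(cls) -> "SingletTable":
        return cls(np.full((20, N_STATES), 1.0 / N_STATES), 0.0, 0)


@dataclass
class PairTable:
    """P(state m of (ψ_t, φ_{t+1}) | residues i, j): 20 × 20 × 11."""

    values: np.ndarray
    pseudocount: float
    n_unclassified: int

    @classmethod
    def uniform(cls) -> "PairTable":
        return cls(np.full((20, 20, N_STATES), 1.0 / N_STATES), 0.0, 0)


def build_singlet_table(
    records: Sequence[tuple], regions: RegionSet, pseudocount: float = 0.5
) -> SingletTable:
    """Build the singlet emission table from coil-library records.

    ``records`` is a sequence of ``(residue, phi, psi)`` tuples (1- or
    3-letter codes).  Counts are normalized per residue row with an additive
    pseudocount per state; records classifying to no region are excluded from
    the counts and tallied in ``n_unclassified``.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    if len(records) == 0 and pseudocount == 0:
        raise InputError("empty record list with pseudocount 0")
    counts = np.zeros((20, N_STATES))
    n_unclassified = 0
    if len(records):
        rows = np.array([aa_index(r[0]) for r in records])
        phis = np.array([float(r[1]) for r in records])
        psis = np.array([float(r[2]) for r in records])
        states = classify_states(phis, psis, regions)
        n_unclassified = int(np.sum(states == UNCLASSIFIED))
        keep = states != UNCLASSIFIED
        np.add.at(counts, (rows[keep], states[keep] - 1), 1.0)
    if pseudocount == 0:
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        if empty.size:
            raise InputError(
                "no classified records for residue(s) "
                f"{', '.join(AA_ORDER[i] for i in empty)} with pseudocount 0"
            )
    values = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + N_STATES * pseudocount
    )
    return SingletTable(values=values, pseudocount=pseudocount, n_unclassified=n_unclassified)


def build_pair_table(
    records: Sequence[tuple], regions: RegionSet, pseudocount: float = 0.5
) -> PairTable:
    """Build the neighbor-pair emission table from coil-library records.

    ``records`` is a sequence of ``(residue_i, residue_j, psi_t, phi_next)``
    tuples.  The (ψ_t, φ_{t+1}) plane uses the same region geometry as the
    (φ, ψ) plane.  Normalization is per (i, j) cell.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    counts = np.zeros((20, 20, N_STATES))
    n_unclassified = 0
    if len(records):
        rows_i = np.array([aa_index(r[0]) for r in records])
        rows_j = np.array([aa_index(r[1]) for r in records])
        psis = np.array([float(r[2]) for r in records])
        phis_next = np.array([float(r[3]) for r in records])
        states = classify_states(psis, phis_next, regions)
        n_unclassified = int(np.sum(states == UNCLASSIFIED))
        keep = states != UNCLASSIFIED
        np.add.at(counts, (rows_i[keep], rows_j[keep], states[keep] - 1), 1.0)
    if pseudocount == 0:
        empty = np.argwhere(counts.sum(axis=2) == 0)
        if empty.size:
            i, j = empty[0]
            raise InputError(
                f"no classified records for residue pair "
                f"({AA_ORDER[i]}, {AA_ORDER[j]}) with pseudocount 0"
            )
    values = (counts + pseudocount) / (
        counts.sum(axis=2, keepdims=True) + N_STATES * pseudocount
    )
    return PairTable(values=values, pseudocount=pseudocount, n_unclassified=n_unclassified)


def emission_probability(
    singlet: SingletTable,
    pair: PairTable,
    i: str,
    j: str,
    m1: int,
    m2: int,
    floor: float = 1e-4,
    singlet_index: str = "i",
) -> float:
    """Emission probability of a candidate dipeptide's torsion observation.

    The product of the singlet probability of state ``m1`` (the (φ_t, ψ_t)
    state) and the neighbor-pair probability of state ``m2`` (the
    (ψ_t, φ_{t+1}) state).  An UNCLASSIFIED state replaces the corresponding
    factor with ``floor``.  ``singlet_index`` selects whether the singlet
    factor is indexed by the residue at grid t (``"i"``, default) or by the
    following residue (``"j"``).
    """
    if floor < 0:
        raise InputError("floor must be >= 0")
    if singlet_index not in ("i", "j"):
        raise InputError(f"singlet_index must be 'i' or 'j', got {singlet_index!r}")
    ii, jj = aa_index(i), aa_index(j)
    srow = ii if singlet_index == "i" else jj
    for m in (m1, m2):
        if not (0 <= int(m) <= N_STATES):
            raise InputError(f"state index out of range: {m}")
    s = floor if m1 == UNCLASSIFIED else float(singlet.values[srow, m1 - 1])
    p = floor if m2 == UNCLASSIFIED else float(pair.values[ii, jj, m2 - 1])
    return s * p
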