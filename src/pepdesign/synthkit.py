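"""Synthetic fixture generators: the no-download test surface.

Everything the real pipeline consumes can be generated here with known
ground truth: energy tables with a planted optimal sequence, coil libraries
drawn from known torsion-state distributions, docked-pose torsion
observations, toy PDB structures and docking result logs.  All generators
are pure functions of their integer seed and spec (bitwise reproducible);
each generator draws from its own named pseudorandom stream, so adding a
generator never perturbs existing fixtures.

The generators emit the same TSV/PDB/log formats the production readers
consume, so fixtures and real inputs are interchangeable.  They do not
attempt to simulate docking physics: the noise model is plain Gaussian in
energy space, with truncation that keeps a planted path strictly dominant
(sufficient condition: margin > 4·noise_sd).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, ONE_TO_THREE, validate_alphabet
from .chain_model import EnergyTables
from .decoder import ObservationSet
from .errors import InputError
from .ramachandran import N_STATES, UNCLASSIFIED, RegionSet, classify_states

# named pseudorandom streams (one per generator)
_STREAMS = {
    "energy": 1,
    "torsion_library": 2,
    "observations": 3,
    "pdb": 4,
    "docking_log": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PlantSpec:
    """Specification of a planted-optimum energy instance.

    ``margin`` (kcal/mol) is how far below the baseline every planted cell
    sits; competing cells receive Gaussian noise truncated so the planted
    path stays strictly dominant.  margin > 4·noise_sd is the documented
    sufficient condition for recovery.
    """

    planted_sequence: str
    margin: float = 1.0
    base_energy: float = -5.0
    noise_sd: float = 0.0
    seed: int = 0
    alphabet: str = AA_ORDER

    def __post_init__(self):
        object.__setattr__(self, "alphabet", validate_alphabet(self.alphabet))
        seq = "".join(self.planted_sequence).upper()
        object.__setattr__(self, "planted_sequence", seq)
        if len(seq) < 2:
            raise InputError("planted sequence must have length >= 2")
        if any(a not in self.alphabet for a in seq):
            raise InputError("planted sequence must use the spec's alphabet")
        if self.margin < 0 or self.noise_sd < 0:
            raise InputError("margin and noise_sd must be >= 0")

    @property
    def n(self) -> int:
        return len(self.planted_sequence)


def synth_energy_tables(spec: PlantSpec) -> EnergyTables:
    """Energy tables whose unique optimal path is the planted sequence.

    Planted cells get ``base_energy − margin``; every other cell gets
    ``base_energy`` plus Gaussian noise clipped at −margin/2, which keeps
    any competing path strictly above the planted one.
    """
    rng = _rng(spec.seed, "energy")
    a = len(spec.alphabet)
    idx = [spec.alphabet.index(c) for c in spec.planted_sequence]

    def noise(shape):
        if spec.noise_sd == 0:
            return np.zeros(shape)
        raw = rng.normal(0.0, spec.noise_sd, size=shape)
        return np.clip(raw, -spec.margin / 2.0, None)

    first = spec.base_energy + noise(a)
    first[idx[0]] = spec.base_energy - spec.margin
    pair_grids = []
    for t in range(spec.n - 1):
        m = spec.base_energy + noise((a, a))
        m[idx[t], idx[t + 1]] = spec.base_energy - spec.margin
        pair_grids.append(m)
    return EnergyTables(first_grid=first, pair_grids=pair_grids, alphabet=spec.alphabet)


# --------------------------------------------------------------------------
# Torsion-state sampling within the region geometry
# --------------------------------------------------------------------------

def _sample_in_state(state: int, regions: RegionSet, rng) -> tuple:
    """Uniform point within a state's rectangle(s), area-weighted."""
    rects = regions.rects_for_state(int(state))
    if not rects:
        raise InputError(f"no rectangles for state {state}")
    areas = np.array(
        [(r.phi_hi - r.phi_lo) * (r.psi_hi - r.psi_lo) for r in rects], dtype=float
    )
    r = rects[rng.choice(len(rects), p=areas / areas.sum())]
    return (
        float(rng.uniform(r.phi_lo, r.phi_hi)),
        float(rng.uniform(r.psi_lo, r.psi_hi)),
    )


def synth_torsion_library(
    state_distribution: dict,
    n_records: int,
    seed: int,
    regions: RegionSet,
    pair: bool = False,
) -> list:
    """Coil-library records drawn from known per-residue state distributions.

    ``state_distribution`` maps a residue (singlet mode) or a
    ``(residue_i, residue_j)`` tuple (pair mode) to an 11-vector of state
    probabilities.  ``n_records`` records are drawn per key; angles are
    uniform within the target state's rectangle(s), so every record
    classifies back to its drawn state.
    """
    rng = _rng(seed, "torsion_library")
    records = []
    for key in state_distribution:
        p = np.asarray(state_distribution[key], dtype=float)
        if p.shape != (N_STATES,) or not np.isclose(p.sum(), 1.0):
            raise InputError(f"state distribution for {key!r} must be a normalized 11-vector")
        states = rng.choice(N_STATES, size=n_records, p=p) + 1
        for s in states:
            x, y = _sample_in_state(int(s), regions, rng)
            if pair:
                ri, rj = key
                records.append((ri, rj, x, y))
            else:
                records.append((key, x, y))
    return records


# --------------------------------------------------------------------------
# Docked-pose torsion observations
# --------------------------------------------------------------------------

#: Representative interior point of the right-handed helical state (state 3);
#: (ψ_t = −40, φ_{t+1} = −40) also classifies to state 3 on the coupling plane.
_UNIFORM_POINT = (-90.0, -40.0, -40.0)


def synth_observations(
    tables: EnergyTables,
    rule="uniform",
    seed: int = 0,
    regions: RegionSet | None = None,
    planted_sequence: str | None = None,
) -> ObservationSet:
    """A complete observation set for every candidate at every grid.

    Rules:

    * ``"uniform"`` — one fixed torsion triple (a helical-state interior
      point) for every candidate, neutralizing emissions for energy-only
      tests;
    * ``"random"`` — per-candidate random torsions, drawn region-first so
      most observations classify (needs ``regions``);
    * ``"adversarial"`` — the planted path's candidates are marked
      unclassified (state 0) while everything else gets the uniform state;
      with an emission floor of zero this vetoes the planted path;
    * a callable ``rule(t, i, j)`` returning a state for the first grid
      (``t = 0``, ``j is None``) or an ``(m1, m2)`` tuple for grid pair t.
    """
    a = len(tables.alphabet)
    n = tables.n
    if rule == "uniform":
        if regions is None:
            regions = RegionSet.default()
        phi, psi, phi_next = _UNIFORM_POINT
        first = np.tile([phi, psi], (a, 1))
        pairs = [np.tile([phi, psi, phi_next], (a, a, 1)) for _ in range(n - 1)]
        return ObservationSet.from_torsions(tables.alphabet, first, pairs, regions)
    if rule == "random":
        if regions is None:
            raise InputError("random observation rule needs a RegionSet")
        rng = _rng(seed, "observations")
        first = np.empty((a, 2))
        for i in range(a):
            first[i] = _sample_in_state(rng.integers(1, N_STATES + 1), regions, rng)
        pairs = []
        for _ in range(n - 1):
            tor = np.empty((a, a, 3))
            for i in range(a):
                for j in range(a):
                    phi, psi = _sample_in_state(
                        rng.integers(1, N_STATES + 1), regions, rng
                    )
                    # choose phi_next so (psi, phi_next) lands in some region
                    compat = [
                        r for r in regions.rects
                        if r.phi_lo <= psi < r.phi_hi
                    ]
                    if compat:
                        r = compat[rng.integers(len(compat))]
                        phi_next = float(rng.uniform(r.psi_lo, r.psi_hi))
                    else:
                        phi_next = float(rng.uniform(-180.0, 180.0))
                    tor[i, j] = (phi, psi, phi_next)
            pairs.append(tor)
        return ObservationSet.from_torsions(tables.alphabet, first, pairs, regions)
    if rule == "adversarial":
        if planted_sequence is None:
            raise InputError("adversarial rule needs the planted sequence")
        idx = [tables.alphabet.index(c) for c in planted_sequence]
        uniform = synth_observations(tables, "uniform", seed, regions)
        first = uniform.first_states.copy()
        first[idx[0]] = UNCLASSIFIED
        pair_states = []
        for t, ps in enumerate(uniform.pair_states):
            ps = ps.copy()
            ps[idx[t], idx[t + 1]] = UNCLASSIFIED
            pair_states.append(ps)
        return ObservationSet(
            alphabet=tables.alphabet, first_states=first, pair_states=pair_states
        )
    if callable(rule):
        first = np.array([int(rule(0, i, None)) for i in range(a)])
        pair_states = []
        for t in range(1, n):
            ps = np.empty((a, a, 2), dtype=int)
            for i in range(a):
                for j in range(a):
                    ps[i, j] = rule(t, i, j)
            pair_states.append(ps)
        return ObservationSet(
            alphabet=tables.alphabet, first_states=first, pair_states=pair_states
        )
    raise InputError(f"unknown observation rule: {rule!r}")


# --------------------------------------------------------------------------
# Forward-kinematics backbone builder (ideal geometry)
# --------------------------------------------------------------------------

# ideal backbone geometry (Å, degrees)
_BOND_C_N = 1.329
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_ANGLE_C_N_CA = 121.7
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_OMEGA_TRANS = 180.0


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with given bond length |cd|, angle b-c-d and torsion a-b-c-d."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nrm = nrm / np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.cos(chi) * np.sin(theta),
            bond * np.sin(chi) * np.sin(theta),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * nrm


def build_dipeptide_backbone(phi_t: float, psi_t: float, phi_next: float) -> dict:
    """Ace-capped dipeptide backbone with prescribed (φ_t, ψ_t, φ_{t+1}).

    Returns the label → coordinate mapping consumed by
    :func:`pepdesign.path_grid.backbone_torsions`; ω is fixed trans.
    """
    ace_c = np.zeros(3)
    n1 = np.array([_BOND_C_N, 0.0, 0.0])
    phi0 = np.pi - np.radians(_ANGLE_C_N_CA)
    ca1 = n1 + _BOND_N_CA * np.array([np.cos(phi0), np.sin(phi0), 0.0])
    c1 = _place(ace_c, n1, ca1, _BOND_CA_C, _ANGLE_N_CA_C, phi_t)
    n2 = _place(n1, ca1, c1, _BOND_C_N, _ANGLE_CA_C_N, psi_t)
    ca2 = _place(ca1, c1, n2, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA_TRANS)
    c2 = _place(c1, n2, ca2, _BOND_CA_C, _ANGLE_N_CA_C, phi_next)
    return {
        "ACE_C": ace_c, "N1": n1, "CA1": ca1, "C1": c1,
        "N2": n2, "CA2": ca2, "C2": c2,
    }


def build_residue_backbone(phi: float, psi: float) -> dict:
    """Ace-capped single residue plus the next nitrogen (closes ψ)."""
    full = build_dipeptide_backbone(phi, psi, -60.0)
    return {k: full[k] for k in ("ACE_C", "N1", "CA1", "C1", "N2")}


# --------------------------------------------------------------------------
# Toy PDB structures
# --------------------------------------------------------------------------

def write_toy_pdb(residues: list, chain_id: str = "A") -> str:
    """PDB text with one CA atom per residue (optionally several altlocs).

    ``residues`` is a list of ``(res_num, res_name, conformers)`` where
    ``conformers`` is a list of ``(altloc, occupancy, (x, y, z))``; use
    altloc ``""`` for a single conformer.
    """
    lines = []
    serial = 1
    for res_num, res_name, conformers in residues:
        for altloc, occ, (x, y, z) in conformers:
            al = altloc if altloc else " "
            lines.append(
                f"ATOM  {serial:5d}  CA {al}{res_name:<3s} {chain_id}{res_num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Docking result logs
# --------------------------------------------------------------------------

def synth_docking_log(
    runs: list,
    single: bool = False,
    res_i: str = "ALA",
    res_j: str = "ALA",
) -> str:
    """Docking-log text in the tolerant dialect the parser consumes.

    ``runs`` is a list of ``(energy, torsions)`` with torsions ``(φ, ψ)``
    for a single amino acid or ``(φ_t, ψ_t, φ_{t+1})`` for a dipeptide;
    coordinates come from the forward-kinematics backbone builder.
    """
    out = []
    for run_no, (energy, torsions) in enumerate(runs, start=1):
        out.append(f"Run: {run_no}")
        out.append(
            f"DOCKED: USER Estimated Free Energy of Binding = {energy:+.2f} kcal/mol"
        )
        if single:
            phi, psi = torsions
            labels = build_residue_backbone(phi, psi)
            atoms = [
                ("ACE", 1, "C", labels["ACE_C"]),
                (res_i, 2, "N", labels["N1"]),
                (res_i, 2, "CA", labels["CA1"]),
                (res_i, 2, "C", labels["C1"]),
                ("NME", 3, "N", labels["N2"]),
            ]
        else:
            phi_t, psi_t, phi_next = torsions
            labels = build_dipeptide_backbone(phi_t, psi_t, phi_next)
            atoms = [
                ("ACE", 1, "C", labels["ACE_C"]),
                (res_i, 2, "N", labels["N1"]),
                (res_i, 2, "CA", labels["CA1"]),
                (res_i, 2, "C", labels["C1"]),
                (res_j, 3, "N", labels["N2"]),
                (res_j, 3, "CA", labels["CA2"]),
                (res_j, 3, "C", labels["C2"]),
            ]
        for serial, (rname, rseq, aname, xyz) in enumerate(atoms, start=1):
            x, y, z = (float(v) for v in xyz)
            out.append(
                f"DOCKED: ATOM {serial} {aname} {rname} {rseq} "
                f"{x:.4f} {y:.4f} {z:.4f}"
            )
    return "\n".join(out) + "\n"


def synth_log_directory(
    tables: EnergyTables,
    first_torsions: np.ndarray,
    pair_torsions: list,
    out_dir,
) -> None:
    """Write a complete docking-log directory for the given instance."""
    root = Path(out_dir)
    (root / "grid1").mkdir(parents=True, exist_ok=True)
    al = tables.alphabet
    for i, aa in enumerate(al):
        text = synth_docking_log(
            [(float(tables.first_grid[i]), tuple(first_torsions[i]))],
            single=True,
            res_i=ONE_TO_THREE[aa],
        )
        (root / "grid1" / f"{aa}.log").write_text(text)
    for t, (m, tor) in enumerate(zip(tables.pair_grids, pair_torsions), start=1):
        d = root / f"pair{t}"
        d.mkdir(parents=True, exist_ok=True)
        for i, ai in enumerate(al):
            for j, aj in enumerate(al):
                text = synth_docking_log(
                    [(float(m[i, j]), tuple(tor[i, j]))],
                    single=False,
                    res_i=ONE_TO_THREE[ai],
                    res_j=ONE_TO_THREE[aj],
                )
                (d / f"{ai}{aj}.log").write_text(text)


def synth_design_fixture(spec: PlantSpec, out_dir, regions: RegionSet | None = None) -> dict:
    """Write a complete, self-consistent design fixture directory.

    Produces results TSVs (planted energies + uniform-rule torsions) and a
    small coil library drawn from the uniform 11-state distribution for every
    residue and pair over the spec's alphabet.  Returns the path map.
    """
    from .io_backends import write_coil_pair, write_coil_singlet, write_results_tsv

    if regions is None:
        regions = RegionSet.default()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    tables = synth_energy_tables(spec)
    obs = synth_observations(tables, "uniform", spec.seed, regions)
    paths = {
        "first_grid": root / "first_grid.tsv",
        "pairs": root / "pairs.tsv",
        "coil_singlet": root / "coil_singlet.tsv",
        "coil_pair": root / "coil_pair.tsv",
    }
    write_results_tsv(
        tables, obs.first_torsions, obs.pair_torsions,
        paths["first_grid"], paths["pairs"],
    )
    uniform = np.full(N_STATES, 1.0 / N_STATES)
    singlet_records = synth_torsion_library(
        {aa: uniform for aa in spec.alphabet}, 33, spec.seed, regions
    )
    pair_records = synth_torsion_library(
        {(ai, aj): uniform for ai in spec.alphabet for aj in spec.alphabet},
        5, spec.seed, regions, pair=True,
    )
    write_coil_singlet(singlet_records, paths["coil_singlet"])
    write_coil_pair(pair_records, paths["coil_pair"])
    return {k: str(v) for k, v in paths.items()}
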