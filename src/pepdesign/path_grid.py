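"""Binding-path and grid-box geometry, and backbone dihedral computation.

The designed peptide's residues sit on an ordered path of "chiral carbon"
positions on the protein surface — implemented as the Cα atoms of either a
docked probe peptide or the partner protein's interface residues (glycine,
though not formally chiral, contributes its Cα like every other residue).
Each path point is the center of a cubic docking grid box whose edge is 2.5
times the candidate's nitrogen-to-terminal-carbon backbone span.

Dihedrals follow the standard IUPAC sign convention; angles are degrees in
(−180, 180] and coordinates are Å throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import gemmi
import numpy as np

from .errors import InputError
from .ramachandran import wrap_angle

#: Grid-box edge multiplier applied to the backbone N-to-C span.
BOX_EDGE_FACTOR: float = 2.5


@dataclass(frozen=True)
class GridBox:
    """A cubic docking search box: center (Å) and edge length (Å)."""

    center: tuple
    edge: float

    def __post_init__(self):
        if not (self.edge > 0):
            raise InputError(f"grid box edge must be positive, got {self.edge}")


def _load_structure(structure) -> gemmi.Structure:
    if isinstance(structure, gemmi.Structure):
        return structure
    return gemmi.read_pdb(str(structure))


def extract_ca_path(
    structure: Union[str, gemmi.Structure],
    chain_id: str,
    residue_ids: Sequence[int],
) -> np.ndarray:
    """Cα coordinates of the requested residues, in the given order.

    ``residue_ids`` use the author (1-based) numbering of the PDB record.
    When alternate locations exist, the highest-occupancy conformer wins
    (ties: the first listed).  Returns an (n, 3) array in Å.
    """
    st = _load_structure(structure)
    if len(st) == 0:
        raise InputError("structure contains no models")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise InputError(f"chain {chain_id!r} not found in structure")
    by_num = {}
    for res in chain:
        by_num.setdefault(res.seqid.num, res)
    coords = []
    for rid in residue_ids:
        res = by_num.get(int(rid))
        if res is None:
            raise InputError(f"residue {rid} not found in chain {chain_id!r}")
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            raise InputError(
                f"no CA atom for residue {rid} in chain {chain_id!r}"
            )
        best = max(cas, key=lambda a: a.occ)  # max() keeps the first on ties
        coords.append([best.pos.x, best.pos.y, best.pos.z])
    return np.asarray(coords, dtype=float)


def grid_boxes(
    path: np.ndarray,
    spans: Union[float, Sequence[float]],
    screening: bool = False,
) -> list[GridBox]:
    """One grid box per path point; edge = 2.5 × backbone span.

    ``spans`` is a single N-to-terminal-C backbone distance (Å) or one per
    path point.  With ``screening=True`` the largest span sizes every box so
    a single box accommodates all 20 (or 400) candidates.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 3 or path.shape[0] < 2:
        raise InputError(f"path must be an (n>=2, 3) array, got shape {path.shape}")
    if np.any(np.linalg.norm(np.diff(path, axis=0), axis=1) == 0):
        raise InputError("consecutive path points must be distinct")
    n = path.shape[0]
    spans = np.broadcast_to(np.asarray(spans, dtype=float), (n,)).copy()
    if np.any(spans <= 0):
        raise InputError("backbone spans must be positive")
    if screening:
        spans[:] = spans.max()
    return [
        GridBox(center=tuple(map(float, c)), edge=float(BOX_EDGE_FACTOR * s))
        for c, s in zip(path, spans)
    ]


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral (degrees, (−180, 180]) about the p2–p3 axis."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or norm_b2 < 1e-9:
        raise InputError("undefined dihedral: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / norm_b2))
    ang = np.degrees(np.arctan2(y, x))
    return float(wrap_angle(ang))


#: Atom labels expected by backbone_torsions: the Ace-cap carbonyl carbon and
#: the N/CA/C backbone atoms of the two residues.
BACKBONE_LABELS = ("ACE_C", "N1", "CA1", "C1", "N2", "CA2", "C2")


def backbone_torsions(atoms: Mapping[str, Sequence[float]]) -> tuple:
    """(φ_t, ψ_t, φ_{t+1}) of an Ace-capped dipeptide.

    ``atoms`` maps the labels in :data:`BACKBONE_LABELS` to 3D coordinates.
    The Ace N-cap supplies the carbonyl carbon that defines φ_t:
    φ_t = C(ace)–N1–CA1–C1, ψ_t = N1–CA1–C1–N2, φ_{t+1} = C1–N2–CA2–C2.
    """
    coords = {}
    for label in BACKBONE_LABELS:
        if label not in atoms:
            raise InputError(f"missing backbone atom {label!r}")
        coords[label] = np.asarray(atoms[label], dtype=float)
    phi_t = dihedral(coords["ACE_C"], coords["N1"], coords["CA1"], coords["C1"])
    psi_t = dihedral(coords["N1"], coords["CA1"], coords["C1"], coords["N2"])
    phi_next = dihedral(coords["C1"], coords["N2"], coords["CA2"], coords["C2"])
    return phi_t, psi_t, phi_next


def single_residue_torsions(atoms: Mapping[str, Sequence[float]]) -> tuple:
    """(φ_1, ψ_1) of an Ace-capped single residue followed by the next N.

    Needs labels ACE_C, N1, CA1, C1 and N2 (the capping/next nitrogen that
    closes ψ_1).
    """
    for label in ("ACE_C", "N1", "CA1", "C1", "N2"):
        if label not in atoms:
            raise InputError(f"missing backbone atom {label!r}")
    c = {k: np.asarray(v, dtype=float) for k, v in atoms.items()}
    phi = dihedral(c["ACE_C"], c["N1"], c["CA1"], c["C1"])
    psi = dihedral(c["N1"], c["CA1"], c["C1"], c["N2"])
    return phi, psi


def export_grid_boxes_tsv(boxes: Sequence[GridBox], path) -> None:
    """Write grid boxes as TSV (center_x, center_y, center_z, edge)."""
    with open(path, "w") as fh:
        fh.write("center_x\tcenter_y\tcenter_z\tedge\n")
        for b in boxes:
            fh.write(
                f"{b.center[0]!r}\t{b.center[1]!r}\t{b.center[2]!r}\t{b.edge!r}\n"
            )
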