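"""Readers, writers and the pluggable energy backend.

Two interchangeable sources feed the design pipeline:

* the canonical plain-TSV results format (energies plus docked torsion
  angles), which is what fixtures and tests use, and
* a directory of docking result logs (one per candidate per grid) in a
  tolerant, line-oriented dialect of the classic docking-log structure:
  run blocks, an "Estimated Free Energy of Binding = X kcal/mol" line and
  ATOM coordinate records (optionally prefixed with "DOCKED:").

Both produce an :class:`~pepdesign.chain_model.EnergyTables` and an
:class:`~pepdesign.decoder.ObservationSet`.  Invoking a docking program is
out of scope; only its results are consumed.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .alphabet import AA_ORDER, normalize_residue, validate_alphabet
from .chain_model import EnergyTables
from .decoder import ObservationSet
from .errors import InputError, ParseError
from .path_grid import backbone_torsions, single_residue_torsions
from .ramachandran import RegionSet


def _read_tsv(path, required: set) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# Energy tables (TSV)
# --------------------------------------------------------------------------

def read_energy_tables(first_grid_file, pair_file, alphabet: str = AA_ORDER) -> EnergyTables:
    """Read first-grid and pair energy TSVs with strict completeness checks."""
    alphabet = validate_alphabet(alphabet)
    a = len(alphabet)
    first = _read_tsv(first_grid_file, {"aa", "energy_kcal_mol"})
    e1 = {}
    for _, row in first.iterrows():
        aa = normalize_residue(row["aa"])
        if aa not in alphabet:
            raise InputError(f"{first_grid_file}: residue {aa} outside alphabet")
        if aa in e1:
            raise InputError(f"{first_grid_file}: duplicate row for residue {aa}")
        e1[aa] = float(row["energy_kcal_mol"])
    missing = [aa for aa in alphabet if aa not in e1]
    if missing:
        raise InputError(
            f"{first_grid_file}: missing first-grid energies for {missing}"
        )

    pair = _read_tsv(pair_file, {"grid_t", "aa_i", "aa_j", "energy_kcal_mol"})
    cells: dict = {}
    for line_no, row in enumerate(pair.itertuples(index=False), start=2):
        t = int(row.grid_t)
        ai, aj = normalize_residue(row.aa_i), normalize_residue(row.aa_j)
        if ai not in alphabet or aj not in alphabet:
            raise InputError(f"{pair_file}: residue pair ({ai}, {aj}) outside alphabet")
        key = (t, ai, aj)
        e = float(row.energy_kcal_mol)
        if key in cells:
            raise InputError(
                f"{pair_file}: duplicate cell (grid {t}, {ai}, {aj}) at line {line_no}"
            )
        cells[key] = e
    grids = sorted({k[0] for k in cells})
    if not grids or grids != list(range(1, len(grids) + 1)):
        raise InputError(f"{pair_file}: grid indices must be contiguous from 1, got {grids}")
    pair_grids = []
    for t in range(1, len(grids) + 1):
        m = np.empty((a, a))
        missing_cells = []
        for i, ai in enumerate(alphabet):
            for j, aj in enumerate(alphabet):
                key = (t, ai, aj)
                if key not in cells:
                    missing_cells.append((t, ai, aj))
                else:
                    m[i, j] = cells[key]
        if missing_cells:
            raise InputError(f"{pair_file}: missing cell(s) {missing_cells[:5]}")
        pair_grids.append(m)
    return EnergyTables(
        first_grid=np.array([e1[aa] for aa in alphabet]),
        pair_grids=pair_grids,
        alphabet=alphabet,
    )


def write_energy_tables(tables: EnergyTables, first_grid_file, pair_file) -> None:
    """Write energy TSVs in normalized form (canonical order, repr floats)."""
    with open(first_grid_file, "w") as fh:
        fh.write("aa\tenergy_kcal_mol\n")
        for aa, e in zip(tables.alphabet, tables.first_grid):
            fh.write(f"{aa}\t{float(e)!r}\n")
    with open(pair_file, "w") as fh:
        fh.write("grid_t\taa_i\taa_j\tenergy_kcal_mol\n")
        for t, m in enumerate(tables.pair_grids, start=1):
            for i, ai in enumerate(tables.alphabet):
                for j, aj in enumerate(tables.alphabet):
                    fh.write(f"{t}\t{ai}\t{aj}\t{float(m[i, j])!r}\n")


# --------------------------------------------------------------------------
# Results TSV (energies + docked torsions): the canonical interchange format
# --------------------------------------------------------------------------

def write_results_tsv(
    tables: EnergyTables,
    first_torsions: np.ndarray,
    pair_torsions: Sequence[np.ndarray],
    first_file,
    pair_file,
) -> None:
    al = tables.alphabet
    with open(first_file, "w") as fh:
        fh.write("aa\tenergy_kcal_mol\tphi\tpsi\n")
        for i, aa in enumerate(al):
            fh.write(
                f"{aa}\t{float(tables.first_grid[i])!r}\t"
                f"{float(first_torsions[i, 0])!r}\t{float(first_torsions[i, 1])!r}\n"
            )
    with open(pair_file, "w") as fh:
        fh.write("grid_t\taa_i\taa_j\tenergy_kcal_mol\tphi_t\tpsi_t\tphi_next\n")
        for t, (m, tor) in enumerate(zip(tables.pair_grids, pair_torsions), start=1):
            for i, ai in enumerate(al):
                for j, aj in enumerate(al):
                    fh.write(
                        f"{t}\t{ai}\t{aj}\t{float(m[i, j])!r}\t"
                        f"{float(tor[i, j, 0])!r}\t{float(tor[i, j, 1])!r}\t"
                        f"{float(tor[i, j, 2])!r}\n"
                    )


def read_results_tsv(first_file, pair_file, alphabet: str = AA_ORDER):
    """Read the canonical results format.

    Returns ``(EnergyTables, first_torsions, pair_torsions)`` where the
    torsion arrays are (A, 2) and a list of (A, A, 3).
    """
    alphabet = validate_alphabet(alphabet)
    a = len(alphabet)
    tables = read_energy_tables(first_file, pair_file, alphabet=alphabet)

    first = _read_tsv(first_file, {"aa", "phi", "psi"})
    first_torsions = np.empty((a, 2))
    for _, row in first.iterrows():
        i = alphabet.index(normalize_residue(row["aa"]))
        first_torsions[i] = (float(row["phi"]), float(row["psi"]))

    pair = _read_tsv(pair_file, {"grid_t", "aa_i", "aa_j", "phi_t", "psi_t", "phi_next"})
    pair_torsions = [np.empty((a, a, 3)) for _ in tables.pair_grids]
    for row in pair.itertuples(index=False):
        t = int(row.grid_t) - 1
        i = alphabet.index(normalize_residue(row.aa_i))
        j = alphabet.index(normalize_residue(row.aa_j))
        pair_torsions[t][i, j] = (
            float(row.phi_t), float(row.psi_t), float(row.phi_next)
        )
    return tables, first_torsions, pair_torsions


def load_results(first_file, pair_file, regions: RegionSet, alphabet: str = AA_ORDER):
    """Read the results TSVs and classify torsions into an ObservationSet."""
    tables, first_torsions, pair_torsions = read_results_tsv(
        first_file, pair_file, alphabet=alphabet
    )
    obs = ObservationSet.from_torsions(
        tables.alphabet, first_torsions, pair_torsions, regions
    )
    return tables, obs


# --------------------------------------------------------------------------
# Coil-library TSV
# --------------------------------------------------------------------------

def read_coil_singlet(path) -> list:
    """Coil-library singlet records: columns {res, phi, psi}."""
    df = _read_tsv(path, {"res", "phi", "psi"})
    return [
        (normalize_residue(r.res), float(r.phi), float(r.psi))
        for r in df.itertuples(index=False)
    ]


def read_coil_pair(path) -> list:
    """Coil-library neighbor-pair records: columns {res_i, res_j, psi_t, phi_next}."""
    df = _read_tsv(path, {"res_i", "res_j", "psi_t", "phi_next"})
    return [
        (
            normalize_residue(r.res_i),
            normalize_residue(r.res_j),
            float(r.psi_t),
            float(r.phi_next),
        )
        for r in df.itertuples(index=False)
    ]


def write_coil_singlet(records: Sequence[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("res\tphi\tpsi\n")
        for res, phi, psi in records:
            fh.write(f"{res}\t{float(phi)!r}\t{float(psi)!r}\n")


def write_coil_pair(records: Sequence[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("res_i\tres_j\tpsi_t\tphi_next\n")
        for ri, rj, psi_t, phi_next in records:
            fh.write(f"{ri}\t{rj}\t{float(psi_t)!r}\t{float(phi_next)!r}\n")


# --------------------------------------------------------------------------
# Docking result logs
# --------------------------------------------------------------------------

@dataclass
class DockingRunRecord:
    """One docking run: its index, binding energy and docked coordinates."""

    run: int
    binding_energy: float   # kcal/mol
    atoms: list             # (res_name, res_seq, atom_name, (x, y, z))


_ENERGY_RE = re.compile(r"Estimated\s+Free\s+Energy\s+of\s+Binding\s*=\s*(\S+)", re.I)
_RUN_RE = re.compile(r"^\s*Run[:\s=]+(\d+)", re.I)


def parse_docking_log(text: str) -> DockingRunRecord:
    """Parse a docking result log and return the best (lowest-energy) run.

    Ties in energy resolve to the earliest run.  Raises :class:`ParseError`
    when the log contains no run blocks or an energy line is unreadable.
    """
    records: list[DockingRunRecord] = []
    current: Optional[DockingRunRecord] = None
    pending_run: Optional[int] = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("DOCKED:"):
            line = line[len("DOCKED:"):].strip()
        m = _RUN_RE.match(line)
        if m:
            pending_run = int(m.group(1))
            continue
        m = _ENERGY_RE.search(line)
        if m:
            try:
                energy = float(m.group(1))
            except ValueError:
                raise ParseError(
                    f"line {line_no}: unparseable binding energy {m.group(1)!r}"
                )
            run = pending_run if pending_run is not None else len(records) + 1
            current = DockingRunRecord(run=run, binding_energy=energy, atoms=[])
            records.append(current)
            pending_run = None
            continue
        if line.startswith(("ATOM", "HETATM")) and current is not None:
            parts = line.split()
            if len(parts) < 8:
                raise ParseError(f"line {line_no}: malformed coordinate record")
            try:
                x, y, z = (float(v) for v in parts[5:8])
                res_seq = int(parts[4])
            except ValueError:
                raise ParseError(f"line {line_no}: malformed coordinate record")
            current.atoms.append((parts[3], res_seq, parts[2], (x, y, z)))
    if not records:
        raise ParseError("no docking run blocks found in log")
    return min(records, key=lambda r: r.binding_energy)  # min keeps earliest tie


def _torsions_from_record(record: DockingRunRecord, single: bool) -> tuple:
    """Map a docked pose's named backbone atoms to torsion angles."""
    ace_c = None
    residues: dict = {}
    for res_name, res_seq, atom_name, xyz in record.atoms:
        if res_name == "ACE" and atom_name == "C":
            ace_c = xyz
        elif res_name != "ACE":
            residues.setdefault(res_seq, {})[atom_name] = xyz
    if ace_c is None:
        raise InputError("missing backbone atom 'ACE_C'")
    seqs = sorted(residues)
    labels = {"ACE_C": ace_c}
    if single:
        if len(seqs) < 2:
            raise InputError("single-residue pose needs the next nitrogen (e.g. NME)")
        r1, r2 = residues[seqs[0]], residues[seqs[1]]
        for lbl, src, name in (
            ("N1", r1, "N"), ("CA1", r1, "CA"), ("C1", r1, "C"), ("N2", r2, "N"),
        ):
            if name not in src:
                raise InputError(f"missing backbone atom {lbl!r}")
            labels[lbl] = src[name]
        return single_residue_torsions(labels)
    if len(seqs) < 2:
        raise InputError("dipeptide pose needs two residues after the Ace cap")
    r1, r2 = residues[seqs[0]], residues[seqs[1]]
    for lbl, src, name in (
        ("N1", r1, "N"), ("CA1", r1, "CA"), ("C1", r1, "C"),
        ("N2", r2, "N"), ("CA2", r2, "CA"), ("C2", r2, "C"),
    ):
        if name not in src:
            raise InputError(f"missing backbone atom {lbl!r}")
        labels[lbl] = src[name]
    return backbone_torsions(labels)


class LogDirBackend:
    """Energy backend over a directory of docking logs.

    Expected layout (one log per candidate per grid, ``.log`` or ``.dlg``)::

        root/grid1/<A>.log          single amino-acid candidates
        root/pair<t>/<AB>.log       dipeptide candidates, t = 1 .. n-1

    Energies are the best-run binding energies; torsion observations are
    computed from the best run's docked coordinates.
    """

    def __init__(self, directory, alphabet: str = AA_ORDER):
        self.root = Path(directory)
        self.alphabet = validate_alphabet(alphabet)
        if not (self.root / "grid1").is_dir():
            raise InputError(f"{self.root}: missing grid1/ directory")
        t = 1
        while (self.root / f"pair{t}").is_dir():
            t += 1
        self.n = t
        if self.n < 2:
            raise InputError(f"{self.root}: missing pair1/ directory")
        self._check_complete()

    def _log_path(self, subdir: str, stem: str) -> Path:
        for ext in (".log", ".dlg"):
            p = self.root / subdir / f"{stem}{ext}"
            if p.exists():
                return p
        raise InputError(f"missing candidate log: {subdir}/{stem}.log")

    def _check_complete(self):
        for aa in self.alphabet:
            self._log_path("grid1", aa)
        for t in range(1, self.n):
            for ai in self.alphabet:
                for aj in self.alphabet:
                    self._log_path(f"pair{t}", f"{ai}{aj}")

    def _best(self, subdir: str, stem: str) -> DockingRunRecord:
        p = self._log_path(subdir, stem)
        try:
            return parse_docking_log(p.read_text())
        except ParseError as exc:
            raise ParseError(f"{p}: {exc}") from exc

    def single_entries(self) -> list:
        """(energy, (phi, psi)) for each first-grid candidate, alphabet order."""
        out = []
        for aa in self.alphabet:
            rec = self._best("grid1", aa)
            out.append((rec.binding_energy, _torsions_from_record(rec, single=True)))
        return out

    def pair_entries(self, t: int) -> list:
        """(energy, (phi_t, psi_t, phi_next)) per (i, j), row-major order."""
        out = []
        for ai in self.alphabet:
            for aj in self.alphabet:
                rec = self._best(f"pair{t}", f"{ai}{aj}")
                out.append(
                    (rec.binding_energy, _torsions_from_record(rec, single=False))
                )
        return out

    def to_inputs(self, regions: RegionSet):
        """Assemble (EnergyTables, ObservationSet) from the log directory."""
        a = len(self.alphabet)
        singles = self.single_entries()
        first_grid = np.array([e for e, _ in singles])
        first_torsions = np.array([tor for _, tor in singles])
        pair_grids, pair_torsions = [], []
        for t in range(1, self.n):
            entries = self.pair_entries(t)
            e = np.array([x for x, _ in entries]).reshape(a, a)
            tor = np.array([x for _, x in entries]).reshape(a, a, 3)
            pair_grids.append(e)
            pair_torsions.append(tor)
        tables = EnergyTables(
            first_grid=first_grid, pair_grids=pair_grids, alphabet=self.alphabet
        )
        obs = ObservationSet.from_torsions(
            self.alphabet, first_torsions, pair_torsions, regions
        )
        return tables, obs


def backend_from_logs(directory, alphabet: str = AA_ORDER) -> LogDirBackend:
    """Build a (completeness-validated) energy backend over a log directory."""
    return LogDirBackend(directory, alphabet=alphabet)


# --------------------------------------------------------------------------
# Reports, FASTA, config
# --------------------------------------------------------------------------

def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fasta(sequence: str, path, header: str = "designed_peptide") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n{sequence}\n")


def load_run_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise InputError(f"run config {path}: expected a mapping")
    return doc
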