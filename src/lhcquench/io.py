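"""File I/O: PDB structures, charge tables, spectra / TA matrices (CSV),
parameter sets and ensemble directories.

Conventions: structures are PDB files read and written through biotite;
pigments are extracted by residue name (CLA / CHL / LUT by default).
Spectra and dA surfaces are CSV with a unit-annotated wavenumber first
column and one column per delay (header row carries the delays in ps).
Transition charges are CSV with columns (pigment_id, transition,
atom_name, charge_e).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .exciton import PigmentGeometry, SnapshotEnsemble
from .tafit import TADataset

logger = logging.getLogger("lhcquench")

#: residue name (PDB) -> pigment type used throughout the package
DEFAULT_RESIDUE_MAP = {"CLA": "CLA", "CHL": "CHL", "LUT": "LUT", "XAT": "LUT", "LUX": "LUT"}


class StructureParseError(ValueError):
    """Malformed structure file."""


class ChargeReconciliationError(ValueError):
    """Charge table lists atoms that are absent from the structure."""


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    residue_map: dict[str, str] | None = None,
) -> list[PigmentGeometry]:
    """Extract pigment geometries from a PDB file.

    Residues whose name maps to a pigment type become one
    :class:`PigmentGeometry` each (coordinates in Angstrom, no charges
    or site energies attached yet); unmapped residues are skipped with a
    logged count.
    """
    if residue_map is None:
        residue_map = DEFAULT_RESIDUE_MAP
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        line = _first_bad_atom_line(path)
        where = f" (line {line})" if line else ""
        raise StructureParseError(f"cannot parse {path}{where}: {exc}") from exc
    pigments: list[PigmentGeometry] = []
    skipped = 0
    for chain in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == chain]
        for res_id in np.unique(sub.res_id):
            res = sub[sub.res_id == res_id]
            res_name = str(res.res_name[0])
            ptype = residue_map.get(res_name)
            if ptype is None:
                skipped += 1
                continue
            pigments.append(
                PigmentGeometry(
                    pigment_id=f"{res_name}{int(res_id)}",
                    pigment_type=ptype,
                    positions=np.asarray(res.coord, dtype=float),
                    atom_names=[str(a) for a in res.atom_name],
                )
            )
    if skipped:
        logger.info("read_structure(%s): skipped %d unmapped residues", path, skipped)
    if not pigments:
        raise StructureParseError(f"{path}: no mappable pigment residues found")
    return pigments


def _first_bad_atom_line(path: Path) -> int | None:
    try:
        for k, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    return k
    except OSError:
        return None
    return None


def write_structure(path: str | Path, pigments: list[PigmentGeometry]) -> None:
    """Write pigments as one PDB model (HETATM records, one residue each)."""
    n = sum(len(p.positions) for p in pigments)
    arr = struc.AtomArray(n)
    i = 0
    for res_id, p in enumerate(pigments, start=1):
        names = p.atom_names or [f"X{k}" for k in range(len(p.positions))]
        for name, pos in zip(names, p.positions):
            arr.coord[i] = pos
            arr.chain_id[i] = "A"
            arr.res_id[i] = res_id
            arr.res_name[i] = p.pigment_type
            arr.atom_name[i] = name
            arr.element[i] = name[0] if name and name[0].isalpha() else "C"
            arr.hetero[i] = True
            i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# charge tables
# ---------------------------------------------------------------------------

def write_charge_table(path: str | Path, pigments: list[PigmentGeometry]) -> None:
    rows = []
    for p in pigments:
        names = p.atom_names or [f"X{k}" for k in range(len(p.positions))]
        for transition, q in p.charges.items():
            for name, charge in zip(names, q):
                rows.append((p.pigment_id, transition, name, charge))
    pd.DataFrame(rows, columns=["pigment_id", "transition", "atom_name", "charge_e"]).to_csv(
        path, index=False
    )


def attach_charges(pigments: list[PigmentGeometry], table: pd.DataFrame | str | Path) -> None:
    """Attach transition charges to pigments, matching on atom names.

    Atoms present in the table but absent from the structure raise a
    :class:`ChargeReconciliationError` listing them.
    """
    if not isinstance(table, pd.DataFrame):
        # keep_default_na: atom names like "NA" must not parse as missing
        table = pd.read_csv(table, keep_default_na=False)
    by_id = {p.pigment_id: p for p in pigments}
    for (pid, transition), grp in table.groupby(["pigment_id", "transition"]):
        p = by_id.get(pid)
        if p is None:
            continue
        names = p.atom_names or []
        missing = sorted(set(grp["atom_name"]) - set(names))
        if missing:
            raise ChargeReconciliationError(
                f"pigment {pid}, transition {transition!r}: charge table atoms "
                f"{missing} not present in the structure"
            )
        lookup = dict(zip(grp["atom_name"], grp["charge_e"]))
        p.charges[str(transition)] = np.array([lookup.get(n, 0.0) for n in names], dtype=float)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def write_ensemble(directory: str | Path, ensemble: SnapshotEnsemble) -> None:
    """Snapshot PDBs + per-pigment charge CSV + site-energy / metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, snap in enumerate(ensemble):
        write_structure(directory / f"snapshot_{k:04d}.pdb", snap)
    first = ensemble.snapshots[0]
    write_charge_table(directory / "charges.csv", first)
    roster = [
        {
            "residue_index": i + 1,
            "pigment_id": p.pigment_id,
            "pigment_type": p.pigment_type,
            "site_energy_cm": p.site_energy,
        }
        for i, p in enumerate(first)
    ]
    meta = {"roster": roster, "metadata": ensemble.metadata, "units": {"site_energy": "cm^-1"}}
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_ensemble(directory: str | Path) -> SnapshotEnsemble:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    roster = meta["roster"]
    charge_table = pd.read_csv(directory / "charges.csv", keep_default_na=False)
    snapshots = []
    for path in sorted(directory.glob("snapshot_*.pdb")):
        pigments = read_structure(path)
        if len(pigments) != len(roster):
            raise StructureParseError(f"{path}: roster size mismatch")
        for p, entry in zip(pigments, roster):
            p.pigment_id = entry["pigment_id"]
            p.pigment_type = entry["pigment_type"]
            p.site_energy = entry["site_energy_cm"]
        attach_charges(pigments, charge_table)
        snapshots.append(pigments)
    if not snapshots:
        raise StructureParseError(f"{directory}: no snapshot files found")
    return SnapshotEnsemble(snapshots=snapshots, metadata=meta.get("metadata", {}))


# ---------------------------------------------------------------------------
# spectra and TA surfaces
# ---------------------------------------------------------------------------

def write_spectrum_csv(path: str | Path, wavenumbers: np.ndarray, spectrum: np.ndarray,
                       label: str = "intensity") -> None:
    df = pd.DataFrame({"wavenumber_cm-1": wavenumbers, label: spectrum})
    df["wavelength_nm"] = 1.0e7 / df["wavenumber_cm-1"]
    df.to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["wavenumber_cm-1"].to_numpy(), df[df.columns[1]].to_numpy()


def write_ta_csv(path: str | Path, dataset: TADataset) -> None:
    """First column wavenumber (cm^-1), one column per delay (header in ps)."""
    df = pd.DataFrame(dataset.da, columns=[f"{t:.6g}" for t in dataset.delays])
    df.insert(0, "wavenumber_cm-1", dataset.wavenumbers)
    df.to_csv(path, index=False)


def read_ta_csv(path: str | Path) -> TADataset:
    df = pd.read_csv(path)
    wavenumbers = df["wavenumber_cm-1"].to_numpy()
    delay_cols = [c for c in df.columns if c != "wavenumber_cm-1"]
    delays = np.array([float(c) for c in delay_cols])
    return TADataset(delays=delays, wavenumbers=wavenumbers, da=df[delay_cols].to_numpy())
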