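"""Readers and writers: XYZ/PDB structures, columnar toy coordinates,
path archives and sample stores.

Coordinates are float64 everywhere internally; text formats emit six
decimal places, the documented lossy boundary.  Archives are single-file
NumPy containers with an explicit format version — a mismatch is an error,
never a silent migration.
"""

from __future__ import annotations

import io as _io
from pathlib import Path as FilePath

import numpy as np
from Bio.Data.IUPACData import atom_weights

from .admd import Path
from .remd import SampleStore
from .system import Conformation, MolecularSystem

ARCHIVE_VERSION = 1
STORE_VERSION = 1


def _element_mass(symbol: str) -> float:
    key = symbol.strip().capitalize()
    try:
        return float(atom_weights[key])
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


# ---------------------------------------------------------------- XYZ / PDB

def read_xyz(path) -> tuple[Conformation, MolecularSystem]:
    """Read a single-frame XYZ file (3D; masses from element symbols)."""
    lines = FilePath(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}, line 1: expected an atom count") from None
    labels, coords = [], []
    for i, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}, line {i}: expected 'El x y z'")
        labels.append(parts[0])
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ValueError(
                f"{path}, line {i}: bad coordinate token") from None
    if len(coords) != n:
        raise ValueError(f"{path}: header promises {n} atoms, "
                         f"found {len(coords)}")
    masses = np.array([_element_mass(s) for s in labels])
    system = MolecularSystem(masses, tuple(labels), dim=3)
    return Conformation(np.array(coords), system), system


def write_xyz(path, coords: np.ndarray, labels, comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(coords)}\n{comment}\n")
        for label, xyz in zip(labels, coords):
            fh.write(f"{label} " + " ".join(f"{v:.6f}" for v in xyz) + "\n")


def write_multiframe_xyz(path, frames: np.ndarray, labels,
                         comment: str = "") -> None:
    """Concatenated XYZ trajectory (one block per frame)."""
    with open(path, "w") as fh:
        for j, frame in enumerate(frames):
            fh.write(f"{len(frame)}\n{comment} frame {j}\n")
            for label, xyz in zip(labels, frame):
                fh.write(f"{label} "
                         + " ".join(f"{v:.6f}" for v in xyz) + "\n")


def read_pdb(path) -> tuple[Conformation, MolecularSystem]:
    """Read the first model of a PDB file (via biotite)."""
    import biotite.structure.io.pdb as pdb
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:
        raise ValueError(f"{path}: malformed PDB ({exc})") from None
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records found")
    labels = [el if el else name[:1] for el, name
              in zip(atoms.element, atoms.atom_name)]
    masses = np.array([_element_mass(s) for s in labels])
    system = MolecularSystem(masses, tuple(labels), dim=3)
    return Conformation(np.asarray(atoms.coord, dtype=float), system), system


def write_pdb(path, frames: np.ndarray, labels) -> None:
    """Write a (multi-)model PDB via biotite; ``frames`` is (M, N, 3) or
    (N, 3)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    stack = struc.AtomArrayStack(frames.shape[0], n)
    stack.coord = frames
    labels = [str(label) for label in labels]
    stack.element = np.array([label.capitalize() for label in labels])
    stack.atom_name = np.array(labels)
    stack.res_name = np.array(["UNK"] * n)
    stack.res_id = np.ones(n, dtype=int)
    stack.chain_id = np.array(["A"] * n)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_structure(path, fmt: str | None = None
                   ) -> tuple[Conformation, MolecularSystem]:
    """Dispatch on format (or file suffix): XYZ or PDB."""
    fmt = (fmt or FilePath(path).suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


# --------------------------------------------------- columnar toy coordinates

def write_toy_coords(path, coords: np.ndarray, header: str = "") -> None:
    """Plain columnar text for 1D/2D toy conformations (one atom per row)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    cols = " ".join(f"coord{d} [Å]" for d in range(coords.shape[1]))
    head = (header + "\n" if header else "") + cols
    # toy endpoints often pin stationary points; keep full precision
    np.savetxt(path, coords, fmt="%.12g", header=head)


def read_toy_coords(path) -> np.ndarray:
    coords = np.loadtxt(path, ndmin=2)
    return coords


# ----------------------------------------------------------------- archives

def write_path_archive(path_file, path: Path,
                       system: MolecularSystem,
                       potential_energies: np.ndarray | None = None,
                       config: dict | None = None) -> None:
    """Single-file archive: coordinates, Δ, masses, labels, per-frame V and
    a config snapshot."""
    import json
    payload = {
        "version": np.array(ARCHIVE_VERSION),
        "frames": path.frames,
        "delta": np.array(path.delta),
        "masses": system.masses,
        "labels": np.array(system.labels),
        "dim": np.array(system.dim),
        "config_json": np.array(json.dumps(config or {})),
    }
    if potential_energies is not None:
        payload["potential_energies"] = np.asarray(potential_energies)
    np.savez(path_file, **payload)


def read_path_archive(path_file) -> dict:
    """Load a path archive; returns path, system and metadata."""
    import json
    try:
        data = np.load(path_file, allow_pickle=False)
    except Exception as exc:
        raise ValueError(f"{path_file}: not a readable archive "
                         f"({exc})") from None
    if "version" not in data:
        raise ValueError(f"{path_file}: missing archive version")
    version = int(data["version"])
    if version != ARCHIVE_VERSION:
        raise ValueError(
            f"{path_file}: archive version {version} != "
            f"supported {ARCHIVE_VERSION}")
    system = MolecularSystem(data["masses"],
                             tuple(str(s) for s in data["labels"]),
                             dim=int(data["dim"]))
    out = {
        "path": Path(data["frames"], float(data["delta"])),
        "system": system,
        "config": json.loads(str(data["config_json"])),
    }
    if "potential_energies" in data:
        out["potential_energies"] = data["potential_energies"]
    return out


def write_sample_store(path_file, store: SampleStore) -> None:
    import json
    payload = {
        "version": np.array(STORE_VERSION),
        "step": store.step,
        "ladder": store.ladder,
        "slot": store.slot,
        "temperature": store.temperature,
        "replica_id": store.replica_id,
        "state_index": store.state_index,
        "potential_energy": store.potential_energy,
        "restraint_energy": store.restraint_energy,
        "rg": store.rg,
        "rmsd_to_final": store.rmsd_to_final,
        "coords_stride": np.array(store.coords_stride),
        "exchange_json": np.array(json.dumps({
            "attempts": {f"{a}-{b}": v for (a, b), v
                         in store.exchange_attempts.items()},
            "accepts": {f"{a}-{b}": v for (a, b), v
                        in store.exchange_accepts.items()},
        })),
    }
    if store.coords is not None:
        payload["coords"] = store.coords
    np.savez(path_file, **payload)


def read_sample_store(path_file) -> SampleStore:
    import json
    data = np.load(path_file, allow_pickle=False)
    if "version" not in data or int(data["version"]) != STORE_VERSION:
        raise ValueError(f"{path_file}: unsupported sample-store version")
    ex = json.loads(str(data["exchange_json"]))

    def unkey(d):
        return {tuple(int(x) for x in k.split("-")): v
                for k, v in d.items()}

    return SampleStore(
        step=data["step"], ladder=data["ladder"], slot=data["slot"],
        temperature=data["temperature"], replica_id=data["replica_id"],
        state_index=data["state_index"],
        potential_energy=data["potential_energy"],
        restraint_energy=data["restraint_energy"],
        rg=data["rg"], rmsd_to_final=data["rmsd_to_final"],
        coords=data["coords"] if "coords" in data else None,
        coords_stride=int(data["coords_stride"]),
        exchange_attempts=unkey(ex["attempts"]),
        exchange_accepts=unkey(ex["accepts"]),
    )


# ------------------------------------------------------------ text reports

def write_quality_report(path_file, columns: dict[str, np.ndarray]) -> None:
    """Columnar text report; column headers carry units."""
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[n], dtype=float)
                           for n in names])
    np.savetxt(path_file, arr, fmt="%.8g", header=" ".join(names))


def read_report(path_file) -> np.ndarray:
    return np.loadtxt(path_file, ndmin=2)
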