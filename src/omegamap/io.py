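"""Ensemble input/output and per-residue geometry.

Conformational ensembles of a single protein chain are represented by
backbone coordinates (N, CA, C, O and, where present, CB) per residue.
Multi-model PDB files are read and written with biotite; MD trajectories
(XTC/DCD/TRR with a PDB topology) are read with MDAnalysis.

Each residue carries a local orthonormal frame built from its three
universally present backbone atoms::

    x = unit(CA -> C)
    z = unit(x  x  unit(CA -> N))
    y = z  x  x

The frame convention is arbitrary but fixed; contact parameters estimated
in the same convention make all downstream orientation terms
self-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: atom slot order of ``Conformation.coords``
BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

_ATOM_SLOT = {name: k for k, name in enumerate(BACKBONE_ATOMS)}

#: average isotope masses of the stored heavy atoms (Da)
ATOM_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999, "CB": 12.011}

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


class ValidationError(ValueError):
    """Raised when an input structure violates a hard invariant."""


@dataclass
class Conformation:
    """A single conformation of one protein chain.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid codes, length ``L``.
    coords : ndarray, shape (L, 5, 3)
        Backbone atom positions in Å, slots ordered as
        ``("N", "CA", "C", "O", "CB")``; missing CB atoms are NaN.
    residue_ids : ndarray of int, shape (L,)
        1-based, sequence-contiguous residue numbering.
    """

    sequence: str
    coords: np.ndarray
    residue_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.sequence) + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atom(self, name: str) -> np.ndarray:
        """Positions of one backbone atom type, shape (L, 3)."""
        return self.coords[:, _ATOM_SLOT[name], :]

    @property
    def ca(self) -> np.ndarray:
        return self.atom("CA")

    @property
    def interaction_sites(self) -> np.ndarray:
        """CB position per residue, CA where CB is absent (glycine)."""
        cb = self.atom("CB").copy()
        missing = ~np.isfinite(cb).all(axis=1)
        cb[missing] = self.atom("CA")[missing]
        return cb

    def validate(self) -> None:
        """Check type invariants; warn on soft violations, raise on hard."""
        L = self.n_residues
        if L < 5:
            raise ValidationError(f"chain length {L} < 5")
        if self.coords.shape != (L, 5, 3):
            raise ValidationError(f"coords shape {self.coords.shape} != {(L, 5, 3)}")
        core = self.coords[:, :4, :]  # N, CA, C, O are mandatory
        if not np.isfinite(core).all():
            bad = int(np.argwhere(~np.isfinite(core).all(axis=(1, 2)))[0, 0])
            raise ValidationError(
                f"missing/non-finite backbone atom in residue {self.residue_ids[bad]}"
            )
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        if ((d < 2.0) | (d > 4.8)).any():
            k = int(np.argwhere((d < 2.0) | (d > 4.8))[0, 0])
            warnings.warn(
                f"consecutive CA-CA distance {d[k]:.2f} A outside [2.0, 4.8] "
                f"between residues {self.residue_ids[k]} and {self.residue_ids[k + 1]}",
                stacklevel=2,
            )


@dataclass
class Ensemble:
    """An ordered set of conformations of one protein sequence."""

    sequence: str
    conformations: list[Conformation]
    provenance: list[str] = field(default_factory=list)

    @property
    def n_conformations(self) -> int:
        return len(self.conformations)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.conformations)

    def __getitem__(self, k: int) -> Conformation:
        return self.conformations[k]

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n, L, 5, 3)."""
        return np.stack([c.coords for c in self.conformations])

    def validate(self) -> None:
        if self.n_conformations < 1:
            raise ValidationError("ensemble has no conformations")
        for k, conf in enumerate(self.conformations):
            if conf.sequence != self.sequence:
                i = next(
                    i for i, (a, b) in enumerate(zip(conf.sequence, self.sequence))
                    if a != b
                )
                raise ValidationError(
                    f"conformation {k}: sequence mismatch at residue {i + 1} "
                    f"({conf.sequence[i]} != {self.sequence[i]})"
                )
            conf.validate()


@dataclass
class ResidueFrame:
    """Local pose of one residue: CA origin and right-handed rotation."""

    origin: np.ndarray
    rotation: np.ndarray


def build_frames(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    """Construct the local frame of every residue.

    Returns
    -------
    origins : ndarray, shape (L, 3)
        CA positions.
    rotations : ndarray, shape (L, 3, 3)
        Right-handed orthonormal matrices whose *rows* are the frame axes
        (x, y, z), i.e. ``rotations[i] @ v`` expresses a lab vector ``v``
        in residue i's frame.

    Raises
    ------
    ValidationError
        If N, CA, C are collinear for some residue.
    """
    ca = conf.atom("CA")
    x = conf.atom("C") - ca
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    u = conf.atom("N") - ca
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    z = np.cross(x, u)
    nz = np.linalg.norm(z, axis=1)
    if (nz < 1e-6).any():
        bad = int(np.argwhere(nz < 1e-6)[0, 0])
        raise ValidationError(
            f"collinear N-CA-C atoms in residue {conf.residue_ids[bad]}"
        )
    z /= nz[:, None]
    y = np.cross(z, x)
    rot = np.stack([x, y, z], axis=1)  # rows = axes
    return ca, rot


def interaction_distance(conf: Conformation, i: int, j: int) -> float:
    """CB–CB Euclidean distance (Å) between residues ``i`` and ``j``
    (1-based), substituting CA where CB is absent (glycine)."""
    L = conf.n_residues
    if i == j:
        raise IndexError("i == j: the pair diagonal is excluded")
    if not (1 <= i <= L and 1 <= j <= L):
        raise IndexError(f"residue index out of range [1, {L}]")
    sites = conf.interaction_sites
    return float(np.linalg.norm(sites[i - 1] - sites[j - 1]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _conf_from_tables(resnames, atom_names, res_index, xyz, n_res):
    """Assemble an (L, 5, 3) coordinate block from flat atom tables."""
    coords = np.full((n_res, 5, 3), np.nan)
    for name, ri, pos in zip(atom_names, res_index, xyz):
        slot = _ATOM_SLOT.get(name)
        if slot is not None:
            coords[ri, slot] = pos
    return coords


def _read_pdb_models(path: Path, chain_id: str | None):
    """All models of one chain from a PDB file -> (sequence, [coords])."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, altloc="occupancy")
    stack = stack[:, struc.filter_amino_acids(stack)]
    chains = np.unique(stack.chain_id)
    if chain_id is None:
        if len(chains) > 1:
            raise ValidationError(
                f"{path.name}: multiple chains {list(chains)}; "
                "select one explicitly with chain_id"
            )
        chain_id = chains[0]
    stack = stack[:, stack.chain_id == chain_id]
    if stack.array_length() == 0:
        raise ValidationError(f"{path.name}: no atoms for chain {chain_id!r}")

    res_starts = struc.get_residue_starts(stack)
    res_index = np.repeat(np.arange(len(res_starts)),
                          np.diff(np.append(res_starts, stack.array_length())))
    resnames = stack.res_name[res_starts]
    try:
        sequence = "".join(_AA3TO1[r] for r in resnames)
    except KeyError as exc:
        raise ValidationError(f"{path.name}: non-standard residue {exc}") from None

    confs = []
    for m in range(stack.stack_depth()):
        coords = _conf_from_tables(resnames, stack.atom_name, res_index,
                                   stack.coord[m], len(resnames))
        confs.append(Conformation(sequence, coords))
    return sequence, confs


def _read_trajectory(traj_path: Path, topology: Path, chain_id: str | None,
                     stride: int, start: int | None, stop: int | None):
    """Trajectory frames of one chain -> (sequence, [coords])."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(traj_path))
    prot = u.select_atoms("protein")
    chains = np.unique(prot.atoms.chainIDs) if hasattr(prot.atoms, "chainIDs") else [""]
    if chain_id is not None and hasattr(prot.atoms, "chainIDs"):
        prot = prot.select_atoms(f"chainID {chain_id}")
    elif len(chains) > 1:
        raise ValidationError(
            f"{traj_path.name}: multiple chains {list(chains)}; "
            "select one explicitly with chain_id"
        )
    sel = prot.select_atoms("name " + " ".join(BACKBONE_ATOMS))
    residues = sel.residues
    try:
        sequence = "".join(_AA3TO1[r.resname.upper()[:3]] for r in residues)
    except KeyError as exc:
        raise ValidationError(f"{traj_path.name}: non-standard residue {exc}") from None
    ridx = {res.resindex: k for k, res in enumerate(residues)}
    res_index = np.array([ridx[a.resindex] for a in sel.atoms])

    confs = []
    for _ts in u.trajectory[start:stop:stride]:
        coords = _conf_from_tables(None, sel.atoms.names, res_index,
                                   sel.atoms.positions.astype(float), len(residues))
        confs.append(Conformation(sequence, coords))
    return sequence, confs


def load_ensemble(
    paths: Sequence[str | Path] | str | Path,
    topology: str | Path | None = None,
    chain_id: str | None = None,
    stride: int = 1,
    start: int | None = None,
    stop: int | None = None,
) -> Ensemble:
    """Load a conformational ensemble from one or more files.

    Parameters
    ----------
    paths : path or list of paths
        Multi-model PDB files, or trajectory files (XTC/DCD/TRR) together
        with ``topology``.  Models/frames are concatenated in input order.
    topology : path, optional
        PDB topology, required for trajectory formats.
    chain_id : str, optional
        Chain to extract; mandatory when a file holds several chains.
    stride, start, stop : int
        Frame subsampling applied to each trajectory file.

    Raises
    ------
    ValidationError
        On sequence mismatch between files (naming the first mismatching
        residue), missing CA atoms, or ambiguous chain selection.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("no input files given")

    sequence = None
    all_confs: list[Conformation] = []
    for path in paths:
        if path.suffix.lower() in (".pdb", ".ent"):
            seq, confs = _read_pdb_models(path, chain_id)
            if stride != 1 or start is not None or stop is not None:
                confs = confs[start:stop:stride]
        else:
            if topology is None:
                raise ValidationError(
                    f"{path.name}: trajectory format requires a PDB topology"
                )
            seq, confs = _read_trajectory(path, Path(topology), chain_id,
                                          stride, start, stop)
        if sequence is None:
            sequence = seq
        elif seq != sequence:
            i = next(
                (i for i, (a, b) in enumerate(zip(seq, sequence)) if a != b),
                min(len(seq), len(sequence)),
            )
            raise ValidationError(
                f"{path.name}: sequence mismatch at residue {i + 1}"
            )
        all_confs.extend(confs)

    ens = Ensemble(sequence, all_confs, provenance=[str(p) for p in paths])
    ens.validate()
    return ens


def write_ensemble_pdb(ens: Ensemble, path: str | Path,
                       indices: Sequence[int] | None = None) -> None:
    """Write (a subset of) an ensemble as a canonical multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if indices is None:
        indices = range(ens.n_conformations)
    L = ens.n_residues
    # atom layout shared by all models: mandatory backbone + present CBs
    template = ens.conformations[indices[0] if len(indices) else 0]
    entries = []  # (res_idx, atom_name, slot)
    for r in range(L):
        for slot, name in enumerate(BACKBONE_ATOMS):
            if np.isfinite(template.coords[r, slot]).all():
                entries.append((r, name, slot))
    n_atoms = len(entries)

    atoms = struc.AtomArray(n_atoms)
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.res_id = np.array([ens.conformations[0].residue_ids[r] for r, _, _ in entries])
    atoms.res_name = np.array([_AA1TO3[ens.sequence[r]] for r, _, _ in entries])
    atoms.atom_name = np.array([name for _, name, _ in entries])
    atoms.element = np.array([name[0] for _, name, _ in entries])
    atoms.hetero = np.zeros(n_atoms, dtype=bool)

    stack = struc.stack([atoms] * len(indices))
    for m, k in enumerate(indices):
        conf = ens.conformations[k]
        stack.coord[m] = np.array([conf.coords[r, slot] for r, _, slot in entries])

    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
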