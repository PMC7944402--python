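"""Ligand-residue contact analysis of MD trajectories.

For a homotetrameric channel with a bound ligand, the quantity of interest is
the per-frame minimum distance between any heavy atom of a residue (in one
subunit) and any heavy atom of the ligand, and the contact frequency — the
fraction of frames in which that minimum lies within a fixed cutoff (default
0.45 nm = 4.5 Å, boundary inclusive). The four subunits of the tetramer are
analysed independently and serve as quasi-independent replicates.

Trajectories are read with mdtraj (PDB topology, XTC/DCD coordinates);
distances are in nm throughout. Minimum-image corrections are applied when
the trajectory carries box vectors (orthorhombic), and skipped for toy
systems without a box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import mdtraj as md
import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySlice",
    "ContactProfile",
    "load_trajectory",
    "min_heavy_atom_distance_series",
    "contact_frequency",
    "profile_report",
]

DEFAULT_CUTOFF_NM = 0.45


@dataclass
class TrajectorySlice:
    """In-memory trajectory: coordinates plus a per-atom annotation table.

    ``coordinates`` has shape (frames, atoms, 3) in nm. ``atom_table`` columns:
    atom_id, name, element, residue_id, residue_name, subunit, is_heavy,
    is_ligand. ``box_lengths`` holds per-frame orthorhombic box edges (nm) or
    None for non-periodic systems. Hydrogens are never heavy; ligand atoms are
    disjoint from protein atoms.
    """

    coordinates: np.ndarray
    atom_table: pd.DataFrame
    box_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if len(self.atom_table) != self.coordinates.shape[1]:
            raise ValueError(
                f"atom table has {len(self.atom_table)} rows for "
                f"{self.coordinates.shape[1]} coordinate columns"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def subunits(self) -> list[str]:
        tab = self.atom_table
        return sorted(tab.loc[~tab.is_ligand, "subunit"].unique())

    def ligand_heavy_indices(self) -> np.ndarray:
        tab = self.atom_table
        idx = tab.index[tab.is_ligand & tab.is_heavy].to_numpy()
        if idx.size == 0:
            raise ValueError("trajectory has no ligand heavy atoms")
        return idx

    def residue_heavy_indices(self, residue_id: int, subunit: str) -> np.ndarray:
        tab = self.atom_table
        sel = (
            (~tab.is_ligand)
            & tab.is_heavy
            & (tab.residue_id == residue_id)
            & (tab.subunit == subunit)
        )
        idx = tab.index[sel].to_numpy()
        if idx.size == 0:
            raise ValueError(
                f"residue {residue_id} in subunit {subunit!r} has no heavy atoms"
            )
        return idx

    @classmethod
    def from_mdtraj(cls, traj: md.Trajectory, ligand_resname: str) -> "TrajectorySlice":
        rows = []
        chains = list(traj.topology.chains)
        multi_chain = len(chains) > 1
        if not multi_chain:
            warnings.warn(
                "topology has a single chain; treating it as one subunit 'A'",
                stacklevel=2,
            )
        for atom in traj.topology.atoms:
            elem = atom.element.symbol if atom.element is not None else ""
            is_h = elem == "H" or (elem == "" and atom.name.startswith("H"))
            rows.append(
                {
                    "atom_id": atom.index,
                    "name": atom.name,
                    "element": elem,
                    "residue_id": atom.residue.resSeq,
                    "residue_name": atom.residue.name,
                    "subunit": chr(ord("A") + atom.residue.chain.index),
                    "is_heavy": not is_h,
                    "is_ligand": atom.residue.name == ligand_resname,
                }
            )
        tab = pd.DataFrame(rows)
        if not tab.is_ligand.any():
            raise ValueError(f"ligand residue {ligand_resname!r} not found in topology")
        box = None
        if traj.unitcell_lengths is not None:
            box = np.asarray(traj.unitcell_lengths, dtype=float)
        return cls(np.asarray(traj.xyz, dtype=float), tab, box)


def load_trajectory(
    topology_path: str, coords_path: str | None, ligand_resname: str
) -> TrajectorySlice:
    """Load a PDB topology plus XTC/DCD coordinates into a TrajectorySlice.

    ``coords_path=None`` analyses the PDB model(s) themselves. A mismatch in
    atom counts between topology and coordinates raises.
    """
    if coords_path is None:
        traj = md.load(topology_path)
    else:
        traj = md.load(coords_path, top=topology_path)
    return TrajectorySlice.from_mdtraj(traj, ligand_resname)


def _pair_min_distances(
    coords: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    box: np.ndarray | None,
) -> np.ndarray:
    # (frames, |a|, |b|, 3) displacement tensor; minimum-image per axis when a
    # box is present (orthorhombic only).
    delta = coords[:, idx_a, None, :] - coords[:, None, idx_b, :]
    if box is not None:
        b = box[:, None, None, :]
        delta -= b * np.round(delta / b)
    d = np.sqrt((delta**2).sum(axis=-1))
    return d.reshape(coords.shape[0], -1).min(axis=1)


def min_heavy_atom_distance_series(
    traj: TrajectorySlice, residue_id: int, subunit: str
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance (nm) between ligand and residue."""
    return _pair_min_distances(
        traj.coordinates,
        traj.ligand_heavy_indices(),
        traj.residue_heavy_indices(residue_id, subunit),
        traj.box_lengths,
    )


@dataclass
class ContactProfile:
    """Contact frequencies and distance series keyed by (residue_id, subunit)."""

    cutoff: float
    n_frames: int
    contact_frequency: dict[tuple[int, str], float]
    min_distance_series: dict[tuple[int, str], np.ndarray]


def contact_frequency(
    traj: TrajectorySlice,
    residues: list[int],
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> ContactProfile:
    """Fraction of frames with the ligand within ``cutoff`` nm of each residue.

    Computed per (residue, subunit) as k/n_frames where k counts frames whose
    minimum heavy-atom distance is ≤ cutoff (boundary counts as contact).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue list")
    freq: dict[tuple[int, str], float] = {}
    series: dict[tuple[int, str], np.ndarray] = {}
    for res in residues:
        for su in traj.subunits:
            d = min_heavy_atom_distance_series(traj, res, su)
            series[(res, su)] = d
            freq[(res, su)] = float(np.count_nonzero(d <= cutoff)) / traj.n_frames
    return ContactProfile(cutoff, traj.n_frames, freq, series)


def profile_report(profile: ContactProfile) -> pd.DataFrame:
    """Long-format table (residue_id, subunit, contact_frequency), sorted."""
    rows = [
        {"residue_id": res, "subunit": su, "contact_frequency": f}
        for (res, su), f in profile.contact_frequency.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["residue_id", "subunit"], kind="stable")
        .reset_index(drop=True)
    )
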