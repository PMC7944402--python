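"""Ligand-residue contact frequencies from a (toy) MD trajectory.

Builds a toy homotetramer + ligand trajectory with prescribed per-residue
contact fractions, writes it to PDB/XTC, reloads it, and measures per-residue
per-subunit contact frequencies at the 4.5-Å heavy-atom cutoff — the same
analysis applied to production trajectories of a channel with a bound
resin-acid derivative.
"""

import tempfile
from pathlib import Path

import kvshift as kv

schedule = {325: 0.5, 360: 0.9, 454: 0.1}   # residue id -> fraction of frames
ts, traj = kv.gen_trajectory(n_frames=50, contact_schedule=schedule, seed=3)

with tempfile.TemporaryDirectory() as tmp:
    pdb, xtc = Path(tmp) / "toy.pdb", Path(tmp) / "toy.xtc"
    traj[0].save(str(pdb))
    traj.save(str(xtc))
    loaded = kv.load_trajectory(str(pdb), str(xtc), ligand_resname="LIG")

profile = kv.contact_frequency(loaded, sorted(schedule), cutoff=0.45)
report = kv.profile_report(profile)
print(report.to_string(index=False))
print("\nEach row: fraction of frames with any ligand heavy atom within "
      "0.45 nm (4.5 Å) of any heavy atom of that residue, per subunit.")
print("The four subunits of the tetramer are independent replicates; here "
      "they reproduce the prescribed schedule", schedule, "exactly.")

series = kv.min_heavy_atom_distance_series(loaded, 360, "A")
print(f"\nmin ligand-I360 distance in subunit A, first 5 frames (nm): "
      f"{[round(float(d), 2) for d in series[:5]]}")
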