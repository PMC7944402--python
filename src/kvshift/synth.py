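"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without experimental recordings or
deposited trajectories:

* current families follow Boltzmann conductance × driving force with
  single-exponential activation (voltage-independent time constant) and
  additive i.i.d. Gaussian noise — only the steady-state segment matters to
  the downstream analysis;
* dose-response tables draw replicate shifts around the hyperbolic
  concentration dependence;
* shift tables across mutant panels realise the additive per-site model with
  Gaussian noise at stated SEM scales;
* toy trajectories place a pseudo-atom per residue in each of four subunits
  and a multi-atom ligand whose anchor atoms toggle in/out of the contact
  cutoff in a prescribed fraction of frames.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import mdtraj as md
import numpy as np
import pandas as pd

from .contacts import DEFAULT_CUTOFF_NM, TrajectorySlice
from .gv import CurrentTraceFamily, VoltageProtocol, boltzmann
from .dose import hyperbolic_shift
from .sites import MutantConfig, ShiftDataset, encode_mutant

__all__ = [
    "CompoundSpec",
    "GroundTruth",
    "gen_current_family",
    "gen_dose_response",
    "gen_shift_table",
    "gen_trajectory",
]


@dataclass(frozen=True)
class CompoundSpec:
    """Charge/pH metadata of a resin-acid derivative.

    ``pKa_membrane`` is the apparent pKa in the lipid membrane (None for
    permanently charged compounds); ``assay_pH`` is the bath pH used so the
    compound is fully in its charged form.
    """

    name: str
    net_charge: int = -1
    pKa_membrane: float | None = None
    assay_pH: float = 7.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.assay_pH <= 14.0:
            raise ValueError("assay_pH must lie in [0, 14]")
        if self.net_charge not in (-1, 0, 1):
            raise ValueError("net_charge must be one of -1, 0, +1")


@dataclass
class GroundTruth:
    """Generating parameters that downstream fits must recover.

    Defaults describe a Shaker-like channel (midpoint −30 mV, slope 10 mV)
    modulated by a compound with the measured Wu50/WT concentration
    dependence (EC50 29.1 µM, maximal shift −36.1 mV) and a single-dose shift
    of −25.5 mV at 100 µM with unchanged maximal conductance.
    """

    control_V_half: float = -30.0      # mV
    control_slope: float = 10.0        # mV, > 0
    control_G_MAX: float = 1.0         # conductance units (µA per mV driving force)
    shift: float = -25.5               # mV, compound-induced midpoint shift
    gmax_ratio: float = 1.0            # G_MAX(compound)/G_MAX(control)
    EC50: float = 29.1                 # µM
    delta_V_MAX: float = -36.1         # mV
    site_contributions: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0              # SD in units of the perturbed signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_slope <= 0:
            raise ValueError("control_slope must be positive")
        if self.EC50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.gmax_ratio <= 0:
            raise ValueError("gmax_ratio must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def gen_current_family(
    protocol: VoltageProtocol,
    truth: GroundTruth,
    condition: str = "control",
    seed: int | None = None,
    tau_ms: float = 5.0,
    leak: float = 0.0,
) -> CurrentTraceFamily:
    """Simulate one family of voltage-clamp sweeps.

    Each sweep carries ``I(t, V) = leak + G(V)·(V − V_K)·(1 − exp(−t/τ))``
    plus additive Gaussian noise of SD ``truth.noise_sd`` per sample, where
    G(V) is the Boltzmann conductance under ``condition``: "control" uses the
    control parameters, "compound" applies the midpoint shift and G_MAX
    scaling. The steady-state window must start well past τ for the window
    mean to equal G(V)·(V − V_K).
    """
    if condition not in ("control", "compound"):
        raise ValueError("condition must be 'control' or 'compound'")
    v = np.asarray(protocol.test_voltages, dtype=float)
    if not (v.min() <= truth.control_V_half <= v.max()):
        raise ValueError("protocol voltages must bracket the control midpoint")
    v_half = truth.control_V_half
    g_max = truth.control_G_MAX
    if condition == "compound":
        v_half = v_half + truth.shift
        g_max = g_max * truth.gmax_ratio
    t = protocol.time_grid
    g = boltzmann(v, g_max, v_half, truth.control_slope)
    driving = v - protocol.reversal_potential
    clean = leak + (g * driving)[:, None] * (1.0 - np.exp(-t[None, :] / tau_ms))
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    noise = rng.normal(0.0, truth.noise_sd, clean.shape) if truth.noise_sd else 0.0
    return CurrentTraceFamily(
        protocol=protocol,
        time_grid=t,
        currents=clean + noise,
        condition_label=condition,
    )


def gen_dose_response(
    truth: GroundTruth,
    concentrations: list[float],
    n_per_conc: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate G(V) shifts at each concentration, summarised as mean ± SEM.

    The noiseless mean at c = EC50 equals ΔV_MAX/2. Returns a table with
    columns (concentration_uM, shift_mV, sem_mV, n).
    """
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("empty concentration list")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if n_per_conc < 1:
        raise ValueError("n_per_conc must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for conc in c:
        mean = hyperbolic_shift(conc, truth.EC50, truth.delta_V_MAX)
        reps = mean + rng.normal(0.0, truth.noise_sd, n_per_conc)
        rows.append(
            {
                "concentration_uM": float(conc),
                "shift_mV": float(reps.mean()),
                "sem_mV": float(reps.std(ddof=1) / np.sqrt(n_per_conc))
                if n_per_conc > 1
                else np.nan,
                "n": n_per_conc,
            }
        )
    return pd.DataFrame(rows)


def gen_shift_table(
    configs: list[MutantConfig],
    site_truth: dict[str, float],
    residual: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    compound: str = "synthetic",
    concentration_uM: float = 100.0,
) -> ShiftDataset:
    """Per-mutant shifts realising the additive site model plus Gaussian noise.

    ``site_truth`` maps site labels to contributions in mV: key ``"S3S4"``
    for the S3/S4 term and one key per pore configuration class (e.g.
    ``"WT_362_454"``). A config whose pore class has no entry raises KeyError.
    """
    if not configs:
        raise ValueError("no mutant configs supplied")
    rng = np.random.default_rng(seed)
    shifts = []
    for cfg in configs:
        enc = encode_mutant(cfg)
        if enc.pore_class not in site_truth:
            raise KeyError(
                f"mutant {cfg.label!r}: no ground-truth contribution for pore "
                f"class {enc.pore_class!r}"
            )
        val = residual + site_truth[enc.pore_class]
        if enc.s3s4_active:
            val += site_truth.get("S3S4", 0.0)
        shifts.append(val + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
    return ShiftDataset.from_records(
        configs, np.asarray(shifts), compound=compound,
        concentration_uM=concentration_uM,
    )


def _toy_topology(
    residues: list[int], n_subunits: int, n_ligand_heavy: int,
    ligand_resname: str = "LIG",
) -> md.Topology:
    top = md.Topology()
    carbon = md.element.carbon
    for s in range(n_subunits):
        chain = top.add_chain()
        for res in residues:
            r = top.add_residue("ALA", chain, resSeq=res)
            top.add_atom("CA", carbon, r)
    lig_chain = top.add_chain()
    lig = top.add_residue(ligand_resname, lig_chain, resSeq=1)
    for k in range(n_ligand_heavy):
        top.add_atom(f"C{k + 1}", carbon, lig)
    top.add_atom("H1", md.element.hydrogen, lig)
    return top


def gen_trajectory(
    n_frames: int,
    contact_schedule: dict[int, float],
    cutoff: float = DEFAULT_CUTOFF_NM,
    seed: int = 0,
    n_subunits: int = 4,
    spacing: float = 5.0,
    ligand_resname: str = "LIG",
) -> tuple[TrajectorySlice, md.Trajectory]:
    """Toy trajectory whose ligand contacts follow a prescribed schedule.

    Each (residue, subunit) pair gets one protein pseudo-atom and one
    dedicated ligand heavy anchor atom, laid out on an x-axis grid with
    ``spacing`` nm between pairs (far larger than the cutoff, so pairs are
    independent). In ``round(fraction · n_frames)`` randomly chosen frames the
    anchor sits 0.6·cutoff from its residue (contact); otherwise it sits at
    spacing/2 (no contact). The same fraction is applied independently in
    every subunit. A single ligand hydrogen rides inside the cutoff of the
    first pair's residue in all frames to assert that hydrogens never count.

    Returns the in-memory :class:`TrajectorySlice` and the corresponding
    mdtraj trajectory (for writing PDB/XTC/DCD files).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not contact_schedule:
        raise ValueError("empty contact schedule")
    for res, frac in contact_schedule.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for residue {res} outside [0, 1]: {frac}")
    if spacing <= 4 * cutoff:
        raise ValueError("spacing must exceed 4x the cutoff to keep pairs independent")
    residues = sorted(contact_schedule)
    pairs = [(res, su) for su in range(n_subunits) for res in residues]
    rng = np.random.default_rng(seed)
    top = _toy_topology(
        residues, n_subunits, n_ligand_heavy=len(pairs),
        ligand_resname=ligand_resname,
    )
    n_protein = n_subunits * len(residues)
    n_atoms = n_protein + len(pairs) + 1
    xyz = np.zeros((n_frames, n_atoms, 3), dtype=np.float32)
    near, far = 0.6 * cutoff, spacing / 2.0
    # protein pseudo-atoms: chain-major ordering matches _toy_topology
    for k, (res, su) in enumerate(pairs):
        prot_idx = su * len(residues) + residues.index(res)
        x = k * spacing
        xyz[:, prot_idx, 0] = x
        lig_idx = n_protein + k
        n_contact = int(round(contact_schedule[res] * n_frames))
        in_contact = rng.choice(n_frames, size=n_contact, replace=False)
        y = np.full(n_frames, far)
        y[in_contact] = near
        xyz[:, lig_idx, 0] = x
        xyz[:, lig_idx, 1] = y
    # ligand hydrogen: permanently within cutoff of pair 0's residue
    xyz[:, n_protein + len(pairs), 1] = 0.3 * cutoff
    traj = md.Trajectory(xyz=xyz, topology=top)
    return TrajectorySlice.from_mdtraj(traj, ligand_resname), traj
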