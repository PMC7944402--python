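"""Published reference measurements shipped with the package.

The fixture transcribes per-mutant G(V) shifts (mean ± SEM, n) measured at
100 µM of the resin-acid derivatives Wu50 (bath pH 9.0, so the compound is
fully charged) and Wu161 (pH 7.4), plus the published concentration-response
parameters for three compounds on the WT channel and the 2R-motif channel.
Rows carry a ``status`` flag: ``measured`` values are reported means,
``inferred`` values are reconstructed from stated differences, ``gmax_block``
marks constructs whose maximal conductance collapsed so no shift could be
measured, and ``eliminated`` marks a reported null effect. Non-numeric rows
are carried, never dropped silently.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dose import DoseResponseFit
from .sites import ShiftDataset
from .synth import CompoundSpec

__all__ = [
    "COMPOUNDS",
    "DOSE_RESPONSE_PARAMS",
    "WU50_EIGHT_MUTANTS",
    "load_published_shifts",
    "wu50_eight_mutant_dataset",
    "published_dose_response",
]

COMPOUNDS: dict[str, CompoundSpec] = {
    "Wu50": CompoundSpec("Wu50", net_charge=-1, pKa_membrane=6.5, assay_pH=9.0),
    "Wu161": CompoundSpec("Wu161", net_charge=-1, pKa_membrane=None, assay_pH=7.4),
    "Wu181": CompoundSpec("Wu181", net_charge=-1, pKa_membrane=None, assay_pH=7.4),
}

# (compound, channel) -> (EC50 µM, SE, ΔV_MAX mV, SE)
DOSE_RESPONSE_PARAMS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("Wu50", "WT"): (29.1, 3.5, -36.1, 1.3),
    ("Wu50", "2R"): (30.0, 5.0, -56.5, 2.6),
    ("Wu50", "2R/W454A"): (27.9, 9.2, -62.3, 6.5),
    ("Wu161", "WT"): (43.7, 6.3, -13.9, 0.6),
    ("Wu161", "2R"): (36.4, 9.0, -45.5, 3.5),
    ("Wu181", "WT"): (1.6, 0.6, -7.8, 0.5),
    ("Wu181", "2R"): (6.1, 1.7, -53.6, 4.0),
}

# Full 2x4 factorial of {±2R motif} x {four S4/pore configuration classes};
# the dataset used for the constrained additive decomposition of Wu50 shifts.
WU50_EIGHT_MUTANTS: tuple[str, ...] = (
    "WT", "2R", "R362Q", "2R/R362Q", "W454A", "2R/W454A",
    "R362Q/W454A", "2R/R362Q/W454A",
)


def _fixture_frame() -> pd.DataFrame:
    with resources.files("kvshift").joinpath("data/published_gv_shifts.csv").open() as fh:
        return pd.read_csv(fh)


def load_published_shifts(
    compound: str, include_unmeasurable: bool = False
) -> ShiftDataset:
    """Shift dataset for one compound ("Wu50" or "Wu161") at 100 µM.

    With ``include_unmeasurable`` rows without a numeric shift (status
    ``gmax_block``) are retained; by default only rows usable in a fit are
    returned (their ``status``/``note`` columns come along either way).
    """
    tab = _fixture_frame()
    known = sorted(tab["compound"].unique())
    if compound not in known:
        raise KeyError(f"unknown compound {compound!r}; available: {known}")
    sub = tab[tab["compound"] == compound].reset_index(drop=True)
    if not include_unmeasurable:
        sub = sub[sub["shift_mV"].notna()].reset_index(drop=True)
    return ShiftDataset(sub)


def wu50_eight_mutant_dataset() -> ShiftDataset:
    """The eight-mutant Wu50 panel spanning all four S4/pore classes ± 2R."""
    return load_published_shifts("Wu50").subset(list(WU50_EIGHT_MUTANTS))


def published_dose_response(compound: str, channel: str) -> DoseResponseFit:
    """Published hyperbolic fit parameters as a :class:`DoseResponseFit`."""
    key = (compound, channel)
    if key not in DOSE_RESPONSE_PARAMS:
        raise KeyError(
            f"no published concentration-response for {key}; "
            f"available: {sorted(DOSE_RESPONSE_PARAMS)}"
        )
    ec50, ec50_se, dvmax, dvmax_se = DOSE_RESPONSE_PARAMS[key]
    return DoseResponseFit(
        EC50=ec50, delta_V_MAX=dvmax, standard_errors=(ec50_se, dvmax_se),
    )
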