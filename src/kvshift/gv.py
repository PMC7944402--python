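"""Conductance-voltage (G(V)) analysis for voltage-clamp current families.

The workflow mirrors standard two-electrode voltage-clamp practice for
voltage-gated K channels: steady-state currents are read from the end of each
test-voltage sweep, converted to conductance through the driving force
``G(V) = I / (V - V_K)``, and the resulting G(V) curve is fitted with a
two-state Boltzmann function

    G(V) = G_MAX / (1 + exp((V_half - V) / s))

whose midpoint ``V_half`` shifts when a channel-modulating compound is applied.
The compound-induced G(V) shift is ``V_half(compound) - V_half(control)``
(negative = opening-promoting), and the relative change in maximal conductance
is ``G_MAX(compound) / G_MAX(control)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "VoltageProtocol",
    "CurrentTraceFamily",
    "GVCurve",
    "BoltzmannFit",
    "steady_state_current",
    "compute_conductance",
    "fit_boltzmann",
    "boltzmann",
    "gv_shift",
    "gmax_ratio",
    "compare_shifts",
]


def boltzmann(v: np.ndarray, g_max: float, v_half: float, slope: float) -> np.ndarray:
    """Two-state Boltzmann conductance curve G(V) = G_MAX/(1+exp((V_half-V)/s))."""
    v = np.asarray(v, dtype=float)
    return g_max / (1.0 + np.exp((v_half - v) / slope))


@dataclass(frozen=True)
class VoltageProtocol:
    """A family of depolarising voltage steps from a fixed holding potential.

    Parameters
    ----------
    test_voltages
        Step potentials in mV, strictly increasing; one sweep per voltage.
    holding_potential
        Pre-step holding potential in mV (−80 mV, or −100 mV for mutants that
        are not fully closed at −80 mV).
    sweep_duration
        Length of each test sweep in ms.
    steady_state_window
        Length (ms) of the end-of-sweep segment averaged to obtain the
        steady-state current.
    reversal_potential
        K+ reversal potential V_K in mV; fixed per dataset.
    sample_interval
        Sampling period of the digitised current in ms.
    """

    test_voltages: tuple[float, ...]
    holding_potential: float = -80.0
    sweep_duration: float = 100.0
    steady_state_window: float = 10.0
    reversal_potential: float = -80.0
    sample_interval: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.test_voltages, dtype=float)
        object.__setattr__(self, "test_voltages", tuple(v))
        if v.size < 1:
            raise ValueError("protocol needs at least one test voltage")
        if np.any(np.diff(v) <= 0):
            raise ValueError("test_voltages must be strictly increasing")
        if self.steady_state_window > self.sweep_duration:
            raise ValueError(
                f"steady-state window ({self.steady_state_window} ms) exceeds "
                f"sweep duration ({self.sweep_duration} ms)"
            )
        if self.steady_state_window <= 0 or self.sweep_duration <= 0:
            raise ValueError("sweep_duration and steady_state_window must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    @property
    def time_grid(self) -> np.ndarray:
        """Sample times in ms, from sample_interval to sweep_duration inclusive."""
        n = int(round(self.sweep_duration / self.sample_interval))
        return np.arange(1, n + 1) * self.sample_interval


@dataclass
class CurrentTraceFamily:
    """Digitised currents for one condition: one sweep per test voltage.

    ``currents`` has shape (n_sweeps, n_samples) in µA on ``time_grid`` (ms).
    """

    protocol: VoltageProtocol
    time_grid: np.ndarray
    currents: np.ndarray
    condition_label: str = "control"

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        n_v = len(self.protocol.test_voltages)
        if self.currents.shape != (n_v, self.time_grid.size):
            raise ValueError(
                f"currents shape {self.currents.shape} does not match "
                f"({n_v} sweeps, {self.time_grid.size} samples)"
            )
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("currents contain non-finite values")


@dataclass
class GVCurve:
    """Conductance versus test voltage for one condition."""

    voltages: np.ndarray
    conductance: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if self.voltages.shape != self.conductance.shape:
            raise ValueError("voltages and conductance must have equal length")


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters with diagnostics.

    G_MAX is the curve amplitude (maximal conductance), V_half the midpoint in
    mV and slope the steepness factor s in mV (s > 0).
    """

    G_MAX: float
    V_half: float
    slope: float
    residual_sum_of_squares: float = np.nan
    converged: bool = True
    standard_errors: tuple[float, float, float] = field(
        default=(np.nan, np.nan, np.nan)
    )

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(v, self.G_MAX, self.V_half, self.slope)


def steady_state_current(family: CurrentTraceFamily) -> list[tuple[float, float]]:
    """Mean current over the end-of-sweep steady-state window, per test voltage.

    Returns a list of (V in mV, I_ss in µA) pairs, one per sweep.
    """
    proto = family.protocol
    t = family.time_grid
    t_start = proto.sweep_duration - proto.steady_state_window
    if t[-1] < proto.sweep_duration - 0.5 * proto.sample_interval:
        raise ValueError(
            "recorded time range ends before the steady-state window"
        )
    mask = t >= t_start - 1e-9
    if not mask.any():
        raise ValueError("steady-state window contains no samples")
    i_ss = family.currents[:, mask].mean(axis=1)
    return list(zip(proto.test_voltages, i_ss.tolist()))


def compute_conductance(
    points: list[tuple[float, float]], v_k: float, condition_label: str = ""
) -> GVCurve:
    """Convert steady-state currents to conductance, G = I / (V - V_K).

    Points at V == V_K have an undefined (0/0) conductance and are dropped
    with a warning.
    """
    if len(points) == 0:
        raise ValueError("no (V, I) points supplied")
    v = np.array([p[0] for p in points], dtype=float)
    i = np.array([p[1] for p in points], dtype=float)
    at_reversal = np.isclose(v, v_k)
    if at_reversal.any():
        warnings.warn(
            f"dropping {int(at_reversal.sum())} point(s) at the reversal "
            f"potential V_K = {v_k} mV (zero driving force)",
            stacklevel=2,
        )
    v, i = v[~at_reversal], i[~at_reversal]
    return GVCurve(v, i / (v - v_k), condition_label=condition_label)


def _initial_guess(v: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    # Data-driven starts: amplitude from the observed maximum, midpoint from
    # the voltage nearest half-max, slope from the 25-75% rise width / 2.2.
    g_max0 = float(g.max())
    v_half0 = float(v[np.argmin(np.abs(g - 0.5 * g_max0))])
    order = np.argsort(v)
    vs, gs = v[order], g[order]
    try:
        v25 = float(np.interp(0.25 * g_max0, gs, vs))
        v75 = float(np.interp(0.75 * g_max0, gs, vs))
        s0 = (v75 - v25) / 2.2
    except Exception:  # pragma: no cover - interp on sorted data rarely fails
        s0 = np.nan
    if not np.isfinite(s0) or s0 <= 0:
        s0 = max((vs[-1] - vs[0]) / 10.0, 1.0)
    return g_max0, v_half0, s0


def fit_boltzmann(
    curve: GVCurve, weights: np.ndarray | None = None
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a G(V) curve.

    Unweighted by default; optional per-point weights (1/variance) may be
    supplied. Non-convergence is flagged via ``converged=False`` rather than
    raised; a flat (constant) curve is rejected.
    """
    v = curve.voltages
    g = curve.conductance
    if np.unique(v).size < 4:
        raise ValueError("need at least 4 distinct voltages spanning the rise")
    if np.allclose(g, g[0]):
        raise ValueError("degenerate flat G(V) curve: Boltzmann parameters undefined")
    p0 = _initial_guess(v, g)
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann,
            v,
            g,
            p0=p0,
            sigma=sigma,
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, optimize.OptimizeWarning):
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((3, 3), np.nan)
        converged = False
    resid = g - boltzmann(v, *popt)
    se = tuple(np.sqrt(np.diag(pcov)).tolist())
    return BoltzmannFit(
        G_MAX=float(popt[0]),
        V_half=float(popt[1]),
        slope=float(popt[2]),
        residual_sum_of_squares=float(resid @ resid),
        converged=converged,
        standard_errors=se,
    )


def gv_shift(control: BoltzmannFit, compound: BoltzmannFit) -> float:
    """Compound-induced G(V) shift: V_half(compound) − V_half(control), mV.

    Negative values mean the curve moves leftward, i.e. channel opening is
    promoted at more negative voltages.
    """
    for name, fit in (("control", control), ("compound", compound)):
        if not fit.converged:
            raise ValueError(f"{name} Boltzmann fit did not converge")
    return compound.V_half - control.V_half


def gmax_ratio(control: BoltzmannFit, compound: BoltzmannFit) -> float:
    """Relative change in maximal conductance, G_MAX(compound)/G_MAX(control).

    1.0 means no change; e.g. a ratio of 0.17 corresponds to an 83% reduction.
    """
    if not (control.converged and compound.converged):
        raise ValueError("both fits must have converged")
    if control.G_MAX <= 0:
        raise ValueError("control G_MAX must be positive")
    return compound.G_MAX / control.G_MAX


def compare_shifts(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t test between two groups of G(V) shifts.

    Welch's unequal-variance variant by default (group sizes in these assays
    are small and unequal, typically n = 2-10); set ``equal_var=True`` for the
    pooled-variance Student t test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 measurements")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
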