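"""Additive binding-site decomposition of G(V) shifts across channel mutants.

Resin-acid derivatives can bind at several pockets around the S4 voltage
sensor of a Shaker-type K channel. Assuming independent sites, each mutant's
measured G(V) shift at a single test concentration is modelled as a sum

    ΔV_model = ΔV_S3/S4 + ΔV_S4/pore + ΔV_Residual

with the constraint structure:

* ΔV_S3/S4 is a single value, active only in channels carrying the 2R motif
  (M356R/A359R); it is 0 otherwise.
* ΔV_S4/pore takes one value per configuration class of the S4/pore pocket:
  the four canonical classes are the WT configuration (R362 and W454 intact),
  R362Q, W454A and R362Q/W454A. Mutants touching further pocket residues
  (R365Q, F416A) fall into extended classes so they are never silently forced
  into a canonical class.
* ΔV_Residual (binding to any remaining site, e.g. the top-VSD pocket) is
  shared by all mutants.

The model is linear in its parameters, so fitting is linear least squares on a
binary indicator design. Because every row carries the residual term and
exactly one pore-class term, the design is typically rank-deficient along the
ridge (residual ↔ pore classes); the fitter then returns the minimum-norm
solution and :func:`solution_ranges` reports, per parameter, the interval
attainable without raising the SSE by more than a stated tolerance —
unbounded ridge directions are flagged (or boxed by explicit bounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MutantConfig",
    "MutantEncoding",
    "ShiftDataset",
    "SiteModelFit",
    "CANONICAL_PORE_CLASSES",
    "S3S4_PARAM",
    "RESIDUAL_PARAM",
    "encode_mutant",
    "build_design_matrix",
    "fit_site_model",
    "solution_ranges",
    "predict_and_correlate",
]

S3S4_PARAM = "S3S4"
RESIDUAL_PARAM = "Residual"
CANONICAL_PORE_CLASSES = ("WT_362_454", "R362Q", "W454A", "R362Q_W454A")

_FLAG_COLUMNS = ("has_2R", "R362Q", "R365Q", "W454A", "F416A")


@dataclass(frozen=True)
class MutantConfig:
    """Mutation flags of one channel construct.

    ``has_2R`` marks the M356R/A359R double-arginine motif at the top of S4;
    the remaining flags are point mutations in the S4/pore pocket.
    """

    label: str
    has_2R: bool = False
    R362Q: bool = False
    R365Q: bool = False
    W454A: bool = False
    F416A: bool = False


@dataclass(frozen=True)
class MutantEncoding:
    """How one mutant enters the additive model."""

    s3s4_active: bool
    pore_class: str
    residual_active: bool = True


def encode_mutant(config: MutantConfig) -> MutantEncoding:
    """Map a mutant to its model terms.

    The S3/S4 term is active only when the 2R motif is present; the residual
    term is always active. Pore-pocket mutations select the pore class; any
    combination involving R365Q or F416A yields an extended class (with a
    warning) rather than being folded into the four canonical ones.
    """
    mutated = [m for m in ("R362Q", "R365Q", "W454A", "F416A") if getattr(config, m)]
    if not mutated:
        pore = "WT_362_454"
    else:
        pore = "_".join(mutated)
        if pore not in CANONICAL_PORE_CLASSES:
            warnings.warn(
                f"mutant {config.label!r}: pore configuration {pore!r} is outside "
                "the four canonical S4/pore classes; using an extended class",
                stacklevel=2,
            )
    return MutantEncoding(s3s4_active=config.has_2R, pore_class=pore)


@dataclass
class ShiftDataset:
    """Per-mutant G(V) shifts for one compound at one concentration.

    ``table`` columns: mutant_label, has_2R, R362Q, R365Q, W454A, F416A,
    compound, concentration_uM, shift_mV, sem_mV, n (plus optional metadata
    such as status/note). All rows of one fitted dataset must share a single
    concentration.
    """

    table: pd.DataFrame

    REQUIRED = (
        "mutant_label", *_FLAG_COLUMNS, "compound", "concentration_uM",
        "shift_mV",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"shift table is missing column(s): {missing}")
        conc = self.table["concentration_uM"].dropna().unique()
        if conc.size > 1:
            raise ValueError(
                f"a fitted dataset must use a single concentration, got {sorted(conc)}"
            )

    @classmethod
    def from_records(
        cls,
        configs: list[MutantConfig],
        shifts: np.ndarray,
        compound: str = "synthetic",
        concentration_uM: float = 100.0,
        sem: np.ndarray | None = None,
        n: np.ndarray | None = None,
    ) -> "ShiftDataset":
        rows = []
        for i, cfg in enumerate(configs):
            rows.append(
                {
                    "mutant_label": cfg.label,
                    **{f: bool(getattr(cfg, f)) for f in _FLAG_COLUMNS},
                    "compound": compound,
                    "concentration_uM": concentration_uM,
                    "shift_mV": float(shifts[i]),
                    "sem_mV": np.nan if sem is None else float(sem[i]),
                    "n": 0 if n is None else int(n[i]),
                }
            )
        return cls(pd.DataFrame(rows))

    @property
    def configs(self) -> list[MutantConfig]:
        return [
            MutantConfig(
                label=str(r.mutant_label),
                **{f: bool(getattr(r, f)) for f in _FLAG_COLUMNS},
            )
            for r in self.table.itertuples(index=False)
        ]

    @property
    def shifts(self) -> np.ndarray:
        return self.table["shift_mV"].to_numpy(dtype=float)

    def subset(self, labels: list[str]) -> "ShiftDataset":
        """Rows for the given mutant labels, in the given order."""
        idx = self.table.set_index("mutant_label")
        missing = [l for l in labels if l not in idx.index]
        if missing:
            raise KeyError(f"mutant(s) not in dataset: {missing}")
        return ShiftDataset(idx.loc[labels].reset_index())


@dataclass
class SiteModelFit:
    """Fitted per-site shift contributions (mV) under the additive model."""

    delta_V_S3S4: float
    delta_V_S4pore: dict[str, float]
    delta_V_residual: float
    sse: float
    parameters: dict[str, float]
    solution_ranges: dict[str, tuple[float, float]]
    predicted: dict[str, float]
    pearson_r_pred_vs_obs: float
    rank: int
    n_parameters: int
    fixed: dict[str, float] = field(default_factory=dict)
    pore_silenced_by_2R: bool = False

    @property
    def degenerate(self) -> bool:
        return self.rank < self.n_parameters


def build_design_matrix(
    dataset: ShiftDataset, pore_silenced_by_2R: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Binary indicator matrix of the additive model, one row per mutant.

    Columns: the S3/S4 term, one column per pore class present in the
    dataset (canonical classes first), and the shared residual. With
    ``pore_silenced_by_2R`` the pore indicator is zeroed in rows carrying the
    2R motif — the variant in which the S3/S4 site dominates and the S4/pore
    pocket adds nothing in 2R channels.
    """
    configs = dataset.configs
    if not configs:
        raise ValueError("empty dataset")
    encodings = [encode_mutant(c) for c in configs]
    classes = [cls for cls in CANONICAL_PORE_CLASSES if any(e.pore_class == cls for e in encodings)]
    classes += sorted({e.pore_class for e in encodings} - set(classes))
    params = [S3S4_PARAM] + [f"pore:{c}" for c in classes] + [RESIDUAL_PARAM]
    col = {p: j for j, p in enumerate(params)}
    x = np.zeros((len(configs), len(params)))
    for i, enc in enumerate(encodings):
        if enc.s3s4_active:
            x[i, col[S3S4_PARAM]] = 1.0
        if not (pore_silenced_by_2R and enc.s3s4_active):
            x[i, col[f"pore:{enc.pore_class}"]] = 1.0
        if enc.residual_active:
            x[i, col[RESIDUAL_PARAM]] = 1.0
    return x, params


def _apply_fixed(
    x: np.ndarray, y: np.ndarray, params: list[str], fixed: dict[str, float]
) -> tuple[np.ndarray, list[int], np.ndarray]:
    unknown = set(fixed) - set(params)
    if unknown:
        raise KeyError(f"fixed parameter(s) not in model: {sorted(unknown)}")
    free = [j for j, p in enumerate(params) if p not in fixed]
    y_adj = y.copy()
    for p, val in fixed.items():
        y_adj = y_adj - x[:, params.index(p)] * val
    return x[:, free], free, y_adj


def fit_site_model(
    dataset: ShiftDataset,
    fixed: dict[str, float] | None = None,
    pore_silenced_by_2R: bool = False,
    weights: np.ndarray | None = None,
    tolerance: float = 0.05,
    bounds: tuple[float, float] | None = None,
) -> SiteModelFit:
    """Least-squares fit of the additive site model to a shift dataset.

    Parameters listed in ``fixed`` (e.g. ``{"Residual": -10.0}``) are held at
    the given value and removed from the free set. Optional ``weights``
    (typically 1/SEM²) give a weighted fit; the default is unweighted. On a
    rank-deficient design the minimum-norm solution is returned and
    ``solution_ranges`` carries the real per-parameter uncertainty (tolerance
    interpreted as a fraction of the minimal SSE; see :func:`solution_ranges`).
    """
    fixed = dict(fixed or {})
    x, params = build_design_matrix(dataset, pore_silenced_by_2R)
    y = dataset.shifts
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        x_fit, y_fit = x * w[:, None], y * w
    else:
        x_fit, y_fit = x, y
    x_free, free_idx, y_adj = _apply_fixed(x_fit, y_fit, params, fixed)
    theta = np.zeros(len(params))
    for p, v in fixed.items():
        theta[params.index(p)] = v
    if free_idx:
        sol, _, rank_free, _ = np.linalg.lstsq(x_free, y_adj, rcond=None)
        theta[free_idx] = sol
    else:
        rank_free = 0
    resid = y_fit - x_fit @ theta
    sse = float(resid @ resid)
    ranges = _ranges_from_design(
        x_free, theta[free_idx], [params[j] for j in free_idx],
        sse, tolerance, bounds,
    )
    for p, v in fixed.items():
        ranges[p] = (v, v)
    pred = x @ theta
    labels = dataset.table["mutant_label"].tolist()
    r = _pearson_or_nan(pred, y)
    par = dict(zip(params, theta.tolist()))
    return SiteModelFit(
        delta_V_S3S4=par.get(S3S4_PARAM, 0.0),
        delta_V_S4pore={
            p.split(":", 1)[1]: v for p, v in par.items() if p.startswith("pore:")
        },
        delta_V_residual=par.get(RESIDUAL_PARAM, 0.0),
        sse=sse,
        parameters=par,
        solution_ranges=ranges,
        predicted=dict(zip(labels, pred.tolist())),
        pearson_r_pred_vs_obs=r,
        rank=int(rank_free) + len(fixed),
        n_parameters=len(params),
        fixed=fixed,
        pore_silenced_by_2R=pore_silenced_by_2R,
    )


def _pearson_or_nan(pred: np.ndarray, obs: np.ndarray) -> float:
    if pred.size < 2 or np.allclose(pred, pred[0]) or np.allclose(obs, obs[0]):
        warnings.warn(
            "Pearson r undefined for constant predictions/observations",
            stacklevel=3,
        )
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def _ranges_from_design(
    x: np.ndarray,
    theta: np.ndarray,
    params: list[str],
    min_sse: float,
    tolerance: float,
    bounds: tuple[float, float] | None,
) -> dict[str, tuple[float, float]]:
    """Per-parameter interval over {θ : SSE(θ) ≤ min_SSE·(1+tolerance)}.

    Writing θ = θ* + δ, SSE(θ) − min_SSE = ||Xδ||². Along the row space of X
    the extent of parameter i is the closed form sqrt(tol)·||S⁻¹Vᵀe_i|| from
    the SVD X = U S Vᵀ; any component of e_i in the null space makes the
    interval unbounded (flagged as ±inf with a warning) unless a box
    ``bounds=(lo, hi)`` on all parameters is given, in which case the ridge
    extent is resolved by linear programming over the null-space coordinates.
    """
    if x.size == 0:
        return {}
    tol = max(min_sse * tolerance, 0.0)
    _, s, vt = np.linalg.svd(x, full_matrices=True)
    keep = np.zeros(vt.shape[0], dtype=bool)
    keep[: s.size] = s > max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    s_r, v_r = s[keep[: s.size]], vt[keep].T            # row space
    null = vt[~keep].T                                  # null space of X
    ranges: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(params):
        e = np.zeros(x.shape[1]); e[i] = 1.0
        row_extent = float(np.sqrt(tol) * np.linalg.norm((v_r.T @ e) / s_r)) if s_r.size else 0.0
        null_comp = null.T @ e if null.shape[1] else np.zeros(0)
        lo = theta[i] - row_extent
        hi = theta[i] + row_extent
        if null_comp.size and not np.allclose(null_comp, 0.0, atol=1e-10):
            if bounds is None:
                warnings.warn(
                    f"parameter {name!r} lies on an unconstrained ridge of the "
                    "design; its range is unbounded (pass bounds= to box it)",
                    stacklevel=3,
                )
                lo, hi = -np.inf, np.inf
            else:
                for sign, store in ((-1.0, "lo"), (1.0, "hi")):
                    res = optimize.linprog(
                        c=sign * -null_comp,  # maximise sign * e·(N b)
                        A_ub=np.vstack([null, -null]),
                        b_ub=np.concatenate(
                            [bounds[1] - theta, theta - bounds[0]]
                        ),
                        bounds=[(None, None)] * null.shape[1],
                        method="highs",
                    )
                    if not res.success:
                        lo, hi = -np.inf, np.inf
                        break
                    extent = float(null_comp @ res.x)
                    if store == "lo":
                        lo = theta[i] + extent - row_extent
                    else:
                        hi = theta[i] + extent + row_extent
        ranges[name] = (lo, hi)
    return ranges


def solution_ranges(
    dataset: ShiftDataset,
    tolerance: float = 0.05,
    fixed: dict[str, float] | None = None,
    pore_silenced_by_2R: bool = False,
    bounds: tuple[float, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Interval of each parameter over all fits with SSE ≤ min_SSE·(1+tolerance).

    ``tolerance`` is a fraction of the minimal SSE (default 5%). A parameter
    that the data leave unconstrained (a ridge direction of a rank-deficient
    design) is reported as (−inf, inf) unless a parameter box is supplied.
    """
    fit = fit_site_model(
        dataset, fixed=fixed, pore_silenced_by_2R=pore_silenced_by_2R,
        tolerance=tolerance, bounds=bounds,
    )
    return fit.solution_ranges


def predict_and_correlate(
    fit: SiteModelFit, dataset: ShiftDataset
) -> tuple[np.ndarray, float]:
    """Model-predicted shift per mutant and Pearson r against observations."""
    x, params = build_design_matrix(dataset, fit.pore_silenced_by_2R)
    missing = [p for p in params if p not in fit.parameters]
    if missing:
        raise KeyError(f"fit does not cover model term(s): {missing}")
    theta = np.array([fit.parameters[p] for p in params])
    pred = x @ theta
    return pred, _pearson_or_nan(pred, dataset.shifts)
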