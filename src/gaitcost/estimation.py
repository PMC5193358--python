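"""Constrained nonlinear least-squares estimation of the weight parameters.

The ten weights of the separable heat-coefficient model are estimated by
minimizing half the mean squared difference between measured average MEE
rates and the model's stride-time-averaged MEE rate over all estimation
strides, subject to second-law inequality constraints:

* both separable factors of each heat coefficient are non-negative for every
  estimation subject and DOF;
* the net metabolic rate at each DOF (work plus heat, excluding BMR and
  cocontraction) is non-negative at every sample -- expended metabolic
  energy cannot be recharged by negative joint work;
* when a subject's maximum aerobic power is known, the stride-average
  model MEE rate lies in [0, VO2max].

The measured quantity is a rate (W); the model integral over a stride is
divided by the stride duration so both sides of the residual are rates.

Because the model MEE average is bilinear in the weights given the
precomputed stride statistics, objective and constraint gradients are
analytic, and the problem is solved with a sequential quadratic programming
method (SLSQP) from multiple seeded starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .energetics import WeightParameters, published_weights
from .subjects import DOFCatalog, SubjectProfile, ValidationError, normalize_parameters
from .trial import GaitTrial

__all__ = [
    "ConditionEntry",
    "EstimationDataset",
    "EstimationOptions",
    "ConstraintReport",
    "EstimationResult",
    "objective",
    "constraint_set",
    "estimate_weights",
    "validate",
]


@dataclass
class ConditionEntry:
    """All strides of one subject at one speed condition plus its measurement.

    ``measured_mee_W`` is the representative (calorimetry) average MEE rate
    for the condition; every stride in ``trials`` maps to it.
    """

    subject: SubjectProfile
    condition: str
    speed_mps: float
    trials: list[GaitTrial]
    measured_mee_W: float


@dataclass
class EstimationDataset:
    """Entries for estimation or validation; N is the total stride count."""

    entries: list[ConditionEntry]
    catalog_by_sex: dict[str, DOFCatalog]

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValidationError("dataset must contain at least one stride")

    @property
    def n_strides(self) -> int:
        return sum(len(e.trials) for e in self.entries)

    def catalog_for(self, subject: SubjectProfile) -> DOFCatalog:
        return self.catalog_by_sex[subject.sex]

    def subjects(self) -> list[SubjectProfile]:
        seen: dict[str, SubjectProfile] = {}
        for e in self.entries:
            seen.setdefault(e.subject.id, e.subject)
        return list(seen.values())


def _trapezoid_mean(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Time-average over the full grid (trapezoid); y may be (n,) or (n, d)."""
    return np.trapezoid(y, t, axis=0) / (t[-1] - t[0])


class _SubjectBlock:
    """Precomputed per-subject stride statistics for fast (re)evaluation."""

    def __init__(self, subject: SubjectProfile, catalog: DOFCatalog,
                 entries: list[tuple[GaitTrial, float]]):
        self.subject = subject
        norm = normalize_parameters(subject, catalog)
        self.m_n, self.a_n, self.h_n = norm.m_n, norm.a_n, norm.h_n
        self.ratio = norm.strength_ratio
        self.tau_n = np.asarray(norm.tau_n)
        self.bmr = subject.bmr_W
        self.vo2max = subject.vo2max_W
        self.measured = np.array([m for _, m in entries])
        wbar, SA, SAt, SB, SBt = [], [], [], [], []
        P_all, A_all, B_all = [], [], []
        for trial, _ in entries:
            power = trial.tau * trial.qd
            absT = np.abs(trial.tau)
            absP = np.abs(power)
            wbar.append(float(_trapezoid_mean(trial.t, power.sum(axis=1))))
            a_mean = _trapezoid_mean(trial.t, absT)      # per-DOF mean |tau|
            b_mean = _trapezoid_mean(trial.t, absP)      # per-DOF mean |tau qd|
            SA.append(a_mean.sum())
            SAt.append(float(a_mean @ self.tau_n))
            SB.append(b_mean.sum())
            SBt.append(float(b_mean @ self.tau_n))
            P_all.append(power.T)
            A_all.append(absT.T)
            B_all.append(absP.T)
        self.wbar = np.array(wbar)
        self.SA, self.SAt = np.array(SA), np.array(SAt)
        self.SB, self.SBt = np.array(SB), np.array(SBt)
        # per-DOF sample pools (n_dof, total_samples) across all strides
        self.P = np.hstack(P_all)
        self.A = np.hstack(A_all)
        self.B = np.hstack(B_all)
        self.stride_slices = np.cumsum([0] + [p.shape[1] for p in P_all])

    # -- model pieces ------------------------------------------------------

    def factors(self, w: np.ndarray) -> tuple[float, float]:
        f_am = w[0] + w[1] * self.m_n + w[2] * self.a_n + w[3] * self.h_n
        f_sl = w[5] + w[6] * self.m_n + w[7] * self.a_n + w[8] * self.h_n
        return float(f_am), float(f_sl)

    def factor_grad(self) -> np.ndarray:
        return np.array([1.0, self.m_n, self.a_n, self.h_n])

    def coefficients(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f_am, f_sl = self.factors(w)
        h_am = f_am * (1.0 + w[4] * self.ratio * self.tau_n)
        h_sl = f_sl * (1.0 + w[9] * self.ratio * self.tau_n)
        return h_am, h_sl

    def predict(self, w: np.ndarray) -> np.ndarray:
        """Stride-average model MEE rate (W) for every stride of this subject."""
        f_am, f_sl = self.factors(w)
        am_term = f_am * (self.SA + w[4] * self.ratio * self.SAt)
        sl_term = f_sl * (self.SB + w[9] * self.ratio * self.SBt)
        return self.wbar + self.bmr + am_term + sl_term

    def predict_jac(self, w: np.ndarray) -> np.ndarray:
        """Jacobian of per-stride predictions w.r.t. the 10 weights."""
        f_am, f_sl = self.factors(w)
        g = self.factor_grad()
        J = np.zeros((len(self.wbar), 10))
        am_basis = self.SA + w[4] * self.ratio * self.SAt
        sl_basis = self.SB + w[9] * self.ratio * self.SBt
        J[:, 0:4] = am_basis[:, None] * g[None, :]
        J[:, 4] = f_am * self.ratio * self.SAt
        J[:, 5:9] = sl_basis[:, None] * g[None, :]
        J[:, 9] = f_sl * self.ratio * self.SBt
        return J

    def eq17_margins(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-DOF min-over-samples margin of the per-DOF non-negativity.

        Returns (margins, argmin sample index per DOF).
        """
        h_am, h_sl = self.coefficients(w)
        G = self.P + h_am[:, None] * self.A + h_sl[:, None] * self.B
        idx = np.argmin(G, axis=1)
        return G[np.arange(G.shape[0]), idx], idx


def _build_blocks(dataset: EstimationDataset) -> list[_SubjectBlock]:
    grouped: dict[str, list[tuple[SubjectProfile, GaitTrial, float]]] = {}
    for e in dataset.entries:
        for trial in e.trials:
            grouped.setdefault(e.subject.id, []).append((e.subject, trial, e.measured_mee_W))
    blocks = []
    for sid, rows in grouped.items():
        subject = rows[0][0]
        catalog = dataset.catalog_for(subject)
        blocks.append(_SubjectBlock(subject, catalog, [(t, m) for _, t, m in rows]))
    return blocks


def objective(w: WeightParameters | Sequence[float], dataset: EstimationDataset) -> float:
    """Half the mean squared residual between measured and model rates.

    ``(1/2) * sum_k (measured_k - model_avg_k)^2 / N`` over the N strides,
    with the model MEE rate time-averaged per stride.
    """
    wv = w.vector if isinstance(w, WeightParameters) else np.asarray(w, float)
    blocks = _build_blocks(dataset)
    sq = 0.0
    n = 0
    for b in blocks:
        r = b.measured - b.predict(wv)
        sq += float(r @ r)
        n += len(r)
    return 0.5 * sq / n


@dataclass
class ConstraintReport:
    """Margins (>= 0 means satisfied) of every inequality constraint group."""

    subject_factor_margins: dict[str, tuple[float, float]]
    dof_factor_margins: dict[str, tuple[float, float]]
    eq17_margins: dict[str, np.ndarray]
    mee_bound_margins: dict[str, tuple[float, float]]
    vo2max_skipped: list[str]

    @property
    def worst(self) -> float:
        vals: list[float] = []
        for d in (self.subject_factor_margins, self.dof_factor_margins,
                  self.mee_bound_margins):
            for pair in d.values():
                vals.extend(pair)
        for m in self.eq17_margins.values():
            vals.append(float(np.min(m)))
        return min(vals)

    def summary(self) -> dict:
        return {
            "worst_subject_factor": min((min(v) for v in self.subject_factor_margins.values()),
                                        default=np.inf),
            "worst_dof_factor": min((min(v) for v in self.dof_factor_margins.values()),
                                    default=np.inf),
            "worst_eq17": min((float(np.min(v)) for v in self.eq17_margins.values()),
                              default=np.inf),
            "worst_mee_bound": min((min(v) for v in self.mee_bound_margins.values()),
                                   default=np.inf),
            "worst": self.worst,
        }


def constraint_set(
    w: WeightParameters | Sequence[float], dataset: EstimationDataset
) -> ConstraintReport:
    """Evaluate all second-law / physiological constraint margins at ``w``.

    Subjects without a known VO2max skip the upper MEE bound with a warning.
    """
    wv = w.vector if isinstance(w, WeightParameters) else np.asarray(w, float)
    blocks = _build_blocks(dataset)
    subj_f: dict[str, tuple[float, float]] = {}
    dof_f: dict[str, tuple[float, float]] = {}
    eq17: dict[str, np.ndarray] = {}
    bounds: dict[str, tuple[float, float]] = {}
    skipped: list[str] = []
    for b in blocks:
        sid = b.subject.id
        f_am, f_sl = b.factors(wv)
        subj_f[sid] = (f_am, f_sl)
        s_am = 1.0 + wv[4] * b.ratio * b.tau_n
        s_sl = 1.0 + wv[9] * b.ratio * b.tau_n
        dof_f[sid] = (float(np.min(s_am)), float(np.min(s_sl)))
        eq17[sid], _ = b.eq17_margins(wv)
        pred = b.predict(wv)
        if b.vo2max is None:
            skipped.append(sid)
        else:
            bounds[sid] = (float(np.min(pred)), float(np.min(b.vo2max - pred)))
    if skipped:
        warnings.warn(
            f"VO2max unknown for subjects {skipped}: upper MEE bound skipped",
            stacklevel=2,
        )
    return ConstraintReport(
        subject_factor_margins=subj_f,
        dof_factor_margins=dof_f,
        eq17_margins=eq17,
        mee_bound_margins=bounds,
        vo2max_skipped=skipped,
    )


@dataclass
class EstimationOptions:
    """Solver options.

    ``multistart`` seeded starts are run (the first two are the packaged
    published weights and the zero vector); the best feasible optimum is
    returned.  ``eq17_mode='aggregated'`` enforces the per-DOF sample
    constraint as a min over all samples and strides per (subject, DOF);
    ``'per_stride'`` keeps one aggregate per (subject, stride, DOF).
    """

    seed: int = 20161228
    multistart: int = 8
    maxiter: int = 200
    ftol: float = 1e-10
    constraint_tol: float = 1e-8
    eq17_mode: str = "aggregated"
    use_vo2max: bool = True
    perturbation: float = 0.3


@dataclass
class EstimationResult:
    weights: WeightParameters
    objective_value: float
    residuals: np.ndarray
    constraint_report: ConstraintReport
    iterations: int
    solver_status: str
    start_index: int
    seed: int
    success: bool


#: Per-component magnitude used to condition the optimizer variables.
_W_SCALE = np.array([1e-4, 1e-4, 1e-4, 1e-3, 1e3, 1.0, 1e-1, 1.0, 1.0, 1e-2])


def _solver_constraints(blocks: list[_SubjectBlock], opts: EstimationOptions):
    """Inequality constraints (value >= 0) in scaled variables, with jacobians."""
    cons = []

    def unscale(z: np.ndarray) -> np.ndarray:
        return z * _W_SCALE

    for b in blocks:
        g = b.factor_grad()
        t_lo, t_hi = float(np.min(b.tau_n)), float(np.max(b.tau_n))

        def f_factors(z, b=b):
            w = unscale(z)
            return np.array(b.factors(w))

        def j_factors(z, b=b, g=g):
            J = np.zeros((2, 10))
            J[0, 0:4] = g
            J[1, 5:9] = g
            return J * _W_SCALE[None, :]

        cons.append({"type": "ineq", "fun": f_factors, "jac": j_factors})

        def f_dof(z, b=b, t_lo=t_lo, t_hi=t_hi):
            w = unscale(z)
            return np.array([
                1.0 + w[4] * b.ratio * t_lo, 1.0 + w[4] * b.ratio * t_hi,
                1.0 + w[9] * b.ratio * t_lo, 1.0 + w[9] * b.ratio * t_hi,
            ])

        def j_dof(z, b=b, t_lo=t_lo, t_hi=t_hi):
            J = np.zeros((4, 10))
            J[0, 4] = b.ratio * t_lo
            J[1, 4] = b.ratio * t_hi
            J[2, 9] = b.ratio * t_lo
            J[3, 9] = b.ratio * t_hi
            return J * _W_SCALE[None, :]

        cons.append({"type": "ineq", "fun": f_dof, "jac": j_dof})

        if opts.eq17_mode == "aggregated":
            ranges = [(0, b.P.shape[1])]
        else:
            ranges = [(int(a), int(c)) for a, c in
                      zip(b.stride_slices[:-1], b.stride_slices[1:])]

        for (lo, hi) in ranges:
            def f_eq17(z, b=b, lo=lo, hi=hi):
                w = unscale(z)
                h_am, h_sl = b.coefficients(w)
                G = (b.P[:, lo:hi] + h_am[:, None] * b.A[:, lo:hi]
                     + h_sl[:, None] * b.B[:, lo:hi])
                return np.min(G, axis=1)

            def j_eq17(z, b=b, lo=lo, hi=hi):
                w = unscale(z)
                h_am, h_sl = b.coefficients(w)
                G = (b.P[:, lo:hi] + h_am[:, None] * b.A[:, lo:hi]
                     + h_sl[:, None] * b.B[:, lo:hi])
                idx = np.argmin(G, axis=1)
                rows = np.arange(G.shape[0])
                a_star = b.A[:, lo:hi][rows, idx]
                p_star = b.B[:, lo:hi][rows, idx]
                f_am, f_sl = b.factors(w)
                g = b.factor_grad()
                s_am = 1.0 + w[4] * b.ratio * b.tau_n
                s_sl = 1.0 + w[9] * b.ratio * b.tau_n
                J = np.zeros((G.shape[0], 10))
                J[:, 0:4] = (a_star * s_am)[:, None] * g[None, :]
                J[:, 4] = a_star * f_am * b.ratio * b.tau_n
                J[:, 5:9] = (p_star * s_sl)[:, None] * g[None, :]
                J[:, 9] = p_star * f_sl * b.ratio * b.tau_n
                return J * _W_SCALE[None, :]

            cons.append({"type": "ineq", "fun": f_eq17, "jac": j_eq17})

        if opts.use_vo2max and b.vo2max is not None:
            def f_bound(z, b=b):
                w = unscale(z)
                pred = b.predict(w)
                return np.concatenate([pred, b.vo2max - pred])

            def j_bound(z, b=b):
                w = unscale(z)
                J = b.predict_jac(w)
                return np.vstack([J, -J]) * _W_SCALE[None, :]

            cons.append({"type": "ineq", "fun": f_bound, "jac": j_bound})
    return cons


def estimate_weights(
    dataset: EstimationDataset, options: Optional[EstimationOptions] = None
) -> EstimationResult:
    """Fit the ten weight parameters by constrained least squares.

    Deterministic given ``options.seed``; returns the best multistart
    optimum whose constraint margins are all above ``-constraint_tol``.
    """
    opts = options or EstimationOptions()
    blocks = _build_blocks(dataset)
    n = sum(len(b.measured) for b in blocks)
    cons = _solver_constraints(blocks, opts)

    def fun(z: np.ndarray) -> float:
        w = z * _W_SCALE
        sq = 0.0
        for b in blocks:
            r = b.measured - b.predict(w)
            sq += float(r @ r)
        return 0.5 * sq / n

    def jac(z: np.ndarray) -> np.ndarray:
        w = z * _W_SCALE
        g = np.zeros(10)
        for b in blocks:
            r = b.measured - b.predict(w)
            g -= r @ b.predict_jac(w)
        return (g / n) * _W_SCALE

    rng = np.random.default_rng(opts.seed)
    w_pub = published_weights().vector
    starts = [w_pub / _W_SCALE, np.zeros(10)]
    while len(starts) < max(opts.multistart, 1):
        base = starts[len(starts) % 2]
        starts.append(base + opts.perturbation * rng.standard_normal(10))
    starts = starts[: max(opts.multistart, 1)]

    best = None
    for k, z0 in enumerate(starts):
        res = optimize.minimize(
            fun, z0, jac=jac, method="SLSQP", constraints=cons,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol},
        )
        w_hat = _restore_feasibility(res.x * _W_SCALE, blocks)
        report = _quiet_constraint_set(w_hat, dataset)
        feasible = report.worst >= -opts.constraint_tol
        key = (not feasible, res.fun)
        if best is None or key < best[0]:
            best = (key, res, w_hat, report, k, feasible)

    _, res, w_hat, report, k, feasible = best
    if not feasible:
        raise RuntimeError(
            "estimation failed: no multistart produced a feasible optimum; "
            f"worst constraint margin {report.worst:.3e} (summary {report.summary()})"
        )
    weights = WeightParameters.from_vector(w_hat, provenance=f"estimate-seed{opts.seed}")
    residuals = np.concatenate([b.measured - b.predict(w_hat) for b in blocks])
    return EstimationResult(
        weights=weights,
        objective_value=float(res.fun),
        residuals=residuals,
        constraint_report=report,
        iterations=int(res.nit),
        solver_status=str(res.message),
        start_index=k,
        seed=opts.seed,
        success=True,
    )


def _restore_feasibility(w: np.ndarray, blocks: list[_SubjectBlock],
                         target: float = 1e-12) -> np.ndarray:
    """Repair small constraint violations left by the SQP iterations.

    The subject factors are linear in the intercepts w0 with unit
    sensitivity, and the per-DOF work-plus-heat margins are linear in the
    shortening-heat intercept w0_sl with non-negative sensitivity
    ``|tau qd| * s_sl`` at the active sample, so raising the intercepts by
    the worst deficit restores feasibility with a minimal objective change.
    """
    w = np.asarray(w, dtype=float).copy()
    for _ in range(25):
        need_am = need_sl = 0.0
        for b in blocks:
            f_am, f_sl = b.factors(w)
            need_am = max(need_am, target - f_am)
            need_sl = max(need_sl, target - f_sl)
        if need_am > 0:
            w[0] += need_am
        if need_sl > 0:
            w[5] += need_sl
        need = 0.0
        for b in blocks:
            margins, idx = b.eq17_margins(w)
            viol = margins < target
            if not np.any(viol):
                continue
            s_sl = 1.0 + w[9] * b.ratio * b.tau_n
            b_star = b.B[np.arange(b.B.shape[0]), idx]
            sens = np.maximum(b_star * s_sl, 1e-9)
            need = max(need, float(np.max((target - margins[viol]) / sens[viol])))
        if need == 0.0 and need_am == 0.0 and need_sl == 0.0:
            break
        w[5] += need
    return w


def _quiet_constraint_set(w, dataset) -> ConstraintReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return constraint_set(w, dataset)


def predict_condition_means(
    weights: WeightParameters, dataset: EstimationDataset
) -> list[dict]:
    """Per-trial model stride-average MEE rate next to its measurement."""
    wv = weights.vector
    rows = []
    for e in dataset.entries:
        catalog = dataset.catalog_for(e.subject)
        block = _SubjectBlock(e.subject, catalog, [(t, e.measured_mee_W) for t in e.trials])
        for j, pred in enumerate(block.predict(wv)):
            rows.append({
                "subject": e.subject.id,
                "condition": e.condition,
                "speed_mps": e.speed_mps,
                "stride": j,
                "model_W": float(pred),
                "measured_W": e.measured_mee_W,
            })
    return rows


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    r = stats.linregress(x, y).rvalue
    return float(r) ** 2


def validate(weights: WeightParameters, dataset: EstimationDataset) -> dict:
    """Validation statistics of the completed model against measurements.

    Per-trial percent error ``|model - measured| / measured * 100``, its mean
    and SD, the pooled (inter-subject) R^2 of model vs measured, and the
    per-subject (intra-subject) R^2 across that subject's trials.  Degenerate
    cases (single point, zero variance) yield NaN with an ``undefined`` flag.
    """
    rows = predict_condition_means(weights, dataset)
    model = np.array([r["model_W"] for r in rows])
    meas = np.array([r["measured_W"] for r in rows])
    pct = np.abs(model - meas) / meas * 100.0
    inter = _r_squared(meas, model)
    intra = {}
    for sid in sorted({r["subject"] for r in rows}):
        sel = np.array([r["subject"] == sid for r in rows])
        intra[sid] = _r_squared(meas[sel], model[sel])
    return {
        "per_trial": rows,
        "pct_error": pct,
        "mean_abs_pct_error": float(np.mean(pct)),
        "sd_abs_pct_error": float(np.std(pct, ddof=1)) if len(pct) > 1 else np.nan,
        "inter_subject_r2": inter,
        "intra_subject_r2": intra,
        "undefined": bool(np.isnan(inter)),
    }
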