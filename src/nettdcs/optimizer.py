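"""Constrained weighted least-squares montage optimization.

Given a lead field L (normal field per unit electrode current) and a
weighted target specification (t, w), find per-electrode currents c that
minimize

    sum_v w_v (sum_e L[v,e] c_e - t_v)^2

subject to the physical and safety constraints

    sum_e c_e = 0                 (Kirchhoff)
    |c_e| <= I_max                (per-electrode cap)
    sum_e |c_e| <= 2 I_tot        (total injected current cap)

The total-current cap is written symmetrically in |c|: with zero net
current, positive currents summing to at most I_tot is the same as the
L1 norm being at most 2 I_tot, and the symmetric form preserves the
anodal/cathodal duality (optimizing against -t yields -c).

The convex program is solved as a smooth quadratic program on split
variables c = p - n (p, n >= 0), which turns the L1 constraint into a
linear one, followed by an exact Karush-Kuhn-Tucker polish on the active
set so that unconstrained and bound-active solutions are recovered to
near machine precision.

Electrode subsets ("channel count") are chosen by greedy backward
elimination: starting from the solution on all candidates, repeatedly
drop the electrode whose removal (after re-solving) increases the
objective least, until the channel budget is met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .fc_target import TargetSpec
from .headmodel import LeadField
from .montage import Montage, validate_montage

__all__ = [
    "ConstraintConfig",
    "OptimizationResult",
    "objective",
    "solve_fixed_set",
    "select_channels",
]

#: Currents below this magnitude are snapped to zero in the final montage.
SNAP_TOL_MA = 1e-3  # 1 uA


@dataclass(frozen=True)
class ConstraintConfig:
    """Safety and cardinality constraints for the current optimization.

    Defaults mirror the published protocol: 4.0 mA total injected current,
    +/-2.0 mA at any single electrode, 12 channels.
    """

    total_injected_mA: float = 4.0
    per_electrode_mA: float = 2.0
    channel_budget: int = 12
    candidates: tuple[str, ...] | None = None  # None = all lead-field labels

    def __post_init__(self):
        if self.total_injected_mA <= 0 or self.per_electrode_mA <= 0:
            raise ValueError("current caps must be positive")
        if self.channel_budget < 2:
            raise ValueError("channel budget must be >= 2")


@dataclass(frozen=True)
class OptimizationResult:
    """Solver output: montage, attained objective and diagnostics."""

    montage: Montage
    objective_value: float
    converged: bool
    active_constraints: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    @property
    def currents_mA(self) -> dict[str, float]:
        return {l: c / 1000.0 for l, c in self.montage.currents_uA.items()}


def objective(L: LeadField | np.ndarray, c_mA: np.ndarray, target: TargetSpec) -> float:
    """Weighted sum of squared field errors, sum_v w_v (L c - t)_v^2."""
    M = L.matrix if isinstance(L, LeadField) else np.asarray(L, dtype=float)
    c = np.asarray(c_mA, dtype=float)
    if M.shape[1] != c.shape[0] or M.shape[0] != target.t.shape[0]:
        raise ValueError(
            f"dimension mismatch: L {M.shape}, c {c.shape}, target {target.t.shape}"
        )
    resid = M @ c - target.t
    return float(np.sum(target.w * resid**2))


# ---------------------------------------------------------------------------
# QP core


def _solve_qp(
    G: np.ndarray, h: np.ndarray, imax: float, itot: float, c0: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Minimize c'Gc - 2h'c subject to sum c = 0, |c| <= imax, sum|c| <= 2 itot.

    Returns (c, converged).  G must be symmetric positive semidefinite.
    ``c0`` optionally warm-starts the solver (e.g. the parent solution
    during greedy elimination).
    """
    k = G.shape[0]
    if k == 0:
        return np.zeros(0), True
    if k == 1:
        return np.zeros(1), True  # sum c = 0 forces c = 0

    # split variables u = [p; n], c = p - n
    def split_obj(u):
        c = u[:k] - u[k:]
        g = G @ c
        f = c @ g - 2.0 * h @ c
        grad_c = 2.0 * g - 2.0 * h
        return f, np.concatenate([grad_c, -grad_c])

    cons = [
        {"type": "eq", "fun": lambda u: np.sum(u[:k]) - np.sum(u[k:]),
         "jac": lambda u: np.concatenate([np.ones(k), -np.ones(k)])},
        {"type": "ineq", "fun": lambda u: 2.0 * itot - np.sum(u),
         "jac": lambda u: -np.ones(2 * k)},
    ]
    # per-electrode |c_e| <= imax as p_e + n_e <= imax
    eye = np.eye(k)
    A_pair = -np.hstack([eye, eye])
    cons.append({"type": "ineq", "fun": lambda u: imax + A_pair @ u, "jac": lambda u: A_pair})

    if c0 is not None and c0.shape == (k,) and _feasible(c0, imax, itot, tol=1e-12):
        x0 = np.concatenate([np.maximum(c0, 0.0), np.maximum(-c0, 0.0)])
    else:
        x0 = np.zeros(2 * k)

    best = None
    converged = False
    for _ in range(3):  # restart on line-search stalls; they occur at the optimum
        res = optimize.minimize(
            split_obj,
            x0,
            jac=True,
            method="SLSQP",
            bounds=[(0.0, imax)] * (2 * k),
            constraints=cons,
            options={"maxiter": 400, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
        # status 8 = "positive directional derivative for linesearch": the
        # SQP step can no longer decrease the objective, i.e. optimal to
        # line-search precision; the KKT polish below finishes the job.
        if res.success or res.status == 8:
            converged = True
            break
        x0 = np.clip(res.x, 0.0, imax)
    c = best.x[:k] - best.x[k:]
    if not converged:
        # high-accuracy fallback with the exact (constant) Hessian
        H = np.block([[2.0 * G, -2.0 * G], [-2.0 * G, 2.0 * G]])
        res2 = optimize.minimize(
            lambda u: split_obj(u)[0],
            np.clip(best.x, 0.0, imax),
            jac=lambda u: split_obj(u)[1],
            hess=lambda u: H,
            method="trust-constr",
            bounds=optimize.Bounds(np.zeros(2 * k), np.full(2 * k, imax)),
            constraints=[
                optimize.LinearConstraint(
                    np.concatenate([np.ones(k), -np.ones(k)])[None, :], 0.0, 0.0
                ),
                optimize.LinearConstraint(np.ones(2 * k)[None, :], -np.inf, 2.0 * itot),
                optimize.LinearConstraint(-A_pair, -np.inf, np.full(k, imax)),
            ],
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000},
        )
        if res2.fun <= best.fun:
            c = res2.x[:k] - res2.x[k:]
            converged = True
    c_pol = _kkt_polish(G, h, c, imax, itot)
    return c_pol, converged


def _qp_value(G, h, c):
    return float(c @ (G @ c) - 2.0 * h @ c)


def _feasible(c, imax, itot, tol=1e-9):
    return (
        abs(np.sum(c)) <= tol
        and np.all(np.abs(c) <= imax + tol)
        and np.sum(np.abs(c)) <= 2.0 * itot + tol
    )


def _kkt_polish(G, h, c0, imax, itot, act_tol=1e-5) -> np.ndarray:
    """Refine a near-optimal point by solving the equality-constrained QP
    on the detected active set exactly (linear KKT system).

    Active per-electrode bounds become fixed values s_e * imax; an active
    L1 budget becomes the linear constraint sum_e s_e c_e = 2 itot with
    near-zero electrodes pinned at zero.  The polished point is kept only
    if it is feasible and does not worsen the objective.
    """
    k = c0.size
    rows = [np.ones(k)]
    rhs = [0.0]
    s = np.sign(c0)
    bound_active = np.abs(c0) >= imax - act_tol
    for e in np.nonzero(bound_active)[0]:
        row = np.zeros(k)
        row[e] = 1.0
        rows.append(row)
        rhs.append(s[e] * imax)
    l1_active = np.sum(np.abs(c0)) >= 2.0 * itot - act_tol
    if l1_active:
        near_zero = np.abs(c0) < act_tol
        rows.append(np.where(near_zero, 0.0, s))
        rhs.append(2.0 * itot)
        for e in np.nonzero(near_zero)[0]:
            row = np.zeros(k)
            row[e] = 1.0
            rows.append(row)
            rhs.append(0.0)
    E = np.vstack(rows)
    d = np.asarray(rhs)
    m = E.shape[0]
    KKT = np.block([[2.0 * G, E.T], [E, np.zeros((m, m))]])
    target = np.concatenate([2.0 * h, d])
    try:
        sol, *_ = np.linalg.lstsq(KKT, target, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return c0
    c = sol[:k]
    if _feasible(c, imax, itot) and _qp_value(G, h, c) <= _qp_value(G, h, c0) + 1e-12:
        return c
    return c0


def _snap_small_currents(c_mA: np.ndarray) -> np.ndarray:
    """Zero currents below 1 uA and re-balance on the largest return electrode."""
    c = c_mA.copy()
    c[np.abs(c) < SNAP_TOL_MA] = 0.0
    imbalance = c.sum()
    if imbalance > 0.0 and np.any(c > 0):
        # shave the surplus off the largest injecting electrode (moves
        # toward zero, so caps stay satisfied)
        c[int(np.argmax(c))] -= imbalance
    elif imbalance < 0.0 and np.any(c < 0):
        c[int(np.argmin(c))] -= imbalance
    return c


def _prepare(L: LeadField, target: TargetSpec, constraints: ConstraintConfig):
    labels = constraints.candidates if constraints.candidates is not None else L.labels
    labels = tuple(labels)
    idx = [L.index(l) for l in labels]
    M = L.matrix[:, idx]
    t = np.asarray(target.t, dtype=float).ravel()
    w = np.asarray(target.w, dtype=float).ravel()
    if M.shape[0] != t.size:
        raise ValueError("target length does not match lead-field samples")
    Wl = M * w[:, None]
    G = M.T @ Wl
    h = M.T @ (w * t)
    const = float(np.sum(w * t * t))
    return labels, G, h, const


def _result_from_currents(labels, c_mA, obj_val, constraints, target, converged, extra=None):
    c_snapped = _snap_small_currents(np.asarray(c_mA, dtype=float))
    currents_uA = {lab: float(c * 1000.0) for lab, c in zip(labels, c_snapped)}
    montage = Montage(currents_uA=currents_uA, polarity=target.polarity)
    report = validate_montage(montage, constraints)
    if not report.valid:  # pragma: no cover - guarded by solver feasibility
        warnings.warn(f"optimized montage violates constraints: {report.flags}")
    active = []
    imax, itot = constraints.per_electrode_mA, constraints.total_injected_mA
    if np.any(np.abs(c_snapped) >= imax - 1e-6):
        active.append("per-electrode-cap")
    if np.sum(np.abs(c_snapped)) >= 2.0 * itot - 1e-6:
        active.append("total-injected-cap")
    diag = {"validation": report, "n_active_electrodes": int(np.sum(np.abs(c_snapped) >= SNAP_TOL_MA))}
    if extra:
        diag.update(extra)
    return OptimizationResult(
        montage=montage,
        objective_value=float(obj_val),
        converged=bool(converged),
        active_constraints=tuple(active),
        diagnostics=diag,
    )


def solve_fixed_set(
    L: LeadField, target: TargetSpec, constraints: ConstraintConfig = ConstraintConfig()
) -> OptimizationResult:
    """Optimal currents on a fixed electrode set (all candidates used).

    Solves the convex weighted least-squares program under the zero-sum,
    per-electrode and total-current constraints; the returned montage is
    validated against the same configuration.
    """
    labels, G, h, const = _prepare(L, target, constraints)
    c, ok = _solve_qp(G, h, constraints.per_electrode_mA, constraints.total_injected_mA)
    obj = _qp_value(G, h, c) + const
    return _result_from_currents(labels, c, obj, constraints, target, ok)


def select_channels(
    L: LeadField, target: TargetSpec, constraints: ConstraintConfig = ConstraintConfig()
) -> OptimizationResult:
    """Montage supported on at most ``channel_budget`` electrodes.

    Greedy backward elimination: solve on the full candidate set, then
    repeatedly remove the electrode whose removal (with re-solve)
    increases the objective least — ties broken toward the
    lexicographically first label — until the budget is met.

    Backward elimination is myopic: occasionally the re-solved optimum on
    the surviving set parks an electrode at zero current, wasting a
    channel.  A completion pass then swaps such dead channels for the
    eliminated candidate whose re-admission lowers the objective most,
    until every budgeted channel carries current or no candidate strictly
    helps.
    """
    labels, G, h, const = _prepare(L, target, constraints)
    budget = constraints.channel_budget
    if budget > len(labels):
        raise ValueError(f"channel budget {budget} exceeds {len(labels)} candidates")
    imax, itot = constraints.per_electrode_mA, constraints.total_injected_mA

    order = np.arange(len(labels))
    active = list(order)
    c, ok = _solve_qp(G, h, imax, itot)
    path = [(len(active), _qp_value(G, h, c) + const)]
    while len(active) > budget:
        best = None
        pos = {i: j for j, i in enumerate(active)}
        # lexicographic candidate order makes ties deterministic
        for e in sorted(active, key=lambda i: labels[i].lower()):
            keep = [i for i in active if i != e]
            sub = np.ix_(keep, keep)
            warm = np.array([c[pos[i]] for i in keep])  # parent solution sans e
            warm -= warm.sum() / max(len(keep), 1)  # restore zero net current
            mx, l1 = np.abs(warm).max(initial=0.0), np.abs(warm).sum()
            if mx > imax or l1 > 2.0 * itot:  # scale back inside the caps
                warm *= min(imax / mx if mx > 0 else 1.0, 2.0 * itot / l1 if l1 > 0 else 1.0)
            c_try, ok_try = _solve_qp(G[sub], h[keep], imax, itot, c0=warm)
            val = _qp_value(G[sub], h[keep], c_try) + const
            if best is None or val < best[0] - 1e-12:
                best = (val, e, keep, c_try, ok_try)
        _, drop, active, c, ok_step = best
        ok = ok and ok_step
        path.append((len(active), best[0]))
    # final re-solve on the surviving set (already done in the last step,
    # but also covers budget == |candidates|)
    sub = np.ix_(active, active)
    c, ok_fin = _solve_qp(G[sub], h[active], imax, itot, c0=c if len(active) == len(c) else None)
    obj = _qp_value(G[sub], h[active], c) + const

    # completion pass: replace structurally-zero channels with the best
    # eliminated candidate while that strictly lowers the objective
    swaps: list[tuple[int, float]] = []
    for _ in range(budget):
        support = int(np.sum(np.abs(c) >= SNAP_TOL_MA))
        pool = [i for i in order if i not in active]
        if support >= len(active) or not pool:
            break
        dead = [i for i, ci in zip(active, c) if abs(ci) < SNAP_TOL_MA]
        trial_set = [i for i in active if i not in dead[:1]] if dead else active
        best_swap = None
        for e in sorted(pool, key=lambda i: labels[i].lower()):
            cand = sorted(trial_set + [e])
            subc = np.ix_(cand, cand)
            c_try, ok_try = _solve_qp(G[subc], h[cand], imax, itot)
            val = _qp_value(G[subc], h[cand], c_try) + const
            if best_swap is None or val < best_swap[0] - 1e-12:
                best_swap = (val, cand, c_try, ok_try)
        if best_swap is None or best_swap[0] >= obj - 1e-10:
            break
        obj, active, c, ok_step = best_swap
        ok = ok and ok_step
        swaps.append((len(active), obj))
    kept_labels = tuple(labels[i] for i in active)
    c_full = np.zeros(len(labels))
    c_full[active] = c
    return _result_from_currents(
        labels,
        c_full,
        obj,
        constraints,
        target,
        ok and ok_fin,
        extra={"selected": kept_labels, "elimination_path": path, "completion_swaps": swaps},
    )
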