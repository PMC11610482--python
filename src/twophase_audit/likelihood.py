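"""Observed-data likelihood and maximum-likelihood fitting.

A partially validated cohort contributes two kinds of terms to the
log-likelihood: validated subjects contribute the complete-data product of
the four component models, unvalidated subjects the same product summed over
the latent true values (y, x).  The validation-sampling probabilities never
enter: validation is by design, so the missing values are missing at random
and Pr(V | Y*, X*, Z) only shifts the log-likelihood by a constant.

Because all variables are discrete, the cohort collapses to contingency-cell
counts and each likelihood, score or EM step costs the same no matter how
large the cohort is.

Fitting uses an EM iteration (E-step: posterior weights over the latent
(y, x); M-step: independent weighted logistic fits for the four component
models) followed by ascent-guarded Newton refinement of the observed-data
log-likelihood.  The fit trace is non-decreasing throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .cells import CellGrid, cell_grid
from .models import ModelSpec, StratumTable, Theta, derive_error_params

__all__ = [
    "Record",
    "Cohort",
    "FitResult",
    "DegenerateRecordError",
    "observed_loglik",
    "posterior_weights",
    "score_vector",
    "fit_mle",
]


class DegenerateRecordError(ValueError):
    """A record whose observed values have zero mass under every latent cell."""


@dataclass(frozen=True)
class Record:
    """One subject: Phase I values always, true (y, x) only when validated."""

    y_star: int
    x_star: int
    z: int = 0
    v: int = 0
    y: int | None = None
    x: int | None = None

    def __post_init__(self) -> None:
        if self.y_star not in (0, 1) or self.x_star not in (0, 1):
            raise ValueError("y_star and x_star must be 0/1")
        if self.v not in (0, 1):
            raise ValueError("v must be 0/1")
        if self.v == 1 and (self.y not in (0, 1) or self.x not in (0, 1)):
            raise ValueError("validated record must carry true y and x")
        if self.v == 0 and (self.y is not None or self.x is not None):
            raise ValueError("unvalidated record must not carry y or x")


class Cohort:
    """Array-backed cohort of subjects.

    ``y`` and ``x`` use -1 for unknown.  The likelihood only reads them where
    ``v == 1``; a simulated cohort may carry the full ground truth alongside
    ``v == 0`` (the truth is simply not looked at until validated).
    """

    def __init__(self, y_star, x_star, z=None, v=None, y=None, x=None,
                 n_z: int | None = None):
        self.y_star = np.asarray(y_star, dtype=np.int8)
        n = self.y_star.shape[0]
        if n == 0:
            raise ValueError("cohort must be nonempty")
        self.x_star = np.asarray(x_star, dtype=np.int8)
        self.z = (np.zeros(n, dtype=np.int16) if z is None
                  else np.asarray(z, dtype=np.int16))
        self.v = (np.zeros(n, dtype=np.int8) if v is None
                  else np.asarray(v, dtype=np.int8))
        self.y = (np.full(n, -1, dtype=np.int8) if y is None
                  else np.asarray(y, dtype=np.int8))
        self.x = (np.full(n, -1, dtype=np.int8) if x is None
                  else np.asarray(x, dtype=np.int8))
        for a in (self.x_star, self.z, self.v, self.y, self.x):
            if a.shape != (n,):
                raise ValueError("cohort arrays must share one length")
        self.n_z = int(n_z) if n_z is not None else max(int(self.z.max()) + 1, 1)
        val = self.v == 1
        if np.any((self.y[val] < 0) | (self.x[val] < 0)):
            raise ValueError("validated subjects must have known y and x")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Record], n_z: int | None = None) -> "Cohort":
        recs = list(records)
        return cls(
            [r.y_star for r in recs], [r.x_star for r in recs],
            [r.z for r in recs], [r.v for r in recs],
            [-1 if r.y is None else r.y for r in recs],
            [-1 if r.x is None else r.x for r in recs],
            n_z=n_z)

    def to_records(self) -> list[Record]:
        out = []
        for i in range(len(self)):
            v = int(self.v[i])
            out.append(Record(
                int(self.y_star[i]), int(self.x_star[i]), int(self.z[i]), v,
                int(self.y[i]) if v else None, int(self.x[i]) if v else None))
        return out

    def __len__(self) -> int:
        return self.y_star.shape[0]

    @property
    def n_validated(self) -> int:
        return int(self.v.sum())

    def stratum_table(self) -> StratumTable:
        return StratumTable.from_arrays(self.y_star, self.x_star, self.z,
                                        n_z=self.n_z)

    def with_validation(self, v: np.ndarray) -> "Cohort":
        """Copy sharing the data arrays but with a new validation indicator
        (the per-subject truth must be available wherever ``v == 1``)."""
        return Cohort(self.y_star, self.x_star, self.z,
                      np.asarray(v, dtype=np.int8), self.y, self.x,
                      n_z=self.n_z)

    def record_stratum_ids(self) -> np.ndarray:
        return ((self.y_star.astype(np.int64) * 2 + self.x_star) * self.n_z
                + self.z)

    # -- collapse to contingency cells ------------------------------------

    def collapse(self, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        """(validated counts per complete-data cell, unvalidated counts per
        sampling stratum) on the spec's :class:`CellGrid`."""
        if spec.n_z != self.n_z:
            raise ValueError("spec.n_z does not match cohort")
        grid = cell_grid(spec)
        val = self.v == 1
        idx = grid.cell_index(self.y_star[val], self.x_star[val],
                              self.y[val], self.x[val], self.z[val])
        if np.any(idx < 0):
            raise ValueError(
                "validated record contradicts an error-free variable in the spec")
        c_v = np.bincount(idx, minlength=grid.n_cells).astype(float)
        c_u = np.bincount(self.record_stratum_ids()[~val],
                          minlength=grid.n_strata).astype(float)
        return c_v, c_u


# ---------------------------------------------------------------------------
# Likelihood pieces


def _collapsed_loglik_batch(grid: CellGrid, flats: np.ndarray,
                            c_v: np.ndarray, c_u: np.ndarray) -> np.ndarray:
    flats = np.atleast_2d(flats)
    lp = grid.log_mass_batch(flats)
    mask_v = c_v > 0
    mask_u = c_u > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lse = logsumexp(
            lp.reshape(-1, grid.n_strata, grid.cells_per_stratum), axis=2)
        out = lp[:, mask_v] @ c_v[mask_v] + lse[:, mask_u] @ c_u[mask_u]
    out[~np.isfinite(out)] = -math.inf
    return out


def _collapsed_loglik(grid: CellGrid, flat: np.ndarray,
                      c_v: np.ndarray, c_u: np.ndarray) -> float:
    return float(_collapsed_loglik_batch(grid, flat[None, :], c_v, c_u)[0])


def observed_loglik(theta: Theta, cohort: Cohort, spec: ModelSpec) -> float:
    """Observed-data log-likelihood of the cohort.

    Returns ``-inf`` (rather than raising) when a required component
    probability is exactly zero.
    """
    grid = cell_grid(spec)
    c_v, c_u = cohort.collapse(spec)
    return _collapsed_loglik(grid, theta.flatten(spec), c_v, c_u)


def posterior_weights(theta: Theta, record: Record, spec: ModelSpec) -> np.ndarray:
    """Posterior Pr(y, x | y*, x*, z) for an unvalidated record, as a 2x2
    array indexed [y, x].  Cells impossible under the spec get weight 0."""
    if record.v == 1:
        raise ValueError("posterior weights are defined for unvalidated records")
    grid = cell_grid(spec)
    flat = theta.flatten(spec)
    mass = grid.masses(flat)
    sid = (record.y_star * 2 + record.x_star) * spec.n_z + record.z
    sel = grid.stratum_id == sid
    total = mass[sel].sum()
    if total <= 0.0:
        raise DegenerateRecordError("record has zero mass in every latent cell")
    w = np.zeros((2, 2))
    w[grid.y[sel], grid.x[sel]] = mass[sel] / total
    return w


def _collapsed_score(grid: CellGrid, flat: np.ndarray,
                     c_v: np.ndarray, c_u: np.ndarray) -> np.ndarray:
    S = grid.scores_validated(flat)
    mass = grid.masses(flat)
    g = c_v @ S
    Sbar = grid.scores_unvalidated(flat, mass)
    g = g + c_u @ Sbar
    return g


def score_vector(theta: Theta, record: Record, spec: ModelSpec) -> np.ndarray:
    """Analytic score (gradient of the record's log-likelihood contribution)
    in the flat parameter order of the spec."""
    grid = cell_grid(spec)
    flat = theta.flatten(spec)
    if record.v == 1:
        idx = int(grid.cell_index(record.y_star, record.x_star,
                                  record.y, record.x, record.z))
        if idx < 0:
            raise ValueError("record contradicts an error-free variable")
        return grid.scores_validated(flat)[idx]
    sid = (record.y_star * 2 + record.x_star) * spec.n_z + record.z
    return grid.scores_unvalidated(flat)[sid]


# ---------------------------------------------------------------------------
# Weighted logistic M-step


def _weighted_logistic(X: np.ndarray, r: np.ndarray, w: np.ndarray,
                       start: np.ndarray | None = None, tol: float = 1e-11,
                       max_iter: int = 60, ridge: float = 1e-8) -> np.ndarray:
    """Ascent-guarded Newton (IRLS) for a weighted logistic log-likelihood.

    A small ridge stabilizes singular steps (empty cells in the validated
    cross-tabulation make separation possible); separation then shows up as
    large but finite coefficients rather than a crash.
    """
    keep = w > 0
    Xk, rk, wk = X[keep], r[keep], w[keep]
    b = np.zeros(X.shape[1]) if start is None else start.astype(float).copy()

    def wll(bv: np.ndarray) -> float:
        eta = Xk @ bv
        return float(wk @ (rk * eta - np.logaddexp(0.0, eta)))

    ll = wll(b)
    eye = np.eye(X.shape[1])
    for _ in range(max_iter):
        p = expit(Xk @ b)
        g = Xk.T @ (wk * (rk - p))
        if np.max(np.abs(g)) < 1e-9:
            break
        h = Xk.T @ (Xk * (wk * p * (1.0 - p))[:, None])
        lam = ridge
        while True:
            try:
                step = np.linalg.solve(h + lam * eye, g)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and g @ step > 0:
                break
            lam = max(lam * 100.0, 1e-6)
            if lam > 1e8:
                return b
        t = 1.0
        for _ in range(40):
            cand = b + t * step
            ll_new = wll(cand)
            if ll_new >= ll - 1e-13:
                break
            t *= 0.5
        else:
            break
        if ll_new - ll < tol and np.max(np.abs(g)) < 1e-6:
            b, ll = cand, ll_new
            break
        b, ll = cand, ll_new
    return b


# ---------------------------------------------------------------------------
# Numerical Hessian


def _num_hessian(f_batch, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps scaled by |x|+1.

    ``f_batch`` evaluates the objective at a batch of points (n, p) -> (n,);
    all 1 + 2p + 2p(p-1) evaluation points go through a single call.
    """
    p = x.size
    h = rel_step * (np.abs(x) + 1.0)
    pts = [x]
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        pts.append(x + ei)
        pts.append(x - ei)
    pairs = [(i, j) for i in range(p) for j in range(i)]
    for i, j in pairs:
        ei = np.zeros(p)
        ei[i] = h[i]
        ej = np.zeros(p)
        ej[j] = h[j]
        pts.extend((x + ei + ej, x + ei - ej, x - ei + ej, x - ei - ej))
    vals = f_batch(np.asarray(pts))
    f0 = vals[0]
    H = np.empty((p, p))
    for i in range(p):
        H[i, i] = (vals[1 + 2 * i] - 2.0 * f0 + vals[2 + 2 * i]) / (h[i] * h[i])
    base = 1 + 2 * p
    for k, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = vals[base + 4 * k: base + 4 * k + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    theta_hat: Theta
    loglik: float
    converged: bool
    iterations: int
    se_beta: float | None
    trace: np.ndarray
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def usable(self) -> bool:
        """Converged, stable and (when standard errors were requested)
        invertible observed information -- the harness discards the rest."""
        return self.converged and not ({"unstable", "singular"} & self.flags)


_COEF_BOUND = 12.0  # |coef| beyond this is treated as a separated/unstable fit


def default_init(cohort: Cohort, spec: ModelSpec) -> Theta:
    """Deterministic starting value: naive logistic fits that treat
    (Y*, X*) as true, plus neutral mildly-informative error-model
    coefficients (baseline rates 0.25 / 0.75)."""
    st = cohort.stratum_table()
    counts = st.counts.astype(float)
    keys = np.array([list(k) for k in st.keys], dtype=float)
    ys_k, xs_k, z_k = keys[:, 0], keys[:, 1], keys[:, 2]
    cols = {"x_star": xs_k, "y": ys_k, "x": xs_k, "z": z_k}

    def naive_fit(which: str, resp: np.ndarray) -> np.ndarray:
        X = np.column_stack([_naive_column(t, cols) for t in spec.terms(which)])
        return _weighted_logistic(X, resp, counts)

    c0, c1 = derive_error_params(0.25, 0.75)
    maps: dict[str, dict[str, float]] = {}
    beta = naive_fit("analysis", ys_k)
    maps["analysis"] = dict(zip(spec.analysis, beta))
    psi = naive_fit("exposure", xs_k)
    maps["exposure"] = dict(zip(spec.exposure, psi))
    if spec.error_in_y:
        maps["outcome_error"] = {"1": c0, "y": c1}
    if spec.error_in_x:
        maps["exposure_error"] = {"1": c0, "x": c1}
    return Theta.from_terms(spec, maps)


def _naive_column(term: str, cols: dict[str, np.ndarray]) -> np.ndarray:
    if term == "1":
        return np.ones_like(cols["y"])
    if ":" in term:
        out = np.ones_like(cols["y"])
        for part in term.split(":"):
            out = out * _naive_column(part, cols)
        return out
    if term.startswith("z@"):
        return (cols["z"] == int(term[2:])).astype(float)
    return cols[term]


def fit_mle(cohort: Cohort, spec: ModelSpec, init: Theta | None = None,
            tol: float = 1e-8, max_iter: int = 1000,
            compute_se: bool = True, method: str = "hybrid") -> FitResult:
    """Maximize the observed-data log-likelihood.

    ``method="hybrid"`` (default) runs EM until the likelihood gain per
    iteration is small, then switches to ascent-guarded Newton steps on the
    observed-data log-likelihood to reach ``tol`` quickly; ``method="em"``
    iterates EM alone.  Both produce a non-decreasing trace.

    Non-convergence, separation (a coefficient beyond +-12) and a singular
    observed information are reported through ``flags`` on the result, never
    raised: the simulation harness counts and discards such replicates.
    """
    grid = cell_grid(spec)
    c_v, c_u = cohort.collapse(spec)
    flat = (init if init is not None else default_init(cohort, spec)).flatten(spec)

    def loglik(v: np.ndarray) -> float:
        return _collapsed_loglik(grid, v, c_v, c_u)

    def loglik_batch(points: np.ndarray) -> np.ndarray:
        return _collapsed_loglik_batch(grid, points, c_v, c_u)

    def em_step(v: np.ndarray) -> np.ndarray:
        w_cells = c_v + grid.posterior(v) * c_u[grid.stratum_id]
        out = v.copy()
        for m, sl in grid.slices.items():
            # a short ascent-guarded inner loop is enough: any increase of
            # the weighted logistic objective keeps EM monotone
            out[sl] = _weighted_logistic(grid.design(m), grid.response(m),
                                         w_cells, start=v[sl], max_iter=8)
        return out

    trace: list[float] = [loglik(flat)]
    converged = False
    flags: set[str] = set()
    iterations = 0
    em_switch_tol = tol if method == "em" else max(tol, 1e-3)
    newton_budget = 60

    while iterations < max_iter and not converged:
        # --- EM phase
        em_this_phase = 0
        while iterations < max_iter:
            new = em_step(flat)
            ll = loglik(new)
            iterations += 1
            em_this_phase += 1
            if ll < trace[-1] - 1e-9:
                flags.add("em_decrease")
            flat = new
            delta = ll - trace[-1]
            trace.append(ll)
            if abs(delta) < tol:
                converged = True
                break
            if method == "hybrid" and iterations >= 5 and (
                    abs(delta) < em_switch_tol or em_this_phase >= 12):
                break
        if converged or method == "em":
            break
        # --- Newton phase on the observed-data log-likelihood
        progressed = False
        for _ in range(newton_budget):
            if iterations >= max_iter:
                break
            g = _collapsed_score(grid, flat, c_v, c_u)
            H = _num_hessian(loglik_batch, flat)
            lam = 0.0
            step = None
            for _ in range(12):
                try:
                    cand = np.linalg.solve(-(H - lam * np.eye(H.shape[0])), g)
                except np.linalg.LinAlgError:
                    cand = None
                if cand is not None and g @ cand > 0:
                    step = cand
                    break
                lam = 1e-6 if lam == 0.0 else lam * 100.0
            if step is None:
                break
            t, ll_new = 1.0, -math.inf
            for _ in range(40):
                ll_new = loglik(flat + t * step)
                if ll_new >= trace[-1] - 1e-12:
                    break
                t *= 0.5
            if ll_new < trace[-1] - 1e-12:
                break
            iterations += 1
            flat = flat + t * step
            delta = ll_new - trace[-1]
            trace.append(max(ll_new, trace[-1]))
            progressed = True
            if abs(delta) < tol and np.max(np.abs(g)) < 1e-5:
                converged = True
                break
        if converged:
            break
        if not progressed:
            # Newton could not ascend; give EM another stretch
            em_switch_tol = max(em_switch_tol / 10.0, tol)
            if em_switch_tol <= tol * 1.001 and method == "hybrid":
                method = "em"  # final stretch: pure EM until tol or max_iter

    if not converged:
        flags.add("nonconverged")
    # Instability means the *analysis* coefficients diverged (empty validated
    # cells can separate them).  A separated nuisance error-model coefficient
    # leaves the target estimable and is tolerated.
    if np.max(np.abs(flat[grid.slices["analysis"]])) > _COEF_BOUND:
        flags.add("unstable")

    se_beta: float | None = None
    if compute_se:
        H = _num_hessian(loglik_batch, flat)
        try:
            cov = np.linalg.inv(-H)
            var = cov[spec.beta_index, spec.beta_index]
            if not np.isfinite(var) or var <= 0:
                raise np.linalg.LinAlgError
            se_beta = float(math.sqrt(var))
        except np.linalg.LinAlgError:
            flags.add("singular")

    return FitResult(
        theta_hat=Theta.from_flat(flat, spec),
        loglik=trace[-1],
        converged=converged,
        iterations=iterations,
        se_beta=se_beta,
        trace=np.asarray(trace),
        flags=frozenset(flags),
    )
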