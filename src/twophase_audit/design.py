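"""Optimal and classical Phase II validation allocations.

The asymptotic variance of the exposure log OR under the two-phase MLE is
``Var(beta-hat) = N^{-1} [I(theta)^{-1}]_{beta,beta}``, where the expected
per-subject Fisher information is an affine function of the per-stratum
sampling probabilities ``pi_{y*x*z} = n_{y*x*z} / N_{y*x*z}``:

    I = sum_s [ pi_s * E(S_v S_v' ; stratum s) + (1 - pi_s) * S_vbar S_vbar'
                * Pr(stratum s) ]

with the validated score ``S_v`` and the unvalidated score ``S_vbar``
evaluated symbolically on the complete-data cells (no subject data needed).
The optimal design (optMLE) minimizes this criterion over integer
allocations summing to the audit budget; an adaptive grid search locates it
over iteratively finer lattices.  Classical comparators (SRS, CC*, BCC*) and
the multiwave approximations optMLE-2 / optMLE-3 are provided alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cells import cell_grid
from .likelihood import Cohort, FitResult, fit_mle
from .models import ModelSpec, Stratum, StratumTable, Theta

__all__ = [
    "Design",
    "GridSchedule",
    "SearchTrace",
    "WavePlan",
    "MultiwaveResult",
    "SearchFailure",
    "MultiwaveFailure",
    "InfeasibleDesignError",
    "InformationModel",
    "fisher_information",
    "var_beta",
    "var_beta_schur",
    "enumerate_candidates",
    "adaptive_grid_search",
    "allocate_srs",
    "allocate_cc_star",
    "allocate_bcc_star",
    "srs_expected",
    "cc_star_expected",
    "draw_wave",
    "draw_srs",
    "draw_cc_star",
    "run_multiwave",
]


class SearchFailure(RuntimeError):
    """The grid search found no usable candidate (e.g., singular information
    at every design); harnesses count and discard such replicates."""


class InfeasibleDesignError(ValueError):
    """Requested allocation cannot be realized from the Phase I strata."""


class MultiwaveFailure(RuntimeError):
    """A wave-level fit or search failed; carries partial results."""

    def __init__(self, message: str, partial: dict | None = None):
        super().__init__(message)
        self.partial = partial or {}


@dataclass
class Design:
    """A Phase II allocation ``n_{y*x*z}`` over the Phase I strata."""

    strata: StratumTable
    alloc: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.alloc, dtype=np.int64)
        if a.shape != self.strata.counts.shape:
            raise ValueError("alloc must align with the stratum table")
        if np.any(a < 0) or np.any(a > self.strata.counts):
            raise InfeasibleDesignError("allocation outside [0, N_s] bounds")
        self.alloc = a

    @property
    def n(self) -> int:
        return int(self.alloc.sum())

    @property
    def pi(self) -> np.ndarray:
        """Per-stratum sampling probabilities n_s / N_s (0 where N_s = 0)."""
        N = self.strata.counts
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = self.alloc / N
        return np.where(N > 0, pi, 0.0)

    def __getitem__(self, stratum) -> int:
        return int(self.alloc[self.strata.index(Stratum(*stratum))])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "strata": {k.label(): int(a)
                       for k, a in zip(self.strata.keys, self.alloc)},
            "phase1": {k.label(): int(c)
                       for k, c in zip(self.strata.keys, self.strata.counts)},
            "provenance": dict(self.provenance),
        }


@dataclass(frozen=True)
class GridSchedule:
    """Step schedule of the adaptive grid search.

    ``steps`` must decrease strictly and end at 1 (the final one-person
    scale); ``m`` is the minimum sampled per nonempty stratum; ``max_grid``
    caps the candidate count of a single iteration -- when exceeded the step
    is inflated (and, at the one-person scale, the neighbourhood shrunk) for
    that iteration and the schedule resumes.  ``early_stop_rel`` optionally
    stops once the best variance improves by less than that fraction.
    """

    steps: tuple[int, ...] = (15, 5, 1)
    m: int = 10
    max_grid: int = 25000
    early_stop_rel: float | None = None

    def __post_init__(self) -> None:
        s = tuple(int(v) for v in self.steps)
        if not s or s[-1] != 1 or any(a <= b for a, b in zip(s, s[1:])) \
                or any(v < 1 for v in s):
            raise ValueError("steps must be strictly decreasing and end at 1")
        object.__setattr__(self, "steps", s)
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class SearchTrace:
    """Per-iteration audit log of the grid search."""

    steps: list[int] = field(default_factory=list)
    n_candidates: list[int] = field(default_factory=list)
    best_alloc: list[np.ndarray] = field(default_factory=list)
    best_var: list[float] = field(default_factory=list)

    def append(self, step: int, n_cand: int, alloc: np.ndarray, var: float) -> None:
        self.steps.append(int(step))
        self.n_candidates.append(int(n_cand))
        self.best_alloc.append(np.asarray(alloc).copy())
        self.best_var.append(float(var))

    def to_dict(self) -> dict:
        return {"steps": self.steps, "n_candidates": self.n_candidates,
                "best_var": self.best_var,
                "best_alloc": [a.tolist() for a in self.best_alloc]}


# ---------------------------------------------------------------------------
# Fisher information and the variance criterion


class InformationModel:
    """Expected information as an affine function of the sampling
    probabilities, pre-assembled once per (theta, spec, strata)."""

    def __init__(self, theta: Theta, spec: ModelSpec, strata: StratumTable):
        if spec.n_z != strata.n_z:
            raise ValueError("spec and stratum table disagree on n_z")
        grid = cell_grid(spec)
        flat = theta.flatten(spec)
        self.spec = spec
        self.strata = strata
        self.N = strata.N
        self.beta_index = spec.beta_index
        p = grid.n_params
        K = grid.n_strata
        cps = grid.cells_per_stratum

        mass = grid.masses(flat, strata.z_dist)
        Sv = grid.scores_validated(flat)
        massb = mass.reshape(K, cps)
        Svb = Sv.reshape(K, cps, p)
        # validated term per stratum: E[S_v S_v' ; stratum]
        A = np.einsum("kc,kci,kcj->kij", massb, Svb, Svb)
        M = massb.sum(axis=1)  # Pr(stratum)
        num = np.einsum("kc,kci->ki", massb, Svb)
        with np.errstate(invalid="ignore", divide="ignore"):
            Sbar = num / M[:, None]
        Sbar[M == 0] = 0.0
        B = np.einsum("k,ki,kj->kij", M, Sbar, Sbar)
        self._B_sum = B.sum(axis=0)
        self._D = (A - B).reshape(K, p * p)
        self._p = p
        self._K = K

    def info(self, pi: np.ndarray) -> np.ndarray:
        """Per-subject expected information at sampling probabilities pi."""
        pi = np.asarray(pi, dtype=float)
        return self._B_sum + (pi @ self._D).reshape(self._p, self._p)

    def var_beta_pi(self, pi: np.ndarray) -> float:
        return self._var_from_info(self.info(pi))

    def _var_from_info(self, I: np.ndarray) -> float:
        b = self.beta_index
        try:
            v = np.linalg.inv(I)[b, b] / self.N
        except np.linalg.LinAlgError:
            return math.inf
        return float(v) if np.isfinite(v) and v > 0 else math.inf

    def var_beta_many(self, allocs: np.ndarray) -> np.ndarray:
        """Var(beta-hat) for a batch of integer allocations (rows aligned
        with the stratum keys); singular candidates map to +inf."""
        allocs = np.atleast_2d(np.asarray(allocs, dtype=float))
        N = self.strata.counts.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pis = np.where(N > 0, allocs / N, 0.0)
        I = (self._B_sum.reshape(1, -1) + pis @ self._D).reshape(
            -1, self._p, self._p)
        b = self.beta_index
        e = np.zeros(self._p)
        e[b] = 1.0
        out = np.full(I.shape[0], math.inf)
        try:
            rhs = np.broadcast_to(e[:, None], (I.shape[0], self._p, 1))
            sol = np.linalg.solve(I, rhs)
            v = sol[:, b, 0] / self.N
            ok = np.isfinite(v) & (v > 0)
            out[ok] = v[ok]
        except np.linalg.LinAlgError:
            for i in range(I.shape[0]):
                out[i] = self._var_from_info(I[i])
        return out


def fisher_information(theta: Theta, spec: ModelSpec, pi: np.ndarray,
                       strata: StratumTable) -> np.ndarray:
    """Per-subject expected Fisher information at per-stratum sampling
    probabilities ``pi`` (aligned with the stratum-table keys)."""
    return InformationModel(theta, spec, strata).info(pi)


def var_beta(theta: Theta, spec: ModelSpec, design: Design,
             strata: StratumTable | None = None) -> float:
    """Asymptotic Var(beta-hat) of a design: the beta diagonal entry of
    ``N^{-1} I^{-1}``; ``+inf`` when the information is singular."""
    strata = strata if strata is not None else design.strata
    return InformationModel(theta, spec, strata).var_beta_pi(design.pi)


def var_beta_schur(theta: Theta, spec: ModelSpec, design: Design,
                   strata: StratumTable | None = None) -> float:
    """Same criterion through the Schur-complement form
    ``N^{-1} {I_bb - I_be' I_ee^{-1} I_be}^{-1}`` (algebraically identical;
    kept as an independent route for cross-checks)."""
    strata = strata if strata is not None else design.strata
    I = InformationModel(theta, spec, strata).info(design.pi)
    b = spec.beta_index
    keep = np.arange(I.shape[0]) != b
    I_bb = I[b, b]
    I_be = I[keep, b]
    I_ee = I[np.ix_(keep, keep)]
    try:
        schur = I_bb - I_be @ np.linalg.solve(I_ee, I_be)
        v = 1.0 / (strata.N * schur)
    except np.linalg.LinAlgError:
        return math.inf
    return float(v) if np.isfinite(v) and v > 0 else math.inf


# ---------------------------------------------------------------------------
# Candidate enumeration


def _bounds(strata: StratumTable, n: int, m: int,
            floor: np.ndarray | None, center: np.ndarray | None,
            radius: int | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N = strata.counts
    active = N > 0
    lower = np.minimum(m, N).astype(np.int64)
    if floor is not None:
        lower = np.maximum(lower, np.asarray(floor, dtype=np.int64))
    lower[~active] = 0
    if center is None:
        other = lower.sum() - lower
        upper = np.minimum(n - other, N)
    else:
        center = np.asarray(center, dtype=np.int64)
        lower = np.maximum(center - radius, lower)
        upper = np.minimum(center + radius, N)
    upper = np.where(active, upper, 0)
    return lower, upper, active


def _grid_estimate(lower, upper, active, step) -> float:
    act = np.flatnonzero(active)
    if act.size <= 1:
        return 1.0
    spans = upper[act[:-1]] - lower[act[:-1]]
    return float(np.prod(spans // step + 1.0))


def enumerate_candidates(strata: StratumTable, n: int, m: int = 10,
                         step: int = 1, center: np.ndarray | None = None,
                         prev_step: int | None = None,
                         floor: np.ndarray | None = None) -> np.ndarray:
    """Lattice of feasible allocations, rows aligned with the stratum keys.

    Free strata take values ``lower + j*step``; the last nonempty stratum in
    key order absorbs the remainder so every candidate sums to ``n``
    exactly.  With ``center`` given, per-stratum bounds become the
    ``prev_step``-person neighbourhood of the centre.  Candidates appear in
    lexicographic stratum-key order; an empty array means no feasible
    candidate at this step.
    """
    if n > strata.N:
        raise InfeasibleDesignError("budget exceeds the Phase I cohort")
    lower, upper, active = _bounds(strata, n, m, floor, center, prev_step)
    K_total = len(strata.keys)
    empty = np.empty((0, K_total), dtype=np.int64)
    act = np.flatnonzero(active)
    if act.size == 0 or np.any(lower[act] > upper[act]) \
            or lower[act].sum() > n or upper[act].sum() < n:
        return empty
    if act.size == 1:
        out = np.zeros((1, K_total), dtype=np.int64)
        out[0, act[0]] = n
        return out
    free, absorber = act[:-1], act[-1]
    values = []
    for s in free:
        vals = np.arange(lower[s], upper[s] + 1, step, dtype=np.int64)
        if vals[-1] != upper[s]:
            # the clipped cap (e.g. the full stratum size) stays reachable
            # even when it falls off the lattice
            vals = np.append(vals, upper[s])
        values.append(vals)
    mesh = np.meshgrid(*values, indexing="ij")
    combos = np.stack([g.ravel() for g in mesh], axis=-1)
    rem = n - combos.sum(axis=1)
    ok = (rem >= lower[absorber]) & (rem <= upper[absorber])
    if not np.any(ok):
        return empty
    out = np.zeros((int(ok.sum()), K_total), dtype=np.int64)
    out[:, free] = combos[ok]
    out[:, absorber] = rem[ok]
    return out


# ---------------------------------------------------------------------------
# Adaptive grid search


def adaptive_grid_search(theta: Theta, spec: ModelSpec, strata: StratumTable,
                         n: int, schedule: GridSchedule | None = None,
                         floor: np.ndarray | None = None
                         ) -> tuple[Design, SearchTrace]:
    """Locate the variance-minimizing allocation (the optMLE design).

    Grids are evaluated at iteratively finer steps over neighbourhoods of
    the running best design; whenever a grid would exceed ``max_grid`` the
    step is inflated (or, at the one-person scale, the neighbourhood halved)
    for that iteration and the schedule resumes.  One-person iterations
    repeat around the new centre until no improvement remains, so the result
    is locally optimal at the one-person scale.  Ties break toward the first
    candidate in enumeration order.
    """
    schedule = schedule or GridSchedule()
    m = schedule.m
    info = InformationModel(theta, spec, strata)
    lower0, upper0, active = _bounds(strata, n, m, floor, None, None)
    act = np.flatnonzero(active)
    if lower0[act].sum() > n:
        raise InfeasibleDesignError(
            "budget below the per-stratum minima (n < sum of lower bounds)")

    trace = SearchTrace()
    center: np.ndarray | None = None
    prev_eff: int | None = None
    best_var = math.inf
    ptr = 0
    for _ in range(200):
        step = schedule.steps[ptr]
        eff, radius = step, prev_eff
        for _ in range(64):
            lo, up, _ = _bounds(strata, n, m, floor, center, radius)
            if _grid_estimate(lo, up, active, eff) <= schedule.max_grid:
                break
            if radius is not None and eff >= 2 * radius and radius > 1:
                radius = max(radius // 2, 1)
            else:
                eff *= 2
        cands = enumerate_candidates(strata, n, m, eff, center=center,
                                     prev_step=radius, floor=floor)
        for _ in range(16):  # lattice may miss the absorber window entirely
            if cands.size:
                break
            eff *= 2
            cands = enumerate_candidates(strata, n, m, eff, center=center,
                                         prev_step=radius, floor=floor)
        if center is not None and cands.size:
            cands = np.vstack([cands, center[None, :]])
        elif not cands.size:
            raise SearchFailure("no feasible candidate designs")
        variances = info.var_beta_many(cands)
        i = int(np.argmin(variances))
        if not np.isfinite(variances[i]):
            raise SearchFailure("information matrix singular at every candidate")
        improved = variances[i] < best_var - 0.0
        previous_best = best_var
        best_var = float(variances[i])
        center = cands[i].copy()
        prev_eff = eff
        trace.append(eff, cands.shape[0], center, best_var)
        if schedule.early_stop_rel is not None and np.isfinite(previous_best):
            if previous_best - best_var < schedule.early_stop_rel * previous_best:
                break
        if eff == 1 and not improved:
            break
        if eff == step and ptr < len(schedule.steps) - 1:
            ptr += 1
    design = Design(strata, center, provenance={
        "allocator": "optMLE", "n": int(n),
        "schedule": list(schedule.steps), "m": int(m),
        "var_beta": best_var,
        "floor": None if floor is None else np.asarray(floor).tolist()})
    return design, trace


# ---------------------------------------------------------------------------
# Classical allocators


def _largest_remainder(quota: np.ndarray, total: int,
                       priority: np.ndarray | None = None) -> np.ndarray:
    base = np.floor(quota).astype(np.int64)
    r = int(total - base.sum())
    frac = quota - base
    key = frac if priority is None else frac + 1e-12 * priority
    order = np.argsort(-key, kind="stable")
    base[order[:r]] += 1
    return base


def srs_expected(strata: StratumTable, n: int) -> np.ndarray:
    """Expected per-stratum allocation of simple random sampling."""
    if n > strata.N:
        raise InfeasibleDesignError("budget exceeds the cohort")
    return n * strata.counts / strata.N


def allocate_srs(strata: StratumTable, n: int,
                 rng: np.random.Generator | None = None) -> Design:
    """SRS allocation: uniform draw over the cohort; the deterministic
    variant rounds the expected allocation by largest remainder."""
    if rng is None:
        alloc = _largest_remainder(srs_expected(strata, n), n)
    else:
        alloc = rng.multivariate_hypergeometric(strata.counts, n)
    return Design(strata, alloc, provenance={"allocator": "SRS"})


def _cc_margin_split(strata: StratumTable, n: int) -> tuple[int, int]:
    counts2 = strata.counts.reshape(2, -1).sum(axis=1)  # Y* margins
    if n > strata.N:
        raise InfeasibleDesignError("budget exceeds the cohort")
    if counts2[0] == 0 or counts2[1] == 0:
        raise InfeasibleDesignError("a Y* margin is empty")
    n0 = n - n // 2  # odd budgets put the extra subject in Y* = 0
    n1 = n // 2
    if n0 > counts2[0]:
        n1 += n0 - counts2[0]
        n0 = int(counts2[0])
    if n1 > counts2[1]:
        n0 += n1 - counts2[1]
        n1 = int(counts2[1])
    n0 = min(n0, int(counts2[0]))
    return n0, n1


def cc_star_expected(strata: StratumTable, n: int) -> np.ndarray:
    """Expected allocation of CC* sampling (equal halves per Y* margin,
    uniform within each margin)."""
    n0, n1 = _cc_margin_split(strata, n)
    counts = strata.counts.reshape(2, -1).astype(float)
    margins = counts.sum(axis=1)
    exp = np.vstack([n0 * counts[0] / margins[0], n1 * counts[1] / margins[1]])
    return exp.ravel()


def allocate_cc_star(strata: StratumTable, n: int,
                     rng: np.random.Generator | None = None) -> Design:
    """CC* allocation: separate equal-sized random samples per Y* stratum."""
    n0, n1 = _cc_margin_split(strata, n)
    half = len(strata.keys) // 2
    if rng is None:
        exp = cc_star_expected(strata, n)
        alloc = np.concatenate([
            _largest_remainder(exp[:half], n0),
            _largest_remainder(exp[half:], n1)])
    else:
        alloc = np.concatenate([
            rng.multivariate_hypergeometric(strata.counts[:half], n0),
            rng.multivariate_hypergeometric(strata.counts[half:], n1)])
    return Design(strata, alloc, provenance={"allocator": "CC*"})


def allocate_bcc_star(strata: StratumTable, n: int) -> Design:
    """BCC* allocation: equal targets over the nonempty (Y*, X*, Z) strata.

    Strata smaller than the running equal share are taken in full and the
    surplus re-spread over the rest until stable; integer remainders go one
    each to the largest-N strata (ties by stratum key order).
    """
    N = strata.counts
    if n > strata.N:
        raise InfeasibleDesignError("budget exceeds the cohort")
    alloc = np.zeros_like(N)
    remaining = [int(s) for s in np.flatnonzero(N > 0)]
    n_rem = int(n)
    while remaining:
        base = n_rem // len(remaining)
        small = [s for s in remaining if N[s] <= base]
        if small:
            for s in small:
                alloc[s] = N[s]
                n_rem -= int(N[s])
                remaining.remove(s)
            continue
        r = n_rem - base * len(remaining)
        order = sorted(remaining, key=lambda s: (-N[s], s))
        for s in remaining:
            alloc[s] = base
        for s in order[:r]:
            alloc[s] += 1
        break
    return Design(strata, alloc, provenance={"allocator": "BCC*"})


# ---------------------------------------------------------------------------
# Realizing designs as subject draws


def draw_wave(cohort: Cohort, increment: np.ndarray | Design,
              already_validated: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Draw the requested number of not-yet-validated subjects uniformly
    within each stratum; returns the boolean mask of newly drawn subjects."""
    inc = increment.alloc if isinstance(increment, Design) else \
        np.asarray(increment, dtype=np.int64)
    already = np.asarray(already_validated, dtype=bool)
    sid = cohort.record_stratum_ids()
    new = np.zeros(len(cohort), dtype=bool)
    for k in range(inc.shape[0]):
        want = int(inc[k])
        if want == 0:
            continue
        pool = np.flatnonzero((sid == k) & ~already)
        if pool.size < want:
            raise InfeasibleDesignError(
                f"stratum {k}: requested {want} of {pool.size} unvalidated")
        new[rng.choice(pool, size=want, replace=False)] = True
    return new


def draw_srs(cohort: Cohort, n: int, already_validated: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    pool = np.flatnonzero(~np.asarray(already_validated, dtype=bool))
    if pool.size < n:
        raise InfeasibleDesignError("budget exceeds the unvalidated pool")
    new = np.zeros(len(cohort), dtype=bool)
    new[rng.choice(pool, size=n, replace=False)] = True
    return new


def draw_cc_star(cohort: Cohort, n: int, already_validated: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    strata = cohort.stratum_table()
    n0, n1 = _cc_margin_split(strata, n)
    already = np.asarray(already_validated, dtype=bool)
    new = np.zeros(len(cohort), dtype=bool)
    for margin, want in ((0, n0), (1, n1)):
        pool = np.flatnonzero((cohort.y_star == margin) & ~already)
        if pool.size < want:
            raise InfeasibleDesignError(f"Y*={margin} margin too small")
        new[rng.choice(pool, size=want, replace=False)] = True
    return new


# ---------------------------------------------------------------------------
# Multiwave orchestration


@dataclass(frozen=True)
class WavePlan:
    """Ordered wave sizes plus the wave-1 mechanism.

    ``wave1`` is one of ``"bcc"`` (default), ``"cc"``, ``"srs"`` or
    ``"optmle"``; the last requires ``theta0`` (e.g., historical parameter
    estimates) to run the grid search for the first wave.  Later waves
    always re-estimate theta from the accumulated data unless ``theta0`` is
    given and ``reuse_theta0`` is set.
    """

    sizes: tuple[int, ...]
    wave1: str = "bcc"
    theta0: Theta | None = None
    reuse_theta0: bool = False

    def __post_init__(self) -> None:
        if not self.sizes or any(int(s) <= 0 for s in self.sizes):
            raise ValueError("wave sizes must be positive")
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if self.wave1 not in ("bcc", "cc", "srs", "optmle"):
            raise ValueError("unknown wave-1 allocator")
        if self.wave1 == "optmle" and self.theta0 is None:
            raise ValueError("wave1='optmle' requires theta0")

    @property
    def n(self) -> int:
        return int(sum(self.sizes))


@dataclass
class MultiwaveResult:
    cohort: Cohort                # with the final validation indicator
    designs: list[Design]         # cumulative design after each wave
    fit: FitResult                # MLE on all waves combined
    wave_fits: list[FitResult]    # interim fits used to plan each later wave
    traces: list[SearchTrace]


def _stratum_counts_of(cohort: Cohort, mask: np.ndarray) -> np.ndarray:
    return np.bincount(cohort.record_stratum_ids()[mask],
                       minlength=4 * cohort.n_z)


def run_multiwave(cohort: Cohort, spec: ModelSpec, plan: WavePlan,
                  schedule: GridSchedule | None = None,
                  rng: np.random.Generator | None = None,
                  design_spec: ModelSpec | None = None,
                  compute_se: bool = True) -> MultiwaveResult:
    """Run a multiwave approximate-optimal validation study.

    Wave 1 uses the plan's allocator; each later wave fits the MLE on the
    data accumulated so far, then grid-searches the *cumulative* design with
    the already-validated counts as per-stratum lower bounds, and draws the
    increment.  The final MLE combines Phase I with every wave.  A
    ``design_spec`` (e.g., main-effects-only misclassification models) makes
    the search use that specification while fitting keeps ``spec``.

    Raises :class:`MultiwaveFailure` when an interim fit is unusable or the
    search fails; the simulation harness counts and discards those.
    """
    schedule = schedule or GridSchedule(steps=(25, 5, 1))
    rng = rng or np.random.default_rng()
    strata = cohort.stratum_table()
    validated = cohort.v.astype(bool).copy()
    designs: list[Design] = []
    wave_fits: list[FitResult] = []
    traces: list[SearchTrace] = []

    n1 = plan.sizes[0]
    if plan.wave1 == "bcc":
        d1 = allocate_bcc_star(strata, n1)
        validated |= draw_wave(cohort, d1, validated, rng)
    elif plan.wave1 == "cc":
        new = draw_cc_star(cohort, n1, validated, rng)
        validated |= new
        d1 = Design(strata, _stratum_counts_of(cohort, new),
                    provenance={"allocator": "CC*"})
    elif plan.wave1 == "srs":
        new = draw_srs(cohort, n1, validated, rng)
        validated |= new
        d1 = Design(strata, _stratum_counts_of(cohort, new),
                    provenance={"allocator": "SRS"})
    else:  # optmle with supplied theta
        theta0 = plan.theta0
        dspec = design_spec or spec
        th = theta0.restrict(spec, dspec) if design_spec is not None else theta0
        d1, tr = adaptive_grid_search(th, dspec, strata, n1, schedule)
        traces.append(tr)
        validated |= draw_wave(cohort, d1, validated, rng)
    designs.append(d1)

    cumulative = n1
    for size in plan.sizes[1:]:
        cumulative += size
        if plan.reuse_theta0 and plan.theta0 is not None:
            theta_w = plan.theta0
        else:
            interim = fit_mle(cohort.with_validation(validated), spec,
                              compute_se=False)
            wave_fits.append(interim)
            # planning only needs a converged interim fit; a separated
            # nuisance coefficient merely shapes the candidate variances,
            # and a truly degenerate theta surfaces as a search failure
            if not interim.converged:
                raise MultiwaveFailure(
                    "interim MLE did not converge; cannot plan the next wave",
                    partial={"designs": designs, "wave_fits": wave_fits})
            theta_w = interim.theta_hat
        dspec = design_spec or spec
        th = theta_w.restrict(spec, dspec) if design_spec is not None else theta_w
        floor = _stratum_counts_of(cohort, validated)
        try:
            design, tr = adaptive_grid_search(th, dspec, strata, cumulative,
                                              schedule, floor=floor)
        except (SearchFailure, InfeasibleDesignError) as exc:
            raise MultiwaveFailure(
                f"grid search failed: {exc}",
                partial={"designs": designs, "wave_fits": wave_fits}) from exc
        traces.append(tr)
        increment = design.alloc - floor
        validated |= draw_wave(cohort, increment, validated, rng)
        designs.append(design)

    final_cohort = cohort.with_validation(validated)
    fit = fit_mle(final_cohort, spec, compute_se=compute_se)
    return MultiwaveResult(cohort=final_cohort, designs=designs, fit=fit,
                           wave_fits=wave_fits, traces=traces)
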