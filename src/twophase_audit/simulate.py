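"""Synthetic cohorts and the replicate study harness.

The generator draws Phase I cohorts from the same factorization the
likelihood assumes: Z ~ Bernoulli(p_z) (optional), X | Z and Y | X, Z from
logistic models, then the error-prone surrogates X* | Y, X, Z and
Y* | X*, Y, X, Z from differential misclassification models whose intercept
and true-variable slope are parametrized by baseline false/true positive
rates (``derive_error_params``).  The harness replicates a scenario, runs
each requested validation design on a shared cohort (paired comparison),
fits the MLE on Phases I + II, and summarizes percent bias, empirical SE,
and efficiency relative to the true-parameter optMLE reference design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import (GridSchedule, InfeasibleDesignError, MultiwaveFailure,
                     SearchFailure, WavePlan, adaptive_grid_search,
                     allocate_bcc_star, draw_cc_star, draw_srs, draw_wave,
                     run_multiwave)
from .likelihood import Cohort, fit_mle
from .models import ModelSpec, SeedStream, Theta, derive_error_params

__all__ = [
    "CovariateBlock",
    "SimScenario",
    "StudyResult",
    "scenario_theta",
    "generate_cohort",
    "run_study",
    "summarize",
    "KNOWN_DESIGNS",
]

KNOWN_DESIGNS = ("SRS", "CC*", "BCC*", "optMLE", "optMLE*",
                 "optMLE-2", "optMLE-2*", "optMLE-3")


@dataclass(frozen=True)
class CovariateBlock:
    """Error-free binary covariate block.

    ``delta1`` / ``delta2`` are the X:Z interaction coefficients of the
    exposure- and outcome-error models; the design-stage robustness study
    varies them while main-effects-only designs ignore them.
    """

    p_z: float = 0.25
    beta_z: float = 0.25    # Z coefficient, analysis model
    psi_z: float = 0.5      # Z coefficient, X | Z model
    alpha_z: float = 1.0    # Z coefficient, outcome-error model
    gamma_z: float = 1.0    # Z coefficient, exposure-error model
    delta1: float = 0.0     # X:Z coefficient, exposure-error model
    delta2: float = 0.0     # X:Z coefficient, outcome-error model

    def __post_init__(self) -> None:
        if not 0.0 < self.p_z < 1.0:
            raise ValueError("p_z must lie in (0, 1)")


@dataclass(frozen=True)
class SimScenario:
    """Generative-model parameters of one simulation setting.

    Defaults give the base setting: N = 10,000 cohort, n = 400 audits,
    Pr(X=1) = 0.1, Pr(Y=1|X=0) = 0.3, log OR 0.3, all baseline error rates
    FPR = 0.1 / TPR = 0.9, with fixed differential cross-terms (0.45 for Y
    in the X* model; 0.275 for X* and X in the Y* model).
    """

    N: int = 10_000
    n: int = 400
    p_x: float = 0.1
    p_y0: float = 0.3
    beta_true: float = 0.3
    fpr_x: float = 0.1
    tpr_x: float = 0.9
    fpr_y: float = 0.1
    tpr_y: float = 0.9
    gamma_y: float = 0.45      # Y coefficient in the X* model
    alpha_xstar: float = 0.275
    alpha_x: float = 0.275
    covariate: CovariateBlock | None = None
    error_mode: str = "both"   # both | outcome-only | exposure-only

    def __post_init__(self) -> None:
        for r in (self.p_x, self.p_y0, self.fpr_x, self.tpr_x,
                  self.fpr_y, self.tpr_y):
            if not 0.0 < r < 1.0:
                raise ValueError("probabilities and rates must lie in (0, 1)")
        if self.error_mode not in ("both", "outcome-only", "exposure-only"):
            raise ValueError("unknown error_mode")
        if not 0 < self.n <= self.N:
            raise ValueError("need 0 < n <= N")

    # -- model structure ---------------------------------------------------

    @property
    def error_in_y(self) -> bool:
        return self.error_mode in ("both", "outcome-only")

    @property
    def error_in_x(self) -> bool:
        return self.error_mode in ("both", "exposure-only")

    def model_spec(self) -> ModelSpec:
        """The (correctly specified) analysis-stage model specification."""
        cov = self.covariate is not None
        z_terms = ("z",) if cov else ()
        analysis = ("1", "x") + z_terms
        exposure = ("1",) + z_terms
        if self.error_in_y:
            xstar = ("x_star",) if self.error_in_x else ()
            outcome_error = ("1",) + xstar + ("y", "x") + z_terms \
                + (("x:z",) if cov else ())
        else:
            outcome_error = None
        if self.error_in_x:
            exposure_error = ("1", "y", "x") + z_terms + (("x:z",) if cov else ())
        else:
            exposure_error = None
        return ModelSpec(analysis=analysis, outcome_error=outcome_error,
                         exposure_error=exposure_error, exposure=exposure,
                         n_z=2 if cov else 1)

    def main_effects_spec(self) -> ModelSpec:
        """Design-stage specification with the misclassification-model
        interactions dropped (the optMLE* / optMLE-2* variants)."""
        spec = self.model_spec()
        if spec.error_in_y:
            spec = spec.drop_terms("outcome_error", ["x:z"])
        if spec.error_in_x:
            spec = spec.drop_terms("exposure_error", ["x:z"])
        return spec

    def true_design_spec(self) -> ModelSpec:
        """The correctly specified design-stage model in minimal form.

        An interaction whose generating coefficient is zero is not part of
        the true model, so the gold-standard design drops it; carrying it
        as a free parameter would (slightly) distort the variance criterion
        with nuisance information the true model does not contain.
        """
        spec = self.model_spec()
        cov = self.covariate
        if cov is None:
            return spec
        if spec.error_in_y and cov.delta2 == 0.0:
            spec = spec.drop_terms("outcome_error", ["x:z"])
        if spec.error_in_x and cov.delta1 == 0.0:
            spec = spec.drop_terms("exposure_error", ["x:z"])
        return spec


def scenario_theta(scenario: SimScenario) -> Theta:
    """Assemble the generating parameter vector of a scenario.

    Intercepts come from the stated prevalences (``beta0 = logit(p_y0)``,
    ``psi0 = logit(p_x)``); each error model's intercept and true-variable
    slope come from its baseline rates via :func:`derive_error_params`; the
    differential cross-terms are the scenario's fixed coefficients.
    """
    spec = scenario.model_spec()
    cov = scenario.covariate
    maps: dict[str, dict[str, float]] = {
        "analysis": {"1": float(logit(scenario.p_y0)),
                     "x": scenario.beta_true},
        "exposure": {"1": float(logit(scenario.p_x))},
    }
    if cov is not None:
        maps["analysis"]["z"] = cov.beta_z
        maps["exposure"]["z"] = cov.psi_z
    if scenario.error_in_y:
        a0, a1 = derive_error_params(scenario.fpr_y, scenario.tpr_y)
        amap = {"1": a0, "y": a1, "x": scenario.alpha_x}
        if scenario.error_in_x:
            amap["x_star"] = scenario.alpha_xstar
        if cov is not None:
            amap["z"] = cov.alpha_z
            amap["x:z"] = cov.delta2
        maps["outcome_error"] = amap
    if scenario.error_in_x:
        g0, g1 = derive_error_params(scenario.fpr_x, scenario.tpr_x)
        gmap = {"1": g0, "y": scenario.gamma_y, "x": g1}
        if cov is not None:
            gmap["z"] = cov.gamma_z
            gmap["x:z"] = cov.delta1
        maps["exposure_error"] = gmap
    return Theta.from_terms(spec, maps)


# ---------------------------------------------------------------------------
# Cohort generation


def _eta(terms: Sequence[str], coefs: np.ndarray,
         cols: Mapping[str, np.ndarray]) -> np.ndarray:
    out = np.zeros_like(cols["x"], dtype=float)
    for t, c in zip(terms, coefs):
        if t == "1":
            out += c
        elif ":" in t:
            prod = np.ones_like(out)
            for part in t.split(":"):
                prod *= cols[part]
            out += c * prod
        elif t.startswith("z@"):
            out += c * (cols["z"] == int(t[2:]))
        else:
            out += c * cols[t]
    return out


def generate_cohort(scenario: SimScenario, rng: np.random.Generator) -> Cohort:
    """Draw a Phase I cohort of size N from the scenario's generative model.

    The true (Y, X) are retained on every record as ground truth, but all
    records start unvalidated (``v = 0``): the likelihood never reads the
    truth until a design validates it.  Identical generators yield
    bit-identical cohorts.
    """
    spec = scenario.model_spec()
    theta = scenario_theta(scenario)
    N = scenario.N
    cov = scenario.covariate
    z = ((rng.random(N) < cov.p_z).astype(np.int8) if cov is not None
         else np.zeros(N, dtype=np.int8))
    cols: dict[str, np.ndarray] = {"z": z.astype(float),
                                   "x": np.zeros(N)}
    x = (rng.random(N) < expit(_eta(spec.exposure, theta.psi, cols))).astype(np.int8)
    cols["x"] = x.astype(float)
    y = (rng.random(N) < expit(_eta(spec.analysis, theta.beta, cols))).astype(np.int8)
    cols["y"] = y.astype(float)
    if scenario.error_in_x:
        p = expit(_eta(spec.exposure_error, theta.gamma, cols))
        x_star = (rng.random(N) < p).astype(np.int8)
    else:
        x_star = x.copy()
    cols["x_star"] = x_star.astype(float)
    if scenario.error_in_y:
        p = expit(_eta(spec.outcome_error, theta.alpha, cols))
        y_star = (rng.random(N) < p).astype(np.int8)
    else:
        y_star = y.copy()
    return Cohort(y_star, x_star, z, v=np.zeros(N, dtype=np.int8),
                  y=y, x=x, n_z=spec.n_z)


# ---------------------------------------------------------------------------
# Replicate harness


@dataclass
class StudyResult:
    """Per-replicate estimates per design, with discard bookkeeping."""

    frame: pd.DataFrame          # replicate, design, beta_hat, usable, flag
    scenario: SimScenario
    reps: int
    designs: tuple[str, ...]

    def beta_hats(self, design: str) -> np.ndarray:
        f = self.frame
        sel = (f["design"] == design) & f["usable"]
        return f.loc[sel, "beta_hat"].to_numpy(dtype=float)

    def discards(self) -> pd.Series:
        f = self.frame
        return (~f["usable"]).groupby(f["design"]).sum()


def _realize_and_fit(cohort: Cohort, scenario: SimScenario, design: str,
                     stream: SeedStream, rep: int,
                     opt_schedule: GridSchedule,
                     wave_schedule: GridSchedule) -> tuple[float, bool, str]:
    """Run one design on one cohort; returns (beta_hat, usable, flag)."""
    spec = scenario.model_spec()
    theta_true = scenario_theta(scenario)
    strata = cohort.stratum_table()
    n = scenario.n
    none = np.zeros(len(cohort), dtype=bool)
    b_idx = spec.analysis.index("x")
    try:
        if design == "SRS":
            v = draw_srs(cohort, n, none, stream.child("srs", rep))
        elif design == "CC*":
            v = draw_cc_star(cohort, n, none, stream.child("cc", rep))
        elif design == "BCC*":
            d = allocate_bcc_star(strata, n)
            v = draw_wave(cohort, d, none, stream.child("strat", rep))
        elif design in ("optMLE", "optMLE*"):
            dspec = (scenario.main_effects_spec() if design == "optMLE*"
                     else scenario.true_design_spec())
            th = theta_true.restrict(spec, dspec)
            d, _ = adaptive_grid_search(th, dspec, strata, n, opt_schedule)
            v = draw_wave(cohort, d, none, stream.child("strat", rep))
        elif design in ("optMLE-2", "optMLE-2*", "optMLE-3"):
            if design == "optMLE-3":
                sizes = (n // 2, n // 4, n - n // 2 - n // 4)
                rng = stream.child("mw3", rep)
            else:
                sizes = (n // 2, n - n // 2)
                rng = stream.child("mw2", rep)
            dspec = (scenario.main_effects_spec()
                     if design == "optMLE-2*" else scenario.true_design_spec())
            res = run_multiwave(cohort, spec, WavePlan(sizes),
                                schedule=wave_schedule, rng=rng,
                                design_spec=dspec, compute_se=False)
            fit = res.fit
            return (float(fit.theta_hat.beta[b_idx]), fit.usable,
                    ",".join(sorted(fit.flags)))
        else:
            raise ValueError(f"unknown design {design!r}")
        fit = fit_mle(cohort.with_validation(v), spec, compute_se=False)
        return (float(fit.theta_hat.beta[b_idx]), fit.usable,
                ",".join(sorted(fit.flags)))
    except (SearchFailure, MultiwaveFailure, InfeasibleDesignError) as exc:
        return (math.nan, False, type(exc).__name__)


def run_study(scenario: SimScenario, designs: Sequence[str], reps: int,
              seed: int, m: int = 10,
              opt_steps: tuple[int, ...] = (15, 5, 1),
              wave_steps: tuple[int, ...] = (25, 5, 1)) -> StudyResult:
    """Replicate a scenario under several validation designs.

    All designs of a replicate share one cohort (a paired comparison that
    sharpens efficiency ratios); subject draws use named per-replicate
    substreams, shared between a design and its misspecified variant so
    that identical allocations validate identical subjects.  Failed
    searches or unusable fits are flagged per design and counted, never
    silently dropped.
    """
    unknown = set(designs) - set(KNOWN_DESIGNS)
    if unknown:
        raise ValueError(f"unknown designs: {sorted(unknown)}")
    stream = SeedStream(seed)
    opt_schedule = GridSchedule(steps=opt_steps, m=m)
    wave_schedule = GridSchedule(steps=wave_steps, m=m)
    rows = []
    for rep in range(reps):
        cohort = generate_cohort(scenario, stream.child("cohort", rep))
        for design in designs:
            beta_hat, usable, flag = _realize_and_fit(
                cohort, scenario, design, stream, rep,
                opt_schedule, wave_schedule)
            rows.append((rep, design, beta_hat, usable, flag))
    frame = pd.DataFrame(rows, columns=["replicate", "design", "beta_hat",
                                        "usable", "flag"])
    return StudyResult(frame=frame, scenario=scenario, reps=reps,
                       designs=tuple(designs))


def summarize(result: StudyResult, reference: str = "optMLE",
              beta_true: float | None = None) -> pd.DataFrame:
    """Percent bias, empirical SE, and efficiency relative to the reference.

    RE is the ratio of empirical variances (reference over design); RI the
    ratio of interquartile-range widths, with quartiles by linear
    interpolation.  Each design is summarized over its own usable
    replicates; discards are reported alongside.
    """
    if reference not in result.designs:
        raise ValueError(f"reference design {reference!r} not in the study")
    beta_true = result.scenario.beta_true if beta_true is None else beta_true
    ref = result.beta_hats(reference)
    if ref.size < 2:
        raise ValueError("fewer than 2 usable replicates for the reference")
    var_ref = float(np.var(ref, ddof=1))
    q1, q3 = np.percentile(ref, [25, 75])
    iqr_ref = float(q3 - q1)
    out = []
    for design in result.designs:
        b = result.beta_hats(design)
        if b.size < 2:
            raise ValueError(f"fewer than 2 usable replicates for {design!r}")
        var_d = float(np.var(b, ddof=1))
        q1, q3 = np.percentile(b, [25, 75])
        iqr_d = float(q3 - q1)
        out.append({
            "design": design,
            "n_used": int(b.size),
            "n_discarded": int(result.reps - b.size),
            "percent_bias": 100.0 * (float(b.mean()) - beta_true) / beta_true,
            "se_empirical": math.sqrt(var_d),
            "re": var_ref / var_d if var_d > 0 else math.inf,
            "ri": iqr_ref / iqr_d if iqr_d > 0 else math.inf,
        })
    table = pd.DataFrame(out).set_index("design")
    table.attrs["reference"] = reference
    table.attrs["beta_true"] = beta_true
    table.attrs["iqr_convention"] = "linear interpolation"
    return table
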