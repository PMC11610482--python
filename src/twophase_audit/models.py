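"""Parameter containers and logistic model components.

A two-phase validation study observes an error-prone binary outcome ``Y*``
and exposure ``X*`` on everyone (Phase I), plus the true ``(Y, X)`` on a
validated subset (Phase II).  Four logistic regressions describe the joint
law of a complete observation:

* analysis model        ``Pr(Y = 1 | X, Z)``  -- the log OR ``beta`` on X is
  the target of inference;
* outcome-error model   ``Pr(Y* = 1 | X*, Y, X, Z)``;
* exposure-error model  ``Pr(X* = 1 | Y, X, Z)``;
* exposure model        ``Pr(X = 1 | Z)``.

The covariate ``Z`` (optional) is a single categorical variable; its marginal
law is always the empirical Phase I distribution and never modelled
parametrically.  All binary terms use {0, 1} coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "Theta",
    "Stratum",
    "StratumTable",
    "SeedStream",
    "component_prob",
    "joint_mass",
    "derive_error_params",
]

MODEL_NAMES = ("analysis", "outcome_error", "exposure_error", "exposure")

#: variables a linear-predictor term may reference
_BASE_VARS = ("x_star", "y", "x", "z")


def _eval_term(term: str, values: Mapping[str, float]) -> float:
    """Evaluate one linear-predictor term at scalar predictor values.

    Terms: ``"1"`` (intercept), a base variable name, ``"z@k"`` for the
    indicator I(z == k), or interactions joined by ``":"``.
    """
    if term == "1":
        return 1.0
    if ":" in term:
        out = 1.0
        for part in term.split(":"):
            out *= _eval_term(part, values)
        return out
    if term.startswith("z@"):
        if "z" not in values:
            raise ValueError("term 'z@k' requires predictor 'z'")
        return 1.0 if int(values["z"]) == int(term[2:]) else 0.0
    if term in _BASE_VARS:
        if term not in values:
            raise ValueError(f"missing predictor {term!r} for a listed term")
        return float(values[term])
    raise ValueError(f"unknown model term {term!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Term lists for the four component models.

    ``outcome_error=None`` declares the outcome error free (``Y* == Y``);
    ``exposure_error=None`` declares the exposure error free (``X* == X``).
    ``n_z`` is the number of categories of the (flattened) covariate Z;
    ``n_z == 1`` means no covariate.
    """

    analysis: tuple[str, ...] = ("1", "x")
    outcome_error: tuple[str, ...] | None = ("1", "x_star", "y", "x")
    exposure_error: tuple[str, ...] | None = ("1", "y", "x")
    exposure: tuple[str, ...] = ("1",)
    n_z: int = 1

    def __post_init__(self) -> None:
        if "1" not in self.analysis or "x" not in self.analysis:
            raise ValueError("analysis model must contain intercept and x")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.outcome_error is None and self.exposure_error is None:
            raise ValueError("at least one variable must be error-prone")

    @property
    def error_in_y(self) -> bool:
        return self.outcome_error is not None

    @property
    def error_in_x(self) -> bool:
        return self.exposure_error is not None

    def terms(self, which: str) -> tuple[str, ...]:
        t = getattr(self, which)
        if t is None:
            raise ValueError(f"model {which!r} is not part of this spec")
        return t

    @property
    def active_models(self) -> tuple[str, ...]:
        return tuple(m for m in MODEL_NAMES if getattr(self, m) is not None)

    def dims(self) -> dict[str, int]:
        return {m: len(self.terms(m)) for m in self.active_models}

    @property
    def n_params(self) -> int:
        return sum(self.dims().values())

    @property
    def beta_index(self) -> int:
        """Flat-vector index of the exposure log OR (the 'x' analysis term)."""
        return self.analysis.index("x")

    def slices(self) -> dict[str, slice]:
        out, offset = {}, 0
        for m in self.active_models:
            p = len(self.terms(m))
            out[m] = slice(offset, offset + p)
            offset += p
        return out

    def drop_terms(self, which: str, terms: Iterable[str]) -> "ModelSpec":
        """A copy with the given terms removed from one model (e.g., to form
        a main-effects-only design-stage specification)."""
        drop = set(terms)
        kept = tuple(t for t in self.terms(which) if t not in drop)
        return ModelSpec(**{**self.__dict__, which: kept})


@dataclass
class Theta:
    """Full parameter vector theta = (beta, eta).

    ``beta`` holds the analysis-model coefficients (the exposure log OR is
    the scalar entry addressed by ``ModelSpec.beta_index``); ``alpha`` and
    ``gamma`` the outcome- and exposure-misclassification coefficients;
    ``psi`` the Pr(X=1|Z) coefficients.  Vector lengths must match the spec.
    """

    beta: np.ndarray
    alpha: np.ndarray | None
    gamma: np.ndarray | None
    psi: np.ndarray

    _FIELD_FOR = {
        "analysis": "beta",
        "outcome_error": "alpha",
        "exposure_error": "gamma",
        "exposure": "psi",
    }

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "gamma", "psi"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"non-finite coefficient in {name}")

    def coefs(self, which: str) -> np.ndarray:
        v = getattr(self, self._FIELD_FOR[which])
        if v is None:
            raise ValueError(f"no coefficients for inactive model {which!r}")
        return v

    def flatten(self, spec: ModelSpec) -> np.ndarray:
        parts = []
        for m in spec.active_models:
            v = self.coefs(m)
            if len(v) != len(spec.terms(m)):
                raise ValueError(f"coefficient length mismatch for {m!r}")
            parts.append(v)
        return np.concatenate(parts)

    @classmethod
    def from_flat(cls, flat: np.ndarray, spec: ModelSpec) -> "Theta":
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (spec.n_params,):
            raise ValueError("flat vector length does not match spec")
        sl = spec.slices()
        kw = {"beta": None, "alpha": None, "gamma": None, "psi": None}
        for m, s in sl.items():
            kw[cls._FIELD_FOR[m]] = flat[s].copy()
        return cls(**kw)

    @classmethod
    def from_terms(cls, spec: ModelSpec,
                   coef_maps: Mapping[str, Mapping[str, float]]) -> "Theta":
        """Build from per-model {term: coefficient} mappings (unlisted terms
        default to zero), so files and configs are order-independent."""
        kw = {"beta": None, "alpha": None, "gamma": None, "psi": None}
        for m in spec.active_models:
            cmap = dict(coef_maps.get(m, {}))
            unknown = set(cmap) - set(spec.terms(m))
            if unknown:
                raise ValueError(f"coefficients for unknown {m} terms: {unknown}")
            kw[cls._FIELD_FOR[m]] = np.array(
                [float(cmap.get(t, 0.0)) for t in spec.terms(m)])
        return cls(**kw)

    def to_terms(self, spec: ModelSpec) -> dict[str, dict[str, float]]:
        return {m: {t: float(c) for t, c in zip(spec.terms(m), self.coefs(m))}
                for m in spec.active_models}

    def restrict(self, spec: ModelSpec, sub: ModelSpec) -> "Theta":
        """Project onto a sub-specification by dropping coefficients whose
        terms the sub-spec omits (used for main-effects-only design stages)."""
        maps = self.to_terms(spec)
        out = {}
        for m in sub.active_models:
            have = maps.get(m, {})
            missing = set(sub.terms(m)) - set(have)
            if missing:
                raise ValueError(f"sub-spec has terms absent from source: {missing}")
            out[m] = {t: have[t] for t in sub.terms(m)}
        return Theta.from_terms(sub, out)


def _linear_predictor(theta: Theta, spec: ModelSpec, which: str,
                      predictors: Mapping[str, float]) -> float:
    coefs = theta.coefs(which)
    return float(sum(c * _eval_term(t, predictors)
                     for t, c in zip(spec.terms(which), coefs)))


def component_prob(theta: Theta, spec: ModelSpec, which: str, response: int,
                   **predictors: float) -> float:
    """Probability of ``response`` (0 or 1) under one component model.

    ``which`` is one of ``analysis``, ``outcome_error``, ``exposure_error``
    or ``exposure``; ``predictors`` must supply every variable the spec's
    term list references.
    """
    if which not in MODEL_NAMES:
        raise ValueError(f"unknown model {which!r}")
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    p1 = float(expit(_linear_predictor(theta, spec, which, predictors)))
    return p1 if response == 1 else 1.0 - p1


def joint_mass(theta: Theta, spec: ModelSpec, y_star: int, x_star: int,
               y: int, x: int, z: int = 0,
               z_dist: Sequence[float] | None = None) -> float:
    """Joint probability Pr(y*, x*, y, x, z) under the component models.

    Pr(z) comes from the empirical ``z_dist`` (1 when there is no covariate).
    When a variable is declared error free the corresponding star value must
    equal the true value, otherwise the mass is zero.
    """
    p = 1.0
    if spec.error_in_y:
        p *= component_prob(theta, spec, "outcome_error", y_star,
                            x_star=x_star, y=y, x=x, z=z)
    elif y_star != y:
        return 0.0
    if spec.error_in_x:
        p *= component_prob(theta, spec, "exposure_error", x_star,
                            y=y, x=x, z=z)
    elif x_star != x:
        return 0.0
    p *= component_prob(theta, spec, "analysis", y, x=x, z=z)
    p *= component_prob(theta, spec, "exposure", x, z=z)
    if spec.n_z > 1:
        if z_dist is None:
            raise ValueError("z_dist required when the spec has a covariate")
        p *= float(z_dist[z])
    elif z_dist is not None:
        p *= float(z_dist[z])
    return p


def derive_error_params(fpr_baseline: float, tpr_baseline: float) -> tuple[float, float]:
    """Intercept and true-variable slope matching baseline error rates.

    For a surrogate S of a true binary variable T (all other conditioning
    variables at their reference level 0), a logistic model
    ``Pr(S=1|T, ...) = expit(c0 + c1*T + ...)`` has baseline false positive
    rate ``fpr = expit(c0)`` and true positive rate ``tpr = expit(c0 + c1)``,
    so ``c0 = logit(fpr)`` and ``c1 = logit(tpr) - logit(fpr)``.  The same
    formulas serve the exposure pair (gamma0, gamma-on-X) and the outcome
    pair (alpha0, alpha-on-Y).
    """
    for r in (fpr_baseline, tpr_baseline):
        if not 0.0 < r < 1.0:
            raise ValueError("error rates at 0 or 1 give infinite coefficients")
    c0 = math.log(fpr_baseline / (1.0 - fpr_baseline))
    c1 = math.log(tpr_baseline / (1.0 - tpr_baseline)) - c0
    return c0, c1


# ---------------------------------------------------------------------------
# Sampling strata


class Stratum(tuple):
    """Phase I sampling stratum key (y_star, x_star, z)."""

    __slots__ = ()

    def __new__(cls, y_star: int, x_star: int, z: int = 0):
        if y_star not in (0, 1) or x_star not in (0, 1) or z < 0:
            raise ValueError("invalid stratum key")
        return super().__new__(cls, (int(y_star), int(x_star), int(z)))

    @property
    def y_star(self) -> int:
        return self[0]

    @property
    def x_star(self) -> int:
        return self[1]

    @property
    def z(self) -> int:
        return self[2]

    def label(self) -> str:
        return f"{self[0]}:{self[1]}:{self[2]}"

    @classmethod
    def from_label(cls, label: str) -> "Stratum":
        a, b, c = label.split(":")
        return cls(int(a), int(b), int(c))


@dataclass
class StratumTable:
    """Phase I stratum counts ``N_{y*x*z}`` and the empirical Z distribution.

    Keys are held in lexicographic (y_star, x_star, z) order; every
    combination appears, possibly with a zero count.
    """

    counts: np.ndarray  # aligned with keys
    n_z: int = 1
    keys: tuple[Stratum, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.keys = tuple(Stratum(ys, xs, z)
                          for ys in (0, 1) for xs in (0, 1)
                          for z in range(self.n_z))
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.keys),):
            raise ValueError("counts length must be 4 * n_z")
        if np.any(c < 0):
            raise ValueError("negative stratum count")
        self.counts = c

    @classmethod
    def from_mapping(cls, mapping: Mapping[Stratum, int], n_z: int | None = None) -> "StratumTable":
        if n_z is None:
            n_z = max(k[2] for k in mapping) + 1
        table = cls(np.zeros(4 * n_z, dtype=np.int64), n_z)
        counts = table.counts.copy()
        index = {k: i for i, k in enumerate(table.keys)}
        for k, v in mapping.items():
            counts[index[Stratum(*k)]] = int(v)
        table.counts = counts
        return table

    @classmethod
    def from_arrays(cls, y_star: np.ndarray, x_star: np.ndarray,
                    z: np.ndarray | None = None, n_z: int | None = None) -> "StratumTable":
        y_star = np.asarray(y_star)
        x_star = np.asarray(x_star)
        z = np.zeros_like(y_star) if z is None else np.asarray(z)
        if n_z is None:
            n_z = int(z.max()) + 1 if z.size else 1
        flat = (y_star * 2 + x_star) * n_z + z
        counts = np.bincount(flat, minlength=4 * n_z)
        return cls(counts.astype(np.int64), n_z)

    def index(self, stratum: Stratum) -> int:
        return self.keys.index(Stratum(*stratum))

    def __getitem__(self, stratum) -> int:
        return int(self.counts[self.index(stratum)])

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def K(self) -> int:
        """Number of nonempty sampling strata."""
        return int(np.count_nonzero(self.counts))

    @property
    def z_dist(self) -> np.ndarray:
        """Empirical Pr(Z = z) from the Phase I margins."""
        per_z = self.counts.reshape(2, 2, self.n_z).sum(axis=(0, 1))
        total = per_z.sum()
        if total == 0:
            raise ValueError("empty stratum table")
        return per_z / total

    def as_mapping(self) -> dict[Stratum, int]:
        return {k: int(c) for k, c in zip(self.keys, self.counts)}


# ---------------------------------------------------------------------------
# Reproducible randomness


@dataclass(frozen=True)
class SeedStream:
    """Named, collision-free substreams derived from one master seed.

    ``child(*path)`` returns a fresh ``numpy.random.Generator`` whose state
    is a pure function of the master seed and the integer path, so
    per-replicate / per-wave draws are reproducible and never collide.
    """

    seed: int

    _SALT = {"cohort": 1, "srs": 2, "cc": 3, "strat": 4, "mw2": 5, "mw3": 6,
             "wave": 7, "misc": 8}

    def child(self, *path: int | str) -> np.random.Generator:
        ints = tuple(self._SALT[p] if isinstance(p, str) else int(p) for p in path)
        return np.random.default_rng(np.random.SeedSequence((int(self.seed),) + ints))
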