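"""Vectorized evaluation grid over the discrete (Y*, X*, Y, X, Z) cells.

With binary outcome/exposure and a categorical covariate, every likelihood,
score and information quantity is a finite sum over at most ``16 * n_z``
complete-data cells.  ``CellGrid`` pre-builds, once per model spec, the
design-matrix rows and responses of each component model on that cell grid;
fitting and design evaluation then reduce to small dense linear algebra
regardless of the cohort size.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import expit

from .models import ModelSpec, Theta

__all__ = ["CellGrid", "cell_grid"]


def _term_column(term: str, cols: dict[str, np.ndarray]) -> np.ndarray:
    if term == "1":
        return np.ones_like(cols["y"], dtype=float)
    if ":" in term:
        out = np.ones_like(cols["y"], dtype=float)
        for part in term.split(":"):
            out = out * _term_column(part, cols)
        return out
    if term.startswith("z@"):
        return (cols["z"] == int(term[2:])).astype(float)
    if term in cols:
        return cols[term].astype(float)
    raise ValueError(f"unknown model term {term!r}")


class CellGrid:
    """Precomputed complete-data cell grid for one :class:`ModelSpec`.

    Cells enumerate (y_star, x_star, y, x, z); when an error model is absent
    the corresponding star variable is pinned to its true value.  Cells are
    ordered so that all cells of a sampling stratum (y_star, x_star, z) are
    contiguous, strata following the lexicographic key order used by
    :class:`~twophase_audit.models.StratumTable`.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        n_z = spec.n_z
        rows = []
        for ys in (0, 1):
            for xs in (0, 1):
                for z in range(n_z):
                    y_vals = (0, 1) if spec.error_in_y else (ys,)
                    x_vals = (0, 1) if spec.error_in_x else (xs,)
                    for y in y_vals:
                        for x in x_vals:
                            rows.append((ys, xs, y, x, z))
        arr = np.array(rows, dtype=np.int64)
        self.y_star, self.x_star, self.y, self.x, self.z = arr.T
        self.n_cells = len(rows)
        self.stratum_id = (self.y_star * 2 + self.x_star) * n_z + self.z
        self.n_strata = 4 * n_z
        # latent cells per stratum (contiguous, equal-sized blocks)
        self.cells_per_stratum = self.n_cells // self.n_strata

        cols = {"x_star": self.x_star, "y": self.y, "x": self.x, "z": self.z}
        self._X: dict[str, np.ndarray] = {}
        self._resp: dict[str, np.ndarray] = {}
        responses = {"analysis": self.y, "outcome_error": self.y_star,
                     "exposure_error": self.x_star, "exposure": self.x}
        for m in spec.active_models:
            self._X[m] = np.column_stack(
                [_term_column(t, cols) for t in spec.terms(m)])
            self._resp[m] = responses[m].astype(float)
        self.slices = spec.slices()
        self.n_params = spec.n_params

        # dense lookup (y*, x*, y, x, z) -> cell index (-1 where impossible)
        lut = -np.ones((2, 2, 2, 2, n_z), dtype=np.int64)
        lut[self.y_star, self.x_star, self.y, self.x, self.z] = np.arange(self.n_cells)
        self._lut = lut

    def design(self, which: str) -> np.ndarray:
        return self._X[which]

    def response(self, which: str) -> np.ndarray:
        return self._resp[which]

    def cell_index(self, y_star, x_star, y, x, z) -> np.ndarray:
        return self._lut[y_star, x_star, y, x, z]

    # -- evaluation --------------------------------------------------------

    def log_mass(self, flat: np.ndarray) -> np.ndarray:
        """Per-cell log Pr(y*, x*, y, x | z) (the empirical Pr(z) excluded)."""
        lp = np.zeros(self.n_cells)
        with np.errstate(invalid="ignore", over="ignore"):
            for m, sl in self.slices.items():
                eta = self._X[m] @ flat[sl]
                lp += self._resp[m] * eta - np.logaddexp(0.0, eta)
        return lp

    def log_mass_batch(self, flats: np.ndarray) -> np.ndarray:
        """Per-cell log mass for a batch of parameter vectors, (n, n_cells).

        One matmul per component model amortizes call overhead over the
        batch; numeric-Hessian evaluation depends on this being cheap.
        """
        flats = np.atleast_2d(flats)
        lp = np.zeros((flats.shape[0], self.n_cells))
        with np.errstate(invalid="ignore", over="ignore"):
            for m, sl in self.slices.items():
                eta = flats[:, sl] @ self._X[m].T
                lp += self._resp[m] * eta - np.logaddexp(0.0, eta)
        return lp

    def masses(self, flat: np.ndarray, z_dist: np.ndarray | None = None) -> np.ndarray:
        """Per-cell joint mass, with Pr(z) from ``z_dist`` when given."""
        mass = np.exp(self.log_mass(flat))
        if z_dist is not None:
            mass = mass * np.asarray(z_dist)[self.z]
        return mass

    def scores_validated(self, flat: np.ndarray) -> np.ndarray:
        """Per-cell score of a validated subject, S_v (n_cells, n_params).

        Each logistic block contributes (response - fitted prob) times its
        design row; the empirical Pr(z) carries no parameters.
        """
        S = np.empty((self.n_cells, self.n_params))
        for m, sl in self.slices.items():
            eta = self._X[m] @ flat[sl]
            resid = self._resp[m] - expit(eta)
            S[:, sl] = resid[:, None] * self._X[m]
        return S

    def stratum_mass(self, mass: np.ndarray) -> np.ndarray:
        return np.bincount(self.stratum_id, weights=mass,
                           minlength=self.n_strata)

    def scores_unvalidated(self, flat: np.ndarray,
                           mass: np.ndarray | None = None) -> np.ndarray:
        """Per-stratum score of an unvalidated subject, S_vbar (n_strata, p):
        the mass-weighted average of S_v over the latent (y, x) cells."""
        if mass is None:
            mass = self.masses(flat)
        S = self.scores_validated(flat)
        num = np.zeros((self.n_strata, self.n_params))
        np.add.at(num, self.stratum_id, mass[:, None] * S)
        denom = self.stratum_mass(mass)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / denom[:, None]
        out[denom == 0] = 0.0
        return out

    def posterior(self, flat: np.ndarray) -> np.ndarray:
        """Per-cell posterior weight Pr(y, x | y*, x*, z) within each stratum."""
        mass = self.masses(flat)
        denom = self.stratum_mass(mass)[self.stratum_id]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = mass / denom
        w[~np.isfinite(w)] = 0.0
        return w

    def flatten(self, theta: Theta) -> np.ndarray:
        return theta.flatten(self.spec)


@lru_cache(maxsize=64)
def cell_grid(spec: ModelSpec) -> CellGrid:
    """Cached :class:`CellGrid` for a spec (specs are frozen, hence hashable)."""
    return CellGrid(spec)
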