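"""File formats: cohort CSV, stratum-count CSV, theta/spec YAML, design JSON.

Cohort files are delimited text with columns ``id, y_star, x_star, z, v, y,
x`` (``z`` optional and repeatable -- multiple z columns are crossed into a
single categorical axis; ``y``/``x`` empty for unvalidated rows).  Model
files label coefficients by term so they are order-independent.  JSON output
keeps full float precision so artifacts survive round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import Design
from .likelihood import Cohort
from .models import ModelSpec, Stratum, StratumTable, Theta

__all__ = [
    "read_cohort", "write_cohort",
    "read_strata", "write_strata",
    "read_spec", "write_spec",
    "read_theta", "write_theta",
    "read_design", "write_design",
    "write_json",
]


class CohortFormatError(ValueError):
    """Malformed cohort file; message names the offending row."""


def _z_columns(columns) -> list[str]:
    return [c for c in columns if c == "z" or
            (c.startswith("z") and c[1:].isdigit())]


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV, validating domains row by row.

    Unvalidated rows must leave ``y`` and ``x`` empty; multiple z columns
    are crossed into one categorical variable with categories labelled in
    first-seen order.
    """
    df = pd.read_csv(path, dtype="object")
    required = {"y_star", "x_star", "v"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"missing required columns: {sorted(missing)}")
    zcols = _z_columns(df.columns)

    def as_binary(col: str, series: pd.Series) -> np.ndarray:
        vals = pd.to_numeric(series, errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortFormatError(f"row {row}: non-binary value in {col!r}")
        return vals.to_numpy(dtype=np.int8)

    y_star = as_binary("y_star", df["y_star"])
    x_star = as_binary("x_star", df["x_star"])
    v = as_binary("v", df["v"])

    n = len(df)
    y = np.full(n, -1, dtype=np.int8)
    x = np.full(n, -1, dtype=np.int8)
    for col, arr in (("y", y), ("x", x)):
        series = df[col] if col in df.columns else pd.Series([None] * n)
        vals = pd.to_numeric(series, errors="coerce")
        present = vals.notna().to_numpy()
        bad_domain = present & ~vals.isin([0, 1]).to_numpy()
        if bad_domain.any():
            row = int(np.flatnonzero(bad_domain)[0])
            raise CohortFormatError(f"row {row}: non-binary value in {col!r}")
        need = v == 1
        if np.any(need & ~present):
            row = int(np.flatnonzero(need & ~present)[0])
            raise CohortFormatError(f"row {row}: validated row missing {col!r}")
        if np.any(~need & present):
            row = int(np.flatnonzero(~need & present)[0])
            raise CohortFormatError(f"row {row}: unvalidated row carries {col!r}")
        arr[present] = vals[present].astype(np.int8)

    if zcols:
        zvals = df[zcols].astype(str).agg("|".join, axis=1)
        seen: dict[str, int] = {}
        codes = np.empty(n, dtype=np.int16)
        for i, label in enumerate(zvals):
            codes[i] = seen.setdefault(label, len(seen))
        z = codes
        n_z = len(seen)
    else:
        z, n_z = None, 1
    return Cohort(y_star, x_star, z, v, y, x, n_z=n_z)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV; y/x of unvalidated rows are blanked (the file
    view never exposes unvalidated truth)."""
    val = cohort.v == 1
    df = pd.DataFrame({
        "id": np.arange(len(cohort)),
        "y_star": cohort.y_star,
        "x_star": cohort.x_star,
        "z": cohort.z,
        "v": cohort.v,
        "y": pd.array(np.where(val, cohort.y, -1)).astype("object"),
        "x": pd.array(np.where(val, cohort.x, -1)).astype("object"),
    })
    df.loc[~val, ["y", "x"]] = ""
    df.to_csv(path, index=False)


def read_strata(path: str | Path) -> StratumTable:
    df = pd.read_csv(path)
    for col in ("y_star", "x_star", "count"):
        if col not in df.columns:
            raise ValueError(f"stratum file missing column {col!r}")
    z = df["z"].astype(int) if "z" in df.columns else pd.Series(0, index=df.index)
    mapping = {Stratum(int(r["y_star"]), int(r["x_star"]), int(zv)): int(r["count"])
               for (_, r), zv in zip(df.iterrows(), z)}
    return StratumTable.from_mapping(mapping)


def write_strata(strata: StratumTable, path: str | Path) -> None:
    rows = [{"y_star": k.y_star, "x_star": k.x_star, "z": k.z, "count": int(c)}
            for k, c in zip(strata.keys, strata.counts)]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- model spec / theta ------------------------------------------------------


def _spec_from_payload(payload: Mapping) -> ModelSpec:
    models = payload["models"]
    def terms(name):
        t = models.get(name)
        return None if t is None else tuple(t)
    return ModelSpec(
        analysis=terms("analysis"),
        outcome_error=terms("outcome_error"),
        exposure_error=terms("exposure_error"),
        exposure=terms("exposure"),
        n_z=int(payload.get("n_z", 1)))


def read_spec(path: str | Path) -> ModelSpec:
    """Spec YAML: ``n_z`` plus per-model term lists."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _spec_from_payload(payload)


def write_spec(spec: ModelSpec, path: str | Path) -> None:
    payload = {"n_z": spec.n_z,
               "models": {m: list(spec.terms(m)) for m in spec.active_models}}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_theta(path: str | Path) -> tuple[Theta, ModelSpec]:
    """Theta YAML: ``n_z`` plus per-model {term: coefficient} maps; term
    order in the file fixes the spec's term order."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    models = payload["models"]
    spec = _spec_from_payload({
        "n_z": payload.get("n_z", 1),
        "models": {m: (None if cm is None else list(cm))
                   for m, cm in models.items()}})
    theta = Theta.from_terms(spec, {m: cm for m, cm in models.items()
                                    if cm is not None})
    return theta, spec


def write_theta(theta: Theta, spec: ModelSpec, path: str | Path) -> None:
    payload = {"n_z": spec.n_z, "models": theta.to_terms(spec)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# -- designs and generic JSON ------------------------------------------------


def write_json(payload, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


def write_design(design: Design, path: str | Path) -> None:
    write_json(design.to_dict(), path)


def read_design(path: str | Path) -> Design:
    payload = json.loads(Path(path).read_text())
    strata = StratumTable.from_mapping(
        {Stratum.from_label(k): v for k, v in payload["phase1"].items()})
    alloc = np.zeros_like(strata.counts)
    for label, count in payload["strata"].items():
        alloc[strata.index(Stratum.from_label(label))] = int(count)
    return Design(strata, alloc, provenance=payload.get("provenance", {}))
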