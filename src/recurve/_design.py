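"""Design-matrix construction shared by the regression and simulation code.

Encoding: binary covariates enter as 0/1; categorical covariates expand to
reference-coded dummy columns named ``name:level`` (first schema level is the
reference); continuous covariates enter as-is.  The intercept column, when
requested, is named ``intercept``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import BINARY, CATEGORICAL, CovariateSchema, ValidationError

INTERCEPT = "intercept"


def design_columns(schema: CovariateSchema, names: Sequence[str], intercept: bool = False) -> list[str]:
    """Column names of the design matrix for the given covariates."""
    cols = [INTERCEPT] if intercept else []
    for name in names:
        spec = schema[name]
        if spec.kind == CATEGORICAL:
            cols.extend(f"{name}:{lvl}" for lvl in spec.levels[1:])
        else:
            cols.append(name)
    return cols


def build_design(
    frame: pd.DataFrame,
    schema: CovariateSchema,
    names: Sequence[str],
    intercept: bool = False,
) -> pd.DataFrame:
    """Expand covariate columns of ``frame`` into a numeric design matrix."""
    for name in names:
        if name not in schema:
            raise ValidationError(f"unknown covariate {name!r}")
        if name not in frame.columns:
            raise ValidationError(f"covariate {name!r} missing from data")
    out: dict[str, np.ndarray] = {}
    n = len(frame)
    if intercept:
        out[INTERCEPT] = np.ones(n)
    for name in names:
        spec = schema[name]
        col = frame[name]
        if spec.kind == CATEGORICAL:
            vals = col.astype(str)
            bad = set(vals.unique()) - set(spec.levels)
            if bad:
                raise ValidationError(f"unknown level(s) {sorted(bad)} for covariate {name!r}")
            for lvl in spec.levels[1:]:
                out[f"{name}:{lvl}"] = (vals == lvl).to_numpy(dtype=float)
        elif spec.kind == BINARY:
            out[name] = col.to_numpy(dtype=float)
        else:
            out[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(out, index=frame.index)


def row_design(
    x: Mapping[str, object],
    schema: CovariateSchema,
    columns: Sequence[str],
) -> np.ndarray:
    """Design vector for a single covariate mapping, ordered like ``columns``."""
    vec = np.zeros(len(columns))
    for j, col in enumerate(columns):
        if col == INTERCEPT:
            vec[j] = 1.0
        elif ":" in col:
            name, lvl = col.split(":", 1)
            if name not in x:
                raise ValidationError(f"covariate {name!r} missing from prediction input")
            val = str(x[name])
            if val not in schema[name].levels:
                raise ValidationError(f"unknown level {val!r} for covariate {name!r}")
            vec[j] = 1.0 if val == lvl else 0.0
        else:
            if col not in x:
                raise ValidationError(f"covariate {col!r} missing from prediction input")
            vec[j] = float(x[col])  # type: ignore[arg-type]
    return vec


def linear_predictor(design: pd.DataFrame, beta: Mapping[str, float]) -> np.ndarray:
    """``X @ beta`` with beta given as a name -> coefficient map.

    Design columns without a coefficient contribute 0; coefficient names
    without a design column are an error.
    """
    missing = set(beta) - set(design.columns)
    if missing:
        raise ValidationError(f"coefficients for unknown design columns: {sorted(missing)}")
    eta = np.zeros(len(design))
    for name, b in beta.items():
        eta += b * design[name].to_numpy()
    return eta
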