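"""Design specification and matrix construction for the regression suite.

Covariates come in three kinds: ``continuous`` (optionally standardized
as (x - mean) / (2 SD), which puts binary and continuous predictors on
a comparable scale), ``binary`` (0/1 as given), and ``dummy_set``
(categorical expanded to indicators, omitting a stated reference
level).  Winter-range dummies default to NM as reference and mtDNA
haplogroup to haplogroup 1, matching the reporting convention of the
source tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Standardized", "standardize", "Covariate", "DesignSpec", "build_design"]


@dataclass
class Standardized:
    """Standardized values plus the centering constants for inversion."""

    values: np.ndarray
    mean: float
    sd: float

    def inverse(self, z: Optional[np.ndarray] = None) -> np.ndarray:
        if z is None:
            z = self.values
        return np.asarray(z) * (2.0 * self.sd) + self.mean


def standardize(values) -> Standardized:
    """(x - mean) / (2 SD); SD uses the population (n) denominator, so two
    points {2, 6} map to {-0.5, +0.5}."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot standardize a constant vector")
    m = float(x.mean())
    sd = float(x.std(ddof=0))
    return Standardized((x - m) / (2.0 * sd), m, sd)


@dataclass
class Covariate:
    name: str
    kind: str  # {"continuous", "binary", "dummy_set"}
    standardized: bool = False     # continuous only
    degree: int = 1                # continuous only: 2 adds a squared term
    reference: Optional[str] = None  # dummy_set only

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "dummy_set"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass
class DesignSpec:
    """Model layout: response column, covariates, optional random intercept."""

    response: str
    covariates: list[Covariate] = field(default_factory=list)
    random_intercept: Optional[str] = None  # grouping column (individual id)


@dataclass
class Design:
    """Materialized design: X includes a leading intercept column."""

    X: np.ndarray
    names: list[str]
    y: np.ndarray
    group_index: Optional[np.ndarray]  # per-record group code, or None
    group_labels: Optional[list[str]]
    meta: dict = field(default_factory=dict)


def build_design(data: pd.DataFrame, spec: DesignSpec) -> Design:
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    meta: dict = {}
    for cov in spec.covariates:
        if cov.kind == "dummy_set":
            vals = data[cov.name].astype(str)
            levels = sorted(vals.unique())
            ref = cov.reference if cov.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov.name}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{cov.name}[{lev}]")
            meta[cov.name] = {"reference": ref, "levels": levels}
        elif cov.kind == "binary":
            cols.append(data[cov.name].to_numpy(float))
            names.append(cov.name)
        else:
            x = data[cov.name].to_numpy(float)
            if cov.standardized:
                st = standardize(x)
                x = st.values
                meta[cov.name] = {"mean": st.mean, "sd": st.sd}
            cols.append(x)
            names.append(cov.name if not cov.standardized else f"{cov.name}_std")
            if cov.degree == 2:
                cols.append(x**2)
                names.append((cov.name if not cov.standardized else f"{cov.name}_std") + "^2")
    X = np.column_stack(cols)
    y = data[spec.response].to_numpy(float)
    group_index = None
    group_labels = None
    if spec.random_intercept is not None:
        gvals = data[spec.random_intercept].astype(str)
        group_labels = sorted(gvals.unique())
        lut = {g: i for i, g in enumerate(group_labels)}
        group_index = gvals.map(lut).to_numpy(int)
    return Design(X, names, y, group_index, group_labels, meta)
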