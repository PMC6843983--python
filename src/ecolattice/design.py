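"""Regression design construction: quantile categories, land-use recode, dummies.

Topographic and proximity covariates enter the species-count model as
quantile categories (quintiles by default, quartiles for aspect) with the
first category as the reference; land use enters as an 8-level categorical
with "other" (urban, beaches, bare rock, water, ...) as the reference.
Temperature-variation covariates stay continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, RecodeError, ValidationError

__all__ = [
    "LANDUSE8",
    "DEFAULT_LANDUSE_MAPPING",
    "CategorizationScheme",
    "quantile_categorize",
    "apply_scheme",
    "recode_landuse",
    "default_schemes",
    "build_design",
]

#: The 8 land-use classes; the first is the reference category.
LANDUSE8 = (
    "other",
    "coniferous_forest",
    "dense_forest",
    "fruit_trees",
    "artificial_vegetated",
    "transitional_scrub",
    "natural_grassland",
    "mixed_forest",
)

#: Default recode of a 22-class land-cover product into the 8 model classes.
#: Raw codes are integers 1..22; override via a mapping file for other
#: cover products.
DEFAULT_LANDUSE_MAPPING: dict[int, str] = {
    1: "other",  # urban fabric
    2: "other",  # industrial / infrastructure
    3: "other",  # beaches and dunes
    4: "other",  # bare rock
    5: "other",  # burnt areas
    6: "other",  # water bodies
    7: "coniferous_forest",
    8: "coniferous_forest",  # open coniferous
    9: "dense_forest",  # broadleaf, canopy >= 40%
    10: "dense_forest",
    11: "fruit_trees",
    12: "fruit_trees",  # berries
    13: "artificial_vegetated",  # urban green / sport areas
    14: "artificial_vegetated",
    15: "transitional_scrub",
    16: "transitional_scrub",
    17: "natural_grassland",
    18: "natural_grassland",  # alpine meadow
    19: "mixed_forest",
    20: "mixed_forest",  # riparian mixed stands
    21: "other",  # arable (grouped: not a named target class)
    22: "other",  # vineyards (grouped)
}

#: Default quantile setup: quintiles everywhere except aspect (quartiles).
QUINTILE_VARIABLES = (
    "slope",
    "hillshade",
    "elevation",
    "dist_urban",
    "dist_road",
    "dist_rail",
)


@dataclass(frozen=True)
class CategorizationScheme:
    """Stored quantile cuts for one variable.

    ``boundaries`` holds the k-1 interior cut points (ascending). Intervals
    are right-closed — a value equal to a boundary falls in the lower
    category — and the first interval is unbounded below, so every value is
    assigned. Category 1 is the reference.
    """

    variable: str
    k: int
    boundaries: tuple[float, ...]
    reference: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DegenerateInputError("need at least 2 categories")
        b = np.asarray(self.boundaries)
        if len(b) != self.k - 1 or np.any(np.diff(b) <= 0):
            raise DegenerateInputError(
                f"{self.variable}: boundaries must be {self.k - 1} strictly "
                "increasing cut points"
            )


def quantile_categorize(
    values, k: int, variable: str = "x"
) -> tuple[np.ndarray, CategorizationScheme]:
    """Assign empirical k-quantile categories 1..k and return the scheme.

    Cut points are the maxima of the k (near-)equal-size slices of the
    sorted data, so with distinct values the category sizes differ by at
    most one from n/k.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < k:
        raise DegenerateInputError(f"{variable}: need >= {k} values")
    if len(np.unique(v)) < k:
        raise DegenerateInputError(
            f"{variable}: fewer than {k} distinct values; cannot form {k} quantile groups"
        )
    order = np.sort(v)
    slices = np.array_split(order, k)
    boundaries = tuple(float(s[-1]) for s in slices[:-1])
    if np.any(np.diff(boundaries) <= 0):
        raise DegenerateInputError(
            f"{variable}: ties collapse quantile boundaries; reduce k"
        )
    scheme = CategorizationScheme(variable=variable, k=k, boundaries=boundaries)
    return apply_scheme(v, scheme), scheme


def apply_scheme(values, scheme: CategorizationScheme) -> np.ndarray:
    """Re-categorize with stored boundaries (right-closed intervals)."""
    v = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(scheme.boundaries), v, side="left") + 1


def recode_landuse(raw_code, mapping: dict | None = None) -> str:
    """Map a raw land-cover code to one of the 8 model classes."""
    mapping = DEFAULT_LANDUSE_MAPPING if mapping is None else mapping
    if raw_code not in mapping:
        raise RecodeError(f"land-use code {raw_code!r} has no recode entry")
    target = mapping[raw_code]
    if target not in LANDUSE8:
        raise RecodeError(
            f"mapping sends {raw_code!r} to unknown class {target!r}; "
            f"expected one of {LANDUSE8}"
        )
    return target


def default_schemes(
    cells: pd.DataFrame,
    quintile_vars=QUINTILE_VARIABLES,
    quartile_vars=("aspect",),
) -> list[CategorizationScheme]:
    """Fit the default quantile schemes on the cell table."""
    schemes = []
    for var in quintile_vars:
        _, s = quantile_categorize(cells[var].to_numpy(), 5, var)
        schemes.append(s)
    for var in quartile_vars:
        _, s = quantile_categorize(cells[var].to_numpy(), 4, var)
        schemes.append(s)
    return schemes


def build_design(
    cells: pd.DataFrame,
    schemes: list[CategorizationScheme],
    landuse_col: str | None = "landuse8",
    continuous: tuple[str, ...] = (),
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix: intercept, category dummies, continuous.

    Column count is 1 + sum_v (k_v - 1) + (len(LANDUSE8) - 1 if land use
    used) + len(continuous). Dummy columns are labelled ``var_q<j>`` for
    quantile category j (j >= 2) and ``landuse8[<class>]`` for non-reference
    land-use classes.
    """
    n = len(cells)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["intercept"]
    for scheme in schemes:
        cats = apply_scheme(cells[scheme.variable].to_numpy(), scheme)
        for j in range(1, scheme.k + 1):
            if j == scheme.reference:
                continue
            cols.append((cats == j).astype(float))
            labels.append(f"{scheme.variable}_q{j}")
    if landuse_col is not None:
        lu = cells[landuse_col].to_numpy()
        unknown = set(lu) - set(LANDUSE8)
        if unknown:
            raise ValidationError(f"unknown land-use labels: {sorted(unknown)}")
        for cls in LANDUSE8[1:]:
            cols.append((lu == cls).astype(float))
            labels.append(f"landuse8[{cls}]")
    for var in continuous:
        vals = cells[var].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValidationError(f"continuous covariate {var} has non-finite values")
        cols.append(vals)
        labels.append(var)
    return np.column_stack(cols), labels
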