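"""Population migration indices: transwell percentages, within-donor relative
migration, and the in vivo homing index.

The homing index compares two co-injected, differently dyed cell populations:
HI = (% far-red in tissue / % violet in tissue) / (% far-red in input /
% violet in input).  HI = 1 means both populations reached the tissue in
proportion to the injected mixture; HI > 1 means the far-red–labeled
population homed better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "MigrationResult",
    "HomingIndex",
    "percent_migrated",
    "relative_migration",
    "relative_migration_by_donor",
    "homing_index",
]


@dataclass
class MigrationResult:
    label: str
    percent_migrated: float
    relative_migration: float | None = None


@dataclass
class HomingIndex:
    value: float
    pct_farred_tissue: float
    pct_violet_tissue: float
    pct_farred_input: float
    pct_violet_input: float


def percent_migrated(n_migrated: float, n_input: float) -> float:
    """Percentage of specific migration: 100 · migrated / input.

    Raises :class:`DataError` for nonpositive input or migrated > input
    (inconsistent counts).
    """
    if n_input <= 0:
        raise DataError("n_input must be > 0")
    if n_migrated < 0:
        raise DataError("n_migrated must be >= 0")
    if n_migrated > n_input:
        raise DataError(f"inconsistent counts: {n_migrated} migrated of {n_input} input")
    return 100.0 * n_migrated / n_input


def relative_migration(treatment_pct: float, reference_pct: float) -> float:
    """Treatment migration as a percentage of a reference condition."""
    if reference_pct <= 0:
        raise DataError("reference percentage must be > 0")
    if treatment_pct < 0:
        raise DataError("treatment percentage must be >= 0")
    return 100.0 * treatment_pct / reference_pct


def relative_migration_by_donor(
    df: pd.DataFrame, reference_label: str,
    label_col: str = "label", donor_col: str = "donor", pct_col: str = "percent_migrated",
) -> pd.DataFrame:
    """Normalize each treatment to the reference condition within each donor.

    Normalization happens inside every donor before any averaging — donors
    differ in baseline motility, and pooled normalization would mix that
    variation into the treatment effect.  Returns the input rows plus a
    ``relative_migration`` column (reference rows read 100).
    """
    out = []
    for donor, sub in df.groupby(donor_col, sort=True):
        ref_rows = sub[sub[label_col] == reference_label]
        if ref_rows.empty:
            raise DataError(f"donor {donor!r}: no reference row {reference_label!r}")
        ref = float(ref_rows[pct_col].mean())
        sub = sub.copy()
        sub["relative_migration"] = [
            relative_migration(v, ref) for v in sub[pct_col].to_numpy(dtype=float)
        ]
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def homing_index(
    pct_farred_tissue: float,
    pct_violet_tissue: float,
    pct_farred_input: float,
    pct_violet_input: float,
) -> HomingIndex:
    """Homing index: (fr_tissue / v_tissue) / (fr_input / v_input).

    Invariant to rescaling the tissue (or input) percentages by a common
    factor, and maps to its reciprocal under a dye swap.  All four inputs
    must be strictly positive.
    """
    vals = (pct_farred_tissue, pct_violet_tissue, pct_farred_input, pct_violet_input)
    if any(not np.isfinite(v) or v <= 0 for v in vals):
        raise DataError("all four percentages must be finite and > 0")
    hi = (pct_farred_tissue / pct_violet_tissue) / (pct_farred_input / pct_violet_input)
    return HomingIndex(hi, *vals)
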