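"""Log2 transformation, per-sample median centering and feature filtering.

Raw linear-scale intensities are log2 transformed, then each sample column is
centred on its median observed value so that global per-run loading and
instrument-response differences cancel.  Peptides entering the peptide-level
differential analysis must be unique to one protein group, must not be decoy
(reversed-sequence) identifications, and must be observed in at least a
configurable fraction of the reference samples — by default half of the
experimental cohort, i.e. at least 5 of 9 samples in a 5-vs-4 design.  For
larger cohorts (n > 60) a 30 % floor is the documented alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PeptideQuantTable, ProteinQuantTable, StudyDesign

__all__ = [
    "LogAbundanceMatrix",
    "FilterCriteria",
    "FilterReport",
    "log2_transform",
    "median_center",
    "filter_peptides",
    "drop_reverse_proteins",
]


@dataclass
class LogAbundanceMatrix:
    """A features × samples matrix of log2 abundances (NaN = missing)."""

    values: pd.DataFrame
    axis_name: str = "feature"
    centered: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def log2_transform(intensity: pd.DataFrame, axis_name: str = "feature") -> LogAbundanceMatrix:
    """Map observed linear intensities to log2; missing stays missing."""
    vals = intensity.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    if np.any(vals[observed] <= 0):
        raise ValueError("log2_transform requires all observed values > 0")
    out = np.full_like(vals, np.nan)
    out[observed] = np.log2(vals[observed])
    return LogAbundanceMatrix(
        values=pd.DataFrame(out, index=intensity.index, columns=intensity.columns),
        axis_name=axis_name,
        centered=False,
    )


def median_center(matrix: LogAbundanceMatrix) -> LogAbundanceMatrix:
    """Subtract each sample column's median observed value (idempotent)."""
    vals = matrix.values
    n_obs = vals.notna().sum(axis=0)
    empty = n_obs[n_obs == 0]
    if len(empty) > 0:
        raise ValueError(
            f"sample(s) with no observed values cannot be centered: {list(empty.index)}"
        )
    centered = vals - vals.median(axis=0, skipna=True)
    return LogAbundanceMatrix(values=centered, axis_name=matrix.axis_name, centered=True)


@dataclass(frozen=True)
class FilterCriteria:
    """Peptide inclusion rules.

    ``min_obs_fraction`` is turned into a count floor of
    ``ceil(min_obs_fraction * n_reference_samples)`` observations; the default
    0.5 reproduces the 5-of-9 rule of a 5-vs-4 experimental cohort.  A value
    of 0 disables the observation criterion.  ``reference_sample_set`` limits
    which samples count toward the threshold; ``None`` means the design's
    experimental samples (or every sample when no design is supplied).
    """

    require_unique: bool = True
    drop_reverse: bool = True
    min_obs_fraction: float = 0.5
    reference_sample_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_obs_fraction <= 1.0):
            raise ValueError("min_obs_fraction must lie in [0, 1]")


@dataclass
class FilterReport:
    """Rows dropped per criterion, in the order the criteria are applied."""

    n_input: int
    dropped_non_unique: int
    dropped_reverse: int
    dropped_low_observation: int
    n_output: int
    min_obs_count: int
    n_reference_samples: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("dropped_non_unique", self.dropped_non_unique),
            ("dropped_reverse", self.dropped_reverse),
            ("dropped_low_observation", self.dropped_low_observation),
            ("output", self.n_output),
        ]
        return pd.DataFrame(rows, columns=["criterion", "rows"]).set_index("criterion")


def filter_peptides(
    peptides: PeptideQuantTable,
    design: StudyDesign | None = None,
    criteria: FilterCriteria | None = None,
) -> tuple[PeptideQuantTable, FilterReport]:
    """Apply the uniqueness / decoy / observation filters in that order."""
    criteria = criteria or FilterCriteria()
    keep = pd.Series(True, index=peptides.peptide_keys)

    dropped_non_unique = 0
    if criteria.require_unique:
        unique = peptides.is_unique
        dropped_non_unique = int((keep & ~unique).sum())
        keep &= unique

    dropped_reverse = 0
    if criteria.drop_reverse:
        fwd = ~peptides.is_reverse
        dropped_reverse = int((keep & ~fwd).sum())
        keep &= fwd

    if criteria.reference_sample_set is not None:
        ref = list(criteria.reference_sample_set)
    elif design is not None:
        ref = design.experimental or design.samples
    else:
        ref = peptides.samples
    missing_ref = [s for s in ref if s not in peptides.samples]
    if missing_ref:
        raise ValueError(f"reference samples {missing_ref} absent from the table")

    threshold = math.ceil(criteria.min_obs_fraction * len(ref))
    dropped_low_observation = 0
    if threshold > 0:
        n_obs = peptides.intensity[ref].notna().sum(axis=1)
        enough = n_obs >= threshold
        dropped_low_observation = int((keep & ~enough).sum())
        keep &= enough

    out = peptides.select(peptides.peptide_keys[keep])
    if len(out.peptide_keys) == 0:
        warnings.warn("all peptides were removed by the filter criteria", stacklevel=2)
    report = FilterReport(
        n_input=len(peptides.peptide_keys),
        dropped_non_unique=dropped_non_unique,
        dropped_reverse=dropped_reverse,
        dropped_low_observation=dropped_low_observation,
        n_output=len(out.peptide_keys),
        min_obs_count=threshold,
        n_reference_samples=len(ref),
    )
    return out, report


def drop_reverse_proteins(proteins: ProteinQuantTable) -> ProteinQuantTable:
    """Remove decoy (reversed-sequence) protein groups."""
    keep = proteins.protein_group_ids[~proteins.is_reverse]
    out = proteins.select(keep)
    if len(keep) == 0:
        warnings.warn("all protein groups are decoys; result is empty", stacklevel=2)
    return out
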