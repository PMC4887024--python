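"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_HIGH = "high"
GROUP_LOW = "low"
VALID_GROUPS = frozenset({GROUP_HIGH, GROUP_LOW})


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class CountMatrix:
    """Protein-by-sample spectral counts plus the sample-to-group map.

    Parameters
    ----------
    counts
        DataFrame with unique protein ids as index and unique sample ids
        as columns.  Integer spectral counts on input; non-negative reals
        after total-count normalization.
    groups
        Series mapping every sample id to ``"high"`` or ``"low"``.
        The comparison throughout the pipeline is always high minus low.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.counts.columns)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.isfinite(vals).all():
            raise ValidationError("counts contain non-finite values")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValidationError(f"samples missing from group map: {missing}")
        bad = set(self.groups.unique()) - VALID_GROUPS
        if bad:
            raise ValidationError(
                f"group labels must be 'high'/'low', got extras: {sorted(bad)}"
            )
        for g in VALID_GROUPS:
            if (self.groups == g).sum() < 1:
                raise ValidationError(f"group {g!r} has no samples")

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def swap_groups(self) -> "CountMatrix":
        """Return a copy with the high/low labels exchanged."""
        swapped = self.groups.map({GROUP_HIGH: GROUP_LOW, GROUP_LOW: GROUP_HIGH})
        return CountMatrix(self.counts.copy(), swapped)
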