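"""Centered log-ratio (clr) machinery for microbiome feature tables.

Relative abundances are stored as fractions of 1 per sample (so 0.01% is
1e-4).  Zeros are handled with a small pseudocount added before the log
and a post-hoc replacement: after the transform, samples in which a
feature was originally absent are pulled down to the minimum transformed
value observed among samples where it was present, so that "absent" is an
equally low value everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

__all__ = ["ClrPolicy", "clr_transform", "prevalence_filter"]

#: default pseudocounts on the fraction scale (0.001% and 0.00001%)
SPECIES_PSEUDOCOUNT = 1e-5
MODULE_PSEUDOCOUNT = 1e-7


@dataclass(frozen=True)
class ClrPolicy:
    """Zero-handling policy for the clr transform.

    pseudocount
        Added to every entry before the log (fraction scale; 1e-5 is
        0.001% relative abundance).
    replacement
        Only ``"min_nonzero_transformed"`` is implemented: originally-zero
        entries are set per feature to the minimum transformed value among
        originally-positive samples.
    """

    pseudocount: float = SPECIES_PSEUDOCOUNT
    replacement: str = "min_nonzero_transformed"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.replacement != "min_nonzero_transformed":
            raise ValueError(f"unknown replacement policy: {self.replacement}")

    @classmethod
    def species(cls) -> "ClrPolicy":
        return cls(pseudocount=SPECIES_PSEUDOCOUNT)

    @classmethod
    def modules(cls) -> "ClrPolicy":
        return cls(pseudocount=MODULE_PSEUDOCOUNT)


def clr_transform(table: pd.DataFrame, policy: ClrPolicy | None = None) -> pd.DataFrame:
    """clr-transform a samples x features relative-abundance table.

    Per sample ``y_f = ln(x_f + pc) - mean_f ln(x_f + pc)``; the zero
    replacement of the policy is then applied per feature.  Features that
    are zero in every sample cannot be placed on the clr scale and are
    returned as NaN columns (callers should have filtered them out).
    """
    if policy is None:
        policy = ClrPolicy.species()
    x = table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise DomainError("relative abundances must be non-negative")
    logx = np.log(x + policy.pseudocount)
    y = logx - logx.mean(axis=1, keepdims=True)
    zero = x == 0
    for j in range(y.shape[1]):
        zj = zero[:, j]
        if zj.any():
            if zj.all():
                y[:, j] = np.nan  # all-absent feature: sentinel, flagged to caller
            else:
                y[zj, j] = y[~zj, j].min()
    return pd.DataFrame(y, index=table.index, columns=table.columns)


def prevalence_filter(
    table: pd.DataFrame,
    kind: str = "species",
    abundance_threshold: float = 1e-4,
    prevalence_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rare features before analysis.

    Species are kept iff their relative abundance exceeds
    ``abundance_threshold`` (default 1e-4, i.e. >0.01%, strict) in at
    least ``prevalence_threshold`` of samples (default >=1%, inclusive).
    Modules (``kind="module"``) are kept iff present (abundance > 0) in at
    least 1% of samples.

    Returns the filtered table and a per-feature report with ``kept`` and
    ``prevalence`` columns.
    """
    if table.empty:
        raise InsufficientDataError("empty abundance table")
    if kind not in ("species", "module"):
        raise ValueError("kind must be 'species' or 'module'")
    x = table.to_numpy(dtype=float)
    hit = x > (abundance_threshold if kind == "species" else 0.0)
    prevalence = hit.mean(axis=0)
    kept = prevalence >= prevalence_threshold
    report = pd.DataFrame(
        {"feature": table.columns, "prevalence": prevalence, "kept": kept}
    ).set_index("feature")
    return table.loc[:, table.columns[kept]], report
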