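"""OTU count-table construction and filtering.

Implements the two-stage table clean-up used for amplicon OTU tables — a
per-sample relative-abundance floor followed by a cross-sample prevalence
floor — plus an optional "predominant rescue" that restores any OTU removed by
the prevalence filter if it was the single most abundant member of at least
one sample. Filters are applied in that fixed order (abundance first), which
matters: "present" for the prevalence filter means nonzero *after* the
abundance filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OTUTable",
    "FilterConfig",
    "FilterResult",
    "filter_abundance",
    "filter_prevalence",
    "rescue_predominant",
    "relative_abundances",
    "apply_filters",
]


@dataclass
class OTUTable:
    """A samples x OTUs nonnegative integer count matrix with a filter log."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    filter_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")

    def copy(self) -> "OTUTable":
        return OTUTable(
            list(self.sample_ids), list(self.otu_ids), self.counts.copy(), list(self.filter_log)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.otu_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OTUTable":
        counts = df.to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise ValueError("OTU table must be numeric")
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   counts.astype(np.int64))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the table clean-up (defaults mirror the reference run)."""

    abundance_floor: float = 5e-5  # 0.005% of each sample's total reads
    prevalence_floor: float = 0.05  # 5% of samples
    rescue_predominant: bool = False
    per_sample_abundance: bool = True  # floor relative to row total vs grand total

    def __post_init__(self) -> None:
        if not (0 <= self.abundance_floor < 1) or not (0 <= self.prevalence_floor < 1):
            raise ValueError("filter floors must lie in [0, 1)")


def filter_abundance(table: OTUTable, floor: float, per_sample: bool = True) -> OTUTable:
    """Zero out, per sample, counts strictly below ``floor`` x the sample total.

    Row totals are taken *before* any zeroing. With ``per_sample=False`` the
    threshold is computed against the grand total instead (the alternative
    reading of a per-run floor).
    """
    if not (0 <= floor < 1):
        raise ValueError("floor must lie in [0, 1)")
    out = table.copy()
    if per_sample:
        thresholds = floor * out.counts.sum(axis=1, keepdims=True)
    else:
        thresholds = np.full((len(out.sample_ids), 1), floor * out.counts.sum())
    out.counts = np.where(out.counts < thresholds, 0, out.counts)
    out.filter_log.append(
        f"abundance_filter(floor={floor}, per_sample={per_sample})"
    )
    return out


def min_presence_count(n_samples: int, floor: float) -> int:
    """Samples an OTU must occur in to survive a prevalence floor of ``floor``."""
    return math.ceil(floor * n_samples)


def filter_prevalence(table: OTUTable, floor: float) -> tuple[OTUTable, int]:
    """Drop OTU columns present (count > 0) in fewer than ceil(floor * n) samples.

    Returns the filtered table and the minimum presence count used; an OTU
    present in exactly that many samples is retained (strict "less than"
    reading of the prevalence rule).
    """
    if not (0 <= floor < 1):
        raise ValueError("floor must lie in [0, 1)")
    minimum = min_presence_count(len(table.sample_ids), floor)
    presence = (table.counts > 0).sum(axis=0)
    keep = presence >= minimum
    out = OTUTable(
        list(table.sample_ids),
        [o for o, k in zip(table.otu_ids, keep) if k],
        table.counts[:, keep].copy(),
        list(table.filter_log),
    )
    removed = [o for o, k in zip(table.otu_ids, keep) if not k]
    out.filter_log.append(
        f"prevalence_filter(floor={floor}, min_presence={minimum}, removed={removed})"
    )
    return out, minimum


def _predominant_otus(table: OTUTable) -> set[str]:
    """OTUs that are the strictly most abundant member of >= 1 sample."""
    winners: set[str] = set()
    for row in table.counts:
        order = np.argsort(row)[::-1]
        if row[order[0]] > 0 and (len(row) == 1 or row[order[0]] > row[order[1]]):
            winners.add(table.otu_ids[order[0]])
    return winners


def rescue_predominant(table_before: OTUTable, table_after: OTUTable) -> OTUTable:
    """Restore prevalence-removed OTUs that dominated at least one sample.

    ``table_before`` is the pre-prevalence-filter (post-abundance-filter)
    table; any of its OTUs missing from ``table_after`` whose count was the
    strict per-sample maximum somewhere gets its whole column back. Ties for
    most-abundant do not confer predominance.
    """
    missing = [o for o in table_before.otu_ids if o not in set(table_after.otu_ids)]
    if not missing:
        out = table_after.copy()
        out.filter_log.append("rescue_predominant(restored=[])")
        return out
    winners = _predominant_otus(table_before)
    restored = [o for o in missing if o in winners]
    kept = set(table_after.otu_ids) | set(restored)
    otu_ids = [o for o in table_before.otu_ids if o in kept]
    col_of = {o: i for i, o in enumerate(table_before.otu_ids)}
    counts = table_before.counts[:, [col_of[o] for o in otu_ids]].copy()
    out = OTUTable(list(table_after.sample_ids), otu_ids, counts, list(table_after.filter_log))
    out.filter_log.append(f"rescue_predominant(restored={restored})")
    return out


def relative_abundances(table: OTUTable) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample relative abundances; all-zero rows are flagged, not dropped silently.

    Returns a DataFrame over the samples with positive totals (rows sum to 1)
    and the list of flagged all-zero sample ids.
    """
    totals = table.counts.sum(axis=1)
    flagged = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if flagged:
        logger.warning("excluding %d all-zero sample(s) from relative abundances: %s",
                       len(flagged), flagged)
    keep = totals > 0
    fractions = table.counts[keep].astype(float) / totals[keep, None]
    df = pd.DataFrame(
        fractions,
        index=pd.Index([s for s, k in zip(table.sample_ids, keep) if k], name="sample_id"),
        columns=table.otu_ids,
    )
    return df, flagged


@dataclass
class FilterResult:
    table: OTUTable
    min_presence: int
    removed_otus: list[str]
    rescued_otus: list[str]


def apply_filters(table: OTUTable, config: FilterConfig) -> FilterResult:
    """Abundance floor, then prevalence floor, then (optionally) predominant rescue."""
    after_abundance = filter_abundance(
        table, config.abundance_floor, per_sample=config.per_sample_abundance
    )
    after_prevalence, minimum = filter_prevalence(after_abundance, config.prevalence_floor)
    removed = [o for o in after_abundance.otu_ids if o not in set(after_prevalence.otu_ids)]
    rescued: list[str] = []
    final = after_prevalence
    if config.rescue_predominant:
        final = rescue_predominant(after_abundance, after_prevalence)
        rescued = [o for o in final.otu_ids if o not in set(after_prevalence.otu_ids)]
    return FilterResult(final, minimum, removed, rescued)
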