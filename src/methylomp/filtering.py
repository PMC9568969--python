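"""Probe trimming and named-subset exclusion/restriction.

Detection failures are assumed to have been converted to missing marks
upstream (raw intensities and detection p-values are out of scope here), so
"trimming failed probes" is a missingness filter. Exclusion removes a named
probe list (e.g. blood/saliva-discordant CpGs, or XY- and SNP-linked CpGs
ahead of clustering); restriction keeps only a named list (e.g. an
age-related CpG panel). When a workflow applies both, exclusions run first.

Every operation returns a :class:`FilterReport` whose counts are additive:
``n_input == n_retained + n_dropped_missing + sum(n_dropped_by_list)``.
Sample columns are never touched by any probe-level filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import BetaMatrix, DataValidationError

logger = logging.getLogger("methylomp")


@dataclass
class FilterReport:
    """Bookkeeping for one probe-level filtering step (or a composition)."""

    n_input: int
    n_dropped_missing: int = 0
    n_dropped_by_list: dict[str, int] = field(default_factory=dict)
    n_not_present: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def validate(self) -> None:
        total = self.n_retained + self.n_dropped_missing + sum(self.n_dropped_by_list.values())
        if total != self.n_input:
            raise AssertionError(
                f"filter report not additive: input {self.n_input} != {total}"
            )

    def combine(self, later: "FilterReport") -> "FilterReport":
        """Compose with a report produced on this report's output matrix."""
        if later.n_input != self.n_retained:
            raise ValueError("reports are not sequential")
        merged_lists = dict(self.n_dropped_by_list)
        for k, v in later.n_dropped_by_list.items():
            merged_lists[k] = merged_lists.get(k, 0) + v
        merged_np = dict(self.n_not_present)
        for k, v in later.n_not_present.items():
            merged_np[k] = merged_np.get(k, 0) + v
        out = FilterReport(
            n_input=self.n_input,
            n_dropped_missing=self.n_dropped_missing + later.n_dropped_missing,
            n_dropped_by_list=merged_lists,
            n_not_present=merged_np,
            n_retained=later.n_retained,
        )
        out.validate()
        return out

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_missing": self.n_dropped_missing,
            "n_dropped_by_list": dict(self.n_dropped_by_list),
            "n_not_present": dict(self.n_not_present),
            "n_retained": self.n_retained,
        }


def drop_failed_probes(
    m: BetaMatrix, max_missing_frac: float = 0.0
) -> tuple[BetaMatrix, FilterReport]:
    """Remove probes whose missing-sample fraction exceeds ``max_missing_frac``.

    The default policy is conservative: any missing value drops the probe
    (matching complete-case correlation downstream). Raises if nothing
    survives.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise DataValidationError("max_missing_frac must lie in [0, 1]")
    frac_missing = np.isnan(m.values).mean(axis=1)
    keep = frac_missing <= max_missing_frac
    if not keep.any():
        raise DataValidationError("empty matrix: all probes removed by missingness filter")
    report = FilterReport(
        n_input=m.n_probes,
        n_dropped_missing=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    report.validate()
    logger.info(
        "missingness filter: %d -> %d probes (dropped %d)",
        report.n_input, report.n_retained, report.n_dropped_missing,
    )
    return BetaMatrix(m.df.loc[keep]), report


def exclude_subset(
    m: BetaMatrix, subset: set[str], name: str
) -> tuple[BetaMatrix, FilterReport]:
    """Remove the named probe subset; idempotent, order-stable.

    Subset members absent from the matrix are counted under
    ``n_not_present[name]`` rather than silently ignored.
    """
    present = m.probe_ids.isin(subset)
    n_present = int(present.sum())
    report = FilterReport(
        n_input=m.n_probes,
        n_dropped_by_list={name: n_present},
        n_not_present={name: len(subset) - n_present},
        n_retained=m.n_probes - n_present,
    )
    report.validate()
    logger.info(
        "exclude %s: %d -> %d probes (%d not present)",
        name, report.n_input, report.n_retained, report.n_not_present[name],
    )
    return BetaMatrix(m.df.loc[~present]), report


def restrict_to_subset(m: BetaMatrix, subset: set[str], name: str) -> BetaMatrix:
    """Keep only probes in the named subset, preserving matrix order."""
    keep = m.probe_ids.isin(subset)
    if not keep.any():
        raise DataValidationError(
            f"restriction to subset {name!r} leaves no probes (empty intersection)"
        )
    logger.info("restrict to %s: %d -> %d probes", name, m.n_probes, int(keep.sum()))
    return BetaMatrix(m.df.loc[keep])
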