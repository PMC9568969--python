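"""Two-level Tukey-fence detection of the outlier methylation phenotype (OMP).

Level 1 (per CpG): across the cohort's samples, a probe's first and third
quartiles define fences ``lower = Q1 - 1.5*IQR`` and ``upper = Q3 + 1.5*IQR``
(IQR = Q3 - Q1). A sample is a *hyper* outlier at that CpG if its beta lies
strictly above the upper fence, *hypo* if strictly below the lower fence;
equality to a fence is never an outlier, and missing betas are never
outliers (they are counted separately so per-individual totals remain
comparable).

Level 2 (per individual): the same Tukey upper fence is applied to the
cohort's distribution of per-individual outlier-CpG counts; individuals whose
count strictly exceeds it carry the OMP. By default every individual is
included in the fences it is judged against (both levels); a leave-one-out
mode is available for the count fence.

An external healthy cohort can replace the internal one as the fence
reference: per-CpG fences come from the reference samples, and the count
fence from the reference cohort's own counts, evaluated leave-one-out so the
reference counts occupy the same out-of-sample position as the test
individuals (with small references, in-sample counts sit systematically
below out-of-sample ones and would miscalibrate the count fence).

The quantile convention is linear interpolation between order statistics by
default; the convention is exposed because fence positions in small cohorts
are sensitive to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import BetaMatrix, DataValidationError

logger = logging.getLogger("methylomp")

QUANTILE_METHODS = ("linear", "lower", "higher", "midpoint")

FENCE_MULTIPLIER = 1.5

#: minimum shared probes for external-reference confirmation
MIN_SHARED_PROBES = 100


def _check_method(quantile_method: str) -> None:
    if quantile_method not in QUANTILE_METHODS:
        raise DataValidationError(
            f"unknown quantile method {quantile_method!r}; choose from {QUANTILE_METHODS}"
        )


@dataclass
class FenceTable:
    """Per-CpG quartiles and Tukey limits."""

    probe_ids: pd.Index
    q1: np.ndarray
    q3: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_used: np.ndarray  # non-missing samples per probe
    excluded_probes: list[str] = field(default_factory=list)  # < 4 non-missing
    quantile_method: str = "linear"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q1": self.q1,
                "q3": self.q3,
                "lower": self.lower,
                "upper": self.upper,
                "n_used": self.n_used,
            },
            index=self.probe_ids,
        )


@dataclass
class OutlierProfile:
    """One individual's outlier CpGs with direction."""

    individual_id: str
    hyper_probes: frozenset[str]
    hypo_probes: frozenset[str]
    n_missing: int = 0

    @property
    def outlier_probes(self) -> dict[str, str]:
        out = {p: "hyper" for p in self.hyper_probes}
        out.update({p: "hypo" for p in self.hypo_probes})
        return out

    @property
    def n_outliers(self) -> int:
        return len(self.hyper_probes) + len(self.hypo_probes)


@dataclass
class OmpResult:
    """Cohort-level count fence and OMP calls."""

    count_upper_limit: float
    profiles: list[OutlierProfile]
    omp_calls: set[str]
    reference_label: str = "internal"
    n_shared_probes: int | None = None

    @property
    def counts(self) -> dict[str, int]:
        return {p.individual_id: p.n_outliers for p in self.profiles}


def tukey_limits(
    values: np.ndarray, quantile_method: str = "linear"
) -> tuple[float, float, float, float]:
    """(q1, q3, lower, upper) of a 1-D sample under the given quantile method."""
    _check_method(quantile_method)
    q1, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    return float(q1), float(q3), float(q1 - FENCE_MULTIPLIER * iqr), float(q3 + FENCE_MULTIPLIER * iqr)


def compute_fences(
    m: BetaMatrix, quantile_method: str = "linear", min_samples: int = 4
) -> FenceTable:
    """Per-probe Tukey fences over each probe's non-missing values.

    Probes with fewer than ``min_samples`` non-missing values are flagged and
    excluded from the fence table. Raises if the matrix has fewer than
    ``min_samples`` samples outright.
    """
    _check_method(quantile_method)
    if m.n_samples < min_samples:
        raise DataValidationError(
            f"need >= {min_samples} samples to compute fences, got {m.n_samples}"
        )
    vals = m.values
    n_used = (~np.isnan(vals)).sum(axis=1)
    ok = n_used >= min_samples
    excluded = list(m.probe_ids[~ok])
    use = vals[ok]
    if np.isnan(use).any():
        q1 = np.nanquantile(use, 0.25, axis=1, method=quantile_method)
        q3 = np.nanquantile(use, 0.75, axis=1, method=quantile_method)
    else:  # fast path
        q1, q3 = np.quantile(use, [0.25, 0.75], axis=1, method=quantile_method)
    iqr = q3 - q1
    table = FenceTable(
        probe_ids=m.probe_ids[ok],
        q1=q1,
        q3=q3,
        lower=q1 - FENCE_MULTIPLIER * iqr,
        upper=q3 + FENCE_MULTIPLIER * iqr,
        n_used=n_used[ok],
        excluded_probes=excluded,
        quantile_method=quantile_method,
    )
    if excluded:
        logger.info("fences: %d probes excluded (< %d non-missing)", len(excluded), min_samples)
    return table


def call_outliers(
    m: BetaMatrix,
    fences: FenceTable,
    individual_ids: Mapping[str, str] | None = None,
) -> list[OutlierProfile]:
    """Per-sample outlier CpGs against a fence table (strict comparisons).

    Fence rows for probes absent from the matrix are ignored; matrix probes
    absent from the fences are an error. ``individual_ids`` optionally maps
    sample ids to individual ids for the returned profiles (default: the
    sample id itself).
    """
    fence_index = pd.Index(fences.probe_ids)
    missing_fences = m.probe_ids.difference(fence_index)
    if len(missing_fences) > 0:
        raise DataValidationError(
            f"{len(missing_fences)} matrix probes have no fences, e.g. "
            f"{list(missing_fences[:5])}"
        )
    pos = fence_index.get_indexer(m.probe_ids)
    lower = fences.lower[pos]
    upper = fences.upper[pos]
    vals = m.values
    with np.errstate(invalid="ignore"):
        hyper = vals > upper[:, None]
        hypo = vals < lower[:, None]
    nan = np.isnan(vals)
    probes = np.asarray(m.probe_ids)
    profiles = []
    for j, sample in enumerate(m.sample_ids):
        ind = individual_ids.get(sample, sample) if individual_ids else sample
        profiles.append(
            OutlierProfile(
                individual_id=ind,
                hyper_probes=frozenset(probes[hyper[:, j]]),
                hypo_probes=frozenset(probes[hypo[:, j]]),
                n_missing=int(nan[:, j].sum()),
            )
        )
    return profiles


def call_omp(
    profiles: Sequence[OutlierProfile],
    quantile_method: str = "linear",
    leave_one_out: bool = False,
    reference_label: str = "internal",
) -> OmpResult:
    """Apply the Tukey upper fence to the per-individual outlier counts.

    Default: every candidate is included in the count fence it is judged
    against. With ``leave_one_out`` each individual is compared to the fence
    of the remaining individuals' counts.
    """
    if len(profiles) < 4:
        raise DataValidationError(f"need >= 4 profiles for a count fence, got {len(profiles)}")
    counts = np.array([p.n_outliers for p in profiles], dtype=float)
    if leave_one_out:
        calls = set()
        limits = []
        for i, p in enumerate(profiles):
            rest = np.delete(counts, i)
            _, _, _, upper = tukey_limits(rest, quantile_method)
            limits.append(upper)
            if counts[i] > upper:
                calls.add(p.individual_id)
        count_upper = float(np.median(limits))
    else:
        _, _, _, count_upper = tukey_limits(counts, quantile_method)
        calls = {p.individual_id for p in profiles if p.n_outliers > count_upper}
    logger.info(
        "count fence (%s): upper limit %.2f, %d/%d called OMP",
        reference_label, count_upper, len(calls), len(profiles),
    )
    return OmpResult(
        count_upper_limit=count_upper,
        profiles=list(profiles),
        omp_calls=calls,
        reference_label=reference_label,
    )


def call_omp_external(
    test: BetaMatrix,
    reference: BetaMatrix,
    quantile_method: str = "linear",
    min_shared_probes: int = MIN_SHARED_PROBES,
    individual_ids: Mapping[str, str] | None = None,
    reference_label: str = "external",
) -> OmpResult:
    """Confirm OMP calls against fences from an external healthy cohort.

    Per-CpG fences come from the reference samples at the probes shared with
    the test matrix. The count fence is built from the reference cohort's own
    counts, evaluated leave-one-out (each reference sample against fences
    from the remaining references) whenever the reference has >= 5 samples so
    that the reference counts occupy the same out-of-sample position as the
    test individuals; at exactly 4 reference samples in-sample counts are
    used instead.
    """
    if reference.n_samples < 4:
        raise DataValidationError("external reference needs >= 4 samples")
    shared = test.probe_ids.intersection(reference.probe_ids)
    if len(shared) < min_shared_probes:
        raise DataValidationError(
            f"only {len(shared)} probes shared with the reference "
            f"(floor {min_shared_probes})"
        )
    test_s = test.select_probes(shared)
    ref_s = reference.select_probes(shared)

    fences = compute_fences(ref_s, quantile_method)
    test_profiles = call_outliers(
        test_s.select_probes(fences.probe_ids), fences, individual_ids
    )

    if ref_s.n_samples >= 5:
        ref_counts = []
        for i, sample in enumerate(ref_s.sample_ids):
            others = ref_s.select_samples([s for s in ref_s.sample_ids if s != sample])
            f_i = compute_fences(others, quantile_method)
            prof = call_outliers(
                ref_s.select_samples([sample]).select_probes(f_i.probe_ids), f_i
            )
            ref_counts.append(prof[0].n_outliers)
    else:
        ref_profiles = call_outliers(ref_s.select_probes(fences.probe_ids), fences)
        ref_counts = [p.n_outliers for p in ref_profiles]

    _, _, _, count_upper = tukey_limits(np.asarray(ref_counts, dtype=float), quantile_method)
    calls = {p.individual_id for p in test_profiles if p.n_outliers > count_upper}
    logger.info(
        "external confirmation (%s): %d shared probes, count limit %.2f, "
        "%d/%d called OMP",
        reference_label, len(shared), count_upper, len(calls), len(test_profiles),
    )
    return OmpResult(
        count_upper_limit=count_upper,
        profiles=test_profiles,
        omp_calls=calls,
        reference_label=reference_label,
        n_shared_probes=len(shared),
    )
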