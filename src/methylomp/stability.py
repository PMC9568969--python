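"""Paired-tissue methylation stability as squared Pearson correlation.

For each individual with both a cord-blood and a saliva sample, stability is
the squared Pearson correlation (R^2) between the two beta vectors over a
configurable CpG subset, complete-case per pair: a CpG missing in either
member of a pair is dropped for that pair only.

The default 95% CI is the Fisher z-transform interval on r with endpoints
squared (if the r-interval spans zero the R^2 lower bound is 0). The
underlying CpG-independence assumption is optimistic for real methylomes,
where neighbouring CpGs are correlated, so a probe-resampling bootstrap CI
is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BetaMatrix, DataValidationError, SampleSheet

logger = logging.getLogger("methylomp")

MIN_SHARED_CPGS = 10


class SamplePair(NamedTuple):
    cord_sample_id: str
    saliva_sample_id: str
    individual_id: str


@dataclass
class StabilityResult:
    individual_id: str
    subset_name: str
    n_cpgs_used: int
    r: float
    r2: float
    ci95_low: float
    ci95_high: float


def pair_samples(sheet: SampleSheet) -> list[SamplePair]:
    """Pair each individual's cord-blood and saliva samples.

    Individuals lacking either tissue are excluded and logged. Raises if no
    individual can be paired.
    """
    cord = {
        r.individual_id: r.sample_id
        for r in sheet.samples_for_tissue("cord_blood").itertuples()
    }
    saliva = {
        r.individual_id: r.sample_id
        for r in sheet.samples_for_tissue("saliva").itertuples()
    }
    pairs = [
        SamplePair(cord[ind], saliva[ind], ind)
        for ind in sheet.individuals
        if ind in cord and ind in saliva
    ]
    unpaired = [ind for ind in sheet.individuals if ind not in {p.individual_id for p in pairs}]
    if unpaired:
        logger.info("unpaired individuals (one tissue only): %s", unpaired)
    if not pairs:
        raise DataValidationError("no individual has both cord blood and saliva samples")
    return pairs


def _fisher_ci_r2(r: float, n: int) -> tuple[float, float]:
    """95% CI on r^2 via Fisher z on r, endpoints squared."""
    if n <= 3 or abs(r) >= 1.0:
        return (r * r, r * r)  # degenerate: no sampling interval available
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    r_lo, r_hi = np.tanh(z - half), np.tanh(z + half)
    if r_lo < 0.0 < r_hi:
        return (0.0, float(max(r_lo**2, r_hi**2)))
    lo, hi = sorted((float(r_lo**2), float(r_hi**2)))
    return (lo, hi)


def _bootstrap_ci_r2(
    x: np.ndarray, y: np.ndarray, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(x)
    r2s = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if xb.std() == 0 or yb.std() == 0:
            r2s[b] = np.nan
            continue
        r2s[b] = np.corrcoef(xb, yb)[0, 1] ** 2
    lo, hi = np.nanpercentile(r2s, [2.5, 97.5])
    return float(lo), float(hi)


def stability_r2(
    cord: BetaMatrix,
    saliva: BetaMatrix,
    pair: SamplePair,
    subset: set[str] | None = None,
    subset_name: str = "all",
    ci_method: str = "fisher",
    n_boot: int = 1000,
    seed: int = 0,
) -> StabilityResult:
    """Complete-case Pearson R^2 between one individual's two tissues.

    ``subset`` optionally restricts the shared CpGs before correlation.
    Requires at least 10 shared non-missing CpGs; a zero-variance vector
    (constant methylome) is an error.
    """
    shared = cord.probe_ids.intersection(saliva.probe_ids)
    if subset is not None:
        shared = shared[shared.isin(subset)]
    x = cord.df.loc[shared, pair.cord_sample_id].to_numpy()
    y = saliva.df.loc[shared, pair.saliva_sample_id].to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < MIN_SHARED_CPGS:
        raise DataValidationError(
            f"{pair.individual_id}/{subset_name}: only {len(x)} shared non-missing "
            f"CpGs (need >= {MIN_SHARED_CPGS})"
        )
    if x.std() == 0 or y.std() == 0:
        raise DataValidationError(
            f"{pair.individual_id}/{subset_name}: constant methylome, correlation undefined"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    if ci_method == "fisher":
        lo, hi = _fisher_ci_r2(r, len(x))
    elif ci_method == "bootstrap":
        lo, hi = _bootstrap_ci_r2(x, y, n_boot, seed)
    else:
        raise DataValidationError(f"unknown ci_method {ci_method!r}")
    return StabilityResult(
        individual_id=pair.individual_id,
        subset_name=subset_name,
        n_cpgs_used=len(x),
        r=r,
        r2=r * r,
        ci95_low=lo,
        ci95_high=hi,
    )


def stability_partition(
    cord: BetaMatrix,
    saliva: BetaMatrix,
    pair: SamplePair,
    outlier_set: set[str],
    ci_method: str = "fisher",
) -> tuple[StabilityResult, StabilityResult, StabilityResult]:
    """Stability over all CpGs, the outlier subset, and its complement.

    ``outlier_set`` must be a nonempty strict subset of the probes shared by
    the two matrices; the all-CpG count equals outlier + non-outlier counts.
    """
    shared = set(cord.probe_ids.intersection(saliva.probe_ids))
    outliers = outlier_set & shared
    if not outliers:
        raise DataValidationError("outlier_set shares no probes with the matrices")
    if outliers >= shared:
        raise DataValidationError("outlier_set covers all shared probes; complement empty")
    non_outliers = shared - outliers
    res_all = stability_r2(cord, saliva, pair, None, "all", ci_method)
    res_out = stability_r2(cord, saliva, pair, outliers, "outlier", ci_method)
    res_non = stability_r2(cord, saliva, pair, non_outliers, "non_outlier", ci_method)
    return res_all, res_out, res_non


def stability_table(
    cord: BetaMatrix,
    saliva: BetaMatrix,
    pairs: Sequence[SamplePair],
    subsets: dict[str, set[str]] | None = None,
    ci_method: str = "fisher",
) -> pd.DataFrame:
    """One row per individual, one R^2 column per subset ('all' first)."""
    subsets = subsets or {}
    rows = []
    for pair in pairs:
        row: dict[str, object] = {"individual_id": pair.individual_id}
        res = stability_r2(cord, saliva, pair, None, "all", ci_method)
        row["r2_all"] = res.r2
        row["ci95_low_all"] = res.ci95_low
        row["ci95_high_all"] = res.ci95_high
        for name, probe_set in subsets.items():
            res = stability_r2(cord, saliva, pair, probe_set, name, ci_method)
            row[f"r2_{name}"] = res.r2
            row[f"ci95_low_{name}"] = res.ci95_low
            row[f"ci95_high_{name}"] = res.ci95_high
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual_id")
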