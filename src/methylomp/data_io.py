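"""Reading, writing and validation of the delimited-text formats used throughout.

All pipeline stages exchange three in-memory containers:

* :class:`BetaMatrix` — a probes x samples matrix of methylation beta values
  (fractions in [0, 1]; NaN marks a missing/failed measurement),
* :class:`SampleSheet` — per-sample metadata (individual, family, tissue,
  timepoint, free-form group label),
* :class:`ProbeAnnotation` — per-probe metadata mirroring Illumina-manifest
  column semantics (chromosome, SNP linkage, gene names and gene-region
  groups) plus named boolean probe subsets.

On-disk, beta matrices and sheets are plain TSV/CSV; probe subsets are plain
text, one probe id per line. The delimiter is inferred from the file
extension (``.csv`` -> comma, anything else -> tab) and can be overridden.
Missing beta values are serialized as ``NA`` by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methylomp")

MISSING_TOKEN = "NA"

TISSUES = ("cord_blood", "saliva")
TIMEPOINTS = ("birth", "childhood")
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: manifest gene-region groups treated as "promoter" by default downstream
PROMOTER_GROUPS = ("TSS200", "TSS1500", "5UTR", "1stExon")


class DataValidationError(ValueError):
    """Raised when an input file or in-memory container violates its contract."""


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Dense probes x samples matrix of beta values.

    Wraps a :class:`pandas.DataFrame` whose index holds probe ids and whose
    columns hold sample ids. Values are floats in [0, 1]; NaN is an explicit
    missing mark. Probe order is preserved exactly as constructed/read and is
    never sorted implicitly.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise DataValidationError(f"duplicate probe id: {dup!r}")
        if self.df.columns.has_duplicates:
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise DataValidationError(f"duplicate sample id: {dup!r}")
        vals = self.df.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"beta value out of [0, 1] at probe {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}: {vals[i, j]}"
            )
        self.df = self.df.astype(float)

    # -- basic views -------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float, copy=False)

    @property
    def n_probes(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    # -- manipulation ------------------------------------------------------

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        """Return the sub-matrix at ``probe_ids`` (order as given)."""
        return BetaMatrix(self.df.loc[list(probe_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.df[list(sample_ids)])

    def equals(self, other: "BetaMatrix") -> bool:
        return self.df.equals(other.df)

    @classmethod
    def from_arrays(
        cls,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "BetaMatrix":
        return cls(
            pd.DataFrame(
                np.asarray(values, dtype=float),
                index=pd.Index(probe_ids, name="probe_id"),
                columns=pd.Index(sample_ids),
            )
        )


def read_beta_matrix(
    path: str | Path,
    missing_token: str = MISSING_TOKEN,
    delimiter: str | None = None,
) -> BetaMatrix:
    """Read a beta matrix from delimited text.

    The file must have a header row ``probe_id, <sample ids...>`` and one row
    per probe. Cells equal to ``missing_token`` become NaN; any other
    non-numeric cell is a hard error naming the offending probe and sample.
    Values outside [0, 1] are a hard error.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    raw.index.name = "probe_id"
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DataValidationError(f"{path}: duplicate probe id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise DataValidationError(f"{path}: duplicate sample id {dup!r}")
    missing = raw == missing_token
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric cell at probe {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}: {raw.iloc[i, j]!r}"
        )
    numeric = numeric.where(~missing, np.nan)
    m = BetaMatrix(numeric)
    logger.info("read beta matrix %s: %d probes x %d samples", path, m.n_probes, m.n_samples)
    return m


def write_beta_matrix(
    m: BetaMatrix,
    path: str | Path,
    missing_token: str = MISSING_TOKEN,
    delimiter: str | None = None,
) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    m.df.to_csv(path, sep=sep, na_rep=missing_token, index_label="probe_id")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ("sample_id", "individual_id", "family_id", "tissue", "timepoint")


@dataclass
class SampleSheet:
    """Cohort design table: one row per array sample.

    Each individual contributes at most one sample per tissue; the optional
    ``group`` column carries a free label (ancestry, conception mode, ...).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise DataValidationError("no samples in sample sheet")
        missing_cols = [c for c in _SHEET_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise DataValidationError(f"sample sheet missing columns: {missing_cols}")
        if "group" not in self.df.columns:
            self.df = self.df.assign(group="")
        bad_tissue = set(self.df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise DataValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
        bad_tp = set(self.df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DataValidationError(f"unknown timepoint labels: {sorted(bad_tp)}")
        if self.df["sample_id"].duplicated().any():
            dup = self.df["sample_id"][self.df["sample_id"].duplicated()].iloc[0]
            raise DataValidationError(f"duplicate sample id: {dup!r}")
        pair = self.df[["individual_id", "tissue"]]
        if pair.duplicated().any():
            ind, tis = pair[pair.duplicated()].iloc[0]
            raise DataValidationError(
                f"individual {ind!r} has more than one {tis!r} sample"
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.df["individual_id"]))

    def samples_for_tissue(self, tissue: str) -> pd.DataFrame:
        return self.df[self.df["tissue"] == tissue]

    def sample_to_individual(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["individual_id"]))

    def families(self) -> dict[str, list[str]]:
        """Family id -> individual ids, in sheet order, de-duplicated."""
        out: dict[str, list[str]] = {}
        for fam, ind in zip(self.df["family_id"], self.df["individual_id"]):
            out.setdefault(fam, [])
            if ind not in out[fam]:
                out[fam].append(ind)
        return out

    def restrict_individuals(self, individuals: Iterable[str]) -> "SampleSheet":
        keep = set(individuals)
        return SampleSheet(self.df[self.df["individual_id"].isin(keep)].copy())


def read_sample_sheet(path: str | Path, delimiter: str | None = None) -> SampleSheet:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise DataValidationError(f"{path}: no samples")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sheet.df.to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Per-probe metadata in manifest style.

    ``df`` is indexed by probe id with columns ``chromosome`` (str label from
    1..22, X, Y), ``snp_linked`` (bool), ``gene_names`` and ``gene_regions``
    (parallel lists of gene symbols and region-group labels such as TSS200 or
    Body). ``subsets`` is a boolean probes x subset-name frame holding named
    probe subsets (e.g. ``blood_saliva_discordant``, ``xy_snp``).
    """

    df: pd.DataFrame
    subsets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise DataValidationError(f"duplicate probe id in annotation: {dup!r}")
        bad_chrom = set(self.df["chromosome"].astype(str)) - set(CHROMOSOMES)
        if bad_chrom:
            raise DataValidationError(f"unknown chromosome labels: {sorted(bad_chrom)}")
        for pid, names, regions in zip(
            self.df.index, self.df["gene_names"], self.df["gene_regions"]
        ):
            if len(names) != len(regions):
                raise DataValidationError(
                    f"probe {pid!r}: gene_names and gene_regions lengths differ"
                )
        if self.subsets.empty:
            self.subsets = pd.DataFrame(index=self.df.index)
        else:
            self.subsets = self.subsets.reindex(self.df.index).fillna(False).astype(bool)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def subset(self, name: str) -> set[str]:
        """Probe ids flagged under the named subset."""
        if name not in self.subsets.columns:
            raise KeyError(f"no probe subset named {name!r}")
        col = self.subsets[name]
        return set(col.index[col])

    def subset_names(self) -> list[str]:
        return list(self.subsets.columns)


def read_probe_annotation(path: str | Path, delimiter: str | None = None) -> ProbeAnnotation:
    """Read a manifest-style annotation TSV.

    Expected columns: probe_id, chromosome, snp_linked (0/1), gene_names and
    gene_regions (semicolon-joined), plus one 0/1 column per named subset.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    core = pd.DataFrame(index=raw.index)
    core["chromosome"] = raw["chromosome"].astype(str)
    core["snp_linked"] = raw["snp_linked"].astype(int).astype(bool)
    core["gene_names"] = [x.split(";") if x else [] for x in raw["gene_names"]]
    core["gene_regions"] = [x.split(";") if x else [] for x in raw["gene_regions"]]
    subset_cols = [
        c for c in raw.columns
        if c not in ("chromosome", "snp_linked", "gene_names", "gene_regions")
    ]
    subsets = raw[subset_cols].astype(int).astype(bool) if subset_cols else pd.DataFrame(index=raw.index)
    return ProbeAnnotation(core, subsets)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    out = pd.DataFrame(index=ann.df.index)
    out["chromosome"] = ann.df["chromosome"]
    out["snp_linked"] = ann.df["snp_linked"].astype(int)
    out["gene_names"] = [";".join(x) for x in ann.df["gene_names"]]
    out["gene_regions"] = [";".join(x) for x in ann.df["gene_regions"]]
    for name in ann.subsets.columns:
        out[name] = ann.subsets[name].astype(int)
    out.to_csv(path, sep=_infer_delimiter(path, delimiter), index_label="probe_id")


# ---------------------------------------------------------------------------
# Probe subset lists
# ---------------------------------------------------------------------------


def read_probe_subset(path: str | Path) -> set[str]:
    """Read a plain-text probe list (one id per line) into a de-duplicated set.

    An empty file yields an empty set with a warning; a missing file is an
    error (propagated as FileNotFoundError).
    """
    path = Path(path)
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    if not ids:
        logger.warning("probe subset %s is empty", path)
    logger.info("read probe subset %s: %d probes", path, len(ids))
    return ids


def write_probe_subset(ids: Iterable[str], path: str | Path) -> None:
    # sorted: set iteration order is not reproducible across interpreter runs
    with open(path, "w") as fh:
        for pid in sorted(set(ids)):
            fh.write(f"{pid}\n")
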