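"""Synthetic EPIC-like methylation cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes: bimodal
per-CpG beta baselines, paired cord-blood/saliva samples with a tunable
cross-tissue Pearson correlation, family blocks sharing per-CpG effects, and
planted "outlier methylation phenotype" (OMP) individuals whose betas at a
chosen fraction of CpGs are displaced beyond the cohort's Tukey fences.

Generative model, per CpG ``j`` and individual ``i``::

    cord_ij   = clip(mu_j              + g_{f(i),j} + e_ij, 0, 1)
    saliva_ij = clip(nu_j + delta_j    + g_{f(i),j} + e'_ij, 0, 1)

where ``mu_j`` is drawn from a hypo/mid/hyper mixture (class centers near
0.1/0.5/0.9), ``g`` is a family-shared effect, ``e`` is individual noise, and
``delta_j`` a small per-CpG tissue offset. The saliva baseline ``nu_j``
equals ``mu_j`` with probability ``p`` and is re-drawn from the mixture
otherwise; ``p`` (and, in the high-correlation limit, a shared-noise weight
``kappa``) is solved in closed form so the expected per-individual Pearson r
between the two tissues equals ``target_pair_r``. Re-drawn CpGs are flagged
as the ``blood_saliva_discordant`` annotation subset, so the discordance
exclusion applied before stability analysis is semantically real here.

Planted individuals receive an additional ``+/- omp_shift`` displacement (in
both tissues; direction Bernoulli(0.5) per probe) at ``omp_frac`` of CpGs,
recorded in :class:`CohortTruth` for recovery tests.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    BetaMatrix,
    CHROMOSOMES,
    DataValidationError,
    ProbeAnnotation,
    PROMOTER_GROUPS,
    SampleSheet,
)

# baseline mixture classes: (center, spread) on the beta scale
_CLASS_CENTERS = np.array([0.10, 0.50, 0.90])
_CLASS_SPREADS = np.array([0.03, 0.08, 0.03])
_CLASS_CLIP = [(0.02, 0.25), (0.30, 0.70), (0.75, 0.98)]


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31, derived from a master seed."""
    return zlib.crc32(f"{label}:{seed}".encode()) & 0x7FFFFFFF


def _default_individuals(n: int) -> list[str]:
    return [f"ind{i + 1:02d}" for i in range(n)]


def _default_families(individuals: Sequence[str]) -> list[list[str]]:
    """Mimic the study design: three twin pairs plus one twins+sibling trio."""
    fams = []
    if len(individuals) >= 9:
        fams = [
            list(individuals[0:3]),  # twins + an older sibling
            list(individuals[3:5]),
            list(individuals[5:7]),
            list(individuals[7:9]),
        ]
    return fams


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 28 individuals (four family
    blocks), 20,000 CpGs, within-cohort noise sd 0.03 beta units, target
    cross-tissue Pearson r 0.95 (squared ~0.9, the level reported for
    cord-blood/saliva stability), and three planted OMP individuals displaced
    by 0.2 beta units at 20% of CpGs — one of them a member of a twin pair,
    mirroring the dizygotic-twin outlier of the study.
    """

    n_probes: int = 20_000
    n_individuals: int = 28
    individuals: tuple[str, ...] | None = None
    families: tuple[tuple[str, ...], ...] | None = None
    frac_hypo: float = 0.40
    frac_mid: float = 0.20
    frac_hyper: float = 0.40
    within_cohort_sd: float = 0.03
    tissue_offset_sd: float = 0.02
    target_pair_r: float = 0.95
    family_effect_sd: float = 0.01
    omp_individuals: tuple[str, ...] = ("ind05", "ind19", "ind26")
    omp_frac: float = 0.20
    omp_shift: float = 0.20
    omp_saliva_noise_sd: float = 0.0
    unassisted_individuals: tuple[str, ...] = ("ind15", "ind16")
    embed_cell_mixture: bool = True  # write leukocyte/epithelial mixtures at marker CpGs
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.frac_hypo + self.frac_mid + self.frac_hyper
        if abs(w - 1.0) > 1e-9:
            raise DataValidationError(f"mixture weights sum to {w}, expected 1")
        if not 0.0 < self.omp_frac < 1.0:
            raise DataValidationError("omp_frac must lie strictly in (0, 1)")
        if not 0.0 <= self.target_pair_r <= 1.0:
            raise DataValidationError("target_pair_r must lie in [0, 1]")
        for name in ("within_cohort_sd", "tissue_offset_sd", "family_effect_sd",
                     "omp_shift", "omp_saliva_noise_sd"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be >= 0")
        if self.individuals is None:
            self.individuals = tuple(_default_individuals(self.n_individuals))
        if len(self.individuals) != self.n_individuals:
            raise DataValidationError("individuals length != n_individuals")
        if self.families is None:
            self.families = tuple(
                tuple(f) for f in _default_families(self.individuals)
            )
        known = set(self.individuals)
        for fam in self.families:
            unknown = set(fam) - known
            if unknown:
                raise DataValidationError(f"family members not in cohort: {sorted(unknown)}")
        unknown = set(self.omp_individuals) - known
        if unknown:
            raise DataValidationError(f"omp individuals not in cohort: {sorted(unknown)}")


@dataclass
class CohortTruth:
    """Ground truth recorded by :func:`simulate_cohort` for recovery tests."""

    planted_omp: set[str]
    displaced_probes: dict[str, dict[str, str]]  # individual -> probe -> hyper/hypo
    per_cpg_baseline: pd.Series  # probe -> cord baseline mean mu_j
    baseline_class: pd.Series  # probe -> hypo/mid/hyper
    discordant_probes: set[str]  # saliva baseline re-drawn
    leukocyte_fraction: dict[str, float] = field(default_factory=dict)  # per sample


def _draw_baselines(rng: np.random.Generator, classes: np.ndarray) -> np.ndarray:
    mu = rng.normal(_CLASS_CENTERS[classes], _CLASS_SPREADS[classes])
    for k, (lo, hi) in enumerate(_CLASS_CLIP):
        sel = classes == k
        mu[sel] = np.clip(mu[sel], lo, hi)
    return mu


def _solve_mixing(spec: CohortSpec, v_baseline: float) -> tuple[float, float]:
    """Closed-form share probability p (and shared-noise weight kappa).

    Solves cov/sqrt(var_cord * var_saliva) = target_pair_r where
    cov = p*V + sd_fam^2 + kappa*sd^2, using the empirical across-probe
    baseline variance V. kappa stays 0 unless even p = 1 cannot reach the
    target (the r -> 1 limit), in which case noise is shared.
    """
    f2 = spec.family_effect_sd ** 2
    s2 = spec.within_cohort_sd ** 2
    var_c = v_baseline + f2 + s2
    var_s = v_baseline + f2 + spec.tissue_offset_sd ** 2 + s2
    need = spec.target_pair_r * np.sqrt(var_c * var_s) - f2
    p = need / v_baseline if v_baseline > 0 else 1.0
    kappa = 0.0
    if p > 1.0:
        p = 1.0
        if s2 > 0:
            kappa = float(np.clip((need - v_baseline) / s2, 0.0, 1.0))
    if p < 0.0:
        warnings.warn(
            "target_pair_r too low for the configured noise; using p = 0",
            RuntimeWarning,
        )
        p = 0.0
    return float(p), kappa


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[BetaMatrix, BetaMatrix, SampleSheet, ProbeAnnotation, CohortTruth]:
    """Generate paired cord-blood and saliva beta matrices plus metadata.

    Deterministic for a fixed ``spec.seed``. Returns (cord, saliva, sheet,
    annotation, truth); cord sample ids are ``<individual>_cb`` and saliva
    sample ids ``<individual>_sal``.
    """
    if spec.omp_individuals and spec.omp_shift < 3 * spec.within_cohort_sd:
        warnings.warn(
            "omp_shift is below 3x within_cohort_sd; planted individuals may "
            "not clear the cohort fences (power may be inadequate)",
            RuntimeWarning,
        )
    rng = np.random.default_rng(spec.seed)
    P, N = spec.n_probes, spec.n_individuals
    probe_ids = np.array([f"cg{j + 1:08d}" for j in range(P)])
    individuals = list(spec.individuals)

    weights = [spec.frac_hypo, spec.frac_mid, spec.frac_hyper]
    classes = rng.choice(3, size=P, p=weights)
    mu = _draw_baselines(rng, classes)

    p_share, kappa = _solve_mixing(spec, float(np.var(mu)))
    redraw = rng.random(P) >= p_share
    nu = mu.copy()
    if redraw.any():
        new_classes = rng.choice(3, size=int(redraw.sum()), p=weights)
        nu[redraw] = _draw_baselines(rng, new_classes)

    delta = rng.normal(0.0, spec.tissue_offset_sd, size=P) if spec.tissue_offset_sd > 0 else np.zeros(P)

    fam_effect = np.zeros((P, N))
    col_of = {ind: k for k, ind in enumerate(individuals)}
    for fam in spec.families:
        g = rng.normal(0.0, spec.family_effect_sd, size=P)
        for ind in fam:
            fam_effect[:, col_of[ind]] += g

    e_cord = rng.normal(0.0, spec.within_cohort_sd, size=(P, N))
    e_fresh = rng.normal(0.0, spec.within_cohort_sd, size=(P, N))
    e_sal = kappa * e_cord + np.sqrt(max(0.0, 1.0 - kappa ** 2)) * e_fresh

    cord = mu[:, None] + fam_effect + e_cord
    sal = nu[:, None] + delta[:, None] + fam_effect + e_sal

    # plant OMP displacement in both tissues; direction Bernoulli(0.5)
    n_disp = int(round(spec.omp_frac * P))
    displaced: dict[str, dict[str, str]] = {}
    for ind in spec.omp_individuals:
        idx = rng.choice(P, size=n_disp, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_disp)
        col = col_of[ind]
        cord[idx, col] += sign * spec.omp_shift
        sal[idx, col] += sign * spec.omp_shift
        if spec.omp_saliva_noise_sd > 0:
            sal[idx, col] += rng.normal(0.0, spec.omp_saliva_noise_sd, size=n_disp)
        displaced[ind] = {
            probe_ids[i]: ("hyper" if s > 0 else "hypo") for i, s in zip(idx, sign)
        }

    np.clip(cord, 0.0, 1.0, out=cord)
    np.clip(sal, 0.0, 1.0, out=sal)

    ann = make_annotation_fixture(
        n_probes=P,
        n_genes=max(1, P // 40),
        promoter_frac=0.35,
        seed=derive_seed(spec.seed, "annotation"),
        probe_ids=list(probe_ids),
    )
    # overwrite the discordance flag with the probes that are truly discordant
    ann.subsets["blood_saliva_discordant"] = pd.Series(redraw, index=ann.df.index)

    truth = CohortTruth(
        planted_omp=set(spec.omp_individuals),
        displaced_probes=displaced,
        per_cpg_baseline=pd.Series(mu, index=probe_ids),
        baseline_class=pd.Series(
            np.array(["hypo", "mid", "hyper"])[classes], index=probe_ids
        ),
        discordant_probes=set(probe_ids[redraw]),
    )

    # embed a two-cell-type mixture at the deconvolution marker CpGs
    ref = make_celltype_reference(seed=derive_seed(spec.seed, "celltype_ref"))
    marker_pos = [int(p[2:]) - 1 for p in ref.index if p in set(probe_ids)]

    fam_of = {ind: None for ind in individuals}
    for k, fam in enumerate(spec.families):
        for ind in fam:
            fam_of[ind] = f"fam{k + 1:02d}"
    singleton = 0
    for ind in individuals:
        if fam_of[ind] is None:
            singleton += 1
            fam_of[ind] = f"solo{singleton:02d}"

    rows = []
    leuko: dict[str, float] = {}
    for ind in individuals:
        group = "unassisted" if ind in spec.unassisted_individuals else "ART"
        rows.append((f"{ind}_cb", ind, fam_of[ind], "cord_blood", "birth", group))
        rows.append((f"{ind}_sal", ind, fam_of[ind], "saliva", "childhood", group))
        leuko[f"{ind}_cb"] = float(rng.uniform(0.88, 0.99))
        leuko[f"{ind}_sal"] = float(rng.uniform(0.55, 0.90))
    sheet = SampleSheet(
        pd.DataFrame(
            rows,
            columns=["sample_id", "individual_id", "family_id", "tissue", "timepoint", "group"],
        )
    )
    truth.leukocyte_fraction = leuko

    if marker_pos and spec.embed_cell_mixture:
        prof = ref.to_numpy()  # markers x 2 (leukocyte, epithelial)
        for ind in individuals:
            for suffix, mat in (("_cb", cord), ("_sal", sal)):
                w = leuko[f"{ind}{suffix}"]
                mix = prof[:, 0] * w + prof[:, 1] * (1 - w)
                mix = mix + rng.normal(0.0, 0.01, size=len(marker_pos))
                mat[marker_pos, col_of[ind]] = np.clip(mix, 0.0, 1.0)

    cord_m = BetaMatrix.from_arrays(probe_ids, [f"{i}_cb" for i in individuals], cord)
    sal_m = BetaMatrix.from_arrays(probe_ids, [f"{i}_sal" for i in individuals], sal)
    return cord_m, sal_m, sheet, ann, truth


def simulate_external_reference(
    spec: CohortSpec,
    truth: CohortTruth,
    n_external: int,
    seed: int | None = None,
) -> BetaMatrix:
    """Draw unplanted cord-blood samples from the same per-CpG baselines.

    Emulates an external healthy reference cohort measured on the same
    probes; sample ids are ``ext01``, ``ext02``, ...
    """
    if seed is None:
        seed = derive_seed(spec.seed, "external")
    rng = np.random.default_rng(seed)
    mu = truth.per_cpg_baseline.to_numpy()
    P = len(mu)
    vals = np.clip(
        mu[:, None] + rng.normal(0.0, spec.within_cohort_sd, size=(P, n_external)),
        0.0,
        1.0,
    )
    ids = [f"ext{i + 1:02d}" for i in range(n_external)]
    return BetaMatrix.from_arrays(list(truth.per_cpg_baseline.index), ids, vals)


def make_annotation_fixture(
    n_probes: int,
    n_genes: int,
    promoter_frac: float,
    seed: int,
    probe_ids: Sequence[str] | None = None,
    frac_xy: float = 0.03,
    frac_snp: float = 0.05,
    frac_discordant: float = 0.005,
    frac_intergenic: float = 0.2,
) -> ProbeAnnotation:
    """Random but seeded manifest-style annotation.

    Probes are assigned to ``n_genes`` genes (a small fraction to two genes,
    ``frac_intergenic`` to none); region labels are promoter groups with
    probability ``promoter_frac`` (else Body/3UTR). When ``promoter_frac > 0``
    each gene is guaranteed at least one promoter probe. A seeded fraction of
    probes is placed on X/Y or flagged SNP-linked (subset ``xy_snp``) or
    flagged blood/saliva-discordant.
    """
    if n_genes < 1:
        raise DataValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if probe_ids is None:
        probe_ids = [f"cg{j + 1:08d}" for j in range(n_probes)]
    probe_ids = list(probe_ids)
    if len(probe_ids) != n_probes:
        raise DataValidationError("probe_ids length != n_probes")
    genes = [f"GENE{g + 1:05d}" for g in range(n_genes)]

    chrom = rng.choice([str(c) for c in range(1, 23)], size=n_probes)
    xy = rng.random(n_probes) < frac_xy
    chrom[xy] = rng.choice(["X", "Y"], size=int(xy.sum()))
    snp = rng.random(n_probes) < frac_snp
    discordant = rng.random(n_probes) < frac_discordant

    body_groups = ("Body", "3UTR")
    gene_names: list[list[str]] = [[] for _ in range(n_probes)]
    gene_regions: list[list[str]] = [[] for _ in range(n_probes)]
    intergenic = rng.random(n_probes) < frac_intergenic
    gene_idx = rng.integers(0, n_genes, size=n_probes)
    second_gene = rng.random(n_probes) < 0.05
    for j in range(n_probes):
        if intergenic[j]:
            continue
        is_prom = rng.random() < promoter_frac
        region = (
            str(rng.choice(PROMOTER_GROUPS)) if is_prom else str(rng.choice(body_groups))
        )
        gene_names[j].append(genes[gene_idx[j]])
        gene_regions[j].append(region)
        if second_gene[j]:
            g2 = genes[(gene_idx[j] + 1) % n_genes]
            region2 = (
                str(rng.choice(PROMOTER_GROUPS))
                if rng.random() < promoter_frac
                else str(rng.choice(body_groups))
            )
            gene_names[j].append(g2)
            gene_regions[j].append(region2)

    if promoter_frac > 0:
        # guarantee >= 1 promoter probe per gene
        has_promoter = {g: False for g in genes}
        for j in range(n_probes):
            for g, r in zip(gene_names[j], gene_regions[j]):
                if r in PROMOTER_GROUPS:
                    has_promoter[g] = True
        candidates = [j for j in range(n_probes) if not gene_names[j]]
        ci = 0
        for g in genes:
            if has_promoter[g]:
                continue
            if ci < len(candidates):
                j = candidates[ci]
                ci += 1
            else:  # fall back to relabelling an existing probe of any gene
                j = int(rng.integers(0, n_probes))
                gene_names[j].clear()
                gene_regions[j].clear()
            gene_names[j].append(g)
            gene_regions[j].append("TSS200")

    df = pd.DataFrame(
        {
            "chromosome": chrom,
            "snp_linked": snp,
            "gene_names": gene_names,
            "gene_regions": gene_regions,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    subsets = pd.DataFrame(
        {
            "xy_snp": np.isin(chrom, ["X", "Y"]) | snp,
            "blood_saliva_discordant": discordant,
        },
        index=df.index,
    )
    return ProbeAnnotation(df, subsets)


def make_celltype_reference(
    seed: int,
    n_markers: int = 8,
    cell_types: tuple[str, ...] = ("leukocyte", "epithelial"),
) -> pd.DataFrame:
    """Synthetic cell-type reference profiles at marker CpGs.

    Returns a markers x cell-types DataFrame of mean betas at CpGs chosen to
    discriminate the types (half near-1 in leukocytes/near-0 in the others,
    half the reverse), standing in for a published marker panel. Marker probe
    ids are drawn from the same ``cg...`` namespace as the simulated cohorts
    (the first ``n_markers`` even-numbered probes), so cohort matrices
    contain them.
    """
    rng = np.random.default_rng(seed)
    markers = [f"cg{2 * (k + 1):08d}" for k in range(n_markers)]
    prof = np.zeros((n_markers, len(cell_types)))
    for k in range(n_markers):
        hi_type = k % len(cell_types)
        for t in range(len(cell_types)):
            prof[k, t] = rng.uniform(0.8, 0.95) if t == hi_type else rng.uniform(0.05, 0.2)
    return pd.DataFrame(prof, index=pd.Index(markers, name="probe_id"), columns=list(cell_types))
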