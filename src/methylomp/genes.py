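"""Cross-individual outlier intersection and promoter-level gene calls.

The outlier CpGs shared by all OMP individuals are split by direction
consistency: *consistently hyper* (above the upper fence in every OMP
individual), *consistently hypo*, and *mixed* (outlier in all, but in
different directions in different individuals). Only the consistent sets
feed gene calling.

A gene is called hypermethylated at its promoter when at least
``min_cpgs_hyper`` (default 3) of its promoter CpGs are consistent outliers
and at least ``min_frac`` (default 80%) of those outlier CpGs are hyper;
hypomethylated analogously with ``min_cpgs_hypo`` (default 5). The
asymmetric minima are the procedure's literal defaults and are configurable.
"Promoter" means the manifest region groups TSS200/TSS1500/5'UTR/1st exon by
default. The 80% fraction is taken over the gene's *outlier* promoter CpGs;
an alternative denominator (all promoter CpGs of the gene) is available
because the rule wording is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_io import DataValidationError, ProbeAnnotation, PROMOTER_GROUPS
from .omp import OutlierProfile

logger = logging.getLogger("methylomp")


@dataclass
class OutlierIntersection:
    """Outlier CpGs common to every OMP individual, split by direction."""

    common_probes: set[str]
    consistent_hyper: set[str]
    consistent_hypo: set[str]
    mixed: set[str]

    def directions(self) -> dict[str, str]:
        """Consistent probes only, probe -> 'hyper'/'hypo'."""
        out = {p: "hyper" for p in self.consistent_hyper}
        out.update({p: "hypo" for p in self.consistent_hypo})
        return out


@dataclass
class GeneCall:
    gene: str
    direction: str  # hyper | hypo
    n_promoter_cpgs_outlier: int
    n_promoter_cpgs_total: int
    frac_direction: float


@dataclass
class PromoterMap:
    """Per-gene promoter outlier CpGs with directions, plus totals."""

    probes_by_gene: dict[str, dict[str, str]]  # gene -> probe -> direction
    total_promoter_cpgs: dict[str, int]  # gene -> promoter CpGs in annotation


def intersect_outliers(
    profiles: Sequence[OutlierProfile], omp_ids: set[str]
) -> OutlierIntersection:
    """Intersect outlier CpG sets across the OMP individuals.

    The three direction classes partition the common set; their counts sum
    to the common count (mixed-direction CpGs explain any shortfall of
    hyper + hypo from the total).
    """
    if not omp_ids:
        raise DataValidationError("omp_ids is empty")
    by_id = {p.individual_id: p for p in profiles}
    missing = omp_ids - set(by_id)
    if missing:
        raise DataValidationError(f"profiles missing for individuals: {sorted(missing)}")
    picked = [by_id[i] for i in sorted(omp_ids)]
    common = set.intersection(*(set(p.hyper_probes | p.hypo_probes) for p in picked))
    hyper = set.intersection(*(set(p.hyper_probes) for p in picked)) & common
    hypo = set.intersection(*(set(p.hypo_probes) for p in picked)) & common
    mixed = common - hyper - hypo
    logger.info(
        "outlier intersection over %d individuals: %d common "
        "(%d hyper-consistent, %d hypo-consistent, %d mixed)",
        len(picked), len(common), len(hyper), len(hypo), len(mixed),
    )
    return OutlierIntersection(common, hyper, hypo, mixed)


def restrict_to_promoters(
    directed_probes: Mapping[str, str],
    ann: ProbeAnnotation,
    promoter_groups: Iterable[str] = PROMOTER_GROUPS,
) -> PromoterMap:
    """Map direction-consistent outlier CpGs onto gene promoters.

    A probe contributes to gene g iff one of its (gene, region) annotation
    pairs has gene = g and region in ``promoter_groups``; a probe annotated
    to several genes contributes to each gene whose pairing is a promoter
    pairing. Also tallies, per gene, the total promoter CpGs in the
    annotation (the alternative rule denominator).
    """
    groups = set(promoter_groups)
    probes_by_gene: dict[str, dict[str, str]] = {}
    totals: dict[str, int] = {}
    directed = dict(directed_probes)
    for pid, names, regions in zip(
        ann.df.index, ann.df["gene_names"], ann.df["gene_regions"]
    ):
        for g, r in zip(names, regions):
            if r not in groups:
                continue
            totals[g] = totals.get(g, 0) + 1
            if pid in directed:
                probes_by_gene.setdefault(g, {})[pid] = directed[pid]
    return PromoterMap(probes_by_gene, totals)


def call_genes(
    promoter_map: PromoterMap,
    min_cpgs_hyper: int = 3,
    min_cpgs_hypo: int = 5,
    min_frac: float = 0.8,
    denominator: str = "outlier",
) -> list[GeneCall]:
    """Apply the promoter hyper/hypomethylation rules gene by gene.

    ``denominator='outlier'`` (default) computes the direction fraction over
    the gene's outlier promoter CpGs; ``'all_promoter'`` uses all promoter
    CpGs of the gene. ``min_frac`` must exceed 0.5 so a gene can never be
    called in both directions. Calls are returned sorted by gene symbol.
    """
    if min_frac <= 0.5:
        raise DataValidationError("min_frac must be > 0.5 (direction would be ambiguous)")
    if denominator not in ("outlier", "all_promoter"):
        raise DataValidationError(f"unknown denominator {denominator!r}")
    calls: list[GeneCall] = []
    for gene in sorted(promoter_map.probes_by_gene):
        dirs = promoter_map.probes_by_gene[gene]
        n_out = len(dirs)
        n_total = promoter_map.total_promoter_cpgs.get(gene, n_out)
        n_hyper = sum(1 for d in dirs.values() if d == "hyper")
        n_hypo = n_out - n_hyper
        denom = n_out if denominator == "outlier" else n_total
        if denom == 0:
            continue
        if n_out >= min_cpgs_hyper and n_hyper / denom >= min_frac:
            calls.append(GeneCall(gene, "hyper", n_out, n_total, n_hyper / denom))
        elif n_out >= min_cpgs_hypo and n_hypo / denom >= min_frac:
            calls.append(GeneCall(gene, "hypo", n_out, n_total, n_hypo / denom))
    logger.info(
        "gene calls: %d hyper, %d hypo",
        sum(1 for c in calls if c.direction == "hyper"),
        sum(1 for c in calls if c.direction == "hypo"),
    )
    return calls


def export_gene_lists(calls: Sequence[GeneCall], outdir: str | Path) -> dict[str, Path]:
    """Write hyper/hypo gene lists (one symbol per line) and a full TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hyper": outdir / "genes_hyper.txt",
        "hypo": outdir / "genes_hypo.txt",
        "calls": outdir / "gene_calls.tsv",
    }
    for direction in ("hyper", "hypo"):
        genes = sorted(c.gene for c in calls if c.direction == direction)
        with open(paths[direction], "w") as fh:
            for g in genes:
                fh.write(f"{g}\n")
        if not genes:
            logger.info("no %smethylated gene calls; wrote empty list", direction)
    df = pd.DataFrame(
        [
            {
                "gene": c.gene,
                "direction": c.direction,
                "n_promoter_cpgs_outlier": c.n_promoter_cpgs_outlier,
                "n_promoter_cpgs_total": c.n_promoter_cpgs_total,
                "frac_direction": c.frac_direction,
            }
            for c in sorted(calls, key=lambda c: c.gene)
        ],
        columns=[
            "gene", "direction", "n_promoter_cpgs_outlier",
            "n_promoter_cpgs_total", "frac_direction",
        ],
    )
    df.to_csv(paths["calls"], sep="\t", index=False)
    return paths


def read_gene_calls(path: str | Path) -> list[GeneCall]:
    """Round-trip reader for the gene-call TSV written by export_gene_lists."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneCall(
            gene=str(r.gene),
            direction=str(r.direction),
            n_promoter_cpgs_outlier=int(r.n_promoter_cpgs_outlier),
            n_promoter_cpgs_total=int(r.n_promoter_cpgs_total),
            frac_direction=float(r.frac_direction),
        )
        for r in df.itertuples()
    ]
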