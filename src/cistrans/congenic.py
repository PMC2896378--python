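"""Trans-regulation estimates from congenic-line comparisons.

A congenic line carries a small donor-strain interval introgressed into a
host genetic background.  In a congenic-versus-control comparison the two
lines differ genetically only inside that interval, so any differentially
expressed gene whose TSS lies outside the interval must be trans regulated
by it.  The fraction of DE genes outside the interval is therefore a
direct estimate of the trans-regulated fraction.

The module also quantifies how background-specific those trans effects
are, by intersecting the congenic DE genes outside the interval with the
genes DE between the parental strains in the same tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval
from .stats_core import ContingencyTable2x2, fisher_exact

logger = logging.getLogger("cistrans")

__all__ = [
    "CongenicDesign",
    "TransEstimate",
    "interval_membership",
    "trans_fraction",
    "interval_enrichment_by_stratum",
    "background_dependence",
]


@dataclass(frozen=True)
class CongenicDesign:
    """A congenic line: the introgressed interval and the strains involved."""

    line_name: str
    interval: GenomicInterval
    donor: str
    host: str


@dataclass(frozen=True)
class TransEstimate:
    """Inside/outside split of congenic DE genes.

    ``trans_fraction`` is ``n_outside / n_de`` (None when no gene is DE).
    """

    n_de: int
    n_inside: int
    n_outside: int
    trans_fraction: float | None

    def __post_init__(self) -> None:
        if self.n_inside + self.n_outside != self.n_de:
            raise ValueError("inside + outside must equal total DE count")


def interval_membership(
    gene: pd.Series | dict, interval: GenomicInterval
) -> bool:
    """True if the gene's TSS falls inside the (half-open) interval.

    Genes are located by TSS alone, so a gene straddling the interval
    boundary follows its TSS.
    """
    return interval.contains(str(gene["chromosome"]), int(gene["tss"]))


def _membership_mask(genes: pd.DataFrame, interval: GenomicInterval) -> np.ndarray:
    return (
        (genes["chromosome"].to_numpy() == interval.chromosome)
        & (genes["tss"].to_numpy() >= interval.start)
        & (genes["tss"].to_numpy() < interval.end)
    ).astype(bool)


def trans_fraction(
    de_genes,
    genes: pd.DataFrame,
    design: CongenicDesign,
) -> TransEstimate:
    """Classify congenic DE genes by interval membership.

    ``de_genes`` is any iterable of gene ids called DE in the
    congenic-versus-control comparison.  Genes absent from the annotation
    raise an error, since membership cannot be determined for them.
    """
    de_set = set(de_genes)
    sub = genes[genes["gene_id"].isin(de_set)]
    missing = de_set - set(sub["gene_id"])
    if missing:
        raise ValueError(f"{len(missing)} DE genes missing from annotation")
    inside = _membership_mask(sub, design.interval)
    n_de = len(sub)
    n_inside = int(inside.sum())
    n_outside = n_de - n_inside
    frac = n_outside / n_de if n_de else None
    if frac is None:
        logger.warning("trans_fraction: no DE genes, fraction undefined")
    else:
        logger.info(
            "trans_fraction[%s]: %d of %d DE genes outside the interval (%.1f%%)",
            design.line_name,
            n_outside,
            n_de,
            100 * frac,
        )
    return TransEstimate(n_de, n_inside, n_outside, frac)


def interval_enrichment_by_stratum(
    de_strict,
    de_loose_only,
    genes: pd.DataFrame,
    design: CongenicDesign,
) -> tuple[ContingencyTable2x2, float]:
    """Is the strict-confidence DE stratum enriched inside the interval?

    ``de_strict`` holds genes DE at the stringent pplr threshold and
    ``de_loose_only`` genes DE only at the relaxed threshold; the strata
    must be disjoint.  Rows of the 2x2 are the strata, the outcome is
    interval membership; returns the table and the two-sided Fisher p
    (p = 1 when a margin is degenerate).  Enrichment of the strict stratum
    inside the interval is the expected signature of cis regulation by the
    introgressed alleles.
    """
    strict = set(de_strict)
    loose = set(de_loose_only)
    overlap = strict & loose
    if overlap:
        raise ValueError(f"strata overlap on {len(overlap)} genes")

    def _split(gene_set):
        sub = genes[genes["gene_id"].isin(gene_set)]
        if len(sub) != len(gene_set):
            raise ValueError("DE genes missing from annotation")
        inside = _membership_mask(sub, design.interval)
        return int(inside.sum()), int((~inside).sum())

    a, b = _split(strict)
    c, d = _split(loose)
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact(table)


def background_dependence(
    parental_de: dict[str, set],
    congenic_de: dict[str, set],
    genes: pd.DataFrame,
    design: CongenicDesign,
) -> pd.DataFrame:
    """Overlap of congenic trans DE genes with parental DE genes, per tissue.

    For each tissue shared by the two dicts (a mismatch in tissue labels is
    an error), the congenic DE genes outside the interval are intersected
    with the parental DE genes.  Under independence the expected overlap is
    ``n_congenic_outside * (parental DE rate among genes outside the
    interval)``; the hypergeometric tail probabilities quantify depletion
    (``p_depleted``, overlap at or below the observed) and enrichment
    (``p_enriched``).  If the trans effects are buffered by genetic
    background, the observed overlap falls at or below chance.
    """
    if set(parental_de) != set(congenic_de):
        raise ValueError(
            f"tissue labels differ: {sorted(parental_de)} vs {sorted(congenic_de)}"
        )
    outside_mask = ~_membership_mask(genes, design.interval)
    outside_genes = set(genes["gene_id"].to_numpy()[outside_mask])
    n_pop = len(outside_genes)

    rows = []
    for tissue in sorted(parental_de):
        cong_out = set(congenic_de[tissue]) & outside_genes
        par_out = set(parental_de[tissue]) & outside_genes
        overlap = len(cong_out & par_out)
        n_draw = len(cong_out)
        n_success = len(par_out)
        expected = n_draw * n_success / n_pop if n_pop else float("nan")
        if n_pop and n_draw:
            hg = stats.hypergeom(n_pop, n_success, n_draw)
            p_dep = float(hg.cdf(overlap))
            p_enr = float(hg.sf(overlap - 1))
        else:
            p_dep = p_enr = float("nan")
        rows.append(
            {
                "tissue": tissue,
                "n_congenic_outside": n_draw,
                "n_parental_outside": n_success,
                "n_genes_outside": n_pop,
                "overlap": overlap,
                "expected_overlap": expected,
                "p_depleted": p_dep,
                "p_enriched": p_enr,
            }
        )
        logger.info(
            "background_dependence[%s/%s]: overlap %d (expected %.2f)",
            design.line_name,
            tissue,
            overlap,
            expected,
        )
    return pd.DataFrame(rows)
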