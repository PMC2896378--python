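"""End-to-end compositions of the pipeline stages.

These helpers wire the individual modules together for the two study
designs: the parental two-strain comparison (differential expression →
haplotype assignment → attribution and percentile scan) and the
congenic-line comparison (differential expression → interval split →
trans fraction, stratum enrichment and background dependence).  They are
what the command-line ``report`` subcommand and the acceptance script run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import attribution, cis_scan, congenic, diffexpr, haplotypes
from .io_formats import AnalysisConfig
from .synthetic_data import SimulatedDataset

logger = logging.getLogger("cistrans")

__all__ = ["ParentalResults", "CongenicResults", "run_parental_analysis", "run_congenic_analysis"]


@dataclass
class ParentalResults:
    """Everything the parental-strain analysis produces."""

    de_results: dict[str, pd.DataFrame]      # tissue -> per-gene results with flags
    de_calls: pd.DataFrame                   # gene x tissue strict DE booleans
    assignments: pd.DataFrame
    hap_flags: pd.DataFrame                  # gene_id, haplotype
    upstream_counts: pd.DataFrame
    attribution: dict[str, attribution.AttributionResult]
    breadth_table: object
    breadth_fisher_p: float
    scan: pd.DataFrame | None = None
    scan_tissue: str | None = None
    extras: dict = field(default_factory=dict)


def run_parental_analysis(
    dataset: SimulatedDataset,
    config: AnalysisConfig,
    scan_tissue: str | None = None,
    run_scan: bool = True,
) -> ParentalResults:
    """Run the full parental-strain pipeline on a dataset.

    Differential expression is computed per tissue (comparison strain vs
    reference), haplotypes are assigned from the SNP table and the
    attribution estimates, breadth contrast and (optionally) the pplr
    percentile scan in ``scan_tissue`` (default: first tissue) are
    computed.
    """
    design = dataset.design
    ref, alt = design.reference, design.alt_strain
    tissues = list(design.tissue_names)

    de_results: dict[str, pd.DataFrame] = {}
    calls = {}
    for tissue in tissues:
        res = diffexpr.compute_expression_results(
            dataset.expression[(alt, tissue)],
            dataset.expression[(ref, tissue)],
            condition_pair=f"{alt}_vs_{ref}:{tissue}",
        )
        res = diffexpr.add_de_flags(res, config)
        de_results[tissue] = res
        calls[tissue] = res.set_index("gene_id")["de_strict"]
    de_calls = pd.DataFrame(calls)

    assignments = haplotypes.assign_haplotypes(
        dataset.snps,
        dataset.blocks,
        reference=ref,
        threshold=config.haplotype_distance_threshold,
    )
    hap_flags = haplotypes.gene_haplotype_flags(
        dataset.genes, assignments, strain=alt, window=config.upstream_window
    )
    upstream_counts = haplotypes.count_upstream_snps(
        dataset.genes, dataset.snps, config.upstream_window, ref, alt
    )

    attrib = attribution.attribution_by_breadth(de_calls, hap_flags)
    breadth_table, breadth_p = attribution.breadth_enrichment_test(de_calls, hap_flags)

    scan = None
    tissue = scan_tissue or tissues[0]
    if run_scan:
        groups = cis_scan.rank_and_partition(de_results[tissue], config.n_percentiles)
        scan = cis_scan.percentile_scan(groups, upstream_counts, config)

    return ParentalResults(
        de_results=de_results,
        de_calls=de_calls,
        assignments=assignments,
        hap_flags=hap_flags,
        upstream_counts=upstream_counts,
        attribution=attrib,
        breadth_table=breadth_table,
        breadth_fisher_p=breadth_p,
        scan=scan,
        scan_tissue=tissue,
    )


@dataclass
class CongenicResults:
    """Everything the congenic-line analysis produces."""

    de_results: pd.DataFrame
    trans_estimate: congenic.TransEstimate
    stratum_table: object
    stratum_fisher_p: float
    background: pd.DataFrame


def run_congenic_analysis(
    dataset: SimulatedDataset,
    config: AnalysisConfig,
    parental: ParentalResults | None = None,
) -> CongenicResults:
    """Run the congenic pipeline: trans fraction, strata, background overlap."""
    if dataset.congenic_expression is None or dataset.congenic_design is None:
        raise ValueError("dataset has no congenic component")
    cdesign = dataset.congenic_design
    layout = dataset.congenic_layout()
    tissue = cdesign.tissue
    res = diffexpr.compute_expression_results(
        dataset.congenic_expression[(cdesign.test_line, tissue)],
        dataset.congenic_expression[(cdesign.control_line, tissue)],
        condition_pair=f"{cdesign.test_line}_vs_{cdesign.control_line}:{tissue}",
    )
    res = diffexpr.add_de_flags(res, config)

    de_strict = res.loc[res["de_strict"], "gene_id"]
    de_loose_only = res.loc[res["de_loose"] & ~res["de_strict"], "gene_id"]
    estimate = congenic.trans_fraction(de_strict, dataset.genes, layout)
    table, p = congenic.interval_enrichment_by_stratum(
        de_strict, de_loose_only, dataset.genes, layout
    )

    if parental is not None and tissue in parental.de_calls.columns:
        parental_sets = {
            tissue: set(parental.de_calls.index[parental.de_calls[tissue]])
        }
        congenic_sets = {tissue: set(de_strict)}
        background = congenic.background_dependence(
            parental_sets, congenic_sets, dataset.genes, layout
        )
    else:
        background = pd.DataFrame()

    return CongenicResults(
        de_results=res,
        trans_estimate=estimate,
        stratum_table=table,
        stratum_fisher_p=p,
        background=background,
    )
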