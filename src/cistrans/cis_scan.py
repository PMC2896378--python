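"""Percentile scan for association between upstream SNPs and expression.

Genes are ranked by pplr and divided into ``n_percentiles`` equal groups.
For each group and each SNP-count threshold ``s`` in 1..max, a 2x2 table
compares genes with at least ``s`` upstream SNPs against genes with none
(genes with 1..s-1 SNPs are excluded from that test), inside the group
versus outside it.  The chi-square p-values are Bonferroni-corrected over
the whole family of ``n_percentiles * max_snp_threshold`` tests.  With cis
structure present, only the lowest-pplr percentiles show a significant
excess of upstream SNPs.

The module also provides the SNP-dose relative-risk curve (risk of being
differentially expressed given >= n upstream SNPs, against genes with
none) and the SNP-under-probe confounder check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import (
    ContingencyTable2x2,
    RelativeRisk,
    chi2_2x2_arrays,
    relative_risk,
)

logger = logging.getLogger("cistrans")

__all__ = [
    "PercentileGroup",
    "ProbeSnpCheck",
    "rank_and_partition",
    "percentile_scan",
    "relative_risk_curve",
    "probe_snp_check",
]


@dataclass(frozen=True)
class PercentileGroup:
    """One rank group of the pplr distribution (1-based index)."""

    index: int
    pplr_low: float
    pplr_high: float
    genes: tuple[str, ...]


def rank_and_partition(results: pd.DataFrame, n_groups: int) -> list[PercentileGroup]:
    """Rank genes by pplr and split into ``n_groups`` near-equal groups.

    Ties are broken by gene id, so the partition is deterministic.  When
    the gene count is not divisible by ``n_groups`` the remainder is spread
    one gene per group starting from the first (lowest-pplr) group, so
    group sizes differ by at most one.
    """
    n = len(results)
    if n < n_groups:
        raise ValueError(f"cannot split {n} genes into {n_groups} groups")
    ranked = results.sort_values(["pplr", "gene_id"], kind="mergesort")
    base, extra = divmod(n, n_groups)
    sizes = [base + 1 if i < extra else base for i in range(n_groups)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    genes = ranked["gene_id"].to_numpy()
    pplr = ranked["pplr"].to_numpy()
    groups = []
    for i in range(n_groups):
        lo, hi = bounds[i], bounds[i + 1]
        groups.append(
            PercentileGroup(
                index=i + 1,
                pplr_low=float(pplr[lo]),
                pplr_high=float(pplr[hi - 1]),
                genes=tuple(genes[lo:hi]),
            )
        )
    return groups


def percentile_scan(
    groups: list[PercentileGroup],
    upstream_counts: pd.DataFrame,
    config,
) -> pd.DataFrame:
    """Chi-square scan of percentile membership against upstream SNP dose.

    For every group ``g`` and threshold ``s`` in 1..``max_snp_threshold``::

                       >= s SNPs   0 SNPs
        in group g         a          b
        not in group       c          d

    Tables with an empty margin, or with an expected cell below
    ``config.min_expected`` (where the chi-square approximation is not
    trustworthy), are flagged untestable and never significant.  The
    Bonferroni threshold is ``alpha / (n_percentiles * max_snp_threshold)``.

    Returns one row per (percentile, snp_threshold) with the table counts,
    statistic, p-value and flags.
    """
    counts = upstream_counts.set_index("gene_id")["n_snps"]
    max_s = config.max_snp_threshold
    n_tests = config.n_percentiles * max_s
    bonferroni_alpha = config.alpha / n_tests

    all_genes = [g for grp in groups for g in grp.genes]
    missing = set(all_genes) - set(counts.index)
    if missing:
        raise ValueError(f"{len(missing)} genes lack upstream SNP counts")
    n_snps = counts.loc[all_genes].to_numpy()
    group_idx = np.repeat([grp.index for grp in groups], [len(grp.genes) for grp in groups])

    # per-group histograms of SNP counts, clipped at max_s
    clipped = np.minimum(n_snps, max_s)
    n_groups = len(groups)
    hist = np.zeros((n_groups + 1, max_s + 1), dtype=np.int64)
    np.add.at(hist, (group_idx, clipped), 1)
    total_hist = hist.sum(axis=0)
    # genes with >= s SNPs per group, via reversed cumulative sums
    ge = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]  # ge[g, s] = genes in g with >= s
    ge_tot = np.cumsum(total_hist[::-1])[::-1]

    rows = []
    for grp in groups:
        g = grp.index
        for s in range(1, max_s + 1):
            a = int(ge[g, s])
            b = int(hist[g, 0])
            c = int(ge_tot[s] - a)
            d = int(total_hist[0] - b)
            rows.append((g, s, a, b, c, d))
    scan = pd.DataFrame(
        rows, columns=["percentile", "snp_threshold", "a", "b", "c", "d"]
    )
    stat, p = chi2_2x2_arrays(
        scan["a"], scan["b"], scan["c"], scan["d"], yates=False
    )
    # expected count of the smallest cell under independence
    n = scan[["a", "b", "c", "d"]].sum(axis=1).to_numpy(dtype=float)
    r_min = np.minimum(scan["a"] + scan["b"], scan["c"] + scan["d"]).to_numpy(dtype=float)
    c_min = np.minimum(scan["a"] + scan["c"], scan["b"] + scan["d"]).to_numpy(dtype=float)
    min_expected = np.where(n > 0, r_min * c_min / np.where(n > 0, n, 1.0), 0.0)
    testable = ~np.isnan(stat) & (min_expected >= config.min_expected)
    scan["chi2_stat"] = stat
    scan["chi2_p"] = p
    scan["min_expected"] = min_expected
    scan["testable"] = testable
    scan["significant_after_bonferroni"] = testable & (p < bonferroni_alpha)
    logger.info(
        "percentile_scan: %d tests (%d testable), %d significant at "
        "family-wise alpha %g",
        len(scan),
        int(testable.sum()),
        int(scan["significant_after_bonferroni"].sum()),
        config.alpha,
    )
    return scan


def relative_risk_curve(
    results: pd.DataFrame,
    upstream_counts: pd.DataFrame,
    pplr_cutoff: float,
    max_n: int = 10,
    lfc_threshold: float | None = None,
    comparator: str = "zero",
) -> tuple[pd.DataFrame, float]:
    """Relative risk of differential expression given >= n upstream SNPs.

    The outcome is ``pplr < pplr_cutoff`` (optionally also requiring
    ``|log2_ratio| > lfc_threshold``).  For each n in 1..``max_n`` the
    exposed group is genes with >= n SNPs; the comparator is genes with no
    upstream SNP (``comparator="zero"``, the default) or genes with fewer
    than n (``comparator="fewer"``).

    Returns the per-n table (n, counts, rr, ci bounds, defined) and the
    Pearson correlation r between n and rr over the defined points (NaN
    with fewer than two defined points).
    """
    if comparator not in ("zero", "fewer"):
        raise ValueError(f"unknown comparator {comparator!r}")
    merged = results.merge(upstream_counts[["gene_id", "n_snps"]], on="gene_id")
    de = merged["pplr"].to_numpy() < pplr_cutoff
    if lfc_threshold is not None:
        de &= merged["log2_ratio"].abs().to_numpy() > lfc_threshold
    n_snps = merged["n_snps"].to_numpy()

    rows = []
    for n in range(1, max_n + 1):
        exposed = n_snps >= n
        control = n_snps == 0 if comparator == "zero" else n_snps < n
        a = int((exposed & de).sum())
        b = int((exposed & ~de).sum())
        c = int((control & de).sum())
        d = int((control & ~de).sum())
        try:
            rr = relative_risk(ContingencyTable2x2(a, b, c, d))
        except ValueError:
            rr = RelativeRisk(np.nan, np.nan, np.nan, defined=False)
        rows.append((n, a, b, c, d, rr.rr, rr.ci_low, rr.ci_high, rr.defined))
    curve = pd.DataFrame(
        rows,
        columns=["n", "a", "b", "c", "d", "rr", "ci_low", "ci_high", "defined"],
    )
    ok = curve["defined"].to_numpy(dtype=bool)
    if ok.sum() >= 2 and curve.loc[ok, "rr"].nunique() > 1:
        r = float(np.corrcoef(curve.loc[ok, "n"], curve.loc[ok, "rr"])[0, 1])
    else:
        r = float("nan")
    return curve, r


@dataclass
class ProbeSnpCheck:
    """Outcome of the SNP-under-probe confounder check.

    A SNP falling inside a probe's 25-mer interval can depress hybridisation
    signal for the non-reference strain (probes are designed against the
    reference sequence) and masquerade as differential expression.  The
    check asks whether DE genes with probe SNPs are biased towards
    under-expression in the non-reference strain.
    """

    n_de: int
    n_de_with_probe_snps: int
    n_excluded_no_probes: int
    table: ContingencyTable2x2 | None
    chi2_stat: float
    chi2_p: float
    directional_excess: float  # (n_over - n_under) / n_under in the non-ref strain
    n_over: int = 0
    n_under: int = 0
    testable: bool = True
    notes: list[str] = field(default_factory=list)


def probe_snp_check(
    probes: pd.DataFrame,
    snps: pd.DataFrame,
    de_results: pd.DataFrame,
    reference: str,
    strain: str,
) -> ProbeSnpCheck:
    """Check whether SNPs under probes confound the DE calls.

    ``de_results`` must contain only the differentially expressed genes and
    carry ``log2_ratio`` oriented as non-reference minus reference (positive
    = over-expressed in the non-reference ``strain``).  A gene is flagged
    when any informative SNP (reference vs ``strain``) falls inside any of
    its probe intervals.  The 2x2 tests probe-SNP presence against
    under-/over-expression in ``strain``; the directional excess reports
    how many more DE genes are over- than under-expressed in ``strain``.
    """
    a = snps[reference].to_numpy(dtype="U1")
    b = snps[strain].to_numpy(dtype="U1")
    informative = (a != b) & (a != "N") & (b != "N")
    inf_chrom = snps["chromosome"].to_numpy()[informative]
    inf_pos = snps["position"].to_numpy()[informative]

    hit_genes: set[str] = set()
    for chrom, grp in probes.groupby("chromosome", sort=False):
        pos = np.sort(inf_pos[inf_chrom == chrom])
        if len(pos) == 0:
            continue
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        hit_genes.update(grp["gene_id"].to_numpy()[hi > lo])

    genes_with_probes = set(probes["gene_id"])
    de = de_results[de_results["gene_id"].isin(genes_with_probes)].copy()
    n_excluded = len(de_results) - len(de)
    notes = []
    if n_excluded:
        notes.append(f"{n_excluded} DE genes without probe coordinates excluded")
        logger.info("probe_snp_check: %s", notes[-1])

    has_snp = de["gene_id"].isin(hit_genes).to_numpy()
    over = de["log2_ratio"].to_numpy() > 0  # over-expressed in non-reference strain
    n_over, n_under = int(over.sum()), int((~over).sum())
    tbl_counts = (
        int((has_snp & ~over).sum()),  # probe SNP, under-expressed
        int((has_snp & over).sum()),
        int((~has_snp & ~over).sum()),
        int((~has_snp & over).sum()),
    )
    directional_excess = (n_over - n_under) / n_under if n_under else float("nan")
    try:
        table = ContingencyTable2x2(*tbl_counts)
        stat_arr, p_arr = chi2_2x2_arrays(*[np.array([x]) for x in tbl_counts])
        stat, p = float(stat_arr[0]), float(p_arr[0])
        testable = not np.isnan(stat)
    except ValueError:
        table, stat, p, testable = None, float("nan"), float("nan"), False
    if not testable:
        notes.append("degenerate table: chi-square untestable")
    return ProbeSnpCheck(
        n_de=len(de),
        n_de_with_probe_snps=int(has_snp.sum()),
        n_excluded_no_probes=n_excluded,
        table=table,
        chi2_stat=stat,
        chi2_p=p,
        directional_excess=float(directional_excess),
        n_over=n_over,
        n_under=n_under,
        testable=testable,
        notes=notes,
    )
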