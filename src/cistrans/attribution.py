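"""Attributable cis fraction of differential expression.

The estimator compares the rate at which differentially expressed genes
sit on a different upstream haplotype between the two strains against the
genome-wide baseline rate.  With

- ``N_h``  : DE genes with haplotype data,
- ``N_hd`` : DE genes on different haplotypes,
- ``G_d``  : genes on different haplotypes (genome-wide),
- ``E``    : genes with haplotype data,

the observed rate is ``o = N_hd / N_h`` and the baseline is
``b = G_d / E``.  The attributable fraction is the excess over baseline::

    AF = (o - b) / (1 - b)

which is the standard attributable-fraction estimator: the proportion of
DE genes whose differential expression is attributable to the haplotype
difference (putatively cis regulation), assuming genes on the same
haplotype are never cis regulated through that window.  For example an
observed rate of 55% over a 30% baseline gives AF = 0.25/0.70 ~ 36%.

A simpler conditional ratio ``N_hd / G_d`` (the probability that a
different-haplotype gene is differentially expressed) is also reported for
transparency; it answers a different question and is not the attributable
fraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import ContingencyTable2x2, chi2_2x2, fisher_exact

logger = logging.getLogger("cistrans")

__all__ = [
    "AttributionInputs",
    "AttributionResult",
    "attributable_cis_fraction",
    "assemble_inputs",
    "attribution_by_breadth",
    "breadth_enrichment_test",
]


@dataclass(frozen=True)
class AttributionInputs:
    """The four counts the attribution estimator needs."""

    N_h: int   # DE genes with haplotype data
    N_hd: int  # DE genes on different haplotypes
    G_d: int   # genes on different haplotypes
    E: int     # genes with haplotype data

    def __post_init__(self) -> None:
        if min(self.N_h, self.N_hd, self.G_d, self.E) < 0:
            raise ValueError("counts must be non-negative")
        if not (self.N_hd <= self.N_h <= self.E):
            raise ValueError(f"require N_hd <= N_h <= E, got {self}")
        if not (self.N_hd <= self.G_d <= self.E):
            raise ValueError(f"require N_hd <= G_d <= E, got {self}")
        if self.N_h - self.N_hd > self.E - self.G_d:
            # DE genes on the same haplotype cannot outnumber all same-
            # haplotype genes: the counts must form a valid 2x2 table
            raise ValueError(f"require N_h - N_hd <= E - G_d, got {self}")


@dataclass(frozen=True)
class AttributionResult:
    """Attribution estimate with its inputs and the excess chi-square test."""

    inputs: AttributionInputs
    frac_de_on_diff_hap: float   # o = N_hd / N_h
    baseline: float              # b = G_d / E
    attributable_fraction: float  # (o - b) / (1 - b)
    conditional_de_rate: float    # N_hd / G_d
    excess_chi2: float
    excess_chi2_p: float


def attributable_cis_fraction(inputs: AttributionInputs) -> AttributionResult:
    """Estimate the fraction of DE genes attributable to haplotype difference.

    Raises ``ValueError`` when ``N_h == 0`` (no DE genes to attribute) or
    ``G_d == E`` (baseline 1: every gene differs, the excess is undefined).
    The accompanying chi-square tests the {DE, non-DE} x {different, same
    haplotype} table for an excess of different-haplotype genes among the
    DE set.
    """
    if inputs.N_h == 0:
        raise ValueError("no differentially expressed genes with haplotype data")
    if inputs.G_d == inputs.E:
        raise ValueError("baseline is 1 (G_d == E): attributable fraction undefined")
    o = inputs.N_hd / inputs.N_h
    b = inputs.G_d / inputs.E
    af = (o - b) / (1.0 - b)
    table = ContingencyTable2x2(
        a=inputs.N_hd,
        b=inputs.N_h - inputs.N_hd,
        c=inputs.G_d - inputs.N_hd,
        d=(inputs.E - inputs.N_h) - (inputs.G_d - inputs.N_hd),
    )
    try:
        stat, p = chi2_2x2(table)
    except ValueError:
        stat, p = float("nan"), float("nan")
    return AttributionResult(
        inputs=inputs,
        frac_de_on_diff_hap=o,
        baseline=b,
        attributable_fraction=af,
        conditional_de_rate=inputs.N_hd / inputs.G_d if inputs.G_d else float("nan"),
        excess_chi2=stat,
        excess_chi2_p=p,
    )


def assemble_inputs(
    de_genes: pd.Series | np.ndarray | set,
    hap_flags: pd.DataFrame,
) -> AttributionInputs:
    """Build :class:`AttributionInputs` from a DE gene set and haplotype flags.

    ``hap_flags`` has columns ``gene_id`` and ``haplotype``
    ("different"/"same"); genes without haplotype data are simply absent
    from it, so the restriction to genes with haplotype data happens here.
    """
    de_set = set(de_genes)
    diff = hap_flags["haplotype"].to_numpy() == "different"
    is_de = hap_flags["gene_id"].isin(de_set).to_numpy()
    return AttributionInputs(
        N_h=int(is_de.sum()),
        N_hd=int((is_de & diff).sum()),
        G_d=int(diff.sum()),
        E=len(hap_flags),
    )


def attribution_by_breadth(
    de_calls: pd.DataFrame,
    hap_flags: pd.DataFrame,
    mode: str = "exactly",
) -> dict[str, AttributionResult]:
    """Attribution per tissue and per tissue-breadth class.

    ``de_calls`` is a boolean gene x tissue DataFrame (index gene_id).
    Classes:

    - each single tissue (genes DE in that tissue);
    - ``any``: genes DE in at least one tissue (the headline class);
    - ``breadth_k`` for k = 1..T: genes DE in exactly k tissues
      (``mode="exactly"``, the per-combination reading of the breadth
      classes) or at least k (``mode="at_least"``).  For k strictly between
      1 and T the class estimate is the mean of the per-combination
      attributable fractions, and the combination results are included
      under ``breadth_k:<t1>&<t2>`` keys.

    Empty classes are omitted with a warning.
    """
    if mode not in ("exactly", "at_least"):
        raise ValueError(f"unknown mode {mode!r}")
    de = de_calls.astype(bool)
    tissues = list(de.columns)
    results: dict[str, AttributionResult] = {}

    def _try(key: str, genes) -> AttributionResult | None:
        try:
            res = attributable_cis_fraction(assemble_inputs(genes, hap_flags))
        except ValueError as exc:
            logger.warning("attribution_by_breadth: class %s omitted (%s)", key, exc)
            return None
        results[key] = res
        return res

    for t in tissues:
        _try(t, de.index[de[t]])
    _try("any", de.index[de.any(axis=1)])  # DE in at least one tissue

    for k in range(1, len(tissues) + 1):
        combos = list(itertools.combinations(tissues, k))
        combo_afs = []
        for combo in combos:
            mask = de[list(combo)].all(axis=1)
            if mode == "exactly":
                for other in tissues:
                    if other not in combo:
                        mask &= ~de[other]
            key = f"breadth_{k}:{'&'.join(combo)}" if len(combos) > 1 else f"breadth_{k}"
            res = _try(key, de.index[mask])
            if res is not None:
                combo_afs.append(res)
        if len(combos) > 1 and combo_afs:
            # class summary: pooled counts plus the mean of per-combination AFs
            pooled = AttributionInputs(
                N_h=sum(r.inputs.N_h for r in combo_afs),
                N_hd=sum(r.inputs.N_hd for r in combo_afs),
                G_d=combo_afs[0].inputs.G_d,
                E=combo_afs[0].inputs.E,
            )
            base = attributable_cis_fraction(pooled)
            results[f"breadth_{k}"] = AttributionResult(
                inputs=pooled,
                frac_de_on_diff_hap=float(
                    np.mean([r.frac_de_on_diff_hap for r in combo_afs])
                ),
                baseline=base.baseline,
                attributable_fraction=float(
                    np.mean([r.attributable_fraction for r in combo_afs])
                ),
                conditional_de_rate=base.conditional_de_rate,
                excess_chi2=base.excess_chi2,
                excess_chi2_p=base.excess_chi2_p,
            )
    return results


def breadth_enrichment_test(
    de_calls: pd.DataFrame,
    hap_flags: pd.DataFrame,
) -> tuple[ContingencyTable2x2, float]:
    """Are different-haplotype DE genes more often DE in every tissue?

    Among genes DE in at least one tissue (and with haplotype data), the
    2x2 table crosses haplotype (different/same) with being DE in all
    tissues.  Returns the table and the two-sided Fisher p.  With a
    degenerate margin the Fisher p is 1 by construction.
    """
    de = de_calls.astype(bool)
    breadth = de.sum(axis=1)
    flags = hap_flags.set_index("gene_id")["haplotype"]
    common = de.index.intersection(flags.index)
    genes = common[breadth.loc[common] >= 1]
    diff = flags.loc[genes] == "different"
    in_all = breadth.loc[genes] == len(de.columns)
    table = ContingencyTable2x2(
        a=int((diff & in_all).sum()),
        b=int((diff & ~in_all).sum()),
        c=int((~diff & in_all).sum()),
        d=int((~diff & ~in_all).sum()),
    )
    return table, fisher_exact(table)
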