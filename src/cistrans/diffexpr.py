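"""Replicate-level differential-expression confidence (PPLR surrogate).

The confidence statistic is the probability of a positive log-ratio
(PPLR): the posterior probability, under a normal model with common
unknown variance and a flat reference prior, that the true log2 difference
between two conditions is positive.  That posterior is a scaled Student-t,
so PPLR is a one-sided t-tail on the replicate means.  Values near 0 or 1
mark confident differential expression in either direction; 0.5 means no
evidence.  For ranking we use ``pplr = min(PPLR, 1 - PPLR)``, which lives
in (0, 0.5] and behaves like a one-sided p-value.

This is a replicate-level surrogate for probe-level PPLR models: it sees
only per-replicate log2 summaries, not probe-level measurement error.

A gene is called differentially expressed when ``|log2 ratio| >
lfc_threshold`` and ``pplr < pplr_threshold`` (both strict).
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cistrans")

__all__ = [
    "pplr_surrogate",
    "pplr_surrogate_matrix",
    "compute_expression_results",
    "call_de",
    "add_de_flags",
    "tissue_breadth",
]


def pplr_surrogate_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise (log2_ratio, PPLR) for replicate matrices ``a`` and ``b``.

    ``a`` and ``b`` are (genes x replicates) arrays of log2 expression with
    at least two replicates each.  log2_ratio = mean(a) - mean(b); PPLR is
    the posterior probability that the underlying difference is positive
    under a pooled-variance normal model, i.e. the CDF at the two-sample
    t statistic with ``na + nb - 2`` degrees of freedom.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 replicates per condition, got {na} and {nb}")
    if a.shape[0] != b.shape[0]:
        raise ValueError("replicate matrices have different numbers of genes")
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    df = na + nb - 2
    se = np.sqrt(ss / df * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.inf * np.sign(diff))
    # zero pooled variance and zero difference: no evidence either way
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    pplr_pos = stats.t.cdf(t, df=df)
    return diff, pplr_pos


def pplr_surrogate(
    replicates_a: Sequence[float], replicates_b: Sequence[float]
) -> tuple[float, float]:
    """Scalar convenience wrapper: (log2_ratio, PPLR) for one gene."""
    lfc, pplr_pos = pplr_surrogate_matrix(
        np.asarray(replicates_a, dtype=float)[None, :],
        np.asarray(replicates_b, dtype=float)[None, :],
    )
    return float(lfc[0]), float(pplr_pos[0])


def compute_expression_results(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    condition_pair: str = "a_vs_b",
) -> pd.DataFrame:
    """Per-gene expression summary for two replicate expression tables.

    Tables must share their gene_id sets; replicate counts may differ.
    Returns columns ``gene_id, condition_pair, log2_ratio, PPLR, pplr``.
    """
    b = expr_b.set_index("gene_id")
    try:
        b = b.loc[expr_a["gene_id"]]
    except KeyError as exc:
        raise ValueError(f"gene sets differ between conditions: {exc}") from exc
    rep_a = [c for c in expr_a.columns if c.startswith("rep_")]
    rep_b = [c for c in b.columns if c.startswith("rep_")]
    lfc, pplr_pos = pplr_surrogate_matrix(
        expr_a[rep_a].to_numpy(), b[rep_b].to_numpy()
    )
    return pd.DataFrame(
        {
            "gene_id": expr_a["gene_id"].to_numpy(),
            "condition_pair": condition_pair,
            "log2_ratio": lfc,
            "PPLR": pplr_pos,
            "pplr": np.minimum(pplr_pos, 1.0 - pplr_pos),
        }
    )


def call_de(log2_ratio: float, pplr: float, lfc_threshold: float, pplr_threshold: float) -> bool:
    """Differential-expression rule: |lfc| > threshold AND pplr < threshold.

    Both comparisons are strict, so a gene sitting exactly on either
    boundary is not called.
    """
    return bool(abs(log2_ratio) > lfc_threshold and pplr < pplr_threshold)


def add_de_flags(results: pd.DataFrame, config) -> pd.DataFrame:
    """Append ``de_strict``/``de_loose`` flags using the config thresholds."""
    out = results.copy()
    big = out["log2_ratio"].abs() > config.lfc_threshold
    out["de_strict"] = big & (out["pplr"] < config.pplr_strict)
    out["de_loose"] = big & (out["pplr"] < config.pplr_loose)
    logger.info(
        "add_de_flags: %d of %d genes DE at pplr < %g (%d at pplr < %g)",
        int(out["de_strict"].sum()),
        len(out),
        config.pplr_strict,
        int(out["de_loose"].sum()),
        config.pplr_loose,
    )
    return out


def tissue_breadth(
    de_calls: pd.DataFrame,
) -> tuple[pd.Series, dict[tuple[str, ...], int]]:
    """Per-gene tissue breadth and Venn-region counts of DE calls.

    ``de_calls`` is a boolean DataFrame indexed by gene with one column per
    tissue.  Returns the per-gene count of tissues in which the gene is DE,
    and a dict mapping each non-empty tissue combination (sorted tuple) to
    the number of genes DE in exactly those tissues.  The Venn regions
    partition the DE genes, so their counts sum to the number of genes DE
    in at least one tissue.
    """
    de = de_calls.astype(bool)
    breadth = de.sum(axis=1)
    tissues = list(de.columns)
    venn: dict[tuple[str, ...], int] = {}
    for k in range(1, len(tissues) + 1):
        for combo in itertools.combinations(tissues, k):
            mask = de[list(combo)].all(axis=1)
            for other in tissues:
                if other not in combo:
                    mask &= ~de[other]
            venn[tuple(combo)] = int(mask.sum())
    return breadth, venn
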