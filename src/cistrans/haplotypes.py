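"""Haplotype-block allele assignment and upstream SNP counting.

Strains are assigned to haplotype alleles block by block: within each block
the Jukes-Cantor distance between a strain and the reference strain is
computed from the aligned SNP alleles (pairwise deletion of missing sites),
and strains closer than a distance threshold carry the same allele as the
reference.  The reference strain in the motivating design is C57BL/6 with
A/J as the comparison strain, but any strain column may play either role.

A gene's regulatory haplotype is anchored to the window immediately
upstream of its TSS: the gene is "different" if that window overlaps any
block where the strain carries a different allele from the reference.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cistrans")

__all__ = [
    "UndefinedDistanceError",
    "SaturationError",
    "jukes_cantor_distance",
    "assign_haplotypes",
    "count_upstream_snps",
    "upstream_windows",
    "gene_haplotype_flags",
]

# Jukes-Cantor saturates when the raw mismatch proportion reaches 3/4
_SATURATION_P = 0.75


class UndefinedDistanceError(ValueError):
    """No comparable (non-missing) sites between the two allele vectors."""


class SaturationError(ValueError):
    """Mismatch proportion >= 3/4: the Jukes-Cantor distance diverges."""


def jukes_cantor_distance(alleles_a: Sequence[str], alleles_b: Sequence[str]) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p) between allele vectors.

    ``p`` is the proportion of differing sites among sites where neither
    vector is ``N`` (pairwise deletion).  Raises
    :class:`UndefinedDistanceError` with zero comparable sites and
    :class:`SaturationError` when ``p >= 0.75``.
    """
    a = np.asarray(alleles_a, dtype="U1")
    b = np.asarray(alleles_b, dtype="U1")
    if a.shape != b.shape:
        raise ValueError(f"allele vectors differ in length: {a.shape} vs {b.shape}")
    comparable = (a != "N") & (b != "N")
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable sites (all missing)")
    p = float((a[comparable] != b[comparable]).sum()) / n_comp
    if p >= _SATURATION_P:
        raise SaturationError(f"mismatch proportion {p:.3f} >= 0.75, distance saturated")
    return float(-0.75 * np.log1p(-(4.0 / 3.0) * p))


def _jc_from_p(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def assign_haplotypes(
    snps: pd.DataFrame,
    blocks: pd.DataFrame,
    reference: str,
    threshold: float = 0.2,
    strains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each strain to a haplotype allele per block by JC distance.

    Parameters
    ----------
    snps
        SNP table (0-based positions, one allele column per strain).
    blocks
        Block table; blocks must not overlap within a chromosome.
    reference
        Strain column used as the reference allele.
    threshold
        Strains at JC distance strictly below this carry the reference
        allele (``same_as_reference`` True).

    Returns
    -------
    DataFrame with one row per (block, non-reference strain): columns
    ``block_id, chromosome, start, end, strain, n_sites, n_diff, distance,
    same_as_reference, status``.  ``status`` is one of

    - ``ok``: distance computed from >= 1 comparable site;
    - ``no_snps``: no SNP in the block — same as reference by default
      (no evidence of divergence), distance 0;
    - ``missing``: sites exist but none are comparable (all N) — the
      assignment is flagged and ``same_as_reference`` left as NA;
    - ``saturated``: mismatch proportion >= 0.75 — treated as different.
    """
    from .io_formats import snp_strains

    all_strains = snp_strains(snps)
    if reference not in all_strains:
        raise ValueError(f"reference strain {reference!r} not in SNP table")
    if strains is None:
        strains = [s for s in all_strains if s != reference]

    ref_alleles = snps[reference].to_numpy(dtype="U1")
    chrom_arr = snps["chromosome"].to_numpy()
    pos_arr = snps["position"].to_numpy()

    records: list[pd.DataFrame] = []
    for chrom, chrom_blocks in blocks.groupby("chromosome", sort=False):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        starts = chrom_blocks["start"].to_numpy()
        ends = chrom_blocks["end"].to_numpy()
        # map each SNP onto the (sorted, non-overlapping) block it falls in
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        nb = len(chrom_blocks)
        ref_c = ref_alleles[sel]
        for strain in strains:
            alt_c = snps[strain].to_numpy(dtype="U1")[sel]
            comp = inside & (ref_c != "N") & (alt_c != "N")
            diff = comp & (ref_c != alt_c)
            n_snp = np.bincount(idx[inside], minlength=nb)
            n_comp = np.bincount(idx[comp], minlength=nb)
            n_diff = np.bincount(idx[diff], minlength=nb)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n_comp > 0, n_diff / np.maximum(n_comp, 1), np.nan)
            distance = _jc_from_p(p)
            saturated = (n_comp > 0) & (p >= _SATURATION_P)
            no_snps = n_snp == 0
            missing = (n_snp > 0) & (n_comp == 0)
            ok = (n_comp > 0) & ~saturated

            status = np.full(nb, "ok", dtype=object)
            status[no_snps] = "no_snps"
            status[missing] = "missing"
            status[saturated] = "saturated"

            dist_out = np.where(no_snps, 0.0, distance)
            dist_out = np.where(saturated | missing, np.nan, dist_out)
            same = np.full(nb, pd.NA, dtype=object)
            same[ok] = distance[ok] < threshold
            same[no_snps] = True
            same[saturated] = False  # extreme divergence cannot be "same"

            records.append(
                pd.DataFrame(
                    {
                        "block_id": chrom_blocks["block_id"].to_numpy(),
                        "chromosome": chrom,
                        "start": starts,
                        "end": ends,
                        "strain": strain,
                        "n_sites": n_comp,
                        "n_diff": n_diff,
                        "distance": dist_out,
                        "same_as_reference": same,
                        "status": status,
                    }
                )
            )
    if not records:
        out = pd.DataFrame(
            columns=[
                "block_id", "chromosome", "start", "end", "strain",
                "n_sites", "n_diff", "distance", "same_as_reference", "status",
            ]
        )
    else:
        out = pd.concat(records, ignore_index=True)
    n_sat = int((out["status"] == "saturated").sum())
    if n_sat:
        logger.warning("assign_haplotypes: %d saturated blocks treated as different", n_sat)
    logger.info(
        "assign_haplotypes: %d block x strain assignments (%d different)",
        len(out),
        int((out["same_as_reference"] == False).sum()),  # noqa: E712
    )
    return out


def upstream_windows(genes: pd.DataFrame, window: int) -> pd.DataFrame:
    """Strand-aware upstream windows of ``window`` bp per gene.

    On the plus strand the window is ``[tss - window, tss)``; on the minus
    strand it covers the ``window`` bases 5' of the TSS in gene orientation,
    i.e. ``[tss + 1, tss + window + 1)`` in genome coordinates.  Windows are
    clipped at zero.
    """
    tss = genes["tss"].to_numpy(dtype=np.int64)
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, tss - window, tss + 1)
    end = np.where(plus, tss, tss + window + 1)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chromosome": genes["chromosome"].to_numpy(),
            "window_start": np.maximum(start, 0),
            "window_end": np.maximum(end, 0),
        }
    )


def count_upstream_snps(
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    window: int,
    strain_a: str,
    strain_b: str,
) -> pd.DataFrame:
    """Count informative SNPs in each gene's upstream window.

    A site is informative when the two strains carry different, non-missing
    alleles.  Returns columns ``gene_id, chromosome, window_start,
    window_end, n_snps``.
    """
    for strain in (strain_a, strain_b):
        if strain not in snps.columns:
            raise ValueError(f"strain {strain!r} not in SNP table")
    wins = upstream_windows(genes, window)
    a = snps[strain_a].to_numpy(dtype="U1")
    b = snps[strain_b].to_numpy(dtype="U1")
    informative = (a != b) & (a != "N") & (b != "N")
    inf_chrom = snps["chromosome"].to_numpy()[informative]
    inf_pos = snps["position"].to_numpy()[informative]

    counts = np.zeros(len(wins), dtype=np.int64)
    for chrom, grp in wins.groupby("chromosome", sort=False):
        pos = np.sort(inf_pos[inf_chrom == chrom])
        lo = np.searchsorted(pos, grp["window_start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["window_end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    wins["n_snps"] = counts
    logger.info(
        "count_upstream_snps: %d genes, %d with >= 1 informative SNP",
        len(wins),
        int((counts > 0).sum()),
    )
    return wins


def gene_haplotype_flags(
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    strain: str,
    window: int,
) -> pd.DataFrame:
    """Flag each gene's upstream haplotype as ``different`` or ``same``.

    The upstream window is intersected with the assigned blocks for
    ``strain``; if any overlapped block carries a different allele from the
    reference the gene is "different" (a single divergent regulatory block
    suffices for a cis hypothesis).  Genes whose window overlaps no block
    with an assessable assignment are excluded from the output and counted
    in the log — they have no haplotype data.

    Returns columns ``gene_id, haplotype`` with ``haplotype`` in
    {"different", "same"}.
    """
    asg = assignments[assignments["strain"] == strain]
    if asg.empty:
        raise ValueError(f"no assignments for strain {strain!r}")
    wins = upstream_windows(genes, window)

    flags = np.full(len(wins), "none", dtype=object)
    for chrom, grp in wins.groupby("chromosome", sort=False):
        blk = asg[asg["chromosome"] == chrom].sort_values("start")
        if blk.empty:
            continue
        starts = blk["start"].to_numpy()
        ends = blk["end"].to_numpy()
        assessable = (blk["status"] != "missing").to_numpy()
        different = assessable & (blk["same_as_reference"] == False).to_numpy()  # noqa: E712
        cum_assess = np.concatenate([[0], np.cumsum(assessable)])
        cum_diff = np.concatenate([[0], np.cumsum(different)])
        # overlapping block range for each window, relying on sorted,
        # non-overlapping blocks
        i0 = np.searchsorted(ends, grp["window_start"].to_numpy(), side="right")
        i1 = np.searchsorted(starts, grp["window_end"].to_numpy(), side="left")
        i1 = np.maximum(i1, i0)
        n_assess = cum_assess[i1] - cum_assess[i0]
        n_diff = cum_diff[i1] - cum_diff[i0]
        res = np.where(n_diff > 0, "different", np.where(n_assess > 0, "same", "none"))
        flags[grp.index.to_numpy()] = res

    keep = flags != "none"
    excluded = int((~keep).sum())
    if excluded:
        logger.info(
            "gene_haplotype_flags: %d of %d genes without haplotype data excluded",
            excluded,
            len(wins),
        )
    out = pd.DataFrame(
        {"gene_id": wins["gene_id"].to_numpy()[keep], "haplotype": flags[keep]}
    )
    logger.info(
        "gene_haplotype_flags: %d genes flagged, %d different",
        len(out),
        int((out["haplotype"] == "different").sum()),
    )
    return out
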