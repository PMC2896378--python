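"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a two-inbred-strain transcriptome study with a
haplotype map:

- a genome of genes on several chromosomes, each gene owning one haplotype
  block around its TSS, with a configurable fraction of blocks on a
  different haplotype between the comparison strain and the reference;
- a SNP table whose within-block allele divergence is consistent with the
  block labels (so Jukes-Cantor assignment can recover them) and whose
  upstream-window SNP counts are Poisson with a much higher mean for
  different-haplotype genes;
- replicate log2 expression for each strain x tissue.  Cis effects are
  drawn once per gene, identical across tissues and tightly reproducible
  (low replicate noise, hence low pplr); trans effects are
  tissue-intermittent, redrawn per tissue and noisier; cis genes are drawn
  only from the different-haplotype stratum while trans genes follow the
  genome-wide haplotype frequencies;
- optionally a congenic-line comparison: interval genes with donor-allele
  cis effects plus a coordinated set of trans targets outside the
  interval, which (with background buffering) are silent in the parental
  comparison.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .congenic import CongenicDesign
from .io_formats import (
    GenomicInterval,
    write_block_table,
    write_expression,
    write_gene_annotation,
    write_probe_table,
    write_snp_table,
)

logger = logging.getLogger("cistrans")

__all__ = [
    "SimulationDesign",
    "CongenicSimDesign",
    "SimulatedDataset",
    "default_interval",
    "generate_genome",
    "generate_snps",
    "generate_probes",
    "generate_expression",
    "generate_congenic",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationDesign:
    """Parameters of the parental-strain simulation.

    Effect sizes and noise levels are in log2 units.  ``frac_cis_de`` /
    ``frac_trans_de`` are the fractions of all genes given cis and trans
    effects; cis genes are drawn only from the different-haplotype stratum
    (a cis effect through the upstream window requires a haplotype
    difference there), so ``frac_cis_de`` cannot exceed
    ``frac_diff_haplotype``.
    """

    n_genes: int = 20000
    n_tissues: int = 3
    frac_diff_haplotype: float = 0.30
    frac_cis_de: float = 0.05
    frac_trans_de: float = 0.10
    cis_lfc_mean: float = 1.0
    cis_lfc_sd: float = 0.2
    trans_lfc_mean: float = 0.8
    trans_lfc_sd: float = 0.3
    cis_replicate_sd: float = 0.15
    trans_replicate_sd: float = 0.35
    null_replicate_sd: float = 0.25
    trans_tissue_prob: float = 0.4
    n_replicates: int = 5
    snp_rate_diff: float = 3.0
    snp_rate_same: float = 0.05
    upstream_window: int = 1000
    # genome geometry: per-gene haplotype blocks of +/- block_flank around
    # the TSS; gene spacing keeps neighbouring blocks disjoint
    n_chromosomes: int = 5
    gene_spacing_min: int = 3000
    gene_spacing_mean: int = 5000
    block_flank: int = 1400
    # within-block backbone sites that encode the haplotype label
    block_n_sites: int = 50
    block_diff_frac: float = 0.40
    block_same_frac: float = 0.02
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    strains: tuple[str, str] = ("C57BL/6", "A/J")
    tissues: tuple[str, ...] = ("liver", "kidney", "spleen")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.frac_cis_de + self.frac_trans_de > 1.0 + 1e-12:
            raise ValueError("frac_cis_de + frac_trans_de must not exceed 1")
        if self.frac_cis_de > self.frac_diff_haplotype:
            raise ValueError("cis genes are drawn from the diff-haplotype stratum")
        for name in (
            "cis_lfc_sd", "trans_lfc_sd", "cis_replicate_sd",
            "trans_replicate_sd", "null_replicate_sd", "baseline_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.gene_spacing_min < 2 * self.block_flank:
            raise ValueError("gene spacing must keep per-gene blocks disjoint")
        if self.block_flank < self.upstream_window + 200:
            raise ValueError("block must contain the upstream window with margin")

    @property
    def tissue_names(self) -> tuple[str, ...]:
        return self.tissues[: self.n_tissues]

    @property
    def reference(self) -> str:
        return self.strains[0]

    @property
    def alt_strain(self) -> str:
        return self.strains[1]


@dataclass
class CongenicSimDesign:
    """Parameters of the congenic-line simulation.

    ``frac_interval_cis`` is the fraction of interval genes given
    donor-allele cis effects (drawn from the different-haplotype genes in
    the interval); ``n_trans_targets`` genes strictly outside the interval
    receive a coordinated log2 effect of ``trans_target_lfc``.  With
    ``background_buffering`` the same targets carry no effect in the
    parental comparison, emulating trans regulation that is only
    observable on the congenic background.
    """

    interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr1", 5_000_000, 10_000_000)
    )
    frac_interval_cis: float = 0.005
    n_trans_targets: int = 13
    trans_target_lfc: float = 1.0
    background_buffering: bool = True
    line_name: str = "Tir1"
    tissue: str = "spleen"

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_interval_cis <= 1.0:
            raise ValueError("frac_interval_cis must lie in [0, 1]")
        if self.n_trans_targets < 0:
            raise ValueError("n_trans_targets must be non-negative")

    @property
    def test_line(self) -> str:
        return f"{self.line_name}CC"

    @property
    def control_line(self) -> str:
        return f"{self.line_name}AA"


def default_interval(design: SimulationDesign) -> GenomicInterval:
    """A congenic-style interval covering the second quarter of chr1.

    Scales with the simulated genome so small test designs get a
    proportionally placed interval.
    """
    per_chrom = design.n_genes // design.n_chromosomes
    span = per_chrom * design.gene_spacing_mean
    return GenomicInterval("chr1", span // 4, span // 2)


def generate_genome(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes and their per-gene haplotype blocks on the genome.

    Returns ``(genes, blocks)``.  Genes carry ``block_id`` and the true
    haplotype label ``true_hap`` ("different"/"same"); blocks carry the
    same label as ``true_label``.  TSSs are at least ``gene_spacing_min``
    apart so neighbouring blocks never overlap.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    n = design.n_genes
    per_chrom = np.array_split(np.arange(n), design.n_chromosomes)
    chroms, tss = [], []
    for ci, idx in enumerate(per_chrom):
        m = len(idx)
        if m == 0:
            continue
        gaps = design.gene_spacing_min + rng.exponential(
            max(design.gene_spacing_mean - design.gene_spacing_min, 1), size=m
        )
        pos = design.gene_spacing_min + np.cumsum(gaps).astype(np.int64)
        chroms.append(np.full(m, f"chr{ci + 1}", dtype=object))
        tss.append(pos)
    chrom_arr = np.concatenate(chroms)
    tss_arr = np.concatenate(tss)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    width = 1000  # nominal gene body length
    start = np.where(strand == "+", tss_arr, tss_arr - (width - 1))
    end = np.where(strand == "+", tss_arr + width, tss_arr + 1)
    ids = np.array([f"g{i:06d}" for i in range(n)])
    block_ids = np.array([f"b{i:06d}" for i in range(n)])
    labels = np.where(
        rng.random(n) < design.frac_diff_haplotype, "different", "same"
    )
    genes = pd.DataFrame(
        {
            "gene_id": ids,
            "chromosome": chrom_arr,
            "start": start,
            "end": end,
            "strand": strand,
            "tss": tss_arr,
            "block_id": block_ids,
            "true_hap": labels,
        }
    )
    blocks = pd.DataFrame(
        {
            "block_id": block_ids,
            "chromosome": chrom_arr,
            "start": tss_arr - design.block_flank,
            "end": tss_arr + design.block_flank,
            "true_label": labels,
        }
    )
    logger.info(
        "generate_genome: %d genes on %d chromosomes, %.1f%% on different haplotypes",
        n,
        design.n_chromosomes,
        100 * float((labels == "different").mean()),
    )
    return genes, blocks


def _backbone_offsets(design: SimulationDesign) -> np.ndarray:
    """Fixed offsets (relative to the TSS) of the within-block backbone sites.

    Sites sit in the block flanks clear of the upstream window on either
    strand, so backbone divergence never contaminates upstream SNP counts.
    """
    n_half = design.block_n_sites // 2
    n_other = design.block_n_sites - n_half
    w, f = design.upstream_window, design.block_flank
    left = np.linspace(-f + 1, -w - 1, n_half).astype(np.int64)
    right = np.linspace(w + 1, f - 1, n_other).astype(np.int64)
    return np.concatenate([left, right])


def generate_snps(
    genes: pd.DataFrame,
    blocks: pd.DataFrame,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the two-strain SNP table implied by the block labels.

    Upstream windows get Poisson-many informative SNPs (mean
    ``snp_rate_diff`` or ``snp_rate_same`` by block label).  Each block
    also carries ``block_n_sites`` backbone sites at fixed offsets whose
    per-site divergence is ``block_diff_frac`` or ``block_same_frac``, so
    Jukes-Cantor assignment at the 0.2 threshold recovers the labels.
    A design with both upstream rates zero models absent SNP data and
    yields an empty table.
    """
    rng = np.random.default_rng(design.seed + 1) if rng is None else rng
    ref, alt = design.strains
    columns = ["chromosome", "position", ref, alt]
    if design.snp_rate_diff == 0 and design.snp_rate_same == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})

    labels = genes["true_hap"].to_numpy()
    diff = labels == "different"
    tss = genes["tss"].to_numpy(dtype=np.int64)
    plus = genes["strand"].to_numpy() == "+"
    chrom = genes["chromosome"].to_numpy()

    # upstream informative SNPs
    lam = np.where(diff, design.snp_rate_diff, design.snp_rate_same)
    k = rng.poisson(lam)
    gene_idx = np.repeat(np.arange(len(genes)), k)
    offsets = rng.integers(0, design.upstream_window, size=k.sum())
    w_start = np.where(plus, tss - design.upstream_window, tss + 1)
    up_pos = w_start[gene_idx] + offsets
    up_chrom = chrom[gene_idx]
    up_informative = np.ones(len(up_pos), dtype=bool)

    # backbone sites at fixed offsets, divergence by block label
    bb_off = _backbone_offsets(design)
    n_bb = len(bb_off)
    bb_pos = (tss[:, None] + bb_off[None, :]).ravel()
    bb_chrom = np.repeat(chrom, n_bb)
    frac = np.where(diff, design.block_diff_frac, design.block_same_frac)
    bb_informative = (rng.random((len(genes), n_bb)) < frac[:, None]).ravel()

    pos = np.concatenate([up_pos, bb_pos])
    chroms = np.concatenate([up_chrom, bb_chrom])
    informative = np.concatenate([up_informative, bb_informative])

    ref_codes = rng.integers(0, 4, size=len(pos))
    alt_codes = np.where(
        informative, (ref_codes + rng.integers(1, 4, size=len(pos))) % 4, ref_codes
    )
    snps = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": pos,
            ref: _BASES[ref_codes],
            alt: _BASES[alt_codes],
        }
    )
    snps = snps.drop_duplicates(subset=["chromosome", "position"])
    snps = snps.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "generate_snps: %d sites (%d informative between %s and %s)",
        len(snps),
        int((snps[ref] != snps[alt]).sum()),
        ref,
        alt,
    )
    return snps


def generate_probes(
    genes: pd.DataFrame,
    n_probes: int = 11,
    probe_length: int = 25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tile each gene body with ``n_probes`` probe intervals of 25 bp."""
    starts = genes["start"].to_numpy(dtype=np.int64)
    ends = genes["end"].to_numpy(dtype=np.int64)
    span = ends - starts - probe_length
    offsets = np.linspace(0, 1, n_probes)
    probe_start = (starts[:, None] + offsets[None, :] * span[:, None]).astype(np.int64)
    return pd.DataFrame(
        {
            "gene_id": np.repeat(genes["gene_id"].to_numpy(), n_probes),
            "chromosome": np.repeat(genes["chromosome"].to_numpy(), n_probes),
            "start": probe_start.ravel(),
            "end": probe_start.ravel() + probe_length,
        }
    )


def _assign_labels(
    genes: pd.DataFrame, design: SimulationDesign, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene regulation labels: cis, trans or null.

    Cis genes come only from the different-haplotype stratum.  Trans genes
    are stratified so their haplotype composition matches the genome-wide
    frequency — trans regulation is blind to the local haplotype.
    """
    n = len(genes)
    diff_idx = np.flatnonzero(genes["true_hap"].to_numpy() == "different")
    same_idx = np.flatnonzero(genes["true_hap"].to_numpy() == "same")
    n_cis = int(round(design.frac_cis_de * n))
    if n_cis > len(diff_idx):
        raise ValueError(
            f"{n_cis} cis genes requested but only {len(diff_idx)} "
            "different-haplotype genes available"
        )
    labels = np.full(n, "null", dtype=object)
    cis_idx = rng.choice(diff_idx, size=n_cis, replace=False)
    labels[cis_idx] = "cis"

    n_trans = int(round(design.frac_trans_de * n))
    n_trans_diff = min(
        int(round(n_trans * design.frac_diff_haplotype)), len(diff_idx) - n_cis
    )
    n_trans_same = n_trans - n_trans_diff
    free_diff = np.setdiff1d(diff_idx, cis_idx, assume_unique=False)
    trans_idx = np.concatenate(
        [
            rng.choice(free_diff, size=n_trans_diff, replace=False),
            rng.choice(same_idx, size=n_trans_same, replace=False),
        ]
    )
    labels[trans_idx] = "trans"
    return labels


def generate_expression(
    genes: pd.DataFrame,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Replicate expression matrices per strain x tissue, plus the truth table.

    Cis genes have one signed log2 effect applied identically in every
    tissue with replicate noise ``cis_replicate_sd``.  Trans genes are
    active in each tissue independently with probability
    ``trans_tissue_prob`` and their effect is redrawn (size and sign) per
    tissue, with noise ``trans_replicate_sd``.  Effects are oriented as
    comparison strain minus reference.

    Returns ``(expression, truth)``; ``expression`` maps
    ``(strain, tissue)`` to a gene x replicate table, ``truth`` records
    the regulation label, haplotype label and true per-tissue effects.
    """
    rng = np.random.default_rng(design.seed + 2) if rng is None else rng
    n = len(genes)
    labels = _assign_labels(genes, design, rng)
    cis = labels == "cis"
    trans = labels == "trans"

    mu = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
    tissues = design.tissue_names
    lfc = np.zeros((n, len(tissues)))
    sign = rng.choice([-1.0, 1.0], size=n)
    cis_effect = sign * rng.normal(design.cis_lfc_mean, design.cis_lfc_sd, size=n)
    lfc[cis, :] = cis_effect[cis, None]
    active = rng.random((n, len(tissues))) < design.trans_tissue_prob
    tsign = rng.choice([-1.0, 1.0], size=(n, len(tissues)))
    teffect = tsign * rng.normal(
        design.trans_lfc_mean, design.trans_lfc_sd, size=(n, len(tissues))
    )
    trans_lfc = np.where(active, teffect, 0.0)
    lfc[trans, :] = trans_lfc[trans, :]

    noise_sd = np.where(
        cis,
        design.cis_replicate_sd,
        np.where(trans, design.trans_replicate_sd, design.null_replicate_sd),
    )

    expression: dict[tuple[str, str], pd.DataFrame] = {}
    rep_cols = [f"rep_{i + 1}" for i in range(design.n_replicates)]
    for ti, tissue in enumerate(tissues):
        for strain, shift in ((design.reference, 0.0), (design.alt_strain, lfc[:, ti])):
            values = (
                mu[:, None]
                + np.asarray(shift).reshape(-1, 1)
                + rng.normal(0.0, 1.0, size=(n, design.n_replicates)) * noise_sd[:, None]
            )
            df = pd.DataFrame(values, columns=rep_cols)
            df.insert(0, "gene_id", genes["gene_id"].to_numpy())
            expression[(strain, tissue)] = df

    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "regulation": labels,
            "true_hap": genes["true_hap"].to_numpy(),
        }
    )
    for ti, tissue in enumerate(tissues):
        truth[f"lfc_{tissue}"] = lfc[:, ti]
    logger.info(
        "generate_expression: %d genes (%d cis, %d trans), %d tissues, %d replicates",
        n,
        int(cis.sum()),
        int(trans.sum()),
        len(tissues),
        design.n_replicates,
    )
    return expression, truth


def generate_congenic(
    genes: pd.DataFrame,
    cdesign: CongenicSimDesign,
    base: SimulationDesign,
    rng: np.random.Generator | None = None,
    parental_truth: pd.DataFrame | None = None,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Replicate expression for a congenic test/control pair, plus truth.

    Interval genes on different haplotypes may receive donor-allele cis
    effects; ``n_trans_targets`` genes outside the interval receive a
    coordinated effect of ``trans_target_lfc``.  With
    ``background_buffering`` and a parental truth table the targets are
    drawn from parental null genes, so the targets show no effect in the
    parental comparison.  Effects are oriented test line minus control.
    """
    rng = np.random.default_rng(base.seed + 3) if rng is None else rng
    interval = cdesign.interval
    tss = genes["tss"].to_numpy(dtype=np.int64)
    inside = (
        (genes["chromosome"].to_numpy() == interval.chromosome)
        & (tss >= interval.start)
        & (tss < interval.end)
    )
    if not inside.any():
        raise ValueError(
            f"congenic interval {interval} contains no simulated genes"
        )
    n = len(genes)
    n_interval = int(inside.sum())
    diff_hap = genes["true_hap"].to_numpy() == "different"
    cis_candidates = np.flatnonzero(inside & diff_hap)
    n_cis = int(round(cdesign.frac_interval_cis * n_interval))
    if n_cis > len(cis_candidates):
        raise ValueError(
            f"{n_cis} interval cis genes requested but only "
            f"{len(cis_candidates)} different-haplotype interval genes exist"
        )
    cis_idx = rng.choice(cis_candidates, size=n_cis, replace=False)

    outside_idx = np.flatnonzero(~inside)
    if cdesign.background_buffering and parental_truth is not None:
        null_genes = set(
            parental_truth.loc[parental_truth["regulation"] == "null", "gene_id"]
        )
        pool = outside_idx[
            np.isin(genes["gene_id"].to_numpy()[outside_idx], list(null_genes))
        ]
    else:
        pool = outside_idx
    if cdesign.n_trans_targets > len(pool):
        raise ValueError("not enough genes outside the interval for trans targets")
    target_idx = rng.choice(pool, size=cdesign.n_trans_targets, replace=False)

    lfc = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    lfc[cis_idx] = sign[cis_idx] * rng.normal(
        base.cis_lfc_mean, base.cis_lfc_sd, size=n_cis
    )
    lfc[target_idx] = cdesign.trans_target_lfc  # coordinated, common sign

    role = np.full(n, "null", dtype=object)
    role[cis_idx] = "interval_cis"
    role[target_idx] = "trans_target"
    noise_sd = np.where(
        role == "interval_cis",
        base.cis_replicate_sd,
        np.where(role == "trans_target", base.trans_replicate_sd, base.null_replicate_sd),
    )

    mu = rng.normal(base.baseline_mean, base.baseline_sd, size=n)
    rep_cols = [f"rep_{i + 1}" for i in range(base.n_replicates)]
    expression: dict[tuple[str, str], pd.DataFrame] = {}
    for line, shift in ((cdesign.test_line, lfc), (cdesign.control_line, 0.0)):
        values = (
            mu[:, None]
            + np.asarray(shift).reshape(-1, 1)
            + rng.normal(0.0, 1.0, size=(n, base.n_replicates)) * noise_sd[:, None]
        )
        df = pd.DataFrame(values, columns=rep_cols)
        df.insert(0, "gene_id", genes["gene_id"].to_numpy())
        expression[(line, cdesign.tissue)] = df

    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "role": role,
            "lfc": lfc,
            "in_interval": inside,
        }
    )
    logger.info(
        "generate_congenic[%s]: %d interval genes (%d cis), %d trans targets",
        cdesign.line_name,
        n_interval,
        n_cis,
        cdesign.n_trans_targets,
    )
    return expression, truth


@dataclass
class SimulatedDataset:
    """A complete simulated study, as produced by :func:`simulate_dataset`."""

    design: SimulationDesign
    genes: pd.DataFrame
    blocks: pd.DataFrame
    snps: pd.DataFrame
    probes: pd.DataFrame
    expression: dict[tuple[str, str], pd.DataFrame]
    truth: pd.DataFrame
    congenic_design: CongenicSimDesign | None = None
    congenic_expression: dict[tuple[str, str], pd.DataFrame] | None = None
    congenic_truth: pd.DataFrame | None = None

    def congenic_layout(self) -> CongenicDesign:
        if self.congenic_design is None:
            raise ValueError("dataset has no congenic component")
        return CongenicDesign(
            line_name=self.congenic_design.line_name,
            interval=self.congenic_design.interval,
            donor=self.design.reference,
            host=self.design.alt_strain,
        )


def simulate_dataset(
    design: SimulationDesign,
    congenic: CongenicSimDesign | None = None,
) -> SimulatedDataset:
    """Generate a full dataset (genome, SNPs, probes, expression, truth)."""
    rng = np.random.default_rng(design.seed)
    genes, blocks = generate_genome(design, rng)
    snps = generate_snps(genes, blocks, design, rng)
    probes = generate_probes(genes, rng=rng)
    expression, truth = generate_expression(genes, design, rng)
    dataset = SimulatedDataset(
        design=design,
        genes=genes,
        blocks=blocks,
        snps=snps,
        probes=probes,
        expression=expression,
        truth=truth,
    )
    if congenic is not None:
        cexpr, ctruth = generate_congenic(
            genes, congenic, design, rng, parental_truth=truth
        )
        dataset.congenic_design = congenic
        dataset.congenic_expression = cexpr
        dataset.congenic_truth = ctruth
    return dataset


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write a simulated dataset to TSV/BED files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_snp_table(dataset.snps, out / "snps.tsv")
    write_block_table(dataset.blocks, out / "blocks.tsv")
    write_gene_annotation(dataset.genes, out / "genes.bed")
    write_probe_table(dataset.probes, out / "probes.bed")
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    all_expr = dict(dataset.expression)
    if dataset.congenic_expression:
        all_expr.update(dataset.congenic_expression)
        dataset.congenic_truth.to_csv(
            out / "congenic_truth.tsv", sep="\t", index=False, float_format="%.6g"
        )
    for (strain, tissue), expr in all_expr.items():
        safe = strain.replace("/", "")
        write_expression(expr, out / f"expr_{safe}_{tissue}.tsv")
    logger.info("write_dataset: wrote %d expression tables to %s", len(all_expr), out)
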