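import numpy as np
import pandas as pd
import pytest

from cistrans.io_formats import AnalysisConfig
from cistrans.synthetic_data import (
    CongenicSimDesign,
    SimulationDesign,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_design():
    """A fast simulation design: small genome, study-default structure."""
    return SimulationDesign(n_genes=2000, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """One shared simulated dataset (with a congenic component) for read-only tests."""
    cdesign = CongenicSimDesign(
        interval=_small_interval(), frac_interval_cis=0.05, n_trans_targets=13
    )
    return simulate_dataset(small_design, congenic=cdesign)


def _small_interval():
    from cistrans.io_formats import GenomicInterval

    # chr1 of the 2000-gene genome spans ~2 Mb; this covers its middle
    return GenomicInterval("chr1", 500_000, 1_500_000)


def make_snp_table(rows, strains=("C57BL/6", "A/J")):
    """Build an internal-representation SNP table from (chrom, pos0, *alleles)."""
    records = []
    for row in rows:
        rec = {"chromosome": row[0], "position": row[1]}
        for strain, allele in zip(strains, row[2:]):
            rec[strain] = allele
        records.append(rec)
    df = pd.DataFrame(records)
    return df.sort_values(["chromosome", "position"]).reset_index(drop=True)


def make_genes(rows):
    """Build a gene table from (gene_id, chrom, tss, strand) with 1 kb bodies."""
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "tss", "strand"])
    width = 1000
    df["start"] = np.where(df["strand"] == "+", df["tss"], df["tss"] - (width - 1))
    df["end"] = np.where(df["strand"] == "+", df["tss"] + width, df["tss"] + 1)
    return df[["gene_id", "chromosome", "start", "end", "strand", "tss"]]
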