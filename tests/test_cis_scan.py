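import numpy as np
import pandas as pd
import pytest

from cistrans.cis_scan import (
    percentile_scan,
    probe_snp_check,
    rank_and_partition,
    relative_risk_curve,
)
from cistrans.io_formats import AnalysisConfig

from conftest import make_snp_table


def _results(pplrs, gene_ids=None):
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(len(pplrs))]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2_ratio": np.ones(len(pplrs)),
            "PPLR": 1.0 - np.asarray(pplrs),
            "pplr": np.asarray(pplrs),
        }
    )


class TestRankAndPartition:
    def test_even_split(self):
        groups = rank_and_partition(_results(np.linspace(0.001, 0.5, 200)), 100)
        assert len(groups) == 100
        assert all(len(g.genes) == 2 for g in groups)

    def test_remainder_spread_from_first_group(self):
        groups = rank_and_partition(_results(np.linspace(0.001, 0.5, 205)), 100)
        sizes = [len(g.genes) for g in groups]
        assert sizes[:5] == [3] * 5
        assert sizes[5:] == [2] * 95
        assert max(sizes) - min(sizes) == 1

    def test_groups_are_sorted_by_pplr(self):
        rng = np.random.default_rng(0)
        groups = rank_and_partition(_results(rng.uniform(0, 0.5, 300)), 10)
        highs = [g.pplr_high for g in groups]
        lows = [g.pplr_low for g in groups]
        assert all(h <= l for h, l in zip(highs, lows[1:]))

    def test_ties_break_by_gene_id(self):
        res = _results([0.1, 0.1, 0.2, 0.2], gene_ids=["gb", "ga", "gd", "gc"])
        groups = rank_and_partition(res, 2)
        assert groups[0].genes == ("ga", "gb")
        assert groups[1].genes == ("gc", "gd")

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="cannot split"):
            rank_and_partition(_results([0.1, 0.2]), 3)


def _counts(gene_ids, n_snps):
    return pd.DataFrame({"gene_id": gene_ids, "n_snps": n_snps})


class TestPercentileScan:
    def test_result_grid_shape(self, config):
        rng = np.random.default_rng(1)
        res = _results(rng.uniform(0, 0.5, 2000))
        counts = _counts(res["gene_id"], rng.poisson(1.0, 2000))
        groups = rank_and_partition(res, config.n_percentiles)
        scan = percentile_scan(groups, counts, config)
        assert len(scan) == config.n_percentiles * config.max_snp_threshold

    def test_first_threshold_column_sums(self, config):
        rng = np.random.default_rng(2)
        res = _results(rng.uniform(0, 0.5, 1000))
        snp = rng.poisson(0.8, 1000)
        counts = _counts(res["gene_id"], snp)
        groups = rank_and_partition(res, config.n_percentiles)
        scan = percentile_scan(groups, counts, config)
        s1 = scan[scan["snp_threshold"] == 1]
        assert ((s1["a"] + s1["c"]) == (snp >= 1).sum()).all()
        assert ((s1["b"] + s1["d"]) == (snp == 0).sum()).all()

    def test_planted_enrichment_found_in_first_percentile(self, config):
        # low-pplr genes get many upstream SNPs, the rest almost none
        n = 5000
        pplr = np.linspace(1e-4, 0.5, n)
        rng = np.random.default_rng(3)
        snp = np.where(np.arange(n) < n // 100, rng.poisson(3.0, n), rng.poisson(0.1, n))
        res = _results(pplr)
        groups = rank_and_partition(res, config.n_percentiles)
        scan = percentile_scan(groups, _counts(res["gene_id"], snp), config)
        sig = scan.loc[scan["significant_after_bonferroni"], "percentile"].unique()
        assert 1 in sig
        assert all(s <= 10 for s in sig)

    def test_bonferroni_flag_monotone_in_alpha(self, config):
        rng = np.random.default_rng(4)
        res = _results(rng.uniform(0, 0.5, 2000))
        counts = _counts(res["gene_id"], rng.poisson(1.0, 2000))
        groups = rank_and_partition(res, config.n_percentiles)
        loose = percentile_scan(groups, counts, config)
        import dataclasses

        strict_cfg = dataclasses.replace(config, alpha=0.001)
        strict = percentile_scan(groups, counts, strict_cfg)
        assert (
            strict["significant_after_bonferroni"] <= loose["significant_after_bonferroni"]
        ).all()

    def test_degenerate_columns_untestable(self, config):
        res = _results(np.linspace(0.01, 0.5, 200))
        counts = _counts(res["gene_id"], np.zeros(200, dtype=int))  # nobody has SNPs
        groups = rank_and_partition(res, 100)
        scan = percentile_scan(groups, counts, config)
        assert not scan["testable"].any()
        assert not scan["significant_after_bonferroni"].any()


class TestRelativeRiskCurve:
    def test_independent_outcome_gives_flat_curve(self):
        rng = np.random.default_rng(5)
        n = 20000
        res = _results(rng.uniform(0, 0.5, n))
        counts = _counts(res["gene_id"], rng.poisson(1.5, n))
        curve, r = relative_risk_curve(res, counts, pplr_cutoff=0.05, max_n=5)
        defined = curve[curve["defined"]]
        assert np.allclose(defined["rr"], 1.0, atol=0.25)

    def test_planted_dose_response_is_monotone_with_high_r(self):
        rng = np.random.default_rng(6)
        n = 20000
        snp = rng.poisson(2.0, n)
        p_de = 0.02 + 0.08 * np.minimum(snp, 8)  # risk rises with SNP count
        de = rng.random(n) < p_de
        pplr = np.where(de, rng.uniform(0, 0.004, n), rng.uniform(0.01, 0.5, n))
        res = _results(pplr)
        curve, r = relative_risk_curve(res, _counts(res["gene_id"], snp), 0.0046, max_n=8)
        assert r > 0.9
        rrs = curve.loc[curve["defined"], "rr"].to_numpy()
        assert rrs[-1] > rrs[0]

    def test_at_most_max_n_points(self):
        res = _results(np.linspace(0.001, 0.5, 100))
        counts = _counts(res["gene_id"], np.tile([0, 1], 50))
        curve, _ = relative_risk_curve(res, counts, 0.05, max_n=10)
        assert len(curve) == 10
        assert not curve.loc[curve["n"] > 1, "defined"].any()  # nobody has >= 2 SNPs


class TestProbeSnpCheck:
    def _probes(self, gene_ids, start=100):
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": "chr1",
                "start": [start + 1000 * i for i in range(len(gene_ids))],
                "end": [start + 1000 * i + 25 for i in range(len(gene_ids))],
            }
        )

    def _de(self, gene_ids, lfc):
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2_ratio": lfc,
                "PPLR": 0.999,
                "pplr": 0.001,
            }
        )

    def test_no_snps_anywhere(self):
        genes = [f"g{i}" for i in range(10)]
        probes = self._probes(genes)
        snps = make_snp_table([("chr2", 5, "A", "G")])
        check = probe_snp_check(probes, snps, self._de(genes, [1.0] * 10), "C57BL/6", "A/J")
        assert check.n_de_with_probe_snps == 0

    def test_snps_under_probes_of_underexpressed_genes_detected(self):
        genes = [f"g{i}" for i in range(40)]
        lfc = [-1.0] * 20 + [1.0] * 20  # first half under-expressed in A/J
        probes = self._probes(genes)
        # plant informative SNPs inside the probes of the under-expressed genes
        snp_rows = [("chr1", 100 + 1000 * i + 5, "A", "G") for i in range(20)]
        check = probe_snp_check(
            probes, make_snp_table(snp_rows), self._de(genes, lfc), "C57BL/6", "A/J"
        )
        assert check.n_de_with_probe_snps == 20
        assert check.chi2_p < 0.001

    def test_balanced_snps_show_no_association(self):
        genes = [f"g{i}" for i in range(40)]
        lfc = ([-1.0] * 10 + [1.0] * 10) * 2
        probes = self._probes(genes)
        snp_rows = [("chr1", 100 + 1000 * i + 5, "A", "G") for i in range(20)]
        check = probe_snp_check(
            probes, make_snp_table(snp_rows), self._de(genes, lfc), "C57BL/6", "A/J"
        )
        assert check.chi2_p > 0.05
        assert check.directional_excess == 0.0

    def test_genes_without_probes_excluded(self):
        genes = [f"g{i}" for i in range(5)]
        probes = self._probes(genes[:3])
        snps = make_snp_table([("chr1", 105, "A", "G")])
        check = probe_snp_check(probes, snps, self._de(genes, [1.0] * 5), "C57BL/6", "A/J")
        assert check.n_excluded_no_probes == 2
        assert check.n_de == 3
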