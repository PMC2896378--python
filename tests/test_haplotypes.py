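import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.haplotypes import (
    SaturationError,
    UndefinedDistanceError,
    assign_haplotypes,
    count_upstream_snps,
    gene_haplotype_flags,
    jukes_cantor_distance,
)

from conftest import make_genes, make_snp_table


def _vectors_with_p(n_sites: int, n_diff: int) -> tuple[list[str], list[str]]:
    a = ["A"] * n_sites
    b = ["C"] * n_diff + ["A"] * (n_sites - n_diff)
    return a, b


class TestJukesCantor:
    def test_identical_vectors(self):
        assert jukes_cantor_distance(list("ACGT"), list("ACGT")) == 0.0

    def test_known_value_at_p_01(self):
        # closed form: -(3/4) ln(1 - 0.4/3) evaluated at p = 0.1
        a, b = _vectors_with_p(10, 1)
        assert jukes_cantor_distance(a, b) == pytest.approx(0.1073256, abs=1e-6)

    def test_saturation_at_three_quarters(self):
        a, b = _vectors_with_p(4, 3)
        with pytest.raises(SaturationError):
            jukes_cantor_distance(a, b)

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            jukes_cantor_distance(["N", "A"], ["C", "N"])

    def test_missing_sites_are_pairwise_deleted(self):
        # N sites drop out: effective vectors are length 2 with 1 mismatch
        d = jukes_cantor_distance(["A", "N", "G"], ["A", "C", "T"])
        a, b = _vectors_with_p(2, 1)
        assert d == pytest.approx(jukes_cantor_distance(a, b))

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_monotone_in_p(self, n_sites, data):
        n_diff = data.draw(st.integers(0, max(0, math.ceil(n_sites * 0.74) - 1)))
        a, b = _vectors_with_p(n_sites, n_diff)
        d = jukes_cantor_distance(a, b)
        assert d == jukes_cantor_distance(b, a)
        assert d >= n_diff / n_sites  # JC correction only stretches distances
        if n_diff + 1 < 0.74 * n_sites:
            a2, b2 = _vectors_with_p(n_sites, n_diff + 1)
            assert jukes_cantor_distance(a2, b2) > d


class TestAssignHaplotypes:
    BLOCKS = pd.DataFrame(
        {"block_id": ["b1"], "chromosome": ["chr1"], "start": [0], "end": [1000]}
    )

    def _assign(self, rows, **kwargs):
        snps = make_snp_table(rows)
        return assign_haplotypes(snps, self.BLOCKS, reference="C57BL/6", **kwargs)

    def test_identical_strain_is_same(self):
        out = self._assign([("chr1", i, "A", "A") for i in range(10)])
        row = out.iloc[0]
        assert row["same_as_reference"] == True  # noqa: E712
        assert row["distance"] == 0.0
        assert row["status"] == "ok"

    def test_thirty_percent_divergence_is_different(self):
        # p = 0.3 over 50 sites: d ~ 0.383 > 0.2
        rows = [("chr1", i, "A", "C" if i < 15 else "A") for i in range(50)]
        out = self._assign(rows)
        assert out.iloc[0]["same_as_reference"] == False  # noqa: E712
        assert out.iloc[0]["distance"] == pytest.approx(
            -0.75 * math.log(1 - 0.4), abs=1e-9
        )

    def test_all_missing_strain_is_flagged(self):
        out = self._assign([("chr1", i, "A", "N") for i in range(5)])
        assert out.iloc[0]["status"] == "missing"
        assert pd.isna(out.iloc[0]["same_as_reference"])

    def test_empty_block_defaults_to_same(self):
        blocks = pd.DataFrame(
            {
                "block_id": ["b1", "b2"],
                "chromosome": ["chr1", "chr1"],
                "start": [0, 5000],
                "end": [1000, 6000],
            }
        )
        snps = make_snp_table([("chr1", 10, "A", "A")])
        out = assign_haplotypes(snps, blocks, reference="C57BL/6").set_index("block_id")
        assert out.loc["b2", "status"] == "no_snps"
        assert out.loc["b2", "same_as_reference"] == True  # noqa: E712
        assert out.loc["b2", "distance"] == 0.0

    def test_saturated_block_is_different(self):
        out = self._assign([("chr1", i, "A", "C") for i in range(10)])
        assert out.iloc[0]["status"] == "saturated"
        assert out.iloc[0]["same_as_reference"] == False  # noqa: E712

    def test_unknown_reference_rejected(self):
        snps = make_snp_table([("chr1", 10, "A", "A")])
        with pytest.raises(ValueError, match="reference"):
            assign_haplotypes(snps, self.BLOCKS, reference="nope")

    def test_recovers_generated_labels(self, small_dataset, small_design, config):
        out = assign_haplotypes(
            small_dataset.snps,
            small_dataset.blocks,
            reference=small_design.reference,
            threshold=config.haplotype_distance_threshold,
        )
        informative = out[out["n_sites"] >= 10].set_index("block_id")
        truth = small_dataset.blocks.set_index("block_id")["true_label"]
        called = np.where(
            informative["same_as_reference"].astype(bool), "same", "different"
        )
        agreement = (called == truth.loc[informative.index]).mean()
        assert agreement >= 0.99


class TestUpstreamCounts:
    def test_strand_aware_window(self):
        genes = make_genes([("g+", "chr1", 5000, "+"), ("g-", "chr1", 5000, "-")])
        snps = make_snp_table(
            [("chr1", 4001, "A", "G"), ("chr1", 4999, "C", "T"), ("chr1", 4500, "A", "A")]
        )
        out = count_upstream_snps(genes, snps, 1000, "C57BL/6", "A/J").set_index("gene_id")
        # '+' window [4000, 5000) holds both informative SNPs
        assert out.loc["g+", "n_snps"] == 2
        # '-' window [5001, 6001) holds none of them
        assert out.loc["g-", "n_snps"] == 0

    def test_no_snps_in_window(self):
        genes = make_genes([("g1", "chr1", 5000, "+")])
        snps = make_snp_table([("chr1", 100, "A", "G")])
        out = count_upstream_snps(genes, snps, 1000, "C57BL/6", "A/J")
        assert out["n_snps"].tolist() == [0]

    def test_only_informative_sites_count(self):
        genes = make_genes([("g1", "chr1", 5000, "+")])
        snps = make_snp_table(
            [("chr1", 4100, "A", "A"), ("chr1", 4200, "A", "N"), ("chr1", 4300, "A", "T")]
        )
        out = count_upstream_snps(genes, snps, 1000, "C57BL/6", "A/J")
        assert out["n_snps"].tolist() == [1]

    def test_window_boundaries_half_open(self):
        genes = make_genes([("g1", "chr1", 5000, "+")])
        snps = make_snp_table(
            [("chr1", 3999, "A", "G"), ("chr1", 4000, "A", "G"), ("chr1", 5000, "A", "G")]
        )
        out = count_upstream_snps(genes, snps, 1000, "C57BL/6", "A/J")
        assert out["n_snps"].tolist() == [1]  # only position 4000 is inside


class TestGeneHaplotypeFlags:
    def _assignments(self, specs):
        # specs: (block_id, start, end, same, status)
        return pd.DataFrame(
            [
                {
                    "block_id": b,
                    "chromosome": "chr1",
                    "start": s,
                    "end": e,
                    "strain": "A/J",
                    "n_sites": 10,
                    "n_diff": 0,
                    "distance": 0.0,
                    "same_as_reference": same,
                    "status": status,
                }
                for b, s, e, same, status in specs
            ]
        )

    def test_single_same_block(self):
        genes = make_genes([("g1", "chr1", 5000, "+")])
        asg = self._assignments([("b1", 3000, 6000, True, "ok")])
        out = gene_haplotype_flags(genes, asg, "A/J", 1000)
        assert out["haplotype"].tolist() == ["same"]

    def test_any_overlapping_different_block_wins(self):
        genes = make_genes([("g1", "chr1", 5000, "+")])
        asg = self._assignments(
            [("b1", 3000, 4500, False, "ok"), ("b2", 4500, 6000, True, "ok")]
        )
        out = gene_haplotype_flags(genes, asg, "A/J", 1000)
        assert out["haplotype"].tolist() == ["different"]

    def test_unassessed_region_is_excluded(self):
        genes = make_genes(
            [("g1", "chr1", 5000, "+"), ("g2", "chr1", 50000, "+")]
        )
        asg = self._assignments([("b1", 3000, 6000, True, "ok")])
        out = gene_haplotype_flags(genes, asg, "A/J", 1000)
        assert out["gene_id"].tolist() == ["g1"]

    def test_missing_status_blocks_do_not_assess(self):
        genes = make_genes([("g1", "chr1", 5000, "+")])
        asg = self._assignments([("b1", 3000, 6000, pd.NA, "missing")])
        out = gene_haplotype_flags(genes, asg, "A/J", 1000)
        assert out.empty
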