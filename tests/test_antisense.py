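"""Sense-antisense pairing, regulation classes and HRE motif scanning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nasctx.antisense import (
    classify_regulation,
    correlate_pairs,
    find_antisense_pairs,
    scan_hre,
)
from nasctx.core import GenomicInterval, Transcript, ValidationError

from conftest import overlap_bp_oracle


def tx(tid, start, end, strand, biotype="coding", chrom="chr1"):
    return Transcript(tid, GenomicInterval(chrom, start, end, strand), biotype=biotype)


class TestFindAntisensePairs:
    def test_same_strand_overlap_is_not_a_pair(self):
        gene = tx("g", 0, 1_000, "+")
        other = tx("t", 500, 1_500, "+", biotype="lncRNA")
        assert find_antisense_pairs([other], [gene]) == []

    def test_ten_percent_boundary_is_inclusive(self):
        # antisense length 1000, overlap exactly 100 bp -> fraction 0.10 kept
        gene = tx("g", 1_900, 5_000, "+")
        anti = tx("a", 1_000, 2_000, "-", biotype="antisense")
        (pair,) = find_antisense_pairs([anti], [gene])
        assert pair.overlap_bp == 100
        assert pair.overlap_fraction == pytest.approx(0.10)
        # one bp less overlap (99/1000) and the pair is dropped
        assert find_antisense_pairs(
            [tx("a2", 1_000, 2_000, "-")], [tx("g2", 1_901, 5_000, "+")]
        ) == []

    def test_nested_antisense_has_fraction_one(self):
        gene = tx("g", 0, 50_000, "+")
        anti = tx("a", 10_000, 20_000, "-", biotype="antisense")
        (pair,) = find_antisense_pairs([anti], [gene])
        assert pair.overlap_fraction == pytest.approx(1.0)
        assert pair.topology == "nested"

    def test_convergent_topology(self):
        # gene -> on the left, antisense <- starting past the gene's 3' end
        gene = tx("g", 0, 10_000, "+")
        anti = tx("a", 8_000, 14_000, "-", biotype="antisense")
        (pair,) = find_antisense_pairs([anti], [gene])
        assert pair.topology == "convergent"

    def test_divergent_topology(self):
        gene = tx("g", 5_000, 15_000, "+")
        anti = tx("a", 1_000, 6_000, "-", biotype="antisense")
        (pair,) = find_antisense_pairs([anti], [gene])
        assert pair.topology == "divergent"

    @pytest.mark.parametrize("seed", range(5))
    def test_overlap_matches_base_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes, antis = [], []
        for i in range(40):
            s = int(rng.integers(0, 4_000))
            genes.append(tx(f"g{i}", s, s + int(rng.integers(100, 2_000)), "+"))
            s2 = int(rng.integers(0, 4_000))
            antis.append(tx(f"a{i}", s2, s2 + int(rng.integers(100, 2_000)), "-"))
        pairs = find_antisense_pairs(antis, genes, min_fraction=1e-9)
        by_key = {(p.sense_id, p.antisense_id): p for p in pairs}
        for g in genes:
            for a in antis:
                ov = overlap_bp_oracle(
                    (g.interval.start, g.interval.end), (a.interval.start, a.interval.end)
                )
                if ov > 0:
                    assert by_key[(g.id, a.id)].overlap_bp == ov
                else:
                    assert (g.id, a.id) not in by_key

    def test_min_fraction_filter_is_monotone(self):
        rng = np.random.default_rng(7)
        genes = [tx(f"g{i}", i * 5_000, i * 5_000 + 3_000, "+") for i in range(30)]
        starts = [i * 5_000 + int(rng.integers(0, 4_000)) for i in range(30)]
        antis = [tx(f"a{i}", s, s + 2_000, "-") for i, s in enumerate(starts)]
        counts = [
            len(find_antisense_pairs(antis, genes, min_fraction=f))
            for f in (0.05, 0.10, 0.25, 0.50, 0.90)
        ]
        assert counts == sorted(counts, reverse=True)


def de_table(rows):
    return pd.DataFrame(rows).set_index("feature")


class TestCorrelatePairs:
    def _pairs(self, n):
        genes = [tx(f"g{i}", i * 10_000, i * 10_000 + 5_000, "+") for i in range(n)]
        antis = [tx(f"a{i}", i * 10_000 + 1_000, i * 10_000 + 4_000, "-") for i in range(n)]
        return find_antisense_pairs(antis, genes)

    def test_equal_fold_changes_give_r_one(self):
        pairs = self._pairs(10)
        tab = de_table(
            [{"feature": f"g{i}", "log2_fc": i * 0.1} for i in range(10)]
            + [{"feature": f"a{i}", "log2_fc": i * 0.1} for i in range(10)]
        )
        corr = correlate_pairs(pairs, tab)
        assert corr.pearson_r == pytest.approx(1.0)

    def test_negated_fold_changes_give_r_minus_one(self):
        pairs = self._pairs(10)
        tab = de_table(
            [{"feature": f"g{i}", "log2_fc": i * 0.1} for i in range(10)]
            + [{"feature": f"a{i}", "log2_fc": -i * 0.1} for i in range(10)]
        )
        assert correlate_pairs(pairs, tab).pearson_r == pytest.approx(-1.0)

    def test_planted_correlation_and_permutation_p(self):
        n = 50
        rng = np.random.default_rng(21)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        pairs = self._pairs(n)
        tab = de_table(
            [{"feature": f"g{i}", "log2_fc": xy[i, 0]} for i in range(n)]
            + [{"feature": f"a{i}", "log2_fc": xy[i, 1]} for i in range(n)]
        )
        corr = correlate_pairs(pairs, tab)
        assert abs(corr.pearson_r - 0.5) < 0.25
        # permutation oracle for the p-value
        r_obs = abs(corr.pearson_r)
        hits = 0
        B = 5_000
        for _ in range(B):
            r_p = abs(stats.pearsonr(xy[:, 0], rng.permutation(xy[:, 1]))[0])
            if r_p >= r_obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (B + 1)
        assert abs(corr.p_value - p_perm) < 3 * np.sqrt(max(p_perm, 1e-4) / B) + 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlate_pairs(self._pairs(2), de_table(
                [{"feature": f"g{i}", "log2_fc": 0.1} for i in range(2)]
                + [{"feature": f"a{i}", "log2_fc": 0.1} for i in range(2)]
            ))


class TestClassifyRegulation:
    def _pair(self):
        gene = tx("HIF1A", 0, 53_000, "+")
        anti = tx("HIF1A-AS", 3_000, 56_000, "-", biotype="antisense")
        return find_antisense_pairs([anti], [gene])

    def test_inverse_regulation_is_asrg(self):
        # sense repressed, antisense strongly induced: the archetype
        tab = de_table([
            {"feature": "HIF1A", "log2_fc": -1.0, "status": "down"},
            {"feature": "HIF1A-AS", "log2_fc": 2.5, "status": "up"},
        ])
        (out,) = classify_regulation(self._pair(), tab)
        assert out.regulation_class == "ASRG"

    def test_coregulated_is_narg(self):
        tab = de_table([
            {"feature": "HIF1A", "log2_fc": 1.2, "status": "up"},
            {"feature": "HIF1A-AS", "log2_fc": 2.5, "status": "up"},
        ])
        (out,) = classify_regulation(self._pair(), tab)
        assert out.regulation_class == "NARG"

    def test_one_sided_de_is_not_regulated_by_default(self):
        tab = de_table([
            {"feature": "HIF1A", "log2_fc": -0.2, "status": "not_DE"},
            {"feature": "HIF1A-AS", "log2_fc": 2.5, "status": "up"},
        ])
        (out,) = classify_regulation(self._pair(), tab)
        assert out.regulation_class == "not_regulated"
        # the looser directional mode classifies on the antisense call alone
        (loose,) = classify_regulation(self._pair(), tab, require_both_de=False)
        assert loose.regulation_class == "ASRG"

    def test_global_sign_flip_preserves_classes(self):
        tab = de_table([
            {"feature": "HIF1A", "log2_fc": -1.0, "status": "down"},
            {"feature": "HIF1A-AS", "log2_fc": 2.5, "status": "up"},
        ])
        flipped = tab.copy()
        flipped["log2_fc"] = -flipped["log2_fc"]
        flipped["status"] = flipped["status"].map({"down": "up", "up": "down"})
        (a,) = classify_regulation(self._pair(), tab)
        (b,) = classify_regulation(self._pair(), flipped)
        assert a.regulation_class == b.regulation_class == "ASRG"

    def test_missing_member_names_the_pair(self):
        tab = de_table([{"feature": "HIF1A", "log2_fc": 0.0, "status": "not_DE"}])
        with pytest.raises(ValidationError, match="HIF1A-AS"):
            classify_regulation(self._pair(), tab)


class TestScanHre:
    def test_no_hits_in_poly_t(self):
        assert scan_hre("TTTTTT") == []

    def test_forward_hit_position(self):
        (hit,) = scan_hre("TTACGTGAA")
        assert (hit.position, hit.strand, hit.matched) == (2, "+", "ACGTG")

    def test_reverse_complement_hit(self):
        (hit,) = scan_hre("TTCACGTAA")
        assert hit.strand == "-"
        assert hit.position == 2
        assert hit.matched == "ACGTG"

    def test_both_r_degeneracies_match(self):
        hits = scan_hre("ACGTGTTTGCGTG")
        assert [(h.position, h.matched) for h in hits if h.strand == "+"] == [
            (0, "ACGTG"), (8, "GCGTG")
        ]

    def test_n_never_matches(self):
        assert [h for h in scan_hre("NCGTG") if h.strand == "+"] == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            scan_hre("ACGTX")

    def test_palindromic_context_found_on_both_strands(self):
        # CACGTG contains ACGTG forward (pos 1) and CACGT reverse (pos 0)
        hits = scan_hre("CACGTG")
        strands = {(h.strand, h.position) for h in hits}
        assert ("+", 1) in strands and ("-", 0) in strands

    def test_offset_shifts_reported_positions(self):
        (hit,) = scan_hre("TTACGTGAA", offset=100)
        assert hit.position == 102
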