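import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyscore import harmonize
from polyscore.containers import complement_allele


def make_weight_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "effect_weight", "source_population",
        ],
    )


class TestEffectiveSampleSize:
    @pytest.mark.parametrize(
        "maf,n,info,expected",
        [
            (0.5, 100, 1.0, 50.0),
            (0.01, 1000, 0.5, 9.9),
            (0.0, 1000, 1.0, 0.0),
        ],
    )
    def test_closed_form(self, maf, n, info, expected):
        assert harmonize.effective_sample_size(maf, n, info) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "maf,n,info", [(-0.1, 10, 1.0), (1.1, 10, 1.0), (0.2, -5, 1.0), (0.2, 10, 1.5)]
    )
    def test_domain_violations_rejected(self, maf, n, info):
        with pytest.raises(ValueError):
            harmonize.effective_sample_size(maf, n, info)

    @given(
        maf=st.floats(0.0, 1.0),
        n=st.floats(0.0, 1e6),
        info=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_in_maf_and_maximized_at_half(self, maf, n, info):
        a = harmonize.effective_sample_size(maf, n, info)
        b = harmonize.effective_sample_size(1.0 - maf, n, info)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-9)
        assert a <= harmonize.effective_sample_size(0.5, n, info) + 1e-9


class TestFilterVariants:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "maf", "info", "n"])

    def test_threshold_rules(self):
        meta = self._meta(
            [
                ("low_info", 0.3, 0.39, 1000),   # info below 0.4
                ("low_effn", 0.01, 0.9, 1000),    # eff_n = 17.82 < 30
                ("kept", 0.5, 1.0, 100),          # eff_n = 50
            ]
        )
        out = harmonize.filter_variants(meta)
        assert list(out["exclusion_reason"]) == ["low_info", "low_eff_n", "none"]
        assert list(out["kept"]) == [False, False, True]
        assert out.loc[1, "eff_n"] == pytest.approx(2 * 0.01 * 0.99 * 1000 * 0.9)

    def test_boundaries_are_inclusive_keeps(self):
        # info exactly 0.4 and eff_n exactly 30 both pass ('<' thresholds)
        meta = self._meta([("edge_info", 0.5, 0.4, 150), ("edge_effn", 0.5, 1.0, 60)])
        out = harmonize.filter_variants(meta)
        assert out["kept"].all()

    def test_missing_metadata_flagged_not_kept(self):
        meta = self._meta([("miss", np.nan, 0.9, 1000)])
        out = harmonize.filter_variants(meta)
        assert not out["kept"].iloc[0]
        assert out["exclusion_reason"].iloc[0] == "missing_meta"


class TestStrandMapping:
    def _mapping(self, strand, new_pos=555):
        return pd.DataFrame(
            {
                "old_chrom": ["1"], "old_pos": [100],
                "new_chrom": ["1"], "new_pos": [new_pos], "strand": [strand],
            }
        )

    def test_minus_strand_complements_alleles(self):
        table = make_weight_table([("v1", "1", 100, "A", "G", 0.5, "EUR")])
        out = harmonize.apply_strand_mapping(table, self._mapping("-"))
        assert (out["effect_allele"].iloc[0], out["other_allele"].iloc[0]) == ("T", "C")
        assert out["pos"].iloc[0] == 555
        assert out["effect_weight"].iloc[0] == 0.5

    def test_plus_strand_identity(self):
        table = make_weight_table([("v1", "1", 100, "A", "G", 0.5, "EUR")])
        out = harmonize.apply_strand_mapping(table, self._mapping("+"))
        assert (out["effect_allele"].iloc[0], out["other_allele"].iloc[0]) == ("A", "G")

    def test_invalid_allele_rejected(self):
        table = make_weight_table([("v1", "1", 100, "N", "G", 0.5, "EUR")])
        with pytest.raises(ValueError, match="A/C/G/T|non-ACGT"):
            harmonize.apply_strand_mapping(table, self._mapping("-"))

    def test_unmapped_variant_dropped_with_warning(self):
        table = make_weight_table(
            [
                ("v1", "1", 100, "A", "G", 0.5, "EUR"),
                ("v2", "1", 200, "C", "T", 0.1, "EUR"),
            ]
        )
        with pytest.warns(UserWarning, match="1 weight-table variants"):
            out = harmonize.apply_strand_mapping(table, self._mapping("+"))
        assert list(out["variant_id"]) == ["v1"]


PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
         ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


class TestMatchAlleles:
    def _panel(self, ref, alt):
        return pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref_allele": [ref], "alt_allele": [alt]}
        )

    @pytest.mark.parametrize("ref,alt", PAIRS)
    @pytest.mark.parametrize("orientation", harmonize.ORIENTATIONS)
    def test_all_orientations_recovered(self, ref, alt, orientation):
        """Brute-force construction: transform the panel pair into each of the
        four representations and check it maps back to that orientation."""
        comp = complement_allele
        effect, other = {
            "direct": (alt, ref),
            "swap": (ref, alt),
            "flip": (comp(alt), comp(ref)),
            "swap_flip": (comp(ref), comp(alt)),
        }[orientation]
        table = make_weight_table([("v", "1", 100, effect, other, 0.3, "EUR")])
        out = harmonize.match_alleles(table, self._panel(ref, alt))
        assert out["excluded_reason"].iloc[0] == "none"
        assert out["orientation"].iloc[0] == orientation

    def test_spec_swap_flip_example(self):
        # effect C / other T vs ref G / alt A: complement C->G matches ref
        table = make_weight_table([("v", "1", 100, "C", "T", 0.3, "EUR")])
        out = harmonize.match_alleles(table, self._panel("G", "A"))
        assert out["orientation"].iloc[0] == "swap_flip"

    def test_palindromic_excluded_by_default(self):
        table = make_weight_table([("v", "1", 100, "A", "T", 0.3, "EUR")])
        out = harmonize.match_alleles(table, self._panel("T", "A"))
        assert out["excluded_reason"].iloc[0] == "ambiguous"
        assert out["orientation"].isna().iloc[0]

    def test_palindromic_assume_plus_strand(self):
        table = make_weight_table([("v", "1", 100, "A", "T", 0.3, "EUR")])
        out = harmonize.match_alleles(
            table, self._panel("T", "A"), ambiguous_policy="assume-plus-strand"
        )
        assert out["orientation"].iloc[0] == "direct"

    def test_unmatched_position_excluded(self):
        table = make_weight_table([("v", "1", 999, "A", "G", 0.3, "EUR")])
        out = harmonize.match_alleles(table, self._panel("G", "A"))
        assert out["excluded_reason"].iloc[0] == "unmatched"

    def test_conflicting_panel_duplicates_rejected(self):
        panel = pd.DataFrame(
            {
                "chrom": ["1", "1"], "pos": [100, 100],
                "ref_allele": ["A", "A"], "alt_allele": ["G", "C"],
            }
        )
        table = make_weight_table([("v", "1", 100, "A", "G", 0.3, "EUR")])
        with pytest.raises(ValueError, match="conflicting alleles"):
            harmonize.match_alleles(table, panel)

    @pytest.mark.parametrize("ref,alt", PAIRS)
    def test_panel_complement_is_an_involution(self, ref, alt):
        """Complementing the panel's alleles swaps direct<->flip and
        swap<->swap_flip."""
        swap_map = {"direct": "flip", "flip": "direct",
                    "swap": "swap_flip", "swap_flip": "swap"}
        comp = complement_allele
        for eff, oth in [(alt, ref), (ref, alt), (comp(alt), comp(ref))]:
            table = make_weight_table([("v", "1", 100, eff, oth, 0.3, "EUR")])
            o1 = harmonize.match_alleles(table, self._panel(ref, alt))
            o2 = harmonize.match_alleles(table, self._panel(comp(ref), comp(alt)))
            assert swap_map[o1["orientation"].iloc[0]] == o2["orientation"].iloc[0]

    def test_filter_and_match_commute_on_kept_sets(self, rng):
        """Quality filtering before or after allele matching keeps the same
        usable variant set."""
        n = 30
        pairs = np.array(PAIRS)[rng.integers(0, len(PAIRS), n)]
        panel = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(n)],
                "chrom": "1",
                "pos": 10 * (np.arange(n) + 1),
                "ref_allele": pairs[:, 0],
                "alt_allele": pairs[:, 1],
                "maf": rng.uniform(0.0, 0.5, n),
                "info": rng.uniform(0.2, 1.0, n),
                "n": 500,
            }
        )
        table = make_weight_table(
            [
                (f"v{j}", "1", 10 * (j + 1), pairs[j, 1], pairs[j, 0],
                 0.1, "EUR")
                for j in range(0, n, 2)  # half the panel
            ]
        )
        # filter then match
        filt = harmonize.filter_variants(panel)
        kept = filt.loc[filt["kept"]].reset_index(drop=True)
        m1 = harmonize.match_alleles(table, kept)
        set1 = set(m1.loc[m1["excluded_reason"] == "none", "variant_id"])
        # match then filter
        m2 = harmonize.match_alleles(table, panel)
        usable = m2.loc[m2["excluded_reason"] == "none"]
        f2 = harmonize.filter_variants(
            panel.iloc[usable["panel_index"].to_numpy(int)]
        )
        set2 = set(usable.loc[f2["kept"].to_numpy(), "variant_id"])
        assert set1 == set2
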