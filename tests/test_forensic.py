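"""Forensic statistics: gene diversity, haplotype spectra, the four
parameters, and the microvariant/CNV/null screen."""

from collections import Counter
from fractions import Fraction

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ylineage.datasets import shanghai_spectrum
from ylineage.forensic import (
    HaplotypeSpectrum,
    LocusFrequencies,
    forensic_parameters,
    gene_diversity,
    haplotype_key,
    haplotype_spectrum,
    locus_frequencies,
    round_half_up,
    variant_haplogroup_crosstab,
    variant_screen,
    VariantReport,
)
from ylineage.panels import get_panel
from ylineage.profiles import AlleleCall
from ylineage.simulate import SimConfig, simulate_population

TINY = get_panel("yfiler").subset(["DYS19", "DYS391"])


class TestGeneDiversity:
    def test_monomorphic_locus_has_zero_diversity(self):
        freqs = LocusFrequencies("DYS19", n=50, freqs={(AlleleCall(15),): 1.0})
        assert gene_diversity(freqs) == 0.0

    def test_two_distinct_alleles_n2_is_one(self):
        freqs = LocusFrequencies(
            "DYS19", n=2,
            freqs={(AlleleCall(15),): 0.5, (AlleleCall(16),): 0.5},
        )
        assert gene_diversity(freqs) == pytest.approx(1.0)

    def test_near_monomorphic_vector_matches_summation_oracle(self):
        # dominant allele at 510/530 with the rest spread thin, the shape
        # of a locus like DYS645 in a real population sample
        counts = {15: 510, 16: 10, 14: 6, 17: 4}
        n = sum(counts.values())
        freqs = LocusFrequencies(
            "DYS645", n=n,
            freqs={(AlleleCall(a),): c / n for a, c in counts.items()},
        )
        sum_sq = sum((c / n) ** 2 for c in counts.values())  # oracle
        expected = n / (n - 1) * (1 - sum_sq)
        assert gene_diversity(freqs) == pytest.approx(expected, abs=1e-15)
        assert 0.0 < expected < 0.12

    def test_requires_two_samples(self):
        freqs = LocusFrequencies("DYS19", n=1, freqs={(AlleleCall(15),): 1.0})
        with pytest.raises(ValueError):
            gene_diversity(freqs)

    def test_multi_copy_locus_counts_sorted_pairs_as_alleles(self, profile_factory):
        profiles = [
            profile_factory("a", "P", {"DYS385a/b": [13, 17]}),
            profile_factory("b", "P", {"DYS385a/b": [17, 13]}),
            profile_factory("c", "P", {"DYS385a/b": [12, 18]}),
        ]
        freqs = locus_frequencies(profiles, "DYS385a/b")
        assert freqs.freqs[(13.0, 17.0)] == pytest.approx(2 / 3)


class TestHaplotypeSpectrum:
    def test_hand_counted_small_population(self, profile_factory):
        same = {"DYS19": 15, "DYS391": 10}
        profiles = [
            profile_factory(f"s{i}", "P", same) for i in range(3)
        ] + [
            profile_factory("s3", "P", {"DYS19": 16, "DYS391": 10}),
            profile_factory("s4", "P", {"DYS19": 15, "DYS391": 11}),
        ]
        spec = haplotype_spectrum(profiles, TINY)
        assert spec.spectrum == {1: 2, 3: 1}
        assert spec.n_haplotypes == 3 and spec.n == 5

    def test_null_calls_are_excluded(self, profile_factory):
        profiles = [
            profile_factory("s0", "P", {"DYS19": 15, "DYS391": 10}),
            profile_factory("s1", "P", {"DYS19": [], "DYS391": 10}),
        ]
        spec = haplotype_spectrum(profiles, TINY)
        assert spec.n == 1

    def test_matches_brute_force_group_by_on_simulated_data(self):
        out = simulate_population(
            SimConfig(n_founders=60, n_generations=30, n_sample=60, seed=8)
        )
        panel = get_panel("yfiler")
        spec = haplotype_spectrum(out.str_profiles, panel)
        # independent group-by oracle
        keys = [haplotype_key(p, panel) for p in out.str_profiles]
        oracle = Counter(Counter(k for k in keys if k is not None).values())
        assert spec.spectrum == dict(oracle)

    def test_spectrum_invariants_enforced(self):
        with pytest.raises(ValueError):
            HaplotypeSpectrum(panel="x", population="p", n=5, spectrum={1: 3})


class TestForensicParameters:
    def test_published_yfiler_columns(self):
        pudong = forensic_parameters(shanghai_spectrum("Pudong", "yfiler"))
        assert pudong.rounded(5) == {
            "n": 689, "H": 619, "FUH": 0.83164, "HD": 0.99957,
            "MP": 0.00189, "DC": 0.89840,
        }
        chongming = forensic_parameters(shanghai_spectrum("Chongming", "yfiler"))
        assert chongming.rounded(5)["MP"] == 0.00334
        assert chongming.rounded(5)["HD"] == 0.99854

    def test_all_singleton_spectrum(self):
        spec = HaplotypeSpectrum.from_counts("x", "p", {1: 40})
        params = forensic_parameters(spec)
        assert params.FUH == params.DC == 1.0
        assert params.MP == pytest.approx(1 / 40)
        assert params.HD == pytest.approx(1.0)

    def test_equals_raw_haplotype_count_oracle(self):
        out = simulate_population(
            SimConfig(n_founders=60, n_generations=30, n_sample=60, seed=8)
        )
        panel = get_panel("ppy23")
        params = forensic_parameters(haplotype_spectrum(out.str_profiles, panel))
        counts = Counter(
            k for k in (haplotype_key(p, panel) for p in out.str_profiles)
            if k is not None
        )
        n = sum(counts.values())
        mp = sum(Fraction(c, n) ** 2 for c in counts.values())
        assert params.MP == pytest.approx(float(mp), abs=1e-15)
        assert params.DC == pytest.approx(len(counts) / n, abs=1e-15)
        assert params.FUH == pytest.approx(
            sum(1 for c in counts.values() if c == 1) / n, abs=1e-15
        )
        assert params.HD == pytest.approx(
            float(Fraction(n, n - 1) * (1 - mp)), abs=1e-15
        )

    @given(
        st.dictionaries(
            st.integers(min_value=1, max_value=6),
            st.integers(min_value=1, max_value=30),
            min_size=1,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_duplicating_a_haplotype_never_raises_fuh_or_dc(self, spectrum):
        assume(sum(k * v for k, v in spectrum.items()) >= 2)
        base = forensic_parameters(
            HaplotypeSpectrum.from_counts("x", "p", dict(spectrum))
        )
        # add one more copy of an existing haplotype with multiplicity k
        k = min(spectrum)
        bumped = dict(spectrum)
        bumped[k] -= 1
        if bumped[k] == 0:
            del bumped[k]
        bumped[k + 1] = bumped.get(k + 1, 0) + 1
        after = forensic_parameters(
            HaplotypeSpectrum.from_counts("x", "p", bumped)
        )
        assert after.FUH <= base.FUH + 1e-12
        assert after.DC <= base.DC + 1e-12

    def test_gd_equals_hd_when_locus_is_whole_panel_haplotype(self):
        out = simulate_population(
            SimConfig(n_founders=50, n_generations=25, n_sample=50, seed=13)
        )
        panel = get_panel("yfiler")
        params = forensic_parameters(haplotype_spectrum(out.str_profiles, panel))
        counts = Counter(
            k for k in (haplotype_key(p, panel) for p in out.str_profiles)
            if k is not None
        )
        n = sum(counts.values())
        freqs = LocusFrequencies(
            "whole-panel", n=n,
            freqs={("%s" % (key,),): c / n for key, c in counts.items()},
        )
        assert gene_diversity(freqs) == pytest.approx(params.HD, abs=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value,nd,expected",
        [(0.898403, 5, 0.89840), (0.000125, 4, 0.0001), (0.0731449, 4, 0.0731),
         (0.5 / 10**5, 5, 0.00001)],
    )
    def test_half_up(self, value, nd, expected):
        assert round_half_up(value, nd) == expected


class TestVariantScreen:
    def test_screen_categories(self, profile_factory):
        panel = get_panel("yfiler_platinum")
        profiles = [
            profile_factory("s1", "P", {"DYS19": [15, 16]}),           # CNV
            profile_factory("s2", "P", {"DYS385a/b": [12, 17.2]}),     # microvariant
            profile_factory("s3", "P", {"DYF387S1a/b": [36, 41, 42]}),  # CNV
            profile_factory("s4", "P", {"DYS518": 38.2}),              # microvariant
        ]
        report = variant_screen(profiles, panel)
        cnv_keys = {(s, l) for s, l, _ in report.cnvs}
        micro_keys = {(s, l) for s, l, _ in report.microvariants}
        assert ("s1", "DYS19") in cnv_keys
        assert ("s3", "DYF387S1a/b") in cnv_keys
        assert ("s2", "DYS385a/b") in micro_keys
        assert ("s2", "DYS385a/b") not in cnv_keys  # 2 alleles is expected
        assert ("s4", "DYS518") in micro_keys
        # loci absent from each profile appear as nulls
        assert ("s1", "DYS391") in report.nulls

    def test_cnv_with_fractional_allele_listed_in_both(self, profile_factory):
        report = variant_screen(
            [profile_factory("s1", "P", {"DYS19": [15, 16.2]})],
            get_panel("yfiler"),
        )
        assert [(s, l) for s, l, _ in report.cnvs] == [("s1", "DYS19")]
        assert [(s, l) for s, l, _ in report.microvariants] == [("s1", "DYS19")]


class TestCrosstab:
    def _report(self, carriers):
        return VariantReport(
            microvariants=[
                (s, "DYS518", (AlleleCall(38.2),)) for s in carriers
            ]
        )

    def test_clade_enrichment_fixture(self):
        # 22 carriers of a .2 allele, 21 of them in one clade
        carriers = [f"c{i}" for i in range(22)]
        calls = {s: "QR" for s in carriers[:21]}
        calls[carriers[21]] = "O1a"
        for i in range(1219 - 22):
            calls[f"n{i}"] = "O2a1" if i % 2 else "C2"
        table = variant_haplogroup_crosstab(
            self._report(carriers), calls, "DYS518", 0.2, "QR"
        )
        assert table[("carrier", "in_clade")] == 21
        assert table[("carrier", "out_clade")] == 1
        assert table[("non_carrier", "in_clade")] == 0
        assert table[("non_carrier", "out_clade")] == 1219 - 22

    def test_no_carriers_gives_zero_row(self):
        table = variant_haplogroup_crosstab(
            VariantReport(), {"a": "QR", "b": "O1a"}, "DYS518", 0.2, "QR"
        )
        assert table[("carrier", "in_clade")] == 0
        assert table[("carrier", "out_clade")] == 0
        assert table[("non_carrier", "in_clade")] == 1

    def test_carrier_without_call_is_error(self):
        with pytest.raises(KeyError):
            variant_haplogroup_crosstab(
                self._report(["ghost"]), {"a": "QR"}, "DYS518", 0.2, "QR"
            )

    def test_simulated_clade_linked_microvariant_is_enriched(self):
        from ylineage.simulate import simulate_population

        cfg = SimConfig(
            n_founders=100, n_generations=50, n_sample=80, seed=4,
            microvariant_rate=0.0, duplication_rate=0.0,
            founder_haplogroup_weights={"QR": 0.3, "O1a": 0.7},
            clade_microvariant=("DYS518", "QR"),
        )
        out = simulate_population(cfg)
        report = variant_screen(out.str_profiles, cfg.panel)
        table = variant_haplogroup_crosstab(
            report, out.true_haplogroups, "DYS518", 0.2, "QR"
        )
        a = table[("carrier", "in_clade")]
        b = table[("carrier", "out_clade")]
        c = table[("non_carrier", "in_clade")]
        d = table[("non_carrier", "out_clade")]
        assert a > 0
        # odds ratio > 1 (Haldane correction for empty cells)
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        assert odds > 1
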