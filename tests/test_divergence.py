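"""Polarization rules, per-offset divergence with dyad folding and the
occupancy / dinucleotide correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nucperiod as nc
from nucperiod.divergence import (
    per_fragment_rate,
    window_gc_correlation,
    correlate_with_occupancy,
)
from nucperiod.genome import Genome, encode
from nucperiod.profiles import site_offsets


def site_row(focal, sib, out1, out2, pos=0):
    return pd.DataFrame(
        {"chrom": ["c1"], "pos": [pos], "focal": [focal], "sib": [sib],
         "out1": [out1], "out2": [out2]}
    )


BASE = st.sampled_from(list("ACGT"))
BASE_OR_N = st.sampled_from(list("ACGTN"))


class TestPolarize:
    def test_standard_vs_stringent_disagreeing_outgroups(self):
        row = site_row("A", "G", "G", "T")
        std = nc.polarize(row, "standard")
        assert std["ancestral"].iloc[0] == "G" and bool(std["diverged"].iloc[0])
        strict = nc.polarize(row, "stringent")
        assert not bool(strict["polarized"].iloc[0])

    def test_conserved_site(self):
        out = nc.polarize(site_row("G", "G", "G", "N"))
        assert out["ancestral"].iloc[0] == "G"
        assert bool(out["polarized"].iloc[0]) and not bool(out["diverged"].iloc[0])

    def test_all_distinct_unpolarizable(self):
        out = nc.polarize(site_row("A", "C", "G", "T"))
        assert not bool(out["polarized"].iloc[0])
        assert out["ancestral"].iloc[0] == "N"

    def test_missing_sib_unpolarizable(self):
        assert not bool(nc.polarize(site_row("A", "N", "G", "G"))["polarized"].iloc[0])

    def test_missing_focal_unpolarizable(self):
        assert not bool(nc.polarize(site_row("N", "G", "G", "G"))["polarized"].iloc[0])

    @given(BASE, BASE_OR_N, BASE_OR_N, BASE_OR_N)
    def test_outgroup_swap_symmetry(self, focal, sib, o1, o2):
        a = nc.polarize(site_row(focal, sib, o1, o2))
        b = nc.polarize(site_row(focal, sib, o2, o1))
        assert a["ancestral"].iloc[0] == b["ancestral"].iloc[0]
        assert bool(a["diverged"].iloc[0]) == bool(b["diverged"].iloc[0])

    @given(BASE_OR_N, BASE_OR_N, BASE_OR_N, BASE_OR_N)
    def test_stringent_subset_of_standard(self, focal, sib, o1, o2):
        row = site_row(focal, sib, o1, o2)
        if bool(nc.polarize(row, "stringent")["polarized"].iloc[0]):
            assert bool(nc.polarize(row, "standard")["polarized"].iloc[0])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            nc.polarize(site_row("A", "A", "A", "A"), "lenient")


def brute_force_divergence(polarized, n147, chrom_len, pathway, weighting, trim, flank=0):
    """Independent per-column recomputation by explicit loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    x, y = pathway
    anc = {}
    foc = {}
    for _, r in polarized.iterrows():
        if r["polarized"]:
            anc[r["pos"]] = r["ancestral"]
            foc[r["pos"]] = r["focal"]
    offs = list(site_offsets(flank))
    width = len(offs)
    # multiplicity of each site over all half-observations
    mult = {}
    halves = []
    for _, f in n147.iterrows():
        left = [f["start"] - flank + j for j in range(width)]
        right = [f["end"] - 1 + flank - j for j in range(width)]
        halves.append(("L", left))
        halves.append(("R", right))
        for p in left + right:
            if 0 <= p < chrom_len:
                mult[p] = mult.get(p, 0) + 1
    anc_count = np.zeros(width)
    div_count = np.zeros(width)
    for strand, positions in halves:
        for j, p in enumerate(positions):
            if p not in anc:
                continue
            a, f = anc[p], foc[p]
            if strand == "R":
                a, f = comp[a], comp[f]
            w = 1.0 if weighting == "per_n147" else 1.0 / mult[p]
            if a == x:
                anc_count[j] += w
                if f == y:
                    div_count[j] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        value = div_count / anc_count
    trim_mask = (np.array(offs) >= -73 - trim) & (np.array(offs) <= -73 + trim - 1)
    value[trim_mask] = np.nan
    return value


@pytest.fixture(scope="module")
def toy_polarized():
    rng = np.random.default_rng(51)
    L = 2000
    bases = rng.choice(list("ACGT"), size=L)
    focal = bases.copy()
    flip = rng.random(L) < 0.15
    for k in np.nonzero(flip)[0]:
        focal[k] = rng.choice([b for b in "ACGT" if b != bases[k]])
    unpol = rng.random(L) < 0.1
    sites = pd.DataFrame(
        {"chrom": "c1", "pos": np.arange(L), "focal": focal,
         "sib": np.where(unpol, "N", bases), "out1": bases, "out2": bases}
    )
    return nc.polarize(sites), L


class TestDivergenceProfile:
    def test_definitional_rate(self):
        # 10 fragments, ancestral G everywhere; 2 focal A at the position
        # mapping to column -30 on the left half of fragments 0 and 1
        L = 3000
        n147 = pd.DataFrame(
            {"chrom": "c1", "start": np.arange(10) * 300, "end": np.arange(10) * 300 + 147}
        )
        pos = np.arange(L)
        focal = np.full(L, "G")
        for f in (0, 1):
            focal[f * 300 + 43] = "A"  # offset -30 = position start+73-30-? (43 = 73-30)
        sites = pd.DataFrame(
            {"chrom": "c1", "pos": pos, "focal": focal, "sib": "G",
             "out1": "G", "out2": "G"}
        )
        prof = nc.divergence_profile(
            nc.polarize(sites), n147, {"c1": L}, ("G", "A"), "per_n147"
        )
        col = np.where(prof.offsets == -30)[0][0]
        # 10 left halves carry ancestral G at column -30 (right halves fold
        # to the complementary C pathway there); 2 of them show focal A
        assert prof.value[col] == pytest.approx(2 / 10)

    @pytest.mark.parametrize("weighting", ["per_n147", "per_site"])
    def test_matches_brute_force_oracle(self, toy_polarized, weighting):
        polarized, L = toy_polarized
        n147 = pd.DataFrame(
            {"chrom": "c1", "start": [100, 150, 600, 900], "end": [247, 297, 747, 1047]}
        )
        got = nc.divergence_profile(polarized, n147, {"c1": L}, ("G", "A"), weighting)
        expected = brute_force_divergence(polarized, n147, L, ("G", "A"), weighting, trim=5)
        np.testing.assert_allclose(got.value, expected, equal_nan=True)

    def test_per_site_equals_per_n147_on_disjoint_set(self, toy_polarized):
        polarized, L = toy_polarized
        n147 = pd.DataFrame(
            {"chrom": "c1", "start": [0, 200, 400, 800], "end": [147, 347, 547, 947]}
        )
        a = nc.divergence_profile(polarized, n147, {"c1": L}, ("G", "A"), "per_n147")
        b = nc.divergence_profile(polarized, n147, {"c1": L}, ("G", "A"), "per_site")
        np.testing.assert_allclose(a.value, b.value, equal_nan=True)

    def test_rates_bounded(self, toy_polarized):
        polarized, L = toy_polarized
        n147 = pd.DataFrame({"chrom": "c1", "start": [100, 130], "end": [247, 277]})
        for pw in [("G", "A"), ("C", "T"), ("A", "G")]:
            prof = nc.divergence_profile(polarized, n147, {"c1": L}, pw)
            ok = ~prof.masked
            assert ((prof.value[ok] >= 0) & (prof.value[ok] <= 1)).all()
            assert (prof.numer <= prof.denom).all()

    def test_phase_recovery_against_generator(self, evolved_chromatin):
        from nucperiod.periodicity import best_lag

        prof = nc.divergence_profile(
            evolved_chromatin["polarized"], evolved_chromatin["n147"],
            evolved_chromatin["genome"].lengths(), ("G", "A"), "per_n147",
        )
        sm = nc.smooth(prof, "fine")
        ref = np.cos(2 * np.pi * (np.abs(prof.offsets) - 5) / 10)
        assert abs(best_lag(sm.value, ref)) <= 1


class TestMergeComplementary:
    def _profile(self, numer, denom, offsets=None):
        numer = np.asarray(numer, float)
        denom = np.asarray(denom, float)
        offsets = np.arange(-len(numer), 0) if offsets is None else offsets
        masked = denom == 0
        value = np.where(masked, np.nan, numer / np.where(denom == 0, 1, denom))
        from nucperiod.profiles import PositionalProfile

        return PositionalProfile(offsets, value, denom, masked, numer=numer, denom=denom)

    def test_equal_counts_average(self):
        a = self._profile([10], [100])
        b = self._profile([30], [100])
        assert nc.merge_complementary(a, b).value[0] == pytest.approx(0.2)

    def test_count_weighted_not_rate_mean(self):
        a = self._profile([9], [90])    # rate 0.1, weight 90
        b = self._profile([3], [10])    # rate 0.3, weight 10
        assert nc.merge_complementary(a, b).value[0] == pytest.approx(0.12)

    def test_all_masked_profile_is_identity(self):
        a = self._profile([5, 7], [50, 70])
        b = self._profile([0, 0], [0, 0])
        merged = nc.merge_complementary(a, b)
        np.testing.assert_allclose(merged.value, a.value)

    def test_offset_mismatch_rejected(self):
        a = self._profile([1], [10], offsets=np.array([-1]))
        b = self._profile([1], [10], offsets=np.array([-2]))
        with pytest.raises(ValueError):
            nc.merge_complementary(a, b)


class TestCorrelations:
    def test_profile_self_correlation_is_one(self, evolved_chromatin):
        prof = nc.divergence_profile(
            evolved_chromatin["polarized"], evolved_chromatin["n147"].head(100),
            evolved_chromatin["genome"].lengths(), ("G", "A"),
        )
        assert nc.dinuc_divergence_correlation(prof, prof) == pytest.approx(1.0)

    def test_in_phase_positive_antiphase_negative(self, evolved_chromatin):
        prof = nc.divergence_profile(
            evolved_chromatin["polarized"], evolved_chromatin["n147"],
            evolved_chromatin["genome"].lengths(), ("G", "A"),
        )
        aa = nc.dinucleotide_profile(
            evolved_chromatin["n147"], evolved_chromatin["genome"], "AA"
        )
        gc = nc.dinucleotide_profile(
            evolved_chromatin["n147"], evolved_chromatin["genome"], "GC"
        )
        # 300 cores give a noisy unsmoothed profile; the sign pattern and a
        # clear positive in-phase correlation are already decisive here (the
        # 2000-core construction is exercised in the acceptance suite)
        assert nc.dinuc_divergence_correlation(prof, aa) > 0.3
        assert nc.dinuc_divergence_correlation(prof, gc) < -0.1

    def test_too_few_columns_rejected(self):
        from nucperiod.profiles import PositionalProfile

        p = PositionalProfile(np.arange(-5, 0), np.ones(5), np.ones(5),
                              np.zeros(5, bool))
        with pytest.raises(ValueError):
            nc.dinuc_divergence_correlation(p, p)

    def test_monotone_rates_give_rho_one(self, toy_polarized):
        polarized, L = toy_polarized
        # craft fragments, then check Spearman of rate vs coverage on a
        # track built so coverage increases exactly with the rate ranking
        n147 = pd.DataFrame(
            {"chrom": "c1", "start": np.arange(8) * 220, "end": np.arange(8) * 220 + 147}
        )
        rates = per_fragment_rate(polarized, n147, {"c1": L}, ("G", "A"))
        order = rates["rate"].rank(method="first").astype(int)
        cov = np.zeros(L, dtype=np.int64)
        for k, (s, e) in enumerate(zip(n147["start"], n147["end"])):
            cov[s:e] = 10 ** 0  # placeholder
        # coverage proportional to rate rank
        for k, (s, e) in enumerate(zip(n147["start"], n147["end"])):
            cov[s:e] = int(order.iloc[k]) * 5
        genome = Genome({"c1": encode("".join(
            np.random.default_rng(0).choice(list("ACGT"), size=L)))})
        res = correlate_with_occupancy(
            polarized, n147, {"c1": cov}, genome, ("G", "A"), min_polarizable=0
        )
        assert res["rho_coverage"] == pytest.approx(1.0)

    def test_permuted_rates_uncorrelated(self):
        rng = np.random.default_rng(52)
        L = 500 * 250
        bases = rng.choice(list("ACGT"), size=L)
        focal = bases.copy()
        flip = rng.random(L) < 0.1
        for k in np.nonzero(flip)[0]:
            focal[k] = rng.choice([b for b in "ACGT" if b != bases[k]])
        sites = pd.DataFrame(
            {"chrom": "c1", "pos": np.arange(L), "focal": focal, "sib": bases,
             "out1": bases, "out2": bases}
        )
        polarized = nc.polarize(sites)
        starts = np.arange(500) * 250
        n147 = pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 147})
        cov = np.zeros(L, dtype=np.int64)
        perm = rng.permutation(500) + 1
        for k, (s, e) in enumerate(zip(n147["start"], n147["end"])):
            cov[s:e] = perm[k]
        genome = Genome({"c1": encode("".join(bases))})
        res = correlate_with_occupancy(
            polarized, n147, {"c1": cov}, genome, ("G", "A"), min_polarizable=50
        )
        assert abs(res["rho_coverage"]) < 0.2
        assert res["p_coverage"] > 0.05

    def test_window_filters_match_direct_count(self, toy_polarized):
        polarized, L = toy_polarized
        genome = Genome({"c1": encode("".join(
            np.random.default_rng(1).choice(list("ACGT"), size=L)))})
        res = window_gc_correlation(
            polarized, genome, ("G", "A"), window=500, min_polarizable=166, max_n=250
        )
        # direct count of qualifying windows: all 4 windows have ~90%
        # polarizable sites and no Ns in the reference
        assert res["n_windows"] == L // 500

    def test_too_few_regions_error(self, toy_polarized):
        polarized, L = toy_polarized
        n147 = pd.DataFrame({"chrom": "c1", "start": [0], "end": [147]})
        genome = Genome({"c1": encode("A" * L)})
        with pytest.raises(ValueError):
            correlate_with_occupancy(
                polarized, n147, {"c1": np.ones(L, dtype=np.int64)}, genome,
                ("G", "A"), min_polarizable=147,
            )
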