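"""Poison-antidote model: survival arithmetic, tetrad enumeration,
viable-pool frequencies and parameter fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sporekit import drive_model as dm
from sporekit import synthetic_data as sd
from tests.conftest import single_killer_config


def _two_killer_config(r=0.5, same_chrom=False, kappa=1.0, pi=1.0):
    chrom2 = "chr1" if same_chrom else "chr2"
    loci = [dm.Locus("A", "chr1", 100, recomb_fraction_to_next=r if same_chrom else None),
            dm.Locus("B", chrom2, 200)]
    return dm.CrossConfig(
        loci=loci,
        parent1={"A": "kA", "B": "ref"},
        parent2={"A": "ref", "B": "kB"},
        killers=[dm.KillerAllele("kA", "A", kappa, pi),
                 dm.KillerAllele("kB", "B", kappa, pi)])


class TestSporeSurvival:
    def test_unprotected_spore_full_penetrance_dies(self):
        k = dm.KillerAllele("k", "L", 1.0, 1.0)
        assert dm.spore_survival_probability({"L": "ref"}, [k]) == 0.0

    def test_carrier_fully_protected(self):
        k = dm.KillerAllele("k", "L", 1.0, 1.0)
        assert dm.spore_survival_probability({"L": "k"}, [k]) == 1.0

    def test_mutual_killing_between_distinct_killers(self):
        """A spore carrying one killer is still killed by the other when
        resistance sets are disjoint."""
        k9 = dm.KillerAllele("cw9", "L", 1.0, 1.0)
        k27 = dm.KillerAllele("cw27", "L", 1.0, 1.0)
        assert dm.spore_survival_probability({"L": "cw9"}, [k9, k27]) == 0.0

    def test_killing_dead_killer_protects(self):
        """A killer with no killing activity (kappa=0) still protects."""
        td = dm.KillerAllele.from_preset("td", "L", "Td")
        assert dm.spore_survival_probability({"L": "td"}, [td]) == 1.0
        assert dm.spore_survival_probability({"L": "ref"}, [td]) == 1.0

    def test_cross_resistance_via_resistance_set(self):
        kA = dm.KillerAllele("kA", "L", 1.0, 1.0)
        kB = dm.KillerAllele("kB", "M", 1.0, 1.0,
                             resistance_set={"kA", "kB"})
        s = dm.spore_survival_probability({"L": "ref", "M": "kB"}, [kA, kB])
        assert s == 1.0

    def test_missing_locus_raises_with_locus_name(self):
        k = dm.KillerAllele("k", "L", 1.0, 1.0)
        with pytest.raises(KeyError, match="L"):
            dm.spore_survival_probability({"M": "ref"}, [k])

    @given(kappa1=st.floats(0, 1), kappa2=st.floats(0, 1),
           pi=st.floats(0, 1))
    def test_monotone_in_kappa_and_pi(self, kappa1, kappa2, pi):
        """Survival is non-increasing in kappa and non-decreasing in pi."""
        lo, hi = sorted([kappa1, kappa2])
        geno = {"L": "k", "M": "other"}
        other = dm.KillerAllele("other", "M", 0.5, 0.0)
        s_hi = dm.spore_survival_probability(
            geno, [dm.KillerAllele("k", "L", hi, pi), other])
        s_lo = dm.spore_survival_probability(
            geno, [dm.KillerAllele("k", "L", lo, pi), other])
        assert s_hi <= s_lo + 1e-12
        s_pi0 = dm.spore_survival_probability(
            geno, [dm.KillerAllele("k", "L", hi, 0.0), other])
        assert s_pi0 <= s_hi + 1e-12

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            dm.KillerAllele("k", "L", 1.5, 1.0)
        with pytest.raises(ValueError):
            dm.KillerAllele("k", "L", 1.0, -0.1)


class TestTetradDistribution:
    def test_single_het_killer_two_two(self):
        dist = dm.tetrad_outcome_distribution(single_killer_config(1.0, 1.0))
        assert np.allclose(dist, [0, 0, 1, 0, 0])

    def test_no_killers_all_viable(self):
        cfg = dm.CrossConfig(loci=[dm.Locus("L", "c", 1)],
                             parent1={"L": "a"}, parent2={"L": "b"})
        dist = dm.tetrad_outcome_distribution(cfg)
        assert np.allclose(dist, [0, 0, 0, 0, 1])

    def test_same_locus_repulsion_kills_everything(self):
        cfg = dm.CrossConfig(
            loci=[dm.Locus("L", "c", 1)],
            parent1={"L": "kA"}, parent2={"L": "kB"},
            killers=[dm.KillerAllele("kA", "L", 1, 1),
                     dm.KillerAllele("kB", "L", 1, 1)])
        dist = dm.tetrad_outcome_distribution(cfg)
        assert np.allclose(dist, [1, 0, 0, 0, 0])

    @pytest.mark.parametrize("seed", range(6))
    def test_distribution_sums_to_one_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        r = float(rng.uniform(0, 0.5))
        cfg = _two_killer_config(r=r, same_chrom=True,
                                 kappa=float(rng.uniform(0, 1)),
                                 pi=float(rng.uniform(0, 1)))
        dist = dm.tetrad_outcome_distribution(cfg)
        assert abs(dist.sum() - 1.0) < 1e-12

    def test_parent_swap_symmetry(self):
        cfg = _two_killer_config(kappa=0.7, pi=0.6)
        assert dm.expected_viability(cfg) == pytest.approx(
            dm.expected_viability(cfg.swapped_parents()), abs=1e-12)


class TestExpectedViability:
    def test_single_het_killer(self):
        assert dm.expected_viability(single_killer_config(1, 1)) == pytest.approx(0.5)

    def test_two_unlinked_killers_in_repulsion(self):
        assert dm.expected_viability(_two_killer_config()) == pytest.approx(0.25)

    def test_both_parents_same_killer_full_viability(self):
        cfg = dm.CrossConfig(
            loci=[dm.Locus("L", "c", 1)],
            parent1={"L": "k"}, parent2={"L": "k"},
            killers=[dm.KillerAllele("k", "L", 1, 1)])
        assert dm.expected_viability(cfg) == pytest.approx(1.0)


class TestViablePoolFrequency:
    def test_unlinked_marker_unaffected(self):
        cfg = dm.CrossConfig(
            loci=[dm.Locus("L", "c1", 1), dm.Locus("M", "c2", 1)],
            parent1={"L": "ref", "M": "m1"},
            parent2={"L": "k", "M": "m2"},
            killers=[dm.KillerAllele("k", "L", 1, 1)])
        assert dm.expected_viable_allele_frequency(cfg, "M", "m1") == pytest.approx(0.5)

    def test_killer_locus_fixed_among_survivors(self):
        cfg = single_killer_config(1.0, 1.0)
        assert dm.expected_viable_allele_frequency(cfg, "L", "ref") == pytest.approx(0.0)

    def test_partial_penetrance_closed_form(self):
        """Carriers survive w.p. 1, non-carriers w.p. 1-kappa, so the
        non-killer allele frequency is (1-kappa)/(2-kappa)."""
        cfg = single_killer_config(0.6, 1.0)
        assert dm.expected_viable_allele_frequency(cfg, "L", "ref") == \
            pytest.approx(0.4 / 1.4)

    def test_no_viable_spores_raises(self):
        cfg = dm.CrossConfig(
            loci=[dm.Locus("L", "c", 1)],
            parent1={"L": "kA"}, parent2={"L": "kB"},
            killers=[dm.KillerAllele("kA", "L", 1, 1),
                     dm.KillerAllele("kB", "L", 1, 1)])
        with pytest.raises(ValueError, match="no viable spores"):
            dm.expected_viable_allele_frequency(cfg, "L", "kA")

    @pytest.mark.parametrize("kappa,pi", [(0.3, 1.0), (0.8, 0.6), (1.0, 0.9)])
    def test_agrees_with_monte_carlo(self, kappa, pi):
        cfg = single_killer_config(kappa, pi)
        expected = dm.expected_viable_allele_frequency(cfg, "L", "ref")
        recs = sd.simulate_meiosis_tetrads(cfg, 3000, seed=42)
        viable = [s.genotypes["L"] for r in recs for s in r.spores if s.viable]
        obs = sum(1 for g in viable if g == "ref") / len(viable)
        se = np.sqrt(expected * (1 - expected) / len(viable))
        assert abs(obs - expected) < 4 * se + 1e-9


class TestFitKillerParameters:
    def test_boundary_mle_from_deterministic_data(self):
        """All carriers viable + all non-carriers dead pins kappa=pi=1."""
        recs = sd.simulate_meiosis_tetrads(single_killer_config(1, 1), 50, seed=1)
        fit = dm.fit_killer_parameters(recs, [dm.KillerAllele("k", "L", 0.5, 0.5)])
        kappa, pi = fit.estimates["k"]
        assert kappa == pytest.approx(1.0, abs=1e-6)
        assert pi == pytest.approx(1.0, abs=1e-6)
        assert "kappa:k" in fit.at_boundary

    def test_recovers_partial_penetrance(self):
        recs = sd.simulate_meiosis_tetrads(single_killer_config(0.8, 1.0),
                                           500, seed=11)
        fit = dm.fit_killer_parameters(recs, [dm.KillerAllele("k", "L", 0.5, 0.5)])
        kappa, _ = fit.estimates["k"]
        assert abs(kappa - 0.8) < 0.05

    def test_weak_antidote_detected_with_full_penetrance(self):
        """Partial carrier death (Tb-like truncation) yields pi < 1 with
        kappa near 1."""
        recs = sd.simulate_meiosis_tetrads(single_killer_config(1.0, 0.7),
                                           500, seed=12)
        fit = dm.fit_killer_parameters(recs, [dm.KillerAllele("k", "L", 0.5, 0.5)])
        kappa, pi = fit.estimates["k"]
        assert kappa > 0.9
        assert pi < 0.95

    def test_non_identifiable_flagged(self):
        cfg = dm.CrossConfig(
            loci=[dm.Locus("L", "c", 1)],
            parent1={"L": "k"}, parent2={"L": "k"},
            killers=[dm.KillerAllele("k", "L", 1, 1)])
        recs = sd.simulate_meiosis_tetrads(cfg, 20, seed=2)
        fit = dm.fit_killer_parameters(recs, [dm.KillerAllele("k", "L", 1, 1)])
        assert "kappa:k" in fit.non_identifiable


class TestConfigSerialization:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _two_killer_config(kappa=0.8, pi=0.9)
        path = tmp_path / "cross.yaml"
        dm.save_cross_config(cfg, path)
        loaded = dm.load_cross_config(path)
        assert [l.id for l in loaded.loci] == [l.id for l in cfg.loci]
        assert loaded.killers[0].kappa == pytest.approx(0.8)
        assert dm.expected_viability(loaded) == pytest.approx(
            dm.expected_viability(cfg))

    def test_presets(self):
        ta = dm.KillerAllele.from_preset("x", "L", "Ta")
        td = dm.KillerAllele.from_preset("x", "L", "Td")
        tb = dm.KillerAllele.from_preset("x", "L", "Tb")
        te = dm.KillerAllele.from_preset("x", "L", "Te")
        assert (ta.kappa, ta.pi) == (1.0, 1.0)
        assert td.kappa == 0.0 and td.pi == 1.0
        assert tb.kappa == 1.0 and te.kappa == 1.0
        assert ta.pi > tb.pi > te.pi

    def test_haldane_fraction_limits(self):
        assert dm.haldane_fraction(0) == 0.0
        assert dm.haldane_fraction(1e12) == pytest.approx(0.5)
        assert 0 < dm.haldane_fraction(10_000) < 0.5
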