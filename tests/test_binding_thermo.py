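"""Sequential two-site Ca2+ binding: identities, free-ligand solve, ITC fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polypull import (
    ITCExperiment,
    SiteThermo,
    fit_sequential,
    free_ligand,
    gibbs_from_enthalpy_entropy,
    gibbs_from_kd,
    sequential_heats,
)
from polypull.binding_thermo import ITCThermogram, bound_fractions
from polypull.presets import monomer_binding_sites, octamer_binding_sites

SATURATING = ITCExperiment(syringe_ligand=50e-3, injection_volumes=tuple([10e-6] * 30))


class TestGibbs:
    def test_unit_kd_is_zero(self):
        assert gibbs_from_kd(1.0) == 0.0

    @pytest.mark.parametrize(
        "kd, expected",
        [(31e-6, -6.15), (200e-6, -5.05), (166e-6, -5.15)],
    )
    def test_from_kd(self, kd, expected):
        assert gibbs_from_kd(kd) == pytest.approx(expected, abs=0.02)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            gibbs_from_kd(0.0)

    @pytest.mark.parametrize(
        "dh, ds, expected",
        [(-7.7, -5.2, -6.15), (-3.2, 6.6, -5.17), (-5.0, 0.0, -5.0)],
    )
    def test_from_enthalpy_entropy(self, dh, ds, expected):
        assert gibbs_from_enthalpy_entropy(dh, ds) == pytest.approx(expected, abs=0.01)


class TestReferenceTableConsistency:
    """Every printed site obeys dG = dH - T*dS and dG = RT*ln(K_d)."""

    @pytest.mark.parametrize(
        "sites", [octamer_binding_sites(), monomer_binding_sites()],
        ids=["octamer", "monomer"],
    )
    def test_identities(self, sites):
        for site in sites:
            dev_hs, dev_kd = site.consistency()
            assert abs(dev_hs) <= 0.1
            assert abs(dev_kd) <= 0.1

    def test_octamer_total_stabilization(self):
        s1, s2 = octamer_binding_sites()
        assert -11.4 <= s1.dG + s2.dG <= -11.3


class TestFreeLigand:
    def test_zero_total_ligand(self):
        assert free_ligand(0.0, 180e-6, 3e4, 6e3) == 0.0

    def test_no_binding(self):
        assert free_ligand(1e-4, 180e-6, 0.0, 0.0) == pytest.approx(1e-4)

    def test_against_independent_bisection(self):
        P, K1, K2, Lt = 180e-6, 1 / 31e-6, 1 / 166e-6, 360e-6

        def residual(L):
            poly = 1 + K1 * L + K1 * K2 * L * L
            return L + P * (K1 * L + 2 * K1 * K2 * L * L) / poly - Lt

        lo, hi = 0.0, Lt
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if residual(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert free_ligand(Lt, P, K1, K2) == pytest.approx(lo, rel=1e-9)

    @given(
        lt=st.floats(1e-7, 1e-2),
        pt=st.floats(1e-7, 1e-3),
        kd1=st.floats(1e-7, 1e-3),
        ratio=st.floats(1.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_conservation_and_fraction_sum(self, lt, pt, kd1, ratio):
        K1, K2 = 1 / kd1, 1 / (kd1 * ratio)
        L = free_ligand(lt, pt, K1, K2)
        f0, f1, f2 = bound_fractions(L, K1, K2)
        assert f0 + f1 + f2 == pytest.approx(1.0, abs=1e-12)
        bound = pt * (f1 + 2 * f2)
        assert L + bound == pytest.approx(lt, rel=1e-9)


class TestSequentialHeats:
    def test_zero_enthalpies_give_zero_heats(self):
        sites = (
            SiteThermo.from_kd_enthalpy(31e-6, 0.0),
            SiteThermo.from_kd_enthalpy(166e-6, 0.0),
        )
        gram = sequential_heats(sites, ITCExperiment())
        assert np.allclose(gram.heats_ucal, 0.0)

    def test_saturating_total_heat(self):
        sites = octamer_binding_sites()
        gram = sequential_heats(sites, SATURATING)
        assert gram.molar_ratio[-1] >= 10
        total_cal = gram.heats_ucal.sum() / 1e6
        expected = (
            SATURATING.cell_volume
            * SATURATING.cell_protein
            * (sites[0].dH + sites[1].dH)
            * 1000.0
        )
        assert total_cal == pytest.approx(expected, rel=0.02)

    def test_exothermic_decay_shape(self):
        gram = sequential_heats(octamer_binding_sites(), ITCExperiment())
        assert gram.heats_ucal[0] < 0  # first injection carries the sign of dH1
        assert np.all(np.diff(gram.heats_ucal) > 0)  # monotone decay of exotherm
        assert abs(gram.heats_ucal[-1]) < 0.1 * abs(gram.heats_ucal[0])


class TestSequentialFit:
    def test_noiseless_recovery(self):
        sites = octamer_binding_sites()
        gram = sequential_heats(sites, ITCExperiment())
        fit = fit_sequential(gram, ITCExperiment())
        assert fit.converged
        s1, s2 = fit.sites
        assert s1.K_d == pytest.approx(31e-6, rel=0.05)
        assert s2.K_d == pytest.approx(166e-6, rel=0.05)
        assert s1.dH == pytest.approx(-8.5, rel=0.02)
        assert s2.dH == pytest.approx(-3.2, rel=0.02)
        assert s1.K_d <= s2.K_d  # sequential convention K1 >= K2

    def test_noisy_recovery_median(self):
        from polypull.synthetic_data import synthesize_itc

        sites = octamer_binding_sites()
        exp = ITCExperiment()
        kd1 = []
        for seed in np.random.SeedSequence(555).spawn(100):
            gram = synthesize_itc(sites, exp, noise_sd_fraction=0.02, rng_seed=seed)
            fit = fit_sequential(gram, exp)
            kd1.append(fit.sites[0].K_d * 1e6)
        assert 21.0 <= np.median(kd1) <= 41.0

    def test_single_site_truth_flags_site2(self):
        sites = (
            SiteThermo.from_kd_enthalpy(31e-6, -8.5),
            SiteThermo.from_kd_enthalpy(1e3, -3.2),  # K2 ~ 0: site II never fills
        )
        gram = sequential_heats(sites, SATURATING)
        fit = fit_sequential(gram, SATURATING)
        assert not fit.site2_identifiable

    def test_too_few_injections(self):
        exp = ITCExperiment(injection_volumes=tuple([10e-6] * 5))
        gram = sequential_heats(octamer_binding_sites(), exp)
        with pytest.raises(ValueError):
            fit_sequential(gram, exp)

    def test_thermogram_validation(self):
        with pytest.raises(ValueError):
            ITCThermogram(heats_ucal=np.array([1.0, np.nan]), molar_ratio=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ITCThermogram(heats_ucal=np.array([1.0]), molar_ratio=np.array([1.0, 2.0]))
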