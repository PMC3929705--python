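"""Steady-state phenylalanine/tyrosine kinetics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dystroflux.synthetic import TracerTruth, simulate_tracer_plateau
from dystroflux.tracer import (
    InconsistentEnrichmentsError,
    PlasmaEnrichment,
    TracerProtocol,
    estimate_fluxes,
    hydroxylation_flux,
    partition_flux,
    plateau_enrichment,
    ra_steady_state,
)


class TestRaSteadyState:
    def test_one_to_one_dilution(self):
        assert ra_steady_state(16.0, 50.0) == pytest.approx(16.0)

    def test_strong_dilution(self):
        # 16 × (100/4 − 1) = 16 × 24
        assert ra_steady_state(16.0, 4.0) == pytest.approx(384.0)

    def test_total_convention(self):
        assert ra_steady_state(16.0, 4.0, "total") == pytest.approx(400.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, 100.0, 101.0])
    def test_rejects_impossible_enrichment(self, bad):
        with pytest.raises(ValueError):
            ra_steady_state(16.0, bad)

    @given(e=st.floats(0.5, 99.5))
    def test_strictly_decreasing_in_enrichment(self, e):
        assert ra_steady_state(16.0, e) > ra_steady_state(16.0, e + 0.4)

    @given(ra=st.floats(10, 1000), i=st.floats(1, 50))
    def test_inverse_pair(self, ra, i):
        """plateau_enrichment is the exact inverse of ra_steady_state."""
        e = plateau_enrichment(i, ra)
        assert ra_steady_state(i, e) == pytest.approx(ra, rel=1e-12)


class TestHydroxylation:
    def test_zero_d4_tyr_means_zero_conversion(self):
        assert hydroxylation_flux(280.0, 0.0, 2.8, 16.0, 400.0) == 0.0

    def test_correction_factor_algebra(self):
        """On/off differ exactly by (i_phe + Ra_phe)/Ra_phe."""
        on = hydroxylation_flux(280.0, 0.5, 2.8, 16.0, 400.0, correction=True)
        off = hydroxylation_flux(280.0, 0.5, 2.8, 16.0, 400.0, correction=False)
        assert off / on == pytest.approx((16.0 + 400.0) / 400.0, rel=1e-12)

    def test_inconsistent_enrichments_flagged(self):
        with pytest.raises(InconsistentEnrichmentsError):
            hydroxylation_flux(280.0, 50.0, 2.8, 16.0, 10.0)


class TestPartitionFlux:
    def test_full_recycling(self):
        r = partition_flux(100.0, 0.0)
        assert r.ps_phe == 100.0 and r.net_balance == 0.0

    def test_seventeen_percent_loss(self):
        r = partition_flux(100.0, 17.0)
        assert r.ps_phe == pytest.approx(83.0)
        assert r.net_balance == pytest.approx(-17.0)
        assert r.hydroxylation_fraction == pytest.approx(0.17)

    @given(
        ra=st.floats(50, 1000),
        frac=st.floats(0, 1),
    )
    def test_flux_conservation(self, ra, frac):
        """ps + q_pt = ra to machine precision for all valid inputs."""
        r = partition_flux(ra, frac * ra)
        assert r.ps_phe + r.q_pt == pytest.approx(r.ra_phe, rel=1e-12)

    def test_protein_units(self):
        # 100 µmol/kg/h × 165.19 g/mol × 1e-6 / 0.04 = 0.413 g protein/kg/h
        r = partition_flux(100.0, 0.0, TracerProtocol())
        assert r.protein_breakdown == pytest.approx(0.413, rel=1e-3)

    def test_rejects_qpt_above_ra(self):
        with pytest.raises(ValueError):
            partition_flux(100.0, 120.0)


class TestRoundTrip:
    @pytest.mark.parametrize("convention", ["tracee", "total"])
    @pytest.mark.parametrize("correction", [True, False])
    def test_noiseless_recovery_machine_precision(self, convention, correction):
        truth = TracerTruth(
            ra_phe_true=417.3,
            ra_tyr_true=290.1,
            hydroxylation_fraction_true=0.17,
            convention=convention,
            correction=correction,
        )
        e = simulate_tracer_plateau(truth)
        r = estimate_fluxes(e, convention=convention, correction=correction)
        assert r.ra_phe == pytest.approx(truth.ra_phe_true, rel=1e-12)
        assert r.ra_tyr == pytest.approx(truth.ra_tyr_true, rel=1e-12)
        assert r.hydroxylation_fraction == pytest.approx(0.17, rel=1e-12)

    def test_zero_fraction_gives_zero_d4(self):
        truth = TracerTruth(400.0, 280.0, hydroxylation_fraction_true=0.0)
        assert simulate_tracer_plateau(truth).e_d4_tyr == 0.0

    def test_fraction_invariant_under_flux_rescaling(self):
        for scale in (0.5, 1.0, 3.0):
            truth = TracerTruth(400.0 * scale, 280.0 * scale)
            r = estimate_fluxes(simulate_tracer_plateau(truth))
            assert r.hydroxylation_fraction == pytest.approx(0.17, rel=1e-12)

    def test_noisy_estimator_nearly_unbiased(self, rng):
        """5% enrichment noise, 1000 replicates: mean within 1% of truth."""
        truth = TracerTruth(400.0, 280.0, enrichment_noise_cv=0.05)
        ras, fracs = [], []
        for _ in range(1000):
            r = estimate_fluxes(simulate_tracer_plateau(truth, rng))
            ras.append(r.ra_phe)
            fracs.append(r.hydroxylation_fraction)
        assert np.mean(ras) == pytest.approx(400.0, rel=0.01)
        assert np.mean(fracs) == pytest.approx(0.17, rel=0.01)


class TestEnrichmentValidation:
    @pytest.mark.parametrize("e5", [0.0, -1.0, 100.0])
    def test_phe_enrichment_bounds(self, e5):
        with pytest.raises(ValueError):
            PlasmaEnrichment(e_d5_phe=e5, e_d4_tyr=0.1, e_d2_tyr=3.0)

    def test_d4_tyr_may_be_zero(self):
        PlasmaEnrichment(e_d5_phe=3.0, e_d4_tyr=0.0, e_d2_tyr=3.0)

    def test_fraction_above_one_rejected_in_truth(self):
        with pytest.raises(ValueError):
            TracerTruth(400.0, 280.0, hydroxylation_fraction_true=1.2)
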