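"""Virtual-patient model and cohort-generator tests."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import truncnorm

import oxyloop as ox
from oxyloop import patient as vp
from tests.conftest import reference_patient


def _admission(pao2, paco2, hco3=24.0, spo2=None):
    return ox.BloodGas(
        pao2=pao2,
        paco2=paco2,
        ph=ox.ph_from_paco2(paco2, hco3),
        spo2=spo2 if spo2 is not None else ox.spo2_from_pao2(pao2),
        fio2=0.21,
    )


class TestInitFromAdmission:
    def test_admission_means_give_expected_gradient(self):
        params, state = ox.init_from_admission(
            _admission(52.73, 48.48), ox.Phenotype.HYPERCAPNIC
        )
        assert params.aado2_base == pytest.approx(36.40, abs=5e-3)
        assert params.paco2_base == 48.48
        assert state.pao2 == 52.73
        assert state.spo2_true == pytest.approx(ox.spo2_from_pao2(52.73))

    def test_zero_gradient_patient(self):
        # hypercapnic gas chosen so the alveolar equation gives PaO2 exactly
        paco2 = 80.0
        pao2 = 713 * 0.21 - 1.25 * paco2  # 49.73: still hypoxemic ARF territory
        params, _ = ox.init_from_admission(
            _admission(pao2, paco2, hco3=38.0), ox.Phenotype.HYPERCAPNIC
        )
        assert params.aado2_base == pytest.approx(0.0, abs=1e-9)

    def test_phenotype_mismatch_rejected(self):
        with pytest.raises(ox.AdmissionInconsistency, match="hypercapnic"):
            ox.init_from_admission(
                _admission(52.73, 48.48), ox.Phenotype.PURELY_HYPOXEMIC
            )

    def test_inconsistent_spo2_rejected(self):
        bad = _admission(52.73, 48.48, spo2=80.0)  # curve value is ~86.9
        with pytest.raises(ox.AdmissionInconsistency, match="dissociation-curve"):
            ox.init_from_admission(bad, ox.Phenotype.HYPERCAPNIC)

    def test_admission_ph_is_preserved_via_bicarbonate(self):
        adm = _admission(52.73, 48.48, hco3=27.0)
        params, _ = ox.init_from_admission(adm, ox.Phenotype.HYPERCAPNIC)
        assert ox.ph_from_paco2(params.paco2_base, params.hco3) == pytest.approx(
            adm.ph, abs=1e-12
        )


class TestAdvance:
    def test_fixed_point_at_baseline(self, rng):
        """At zero flow with no disturbances the admission state is the
        attractor: a long advance converges back to the admission PaO2."""
        ref = reference_patient(
            ox.Phenotype.PURELY_HYPOXEMIC, noise_sd=0.0, disturbance_rate=0.0
        )
        st = replace(ref.state, pao2=90.0, spo2_true=ox.spo2_from_pao2(90.0))
        for _ in range(200):
            st = ox.advance(ref.params, st, flow=0.0, dt=30.0, rng=rng)
        assert st.pao2 == pytest.approx(ref.state.pao2, abs=1e-6)

    def test_first_order_response_at_dt_tau(self, rng):
        """One step of dt = tau shrinks the gap to the target by a factor e."""
        ref = reference_patient(
            ox.Phenotype.PURELY_HYPOXEMIC, noise_sd=0.0, disturbance_rate=0.0
        )
        flow = 2.0
        target = ox.pao2_from_alveolar(
            ox.fio2_from_flow(flow), ref.state.paco2, ref.params.aado2_base
        )
        gap0 = target - ref.state.pao2
        st = ox.advance(ref.params, ref.state, flow=flow, dt=ref.params.tau_o2, rng=rng)
        assert target - st.pao2 == pytest.approx(gap0 / math.e, rel=1e-9)

    def test_hypoxemic_paco2_constant(self, rng):
        ref = reference_patient(
            ox.Phenotype.PURELY_HYPOXEMIC, noise_sd=0.0, disturbance_rate=0.0
        )
        st = ref.state
        for flow in (0.0, 5.0, 30.0, 10.0):
            st = ox.advance(ref.params, st, flow=flow, dt=60.0, rng=rng)
            assert st.paco2 == ref.params.paco2_base

    def test_hypercapnic_retention_above_threshold(self, rng):
        """SpO2 held above the retention threshold drives PaCO2 up at the
        configured linear rate; below it, PaCO2 recovers to baseline."""
        ref = reference_patient(
            ox.Phenotype.HYPERCAPNIC, noise_sd=0.0, disturbance_rate=0.0
        )
        p = ref.params
        hi_pao2 = ox.pao2_from_spo2(p.retention_threshold + 2.0)
        st = replace(ref.state, pao2=hi_pao2, spo2_true=p.retention_threshold + 2.0)
        st1 = ox.advance(p, st, flow=30.0, dt=60.0, rng=rng)
        # one minute at +2% excess: rise of rate*2 mmHg (pre-step saturation)
        assert st1.paco2 - st.paco2 == pytest.approx(p.co2_retention_rate * 2.0, rel=1e-9)
        # recovery: once saturation is below threshold, drift reverses and
        # stops exactly at baseline
        low = replace(
            st1, pao2=52.73, spo2_true=ox.spo2_from_pao2(52.73), paco2=p.paco2_base + 0.4
        )
        st2 = ox.advance(p, low, flow=0.0, dt=600.0, rng=rng)
        assert st2.paco2 == p.paco2_base

    def test_retention_never_below_baseline(self, rng):
        ref = reference_patient(
            ox.Phenotype.HYPERCAPNIC, noise_sd=0.0, disturbance_rate=0.0
        )
        st = ref.state
        for _ in range(50):
            st = ox.advance(ref.params, st, flow=0.0, dt=60.0, rng=rng)
            assert st.paco2 >= ref.params.paco2_base

    def test_spo2_true_tracks_pao2(self, rng):
        ref = reference_patient(ox.Phenotype.HYPERCAPNIC)
        st = ref.state
        for _ in range(20):
            st = ox.advance(ref.params, st, flow=3.0, dt=3.0, rng=rng)
            assert st.spo2_true == pytest.approx(ox.spo2_from_pao2(st.pao2), abs=1e-12)

    def test_disturbance_raises_gradient_then_clears(self):
        ref = reference_patient(
            ox.Phenotype.PURELY_HYPOXEMIC, noise_sd=0.0, disturbance_rate=3600.0,
            disturbance_duration=10.0,
        )
        rng = np.random.default_rng(0)
        st = ox.advance(ref.params, ref.state, 0.0, 3.0, rng)  # onset ~certain
        assert st.aado2_now == ref.params.aado2_base + ref.params.disturbance_magnitude
        quiet = replace(ref.params, disturbance_rate=0.0)
        while st.t <= st.disturbance_until + 3.0:
            st = ox.advance(quiet, st, 0.0, 3.0, rng)
        assert st.aado2_now == ref.params.aado2_base

    def test_preconditions(self, rng):
        ref = reference_patient(ox.Phenotype.HYPERCAPNIC)
        with pytest.raises(ValueError):
            ox.advance(ref.params, ref.state, flow=0.0, dt=0.0, rng=rng)
        with pytest.raises(ValueError):
            ox.advance(ref.params, ref.state, flow=-1.0, dt=3.0, rng=rng)


class TestMeasure:
    def test_noiseless_measurement_is_exact(self):
        ref = reference_patient(ox.Phenotype.HYPERCAPNIC, noise_sd=0.0)
        rng = np.random.default_rng(5)
        assert ox.measure_spo2(ref.params, ref.state, rng) == ref.state.spo2_true

    def test_seeded_series_identical(self):
        ref = reference_patient(ox.Phenotype.HYPERCAPNIC)
        a = [
            ox.measure_spo2(ref.params, ref.state, np.random.default_rng(11))
            for _ in range(1)
        ]
        r1, r2 = np.random.default_rng(11), np.random.default_rng(11)
        s1 = [ox.measure_spo2(ref.params, ref.state, r1) for _ in range(100)]
        s2 = [ox.measure_spo2(ref.params, ref.state, r2) for _ in range(100)]
        assert s1 == s2

    def test_sample_mean_unbiased(self):
        ref = reference_patient(ox.Phenotype.HYPERCAPNIC, noise_sd=0.5)
        rng = np.random.default_rng(2024)
        draws = [ox.measure_spo2(ref.params, ref.state, rng) for _ in range(10_000)]
        # CLT: mean of 1e4 draws within 3*sd/100 of the true value
        assert abs(np.mean(draws) - ref.state.spo2_true) < 3 * 0.5 / 100


class TestGenerateCohort:
    def test_reference_cohort_composition(self):
        cohort = ox.generate_cohort(13, 10, seed=42)
        assert len(cohort) == 23
        labels = [ox.classify_arf(p.admission) for p in cohort]
        assert sum(l is ox.Phenotype.HYPERCAPNIC for l in labels) == 13
        assert sum(l is ox.Phenotype.PURELY_HYPOXEMIC for l in labels) == 10

    def test_single_hypoxemic_patient_bounds(self):
        (p,) = ox.generate_cohort(0, 1, seed=0)
        assert p.params.paco2_base <= 45.0
        assert p.params.phenotype is ox.Phenotype.PURELY_HYPOXEMIC

    def test_admission_pao2_matches_truncated_normal(self):
        """Sample mean of admission PaO2 agrees with the truncated-normal
        oracle mean (truncation shifts it below the untruncated 52.73)."""
        cohort = ox.generate_cohort(0, 200, seed=9)
        pao2 = np.array([p.state.pao2 for p in cohort])
        lo, hi = vp.ADMISSION_PAO2_BOUNDS
        a = (lo - vp.ADMISSION_PAO2_MEAN) / vp.ADMISSION_PAO2_SD
        b = (hi - vp.ADMISSION_PAO2_MEAN) / vp.ADMISSION_PAO2_SD
        dist = truncnorm(a, b, loc=vp.ADMISSION_PAO2_MEAN, scale=vp.ADMISSION_PAO2_SD)
        se = dist.std() / np.sqrt(len(pao2))
        assert abs(pao2.mean() - dist.mean()) < 3 * se

    def test_spo2_derived_from_curve_not_drawn(self):
        for p in ox.generate_cohort(3, 3, seed=5):
            assert p.state.spo2_true == pytest.approx(
                ox.spo2_from_pao2(p.state.pao2), abs=1e-12
            )

    def test_gradient_nonnegative_for_all_draws(self):
        for p in ox.generate_cohort(60, 0, seed=17):
            assert p.params.aado2_base >= 0.0

    def test_reproducible_and_seed_sensitive(self):
        r1 = ox.cohort_roster(ox.generate_cohort(4, 4, seed=3))
        r2 = ox.cohort_roster(ox.generate_cohort(4, 4, seed=3))
        r3 = ox.cohort_roster(ox.generate_cohort(4, 4, seed=4))
        assert r1.equals(r2)
        assert not r1.equals(r3)

    def test_overrides_apply_to_all(self):
        for p in ox.generate_cohort(2, 2, seed=1, noise_sd=0.0, tau_o2=30.0):
            assert p.params.noise_sd == 0.0
            assert p.params.tau_o2 == 30.0

    def test_roster_table(self, tmp_path):
        cohort = ox.generate_cohort(2, 1, seed=8)
        roster = ox.cohort_roster(cohort)
        assert list(roster["id"]) == ["P01", "P02", "P03"]
        assert set(roster["phenotype"]) == {"hypercapnic", "purely_hypoxemic"}
        path = tmp_path / "roster.csv"
        roster.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == list(roster.columns)
        assert len(back) == 3

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ox.generate_cohort(-1, 5, seed=0)
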