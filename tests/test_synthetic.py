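"""Synthetic cytometry generator: determinism, planted-parameter recovery."""
import numpy as np
import pandas as pd
import pytest

from binbat.events import StimulationCondition
from binbat.synthetic import (
    ADULT_COHORT,
    CHILD_COHORT,
    CD32KineticsSpec,
    CohortSpec,
    PopulationSpec,
    ResponseModel,
    default_populations,
    sample_basophil_cd63,
    simulate_cohort,
    simulate_events,
    simulate_ofc_series,
    simulate_patient,
    write_cohort,
)

from conftest import ANTI_IGE, FMLP, GLUTEN_400, NEG_CTRL


def _baso_activated_fraction(table):
    baso = table.truth["population"] == "basophil"
    return table.truth.loc[baso, "activated"].mean(), int(baso.sum())


def _allergen(conc):
    return StimulationCondition("allergen", allergen="gluten", concentration=conc)


class TestResponseModel:
    def test_negative_control_weight_is_baseline(self):
        assert ResponseModel(f_base=0.01).activation_weight(NEG_CTRL) == 0.01

    def test_hill_midpoint(self):
        m = ResponseModel(f_base=0.01, f_max=0.6, ec50=40.0, hill=1.7)
        assert m.activation_weight(_allergen(40.0)) == pytest.approx((0.01 + 0.6) / 2)

    def test_saturation_limit(self):
        m = ResponseModel(f_base=0.01, f_max=0.6, ec50=40.0)
        assert m.activation_weight(_allergen(1e9)) == pytest.approx(0.6, abs=1e-6)

    def test_dose_monotonicity(self):
        m = ResponseModel(hill=2.3, ec50=25.0)
        doses = np.logspace(-2, 4, 50)
        w = [m.activation_weight(_allergen(d)) for d in doses]
        assert np.all(np.diff(w) >= 0)
        assert all(m.f_base <= wi <= m.f_max for wi in w)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ResponseModel(f_max=0.005)  # below f_base
        with pytest.raises(ValueError):
            ResponseModel(ec50=-1)


class TestSimulateEvents:
    def test_deterministic_for_fixed_seed(self):
        pops = default_populations()
        a = simulate_events(pops, ResponseModel(), GLUTEN_400, 5000, seed=9)
        b = simulate_events(pops, ResponseModel(), GLUTEN_400, 5000, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_fractions_must_sum_to_one(self):
        pops = default_populations()
        bad = [PopulationSpec(p.name, p.fraction * 0.5, p.channels) for p in pops]
        with pytest.raises(ValueError, match="sum"):
            simulate_events(bad, ResponseModel(), NEG_CTRL, 100, seed=0)

    def test_nonpositive_event_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_events(default_populations(), ResponseModel(), NEG_CTRL, 0, seed=0)

    @pytest.mark.parametrize("dose,expected", [
        (None, 0.01),              # negative control -> baseline
        (40.0, (0.01 + 0.6) / 2),  # EC50 -> Hill midpoint
        (1e7, 0.6),                # saturating dose -> f_max
    ])
    def test_planted_activation_fraction_recovered(self, dose, expected):
        """Empirical activated-label frequency within 3 binomial SE of plan."""
        cond = NEG_CTRL if dose is None else _allergen(dose)
        # large basophil fraction so the basophil event count is ~100k
        pops = [
            PopulationSpec("basophil", 0.5, default_populations()[0].channels),
            PopulationSpec("other_leukocyte", 0.5, default_populations()[1].channels),
        ]
        t = simulate_events(pops, ResponseModel(f_base=0.01, f_max=0.6, ec50=40.0),
                            cond, 200_000, seed=11)
        frac, n = _baso_activated_fraction(t)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_label_frequency_recovery_across_seeds(self):
        """Planted weight recovered within 4 SE in >= 99% of seeds."""
        w = 0.3
        n = 5000
        resp = ResponseModel(f_base=w, f_max=0.9)  # weight w at dose 0 via f_base
        ok = 0
        seeds = 60
        for s in range(seeds):
            v, act = sample_basophil_cd63(resp, NEG_CTRL, n, seed=s)
            ok += abs(act.mean() - w) <= 4 * np.sqrt(w * (1 - w) / n)
        assert ok / seeds >= 0.99


class TestSimulatePatient:
    def test_tolerant_allergen_weight_is_baseline(self):
        p = simulate_patient("tolerant", seed=1)
        w = {s.record.condition.label: s.planted_weight for s in p.samples}
        assert w["gluten_400"] == pytest.approx(0.01)
        assert w["negative_control"] == pytest.approx(0.01)
        assert w["fMLP"] > 0.1  # fMLP pathway intact

    def test_allergic_responder_anti_ige_saturates(self):
        resp = ResponseModel(f_max=0.55)
        p = simulate_patient("allergic", response=resp, seed=2)
        w = {s.record.condition.label: s.planted_weight for s in p.samples}
        assert w["anti_IgE"] == pytest.approx(0.55)
        assert w["gluten_400"] > 0.4          # wheat-derived allergen responds
        assert w["timothy_grass_1"] == pytest.approx(0.01)  # unrelated pollen

    def test_non_responder_fmlp_only(self):
        resp = ResponseModel(f_max=0.55)
        p = simulate_patient("allergic", non_responder=True, response=resp, seed=3)
        w = {s.record.condition.label: s.planted_weight for s in p.samples}
        assert w["anti_IgE"] == pytest.approx(0.01)
        assert w["gluten_400"] == pytest.approx(0.01)
        assert w["fMLP"] == pytest.approx(0.55)

    def test_tolerant_non_responder_rejected(self):
        with pytest.raises(ValueError):
            simulate_patient("tolerant", non_responder=True)


class TestSimulateCohort:
    def test_study_presets_have_paper_counts(self):
        child = simulate_cohort(CHILD_COHORT)
        assert len(child.patients) == 25
        assert sum(p.record.non_responder for p in child.patients) == 1
        adult = simulate_cohort(ADULT_COHORT)
        assert len(adult.patients) == 27
        statuses = [p.record.status for p in adult.patients]
        assert statuses.count("allergic") == 18 and statuses.count("tolerant") == 9

    def test_all_tolerant_cohort(self):
        c = simulate_cohort(CohortSpec(n_allergic=0, n_tolerant=5, seed=4))
        assert all(p.record.status == "tolerant" for p in c.patients)
        assert all(s.planted_weight == pytest.approx(0.01)
                   for p in c.patients for s in p.samples
                   if s.record.condition.kind == "allergen")

    def test_sige_values_positive_and_separated(self):
        c = simulate_cohort(CohortSpec(n_allergic=13, n_tolerant=11, seed=5))
        sige = c.sige.set_index("patient_id")
        assert (sige > 0).all().all()
        status = {p.record.patient_id: p.record.status for p in c.patients}
        allergic = sige.loc[[k for k, v in status.items() if v == "allergic"], "tri_a_19"]
        tolerant = sige.loc[[k for k, v in status.items() if v == "tolerant"], "tri_a_19"]
        assert allergic.min() > tolerant.max()  # planted near-perfect separator

    def test_same_seed_identical_manifest_and_events(self, tmp_path):
        spec = CohortSpec(n_allergic=1, n_tolerant=1, seed=6)
        d1 = write_cohort(simulate_cohort(spec), tmp_path / "a", n_events=2000)
        d2 = write_cohort(simulate_cohort(spec), tmp_path / "b", n_events=2000)
        m1 = (d1 / "manifest.csv").read_text()
        m2 = (d2 / "manifest.csv").read_text()
        assert m1 == m2
        f = pd.read_csv(d1 / "manifest.csv")["file"].iloc[0]
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_allergic=2, n_tolerant=3, non_responder_count=3)


class TestOfcSeries:
    def test_tolerant_noise_free_fractions_equal(self):
        spec = CD32KineticsSpec(baseline_fraction=0.5, noise_sd=0.0)
        s = simulate_ofc_series("tolerant_uneventful", spec, seed=7, n_events=1000)
        assert len(set(s.planted_fractions.values())) == 1

    def test_allergic_downregulation_arithmetic(self):
        spec = CD32KineticsSpec(baseline_fraction=0.5, downregulation_factor=0.6,
                                noise_sd=0.0)
        s = simulate_ofc_series("allergic_reaction", spec, seed=8, n_events=1000)
        assert s.planted_fractions["baseline"] == pytest.approx(0.5)
        assert s.planted_fractions["post_outcome"] == pytest.approx(0.3)

    def test_recovered_cd32_fraction_matches_plan(self):
        """Empirical CD32+ label frequency within 3 SE of the planted fraction."""
        spec = CD32KineticsSpec(baseline_fraction=0.7, noise_sd=0.0)
        pops = [
            PopulationSpec("basophil", 0.5, default_populations()[0].channels),
            PopulationSpec("other_leukocyte", 0.5, default_populations()[1].channels),
        ]
        s = simulate_ofc_series("allergic_reaction", spec, seed=9,
                                populations=pops, n_events=100_000)
        for tp, t in s.tables.items():
            baso = t.truth["population"] == "basophil"
            frac = t.truth.loc[baso, "cd32_positive"].mean()
            w = s.planted_fractions[tp]
            se = np.sqrt(w * (1 - w) / baso.sum())
            assert abs(frac - w) < 3 * se
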