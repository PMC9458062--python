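import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radiokinetics import I131
from radiokinetics.biokinetics import (
    BiokineticModel,
    ExponentialTerm,
    Representation,
    TimeActivityCurve,
    TimeActivitySample,
    evaluate,
    fit_model,
    load_models_json,
    phase_half_lives,
    round_sig,
    save_models_json,
    to_biological,
    to_effective,
)
from radiokinetics.nuclide import STABLE

from conftest import make_noise_free_curve


def q_model(terms, region="blood", nuclide=I131):
    return BiokineticModel(
        region=region,
        representation=Representation.biological_q,
        nuclide=nuclide,
        terms=[ExponentialTerm(coefficient_pct_ia=c, rate_per_h=r)
               for c, r in terms],
    )


random_terms = st.lists(
    st.tuples(st.floats(min_value=0.1, max_value=100),
              st.floats(min_value=1e-2, max_value=10)),
    min_size=1, max_size=3,
)


class TestRepresentationConversion:
    def test_to_effective_matches_published_rates(self, blood_q):
        a = to_effective(blood_q)
        assert [round(tm.rate_per_h, 3) for tm in a.terms] == [1.524, 0.033]
        assert [tm.coefficient_pct_ia for tm in a.terms] == [89.8, 10.2]

    def test_to_biological_matches_decay_corrected_rates(self, blood_a):
        q = to_biological(blood_a)
        assert q.terms[0].rate_per_h == pytest.approx(1.5204, abs=5e-4)
        assert q.terms[1].rate_per_h == pytest.approx(0.0294, abs=5e-4)

    def test_stable_label_is_identity(self):
        m = q_model([(50, 1.0)], nuclide=STABLE)
        a = to_effective(m)
        assert a.terms[0].rate_per_h == pytest.approx(1.0, rel=1e-12)

    def test_double_conversion_rejected(self, blood_q, blood_a):
        with pytest.raises(ValueError, match="already"):
            to_effective(to_effective(blood_q))
        with pytest.raises(ValueError, match="already"):
            to_biological(to_biological(blood_a))

    def test_rate_at_or_below_lambda_r_rejected(self):
        lam_r = I131.decay_constant_per_h
        m = BiokineticModel(
            region="r", representation=Representation.effective_A, nuclide=I131,
            terms=[ExponentialTerm(coefficient_pct_ia=10, rate_per_h=lam_r)],
        )
        with pytest.raises(ValueError, match="non-positive"):
            to_biological(m)

    @settings(deadline=None, derandomize=True)
    @given(random_terms)
    def test_round_trip_identity(self, terms):
        m = q_model(terms)
        back = to_biological(to_effective(m))
        assert np.allclose(back.coefficients, m.coefficients, rtol=1e-12)
        assert np.allclose(back.rates, m.rates, rtol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(random_terms, st.floats(min_value=0, max_value=200))
    def test_decay_correction_identity(self, terms, t):
        """q(t) = A(t)·exp(λR·t) for every model and time."""
        m = q_model(terms)
        lhs = evaluate(m, t)
        rhs = evaluate(to_effective(m), t) * math.exp(
            I131.decay_constant_per_h * t)
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestEvaluate:
    def test_t0_is_coefficient_sum(self, blood_a):
        assert evaluate(blood_a, 0.0) == pytest.approx(100.0)

    def test_half_life_point(self):
        m = q_model([(100, 1.0)])
        assert evaluate(m, math.log(2)) == pytest.approx(50.0)

    def test_long_time_limit(self, blood_a):
        assert evaluate(blood_a, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self, blood_a):
        with pytest.raises(ValueError):
            evaluate(blood_a, -0.1)

    @settings(deadline=None, derandomize=True)
    @given(random_terms, st.floats(min_value=0, max_value=100),
           st.floats(min_value=1e-6, max_value=100))
    def test_strictly_decreasing_nonnegative(self, terms, t, dt):
        m = q_model(terms)
        v1, v2 = evaluate(m, t), evaluate(m, t + dt)
        assert v2 < v1
        assert v2 >= 0


class TestPhaseHalfLives:
    def test_biological_phases_print_as_published(self, blood_q):
        hl = [round_sig(h, 2) for h in phase_half_lives(blood_q)]
        assert hl == [0.46, 24.0]

    def test_effective_phases_print_as_published(self, blood_a):
        hl = [round_sig(h, 2) for h in phase_half_lives(blood_a)]
        assert hl == [0.45, 21.0]

    def test_single_term(self):
        assert phase_half_lives(q_model([(1, 1.0)])) == [
            pytest.approx(math.log(2))]


class TestFitModel:
    def test_q_domain_curve_yields_q_model(self, blood_curve_q, nuclide):
        m = fit_model(blood_curve_q, nuclide, n_terms=2)
        assert m.representation is Representation.biological_q
        assert m.coefficients == pytest.approx([89.8, 10.2], rel=1e-6)
        assert m.rates == pytest.approx([1.520, 0.029], rel=1e-6)
        assert m.fit_diagnostics.rss < 1e-12

    def test_a_domain_curve_yields_a_model(self, blood_a, nuclide):
        curve = make_noise_free_curve(
            blood_a, [0.25, 0.5, 1, 2, 3, 5, 8, 24, 48, 96, 120, 144],
            decay_corrected=False)
        m = fit_model(curve, nuclide, n_terms=2)
        assert m.representation is Representation.effective_A
        assert m.rates == pytest.approx([1.524, 0.033], rel=1e-6)

    def test_auto_term_selection_picks_two(self, blood_curve_q, nuclide):
        m = fit_model(blood_curve_q, nuclide, n_terms="auto")
        assert len(m.terms) == 2

    def test_insufficient_samples_rejected(self, nuclide):
        curve = TimeActivityCurve(region="x", samples=[
            TimeActivitySample(time_h=1.0, value_pct_ia=10.0),
            TimeActivitySample(time_h=2.0, value_pct_ia=5.0),
        ])
        with pytest.raises(ValueError, match="at least"):
            fit_model(curve, nuclide, n_terms=2)


class TestTypesAndSerialization:
    def test_curve_requires_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            TimeActivityCurve(region="x", samples=[
                TimeActivitySample(time_h=2.0, value_pct_ia=1.0),
                TimeActivitySample(time_h=1.0, value_pct_ia=2.0),
            ])

    def test_curve_requires_consistent_flag(self):
        with pytest.raises(ValueError, match="decay_corrected"):
            TimeActivityCurve(region="x", samples=[
                TimeActivitySample(time_h=1.0, value_pct_ia=1.0,
                                   decay_corrected=True),
                TimeActivitySample(time_h=2.0, value_pct_ia=0.5,
                                   decay_corrected=False),
            ])

    def test_terms_sorted_on_construction(self):
        m = q_model([(10, 0.03), (90, 1.5)])
        assert m.rates[0] > m.rates[1]

    def test_json_round_trip(self, tmp_path, blood_q):
        path = tmp_path / "models.json"
        save_models_json([blood_q], path)
        (loaded,) = load_models_json(path)
        assert loaded == blood_q
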