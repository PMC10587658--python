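"""Parameter loading/validation, population derivation, genotype risk
stratification and life tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyp2c19_cea import (
    InfeasibleParametersError,
    ParameterError,
    derive_genotype_risks,
    estimate_population,
    generate_life_table,
    get_value,
    load_life_table,
    load_parameters,
    save_life_table,
    save_parameters,
    with_value,
)
from cyp2c19_cea.parameters import SCALAR_PARAMETERS, ParameterSet


class TestParameterFile:
    def test_default_file_round_trips_and_holds_headline_values(
        self, paper_params, tmp_path
    ):
        path = tmp_path / "params.yaml"
        save_parameters(paper_params, path)
        reloaded = load_parameters(path)
        assert reloaded == paper_params  # bit-identical round trip
        assert reloaded.costs.test == 60.0
        assert reloaded.costs.staff == 16.91
        assert reloaded.economics.lambda_per_qaly == 20000.0
        assert reloaded.economics.discount_rate == 0.035
        assert reloaded.cohort.start_age == 67
        assert reloaded.cohort.cohort_size == 60424

    def test_out_of_range_field_is_rejected_by_name(self, paper_params, tmp_path):
        data = paper_params.model_dump()
        data["genetics"]["lof_prevalence"] = 1.5
        path = tmp_path / "bad.yaml"
        import yaml

        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ParameterError, match="lof_prevalence"):
            load_parameters(path)

    def test_unknown_keys_rejected(self, paper_params, tmp_path):
        data = paper_params.model_dump()
        data["unexpected_section"] = {"x": 1}
        import yaml

        path = tmp_path / "extra.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ParameterError, match="unexpected_section"):
            load_parameters(path)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "broken.yaml"
        path.write_text("cohort: [unbalanced\n")
        import yaml

        with pytest.raises(yaml.YAMLError):
            load_parameters(path)

    def test_all_zero_probabilities_are_a_valid_degenerate_model(self, paper_params):
        data = paper_params.model_dump()
        for key in data["risks"]:
            data["risks"][key] = 0.0
        ps = ParameterSet.model_validate(data)
        assert ps.risks.p_stroke_clopidogrel_avg == 0.0

    def test_registry_covers_threshold_parameters_and_round_trips(self, paper_params):
        for name in (
            "rr_clopidogrel_no_lof",
            "test_cost",
            "tolerance_clopidogrel",
            "tolerance_mrd_aspirin",
        ):
            assert name in SCALAR_PARAMETERS
        updated = with_value(paper_params, "test_cost", 99.0)
        assert get_value(updated, "test_cost") == 99.0
        assert get_value(paper_params, "test_cost") == 60.0  # original untouched
        with pytest.raises(ParameterError, match="unknown parameter"):
            with_value(paper_params, "nonexistent", 1.0)


class TestEstimatePopulation:
    @pytest.mark.parametrize(
        "incidence, population, frac, expected",
        [
            (1.07, 66_436_000, 0.85, (71_087, 60_424)),  # published UK derivation
            (0.0, 5_000_000, 0.85, (0, 0)),
            (1.0, 1_000_000, 0.5, (1_000, 500)),
        ],
    )
    def test_examples(self, incidence, population, frac, expected):
        counts = estimate_population(incidence, population, frac)
        assert (counts.first_strokes, counts.ischaemic_strokes) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            estimate_population(-1.0, 1000, 0.5)
        with pytest.raises(ParameterError):
            estimate_population(1.0, 1000, 1.5)

    @given(
        incidence=st.floats(0.01, 10.0),
        population=st.floats(1e4, 1e8),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_homogeneous_degree_one_in_population(self, incidence, population, scale):
        base = incidence / 1000.0 * population
        scaled = incidence / 1000.0 * (population * scale)
        assert scaled == pytest.approx(base * scale, rel=1e-12)


class TestGenotypeRisks:
    def test_no_stratification_when_rr_is_one(self):
        p_no, p_lof = derive_genotype_risks(0.04, 1.0, 0.25)
        assert p_no == pytest.approx(0.04, abs=1e-15)
        assert p_lof == pytest.approx(0.04, abs=1e-15)

    def test_published_stratified_risk(self):
        p_no, p_lof = derive_genotype_risks(0.03974, 0.702, 0.25)
        assert round(p_no, 4) == 0.0279  # the reported 2.79 %/yr for non-carriers
        assert p_lof == pytest.approx(0.0753, abs=5e-5)

    def test_hand_worked_mixture(self):
        p_no, p_lof = derive_genotype_risks(0.05, 0.8, 0.2)
        assert p_no == pytest.approx(0.04, abs=1e-15)
        assert p_lof == pytest.approx(0.09, abs=1e-15)
        assert 0.8 * p_no + 0.2 * p_lof == pytest.approx(0.05, abs=1e-15)

    @given(
        p_avg=st.floats(0.0, 0.5),
        rr=st.floats(0.1, 1.5),
        f=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, derandomize=True)
    def test_mixture_identity(self, p_avg, rr, f):
        try:
            p_no, p_lof = derive_genotype_risks(p_avg, rr, f)
        except InfeasibleParametersError:
            return
        assert (1 - f) * p_no + f * p_lof == pytest.approx(p_avg, abs=1e-12)

    def test_infeasible_combination_raises(self):
        # rr so high that carriers would need a negative risk
        with pytest.raises(InfeasibleParametersError):
            derive_genotype_risks(0.4, 1.4, 0.1)
        with pytest.raises(ParameterError):
            derive_genotype_risks(0.04, 0.7, 0.0)


class TestLifeTable:
    def test_gompertz_is_monotone_and_closes(self):
        table = generate_life_table(1e-4, 0.09, 67, 100)
        assert np.all(np.diff(table.q[:-1]) >= 0)
        assert table.q_at(100) == 1.0

    def test_closed_form_value(self):
        table = generate_life_table(1e-4, 0.09, 67, 100)
        expected = 1.0 - math.exp(-1e-4 * math.exp(0.09 * 67))
        assert table.q_at(67) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ParameterError):
            generate_life_table(0.0, 0.09, 67, 100)
        with pytest.raises(ParameterError):
            generate_life_table(1e-4, -0.1, 67, 100)

    def test_file_round_trip(self, tmp_path):
        table = generate_life_table(2e-5, 0.097, 67, 100)
        path = tmp_path / "life.tsv"
        save_life_table(table, path)
        reloaded = load_life_table(path)
        assert np.array_equal(reloaded.ages, table.ages)
        assert np.array_equal(reloaded.q, table.q)

    def test_table_without_closure_rejected(self, tmp_path):
        path = tmp_path / "open.tsv"
        path.write_text("age\tq\n67\t0.01\n68\t0.02\n")
        with pytest.raises(ParameterError, match="q = 1"):
            load_life_table(path)
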