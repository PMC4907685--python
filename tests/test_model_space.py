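"""Architecture construction, enumeration and validation."""


import pytest
from hypothesis import given, strategies as st

from m1dcm.errors import InvalidArchitectureError
from m1dcm.model_space import (
    Connection,
    ConditionModulationDesign,
    M1_OPTIONAL_EDGES,
    ModelSpec,
    Population,
    build_m1_core,
    build_reduced_cmc,
    count_connections,
    default_design,
    enumerate_m1_models,
    compared_model_space,
    validate_model,
    winning_m1_model,
)

P = Population


class TestM1Core:
    def test_thirteen_connections(self):
        assert count_connections(build_m1_core()) == 13

    def test_nine_inter_population_and_four_self(self):
        core = build_m1_core()
        assert sum(not c.is_self for c in core.connections) == 9
        assert sum(c.is_self for c in core.connections) == 4

    def test_populations_are_three_pyramidal_plus_interneurons(self):
        core = build_m1_core()
        assert set(core.populations) == {P.SP, P.MP, P.DP, P.II}
        assert P.SS not in core.populations

    def test_all_three_layer_inputs_present(self):
        assert set(build_m1_core().inputs) == {"Es", "Em", "Ed"}

    def test_interneurons_reciprocally_connected_to_all_pyramidal(self):
        core = build_m1_core()
        for pyr in (P.SP, P.MP, P.DP):
            assert core.has_connection(P.II, pyr)
            assert core.has_connection(pyr, P.II)

    def test_no_optional_edges_in_core(self):
        core = build_m1_core()
        for s, t in M1_OPTIONAL_EDGES:
            assert not core.has_connection(s, t)


class TestEnumeration:
    def test_eight_models(self):
        assert len(enumerate_m1_models()) == 8

    def test_degenerate_empty_optional_set(self):
        models = enumerate_m1_models(optional_edges=())
        assert len(models) == 1
        assert models[0] == build_m1_core()

    def test_exactly_one_model_has_all_three_optional_edges(self):
        full = [
            m for m in enumerate_m1_models()
            if all(m.has_connection(s, t) for s, t in M1_OPTIONAL_EDGES)
        ]
        assert len(full) == 1

    def test_models_unique_and_valid(self):
        models = enumerate_m1_models()
        assert len(set(models)) == 8
        for m in models:
            assert validate_model(m) == []

    def test_power_set_size_for_k_optional(self):
        for k in range(3):
            models = enumerate_m1_models(optional_edges=M1_OPTIONAL_EDGES[:k])
            assert len(models) == 2 ** k

    def test_rejects_non_m1_core(self):
        with pytest.raises(InvalidArchitectureError):
            enumerate_m1_models(core=build_reduced_cmc())


class TestWinningModel:
    def test_fourteen_connections(self):
        assert count_connections(winning_m1_model()) == 14

    def test_contains_deep_to_superficial_feedback(self):
        assert winning_m1_model().has_connection(P.DP, P.SP)

    def test_no_deep_middle_reciprocal_connections(self):
        w = winning_m1_model()
        assert not w.has_connection(P.MP, P.DP)
        assert not w.has_connection(P.DP, P.MP)

    def test_equals_enumerated_subset_dp_sp_only(self):
        target = [
            m for m in enumerate_m1_models()
            if m.has_connection(P.DP, P.SP)
            and not m.has_connection(P.DP, P.MP)
            and not m.has_connection(P.MP, P.DP)
        ]
        assert target == [winning_m1_model()]


class TestReducedCMC:
    def test_contains_spiny_stellate(self):
        assert P.SS in build_reduced_cmc().populations

    def test_family(self):
        assert build_reduced_cmc().architecture_family == "reduced_cmc"

    def test_twelve_connections_in_declared_default_graph(self):
        assert count_connections(build_reduced_cmc()) == 12

    def test_granular_input_only(self):
        cmc = build_reduced_cmc()
        assert list(cmc.inputs) == ["Eg"]
        assert cmc.inputs["Eg"] is P.SS

    def test_valid(self):
        assert validate_model(build_reduced_cmc()) == []


class TestComparedModelSpace:
    def test_nine_models_ordered_winning_then_cmc(self):
        space = compared_model_space()
        assert len(space) == 9
        assert space[0] == winning_m1_model()
        assert space[1] == build_reduced_cmc()
        assert len(set(space)) == 9


class TestValidation:
    def test_winning_model_has_no_violations(self):
        assert validate_model(winning_m1_model()) == []

    def test_excitatory_interneuron_output_flagged(self):
        core = build_m1_core()
        bad = [
            Connection(c.source, c.target, sign="excitatory")
            if (c.source is P.II and c.target is P.SP) else c
            for c in core.connections
        ]
        model = ModelSpec(core.name, core.populations, tuple(bad), core.inputs)
        violations = validate_model(model)
        assert len(violations) == 1
        assert "sign" in violations[0]

    def test_m1_with_three_populations_flagged(self):
        model = ModelSpec(
            name="broken",
            populations=(P.SP, P.DP, P.II),
            connections=(Connection(P.SP, P.DP), Connection(P.II, P.SP)),
            inputs={"Es": P.SP, "Em": P.SP, "Ed": P.DP},
        )
        assert any("four populations" in v for v in validate_model(model))

    def test_duplicate_connection_flagged(self):
        core = build_m1_core()
        model = ModelSpec(
            core.name, core.populations,
            core.connections + (core.connections[0],), core.inputs,
        )
        assert any("duplicate" in v for v in validate_model(model))

    def test_spiny_stellate_outside_cmc_flagged(self):
        model = ModelSpec(
            name="bad",
            populations=(P.SS, P.SP, P.DP, P.II),
            connections=(),
            inputs={"Es": P.SP, "Em": P.SP, "Ed": P.DP},
            architecture_family="m1",
        )
        assert any("spiny_stellate" in v for v in validate_model(model))

    def test_inhibitory_out_edges_only_from_interneurons(self):
        for m in enumerate_m1_models():
            for c in m.connections:
                if c.sign == "inhibitory" and not c.is_self:
                    assert c.source is P.II


class TestSerialisation:
    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_round_trip_lossless(self, fmt):
        for model in [winning_m1_model(), build_reduced_cmc()]:
            if fmt == "yaml":
                restored = ModelSpec.from_yaml(model.to_yaml())
            else:
                restored = ModelSpec.from_json(model.to_json())
            assert restored == model
            assert restored.name == model.name
            assert [c.modulated for c in restored.connections] == [
                c.modulated for c in model.connections
            ]

    @given(st.integers(min_value=0, max_value=7))
    def test_round_trip_all_enumerated(self, i):
        model = enumerate_m1_models()[i]
        assert ModelSpec.from_yaml(model.to_yaml()) == model


class TestDesign:
    def test_rest_is_reference(self):
        with pytest.raises(InvalidArchitectureError):
            ConditionModulationDesign(conditions=("grip", "rest"))

    def test_default_design_modulates_everything(self):
        model = winning_m1_model()
        design = default_design(model)
        assert design.modulated_connections == tuple(range(14))
        assert set(design.modulated_inputs) == {"Es", "Em", "Ed"}
        assert design.non_rest_conditions == ("grip", "post_grip")
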