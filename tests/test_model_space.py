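"""Model-space structure: validation, moves, counting, distance, resolution."""

from __future__ import annotations

import numpy as np
import pytest

from famos.model_space import (
    DefaultRule,
    ModelId,
    ModelSpaceError,
    ParameterSpace,
    backward_neighbors,
    count_models,
    forward_neighbors,
    most_distant_model,
    random_model,
    resolve_parameters,
    swap_neighbors,
    validate_model,
)

from conftest import all_valid_models, brute_force_neighbors, random_space


class TestSpaceConstruction:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ModelSpaceError, match="duplicate"):
            ParameterSpace(parameter_names=("a", "a"))

    def test_unknown_reference_rejected(self):
        with pytest.raises(ModelSpaceError, match="unknown"):
            ParameterSpace(parameter_names=("a",), critical_sets=[{"zz"}])

    def test_fixed_and_critical_conflict(self):
        with pytest.raises(ModelSpaceError, match="fixed and critical"):
            ParameterSpace(
                parameter_names=("a", "b"),
                critical_sets=[{"a"}],
                fixed_values={"a": 1.0},
            )

    def test_cyclic_default_rules_detected_at_load(self):
        with pytest.raises(ModelSpaceError, match="cyclic"):
            ParameterSpace(
                parameter_names=("a", "b"),
                default_rules={
                    "a": (DefaultRule("b"),),
                    "b": (DefaultRule("a"),),
                },
            )

    def test_bad_bounds(self):
        with pytest.raises(ModelSpaceError, match="lower < upper"):
            ParameterSpace(parameter_names=("a",), bounds={"a": (1.0, 1.0)})


class TestValidateModel:
    def test_critical_set_satisfied_by_one_member(self, critical_space):
        m = ModelId.from_names(critical_space, ["mu_AB"])
        assert validate_model(m, critical_space)

    def test_empty_model_invalid(self, simple_space):
        assert not validate_model(ModelId((0, 0, 0, 0)), simple_space)

    def test_untouched_critical_set_invalid(self, critical_space):
        m = ModelId.from_names(critical_space, ["rho_B"])
        assert not validate_model(m, critical_space)

    def test_included_fixed_parameter_invalid(self):
        space = ParameterSpace(parameter_names=("a", "b"), fixed_values={"b": 2.0})
        assert not validate_model(ModelId((1, 1)), space)

    def test_length_mismatch_raises(self, simple_space):
        with pytest.raises(ModelSpaceError, match="length"):
            validate_model(ModelId((1, 0)), simple_space)


class TestNeighborhoods:
    def test_forward_from_empty(self):
        space = ParameterSpace(parameter_names=("a", "b", "c"))
        got = forward_neighbors(ModelId((0, 0, 0)), space)
        assert {str(m) for m in got} == {"100", "010", "001"}

    def test_forward_from_global_empty(self, simple_space):
        assert forward_neighbors(simple_space.global_model(), simple_space) == []

    def test_forward_count_16_parameter_space(self):
        space = ParameterSpace(parameter_names=tuple(f"p{i}" for i in range(16)))
        m = ModelId.from_names(space, [f"p{i}" for i in range(5)])
        assert len(forward_neighbors(m, space)) == 11

    def test_backward_simple(self):
        space = ParameterSpace(parameter_names=("a", "b", "c"))
        got = backward_neighbors(ModelId((1, 1, 0)), space)
        assert {str(m) for m in got} == {"010", "100"}

    def test_backward_respects_critical_set(self, critical_space):
        m = ModelId.from_names(critical_space, ["mu_AB", "rho_B"])
        got = backward_neighbors(m, critical_space)
        # dropping mu_AB would empty the critical set: absent
        assert ModelId.from_names(critical_space, ["rho_B"]) not in got
        assert ModelId.from_names(critical_space, ["mu_AB"]) in got

    def test_backward_from_singleton_empty(self, simple_space):
        m = ModelId((1, 0, 0, 0))
        assert backward_neighbors(m, simple_space) == []

    def test_swap_replaces_within_set(self):
        space = ParameterSpace(
            parameter_names=("mu_AB", "rho_B", "x"),
            swap_sets=[{"mu_AB", "rho_B"}],
        )
        m = ModelId.from_names(space, ["mu_AB", "x"])
        got = swap_neighbors(m, space)
        assert got == [ModelId.from_names(space, ["rho_B", "x"])]

    def test_swap_without_sets_empty(self, simple_space):
        m = ModelId((1, 1, 0, 0))
        assert swap_neighbors(m, simple_space) == []

    def test_swap_full_set_pair_count(self):
        # brute force over the 4-bit space: 2 included x 2 excluded = 4 swaps
        space = ParameterSpace(
            parameter_names=("a", "b", "c", "d"),
            swap_sets=[{"a", "b", "c", "d"}],
        )
        m = ModelId((1, 1, 0, 0))
        got = swap_neighbors(m, space)
        assert len(got) == 4
        assert set(got) == set(brute_force_neighbors(m, space, "swap"))

    def test_critical_sets_act_as_swap_sets(self, critical_space):
        m = ModelId.from_names(critical_space, ["mu_AB"])
        got = swap_neighbors(m, critical_space)
        assert ModelId.from_names(critical_space, ["mu_CB"]) in got

    @pytest.mark.parametrize("method", ["forward", "backward", "swap"])
    @pytest.mark.parametrize("trial", range(8))
    def test_neighbors_match_brute_force_oracle(self, method, trial):
        """Generated neighbourhoods equal exhaustive enumeration on
        random spaces with up to 12 parameters."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 13))
        space = random_space(rng, n)
        valid = all_valid_models(space)
        if not valid:
            pytest.skip("degenerate random space")
        for m in (rng.choice(len(valid), size=min(5, len(valid)), replace=False)):
            alpha = valid[int(m)]
            got = {
                "forward": forward_neighbors,
                "backward": backward_neighbors,
                "swap": swap_neighbors,
            }[method](alpha, space)
            assert len(got) == len(set(got))  # no duplicates
            assert set(got) == set(brute_force_neighbors(alpha, space, method))

    def test_forward_backward_symmetry(self):
        rng = np.random.default_rng(7)
        space = random_space(rng, 8)
        for alpha in all_valid_models(space):
            for beta in forward_neighbors(alpha, space):
                assert alpha in backward_neighbors(beta, space)

    def test_all_emitted_neighbors_valid_and_at_right_distance(self):
        rng = np.random.default_rng(11)
        space = random_space(rng, 9)
        for alpha in all_valid_models(space)[:40]:
            for m in forward_neighbors(alpha, space) + backward_neighbors(alpha, space):
                assert validate_model(m, space)
                assert alpha.hamming(m) == 1
            for m in swap_neighbors(alpha, space):
                assert validate_model(m, space)
                assert alpha.hamming(m) == 2 and m.k == alpha.k


class TestCountModels:
    @pytest.mark.parametrize(
        "n,expected", [(16, 65535), (25, 33_554_432 - 1), (1, 1), (42, 2**42 - 1)]
    )
    def test_counts(self, n, expected):
        assert count_models(n) == expected

    def test_25_parameters_exceed_33_million(self):
        assert count_models(25) > 3.3e7

    def test_invalid_n(self):
        with pytest.raises(ModelSpaceError):
            count_models(0)


class TestMostDistant:
    def test_single_tested_global(self, simple_space):
        # complement of the all-ones model is the (invalid) empty model,
        # so the optimum is any single-parameter model at distance 3;
        # the canonical tie-break picks the lexicographically smallest
        got = most_distant_model([simple_space.global_model()], simple_space)
        assert str(got) == "0001"
        assert got.hamming(simple_space.global_model()) == 3

    def test_two_tested_brute_force(self):
        space = ParameterSpace(parameter_names=("a", "b"))
        got = most_distant_model(
            [ModelId((1, 0)), ModelId((0, 1))], space
        )
        assert str(got) == "11"  # the only model at min-distance 1 from both

    def test_respects_critical_sets(self, critical_space):
        tested = [critical_space.global_model()]
        got = most_distant_model(tested, critical_space)
        assert validate_model(got, critical_space)

    @pytest.mark.parametrize("trial", range(5))
    def test_heuristic_matches_exhaustive_min_distance(self, trial):
        """The hill climb attains the same optimal min-distance as
        exhaustive search on 12-parameter instances."""
        rng = np.random.default_rng(50 + trial)
        space = random_space(rng, 12)
        valid = all_valid_models(space)
        if not valid:
            pytest.skip("degenerate random space")
        tested = [valid[int(i)] for i in rng.choice(len(valid), size=6, replace=False)]
        exact = most_distant_model(tested, space, exhaustive_limit=20)
        heur = most_distant_model(tested, space, exhaustive_limit=0, seed=trial)
        d_exact = min(exact.hamming(t) for t in tested)
        d_heur = min(heur.hamming(t) for t in tested)
        assert validate_model(heur, space)
        assert d_heur == d_exact

    def test_empty_tested_raises(self, simple_space):
        with pytest.raises(ModelSpaceError):
            most_distant_model([], simple_space)


class TestRandomModel:
    def test_valid_and_seedable(self, critical_space):
        rng = np.random.default_rng(3)
        models = [random_model(critical_space, rng) for _ in range(20)]
        assert all(validate_model(m, critical_space) for m in models)
        again = [random_model(critical_space, np.random.default_rng(3)) for _ in range(1)]
        assert again[0] == models[0]


class TestResolveParameters:
    @pytest.fixture
    def chain_space(self):
        """Three-deep inheritance chain r0 <- r1 <- r2 plus a literal."""
        return ParameterSpace(
            parameter_names=("r0", "r1", "r2", "lit"),
            default_rules={
                "r1": (DefaultRule("r0"),),
                "r2": (DefaultRule("r1"),),
                "lit": (DefaultRule(0.0),),
            },
        )

    def test_chain_inheritance(self, chain_space):
        m = ModelId.from_names(chain_space, ["r0"])
        out = resolve_parameters(m, {"r0": 0.5}, chain_space)
        assert out.tolist() == [0.5, 0.5, 0.5, 0.0]

    def test_chain_restarts_at_selected_generation(self, chain_space):
        m = ModelId.from_names(chain_space, ["r0", "r2"])
        out = resolve_parameters(m, {"r0": 0.5, "r2": 0.9}, chain_space)
        assert out.tolist() == [0.5, 0.5, 0.9, 0.0]

    def test_guarded_rule_falls_through(self):
        # s tracks c unless any of {s} is included (impossible when s
        # itself is excluded), mimicking environment inheritance
        space = ParameterSpace(
            parameter_names=("c", "s", "s2"),
            default_rules={
                "s": (DefaultRule("c"),),
                "s2": (
                    DefaultRule("s", only_if_any=frozenset({"s", "s2"})),
                    DefaultRule("c"),
                ),
            },
        )
        m = ModelId.from_names(space, ["c"])
        out = resolve_parameters(m, {"c": 0.3}, space)
        assert out.tolist() == [0.3, 0.3, 0.3]
        # once s is selected, s2 inherits from s rather than c
        m2 = ModelId.from_names(space, ["c", "s"])
        out2 = resolve_parameters(m2, {"c": 0.3, "s": 0.7}, space)
        assert out2.tolist() == [0.3, 0.7, 0.7]

    def test_fixed_value_used(self):
        space = ParameterSpace(parameter_names=("a", "b"), fixed_values={"b": 4.5})
        out = resolve_parameters(ModelId((1, 0)), {"a": 1.0}, space)
        assert out.tolist() == [1.0, 4.5]

    def test_no_rule_resolves_to_zero(self, simple_space):
        out = resolve_parameters(ModelId((1, 0, 0, 0)), {"a": 2.0}, simple_space)
        assert out.tolist() == [2.0, 0.0, 0.0, 0.0]

    def test_missing_fitted_value_raises(self, simple_space):
        with pytest.raises(ModelSpaceError, match="missing"):
            resolve_parameters(ModelId((1, 1, 0, 0)), {"a": 1.0}, simple_space)

    def test_idempotent_and_total(self, chain_space):
        m = ModelId.from_names(chain_space, ["r0"])
        out1 = resolve_parameters(m, {"r0": 0.5}, chain_space)
        out2 = resolve_parameters(m, {"r0": 0.5}, chain_space)
        assert np.array_equal(out1, out2)
        assert out1.shape == (chain_space.n,)
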