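"""iMAT integration: discretization, GPR logic, MILP vs brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipoclock.metabolic import (
    InfeasibleModelError,
    MetabolicModel,
    Reaction,
    activity_time_course,
    cosinor_r_squared,
    discretize_expression,
    eval_gpr,
    imat_solve,
    map_gpr_states,
    map_reactions_to_genes,
    parse_gpr,
    rhythmic_reactions,
)
from adipoclock.simulate import TOY_MODEL_CATALOGUE, make_toy_metabolic_model


class TestDiscretize:
    def test_deciles_of_one_to_ten(self):
        s = discretize_expression(
            pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
        )
        assert s.tolist() == [-1, -1, 0, 0, 0, 0, 0, 0, 1, 1]

    def test_all_equal_is_all_neutral(self):
        s = discretize_expression(np.full(8, 3.3))
        assert (s == 0).all()

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            discretize_expression(np.arange(5.0), low_pct=80, high_pct=20)

    def test_tail_fractions_near_nominal(self):
        rng = np.random.default_rng(0)
        s = discretize_expression(rng.normal(size=1000))
        assert abs((s == -1).mean() - 0.20) <= 0.01
        assert abs((s == 1).mean() - 0.20) <= 0.01

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=5, max_size=30),
        st.integers(0, 29),
        st.floats(0.1, 5.0),
    )
    def test_monotone_in_each_gene(self, values, pos, bump):
        """Raising one gene's value never lowers its state."""
        arr = np.asarray(values)
        pos = pos % len(arr)
        before = discretize_expression(arr)[pos]
        arr2 = arr.copy()
        arr2[pos] += bump
        after = discretize_expression(arr2)[pos]
        assert after >= before


class TestGpr:
    def test_and_is_min(self):
        assert eval_gpr("g1 and g2", {"g1": 1, "g2": -1}) == -1

    def test_or_is_max(self):
        assert eval_gpr("g1 or g2", {"g1": -1, "g2": 1}) == 1

    def test_nested_expression(self):
        rule = "(g1 and g2) or (g3 and g4)"
        states = {"g1": 1, "g2": 0, "g3": 1, "g4": 1}
        assert eval_gpr(rule, states) == 1

    def test_missing_gene_is_neutral(self):
        assert eval_gpr("g1 and gX", {"g1": 1}) == 0

    def test_malformed_rule_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_gpr("g1 and (g2 or")

    def test_map_gpr_states_defaults(self):
        model = make_toy_metabolic_model("chain3")
        states = map_gpr_states(model, {"g1": 1, "g2": -1})
        assert states["R1"] == 1 and states["R2"] == -1
        assert states["EX_A"] == 0  # no GPR -> neutral

    def test_malformed_gpr_reaction_neutral(self):
        model = MetabolicModel(
            id="m", metabolites=["A"], genes=["g1"],
            reactions=[
                Reaction("EX_in", {"A": 1.0}, lb=-10, exchange=True),
                Reaction("EX_out", {"A": -1.0}, lb=-10, exchange=True,
                         gpr="g1 and ("),
            ],
        )
        states = map_gpr_states(model, {"g1": 1})
        assert states["EX_out"] == 0


class TestImatSolve:
    def test_chain_activation_routes_full_flux(self):
        model = make_toy_metabolic_model("chain3")
        flux, activity, congruency = imat_solve(model, {"R1": 1})
        assert congruency == 1
        v = dict(zip(model.reaction_ids, flux))
        assert abs(v["R1"]) >= 1.0 and abs(v["R2"]) >= 1.0
        S = model.stoichiometric_matrix()
        assert np.abs(S @ flux).max() <= 1e-6
        assert activity["R1"] == 1

    def test_branch_competition(self):
        model = make_toy_metabolic_model("branch")
        flux, activity, congruency = imat_solve(model, {"R1": -1, "R2": 1})
        assert congruency == 2
        v = dict(zip(model.reaction_ids, flux))
        assert abs(v["R1"]) <= 1e-6 and abs(v["R2"]) >= 1.0
        assert activity["R1"] == -1 and activity["R2"] == 1

    def test_all_neutral_gives_zero_congruency(self):
        model = make_toy_metabolic_model("chain3")
        _, _, congruency = imat_solve(model, {})
        assert congruency == 0

    def test_deterministic_flux(self):
        model = make_toy_metabolic_model("loop")
        f1, a1, c1 = imat_solve(model, {"R1": 1, "R4": -1})
        f2, a2, c2 = imat_solve(model, {"R1": 1, "R4": -1})
        assert np.array_equal(f1, f2) and c1 == c2

    def test_lexicographic_stage_minimises_total_flux(self):
        """With R1 forced active in the diamond, the canonical optimum
        routes flux through the top branch only, at the minimal total."""
        model = make_toy_metabolic_model("diamond")
        flux, _, congruency = imat_solve(model, {"R1": 1})
        v = dict(zip(model.reaction_ids, flux))
        assert congruency == 1
        assert abs(v["R3"]) <= 1e-6 and abs(v["R4"]) <= 1e-6
        assert np.abs(flux).sum() == pytest.approx(4.0, abs=1e-6)

    def test_epsilon_validation(self):
        model = make_toy_metabolic_model("chain3")
        with pytest.raises(ValueError):
            imat_solve(model, {}, epsilon=1e-9, zero_tol=1e-6)

    @pytest.mark.parametrize("name", sorted(TOY_MODEL_CATALOGUE))
    def test_matches_brute_force_on_catalogue(self, name, brute_force_imat):
        model = make_toy_metabolic_model(name)
        rng = np.random.default_rng(17)
        gpr_rxns = [r.id for r in model.reactions if r.gpr]
        trials = [
            {rid: 1 for rid in gpr_rxns},
            {rid: -1 for rid in gpr_rxns},
        ]
        for _ in range(6):
            trials.append({
                rid: int(rng.integers(-1, 2)) for rid in gpr_rxns
            })
        for states in trials:
            _, _, congruency = imat_solve(model, states)
            expected = brute_force_imat(model, states)
            assert congruency == expected, (name, states)

    def test_monotone_congruency(self, brute_force_imat):
        """Adding a satisfiable state never decreases optimal congruency."""
        model = make_toy_metabolic_model("chain5")
        base = {"R1": 1}
        _, _, c0 = imat_solve(model, base)
        extended = dict(base, R3=1)
        _, _, c1 = imat_solve(model, extended)
        assert c1 >= c0

    def test_infeasible_model_raises(self):
        # mass cannot balance: A is produced but never consumed, forced flux
        model = MetabolicModel(
            id="bad", metabolites=["A"], genes=["g1"],
            reactions=[Reaction("R1", {"A": 1.0}, lb=1.0, ub=2.0, gpr="g1")],
        )
        with pytest.raises(InfeasibleModelError):
            imat_solve(model, {"R1": 1})


class TestActivityTimeCourse:
    def _oscillating_expression(self):
        """chain5 genes swing from above to below a band of 20 padding
        genes, so they occupy the top quintile at the peak and the bottom
        quintile at the trough (5 of 25 genes = 20%)."""
        model = make_toy_metabolic_model("chain5")
        times = [f"t{i}" for i in range(5)]
        phase = np.array([1.0, 0.3, -1.0, 0.3, 1.0])  # cosine at 6-h steps
        rows = {}
        for g in model.genes:
            rows[g] = 8.5 + 3.0 * phase  # 11.5 at peak, 5.5 at trough
        for i in range(20):
            rows[f"pad{i}"] = np.full(5, 7.5 + 2.0 * i / 19)  # 7.5..9.5
        return model, pd.DataFrame(rows, index=times).T

    def test_constant_expression_no_candidates(self):
        model = make_toy_metabolic_model("chain3")
        expr = pd.DataFrame(
            {f"t{i}": [5.0, 6.0, 7.0] for i in range(5)},
            index=["g1", "g2", "pad"],
        )
        profiles = activity_time_course(model, expr)
        assert all(not p.has_state_change for p in profiles)

    def test_oscillating_pathway_changes_state(self):
        model, expr = self._oscillating_expression()
        profiles = activity_time_course(model, expr)
        assert len(profiles[0].states) == 5
        by_id = {p.reaction_id: p for p in profiles}
        assert by_id["R1"].has_state_change
        assert by_id["R3"].has_state_change


class TestRhythmicReactions:
    def _profile(self, states):
        from adipoclock.metabolic import ReactionActivityProfile

        arr = np.asarray(states)
        return ReactionActivityProfile(
            "r", arr, has_state_change=bool(np.ptp(arr) > 0)
        )

    def test_quadrature_cosine_profile_is_rhythmic(self):
        times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        kept = rhythmic_reactions([self._profile([1, 0, -1, 0, 1])], times)
        assert len(kept) == 1
        assert kept[0].cosinor_r_squared == pytest.approx(1.0)

    def test_twelve_hour_alternation_rejected(self):
        times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        profiles = [self._profile([1, -1, 1, -1, 1])]
        kept = rhythmic_reactions(profiles, times)
        assert kept == []
        assert profiles[0].cosinor_r_squared < 0.8

    def test_constant_profile_excluded_before_fitting(self):
        times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        prof = self._profile([1, 1, 1, 1, 1])
        kept = rhythmic_reactions([prof], times)
        assert kept == [] and np.isnan(prof.cosinor_r_squared)

    def test_threshold_is_inclusive(self):
        times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        prof = self._profile([1, 0, -1, 0, 1])
        prof.cosinor_r_squared = np.nan
        kept = rhythmic_reactions([prof], times, r2_threshold=1.0)
        assert len(kept) == 1  # R^2 == threshold counts

    def test_closed_form_least_squares_agreement(self):
        """Oracle: direct lstsq projection matches the reported R^2."""
        times = np.array([1.0, 7.5, 13.0, 19.0, 25.5])
        y = np.array([1.0, 0.0, -1.0, 0.0, 1.0])
        w = 2 * np.pi / 24
        X = np.column_stack([np.ones(5), np.cos(w * times), np.sin(w * times)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = ((y - X @ beta) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert cosinor_r_squared(y, times) == pytest.approx(1 - sse / sst)


class TestGeneMapping:
    def test_union_of_gpr_genes_by_subsystem(self):
        from adipoclock.metabolic import ReactionActivityProfile

        model = make_toy_metabolic_model("chain5")
        rhythmic = [
            ReactionActivityProfile("R1", np.array([1, 0, -1, 0, 1]), True),
            ReactionActivityProfile("R2", np.array([1, 0, -1, 0, 1]), True),
        ]
        mapped = map_reactions_to_genes(model, rhythmic)
        assert mapped == {"upper": ["g1", "g2", "g3", "g4"]}

    def test_empty_when_no_rhythmic_reactions(self):
        model = make_toy_metabolic_model("chain3")
        assert map_reactions_to_genes(model, []) == {}


def test_sbml_round_trip(tmp_path):
    """Native container -> cobra -> SBML -> native reader."""
    import cobra

    from adipoclock.metabolic import read_model_sbml

    model = make_toy_metabolic_model("branch")
    cm = cobra.Model(model.id)
    for met in model.metabolites:
        cm.add_metabolites(cobra.Metabolite(met, compartment="c"))
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lb, upper_bound=rxn.ub)
        cm.add_reactions([cr])
        cr.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in rxn.stoich.items()}
        )
        cr.gene_reaction_rule = rxn.gpr
        cr.subsystem = rxn.subsystem
    path = tmp_path / "branch.xml"
    cobra.io.write_sbml_model(cm, str(path))
    back = read_model_sbml(path)
    assert sorted(back.reaction_ids) == sorted(model.reaction_ids)
    assert set(back.genes) == set(model.genes)
    by_id = {r.id: r for r in back.reactions}
    assert by_id["R1"].stoich == {"A": -1.0, "B": 1.0}
    assert by_id["R1"].gpr == "g1"
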