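import math

import pytest

from fluxkit import (
    ModelValidationError,
    UnknownIdError,
    apply_knockout,
    essential_entities,
    knockout_scan,
    make_pairs,
    pairwise_knockout_scan,
    solve_fba,
)
from fluxkit.gpr import parse_gpr
from fluxkit.perturbation import records_table


def test_gene_knockout_respects_gpr_boolean(chain_toy):
    model, _ = chain_toy
    model.get_reaction("R_mid").gpr = parse_gpr("(g1 and g2) or g3")
    still_open = apply_knockout(model, "gene", {"g1"})
    assert still_open.get_reaction("R_mid").upper_bound == math.inf
    closed = apply_knockout(model, "gene", {"g1", "g3"})
    assert (closed.get_reaction("R_mid").lower_bound,
            closed.get_reaction("R_mid").upper_bound) == (0.0, 0.0)


def test_gene_knockout_leaves_gpr_free_reactions_untouched(chain_toy):
    model, _ = chain_toy
    model.get_reaction("R_mid").gpr = parse_gpr("g1")
    mutant = apply_knockout(model, "gene", {"g1"})
    assert mutant.get_reaction("R_up").upper_bound == 10.0  # no GPR, untouched
    assert mutant.get_reaction("R_ex").upper_bound == math.inf


def test_unknown_entity_raises(chain_toy):
    with pytest.raises(UnknownIdError):
        apply_knockout(chain_toy[0], "reaction", {"nope"})


def test_catalyst_knockout(chain_toy):
    model, _ = chain_toy
    model.get_reaction("R_mid").catalysts = ["enzA"]
    mutant = apply_knockout(model, "catalyst", {"enzA"})
    assert mutant.get_reaction("R_mid").upper_bound == 0.0
    assert solve_fba(mutant).objective_value == pytest.approx(0.0, abs=1e-9)


def test_knockdown_fraction_scales_bounds(chain_toy):
    model, _ = chain_toy
    half = apply_knockout(model, "reaction", {"R_up"}, fraction=0.5)
    assert half.get_reaction("R_up").upper_bound == 5.0
    assert solve_fba(half).objective_value == pytest.approx(5.0, abs=1e-9)
    with pytest.raises(ModelValidationError):
        apply_knockout(model, "reaction", {"R_up"}, fraction=1.5)


def test_chain_scan_every_step_essential(chain_toy):
    model, expected = chain_toy
    records = knockout_scan(model, "reaction")
    assert [r.entities[0] for r in records] == [r.id for r in model.reactions]
    assert all(r.growth_ratio == pytest.approx(0.0, abs=1e-9) for r in records)
    essential = essential_entities(records, 90.0)
    assert sorted(e[0] for e in essential) == sorted(expected["essential_reactions"])


def test_branch_scan_reroutes_around_single_knockouts(branch_toy):
    model, expected = branch_toy
    records = {r.entities[0]: r for r in knockout_scan(model, "reaction")}
    for rid in expected["singly_nonessential"]:
        assert records[rid].growth_ratio == pytest.approx(1.0, abs=1e-6)
    for rid in expected["essential_reactions"]:
        assert records[rid].growth_ratio == pytest.approx(0.0, abs=1e-9)


def test_scan_equals_manual_knockout_plus_fba(branch_toy):
    model, _ = branch_toy
    records = knockout_scan(model, "reaction")
    wt = solve_fba(model).objective_value
    for rec in records:
        manual = solve_fba(apply_knockout(model, "reaction", rec.entities))
        assert rec.mutant_objective == pytest.approx(manual.objective_value, abs=1e-9)
        assert rec.wild_type_objective == pytest.approx(wt, abs=1e-9)


def test_make_pairs():
    assert make_pairs(["a", "b", "c"]) == [("a", "b"), ("a", "c"), ("b", "c")]
    assert make_pairs(["a"]) == []
    for n in (2, 10, 50):
        ids = [f"x{i:02d}" for i in range(n)]
        pairs = make_pairs(ids)
        assert len(pairs) == n * (n - 1) // 2
        assert all(a < b for a, b in pairs)
        assert len(set(pairs)) == len(pairs)
    with pytest.raises(ModelValidationError):
        make_pairs(["a", "a"])


def test_pairwise_synthetic_lethality(branch_toy):
    model, expected = branch_toy
    pairs = make_pairs(expected["branch_reactions"])
    records = pairwise_knockout_scan(model, "reaction", pairs)
    lethal = sorted(r.entities for r in records if r.growth_ratio < 1e-6)
    assert lethal == sorted(expected["lethal_pairs"])


def test_pair_of_essentials_is_lethal(chain_toy):
    model, _ = chain_toy
    records = pairwise_knockout_scan(model, "reaction", [("R_up", "R_mid")])
    assert records[0].growth_ratio == pytest.approx(0.0, abs=1e-9)


def test_pair_ratio_bounded_by_single_ratios(branch_toy):
    """Knockouts only restrict the feasible set: ratio(pair) <= min single."""
    model, _ = branch_toy
    singles = {r.entities[0]: r.growth_ratio for r in knockout_scan(model, "reaction")}
    pairs = make_pairs([r.id for r in model.reactions])
    for rec in pairwise_knockout_scan(model, "reaction", pairs):
        a, b = rec.entities
        assert rec.growth_ratio <= min(singles[a], singles[b]) + 1e-6


def test_nested_knockout_monotonicity(branch_toy):
    model, _ = branch_toy
    sets = [("R_b1",), ("R_b1", "R_c1"), ("R_b1", "R_c1", "R_c2")]
    objs = [
        solve_fba(apply_knockout(model, "reaction", s)).objective_value for s in sets
    ]
    assert objs[1] <= objs[0] + 1e-9 and objs[2] <= objs[1] + 1e-9


def test_gene_pair_lethality(lethal_pair_toy):
    model, expected = lethal_pair_toy
    singles = knockout_scan(model, "gene")
    assert all(r.growth_ratio == pytest.approx(1.0, abs=1e-6) for r in singles)
    pair = pairwise_knockout_scan(model, "gene", [expected["lethal_gene_pair"]])
    assert pair[0].growth_ratio == pytest.approx(0.0, abs=1e-9)


def test_gene_absent_from_all_gprs_changes_nothing(lethal_pair_toy):
    model, _ = lethal_pair_toy
    model.get_reaction("R_up").gpr = parse_gpr("g_extra")
    before = solve_fba(model).objective_value
    mutant = apply_knockout(model, "gene", {"g1"})  # isozyme g2 still carries
    assert solve_fba(mutant).objective_value == pytest.approx(before, abs=1e-9)


def test_essential_entities_thresholds():
    from fluxkit.perturbation import KnockoutRecord

    rec = lambda ratio: KnockoutRecord("reaction", ("R",), "optimal", ratio, ratio, 1.0)
    assert essential_entities([rec(0.0)], 90.0) == [("R",)]
    assert essential_entities([rec(0.5)], 90.0) == []
    assert essential_entities([rec(0.5)], 40.0) == [("R",)]
    with pytest.raises(ModelValidationError):
        essential_entities([rec(0.0)], 150.0)


def test_zero_wild_type_warns_and_reports_zero_ratio(chain_toy):
    model, _ = chain_toy
    blocked = apply_knockout(model, "reaction", {"R_up"})
    with pytest.warns(UserWarning, match="wild-type objective is zero"):
        records = knockout_scan(blocked, "reaction")
    assert all(r.growth_ratio == 0.0 for r in records)


def test_records_table_shape(branch_toy):
    table = records_table(knockout_scan(branch_toy[0], "reaction"))
    assert list(table.columns) == [
        "entities", "kind", "status", "mutant_objective", "growth_ratio",
    ]
    assert len(table) == 6
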