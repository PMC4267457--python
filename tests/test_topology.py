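from fractions import Fraction

import numpy as np
import pytest

from fluxkit import (
    SizeCapError,
    UnknownIdError,
    build_stoich_matrix,
    chokepoint_report,
    chokepoints,
    identify_cycles,
    identify_extreme_paths,
    parse_flat_reactions,
    species_participation,
    split_reversible,
)
from fluxkit.core import MetabolicModel, Reaction, Species
from fluxkit.topology import _double_description

from oracles import extreme_ray_oracle


# -- species participation ----------------------------------------------

def test_participation_roles(chain_toy):
    model, _ = chain_toy
    assert species_participation(model, ["A"], "reactant") == {"A": ["R_mid"]}
    assert species_participation(model, ["A"], "product") == {"A": ["R_up"]}
    assert species_participation(model, ["A"], "any") == {"A": ["R_up", "R_mid"]}


def test_participation_reversible_matches_both_roles():
    m = parse_flat_reactions("R1 : A <-> B\n")
    assert species_participation(m, ["A"], "product") == {"A": ["R1"]}
    assert species_participation(m, ["A"], "reactant") == {"A": ["R1"]}


def test_participation_any_is_union_of_roles(branch_toy):
    model, _ = branch_toy
    for sid in ("A", "B", "D"):
        reac = set(species_participation(model, [sid], "reactant")[sid])
        prod = set(species_participation(model, [sid], "product")[sid])
        any_ = set(species_participation(model, [sid], "any")[sid])
        assert any_ == reac | prod


def test_participation_unknown_species(chain_toy):
    with pytest.raises(UnknownIdError):
        species_participation(chain_toy[0], ["nope"])


# -- chokepoints ---------------------------------------------------------

def test_chokepoints_fan_out_network():
    m = parse_flat_reactions("R1 : A -> B\nR2 : B -> C\nR3 : B -> D\n")
    report = chokepoint_report(m)
    assert sorted(report) == ["R1", "R2", "R3"]
    assert report["R1"]["uniquely_consumes"] == ["A"]
    assert report["R1"]["uniquely_produces"] == ["B"]
    assert report["R2"]["uniquely_produces"] == ["C"]


def test_parallel_route_removes_chokepoint_status():
    m = parse_flat_reactions(
        "R1 : A -> B\nR2 : B -> C\nR3 : B -> D\nR4 : A -> B\n"
    )
    found = set(chokepoints(m))
    assert "R1" not in found and "R4" not in found
    assert {"R2", "R3"} <= found


def test_chokepoints_empty_network():
    assert chokepoints(MetabolicModel("empty")) == []


def test_chokepoints_exclude_currency_species():
    m = parse_flat_reactions("R1 : A -> B + atp\nR2 : B -> C\n")
    assert "R1" in chokepoints(m)
    # ignoring atp must not change R1's status (it is unique for A and B too)
    assert "R1" in chokepoints(m, exclude_species={"atp"})


def test_chokepoints_exclude_exchanges(chain_toy):
    # R_up/R_ex touch boundary species and are not chokepoint candidates
    assert chokepoints(chain_toy[0]) == ["R_mid"]


def test_chokepoints_invariant_under_reordering(branch_toy):
    model, _ = branch_toy
    before = set(chokepoints(model))
    model.reactions = list(reversed(model.reactions))
    assert set(chokepoints(model)) == before


def _definition_check(model, exclude=()):
    """Literal restatement of the chokepoint definition, written separately
    from the implementation: on the split network, excluding exchanges, a
    reaction is a chokepoint iff it is the sole consumer or sole producer
    of some internal metabolite."""
    from fluxkit import detect_exchange_reactions
    from fluxkit.stoichiometry import fold_split_id

    split = split_reversible(model)
    ex = set(detect_exchange_reactions(split))
    rxns = [r for r in split.reactions if r.id not in ex]
    internal = {s.id for s in split.internal_species} - set(exclude)
    out = set()
    for r in rxns:
        for sid, coeff in r.stoichiometry.items():
            if sid not in internal:
                continue
            same_role = [
                o.id
                for o in rxns
                if (o.stoichiometry.get(sid, 0) < 0) == (coeff < 0)
                and o.stoichiometry.get(sid, 0) != 0
            ]
            if same_role == [r.id]:
                out.add(fold_split_id(split, r.id))
    return out


def test_chokepoints_match_definition_on_random_networks():
    rng = np.random.default_rng(2024)
    species = ["A", "B", "C", "D", "E"]
    for _ in range(25):
        n = int(rng.integers(2, 7))
        reactions = []
        for i in range(n):
            src, dst = rng.choice(len(species), size=2, replace=False)
            stoich = {species[src]: -1, species[dst]: 1}
            if rng.random() < 0.3:
                extra = species[int(rng.integers(len(species)))]
                stoich.setdefault(extra, int(rng.integers(1, 3)))
            reactions.append(
                Reaction(f"R{i}", stoich, reversible=bool(rng.random() < 0.3))
            )
        model = MetabolicModel("rand", [Species(s) for s in species], reactions)
        assert set(chokepoints(model)) == _definition_check(model)


# -- extreme paths and cycles -------------------------------------------

def test_chain_has_single_extreme_path(chain_toy):
    model, expected = chain_toy
    rays = identify_extreme_paths(model)
    assert len(rays) == expected["n_extreme_paths"]
    assert rays[0].coefficients == {
        "R_up": Fraction(1), "R_mid": Fraction(1), "R_ex": Fraction(1)
    }
    assert rays[0].kind == "extreme_path"


def test_branch_has_one_path_per_route(branch_toy):
    model, expected = branch_toy
    rays = identify_extreme_paths(model)
    assert len(rays) == expected["n_extreme_paths"]
    supports = {ray.support() for ray in rays}
    assert supports == {
        frozenset({"R_up", "R_b1", "R_c1", "R_ex"}),
        frozenset({"R_up", "R_b2", "R_c2", "R_ex"}),
    }


def test_dead_network_has_no_rays():
    m = parse_flat_reactions("R1 : A -> B\n")  # no exchange, irreversible
    assert identify_extreme_paths(m) == []


def test_cycle_detection(cycle_toy):
    model, expected = cycle_toy
    cycles = identify_cycles(model)
    assert len(cycles) == expected["n_cycles"]
    assert cycles[0].support() == frozenset(expected["cycle_support"])
    assert cycles[0].kind == "internal_cycle"


def test_pure_chain_has_no_cycles(chain_toy):
    assert identify_cycles(chain_toy[0]) == []


def test_reversible_pair_forms_one_cycle():
    m = parse_flat_reactions("R1 : A <-> B\n")
    cycles = identify_cycles(m)
    assert len(cycles) == 1
    assert cycles[0].support() == {"R1_fwd", "R1_rev"}


def test_rays_balance_exactly(any_toy):
    """S . ray = 0 in exact arithmetic and every coefficient >= 0."""
    model, _ = any_toy
    split = split_reversible(model)
    S = build_stoich_matrix(split)
    for ray in identify_extreme_paths(model):
        assert all(c > 0 for c in ray.coefficients.values())
        for i in range(len(S.row_ids)):
            balance = sum(
                S.entries.get((i, j), Fraction(0)) * ray.coefficients.get(rid, Fraction(0))
                for j, rid in enumerate(S.col_ids)
            )
            assert balance == 0


def test_size_cap_refusal(branch_toy):
    with pytest.raises(SizeCapError, match="6"):
        identify_extreme_paths(branch_toy[0], size_cap=5)


def test_double_description_matches_support_enumeration():
    """DD output equals brute-force support enumeration on random small
    stoichiometries (<= 8 reactions)."""
    rng = np.random.default_rng(77)
    for _ in range(30):
        m = int(rng.integers(1, 4))  # species
        n = int(rng.integers(2, 9))  # reactions
        rows = [
            [Fraction(int(rng.integers(-2, 3))) for _ in range(n)] for _ in range(m)
        ]
        dd = {
            tuple(vec)
            for vec in _double_description(rows, n)
        }
        brute = extreme_ray_oracle(rows, n)
        assert dd == brute


def test_toy_rays_match_oracle(any_toy):
    model, _ = any_toy
    split = split_reversible(model)
    S = build_stoich_matrix(split)
    n = len(S.col_ids)
    rows = [
        [S.entries.get((i, j), Fraction(0)) for j in range(n)]
        for i in range(len(S.row_ids))
    ]
    expected = extreme_ray_oracle(rows, n)
    got = set()
    for ray in identify_extreme_paths(model):
        got.add(tuple(ray.coefficients.get(rid, Fraction(0)) for rid in S.col_ids))
    assert got == expected
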