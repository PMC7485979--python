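"""Patch clustering, disruption scoring and exact set-cover panel design."""

import itertools

import numpy as np
import pytest

from epimode import (MutationSpec, Patch, ToySpec, cluster_patches,
                     design_variant_panel, make_toy_complex, score_disruption)
from epimode.paneldesign import check_coverage, enumerate_candidate_variants, read_ddg_table


def key(n, chain="T"):
    return (chain, n, "")


# ---------------------------------------------------------------------------
# clustering

def brute_force_clusters(keys, coords, radius):
    """Transitive closure of the pairwise <= radius relation."""
    n = len(keys)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(keys[i])
    return {frozenset(g) for g in groups.values()}


def test_two_far_groups_make_two_patches(toy, toy_part):
    epitopes = {"M1": {key(1), key(2)}, "M2": {key(8), key(9)}}
    patches = cluster_patches(epitopes, toy, radius=8.5)
    assert len(patches) == 2
    assert {p.residues for p in patches} == {
        frozenset({key(1), key(2)}), frozenset({key(8), key(9)})}
    assert {p.member_models for p in patches} == {frozenset({"M1"}), frozenset({"M2"})}


def test_chained_residues_make_one_patch(toy):
    epitopes = {"M1": {key(n) for n in range(1, 7)}}
    patches = cluster_patches(epitopes, toy, radius=8.5)
    assert len(patches) == 1
    assert patches[0].residues == frozenset(key(n) for n in range(1, 7))


def test_planted_three_clusters_match_brute_force(toy):
    epitopes = {"M1": {key(1), key(2)}, "M2": {key(5), key(6)}, "M3": {key(10), key(11)}}
    patches = cluster_patches(epitopes, toy, radius=8.5)
    keys = sorted(set().union(*epitopes.values()))
    coords = [toy.residue(k).rep_coord() for k in keys]
    assert {p.residues for p in patches} == brute_force_clusters(keys, coords, 8.5)
    assert len(patches) == 3


def test_missing_epitope_residue_is_named(toy):
    with pytest.raises(KeyError, match="99"):
        cluster_patches({"M1": {key(99)}}, toy)


# ---------------------------------------------------------------------------
# disruption scoring

def test_disruption_proxy_orders_contact_over_noncontact(toy, toy_part):
    contacting = MutationSpec(key(6), wt="A", sub="K")  # in the planted epitope
    remote = MutationSpec(key(11), wt="A", sub="K")
    s_contact = score_disruption(toy, contacting, toy_part)
    s_remote = score_disruption(toy, remote, toy_part)
    assert s_remote == 0.0
    assert s_contact > s_remote


def test_disruption_zero_for_same_class_substitution(toy, toy_part):
    same_class = MutationSpec(key(6), wt="A", sub="V")  # both hydrophobic
    assert score_disruption(toy, same_class, toy_part) == 0.0


def test_disruption_wt_mismatch_rejected(toy, toy_part):
    with pytest.raises(ValueError, match="ALA"):
        score_disruption(toy, MutationSpec(key(6), wt="H", sub="K"), toy_part)


def test_ddg_table_passthrough(toy, toy_part, tmp_path):
    p = tmp_path / "ddg.tsv"
    p.write_text("chain\tnumber\ticode\twt\tsub\tddg\nT\t6\t-\tA\tK\t2.75\n")
    table = read_ddg_table(p)
    m = MutationSpec(key(6), wt="A", sub="K")
    assert score_disruption(toy, m, toy_part, table=table) == 2.75
    with pytest.raises(KeyError):
        score_disruption(toy, MutationSpec(key(6), wt="A", sub="W"), toy_part, table=table)


# ---------------------------------------------------------------------------
# set cover

def exhaustive_min_cover_size(candidates, universe):
    """Smallest number of candidate coverage sets whose union is the universe."""
    for size in range(0, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if frozenset().union(*combo, frozenset()) >= universe:
                return size
    return None


def single_position_patches(positions):
    return [Patch(frozenset({p}), frozenset()) for p in positions]


def test_single_model_single_patch():
    epitopes = {"M1": {key(1), key(2)}}
    patches = [Patch(frozenset({key(1), key(2)}), frozenset({"M1"}))]
    panels = design_variant_panel(epitopes, patches)
    assert panels[0].objective[0] == 1
    assert panels[0].covered_models == {"M1"}
    assert check_coverage(panels[0], epitopes)


def test_three_models_two_patches_minimal_size_two():
    a, b, c, d, e, f, g, h = (key(n) for n in range(1, 9))
    epitopes = {"M1": {a, b, c}, "M2": {c, d, e}, "M3": {f, g, h}}
    patches = [Patch(frozenset({a, b, c, d, e}), frozenset({"M1", "M2"})),
               Patch(frozenset({f, g, h}), frozenset({"M3"}))]
    panels = design_variant_panel(epitopes, patches)
    best = panels[0]
    assert best.objective[0] == 2
    assert best.covered_models == {"M1", "M2", "M3"}
    assert not best.uncoverable_models
    assert check_coverage(best, epitopes)


def test_uncoverable_model_is_reported():
    epitopes = {"M1": {key(1)}, "M2": {key(50)}}
    patches = [Patch(frozenset({key(1)}), frozenset({"M1"}))]
    panels = design_variant_panel(epitopes, patches)
    assert panels[0].uncoverable_models == {"M2"}
    assert panels[0].covered_models == {"M1"}


def random_instance(rng, n_models, n_positions):
    positions = [key(i) for i in range(1, n_positions + 1)]
    epitopes = {
        f"M{m}": set(rng.choice(len(positions),
                                size=rng.integers(1, min(4, n_positions) + 1),
                                replace=False))
        for m in range(n_models)
    }
    epitopes = {m: {positions[i] for i in idx} for m, idx in epitopes.items()}
    # patches: random contiguous blocks covering all positions
    patches = []
    start = 0
    while start < n_positions:
        width = int(rng.integers(2, 6))
        block = positions[start:start + width]
        members = frozenset(m for m, e in epitopes.items() if set(block) & e)
        patches.append(Patch(frozenset(block), members))
        start += width
    return epitopes, patches


@pytest.mark.parametrize("trial", range(20))
def test_panel_size_equals_exhaustive_minimum(trial):
    rng = np.random.default_rng(1000 + trial)
    epitopes, patches = random_instance(rng, n_models=int(rng.integers(2, 9)),
                                        n_positions=int(rng.integers(4, 13)))
    panels = design_variant_panel(epitopes, patches, k=3)
    best = panels[0]
    coverable = frozenset(epitopes) - best.uncoverable_models
    candidates = [v.covered_models for v, _ in
                  enumerate_candidate_variants(epitopes, patches, k=3)]
    assert best.objective[0] == exhaustive_min_cover_size(candidates, coverable)
    assert check_coverage(best, epitopes)
    assert best.objective[0] <= len(epitopes)


def test_adding_a_model_never_shrinks_the_panel():
    rng = np.random.default_rng(7)
    epitopes, patches = random_instance(rng, n_models=5, n_positions=10)
    base = design_variant_panel(epitopes, patches)[0]
    grown = dict(epitopes)
    grown["M_extra"] = {key(1), key(2)}
    patches_grown = [Patch(p.residues, p.member_models | {"M_extra"}
                           if p.residues & grown["M_extra"] else p.member_models)
                     for p in patches]
    bigger = design_variant_panel(grown, patches_grown)[0]
    assert (bigger.objective[0] + len(bigger.uncoverable_models)
            >= base.objective[0] + len(base.uncoverable_models))


def test_alternate_panels_are_distinct_and_ordered():
    a, b, c, d = key(1), key(2), key(3), key(4)
    epitopes = {"M1": {a, b}, "M2": {c, d}, "M3": {a, c}}
    patches = [Patch(frozenset({a, b}), frozenset({"M1", "M3"})),
               Patch(frozenset({c, d}), frozenset({"M2", "M3"}))]
    panels = design_variant_panel(epitopes, patches, alternates=2,
                                  disruption={a: 2.0, b: 1.0, c: 1.0, d: 3.0})
    assert len(panels) == 3
    sizes = [p.objective[0] for p in panels]
    assert sizes == sorted(sizes)
    seen = {tuple(sorted(tuple(sorted(v.positions)) for v in p.variants)) for p in panels}
    assert len(seen) == len(panels)
    for p in panels:
        assert check_coverage(p, epitopes)
    # among equal-size panels, higher total disruption ranks first
    assert panels[0].objective[1] >= panels[1].objective[1] or sizes[0] < sizes[1]
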