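"""Position calls, consistency filtering, surrogate energies and ranking."""

import itertools

import numpy as np
import pytest

from epimode import (AssayEntry, AssayTable, ChainPartition, EnergyScore,
                     SymmetryMap, call_positions, filter_models,
                     rank_and_select, score_interface, spearman_rho)
from epimode.filterrank import parse_mutation, read_energy_table
from epimode.interface import contacts_under_symmetry

from conftest import random_rigid_transform


def table(rows, wt=128.0):
    entries = [AssayEntry("WT", (), wt)]
    for vid, muts, kd in rows:
        entries.append(AssayEntry(vid, tuple(parse_mutation(m) for m in muts), kd))
    return AssayTable.from_entries(entries)


# ---------------------------------------------------------------------------
# calls

def test_triple_mutant_and_singles_reproduce_measured_fold_changes():
    """128 -> 427 nM is a ~3.3-fold loss; the 194/187 nM singles are ~1.5-fold
    losses and called disruptive; an unchanged single stays neutral."""
    assay = table([
        ("Var3", ["A.H310A", "A.N315K", "A.H435K"], 427.0),
        ("H310A", ["A.H310A"], 194.0),
        ("N315K", ["A.N315K"], 187.0),
        ("H435K", ["A.H435K"], 128.0),
    ])
    calls = {c.position: c for c in call_positions(assay)}
    assert calls[("A", 310, "")].status == "disrupted"
    assert calls[("A", 310, "")].fold_change == pytest.approx(194 / 128, abs=1e-6)
    assert calls[("A", 315, "")].status == "disrupted"
    assert calls[("A", 315, "")].fold_change == pytest.approx(187 / 128, abs=1e-6)
    assert calls[("A", 435, "")].status == "neutral"
    # the triple mutant's 3.3-fold loss yields no per-position constraint of its own
    from epimode.filterrank import variant_fold_changes
    assert variant_fold_changes(assay)["Var3"] == pytest.approx(427 / 128, abs=1e-6)


def test_boundary_fold_disrupted_at_explicit_threshold():
    assay = table([("X", ["A.A10K"], 194.0)])
    call, = call_positions(assay, threshold=1.5)
    assert call.fold_change == pytest.approx(1.5156, abs=1e-3)
    assert call.status == "disrupted"


def test_equal_kd_is_neutral_and_multis_untested():
    assay = table([
        ("same", ["A.A10K"], 128.0),
        ("double", ["A.A11K", "A.A12K"], 500.0),
    ])
    calls = {c.position: c for c in call_positions(assay)}
    assert calls[("A", 10, "")].status == "neutral"
    assert calls[("A", 11, "")].status == "untested"
    assert calls[("A", 12, "")].status == "untested"
    assert np.isnan(calls[("A", 11, "")].fold_change)


def test_missing_wt_rejected():
    with pytest.raises(ValueError, match="WT"):
        AssayTable.from_entries([AssayEntry("V1", (), 100.0)])


def test_assay_csv_round_trip(tmp_path):
    assay = table([("V1", ["A.H310A"], 427.0)])
    p = tmp_path / "assay.csv"
    assay.to_csv(p)
    back = AssayTable.from_csv(p)
    assert back.wt_kd == assay.wt_kd
    assert back.entries["V1"].kd_nm == 427.0
    assert back.entries["V1"].mutations[0].position == ("A", 310, "")


# ---------------------------------------------------------------------------
# filtering

def k(n, chain="T"):
    return (chain, n, "")


def call(pos, status):
    from epimode.filterrank import PositionCall
    return PositionCall(position=pos, status=status, fold_change=float("nan"))


def brute_force_filter(epitopes, calls, sym=None):
    out = []
    for m, epi in epitopes.items():
        epi = frozenset(epi)
        ok = True
        for c in calls:
            hit = contacts_under_symmetry(epi, c.position, sym)
            if c.status == "disrupted" and not hit:
                ok = False
            if c.status == "neutral" and hit:
                ok = False
        if ok:
            out.append(m)
    return sorted(out)


def test_stated_filter_example():
    epitopes = {"M1": {k(1), k(2)}, "M2": {k(2), k(5)}, "M3": {k(1), k(5)}}
    calls = [call(k(1), "disrupted"), call(k(2), "disrupted"), call(k(5), "neutral")]
    assert filter_models(epitopes, calls) == ["M1"]


def test_no_calls_keeps_every_model():
    epitopes = {"M1": {k(1)}, "M2": {k(2)}}
    assert filter_models(epitopes, []) == ["M1", "M2"]


def test_contradictory_calls_empty_result():
    epitopes = {"M1": {k(1)}, "M2": {k(2)}}
    calls = [call(k(1), "disrupted"), call(k(1), "neutral")]
    assert filter_models(epitopes, calls) == []


def test_adding_calls_never_enlarges_consistent_set():
    rng = np.random.default_rng(11)
    epitopes = {f"M{i}": {k(int(n)) for n in rng.choice(10, 3, replace=False)}
                for i in range(6)}
    calls = []
    prev = set(filter_models(epitopes, calls))
    for pos, status in [(k(0), "disrupted"), (k(4), "neutral"), (k(7), "disrupted")]:
        calls.append(call(pos, status))
        cur = set(filter_models(epitopes, calls))
        assert cur <= prev
        prev = cur


@pytest.mark.parametrize("trial", range(50))
def test_filter_matches_exhaustive_predicate(trial):
    rng = np.random.default_rng(2000 + trial)
    use_sym = trial % 2 == 1
    sym = SymmetryMap(equivalences=(frozenset({"A", "B"}),)) if use_sym else None
    chains = ["A", "B"] if use_sym else ["T"]
    epitopes = {
        f"M{i}": {(str(rng.choice(chains)), int(n), "")
                  for n in rng.choice(12, int(rng.integers(1, 5)), replace=False)}
        for i in range(int(rng.integers(2, 7)))
    }
    statuses = ["disrupted", "neutral", "untested"]
    calls = [call((str(rng.choice(chains)), int(n), ""), str(rng.choice(statuses)))
             for n in rng.choice(12, int(rng.integers(0, 5)), replace=False)]
    assert filter_models(epitopes, calls, sym) == brute_force_filter(epitopes, calls, sym)


def test_homodimer_contact_counts_on_either_protomer(homodimer):
    s, sym, part = homodimer
    from epimode import epitope_of_model
    epi = epitope_of_model(s, part)  # binder touches chain A only
    assert contacts_under_symmetry(epi, ("B", 5, ""), sym)
    assert not contacts_under_symmetry(epi, ("B", 5, ""), None)
    consistent = filter_models({"M": epi}, [call(("B", 5, ""), "disrupted")], sym)
    assert consistent == ["M"]


# ---------------------------------------------------------------------------
# surrogate energy

def test_separated_chains_score_zero(toy, toy_part):
    far = toy.transform(np.eye(3), np.array([0.0, 50.0, 0.0]),
                        chain_ids=toy_part.binder_chains)
    assert score_interface(far, toy_part).value == 0.0


def test_lj_minimum_at_analytic_distance():
    from epimode.filterrank import pair_energy
    sigma, eps = 3.4, 0.09
    r_min = 2 ** (1 / 6) * sigma
    assert pair_energy(r_min, sigma, eps, sigma, eps) == pytest.approx(-eps, abs=1e-12)
    assert pair_energy(r_min * 1.1, sigma, eps, sigma, eps) > -eps


def test_score_symmetric_in_partition_and_rigid_invariant(toy, toy_part):
    e = score_interface(toy, toy_part).value
    assert score_interface(toy, toy_part.swapped()).value == pytest.approx(e, abs=1e-9)
    rng = np.random.default_rng(5)
    rot, t = random_rigid_transform(rng)
    moved = toy.transform(rot, t)
    assert score_interface(moved, toy_part).value == pytest.approx(e, abs=1e-6)
    assert e != 0.0  # the docked pose has interacting pairs


def test_clash_flagged(toy, toy_part):
    squashed = toy.transform(np.eye(3), np.array([0.0, -3.97, 0.0]),
                             chain_ids=toy_part.binder_chains)
    score = score_interface(squashed, toy_part)
    assert score.clash


def test_energy_table_import(tmp_path, toy, toy_part):
    p = tmp_path / "energies.tsv"
    p.write_text("model_id\tenergy\n" + f"{toy.id}\t-123.5\n")
    score = score_interface(toy, toy_part, scorer="table", table=read_energy_table(p))
    assert score.value == -123.5 and score.source == "imported"


# ---------------------------------------------------------------------------
# ranking

def test_rank_excludes_unfiltered_global_minimum():
    scores = [EnergyScore("M1", -5.0, "builtin"), EnergyScore("M2", -9.0, "builtin"),
              EnergyScore("M3", -1.0, "builtin")]
    result = rank_and_select(scores, ["M1", "M3"])
    assert result.order == ("M1", "M3")
    assert result.selected == "M1"  # M2, the global minimum, was filtered out


def test_rank_singleton_and_empty():
    scores = [EnergyScore("M1", -5.0, "builtin")]
    assert rank_and_select(scores, ["M1"]).selected == "M1"
    empty = rank_and_select(scores, [])
    assert empty.selected is None and empty.no_consistent_model


def test_rank_ties_break_lexicographically():
    scores = [EnergyScore(m, -2.0, "builtin") for m in ("Mb", "Ma", "Mc")]
    assert rank_and_select(scores, ["Mb", "Ma", "Mc"]).order == ("Ma", "Mb", "Mc")


# ---------------------------------------------------------------------------
# spearman

def rank_formula_rho(x, y):
    """Direct average-rank Pearson-on-ranks computation."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean(); ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


@pytest.mark.parametrize("x,y,expected", [
    ([1, 2, 3], [10, 20, 30], 1.0),
    ([1, 2, 3], [3, 2, 1], -1.0),
])
def test_spearman_perfect_correlations(x, y, expected):
    assert spearman_rho(x, y) == pytest.approx(expected)


def test_spearman_ties_match_rank_formula():
    x, y = [1, 2, 2, 4], [1, 3, 2, 4]
    assert spearman_rho(x, y) == pytest.approx(rank_formula_rho(x, y), abs=1e-12)


def test_spearman_constant_flagged():
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))
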