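import itertools

import numpy as np
import pandas as pd
import pytest

from polyrep.annotate import annotate_library
from polyrep.clones import CloneSet, group_clones, flag_related, oligoclonality
from polyrep.simulate import serialize_mutations
from polyrep.tables import load_igg_annotations

from conftest import chain_sequences


def rec(rid, hv="1-4", kv="4-91", hc="ARAAAA", kc="QQQQT", hm=(), km=(), iso="IgG"):
    return {"id": rid, "isotype": iso, "heavy_v": hv, "kappa_v": kv,
            "heavy_cdr3": hc, "kappa_cdr3": kc,
            "heavy_mutations": serialize_mutations(list(hm)),
            "kappa_mutations": serialize_mutations(list(km))}


def test_published_66_week_igg_rows_give_exactly_two_clone_sets():
    igg = load_igg_annotations()
    sets, membership = group_clones(igg[igg.age_weeks == 66])
    got = sorted(sorted(s.member_ids) for s in sets)
    assert got == [["H2h4.7.21", "H2h4.7.25"],
                   ["H2h4.7.50", "H2h4.7.8", "H2h4.7.94"]]
    assert (membership["status"] == "identical-clone").all()


def test_all_unique_library_yields_zero_clone_sets(reference, shm_free_library):
    seqs = chain_sequences(shm_free_library)
    annot = annotate_library(seqs, reference)
    prod = annot[annot.heavy_productive.astype(bool) & annot.kappa_productive.astype(bool)]
    sets, membership = group_clones(prod)
    assert sets == [] and membership.empty


def test_simulated_expansion_recovered_as_truth_partition(reference, aged_sjs_library):
    seqs = chain_sequences(aged_sjs_library)
    meta = aged_sjs_library.metadata_frame()
    annot = annotate_library(seqs, reference,
                             metadata=meta[["id", "strain", "age_weeks", "isotype",
                                            "subclass"]])
    prod = annot[annot.heavy_productive.astype(bool) & annot.kappa_productive.astype(bool)]
    sets, _ = group_clones(prod)
    truth = {}
    for r in aged_sjs_library.records:
        if r.truth.clone_id:
            truth.setdefault(r.truth.clone_id, set()).add(r.id)
    assert {s.member_ids for s in sets} == set(map(frozenset, truth.values()))


def test_related_member_reports_three_heavy_two_kappa_extras(reference, aged_sjs_library):
    seqs = chain_sequences(aged_sjs_library)
    annot = annotate_library(seqs, reference,
                             metadata=aged_sjs_library.metadata_frame()[
                                 ["id", "strain", "age_weeks", "isotype", "subclass"]])
    prod = annot[annot.heavy_productive.astype(bool) & annot.kappa_productive.astype(bool)]
    sets, _ = group_clones(prod)
    big = next(s for s in sets if len(s) == 3)
    statuses = flag_related(big)
    related = [v for v in statuses.values() if v[0] == "clonally-related"]
    identical = [v for v in statuses.values() if v[0] == "identical-clone"]
    assert len(related) == 1 and len(identical) == 2
    assert related[0][1:] == (3, 2)
    assert all(v[1:] == (0, 0) for v in identical)


def test_identical_members_have_zero_extras():
    rows = [rec("a"), rec("b"), rec("c")]
    sets, membership = group_clones(pd.DataFrame(rows))
    assert len(sets) == 1 and len(sets[0]) == 3
    assert (membership["extra_heavy_mutations"] == 0).all()
    assert (membership["status"] == "identical-clone").all()


def test_superset_mutations_admit_clonally_related_member():
    shared = [(10, "A", "G")]
    rows = [rec("a", hm=shared), rec("b", hm=shared),
            rec("c", hm=shared + [(50, "C", "T"), (70, "G", "A"), (90, "T", "C")],
                km=[(5, "A", "C"), (40, "G", "T")])]
    sets, membership = group_clones(pd.DataFrame(rows))
    assert len(sets) == 1
    status = flag_related(sets[0])
    assert status["c"] == ("clonally-related", 3, 2)
    assert status["a"] == ("identical-clone", 0, 0)


def test_disjoint_mutation_sets_fall_into_separate_clusters():
    rows = [rec("a", hm=[(10, "A", "G")]), rec("b", hm=[(20, "C", "T")])]
    sets, _ = group_clones(pd.DataFrame(rows))
    assert sets == []  # two incomparable singletons, no multi-member set


def test_different_cdr3_blocks_grouping_by_default():
    rows = [rec("a", hc="ARAAAA"), rec("b", hc="ARAAAT")]
    sets, _ = group_clones(pd.DataFrame(rows))
    assert sets == []
    relaxed, _ = group_clones(pd.DataFrame(rows), require_cdr3_identity=False,
                              min_cdr3_identity=0.8)
    assert len(relaxed) == 1


def test_isotypes_grouped_separately_by_default():
    rows = [rec("a", iso="IgM"), rec("b", iso="IgG")]
    assert group_clones(pd.DataFrame(rows))[0] == []
    cross, _ = group_clones(pd.DataFrame(rows), group_by_isotype=False)
    assert len(cross) == 1


def test_transitive_closure_chains_identical_and_related():
    """identical pair + related member + doubly-related member -> one set."""
    m1 = [(10, "A", "G")]
    m2 = m1 + [(30, "C", "A")]
    m3 = m2 + [(60, "G", "T")]
    rows = [rec("a", hm=m1), rec("b", hm=m1), rec("c", hm=m2), rec("d", hm=m3)]
    sets, _ = group_clones(pd.DataFrame(rows))
    assert len(sets) == 1 and sorted(sets[0].member_ids) == ["a", "b", "c", "d"]


def test_ns_records_excluded_from_grouping():
    rows = [rec("a"), rec("b"), rec("c", hv="NS", hc="NS")]
    sets, membership = group_clones(pd.DataFrame(rows))
    assert sorted(sets[0].member_ids) == ["a", "b"]
    assert "c" not in set(membership["id"])


def test_grouping_is_a_partition_and_order_invariant():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(30):
        hv = f"1-{rng.integers(1, 4)}"
        shared = [(10, "A", "G")] if rng.random() < 0.5 else []
        rows.append(rec(f"r{i:02d}", hv=hv, hm=shared))
    df = pd.DataFrame(rows)
    sets1, mem1 = group_clones(df)
    shuffled = df.sample(frac=1.0, random_state=1)
    sets2, mem2 = group_clones(shuffled)
    ids1 = [m for s in sets1 for m in s.member_ids]
    assert len(ids1) == len(set(ids1))  # no record in two sets
    assert {s.member_ids for s in sets1} == {s.member_ids for s in sets2}


def brute_force_partition(df):
    """All-pairs clone/related relation + transitive closure (independent oracle)."""
    from polyrep.simulate import parse_mutations

    recs = df.to_dict("records")
    n = len(recs)

    def related(x, y):
        if (x["isotype"], x["heavy_v"], x["kappa_v"]) != \
           (y["isotype"], y["heavy_v"], y["kappa_v"]):
            return False
        if x["heavy_cdr3"] != y["heavy_cdr3"] or x["kappa_cdr3"] != y["kappa_cdr3"]:
            return False
        hx = set(parse_mutations(x["heavy_mutations"]))
        hy = set(parse_mutations(y["heavy_mutations"]))
        kx = set(parse_mutations(x["kappa_mutations"]))
        ky = set(parse_mutations(y["kappa_mutations"]))
        return (hx <= hy and kx <= ky) or (hy <= hx and ky <= kx)

    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for gi, gj in itertools.combinations(range(len(groups)), 2):
            if any(related(recs[i], recs[j]) for i in groups[gi] for j in groups[gj]):
                groups[gi] |= groups[gj]
                del groups[gj]
                changed = True
                break
    return [frozenset(recs[i]["id"] for i in g) for g in groups if len(g) > 1]


def test_grouping_matches_brute_force_oracle_on_random_libraries():
    rng = np.random.default_rng(77)
    for trial in range(5):
        rows = []
        for i in range(40):
            hv = f"1-{rng.integers(1, 3)}"
            kv = f"4-{rng.integers(1, 3)}"
            hc = "AR" + "AG"[rng.integers(2)]
            muts = [(int(p), "A", "G") for p in rng.choice(90, rng.integers(0, 3),
                                                           replace=False)]
            rows.append(rec(f"t{trial}r{i:02d}", hv=hv, kv=kv, hc=hc, hm=muts))
        df = pd.DataFrame(rows)
        sets, _ = group_clones(df)
        assert {s.member_ids for s in sets} == set(brute_force_partition(df))


# ---------------------------------------------------------------------------
# oligoclonality


def stratum_frame(ids, strain="S", age=66, iso="IgG"):
    return pd.DataFrame({"id": ids, "strain": strain, "age_weeks": age,
                         "isotype": iso})


def test_no_sets_gives_zero_fraction():
    out = oligoclonality([], stratum_frame([]), {("S", 66, "IgG"): 10})
    assert out.loc[0, "expanded_fraction"] == 0.0


def test_five_members_over_denominator_24():
    members = ["a", "b", "c", "d", "e"]
    cs1 = CloneSet("CS1", "1-4", "4-91", "X", "Y", "IgG")
    cs2 = CloneSet("CS2", "5-6", "12-46", "X", "Y", "IgG")
    from polyrep.clones import CloneMember

    cs1.members = [CloneMember(i, "identical-clone", 0, 0) for i in members[:3]]
    cs2.members = [CloneMember(i, "identical-clone", 0, 0) for i in members[3:]]
    out = oligoclonality([cs1, cs2], stratum_frame(members), {("S", 66, "IgG"): 24})
    row = out.iloc[0]
    assert row["n_clone_sets"] == 2 and row["largest_set_size"] == 3
    assert row["expanded_fraction"] == pytest.approx(5 / 24)


def test_zero_denominator_flagged_undefined():
    out = oligoclonality([], stratum_frame([]), {("S", 28, "IgG"): 0})
    assert not out.loc[0, "defined"]
    assert np.isnan(out.loc[0, "expanded_fraction"])
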