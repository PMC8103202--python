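import dataclasses

import numpy as np
import pandas as pd
import pytest

from polyrep.germline import HEAVY, KAPPA
from polyrep.reactivity import classify_od_table
from polyrep.simulate import (
    ANTIGENS,
    HybridomaLibrary,
    SimulationConfig,
    SimulationError,
    emit_reactivity,
    expand_clones,
    mutate,
    parse_mutations,
    read_library,
    recombine,
    serialize_mutations,
    simulate_library,
    simulate_study,
    sjs_preset,
    b6_preset,
    write_library,
)

from conftest import chain_sequences


# ---------------------------------------------------------------------------
# recombination


def test_zero_trim_zero_insert_is_pure_concatenation(reference):
    rng = np.random.default_rng(3)
    ct = recombine(reference, HEAVY, rng, v_trim_mean=0, d_trim_mean=0,
                   j_trim_mean=0, n_ins_mean=0, force_productive=False)
    v = reference.get(HEAVY, "V", ct.v_gene).seq
    d = reference.get(HEAVY, "D", ct.d_gene).seq
    j = reference.get(HEAVY, "J", ct.j_gene).seq
    assert ct.seq == v + d + j


def test_recombination_is_deterministic_given_seed(reference):
    a = recombine(reference, HEAVY, np.random.default_rng(11))
    b = recombine(reference, HEAVY, np.random.default_rng(11))
    assert a == b


def test_recombine_empty_pool_is_configuration_error(reference):
    from polyrep.germline import GermlineReference

    with pytest.raises(SimulationError, match="empty segment pool"):
        recombine(GermlineReference(), HEAVY, np.random.default_rng(0))


def test_forced_productive_junctions_are_in_frame_stop_free(reference):
    rng = np.random.default_rng(5)
    for _ in range(50):
        ct = recombine(reference, KAPPA, rng)
        assert ct.productive
        assert ct.cdr3_aa and "*" not in ct.cdr3_aa


def test_heavy_junction_lengths_predominantly_7_to_15(reference):
    """Default trim/insertion settings give mostly 7-15 aa heavy CDR3s."""
    rng = np.random.default_rng(17)
    lens = []
    for _ in range(1000):
        ct = recombine(reference, HEAVY, rng)
        assert ct.cdr3_aa is not None
        lens.append(len(ct.cdr3_aa))
    lens = np.asarray(lens)
    assert ((lens >= 7) & (lens <= 15)).mean() >= 0.85
    assert 7 <= np.median(lens) <= 15


# ---------------------------------------------------------------------------
# somatic hypermutation


def test_mutation_rate_zero_leaves_sequence_unchanged(reference):
    seq = reference.segments(HEAVY, "V")[0].seq
    out, muts = mutate(seq, 0.0, np.random.default_rng(0))
    assert out == seq and muts == []


def test_mutation_count_matches_poisson_oracle():
    """Mean count over many replicates within 3 SE of rate x length."""
    seq = "ACGT" * 75  # 300 nt
    rate = 0.01
    rng = np.random.default_rng(99)
    counts = [len(mutate(seq, rate, rng)[1]) for _ in range(10_000)]
    expected = rate * len(seq)
    se = np.sqrt(expected / len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se


def test_mutations_are_recorded_faithfully():
    seq = "ACGT" * 50
    out, muts = mutate(seq, 0.05, np.random.default_rng(1))
    assert len(muts) == sum(a != b for a, b in zip(seq, out))
    for pos, old, new in muts:
        assert seq[pos] == old and out[pos] == new and old != new


def test_hotspot_weighting_concentrates_mutations():
    seq = ("TAC" + "AGC" * 20) * 5  # WRC motifs at fixed spots
    rng = np.random.default_rng(2)
    hot_positions = set()
    for _ in range(300):
        _, muts = mutate(seq, 0.01, rng, hotspot_weight=25.0)
        hot_positions.update(p for p, _, _ in muts)
    from polyrep.simulate import _hotspot_weights

    w = _hotspot_weights(seq, 25.0)
    frac_hot = sum(1 for p in hot_positions if w[p] > 1) / max(len(hot_positions), 1)
    assert frac_hot > (w > 1).mean()  # enriched relative to uniform


def test_negative_rate_rejected():
    with pytest.raises(SimulationError):
        mutate("ACGT", -1.0, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# clonal expansion


def test_expansion_zero_lineages_leaves_library_unchanged(shm_free_library, reference):
    out = expand_clones(shm_free_library, reference, np.random.default_rng(0),
                        lineage_sizes=())
    assert out.records is shm_free_library.records


def test_expansion_of_empty_library_errors(reference):
    with pytest.raises(SimulationError):
        expand_clones(HybridomaLibrary([]), reference, np.random.default_rng(0),
                      lineage_sizes=(2,))


def test_oversized_lineage_request_errors():
    with pytest.raises(SimulationError, match="exceed"):
        sjs_preset(66, library_size=4, n_expanded_lineages=1, lineage_sizes=(5,))


def test_expansion_copies_share_sequences_and_extras_are_supersets(aged_sjs_library):
    by_clone = {}
    for r in aged_sjs_library.records:
        if r.truth.clone_id:
            by_clone.setdefault(r.truth.clone_id, []).append(r)
    assert sorted(len(v) for v in by_clone.values()) == [2, 3]
    for members in by_clone.values():
        founder = next(m for m in members if m.truth.clone_role == "founder")
        for m in members:
            if m.truth.clone_role == "identical":
                assert m.heavy_seq == founder.heavy_seq
                assert m.kappa_seq == founder.kappa_seq
            elif m.truth.clone_role == "related":
                fh = set(map(tuple, founder.truth.heavy.mutations))
                mh = set(map(tuple, m.truth.heavy.mutations))
                fk = set(map(tuple, founder.truth.kappa.mutations))
                mk = set(map(tuple, m.truth.kappa.mutations))
                assert fh < mh and fk < mk
                assert len(mh - fh) == 3 and len(mk - fk) == 2


def test_expansion_labels_reproducible(reference):
    cfg = dict(n_expanded_lineages=1, lineage_sizes=(3,),
               extra_members_per_lineage=(1,))
    a = simulate_library(sjs_preset(66, 40, seed=21, **cfg), reference)
    b = simulate_library(sjs_preset(66, 40, seed=21, **cfg), reference)
    assert [(r.id, r.truth.clone_id, r.truth.clone_role) for r in a.records] == \
           [(r.id, r.truth.clone_id, r.truth.clone_role) for r in b.records]


# ---------------------------------------------------------------------------
# configuration validation


@pytest.mark.parametrize("field_name,value", [
    ("polyreactive_frac", 1.5),
    ("reactive_frac", -0.1),
    ("shm_rate_per_nt", -1e-3),
    ("isotype_probs", {"IgM": 0.7, "IgG": 0.7}),
])
def test_invalid_configs_rejected(field_name, value):
    cfg = SimulationConfig()
    setattr(cfg, field_name, value)
    with pytest.raises(SimulationError):
        cfg.validate()


# ---------------------------------------------------------------------------
# ELISA emission


def test_zero_binding_zero_noise_od_equals_background(shm_free_library):
    meta, blanks = emit_reactivity(shm_free_library, noise_sigma=0.0, bg_sd=0.0,
                                   bg_mean=0.07)
    nonreactive = [i for i, r in enumerate(shm_free_library.records)
                   if r.truth.category == "non-reactive"]
    assert nonreactive
    for ag in ANTIGENS:
        assert np.allclose(meta.loc[nonreactive, ag], 0.07)
    assert np.allclose(blanks["od"], 0.07)


def test_noiseless_categories_round_trip_exactly(shm_free_library):
    meta, _ = emit_reactivity(shm_free_library, noise_sigma=0.0, bg_sd=0.0)
    cfg = shm_free_library.config
    classified, _ = classify_od_table(meta, policy="fixed", cutoff=cfg.bg_mean)
    truth = [r.truth.category for r in shm_free_library.records]
    assert (classified["category"].to_numpy() == np.array(truth)).all()


def test_default_noise_category_recovery_at_least_95pct(reference):
    cfg = sjs_preset(47, library_size=500, seed=31)
    lib = simulate_library(cfg, reference)
    meta, blanks = emit_reactivity(lib)
    classified, _ = classify_od_table(meta, blanks)
    truth = np.array([r.truth.category for r in lib.records])
    assert (classified["category"].to_numpy() == truth).mean() >= 0.95


def test_anti_ro52_records_are_always_polyreactive(aged_sjs_library):
    for r in aged_sjs_library.records:
        if r.truth.ro52:
            assert r.truth.category == "polyreactive"
            assert sum(v > 0 for v in r.truth.binding.values()) >= 3


# ---------------------------------------------------------------------------
# file round trip


def test_write_read_round_trip(tmp_path, aged_sjs_library):
    write_library(aged_sjs_library, tmp_path, np.random.default_rng(4))
    back = read_library(tmp_path)
    assert len(back) == len(aged_sjs_library)
    for a, b in zip(aged_sjs_library.records, back.records):
        assert (a.id, a.strain, a.age_weeks, a.isotype, a.subclass) == \
               (b.id, b.strain, b.age_weeks, b.isotype, b.subclass)
        assert a.heavy_seq == b.heavy_seq and a.kappa_seq == b.kappa_seq
        assert a.truth.category == b.truth.category
        assert a.truth.clone_id == b.truth.clone_id
        assert a.truth.binding == pytest.approx(b.truth.binding)
        if a.truth.heavy:
            assert sorted(map(tuple, a.truth.heavy.mutations)) == \
                   sorted(map(tuple, b.truth.heavy.mutations))


def test_empty_library_writes_valid_headers(tmp_path):
    write_library(HybridomaLibrary([]), tmp_path, np.random.default_rng(0))
    meta = pd.read_csv(tmp_path / "meta_od.tsv", sep="\t")
    assert list(meta.columns[:6]) == ["id", "strain", "age_weeks", "isotype",
                                      "subclass", "autoreactive_flag"]
    assert len(meta) == 0
    assert (tmp_path / "heavy.fasta").read_text() == ""


def test_study_preset_strata_sizes(reference):
    lib = simulate_study(seed=3, sjs_size=56, b6_size=62, reference=reference)
    meta = lib.metadata_frame()
    sjs = meta[meta.strain == "NOD.H-2h4"]
    b6 = meta[meta.strain == "C57BL/6J"]
    assert len(sjs) == 168 and len(b6) == 186
    assert sjs.groupby("age_weeks").size().to_dict() == {28: 56, 47: 56, 66: 56}
    assert b6.groupby("age_weeks").size().to_dict() == {26: 62, 47: 62, 69: 62}


def test_seeded_study_is_byte_identical(tmp_path, reference):
    a = simulate_study(seed=5, sjs_size=12, b6_size=12, reference=reference)
    b = simulate_study(seed=5, sjs_size=12, b6_size=12, reference=reference)
    write_library(a, tmp_path / "a", np.random.default_rng(1))
    write_library(b, tmp_path / "b", np.random.default_rng(1))
    for name in ("heavy.fasta", "kappa.fasta", "meta_od.tsv", "blanks.tsv", "truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_mutation_serialization_round_trip():
    muts = [(12, "A", "G"), (40, "C", "T"), (3, "G", "A")]
    assert parse_mutations(serialize_mutations(muts)) == sorted(muts)
    assert parse_mutations("") == []
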