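import numpy as np
import pytest

from pdakit import (
    Alignment,
    AnnotationTable,
    EnsembleDCAResult,
    PairedFamily,
    PlantedPairedSpec,
    concatenate,
    coupling_scores,
    ensemble_run,
    make_paired_family,
    normalize_scores,
    random_matching,
    sequence_weights,
)
from pdakit.errors import AnnotationLookupError, DataError, SchemaError

AA = "ACDEFGHIKLMNPQRSTVWY"


# --------------------------------------------------------------- weights

def test_duplicate_and_triplicate_weights(rng):
    base = "".join(rng.choice(list(AA), size=30))
    other = "".join(rng.choice(list(AA), size=30))
    third = "".join(rng.choice(list(AA), size=30))
    aln = Alignment.from_records(
        [("a1", base), ("a2", base), ("b", other),
         ("c1", third), ("c2", third), ("c3", third)]
    )
    w = sequence_weights(aln)
    lut = dict(zip(w.ids, w.weights))
    assert lut["a1"] == lut["a2"] == pytest.approx(0.5)
    assert lut["b"] == pytest.approx(1.0)
    assert lut["c1"] == lut["c2"] == lut["c3"] == pytest.approx(1 / 3)
    assert w.effective_sequences == pytest.approx(3.0)


def test_effective_sequences_bounded_by_n(rng):
    records = [
        (f"s{i}", "".join(rng.choice(list(AA), size=25))) for i in range(15)
    ]
    aln = Alignment.from_records(records)
    w = sequence_weights(aln)
    assert w.effective_sequences <= len(aln) + 1e-12
    # random 25-mers over 20 letters are all < 90% identical
    assert w.effective_sequences == pytest.approx(float(len(aln)))


def test_weights_identity_threshold_boundary():
    # 9 of 10 columns identical: identity exactly 0.9 -> neighbors
    aln = Alignment.from_records([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKV")])
    w = sequence_weights(aln, identity_threshold=0.90)
    assert np.allclose(w.weights, 0.5)


# -------------------------------------------------------------- matching

def _family(org_sizes_a, org_sizes_b, width=6, seed=0):
    rng = np.random.default_rng(seed)
    ids_a, seqs_a, ann_a = [], [], {}
    ids_b, seqs_b, ann_b = [], [], {}
    for org, n in org_sizes_a.items():
        for i in range(n):
            sid = f"{org}_A{i}"
            ids_a.append(sid)
            seqs_a.append("".join(rng.choice(list(AA), size=width)))
            ann_a[sid] = ("A", org)
    for org, n in org_sizes_b.items():
        for i in range(n):
            sid = f"{org}_B{i}"
            ids_b.append(sid)
            seqs_b.append("".join(rng.choice(list(AA), size=width)))
            ann_b[sid] = ("B", org)
    return PairedFamily(
        Alignment(tuple(ids_a), tuple(seqs_a)),
        AnnotationTable(ann_a),
        Alignment(tuple(ids_b), tuple(seqs_b)),
        AnnotationTable(ann_b),
    )


def test_matching_cardinality_and_distinctness():
    pf = _family({"o1": 2}, {"o1": 3})
    m = random_matching(pf, seed=5)
    assert len(m.pairs) == 2
    b_ids = [b for _, b in m.pairs]
    assert len(set(b_ids)) == 2


def test_matching_single_pair_is_forced():
    pf = _family({"o1": 1}, {"o1": 1})
    for seed in range(5):
        m = random_matching(pf, seed)
        assert m.pairs == (("o1_A0", "o1_B0"),)


def test_matching_skips_one_sided_organisms():
    pf = _family({"o1": 1, "o2": 2}, {"o1": 1, "o3": 4})
    m = random_matching(pf, seed=1)
    assert len(m.pairs) == 1  # only o1 has both families


def test_matching_choices_are_uniform():
    pf = _family({"o1": 1}, {"o1": 3})
    counts = {f"o1_B{i}": 0 for i in range(3)}
    n = 1000
    for seed in range(n):
        (_, b), = random_matching(pf, seed).pairs
        counts[b] += 1
    # binomial(1000, 1/3): sd ~ 14.9; allow 4 sd
    for c in counts.values():
        assert abs(c - n / 3) < 4 * np.sqrt(n * (1 / 3) * (2 / 3))


def test_matching_invariants_over_random_instances(rng):
    for trial in range(100):
        orgs = [f"o{i}" for i in range(int(rng.integers(1, 6)))]
        sizes_a = {o: int(rng.integers(0, 4)) for o in orgs}
        sizes_b = {o: int(rng.integers(0, 4)) for o in orgs}
        if not any(sizes_a.values()) or not any(sizes_b.values()):
            continue
        pf = _family(
            {o: n for o, n in sizes_a.items() if n},
            {o: n for o, n in sizes_b.items() if n},
            seed=trial,
        )
        m = random_matching(pf, seed=int(rng.integers(1 << 30)))
        a_used = [a for a, _ in m.pairs]
        b_used = [b for _, b in m.pairs]
        assert len(set(a_used)) == len(a_used)
        assert len(set(b_used)) == len(b_used)
        per_org = {}
        for a, b in m.pairs:
            oa = pf.annotations_a.organism_of(a)
            ob = pf.annotations_b.organism_of(b)
            assert oa == ob
            per_org[oa] = per_org.get(oa, 0) + 1
        for o in orgs:
            expected = min(sizes_a.get(o, 0), sizes_b.get(o, 0))
            assert per_org.get(o, 0) == expected


# ----------------------------------------------------------- concatenate

def test_concatenate_widths_and_content():
    pf = _family({"o1": 1}, {"o1": 1}, width=6)
    m = random_matching(pf, 0)
    joint = concatenate(pf, m)
    assert joint.width == 12
    sid, seq = joint.records[0]
    assert sid == "o1_A0|o1_B0"
    assert seq == pf.alignment_a.sequences[0] + pf.alignment_b.sequences[0]


def test_concatenate_empty_matching():
    pf = _family({"o1": 1}, {"o2": 1})
    joint = concatenate(pf, random_matching(pf, 0))
    assert len(joint) == 0 and joint.width == 12


def test_concatenate_dangling_id_errors():
    from pdakit.dca_ensemble import Matching

    pf = _family({"o1": 1}, {"o1": 1})
    with pytest.raises(AnnotationLookupError):
        concatenate(pf, Matching((("ghost", "o1_B0"),), 0))


# ----------------------------------------------------------- normalization

def test_normalize_affine_map():
    out = normalize_scores(np.array([[2.0, 6.0, 10.0]]))
    assert np.allclose(out, [[0.0, 0.5, 1.0]])


def test_normalize_degenerate_cases():
    with pytest.warns(UserWarning):
        assert normalize_scores(np.array([[5.0]])) == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        assert np.allclose(normalize_scores(np.full((2, 2), 3.0)), 0.0)


def test_normalize_invariant_under_positive_affine(rng):
    s = rng.random((4, 5))
    assert np.allclose(normalize_scores(s), normalize_scores(2.5 * s + 7.0))


# -------------------------------------------------------- coupling scores

def _binary_fixture(seed, n=80, la=8, lb=8, planted=(2, 5), rho=1.0):
    """All columns two-state; planted pair copied with prob rho."""
    rng = np.random.default_rng(seed)
    states_a = rng.integers(0, 2, size=(n, la))
    states_b = rng.integers(0, 2, size=(n, lb))
    copy = rng.random(n) < rho
    states_b[:, planted[1]] = np.where(
        copy, states_a[:, planted[0]], 1 - states_a[:, planted[0]]
    )
    letters = np.array([["A", "C"], ["D", "E"], ["F", "G"], ["H", "I"],
                        ["K", "L"], ["M", "N"], ["P", "Q"], ["R", "S"]])
    rows = []
    for r in range(n):
        sa = "".join(letters[j % 8][states_a[r, j]] for j in range(la))
        sb = "".join(letters[j % 8][states_b[r, j]] for j in range(lb))
        rows.append((f"s{r}", sa + sb))
    joint = Alignment.from_records(rows)
    return joint, la


def test_planted_pair_tops_inter_scores_in_binary_model():
    wins = 0
    for seed in range(20):
        joint, la = _binary_fixture(seed)
        w = sequence_weights(joint)
        inter = coupling_scores(joint, w, la)
        if np.unravel_index(np.argmax(inter), inter.shape) == (2, 5):
            wins += 1
    assert wins >= 19  # >= 95% of fixtures


def test_conserved_columns_do_not_outscore_planted_pair():
    joint, la = _binary_fixture(3)
    # make two columns strictly conserved
    rows = [(sid, "W" + seq[1 : la] + "Y" + seq[la + 1 :])
            for sid, seq in joint.records]
    joint2 = Alignment.from_records(rows)
    w = sequence_weights(joint2)
    inter = coupling_scores(joint2, w, la)
    assert inter[0, 0] <= inter[2, 5]


def test_scores_invariant_under_sequence_permutation(rng):
    joint, la = _binary_fixture(1, n=40)
    w = sequence_weights(joint)
    inter = coupling_scores(joint, w, la)
    order = rng.permutation(len(joint))
    shuffled = Alignment.from_records([joint.records[i] for i in order])
    w2 = sequence_weights(shuffled)
    inter2 = coupling_scores(shuffled, w2, la)
    assert np.allclose(inter, inter2, atol=1e-9)


def test_coupling_requires_enough_sequences():
    joint, la = _binary_fixture(0, n=5)
    w = sequence_weights(joint)
    with pytest.raises(DataError):
        coupling_scores(joint, w, la, min_sequences=10)


# ---------------------------------------------------------------- ensemble

def _result(frac, thr=0.05):
    frac = np.asarray(frac, dtype=float)
    return EnsembleDCAResult(
        n_realizations=300,
        appearance_fraction=frac,
        score_threshold=0.8,
        appearance_threshold=thr,
        base_seed=0,
        scorer_name="mean_field_scores",
        n_a=frac.shape[0],
        n_b=frac.shape[1],
    )


def test_appearance_threshold_arithmetic():
    res = _result([[30 / 300, 14 / 300]])
    assert res.appearance_fraction[0, 0] == pytest.approx(0.10)
    assert (0, 0) in res.selected_pairs
    assert (0, 1) not in res.selected_pairs


def test_selected_pairs_monotone_in_threshold():
    frac = np.array([[0.0, 0.04, 0.05, 0.2]])
    loose = set(_result(frac, thr=0.03).selected_pairs)
    tight = set(_result(frac, thr=0.10).selected_pairs)
    assert tight <= loose


def test_single_paralog_fractions_are_zero_or_one():
    spec = PlantedPairedSpec(
        n_organisms=40, paralogs_a=1, paralogs_b=1,
        n_positions_a=10, n_positions_b=10,
        planted_pairs=((1, 4),), coupling_strength=1.0, seed=3,
    )
    pf, _ = make_paired_family(spec)
    res = ensemble_run(pf, n_realizations=5, base_seed=9)
    assert set(np.unique(res.appearance_fraction)) <= {0.0, 1.0}
    assert res.appearance_fraction[1, 4] == 1.0


def test_ensemble_recovers_planted_pair_with_paralogs():
    spec = PlantedPairedSpec(
        n_organisms=40, paralogs_a=2, paralogs_b=2,
        n_positions_a=10, n_positions_b=10,
        planted_pairs=((1, 4),), coupling_strength=1.0, seed=4,
    )
    pf, truth = make_paired_family(spec)
    res = ensemble_run(pf, n_realizations=20, base_seed=17)
    assert res.appearance_fraction[1, 4] >= res.appearance_threshold
    assert (1, 4) in res.selected_pairs


def test_ensemble_output_table_is_one_based(tmp_path):
    spec = PlantedPairedSpec(
        n_organisms=20, paralogs_a=1, paralogs_b=1,
        n_positions_a=6, n_positions_b=6,
        planted_pairs=((0, 0),), coupling_strength=1.0, seed=5,
    )
    pf, _ = make_paired_family(spec)
    res = ensemble_run(pf, n_realizations=2, base_seed=0)
    df = res.to_frame()
    assert df["pos_a"].min() == 1 and df["pos_b"].min() == 1
    assert df["pos_a"].max() == 6
    sel = df[(df.pos_a == 1) & (df.pos_b == 1)].iloc[0]
    assert bool(sel.selected)


def test_ensemble_rejects_zero_realizations():
    pf = _family({"o1": 1}, {"o1": 1})
    with pytest.raises(SchemaError):
        ensemble_run(pf, n_realizations=0)
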