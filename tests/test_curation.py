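import numpy as np
import pytest

from phoskin.curation import (
    build_pools,
    extract_windows,
    sample_easy_test,
    sample_training_negatives,
    split_dataset,
)
from phoskin.records import (
    AnnotationRow,
    PairLabel,
    PeptideWindow,
    SubstrateRecord,
    validate_annotation_rows,
)


class TestExtractWindows:
    def test_short_substrate_is_padded(self):
        windows = extract_windows(SubstrateRecord("S1", "MSAYT"))
        by_pos = {w.site_position: w.residues for w in windows}
        assert set(by_pos) == {1, 3, 4}
        assert by_pos[1] == "----MSAYT--"
        assert by_pos[3] == "--MSAYT----"

    def test_substrate_without_sty_gives_nothing(self):
        assert extract_windows(SubstrateRecord("S1", "AAAAA")) == []

    def test_length_eleven_substrate_has_unpadded_window(self):
        (w,) = extract_windows(SubstrateRecord("S1", "AAAAASAAAAA"))
        assert w.residues == "AAAAASAAAAA" and "-" not in w.residues

    def test_duplicate_windows_deduplicated_per_substrate(self):
        # two S positions with identical flanking context
        seq = "AAAAASAAAAA" + "AAAAASAAAAA"
        windows = extract_windows(SubstrateRecord("S1", seq))
        assert len(windows) == 1

    def test_every_window_is_sty_centered(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        for w in extract_windows(SubstrateRecord("S1", seq)):
            assert w.residues[5] in "STY"


class TestBuildPools:
    def _fixture(self):
        subs = [
            SubstrateRecord("S1", "AAAAASAAAAATTTTTYTTTT"),
            SubstrateRecord("S2", "CCCCCSCCCCCGGGGGSGGGG"),
        ]
        rows = [
            AnnotationRow("K1", "S1", 5, "S"),
            AnnotationRow("K2", "S2", 5, "S"),
        ]
        table = validate_annotation_rows(rows, subs)
        return subs, table

    def test_cross_kinase_sites_become_hard_negatives(self):
        subs, table = self._fixture()
        positives, pools = build_pools(table, subs)
        assert [w.site_position for w in positives["K1"]] == [5]
        hard_k2 = {(w.source_substrate_id, w.site_position) for w in pools.hard["K2"]}
        assert ("S1", 5) in hard_k2
        hard_k1 = {(w.source_substrate_id, w.site_position) for w in pools.hard["K1"]}
        assert ("S2", 5) in hard_k1

    def test_shared_site_is_hard_negative_for_neither(self):
        subs = [SubstrateRecord("S1", "AAAAASAAAAA")]
        rows = [AnnotationRow("K1", "S1", 5, "S"), AnnotationRow("K2", "S1", 5, "S")]
        table = validate_annotation_rows(rows, subs)
        positives, pools = build_pools(table, subs)
        assert positives["K1"] == positives["K2"]
        assert pools.hard["K1"] == [] and pools.hard["K2"] == []

    def test_unannotated_sites_become_easy_negatives(self):
        # 10 distinct S-centered windows, 3 annotated -> 7 easy negatives
        seq = "".join(ch * 5 + "S" + ch * 5 for ch in "ACDEFGHIKL")
        sub = SubstrateRecord("S1", seq)
        sty = [i for i, aa in enumerate(seq) if aa in "STY"]
        assert len(sty) == 10
        rows = [AnnotationRow("K1", "S1", p, "S") for p in sty[:3]]
        table = validate_annotation_rows(rows, [sub])
        _, pools = build_pools(table, [sub])
        assert len(pools.easy) == 7

    def test_pool_disjointness(self):
        subs, table = self._fixture()
        positives, pools = build_pools(table, subs)
        easy_keys = {(w.source_substrate_id, w.site_position) for w in pools.easy}
        for k in positives:
            pos_keys = {(w.source_substrate_id, w.site_position) for w in positives[k]}
            hard_keys = {(w.source_substrate_id, w.site_position) for w in pools.hard[k]}
            assert not pos_keys & hard_keys
            assert not pos_keys & easy_keys
            assert not hard_keys & easy_keys


def _random_problem(seed):
    """A small random annotation problem for split/sampling tests."""
    rng = np.random.default_rng(seed)
    subs = [
        SubstrateRecord(f"S{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80)))
        for i in range(6)
    ]
    rows, seen = [], set()
    for k in range(3):
        n_sites = int(rng.integers(1, 60))
        for _ in range(n_sites):
            sub = subs[int(rng.integers(len(subs)))]
            sty = [i for i, aa in enumerate(sub.sequence) if aa in "STY"]
            if not sty:
                continue
            pos = int(rng.choice(sty))
            if (k, sub.substrate_id, pos) in seen:
                continue
            seen.add((k, sub.substrate_id, pos))
            rows.append(AnnotationRow(f"K{k}", sub.substrate_id, pos, sub.sequence[pos]))
    return subs, validate_annotation_rows(rows, subs)


class TestSplitDataset:
    def _positives(self, n, kinase="K1"):
        rng = np.random.default_rng(1)
        out = []
        seen = set()
        while len(out) < n:
            body = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=10))
            res = body[:5] + "S" + body[5:]
            if res in seen:
                continue
            seen.add(res)
            out.append(PeptideWindow(res, f"SUB{len(out)}", 20))
        return {kinase: out}

    def _pools(self, n_hard=200):
        rng = np.random.default_rng(2)
        hard = []
        for i in range(n_hard):
            body = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=10))
            hard.append(PeptideWindow(body[:5] + "T" + body[5:], f"H{i}", 3))
        from phoskin.curation import NegativePools

        return NegativePools(hard={"K1": hard}, easy=list(hard[:50]))

    def test_seventy_fifteen_fifteen(self):
        split = split_dataset(self._positives(100), self._pools(), seed=3)
        n_pos = lambda part: sum(p.label is PairLabel.POSITIVE for p in part)
        assert n_pos(split.train) == 70
        assert n_pos(split.validation) == 15
        assert n_pos(split.test) == 15

    def test_each_heldout_positive_gains_one_hard_negative(self):
        split = split_dataset(self._positives(100), self._pools(), seed=3)
        for part in (split.validation, split.test):
            labels = [p.label for p in part]
            assert labels.count(PairLabel.POSITIVE) == labels.count(PairLabel.HARD_NEGATIVE)

    def test_small_kinases_are_train_only(self):
        for n in (49, 50):
            split = split_dataset(self._positives(n), self._pools(), seed=3)
            assert len(split.validation) == 0 and len(split.test) == 0
            assert sum(p.label is PairLabel.POSITIVE for p in split.train) == n

    def test_rounding_floors_heldout_sets(self):
        split = split_dataset(self._positives(99), self._pools(), seed=3)
        n_pos = lambda part: sum(p.label is PairLabel.POSITIVE for p in part)
        assert (n_pos(split.train), n_pos(split.validation), n_pos(split.test)) == (71, 14, 14)

    def test_same_seed_reproduces_split(self):
        a = split_dataset(self._positives(80), self._pools(), seed=9)
        b = split_dataset(self._positives(80), self._pools(), seed=9)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test

    def test_no_pair_in_two_partitions(self):
        split = split_dataset(self._positives(100), self._pools(), seed=4)
        seen = {}
        for name in ("train", "validation", "test"):
            for p in split.partition(name):
                key = (p.kinase_id, p.peptide.source_substrate_id, p.peptide.site_position)
                assert seen.setdefault(key, name) == name

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._positives(10), self._pools(), ratio=(0.5, 0.2, 0.2))


class TestSampleTrainingNegatives:
    def test_paper_ratio_sixteen(self):
        positives, pools, split = _split_for_sampling(n_pos=10)
        train = sample_training_negatives(split, pools, n_easy=15, m_hard=1, seed=0)
        labels = [p.label for p in train]
        assert labels.count(PairLabel.POSITIVE) == 10
        assert len(train) - 10 == 160  # 1:16 positive:negative

    def test_zero_negatives_leaves_train_unchanged(self):
        _, pools, split = _split_for_sampling(n_pos=7)
        assert sample_training_negatives(split, pools, 0, 0, seed=0) == split.train

    def test_one_easy_one_hard(self):
        _, pools, split = _split_for_sampling(n_pos=7)
        train = sample_training_negatives(split, pools, 1, 1, seed=0)
        assert len(train) == 7 * 3

    def test_empty_easy_pool_with_n_easy_errors(self):
        _, pools, split = _split_for_sampling(n_pos=5)
        pools.easy = []
        with pytest.raises(ValueError):
            sample_training_negatives(split, pools, 1, 0, seed=0)

    def test_heldout_hard_negatives_never_reused_in_train(self):
        positives, pools, split = _split_for_sampling(n_pos=100)
        train = sample_training_negatives(split, pools, 0, 2, seed=5)
        used = split.used_hard["K1"]
        for p in train:
            if p.label is PairLabel.HARD_NEGATIVE:
                key = (p.peptide.source_substrate_id, p.peptide.site_position)
                assert key not in used


def _split_for_sampling(n_pos):
    rng = np.random.default_rng(7)
    pos = []
    for i in range(n_pos):
        body = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=10))
        pos.append(PeptideWindow(body[:5] + "S" + body[5:], f"P{i}", 30))
    hard = []
    for i in range(max(300, 4 * n_pos)):
        body = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=10))
        hard.append(PeptideWindow(body[:5] + "T" + body[5:], f"H{i}", 9))
    easy = []
    for i in range(50):
        body = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=10))
        easy.append(PeptideWindow(body[:5] + "Y" + body[5:], f"E{i}", 12))
    from phoskin.curation import NegativePools

    positives = {"K1": pos}
    pools = NegativePools(hard={"K1": hard}, easy=easy)
    split = split_dataset(positives, pools, seed=7)
    return positives, pools, split


def test_sample_easy_test_pairs_random_kinases():
    _, pools, _ = _split_for_sampling(n_pos=5)
    pairs = sample_easy_test(pools, ["K1", "K2"], size=40, seed=0)
    assert len(pairs) == 40
    assert all(p.label is PairLabel.EASY_NEGATIVE for p in pairs)
    assert {p.kinase_id for p in pairs} <= {"K1", "K2"}


class TestRandomizedInvariants:
    """Pool/split invariants over randomized small problems."""

    @pytest.mark.parametrize("seed", range(25))
    def test_invariants_hold(self, seed):
        subs, table = _random_problem(seed)
        positives, pools = build_pools(table, subs)
        annotated = table.sites()
        easy_keys = {(w.source_substrate_id, w.site_position) for w in pools.easy}
        # easy negatives never overlap annotated sites
        assert not easy_keys & annotated
        for k, pos in positives.items():
            pos_keys = {(w.source_substrate_id, w.site_position) for w in pos}
            hard_keys = {(w.source_substrate_id, w.site_position) for w in pools.hard[k]}
            assert not pos_keys & hard_keys
            assert pos_keys | hard_keys <= annotated
        split = split_dataset(positives, pools, min_positives=20, seed=seed)
        seen = {}
        for name in ("train", "validation", "test"):
            for p in split.partition(name):
                key = (p.kinase_id, p.peptide.residues, p.peptide.source_substrate_id, p.peptide.site_position)
                assert seen.setdefault(key, name) == name
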