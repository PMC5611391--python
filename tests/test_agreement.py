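"""Agreement measures: GTV/GTA, slice counts, concordance, the
central/peripheral rule, and per-observer aggregation — each checked
against independently coded flat-loop oracles."""

import math

import numpy as np
import pytest

from delinmetrics import (
    AgreementConfig,
    Delineation,
    ObserverRecord,
    StudyDataset,
    classify_central_peripheral,
    gross_tumor_area,
    gross_tumor_volume,
    mask_area,
    observer_set_agreement,
    observer_slice_mask,
    pairwise_concordance,
    set_agreement,
    slices_delineated,
    summary_tables,
)

from conftest import make_stack, square


def block(h, w, y0, x0, s):
    m = np.zeros((h, w), dtype=bool)
    m[y0:y0 + s, x0:x0 + s] = True
    return m


class TestPairwiseConcordance:
    def test_identical_masks_score_100(self):
        m = block(8, 8, 1, 1, 3)
        assert pairwise_concordance(m, m, "jaccard") == 100.0
        assert pairwise_concordance(m, m, "dice") == 100.0

    def test_disjoint_masks_score_0(self):
        a, b = block(8, 8, 0, 0, 3), block(8, 8, 4, 4, 3)
        assert pairwise_concordance(a, b, "jaccard") == 0.0
        assert pairwise_concordance(a, b, "dice") == 0.0

    def test_offset_blocks(self):
        # 3x3 blocks offset by (1,1): |A|=|B|=9, intersection 4
        a, b = block(8, 8, 1, 1, 3), block(8, 8, 2, 2, 3)
        assert pairwise_concordance(a, b, "jaccard") == pytest.approx(100 * 4 / 14)
        assert pairwise_concordance(a, b, "dice") == pytest.approx(100 * 8 / 18)

    def test_both_empty_is_nan(self):
        e = np.zeros((4, 4), dtype=bool)
        assert math.isnan(pairwise_concordance(e, e))

    def test_properties_on_random_masks(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            a = rng.random((12, 12)) < 0.3
            b = rng.random((12, 12)) < 0.3
            if not (a.any() or b.any()):
                continue
            j = pairwise_concordance(a, b, "jaccard")
            d = pairwise_concordance(a, b, "dice")
            assert 0.0 <= j <= d <= 100.0
            assert j == pairwise_concordance(b, a, "jaccard")
            # translation of both masks together preserves concordance
            at, bt = np.roll(a, (2, 1), (0, 1)), np.roll(b, (2, 1), (0, 1))
            assert pairwise_concordance(at, bt, "jaccard") == pytest.approx(j)

    def test_matches_flat_pixel_loop(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            a = rng.random((10, 10)) < 0.4
            b = rng.random((10, 10)) < 0.4
            if not (a.any() or b.any()):
                continue
            inter = union = 0
            for i in range(10):
                for j in range(10):
                    if a[i, j] and b[i, j]:
                        inter += 1
                    if a[i, j] or b[i, j]:
                        union += 1
            assert pairwise_concordance(a, b, "jaccard") == pytest.approx(
                100 * inter / union
            )


class TestVolumes:
    def test_gtv_sums_slice_unions(self, toy_dataset):
        # E1 draws a 36 px square on slices 0 and 1
        assert gross_tumor_volume(toy_dataset, "E1", "s") == 72

    def test_gtv_counts_overlap_once(self):
        stack = make_stack()
        delins = [
            Delineation("o", "s", 0, square(1, 1, 4, 4)),   # 16 px
            Delineation("o", "s", 0, square(3, 3, 5, 5)),   # 9 px, overlap 4
        ]
        ds = StudyDataset([stack], [ObserverRecord("o", "expert", delins)])
        assert gross_tumor_volume(ds, "o", "s") == 21

    def test_gtv_no_delineations_is_zero(self, toy_dataset):
        ds = StudyDataset(
            toy_dataset.stacks,
            toy_dataset.observers + [ObserverRecord("idle", "novice")],
        )
        assert gross_tumor_volume(ds, "idle", "s") == 0

    def test_gtv_rejects_independent_set(self):
        stack = make_stack(set_id="1", independent=True, labels=["central"] * 4)
        ds = StudyDataset([stack], [ObserverRecord("o", "expert")])
        with pytest.raises(ValueError, match="independent"):
            gross_tumor_volume(ds, "o", "1")

    def test_gta_mean_per_delineated_slice(self):
        stack = make_stack(set_id="1", n_slices=16, independent=True,
                           labels=["central"] * 8 + ["peripheral"] * 8)
        delins = [
            Delineation("o", "1", 0, square(1, 1, 10, 10)),   # 100 px
            Delineation("o", "1", 5, square(1, 1, 7, 7)),     # 49 px
        ]
        ds = StudyDataset([stack], [ObserverRecord("o", "expert", delins)])
        assert gross_tumor_area(ds, "o", "1") == pytest.approx((100 + 49) / 2)

    def test_gta_zero_slices_is_nan(self):
        stack = make_stack(set_id="1", independent=True, labels=["central"] * 4)
        ds = StudyDataset([stack], [ObserverRecord("o", "expert")])
        assert math.isnan(gross_tumor_area(ds, "o", "1"))

    def test_slices_delineated_uses_set_semantics(self):
        stack = make_stack(n_slices=8)
        sq = square(1, 1, 4, 4)
        delins = [Delineation("o", "s", k, sq) for k in (3, 4, 5, 5)]
        ds = StudyDataset([stack], [ObserverRecord("o", "expert", delins)])
        assert slices_delineated(ds, "o", "s") == 3

    def test_gtv_matches_flat_pixel_loop(self):
        rng = np.random.default_rng(8)
        stack = make_stack(n_slices=3, size=20)
        delins = []
        for k in range(3):
            for _ in range(2):
                verts = rng.uniform(1, 18, size=(5, 2))
                delins.append(Delineation("o", "s", k, verts))
        ds = StudyDataset([stack], [ObserverRecord("o", "expert", delins)])
        expected = 0
        for k in range(3):
            union = observer_slice_mask(ds.observer("o"), "s", k, 20, 20)
            count = 0
            for i in range(20):
                for j in range(20):
                    if union[i, j]:
                        count += 1
            expected += count
        assert gross_tumor_volume(ds, "o", "s") == expected


class TestCentralPeripheral:
    def _count_dataset(self, counts, n_obs=8):
        """Observer i draws (the same square) on slice k iff i < counts[k]."""
        stack = make_stack(n_slices=len(counts), size=16)
        sq = square(2, 2, 6, 6)
        observers = []
        for i in range(n_obs):
            delins = [
                Delineation(f"o{i}", "s", k, sq)
                for k, c in enumerate(counts) if i < c
            ]
            observers.append(ObserverRecord(f"o{i}", "expert" if i % 2 else "novice",
                                            delins))
        return StudyDataset([stack], observers)

    def test_top_k_by_observer_count(self):
        ds = self._count_dataset([2, 5, 8, 8, 8, 8, 8, 5, 2])
        labels = classify_central_peripheral(ds, "s", AgreementConfig(central_k=5))
        central = {k for k, v in labels.items() if v == "central"}
        assert central == {2, 3, 4, 5, 6}

    def test_tie_broken_by_area_then_index(self):
        # equal observer counts everywhere; slice 4 has the largest area
        stack = make_stack(n_slices=6, size=24)
        obs = []
        for i in range(2):
            delins = [
                Delineation(f"o{i}", "s", k,
                            square(2, 2, 10, 10) if k == 4 else square(2, 2, 6, 6))
                for k in range(6)
            ]
            obs.append(ObserverRecord(f"o{i}", "expert", delins))
        ds = StudyDataset([stack], obs)
        labels = classify_central_peripheral(ds, "s", AgreementConfig(central_k=5))
        central = {k for k, v in labels.items() if v == "central"}
        assert 4 in central            # area tie-break wins first
        assert central == {0, 1, 2, 3, 4}  # then lowest index

    def test_metadata_labels_returned_unchanged(self):
        labels_in = ["central"] * 2 + ["peripheral"] * 2
        stack = make_stack(set_id="1", independent=True, labels=labels_in)
        ds = StudyDataset([stack], [])
        labels = classify_central_peripheral(ds, "1")
        assert [labels[k] for k in range(4)] == labels_in

    def test_fewer_delineated_than_k_warns(self, toy_dataset):
        # only 3 slices carry any delineation; default k = 5
        with pytest.warns(UserWarning, match="central_k"):
            labels = classify_central_peripheral(toy_dataset, "s")
        central = {k for k, v in labels.items() if v == "central"}
        assert central == {0, 1, 2}

    def test_exactly_k_central_when_enough_slices(self):
        ds = self._count_dataset([1, 2, 3, 4, 5, 6, 7, 8], n_obs=8)
        labels = classify_central_peripheral(ds, "s", AgreementConfig(central_k=5))
        assert sum(v == "central" for v in labels.values()) == 5


def agreement_oracle(ds, observer_id, set_id, labels, formula="jaccard"):
    """Flat loop over (peer, slice): deliberately independent of the
    pandas implementation."""
    stack = ds.stack(set_id)
    me = ds.observer(observer_id)
    peers = [o for o in ds.observers_in_group(me.group)
             if o.observer_id != observer_id]
    drew = {
        o.observer_id: {d.slice_index for d in o.delineations if d.set_id == set_id}
        for o in ds.observers
    }
    out = {}
    for loc in ("central", "peripheral"):
        slice_means = []
        for k in range(stack.n_slices):
            if labels[k] != loc:
                continue
            vals = []
            for p in peers:
                a_drew = k in drew[observer_id]
                b_drew = k in drew[p.observer_id]
                if not a_drew and not b_drew:
                    continue
                if a_drew and b_drew:
                    ma = observer_slice_mask(me, set_id, k, stack.width, stack.height)
                    mb = observer_slice_mask(p, set_id, k, stack.width, stack.height)
                    vals.append(pairwise_concordance(ma, mb, formula))
                else:
                    vals.append(0.0)
            if vals:
                slice_means.append(float(np.mean(vals)))
        out[loc] = float(np.mean(slice_means)) if slice_means else math.nan
    return out


class TestObserverSetAgreement:
    def test_identical_delineations_score_100(self):
        stack = make_stack(n_slices=3)
        sq = square(2, 2, 8, 8)
        obs = [
            ObserverRecord(f"e{i}", "expert",
                           [Delineation(f"e{i}", "s", k, sq) for k in range(3)])
            for i in range(2)
        ]
        ds = StudyDataset([stack], obs)
        with pytest.warns(UserWarning):  # fewer delineated slices than k=5
            row = observer_set_agreement(ds, "e0", "s")
        assert row["central"] == pytest.approx(100.0)

    def test_disjoint_delineations_score_0(self):
        stack = make_stack(n_slices=3)
        obs = [
            ObserverRecord("e0", "expert",
                           [Delineation("e0", "s", k, square(1, 1, 5, 5))
                            for k in range(3)]),
            ObserverRecord("e1", "expert",
                           [Delineation("e1", "s", k, square(10, 10, 14, 14))
                            for k in range(3)]),
        ]
        ds = StudyDataset([stack], obs)
        with pytest.warns(UserWarning):
            row = observer_set_agreement(ds, "e0", "s")
        assert row["central"] == 0.0

    def test_singleton_group_is_nan(self, toy_dataset):
        ds = StudyDataset(
            toy_dataset.stacks,
            [o for o in toy_dataset.observers if o.observer_id != "N2"],
        )
        with pytest.warns(UserWarning):
            row = observer_set_agreement(ds, "N1", "s")
        assert math.isnan(row["central"]) and math.isnan(row["peripheral"])

    def test_matches_flat_loop_oracle_on_toy_set(self, toy_dataset):
        config = AgreementConfig(central_k=2)
        result = set_agreement(toy_dataset, "s", config)
        for oid in ("E1", "E2", "E3", "N1", "N2"):
            expected = agreement_oracle(toy_dataset, oid, "s", result.slice_labels)
            row = result.table.set_index("observer_id").loc[oid]
            for loc in ("central", "peripheral"):
                if math.isnan(expected[loc]):
                    assert math.isnan(row[loc])
                else:
                    assert row[loc] == pytest.approx(expected[loc], abs=1e-9)

    def test_matches_oracle_on_random_study(self):
        rng = np.random.default_rng(55)
        stack = make_stack(n_slices=6, size=20)
        observers = []
        for i in range(6):
            group = "expert" if i < 3 else "novice"
            delins = []
            for k in range(6):
                if rng.random() < 0.6:
                    x0, y0 = rng.uniform(1, 8, size=2)
                    s = rng.uniform(3, 9)
                    delins.append(
                        Delineation(f"o{i}", "s", k, square(x0, y0, x0 + s, y0 + s))
                    )
            observers.append(ObserverRecord(f"o{i}", group, delins))
        ds = StudyDataset([stack], observers)
        config = AgreementConfig(central_k=3)
        result = set_agreement(ds, "s", config)
        for oid in (o.observer_id for o in observers):
            expected = agreement_oracle(ds, oid, "s", result.slice_labels)
            row = result.table.set_index("observer_id").loc[oid]
            for loc in ("central", "peripheral"):
                if math.isnan(expected[loc]):
                    assert math.isnan(row[loc])
                else:
                    assert row[loc] == pytest.approx(expected[loc], abs=1e-9)


class TestSummaryTables:
    def test_group_means_match_groupby_oracle(self, toy_dataset):
        tables = summary_tables(toy_dataset, AgreementConfig(central_k=2))
        gtv = tables["gta_gtv"]
        expert_vals = [gross_tumor_volume(toy_dataset, oid, "s")
                       for oid in ("E1", "E2", "E3")]
        row = gtv[(gtv["group"] == "expert")].iloc[0]
        assert row["mean"] == pytest.approx(np.mean(expert_vals), abs=1e-9)
        assert row["sd"] == pytest.approx(np.std(expert_vals, ddof=1), abs=1e-9)

    def test_agreement_table_layout(self, toy_dataset):
        tables = summary_tables(toy_dataset, AgreementConfig(central_k=2))
        agr = tables["agreement"]
        assert set(agr.columns) == {"set_id", "location", "group", "mean", "sd"}
        assert set(agr["location"]) == {"central", "peripheral"}
        valid = agr["mean"].dropna()
        assert ((valid >= 0) & (valid <= 100)).all()

    def test_deterministic(self, toy_dataset):
        t1 = summary_tables(toy_dataset, AgreementConfig(central_k=2))
        t2 = summary_tables(toy_dataset, AgreementConfig(central_k=2))
        for name in t1:
            assert t1[name].equals(t2[name])
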