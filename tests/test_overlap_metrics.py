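"""Overlap index identities, concordance bins and cohort aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petsubvol.image_io import BinaryMask, VolumeGrid
from petsubvol.overlap_metrics import (
    ConcordanceCategory,
    classify_concordance,
    cohort_overlap_table,
    overlap_indices,
    overlap_presence_counts,
)

GRID = VolumeGrid((4, 4, 4), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))


def _mask(indices):
    m = np.zeros(GRID.shape, dtype=bool)
    for i in indices:
        m[i] = True
    return BinaryMask(GRID, m)


def test_identical_masks_score_one_everywhere():
    a = _mask([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
    res = overlap_indices(a, a)
    assert (res.dice, res.jaccard, res.of, res.vci, res.vcr) == (1, 1, 1, 1, 1)


def test_disjoint_masks_score_zero():
    res = overlap_indices(_mask([(0, 0, 0)]), _mask([(3, 3, 3)]))
    assert (res.dice, res.jaccard, res.of, res.vci, res.vcr) == (0, 0, 0, 0, 0)
    assert res.intersection_cc == 0.0


def test_nested_eight_four_example():
    a = _mask([(i, j, 0) for i in range(4) for j in range(2)])       # 8 voxels
    b = _mask([(i, 0, 0) for i in range(4)])                          # 4, subset of a
    res = overlap_indices(a, b)
    assert res.dice == pytest.approx(8 / 12)
    assert res.jaccard == pytest.approx(0.5)
    assert res.of == 1.0
    assert res.vci == pytest.approx(0.5)
    assert res.vcr == 1.0
    assert res.intersection_cc == pytest.approx(4 * 0.064)


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        overlap_indices(_mask([]), _mask([(0, 0, 0)]))


def test_grid_mismatch_rejected():
    other = VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
    b = BinaryMask(other, np.ones(other.shape, dtype=bool))
    with pytest.raises(ValueError, match="grid"):
        overlap_indices(_mask([(0, 0, 0)]), b)


def _random_nonempty(rng, p=0.3):
    while True:
        m = rng.random(GRID.shape) < p
        if m.any():
            return BinaryMask(GRID, m)


def test_invariants_on_random_pairs(rng):
    for _ in range(300):
        a, b = _random_nonempty(rng), _random_nonempty(rng)
        r = overlap_indices(a, b)
        for v in (r.dice, r.jaccard, r.of, r.vci, r.vcr):
            assert 0.0 <= v <= 1.0
        assert r.jaccard <= r.dice <= r.of + 1e-12
        assert r.dice == pytest.approx(2 * r.jaccard / (1 + r.jaccard))
        inter = round(r.intersection_cc / GRID.voxel_volume_cc)
        assert round(r.vci * a.voxel_count) == inter
        assert round(r.vcr * b.voxel_count) == inter
        # OF = 1 iff the smaller mask is contained in the larger
        contained = np.all(b.membership[a.membership]) or np.all(a.membership[b.membership])
        assert (r.of == 1.0) == bool(contained)


@pytest.mark.parametrize(
    "value,category",
    [
        (0.0, ConcordanceCategory.VERY_LOW),
        (0.2, ConcordanceCategory.VERY_LOW),
        (0.20001, ConcordanceCategory.LOW),
        (0.4, ConcordanceCategory.LOW),
        (0.52, ConcordanceCategory.MODERATE),
        (0.6, ConcordanceCategory.MODERATE),
        (0.8, ConcordanceCategory.GOOD),
        (0.80001, ConcordanceCategory.VERY_GOOD),
        (1.0, ConcordanceCategory.VERY_GOOD),
    ],
)
def test_concordance_bins(value, category):
    assert classify_concordance(value) is category


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.floats(0.0, 1.0, allow_nan=False))
def test_concordance_total_and_ordered_on_unit_interval(value):
    cat = classify_concordance(value)
    order = list(ConcordanceCategory)
    # category index grows with the value (total, ordered classification)
    assert order.index(cat) == min(4, int(np.ceil(max(value, 1e-12) / 0.2)) - 1)


def test_concordance_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_concordance(1.2)


def test_single_patient_cohort_table_has_sd_zero():
    rec = {"I" + str(x): _mask([(0, 0, 0), (1, 0, 0)]) for x in range(30, 100, 10)}
    rec["R40"] = _mask([(1, 0, 0), (2, 0, 0)])
    df = cohort_overlap_table([rec], "R40")
    assert len(df) == 7
    assert (df.filter(like="_sd") == 0).all().all()
    single = overlap_indices(rec["I40"], rec["R40"])
    assert df.loc["I40", "dice_mean"] == pytest.approx(single.dice)


def test_of_column_is_one_when_recurrence_equals_baseline():
    masks = {f"I{x}": _mask([(0, 0, 0), (1, 1, 1)]) for x in range(30, 100, 10)}
    masks["R40"] = masks["I40"]
    df = cohort_overlap_table([masks] * 3, "R40")
    assert df.loc["I40", "of_mean"] == 1.0


def test_presence_counts_and_percentage():
    base = {f"I{x}": _mask([(0, 0, 0)]) for x in range(30, 100, 10)}
    overlapping = dict(base, R90=_mask([(0, 0, 0), (1, 1, 1)]))
    disjoint = dict(base, R90=_mask([(3, 3, 3)]))
    df = overlap_presence_counts([overlapping, disjoint, disjoint], "R90")
    assert df.loc["I30", "n_overlap"] == 1
    assert df.loc["I30", "percent"] == 33
    assert (df["n_total"] == 3).all()


def test_presence_counts_monotone_for_nested_series(rng):
    records = []
    for _ in range(10):
        center = rng.integers(0, 4, 3)
        rec = {}
        for x in range(30, 100, 10):
            # shrinking nested boxes
            r = max(0, (95 - x) // 25)
            m = np.zeros(GRID.shape, dtype=bool)
            sl = tuple(slice(max(0, c - r), min(4, c + r + 1)) for c in center)
            m[sl] = True
            rec[f"I{x}"] = BinaryMask(GRID, m)
        rec["R90"] = _random_nonempty(rng)
        records.append(rec)
    counts = overlap_presence_counts(records, "R90")["n_overlap"].to_numpy()
    assert np.all(np.diff(counts) <= 0)
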