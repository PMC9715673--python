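"""Phantom generator: determinism, lesion behaviour, splits, manifest IO."""

import dataclasses

import numpy as np
import pytest

from igcbir import phantoms as P
from igcbir.retrieval import ssim


@pytest.fixture(scope="module")
def config():
    return P.PhantomConfig(seed=3)


@pytest.fixture(scope="module")
def dataset(config):
    return P.generate_dataset(config, 120)


@pytest.mark.parametrize("field,value", [
    ("image_size", 16),
    ("class_balance", 0.0),
    ("class_balance", 1.0),
    ("lesion_region", (0.2, 0.3, 1.2, 0.9)),
    ("severity_range", (0.5, 0.2)),
    ("background_modes", 0),
    ("condition", "fracture"),
])
def test_invalid_config_names_field(config, field, value):
    bad = dataclasses.replace(config, **{field: value})
    with pytest.raises(P.PhantomConfigError, match=field):
        bad.validate()


def test_dataset_class_balance_and_determinism(config, dataset):
    assert sum(s.label for s in dataset) == round(120 * config.class_balance)
    again = P.generate_dataset(config, 120)
    for a, b in zip(dataset, again):
        assert np.array_equal(a.image, b.image)
        assert (a.label, a.severity, a.background_mode) == (b.label, b.severity, b.background_mode)


def test_label_severity_consistency(dataset):
    for s in dataset:
        assert (s.label == 1) == (s.severity > 0)
        assert s.image.min() >= 0 and s.image.max() <= 1


def test_negative_has_no_lesion(config):
    # rendering the same sample id with severity 0 or a positive severity
    # must differ only inside the lesion region
    neg = P.render_sample(config, "x", 11, 1, 0, 0.0)
    pos = P.render_sample(config, "x", 11, 1, 1, 0.8)
    diff = np.abs(pos.image - neg.image)
    s = config.image_size
    r0, c0, r1, c1 = (np.array(config.lesion_region) * (s - 1)).astype(int)
    outside = diff.copy()
    outside[r0:r1 + 1, c0:c1 + 1] = 0
    assert outside.max() == 0
    assert diff[r0:r1 + 1, c0:c1 + 1].max() > 0


def test_lesion_mean_contrast_monotone_in_severity(config):
    """Mean intensity offset inside the lesion region strictly increases."""
    s = config.image_size
    r0, c0, r1, c1 = (np.array(config.lesion_region) * (s - 1)).astype(int)
    for condition in ("effusion", "pneumonia"):
        cfg = dataclasses.replace(config, condition=condition)
        base = P.render_sample(cfg, "x", 5, 2, 0, 0.0)
        means = []
        for sev in [0.2, 0.35, 0.5, 0.65, 0.8, 0.9]:
            img = P.render_sample(cfg, "x", 5, 2, 1, sev).image
            means.append((img - base.image)[r0:r1 + 1, c0:c1 + 1].mean())
        assert all(np.diff(means) > 0), f"{condition}: {means}"


def test_ground_truth_ranking_rules():
    def mk(sid, label, sev):
        return P.PhantomSample(sid, np.zeros((32, 32)), label, sev, 0)

    q = mk("q", 1, 0.85)
    cat = [mk("A", 1, 0.9), mk("B", 1, 0.1), mk("C", 1, 0.5)]
    assert P.ground_truth_ranking(q, cat) == ["A", "C", "B"]

    qneg = mk("q", 0, 0.0)
    cat = [mk("pos", 1, 0.7), mk("neg", 0, 0.0)]
    assert P.ground_truth_ranking(qneg, cat) == ["neg", "pos"]

    # exact severity ties: same label first, then ascending id
    q = mk("q", 1, 0.5)
    cat = [mk("b", 1, 0.5), mk("a", 1, 0.5), mk("z", 0, 0.0)]
    assert P.ground_truth_ranking(q, cat) == ["a", "b", "z"]

    with pytest.raises(ValueError):
        P.ground_truth_ranking(q, [])


class TestMakeSplits:
    def test_counts_and_protocols(self, dataset):
        for n_queries in (10, 5):  # effusion and pneumonia protocols
            splits = P.make_splits(dataset, n_queries, p=10, seed=1)
            assert len(splits) == n_queries
            assert all(sp.p == 10 for sp in splits)

    def test_disjoint_and_proportions(self, dataset):
        splits = P.make_splits(dataset, 10, p=10, seed=1)
        used = [i for sp in splits for i in (sp.query_id, *sp.catalogue_ids)]
        assert len(used) == len(set(used))
        by_id = {s.sample_id: s for s in dataset}
        pool_frac = sum(s.label for s in dataset) / len(dataset)
        for sp in splits:
            cat_pos = sum(by_id[c].label for c in sp.catalogue_ids)
            assert abs(cat_pos - 10 * pool_frac) <= 1

    def test_catalogue_is_ground_truth_ordered(self, dataset):
        by_id = {s.sample_id: s for s in dataset}
        for sp in P.make_splits(dataset, 5, p=10, seed=2):
            expected = P.ground_truth_ranking(by_id[sp.query_id],
                                              [by_id[c] for c in sp.catalogue_ids])
            assert list(sp.catalogue_ids) == expected

    def test_deterministic(self, dataset):
        assert P.make_splits(dataset, 5, 10, seed=7) == P.make_splits(dataset, 5, 10, seed=7)

    def test_insufficient_samples(self, dataset):
        with pytest.raises(ValueError, match="insufficient"):
            P.make_splits(dataset[:20], 10, p=10, seed=0)


class TestManifest:
    def test_round_trip(self, config, dataset, tmp_path):
        samples = dataset[:20]
        splits = P.make_splits(dataset, 1, p=10, seed=0)
        P.write_manifest(dataset, splits, tmp_path)
        rsamples, rsplits = P.read_manifest(tmp_path)
        for a, b in zip(dataset, rsamples):
            assert a.sample_id == b.sample_id
            assert np.array_equal(a.image, b.image)  # 8-bit quantized: lossless
            assert a.label == b.label and a.severity == b.severity
        assert rsplits == splits

    def test_unknown_split_id_rejected(self, dataset, tmp_path):
        splits = P.make_splits(dataset, 1, p=10, seed=0)
        bad = [P.QueryCatalogueSplit("splitX", "nope", splits[0].catalogue_ids)]
        P.write_manifest(dataset, bad, tmp_path)
        with pytest.raises(P.DataLayoutError, match="nope"):
            P.read_manifest(tmp_path)

    def test_empty_dataset(self, tmp_path):
        P.write_manifest([], [], tmp_path)
        samples, splits = P.read_manifest(tmp_path)
        assert samples == [] and splits == []

    def test_missing_image_listed(self, dataset, tmp_path):
        P.write_manifest(dataset[:5], [], tmp_path)
        victim = dataset[2].sample_id
        (tmp_path / "images" / f"{victim}.png").unlink()
        with pytest.raises(P.DataLayoutError, match=victim):
            P.read_manifest(tmp_path)


def test_global_similarity_is_background_dominated(bench):
    """Whole-image SSIM retrieves background look-alikes, not severity matches:
    the top-SSIM catalogue item shares the query's background mode more often
    than it is the true rank-1 severity match."""
    by_id = {s.sample_id: s for s in bench.samples["test"]}
    same_mode, rank1_match = 0, 0
    for sp in bench.splits:
        q = by_id[sp.query_id]
        best = max(sp.catalogue_ids, key=lambda c: ssim(q.image, by_id[c].image))
        same_mode += by_id[best].background_mode == q.background_mode
        rank1_match += best == sp.catalogue_ids[0]
    assert len(bench.splits) >= 10
    assert same_mode > rank1_match
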