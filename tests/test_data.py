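"""Dataset assembly, views, normalization and CSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imbalsim2real import (
    DomainSample,
    ImbalancedDataset,
    apply_normalizer,
    assemble_dataset,
    dataset_view,
    fit_normalizer,
    invert_normalizer,
    read_dataset_csv,
    read_samples_csv,
    write_dataset_csv,
    write_samples_csv,
)


def _samples(n, domain, seed=0, d=2):
    rng = np.random.default_rng(seed)
    return [
        DomainSample(tuple(rng.normal(size=d)), float(rng.normal()), domain)
        for _ in range(n)
    ]


def _paired_setup(n_source, n_target, n_paired, seed=0):
    rng = np.random.default_rng(seed)
    source = _samples(n_source, "sim", seed)
    target = []
    for i in range(n_paired):
        target.append(
            DomainSample(source[i].covariates, float(rng.normal()), "real")
        )
    target.extend(_samples(n_target - n_paired, "real", seed + 1))
    pairing = [(i, i) for i in range(n_paired)]
    return source, target, pairing


@pytest.mark.parametrize(
    "n_source,n_target,n_paired,exp_us,exp_ut",
    [
        (370, 30, 30, 340, 0),  # group A partition
        (350, 50, 20, 330, 30),  # group C partition
        (370, 30, 10, 360, 20),  # group B partition
    ],
)
def test_assemble_count_identities(n_source, n_target, n_paired, exp_us, exp_ut):
    source, target, pairing = _paired_setup(n_source, n_target, n_paired)
    ds = assemble_dataset(source, target, pairing)
    assert len(ds.unpaired_source) == exp_us
    assert len(ds.unpaired_target) == exp_ut
    assert ds.n_source == ds.n_paired + len(ds.unpaired_source)
    assert ds.n_target == ds.n_paired + len(ds.unpaired_target)


def test_assemble_rejects_duplicate_pairing_index():
    source = _samples(2, "sim")
    target = _samples(2, "real")
    with pytest.raises(ValueError, match="unique"):
        assemble_dataset(source, target, [(0, 0), (1, 0)])


def test_assemble_rejects_covariate_mismatch():
    source = _samples(2, "sim")
    target = _samples(2, "real", seed=5)
    with pytest.raises(ValueError, match="mismatch"):
        assemble_dataset(source, target, [(0, 0)])


def test_dataset_views(toy_dataset):
    paired = dataset_view(toy_dataset, "paired_only")
    assert len(paired) == 2
    assert all(s.domain == "sim" and r.domain == "real" for s, r in paired)
    everything = dataset_view(toy_dataset, "all")
    assert len(everything) == toy_dataset.n_source + toy_dataset.n_target
    assert dataset_view(ImbalancedDataset(), "all") == []
    with pytest.raises(ValueError, match="view"):
        dataset_view(toy_dataset, "half")


def test_group_b_views():
    source, target, pairing = _paired_setup(370, 30, 10)
    ds = assemble_dataset(source, target, pairing)
    assert len(dataset_view(ds, "paired_only")) == 10
    allv = dataset_view(ds, "all")
    assert sum(s.domain == "sim" for s in allv) == 370
    assert sum(s.domain == "real" for s in allv) == 30


class TestNormalizer:
    def test_training_features_standardized(self, toy_dataset):
        stats = fit_normalizer(toy_dataset)
        cov = np.array(
            [s.covariates for s in toy_dataset.source_samples() + toy_dataset.target_samples()]
        )
        z = stats.normalize_cov(cov)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)

    def test_round_trip_identity(self, toy_dataset):
        stats = fit_normalizer(toy_dataset)
        samples = toy_dataset.source_samples() + toy_dataset.target_samples()
        back = invert_normalizer(stats, apply_normalizer(stats, samples))
        for orig, rec in zip(samples, back):
            np.testing.assert_allclose(rec.covariates, orig.covariates, atol=1e-9)
            assert abs(rec.response - orig.response) < 1e-9

    def test_two_point_z_scoring(self):
        # {-1, 1} has population mean 0 and sd 1: z-scores are unchanged
        ds = assemble_dataset(
            [
                DomainSample((-1.0, 0.0), -1.0, "sim"),
                DomainSample((1.0, 1.0), 1.0, "sim"),
            ],
            [DomainSample((0.0, 0.5), 0.0, "real"), DomainSample((0.5, 0.25), 1.0, "real")],
            [],
        )
        stats = fit_normalizer(ds)
        z = stats.normalize_resp(np.array([-1.0, 1.0]), "sim")
        np.testing.assert_allclose(z, [-1.0, 1.0], atol=1e-12)

    def test_zero_variance_feature_named(self):
        ds = assemble_dataset(
            [DomainSample((1.0, 3.0), 0.0, "sim"), DomainSample((1.0, 4.0), 1.0, "sim")],
            [DomainSample((1.0, 5.0), 0.5, "real"), DomainSample((1.0, 6.0), 1.5, "real")],
            [],
        )
        with pytest.raises(ValueError, match="x1"):
            fit_normalizer(ds)


class TestCsv:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("x1,x2,response,domain,pair_id\n0.5,2.0,1.0,sim,\n")
        (sample,) = read_samples_csv(p)
        assert sample == DomainSample((0.5, 2.0), 1.0, "sim", None)

    def test_round_trip(self, tmp_path):
        samples = [
            DomainSample((0.5, 2.0), 1.0, "sim", 0),
            DomainSample((0.5, 2.0), 3.0, "real", 0),
            DomainSample((-1.5, 0.25), -2.0, "sim"),
        ]
        p = tmp_path / "s.csv"
        write_samples_csv(samples, p)
        assert read_samples_csv(p) == samples

    def test_unknown_domain_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("x1,x2,response,domain,pair_id\n0.5,2.0,1.0,simu,\n")
        with pytest.raises(ValueError, match="row 2"):
            read_samples_csv(p)

    def test_non_numeric_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("x1,x2,response,domain,pair_id\n1.0,2.0,3.0,sim,\nx,2.0,1.0,real,\n")
        with pytest.raises(ValueError, match="row 3"):
            read_samples_csv(p)

    def test_dataset_round_trip(self, tmp_path, toy_dataset):
        p = tmp_path / "ds.csv"
        write_dataset_csv(toy_dataset, p)
        ds2 = read_dataset_csv(p)
        assert ds2.paired == toy_dataset.paired
        assert ds2.unpaired_source == toy_dataset.unpaired_source
        assert ds2.unpaired_target == toy_dataset.unpaired_target

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.floats(-1e6, 1e6, allow_nan=False),
                st.sampled_from(["sim", "real"]),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip_property(self, rows):
        import tempfile, os

        samples = [DomainSample((a, a + 1.0), b, d) for a, b, d in rows]
        fd, path = tempfile.mkstemp(suffix=".csv")
        os.close(fd)
        try:
            write_samples_csv(samples, path)
            assert read_samples_csv(path) == samples
        finally:
            os.unlink(path)
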