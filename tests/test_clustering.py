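"""Feature assembly, unsupervised selection and cluster recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcmecg.clustering import (CohortFeatureMatrix, assemble_features, cluster,
                               compare_partitions, select_features)


def tiny_tables(n_subjects=2, leads=("V4",)):
    fits, bms = [], []
    rng = np.random.default_rng(0)
    for i in range(n_subjects):
        sid = f"s{i}"
        for lead in leads:
            fits.append((sid, lead, 9.0 + rng.normal(), *rng.normal(size=4), 0.01))
            bms.append((sid, lead, "t_polarity", 1.0))
            bms.append((sid, lead, "t_amplitude_mv", 0.3 + 0.1 * rng.normal()))
    fits = pd.DataFrame(fits, columns=["subject_id", "lead", "sigma_ms",
                                       "c0", "c1", "c2", "c3", "nrmse"])
    bms = pd.DataFrame(bms, columns=["subject_id", "lead", "biomarker", "value"])
    return fits, bms


def test_feature_counts_per_mode():
    fits, bms = tiny_tables()
    m1 = assemble_features(fits, bms, ["V4"], mode="qrs_only")
    assert len(m1.feature_names) == 5  # c0..c3 + sigma
    m2 = assemble_features(fits, bms, ["V4"], mode="qrs_plus_t")
    assert len(m2.feature_names) == 7  # + t_polarity, t_amplitude


def test_z_scoring_and_denormalization():
    fits, bms = tiny_tables(n_subjects=20)
    m = assemble_features(fits, bms, ["V4"], mode="qrs_plus_t")
    cont = [j for j, n in enumerate(m.feature_names) if "polarity" not in n]
    assert np.allclose(m.values[:, cont].mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(m.values[:, cont].std(axis=0), 1.0, atol=1e-9)
    pol = m.feature_names.index("V4:t_polarity")
    assert set(np.unique(m.values[:, pol])) <= {-1.0, 1.0}
    # de-normalization restores raw values exactly
    raw = m.denormalized()
    assert raw[:, m.feature_names.index("V4:sigma")] == pytest.approx(
        fits.sort_values("subject_id")["sigma_ms"].to_numpy())


def test_missing_lead_reported_by_subject():
    fits, bms = tiny_tables(leads=("V4", "V5"))
    fits = fits[~((fits.subject_id == "s1") & (fits.lead == "V5"))]
    with pytest.raises(ValueError, match="s1"):
        assemble_features(fits, bms, ["V4", "V5"], mode="qrs_only")


def make_matrix(X, names=None):
    n, d = X.shape
    return CohortFeatureMatrix([f"s{i}" for i in range(n)],
                               names or [f"f{j}" for j in range(d)],
                               X, np.zeros(d), np.ones(d))


def test_selection_none_is_identity():
    rng = np.random.default_rng(1)
    m = make_matrix(rng.standard_normal((30, 4)))
    out = select_features(m, {"method": "none"})
    np.testing.assert_array_equal(out.values, m.values)


def test_duplicated_column_dropped():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(40)
    X = np.column_stack([x, rng.standard_normal(40), x])
    out = select_features(make_matrix(X), {"method": "variance_redundancy"})
    assert len(out.feature_names) == 2 and "f2" not in out.feature_names


def test_pure_noise_column_dropped_by_laplacian():
    """Two tight blobs + one permutation-null noise feature: the noise
    column fails its own permutation comparison and is removed."""
    rng = np.random.default_rng(3)
    n = 60
    labels = np.repeat([0, 1, 2], n // 3)
    f0 = (labels == 0) * 6.0 + 0.3 * rng.standard_normal(n)
    f1 = (labels == 2) * 6.0 + 0.3 * rng.standard_normal(n)
    noise = rng.standard_normal(n)
    X = np.column_stack([f0, f1, noise])
    X = (X - X.mean(0)) / X.std(0)
    out = select_features(make_matrix(X), {"method": "laplacian", "seed": 0})
    assert "f2" not in out.feature_names
    assert "f0" in out.feature_names and "f1" in out.feature_names


def test_selection_refusing_to_empty():
    X = np.ones((20, 2))
    with pytest.raises(ValueError, match="removed all"):
        select_features(make_matrix(X), {"method": "variance_redundancy"})


def test_two_separated_blobs_recovered_exactly():
    rng = np.random.default_rng(4)
    a = rng.normal(0.0, 0.1, size=(25, 3))
    b = rng.normal(5.0, 0.1, size=(25, 3))  # >=10x within-blob sd apart
    m = make_matrix(np.vstack([a, b]))
    res = cluster(m, k_range=range(2, 6), seed=0)
    truth = np.repeat([0, 1], 25)
    assert res.k == 2
    assert compare_partitions(res.labels, truth) == 1.0


def test_cluster_determinism():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(i * 4, 0.5, size=(20, 4)) for i in range(3)])
    m = make_matrix(X)
    r1 = cluster(m, seed=3)
    r2 = cluster(m, seed=3)
    np.testing.assert_array_equal(r1.labels, r2.labels)
    assert r1.validity_by_k == r2.validity_by_k


def test_kmedoids_config_recovers_blobs():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(6, 0.2, (20, 2))])
    res = cluster(make_matrix(X), k_range=range(2, 5), seed=1,
                  algorithm="kmedoids")
    assert res.k == 2
    assert compare_partitions(res.labels, np.repeat([0, 1], 20)) == 1.0


def test_degenerate_matrix_rejected():
    with pytest.raises(ValueError, match="distinct"):
        cluster(make_matrix(np.ones((30, 3))), k_range=range(2, 4))


def test_ari_identity_and_permutation_invariance():
    labels = np.array([0, 0, 1, 1, 2, 2, 2])
    assert compare_partitions(labels, labels) == 1.0
    permuted = np.array([2, 2, 0, 0, 1, 1, 1])  # same partition, renamed
    assert compare_partitions(labels, permuted) == 1.0
    with pytest.raises(ValueError):
        compare_partitions(labels, labels[:-1])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=8, max_size=40),
       st.permutations([0, 1, 2, 3]))
def test_ari_invariant_under_label_renaming(labels, perm):
    renamed = [perm[l] for l in labels]
    assert compare_partitions(labels, renamed) == pytest.approx(1.0)


def test_ari_chance_level_near_zero():
    """Against uniformly random labelings the chance-adjusted index
    averages to ~0 (Monte-Carlo oracle)."""
    rng = np.random.default_rng(7)
    base = rng.integers(0, 4, size=1000)
    vals = [compare_partitions(base, rng.integers(0, 4, size=1000))
            for _ in range(100)]
    assert abs(float(np.mean(vals))) < 0.02
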