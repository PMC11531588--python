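"""Window enumeration, the 11-px attribution rule, and balanced sampling."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clamcore.voxelize import (
    assign_labels,
    build_balanced_dataset,
    collapse_count,
    enumerate_windows,
    extract_voxel,
    point_rect_distance,
)


def brute_force_attribution(points, origins, w, threshold):
    """Exhaustive oracle: min distance from a clam to every pixel of the
    window footprint, tested pairwise."""
    out = np.zeros((len(origins), len(points)), dtype=bool)
    for i, (x0, y0) in enumerate(origins):
        px, py = np.meshgrid(np.arange(x0, x0 + w), np.arange(y0, y0 + w),
                             indexing="ij")
        for j, (cx, cy) in enumerate(points):
            d = np.sqrt((px - cx) ** 2 + (py - cy) ** 2).min()
            out[i, j] = d < threshold or d == 0
    return out


# ------------------------------------------------------------ enumeration
@pytest.mark.parametrize(
    "nx,ny,w,stride,expected",
    [
        (125, 100, 25, 1, 7676),
        (25, 25, 25, 1, 1),
        (125, 100, 25, 25, 20),
        (40, 40, 10, 1, 31 * 31),
    ],
)
def test_enumeration_counts(nx, ny, w, stride, expected):
    origins = enumerate_windows(nx, ny, w=w, stride=stride)
    assert len(origins) == expected
    assert origins.min() >= 0
    assert origins[:, 0].max() == ((nx - w) // stride) * stride
    assert origins[:, 1].max() == ((ny - w) // stride) * stride


def test_single_window_origin():
    np.testing.assert_array_equal(enumerate_windows(25, 25), [[0, 0]])


def test_window_too_large_errors():
    with pytest.raises(ValueError):
        enumerate_windows(20, 30, w=25)


@given(
    nx=st.integers(5, 40),
    ny=st.integers(5, 40),
    w=st.integers(2, 5),
    stride=st.integers(1, 6),
)
@settings(deadline=None, max_examples=60)
def test_enumeration_matches_count_formula(nx, ny, w, stride):
    origins = enumerate_windows(nx, ny, w=w, stride=stride)
    expected = ((nx - w) // stride + 1) * ((ny - w) // stride + 1)
    assert len(origins) == expected


# ------------------------------------------------------------ attribution
def test_attribution_examples():
    origins = np.array([[0, 0]])
    labels = assign_labels(origins, np.array([[12, 12]]), w=25)
    assert labels.loc[0, "n_clams"] == 1 and labels.loc[0, "presence"] == "presence"
    # boundary pixel is x=24: distance 12 >= 11 -> excluded (strict rule)
    labels = assign_labels(origins, np.array([[36, 12]]), w=25)
    assert labels.loc[0, "n_clams"] == 0 and labels.loc[0, "presence"] == "absence"
    # distance 10 < 11 -> attributed
    labels = assign_labels(origins, np.array([[34, 12]]), w=25)
    assert labels.loc[0, "n_clams"] == 1


def test_attribution_matches_brute_force_oracle(rng):
    for _ in range(25):
        nx, ny = rng.integers(12, 41, size=2)
        w = int(rng.integers(4, min(nx, ny) + 1))
        pts = np.column_stack(
            [rng.integers(0, nx, size=6), rng.integers(0, ny, size=6)]
        )
        origins = enumerate_windows(nx, ny, w=w, stride=int(rng.integers(1, 5)))
        dist = point_rect_distance(pts, origins, w)
        fast = (dist == 0) | (dist < 11)
        slow = brute_force_attribution(pts, origins, w, 11)
        np.testing.assert_array_equal(fast, slow)


def test_threshold_monotonicity(rng):
    nx = ny = 30
    pts = np.column_stack([rng.integers(0, nx, 10), rng.integers(0, ny, 10)])
    origins = enumerate_windows(nx, ny, w=8, stride=3)
    prev = None
    for thr in (1, 5, 11, 20):
        labels = assign_labels(origins, pts, w=8, threshold_px=thr)
        counts = labels["n_clams"].to_numpy()
        if prev is not None:
            assert np.all(counts >= prev)
        prev = counts


def test_presence_count_consistency(rng):
    pts = np.column_stack([rng.integers(0, 40, 12), rng.integers(0, 40, 12)])
    labels = assign_labels(enumerate_windows(40, 40, w=10), pts, w=10)
    assert (
        (labels["presence"] == "presence") == (labels["count"] != "0")
    ).all()
    for _, row in labels.iterrows():
        assert len(row["clam_ids"]) == row["n_clams"]


def test_positions_outside_grid_rejected():
    with pytest.raises(ValueError, match="outside"):
        assign_labels(
            enumerate_windows(30, 30, w=10),
            np.array([[5, 5], [35, 2]]),
            w=10,
            grid_shape=(30, 30),
        )


def test_chebyshev_metric_option():
    # point at (30, 30) from window [0,24]^2: dx=dy=6 -> euclidean 8.49,
    # chebyshev 6
    d_e = point_rect_distance([[30, 30]], [[0, 0]], 25, metric="euclidean")
    d_c = point_rect_distance([[30, 30]], [[0, 0]], 25, metric="chebyshev")
    assert d_e[0, 0] == pytest.approx(np.hypot(6, 6))
    assert d_c[0, 0] == 6


# ---------------------------------------------------------- count labels
@pytest.mark.parametrize("n,expected", [(0, "0"), (1, "1"), (2, "ge2"), (3, "ge2"), (7, "ge2")])
def test_collapse_count(n, expected):
    assert collapse_count(n) == expected


def test_collapse_count_negative_errors():
    with pytest.raises(ValueError):
        collapse_count(-1)


# ------------------------------------------------------ balanced sampling
def _manifest(n_abs=100, n_pres=100):
    rows = []
    for i in range(n_abs):
        rows.append(("B1", "C", i, 0, 0, "absence", "0"))
    for i in range(n_pres):
        rows.append(("B2", "A", i, 0, 1, "presence", "1"))
    return pd.DataFrame(
        rows,
        columns=["bucket_id", "bucket_type", "x0", "y0", "n_clams",
                 "presence", "count"],
    )


def test_balanced_sampling_counts_and_determinism():
    m = _manifest()
    ds1 = build_balanced_dataset(m, "presence", 50, seed=3)
    ds2 = build_balanced_dataset(m, "presence", 50, seed=3)
    assert (ds1["label"] == "absence").sum() == 50
    assert (ds1["label"] == "presence").sum() == 50
    pd.testing.assert_frame_equal(ds1, ds2)
    ds3 = build_balanced_dataset(m, "presence", 50, seed=4)
    assert not ds1[["bucket_id", "x0", "y0"]].equals(ds3[["bucket_id", "x0", "y0"]])


def test_balanced_sampling_caps_small_stratum(caplog):
    m = _manifest(n_abs=10, n_pres=100)
    with caplog.at_level(logging.WARNING):
        ds = build_balanced_dataset(m, "presence", 50, seed=0)
    assert (ds["label"] == "absence").sum() == 10
    assert (ds["label"] == "presence").sum() == 50
    assert any("using all" in r.message for r in caplog.records)


def test_balanced_sampling_empty_stratum_errors():
    m = _manifest(n_abs=0, n_pres=10)
    with pytest.raises(ValueError, match="no windows"):
        build_balanced_dataset(m, "presence", 5, seed=0)


# ------------------------------------------------------------- extraction
def test_extract_voxel_downsample_mean_pool_oracle(rng):
    grid = rng.random((10, 10, 12)).astype(np.float32)
    out = extract_voxel(grid, 2, 3, w=4, z_downsample=4)
    assert out.shape == (4, 4, 3)
    expected = grid[2:6, 3:7, :12].reshape(4, 4, 3, 4).mean(axis=3)
    np.testing.assert_allclose(out, expected, rtol=1e-6)


def test_extract_voxel_truncates_remainder(rng):
    grid = rng.random((8, 8, 11)).astype(np.float32)
    out = extract_voxel(grid, 0, 0, w=8, z_downsample=4)
    assert out.shape == (8, 8, 2)
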