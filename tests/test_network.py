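"""Co-methylation network: adjacency, TOM, module detection, merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methdyn.core import GeneModel, MethylomePanel
from methdyn.network import (DmsMatrix, correlation_adjacency,
                             detect_modules, detect_modules_blockwise,
                             merge_close_modules, module_profile_summary,
                             preprocess_dms_matrix, topological_overlap)
from methdyn.simulate import simulate_comethylation_matrix

from conftest import make_methylome


def tom_brute_force(a):
    """Triple-loop TOM reference."""
    n = len(a)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a0[i, u] * a0[u, j] for u in range(n))
            out[i, j] = (shared + a0[i, j]) / \
                (min(k[i], k[j]) + 1 - a0[i, j])
    return out


def test_adjacency_values():
    x = np.array([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9], [0.9, 0.5, 0.1]])
    adj = correlation_adjacency(x, power=6)
    assert adj[0, 1] == pytest.approx(1.0)
    assert adj[0, 2] == pytest.approx(1.0)  # |corr| = 1 either sign
    two = np.array([[0.0, 1.0, 0.0, 1.0], [0.0, 0.5, 0.5, 1.0]])
    r = np.corrcoef(two)[0, 1]
    assert correlation_adjacency(two, power=6)[0, 1] == \
        pytest.approx(abs(r) ** 6)
    assert 0.5 ** 6 == 0.015625  # soft-threshold reference point
    with pytest.raises(ValueError, match="constant row"):
        correlation_adjacency(np.array([[1.0, 1.0, 1.0], [0, 1, 2.0]]))


def test_tom_degenerate_cases():
    a2 = np.array([[1.0, 0.3], [0.3, 1.0]])
    assert np.allclose(topological_overlap(a2), a2)
    ones = np.ones((5, 5))
    assert np.allclose(topological_overlap(ones), 1.0)


def test_tom_matches_brute_force(rng):
    for n in (5, 12, 20, 30):
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        got = topological_overlap(a)
        want = tom_brute_force(a)
        assert np.max(np.abs(got - want)) < 1e-10


def test_planted_modules_recovered():
    mat, truth = simulate_comethylation_matrix(
        n_blocks=2, block_size=100, n_samples=20, within_corr=0.9, seed=2)
    tom = topological_overlap(correlation_adjacency(mat))
    asg = merge_close_modules(detect_modules(tom, mat), mat)
    assert len(asg.sizes) == 2
    assert adjusted_rand_score(truth, asg.labels) >= 0.8
    co_assigned = np.mean([asg.labels[i] == asg.labels[j] != 0
                           for i in range(0, 100, 7)
                           for j in range(i + 1, 100, 11)])
    assert co_assigned >= 0.9


def test_noise_rows_stay_unassigned():
    for seed in (1, 2, 3):
        mat, _ = simulate_comethylation_matrix(
            n_blocks=0, block_size=0, n_samples=20, n_noise=150, seed=seed)
        tom = topological_overlap(correlation_adjacency(mat))
        asg = detect_modules(tom, mat)
        assert (asg.labels == 0).all()


def test_uncorrelated_rows_unassigned_next_to_blocks():
    mat, truth = simulate_comethylation_matrix(
        n_blocks=2, block_size=60, n_samples=20, within_corr=0.9,
        n_noise=40, seed=5)
    tom = topological_overlap(correlation_adjacency(mat))
    asg = merge_close_modules(detect_modules(tom, mat), mat)
    noise_labels = asg.labels[truth == 0]
    assert (noise_labels == 0).mean() >= 0.9


def test_small_input_warns_and_returns_unassigned():
    mat, _ = simulate_comethylation_matrix(n_blocks=1, block_size=10,
                                           n_samples=8, seed=1)
    tom = topological_overlap(correlation_adjacency(mat))
    with pytest.warns(UserWarning):
        asg = detect_modules(tom, mat, min_module_size=30)
    assert (asg.labels == 0).all()


def test_eigenprofile_maximises_variance_share(rng):
    mat, _ = simulate_comethylation_matrix(n_blocks=1, block_size=60,
                                           n_samples=15, seed=7)
    tom = topological_overlap(correlation_adjacency(mat))
    asg = detect_modules(tom, mat)
    (module,) = asg.sizes
    e = asg.eigenprofiles[module]
    z = mat.to_numpy()[asg.labels == module]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    share_e = np.linalg.norm(z @ e) ** 2
    for _ in range(100):
        v = rng.standard_normal(z.shape[1])
        v /= np.linalg.norm(v)
        assert np.linalg.norm(z @ v) ** 2 <= share_e + 1e-9


def test_merge_close_modules_behaviour():
    mat, truth = simulate_comethylation_matrix(
        n_blocks=2, block_size=50, n_samples=20, within_corr=0.9, seed=9)
    tom = topological_overlap(correlation_adjacency(mat))
    asg = detect_modules(tom, mat)
    n_before = len(asg.sizes)
    # distinct latent signals: nothing merges at the default threshold
    kept = merge_close_modules(asg, mat)
    assert len(kept.sizes) <= n_before
    # duplicated block: the two copies share a latent profile and merge
    dup = pd.concat([mat.iloc[truth == 1]] * 2, ignore_index=True)
    dup.index = [f"r{i}" for i in range(len(dup))]
    tom2 = topological_overlap(correlation_adjacency(dup))
    asg2 = detect_modules(tom2, dup, min_module_size=20, cut_height=0.9)
    if len(asg2.sizes) >= 2:
        merged = merge_close_modules(asg2, dup)
        assert len(merged.sizes) < len(asg2.sizes)


def test_pipeline_is_deterministic():
    mat, _ = simulate_comethylation_matrix(seed=11)
    runs = []
    for _ in range(2):
        tom = topological_overlap(correlation_adjacency(mat))
        asg = merge_close_modules(detect_modules(tom, mat), mat)
        runs.append(asg.labels.copy())
    assert np.array_equal(runs[0], runs[1])
    block = detect_modules_blockwise(mat)
    assert np.array_equal(block.labels,
                          detect_modules_blockwise(mat).labels)


def test_module_profile_summary():
    mat = pd.DataFrame(np.tile([0.2, 0.8, 0.5], (40, 1)),
                       index=[f"l{i}" for i in range(40)],
                       columns=["m1", "m2", "m3"])
    from methdyn.network import ModuleAssignment
    asg = ModuleAssignment(list(mat.index), np.ones(40, dtype=int))
    summary = module_profile_summary(asg, mat)
    assert (summary["sd"] == 0).all()
    assert summary.set_index("methylome")["mean"].to_dict() == \
        {"m1": 0.2, "m2": 0.8, "m3": 0.5}
    assert summary["mean"].between(0, 1).all()


# ---------------------------------------------------------------------------
# preprocessing

def _tiny_panel(positions, levels_by_sample, coverage=20):
    methylomes = {}
    for name, levels in levels_by_sample.items():
        levels = np.asarray(levels, dtype=float)
        cov = np.where(np.isnan(levels), 0, coverage).astype(int)
        meth = np.round(np.nan_to_num(levels) * cov).astype(int)
        methylomes[name] = make_methylome(positions, meth, cov - meth,
                                          name=name)
    return MethylomePanel.from_methylomes(methylomes)


def test_preprocess_window_merge_and_missing():
    genes = [GeneModel("g", "chr1", "+", tss=50_000, tes=60_000)]
    # 12 kb upstream (out), 3 kb upstream (in), two close sites (merge),
    # one site missing in sample c (dropped)
    positions = np.array([38_000, 47_000, 55_000, 55_150, 58_000])
    nan = np.nan
    panel = _tiny_panel(positions, {
        "a": [0.1, 0.2, 0.4, 0.6, 0.9],
        "b": [0.1, 0.3, 0.5, 0.7, 0.8],
        "c": [0.1, 0.4, 0.6, 0.8, nan]})
    dms = pd.DataFrame({"chrom": "chr1", "pos": positions})
    matrix = preprocess_dms_matrix(dms, genes, panel, merge_gap=200)
    assert matrix.provenance["n_input"] == 5
    assert matrix.provenance["n_in_gene_window"] == 4   # 38 kb site removed
    assert matrix.provenance["n_merged_loci"] == 3      # 55 000+55 150 fused
    assert matrix.provenance["n_complete_loci"] == 2    # 58 000 row dropped
    merged_row = matrix.values.loc["chr1:54999-55150"]
    assert merged_row["a"] == pytest.approx(0.5)  # coverage-weighted mean
    with pytest.raises(ValueError):
        preprocess_dms_matrix(
            pd.DataFrame({"chrom": ["chr1"], "pos": [5]}), genes, panel)


def test_dms_matrix_validates():
    good = pd.DataFrame(np.full((3, 3), 0.5),
                        columns=["a", "b", "c"])
    DmsMatrix(good)
    bad = good.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValueError):
        DmsMatrix(bad)
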