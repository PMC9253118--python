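"""Adjacency, topological overlap, module detection, hypergeometric enrichment."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from thermomem.coexpr import (
    CoexprError,
    NetworkConfig,
    build_adjacency,
    detect_modules,
    module_enrichment,
    scale_free_fit,
    soft_power_scan,
    topological_overlap,
)
from thermomem.simulate import simulate_module_expression


def _expr_with_cor(cor: float, n: int = 400, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    a = z
    b = cor * z + np.sqrt(1 - cor**2) * rng.normal(size=n)
    return pd.DataFrame([a, b], index=["gA", "gB"])


def test_adjacency_formulas():
    expr = _expr_with_cor(0.5, n=100_000, seed=1)
    cfg = NetworkConfig(soft_power=2)
    a = build_adjacency(expr, cfg)
    assert a.loc["gA", "gA"] == 1.0
    assert a.loc["gA", "gB"] == pytest.approx(0.25, abs=0.01)  # 0.5^2
    cor = np.corrcoef(expr.to_numpy())[0, 1]
    signed = build_adjacency(expr, NetworkConfig(soft_power=2, signed=True))
    assert signed.loc["gA", "gB"] == pytest.approx(((1 + cor) / 2) ** 2, abs=1e-12)
    assert np.allclose(a, a.T)


def test_raising_power_never_increases_adjacency():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(rng.normal(size=(20, 30)),
                        index=[f"g{i}" for i in range(20)])
    prev = None
    for beta in (1, 2, 4, 8):
        a = build_adjacency(expr, NetworkConfig(soft_power=beta)).to_numpy()
        np.fill_diagonal(a, 0)
        if prev is not None:
            assert (a <= prev + 1e-12).all()
        prev = a


def test_constant_gene_rejected_in_adjacency():
    expr = pd.DataFrame([[1.0, 1, 1], [0, 1, 2]], index=["flat", "ok"])
    with pytest.raises(CoexprError, match="flat"):
        build_adjacency(expr)


def test_tom_hand_values_and_bounds():
    # 3-node complete graph with all a = 1: TOM = (1 + 1)/(2 + 1 - 1) = 1
    ones = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
    tom = topological_overlap(ones)
    assert np.allclose(tom, 1.0)
    # no edges -> off-diagonal 0
    eye = pd.DataFrame(np.eye(4))
    tom0 = topological_overlap(eye)
    assert np.allclose(tom0.to_numpy()[~np.eye(4, dtype=bool)], 0.0)
    # random adjacency: symmetric, in [0, 1], unit diagonal
    rng = np.random.default_rng(3)
    m = rng.uniform(size=(10, 10))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    tomr = topological_overlap(pd.DataFrame(m)).to_numpy()
    assert np.allclose(tomr, tomr.T)
    assert tomr.min() >= 0 and tomr.max() <= 1
    assert np.allclose(np.diag(tomr), 1.0)


def test_scale_free_fit_on_power_law_connectivity():
    rng = np.random.default_rng(4)
    k = (rng.pareto(2.0, size=3000) + 1) * 3
    assert scale_free_fit(k) >= 0.8
    # mass concentrated at high connectivity: frequency rises with k, so the
    # positive slope is penalised and the index goes negative
    k_anti = 50.0 - np.clip((rng.pareto(2.0, size=3000) + 1) * 3, None, 45.0)
    assert scale_free_fit(k_anti) < 0


def test_power_scan_grid_and_connectivity_monotone(small_counts):
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.normal(size=(80, 30)),
                        index=[f"g{i}" for i in range(80)])
    scan = soft_power_scan(expr, NetworkConfig(power_grid=(1, 6)))
    assert len(scan) == 2
    assert (
        scan.loc[scan.power == 6, "mean_connectivity"].iloc[0]
        < scan.loc[scan.power == 1, "mean_connectivity"].iloc[0]
    )
    one = soft_power_scan(expr, NetworkConfig(power_grid=(6,)))
    assert len(one) == 1


def _planted_partition(seed=6):
    expr, labels = simulate_module_expression(
        (60, 60), n_noise=30, n_samples=60, within_cor=0.8, seed=seed
    )
    cfg = NetworkConfig(min_module_size=30, cut_height=0.99)
    tom = topological_overlap(build_adjacency(expr, cfg))
    return expr, labels, detect_modules(tom, expr, cfg)


def test_two_planted_modules_recovered_exactly():
    expr, labels, part = _planted_partition()
    module_genes = [g for g, m in labels.items() if m > 0]
    truth = [labels[g] for g in module_genes]
    got = [part.labels[g] for g in module_genes]
    assert adjusted_rand_score(truth, got) == 1.0
    assert part.labels.value_counts().sum() == len(expr)
    # eigengene sign anchored: positive mean loading
    for m in range(1, part.n_modules + 1):
        sub = expr.loc[part.labels.index[part.labels == m]]
        z = (sub - sub.mean(axis=1).to_numpy()[:, None]).div(
            sub.std(axis=1), axis=0
        )
        loadings = z.to_numpy() @ part.eigengenes[f"ME{m}"].to_numpy()
        assert loadings.mean() > 0


def test_independent_noise_stays_unassigned():
    expr, _ = simulate_module_expression((), n_noise=120, n_samples=60, seed=7)
    cfg = NetworkConfig(min_module_size=30, cut_height=0.99)
    tom = topological_overlap(build_adjacency(expr, cfg))
    part = detect_modules(tom, expr, cfg)
    assert (part.labels == 0).mean() >= 0.9


def test_partition_deterministic():
    _, _, p1 = _planted_partition(seed=8)
    _, _, p2 = _planted_partition(seed=8)
    pd.testing.assert_series_equal(p1.labels, p2.labels)


def _hypergeom_oracle(N, K, n, x):
    """Exact upper tail by rational enumeration."""
    total = Fraction(0)
    for i in range(x, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def test_enrichment_p_matches_exact_enumeration():
    from scipy.stats import hypergeom

    assert hypergeom.sf(3, 10, 5, 4) == pytest.approx(5 / 210, abs=1e-15)
    for N in (5, 8, 12):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for x in range(0, min(n, K) + 1):
                    assert float(hypergeom.sf(x - 1, N, K, n)) == pytest.approx(
                        _hypergeom_oracle(N, K, n, x), abs=1e-12
                    )


def test_module_enrichment_table():
    labels = pd.Series(
        [1] * 5 + [2] * 5, index=[f"g{i}" for i in range(10)], name="module"
    )
    part_eig = pd.DataFrame()
    from thermomem.coexpr import ModulePartition

    part = ModulePartition(labels=labels, eigengenes=part_eig, n_modules=2)
    targets = {"TF": {"g0", "g1", "g2", "g3", "g9"}}
    enr = module_enrichment(part, targets, include_intersection=False)
    row = enr[(enr.module == 1)].iloc[0]
    # overlap 4 of module 5, K=5, N=10: p = sum_{i>=4} C(5,i)C(5,5-i)/C(10,5)
    expect = _hypergeom_oracle(10, 5, 5, 4)
    assert row.p == pytest.approx(expect, abs=1e-12)
    # zero overlap -> upper tail is 1
    none = module_enrichment(part, {"TF": {"g5", "g6"}},
                             include_intersection=False)
    assert none[(none.module == 1)].iloc[0].p == pytest.approx(1.0)


def test_planted_target_concentration_detected():
    expr, labels, part = _planted_partition(seed=9)
    m1 = [g for g, m in labels.items() if m == 1]
    noise = [g for g, m in labels.items() if m == 0]
    targets = set(m1[:20]) | set(noise[:5])  # 80% inside one planted module
    enr = module_enrichment(part, {"TF": targets}, include_intersection=False)
    enriched = enr[enr.module == part.labels[m1[0]]]
    others = enr[enr.module != part.labels[m1[0]]]
    assert (enriched.adj_p < 0.001).all()
    assert (others.p > 0.05).all()
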