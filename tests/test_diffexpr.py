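"""Normalisation, weighted fits, empirical-Bayes moderation, contrasts, MDS."""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import polygamma

from thermomem.diffexpr import (
    DesignError,
    GeneExpressionLM,
    LinearModelFit,
    ModerationParams,
    WeightedExpression,
    cell_means_design,
    classical_mds,
    contrast_test,
    decide_global,
    empirical_bayes_moderate,
    fit_gene_models,
    logcpm,
    precision_weighted_logcpm,
    quantile_normalize,
    sample_correlation,
    trigamma_inverse,
)


# --------------------------------------------------------------------- logCPM


def test_logcpm_matches_direct_formula():
    counts = pd.DataFrame({"s1": [100, 10**6 - 100]}, index=["g1", "g2"])
    y, lib = logcpm(counts)
    assert lib["s1"] == 10**6
    assert y.loc["g1", "s1"] == pytest.approx(
        np.log2(100.5 / (10**6 + 1) * 1e6), abs=1e-9
    )
    assert y.loc["g1", "s1"] == pytest.approx(6.651, abs=1e-3)


def test_quantile_normalization_properties():
    rng = np.random.default_rng(0)
    y = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    qn, ref = quantile_normalize(y)
    # all columns share the identical sorted multiset
    sorted_cols = np.sort(qn.to_numpy(), axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]])
    # identical columns -> identity
    same = pd.DataFrame(np.tile(y[["a"]].to_numpy(), (1, 3)), columns=list("xyz"))
    qn2, _ = quantile_normalize(same)
    assert np.allclose(qn2.to_numpy(), same.to_numpy())
    # permuted columns -> identical sorted vectors (already covered) and
    # the permutation is preserved within each column
    perm = y.copy()
    perm["b"] = y["a"].sample(frac=1, random_state=1).to_numpy()
    qn3, _ = quantile_normalize(perm[["a", "b"]])
    assert sorted(qn3["a"]) == sorted(qn3["b"])


def test_all_zero_sample_rejected():
    counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(DesignError, match="zero library"):
        precision_weighted_logcpm(counts)


# ------------------------------------------------------------------ WLS fits


def _manual_we(y: pd.DataFrame, w: pd.DataFrame | None = None) -> WeightedExpression:
    if w is None:
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
    return WeightedExpression(
        exprs=y, weights=w, lib_sizes=pd.Series(1.0, index=y.columns),
        all_zero=pd.Index([]),
    )


def _two_group_design(n_per: int) -> pd.DataFrame:
    cols = ["g1"] * n_per + ["g2"] * n_per
    X = pd.get_dummies(pd.Series(cols)).astype(float)
    X.index = [f"s{i}" for i in range(2 * n_per)]
    return X


def test_equal_weights_reduce_to_ols():
    rng = np.random.default_rng(1)
    X = _two_group_design(4)
    y = pd.DataFrame(rng.normal(size=(20, 8)), columns=X.index)
    fit = fit_gene_models(_manual_we(y), X)
    # OLS on a cell-means design = group means
    means = np.column_stack(
        [y.iloc[:, :4].mean(axis=1), y.iloc[:, 4:].mean(axis=1)]
    )
    assert np.allclose(fit.coef.to_numpy(), means, atol=1e-10)


def test_saturated_design_interpolates_noise_free_means(small_config, small_truth):
    # zero-noise expression: coefficients reproduce the planted cell means
    sheet_cols = ["WT.control.0h", "WT.heat.0h"]
    X = pd.DataFrame(
        [[1.0, 0], [1, 0], [0, 1], [0, 1]], columns=sheet_cols,
        index=[f"s{i}" for i in range(4)],
    )
    planted = np.array([[5.0, 7.0], [3.0, 3.0]])
    y = pd.DataFrame(planted @ X.to_numpy().T, columns=X.index,
                     index=["gA", "gB"])
    fit = fit_gene_models(_manual_we(y), X)
    assert np.allclose(fit.coef.to_numpy(), planted, atol=1e-12)
    assert np.allclose(fit.s2, 0.0, atol=1e-20)


def test_rank_deficient_design_names_aliased_columns():
    X = _two_group_design(3)
    X["dup"] = X["g1"]
    y = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                     columns=X.index)
    with pytest.raises(DesignError, match="dup"):
        fit_gene_models(_manual_we(y), X)


# --------------------------------------------------------- empirical Bayes


def test_trigamma_inverse_round_trip():
    for y in (1e-5, 0.01, 0.5, 2.0, 50.0, 1e6):
        x = trigamma_inverse(y)
        assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


def _fit_from_s2(s2: np.ndarray, df: float) -> LinearModelFit:
    g = len(s2)
    return LinearModelFit(
        coef=pd.DataFrame(np.zeros((g, 1)), columns=["c"]),
        s2=s2,
        df_resid=np.full(g, float(df)),
        cov_unscaled=np.ones((g, 1, 1)),
        design=pd.DataFrame(np.ones((int(df) + 1, 1)), columns=["c"]),
        zero_df=pd.Index([]),
    )


def test_prior_recovery_from_scaled_f_sample():
    rng = np.random.default_rng(10)
    d0, s0_2, dg = 4.0, 2.0, 10.0
    s2 = s0_2 * stats.f.rvs(dg, d0, size=5000, random_state=rng)
    mod = empirical_bayes_moderate(_fit_from_s2(s2, dg))
    assert mod.d0 == pytest.approx(d0, rel=0.15)
    assert mod.s0_2 == pytest.approx(s0_2, rel=0.15)


def test_moderation_limits():
    rng = np.random.default_rng(11)
    s2 = 1.5 * stats.f.rvs(10, 5, size=400, random_state=rng)
    fit = _fit_from_s2(s2, 10.0)
    mod = empirical_bayes_moderate(fit)
    assert 0 < mod.d0 < np.inf
    # 0 < d0 < inf: posterior strictly between s_g^2 and s0^2
    inside = (
        (np.minimum(fit.s2, mod.s0_2) < mod.s2_post)
        & (mod.s2_post < np.maximum(fit.s2, mod.s0_2))
    )
    assert inside[np.abs(fit.s2 - mod.s0_2) > 1e-6].all()
    # d0 = 0 -> ordinary t
    r0 = contrast_test(fit, mod, np.array([1.0]), "c", d0=0.0)
    t_ordinary = fit.coef.to_numpy()[:, 0] / np.sqrt(fit.s2)
    assert np.allclose(np.nan_to_num(r0.table["t"]), np.nan_to_num(t_ordinary))
    # d0 = inf -> posterior variance is s0^2 everywhere
    rinf = contrast_test(fit, mod, np.array([1.0]), "c", d0=np.inf)
    assert rinf.table["t"].abs().max() == 0.0  # coefs are 0 here; just no NaN
    identical = _fit_from_s2(np.full(50, 3.0), 10.0)
    mod_id = empirical_bayes_moderate(identical)
    assert np.isinf(mod_id.d0)
    assert np.allclose(mod_id.s2_post, mod_id.s0_2)


# ----------------------------------------------------------------- contrasts


def test_interaction_contrast_antisymmetry(small_counts):
    counts, sheet = small_counts
    res = GeneExpressionLM.from_counts(counts, sheet).fit()
    fwd = res.interaction_contrast("OE", "KO", "0h").table
    rev = res.interaction_contrast("KO", "OE", "0h").table
    assert np.allclose(fwd["logFC"], -rev["logFC"])
    assert np.allclose(fwd["t"], -rev["t"])


def test_additive_genes_have_null_interaction(small_counts, small_truth):
    counts, sheet = small_counts
    res = GeneExpressionLM.from_counts(counts, sheet).fit()
    r = res.interaction_contrast("OE", "WT", "0h").table
    nulls = r.drop(index=list(small_truth.direct_targets))
    se = nulls["logFC"].std() / np.sqrt(len(nulls))
    assert abs(nulls["logFC"].mean()) < 3 * se + 0.02


def test_planted_interaction_recovered_at_ten_replicates():
    from thermomem.simulate import SimulationConfig, plant_truth, simulate_counts

    cfg = SimulationConfig(n_genes=600, n_direct_targets=20, n_modules=1,
                           module_sizes=(30,), replicates=10,
                           n_ct_genes=10, n_ct_undetectable=0,
                           n_decoy_peaks=0, seed=21)
    truth = plant_truth(cfg)
    counts, sheet = simulate_counts(cfg, truth)
    res = GeneExpressionLM.from_counts(counts, sheet).fit()
    for tp in ("0h",):
        r = res.interaction_contrast("OE", "WT", tp).table
        act = [g for g, t in truth.direct_targets.items()
               if t.direction == "activated" and tp in t.timepoints]
        assert r.loc[act, "logFC"].mean() == pytest.approx(
            cfg.target_interaction_lfc, abs=0.2
        )
        ko = res.interaction_contrast("KO", "WT", tp).table
        assert ko.loc[act, "logFC"].mean() == pytest.approx(
            -cfg.target_interaction_lfc, abs=0.2
        )


# ----------------------------------------------------------- global decisions


def test_bh_worked_example_and_single_p():
    fit = _fit_from_s2(np.ones(4), 10.0)
    r = contrast_test(fit, ModerationParams(0.0, 1.0, np.ones(4)),
                      np.array([1.0]), "c", d0=0.0)
    r.table["p"] = [0.01, 0.02, 0.03, 0.04]
    r.table["logFC"] = [1.0, -1.0, 1.0, 1.0]
    decide_global([r], alpha=0.05)
    assert np.allclose(r.table["adj_p"], 0.04)
    assert list(r.table["decision"]) == [1, -1, 1, 1]
    single = contrast_test(fit, ModerationParams(0.0, 1.0, np.ones(4)),
                           np.array([1.0]), "c", d0=0.0)
    single.table = single.table.iloc[:1].copy()
    single.table["p"] = [0.031]
    decide_global([single], alpha=0.05)
    assert single.table["adj_p"].iloc[0] == pytest.approx(0.031)


def test_alpha_one_saturates_decisions():
    fit = _fit_from_s2(np.ones(10), 10.0)
    r = contrast_test(fit, ModerationParams(0.0, 1.0, np.ones(10)),
                      np.array([1.0]), "c", d0=0.0)
    rng = np.random.default_rng(0)
    r.table["p"] = rng.uniform(size=10)
    r.table["logFC"] = rng.normal(size=10)
    decide_global([r], alpha=0.999999, lfc=0.0)
    assert (r.table["decision"] != 0).all()
    with pytest.raises(DesignError):
        decide_global([r], alpha=1.5)


# ---------------------------------------------------------------- diagnostics


def test_sample_correlation_properties():
    y = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [3.0, 2, 1]},
                     index=["g1", "g2", "g3"])
    corr, order = sample_correlation(y)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)  # reversed ranks, 2 used dims
    assert set(order) == {"a", "b", "c"}


def test_zero_variance_sample_recorded_missing():
    y = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 2, 2]})
    corr, order = sample_correlation(y)
    assert np.isnan(corr.loc["a", "b"])
    assert order[-1] == "b"


def test_mds_collinear_configuration_exact():
    pos = np.array([0.0, 3.0, 7.0])
    D = np.abs(pos[:, None] - pos[None, :])
    coords, evals = classical_mds(D, dims=1, is_distance=True)
    rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
    assert np.allclose(rec, D, atol=1e-9)


def test_mds_two_dimensional_exactness_and_degenerate():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(6, 2))
    # expression frame with 2 "genes" = the coordinates
    expr = pd.DataFrame(pts.T, columns=[f"s{i}" for i in range(6)])
    coords, _ = classical_mds(expr, dims=2)
    D_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    D_out = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    assert np.allclose(D_in, D_out, atol=1e-9)
    same = pd.DataFrame(np.ones((3, 4)))
    coords0, _ = classical_mds(same, dims=2)
    assert np.allclose(coords0, 0.0, atol=1e-9)


# ------------------------------------------------------- independent oracle


LIMMA_SCRIPT = textwrap.dedent(
    """
    suppressMessages(library(limma))
    args <- commandArgs(trailingOnly=TRUE)
    y <- as.matrix(read.csv(args[1], row.names=1, check.names=FALSE))
    design <- as.matrix(read.csv(args[2], row.names=1, check.names=FALSE))
    fit <- lmFit(y, design)
    cm <- matrix(c(1, -1), ncol=1, dimnames=list(colnames(design), "diff"))
    fit2 <- eBayes(contrasts.fit(fit, cm))
    out <- data.frame(t=fit2$t[, 1], p=fit2$p.value[, 1])
    write.csv(out, args[3])
    cat(fit2$df.prior, fit2$s2.prior, sep="\\n")
    """
)


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Dual-route check: our WLS + trigamma-inversion moderation against the
    independent Bioconductor implementation on a shared matrix."""
    rng = np.random.default_rng(42)
    X = _two_group_design(4)
    y = pd.DataFrame(
        rng.normal(size=(150, 8)) * rng.uniform(0.5, 2.0, size=(150, 1)),
        index=[f"g{i}" for i in range(150)], columns=X.index,
    )
    y.iloc[:20, 4:] += 1.5  # some true differences

    ypath, xpath, opath = tmp_path / "y.csv", tmp_path / "X.csv", tmp_path / "o.csv"
    y.to_csv(ypath)
    X.to_csv(xpath)
    script = tmp_path / "limma.R"
    script.write_text(LIMMA_SCRIPT)
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(ypath), str(xpath), str(opath)],
        capture_output=True, text=True, timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    d0_ref, s02_ref = (float(v) for v in proc.stdout.split())
    ref = pd.read_csv(opath, index_col=0)

    fit = fit_gene_models(_manual_we(y), X)
    mod = empirical_bayes_moderate(fit)
    mine = contrast_test(fit, mod, np.array([1.0, -1.0]), "diff")

    assert mod.d0 == pytest.approx(d0_ref, rel=1e-4)
    assert mod.s0_2 == pytest.approx(s02_ref, rel=1e-4)
    assert np.allclose(mine.table["t"], ref["t"], atol=1e-6)
    assert np.allclose(mine.table["p"], ref["p"], atol=1e-8)
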