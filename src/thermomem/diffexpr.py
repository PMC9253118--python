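"""Moderated differential expression for factorial RNA-seq designs.

The chain implemented here is the standard linear-model route for bulk
RNA-seq counts:

1. log2 counts-per-million with a 0.5 count offset, a mean-variance trend
   fitted by locally weighted regression on sqrt residual standard
   deviations, and per-observation inverse-variance precision weights
   (predicted sd^-4);
2. quantile normalisation of the log-expression columns onto the column-mean
   reference distribution;
3. per-gene weighted least squares on a cell-means design over
   genotype x condition x timepoint;
4. empirical-Bayes variance moderation: the per-gene residual variances are
   shrunk towards a prior (d0, s0^2) estimated by matching the moments of
   log s_g^2 to a scaled-F distribution (trigamma inversion), giving
   posterior variances s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) and
   moderated t statistics on d0 + d_g degrees of freedom;
5. arbitrary linear contrasts, including the second-order interaction
   contrast (heat - control)_genotype - (heat - control)_WT per timepoint;
6. a global Benjamini-Hochberg decision over the pooled p-values of all
   contrasts.

The model/results pair (`GeneExpressionLM` / `GeneExpressionLMResults`)
carries the whole chain; the module-level functions expose the individual
steps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WeightedExpression",
    "ModerationParams",
    "ModeratedTestResult",
    "GeneExpressionLM",
    "GeneExpressionLMResults",
    "DesignError",
    "precision_weighted_logcpm",
    "quantile_normalize",
    "fit_gene_models",
    "empirical_bayes_moderate",
    "interaction_contrast",
    "heat_contrast",
    "decide_global",
    "sample_correlation",
    "classical_mds",
    "trigamma_inverse",
]


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable design / configuration."""


# --------------------------------------------------------------------------
# normalisation and precision weights


@dataclass
class WeightedExpression:
    """Normalised log2 expression with per-observation precision weights."""

    exprs: pd.DataFrame      # genes x samples, log2 scale, quantile normalised
    weights: pd.DataFrame    # same shape, > 0
    lib_sizes: pd.Series
    all_zero: pd.Index       # genes with zero counts everywhere (retained, flagged)
    reference_distribution: np.ndarray = field(repr=False, default=None)


def logcpm(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """log2((count + 0.5) / (libsize + 1) * 1e6) with column-sum library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise DesignError(f"samples with zero library size: {bad}")
    y = np.log2((counts.to_numpy() + 0.5) / (lib.to_numpy()[None, :] + 1.0) * 1e6)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns), lib


def quantile_normalize(y: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Map every column onto the column-mean reference distribution.

    After normalisation all columns share the identical sorted value multiset
    (the reference = mean of the per-column sorted vectors).
    """
    arr = y.to_numpy()
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = ref
    return pd.DataFrame(out, index=y.index, columns=y.columns), ref


def precision_weighted_logcpm(
    counts: pd.DataFrame,
    design: pd.DataFrame | np.ndarray | None = None,
    span: float = 0.5,
    robust_iters: int = 2,
) -> WeightedExpression:
    """Precision-weighted, quantile-normalised log2-CPM expression.

    The mean-variance trend (lowess of sqrt residual sd against average log2
    count) is fitted on the un-normalised log-CPM values and the weights are
    kept fixed afterwards; quantile normalisation is applied last.  ``design``
    defaults to an intercept-only model when omitted.
    """
    if counts.shape[1] < 2:
        raise DesignError("need >= 2 samples")
    y, lib = logcpm(counts)
    all_zero = counts.index[(counts == 0).all(axis=1)]

    X = _as_design(design, counts.shape[1])
    # unweighted per-gene fit for residual sd
    beta, fitted, s, dfres = _ols_all_genes(y.to_numpy(), X)

    # trend on genes with positive residual variance and some signal
    mean_log_count = y.to_numpy().mean(axis=1) + np.log2(lib.to_numpy() + 1.0).mean() - np.log2(1e6)
    ok = (s > 0) & ~y.index.isin(all_zero)
    if ok.sum() < 10:
        # too few genes to fit a trend; fall back to equal weights
        w = np.ones_like(y.to_numpy())
    else:
        sx = mean_log_count[ok]
        sy = np.sqrt(s[ok])
        smooth = lowess(sy, sx, frac=span, it=robust_iters, return_sorted=True)
        xs, ys = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)
        # per-observation fitted log2 count -> predicted sqrt-sd -> weight
        fitted_logcount = fitted + (np.log2(lib.to_numpy() + 1.0) - np.log2(1e6))[None, :]
        pred = np.interp(fitted_logcount, xs, ys)
        w = pred ** -4.0
    weights = pd.DataFrame(w, index=y.index, columns=y.columns)

    yqn, ref = quantile_normalize(y)
    return WeightedExpression(
        exprs=yqn,
        weights=weights,
        lib_sizes=lib,
        all_zero=all_zero,
        reference_distribution=ref,
    )


def _as_design(design, n_samples: int) -> np.ndarray:
    if design is None:
        return np.ones((n_samples, 1))
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n_samples:
        raise DesignError(
            f"design has {X.shape[0]} rows for {n_samples} samples"
        )
    return X


def _ols_all_genes(Y: np.ndarray, X: np.ndarray):
    """Unweighted per-gene OLS (shared design). Returns beta, fitted, sd, df."""
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T                       # genes x p
    fitted = beta @ X.T                     # genes x n
    resid = Y - fitted
    dfres = Y.shape[1] - np.linalg.matrix_rank(X)
    if dfres <= 0:
        return beta, fitted, np.zeros(Y.shape[0]), 0
    s = np.sqrt((resid ** 2).sum(axis=1) / dfres)
    return beta, fitted, s, dfres


# --------------------------------------------------------------------------
# design construction and per-gene weighted least squares


def cell_means_design(sheet: pd.DataFrame) -> pd.DataFrame:
    """One indicator column per genotype.condition.timepoint cell."""
    for col in ("genotype", "condition", "timepoint"):
        if col not in sheet.columns:
            raise DesignError(f"sample sheet missing column {col!r}")
    cell = (
        sheet["genotype"].astype(str)
        + "."
        + sheet["condition"].astype(str)
        + "."
        + sheet["timepoint"].astype(str)
    )
    X = pd.get_dummies(cell).astype(float)
    X.index = (
        sheet["sample_id"] if "sample_id" in sheet.columns else sheet.index
    )
    X = X[sorted(X.columns)]
    return X


@dataclass
class LinearModelFit:
    """Per-gene WLS fit on a shared design."""

    coef: pd.DataFrame            # genes x coefficients
    s2: np.ndarray                # per-gene residual variance
    df_resid: np.ndarray          # per-gene residual df
    cov_unscaled: np.ndarray      # genes x p x p, (X' W X)^-1
    design: pd.DataFrame
    zero_df: pd.Index             # genes with no residual df (flagged)


def fit_gene_models(
    we: WeightedExpression, design: pd.DataFrame
) -> LinearModelFit:
    """Weighted least squares for every gene with the observation weights."""
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(design)
        raise DesignError(f"design is rank-deficient; aliased columns: {aliased}")
    Y = we.exprs.loc[:, design.index].to_numpy()
    W = we.weights.loc[:, design.index].to_numpy()
    n, p = X.shape

    XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
    XtWy = np.einsum("np,gn->gp", X, W * Y, optimize=True)
    cov = np.linalg.inv(XtWX)
    beta = np.einsum("gpq,gq->gp", cov, XtWy, optimize=True)
    resid = Y - beta @ X.T
    dfres = n - p
    rss = (W * resid ** 2).sum(axis=1)
    if dfres > 0:
        s2 = rss / dfres
        df = np.full(Y.shape[0], float(dfres))
    else:
        s2 = np.full(Y.shape[0], np.nan)
        df = np.zeros(Y.shape[0])
    zero_df = we.exprs.index[df == 0]
    return LinearModelFit(
        coef=pd.DataFrame(beta, index=we.exprs.index, columns=design.columns),
        s2=s2,
        df_resid=df,
        cov_unscaled=cov,
        design=design,
        zero_df=zero_df,
    )


def _aliased_columns(design: pd.DataFrame) -> list[str]:
    X = design.to_numpy(dtype=float)
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
        else:
            aliased.append(design.columns[j])
    return aliased


# --------------------------------------------------------------------------
# empirical-Bayes moderation


@dataclass
class ModerationParams:
    """Scaled-F prior for residual variances and the shrunken posteriors."""

    d0: float                 # prior df (np.inf sentinel allowed)
    s0_2: float               # prior variance
    s2_post: np.ndarray       # posterior (moderated) variances per gene


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def empirical_bayes_moderate(fit: LinearModelFit) -> ModerationParams:
    """Estimate (d0, s0^2) and shrink the per-gene residual variances.

    Moment matching of log s_g^2 against a scaled-F prior: the excess
    variance of ``log s_g^2 - digamma(d_g/2) + log(d_g/2)`` over its sampling
    component ``trigamma(d_g/2)`` determines d0 through the trigamma inverse;
    no excess (all s_g^2 essentially identical) yields the d0 = inf sentinel
    with posterior variance s0^2 everywhere.
    """
    ok = (fit.df_resid > 0) & np.isfinite(fit.s2) & (fit.s2 > 0)
    if ok.sum() < 10:
        raise DesignError("need >= 10 genes with positive residual df")
    s2 = fit.s2[ok]
    df = fit.df_resid[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))

    s2_full = np.where(ok, fit.s2, 0.0)
    df_full = fit.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(s2_full, s0_2)
    else:
        s2_post = (d0 * s0_2 + df_full * s2_full) / (d0 + df_full)
    return ModerationParams(d0=float(d0), s0_2=s0_2, s2_post=s2_post)


# --------------------------------------------------------------------------
# contrasts and decisions


@dataclass
class ModeratedTestResult:
    """Per-gene test of one contrast (before/after the global BH decision)."""

    name: str
    table: pd.DataFrame  # columns: logFC, t, p (adj_p, decision added later)

    def __len__(self) -> int:
        return len(self.table)


def contrast_test(
    fit: LinearModelFit,
    moderation: ModerationParams,
    contrast: pd.Series | np.ndarray,
    name: str,
    d0: float | None = None,
) -> ModeratedTestResult:
    """Moderated t-test of a linear contrast of the coefficients.

    Passing ``d0=0`` reduces to the ordinary t-test on the raw residual
    variances (no shrinkage)."""
    c = _contrast_vector(fit, contrast)
    lfc = fit.coef.to_numpy() @ c
    v = np.einsum("p,gpq,q->g", c, fit.cov_unscaled, c, optimize=True)
    d0_eff = moderation.d0 if d0 is None else d0
    if d0_eff == 0:
        s2 = fit.s2
    elif np.isinf(d0_eff):
        s2 = np.full_like(fit.s2, moderation.s0_2)
    else:
        s2 = (d0_eff * moderation.s0_2 + fit.df_resid * np.where(
            fit.df_resid > 0, fit.s2, 0.0)) / (d0_eff + fit.df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2 * v)
    df_total = np.minimum(fit.df_resid + d0_eff, 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"logFC": lfc, "t": t, "p": p}, index=fit.coef.index
    )
    return ModeratedTestResult(name=name, table=table)


def _contrast_vector(fit: LinearModelFit, contrast) -> np.ndarray:
    if isinstance(contrast, pd.Series):
        c = np.zeros(fit.coef.shape[1])
        for key, val in contrast.items():
            if key not in fit.coef.columns:
                raise DesignError(f"unknown coefficient {key!r} in contrast")
            c[fit.coef.columns.get_loc(key)] = val
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.coef.shape[1],):
        raise DesignError(
            f"contrast length {c.shape} does not match {fit.coef.shape[1]} coefficients"
        )
    return c


def _cell(geno: str, cond: str, tp: str) -> str:
    return f"{geno}.{cond}.{tp}"


def heat_contrast(
    fit: LinearModelFit,
    moderation: ModerationParams,
    genotype: str,
    timepoint: str,
) -> ModeratedTestResult:
    """heat - control within one genotype at one timepoint."""
    spec = pd.Series(
        {
            _cell(genotype, "heat", timepoint): 1.0,
            _cell(genotype, "control", timepoint): -1.0,
        }
    )
    return contrast_test(fit, moderation, spec, name=f"heat_{genotype}@{timepoint}")


def interaction_contrast(
    fit: LinearModelFit,
    moderation: ModerationParams,
    genoA: str,
    genoB: str,
    timepoint: str,
) -> ModeratedTestResult:
    """(heat - control)_genoA - (heat - control)_genoB at one timepoint."""
    spec = pd.Series(
        {
            _cell(genoA, "heat", timepoint): 1.0,
            _cell(genoA, "control", timepoint): -1.0,
            _cell(genoB, "heat", timepoint): -1.0,
            _cell(genoB, "control", timepoint): 1.0,
        }
    )
    return contrast_test(
        fit, moderation, spec, name=f"{genoA}_vs_{genoB}@{timepoint}"
    )


def decide_global(
    results: list[ModeratedTestResult],
    alpha: float = 0.05,
    lfc: float = 0.0,
) -> list[ModeratedTestResult]:
    """Global BH decision: adjust the pooled p-vector across all contrasts.

    Adds ``adj_p`` and ``decision`` (-1/0/+1 by logFC sign) columns in place
    and returns the same list.  A decision is non-zero iff adj_p <= alpha and
    |logFC| >= lfc.
    """
    if not 0 < alpha < 1:
        raise DesignError(f"alpha must be in (0, 1), got {alpha}")
    pooled = np.concatenate([r.table["p"].to_numpy() for r in results])
    finite = np.isfinite(pooled)
    adj = np.full_like(pooled, np.nan)
    if finite.any():
        adj[finite] = multipletests(pooled[finite], method="fdr_bh")[1]
    offset = 0
    for r in results:
        m = len(r.table)
        r.table["adj_p"] = adj[offset : offset + m]
        sig = (r.table["adj_p"] <= alpha) & (r.table["logFC"].abs() >= lfc)
        r.table["decision"] = np.where(
            sig, np.sign(r.table["logFC"]).astype(int), 0
        )
        offset += m
    return results


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper, kept for direct use)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# --------------------------------------------------------------------------
# sample-level diagnostics


def sample_correlation(
    we: WeightedExpression | pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Pairwise Pearson correlation of samples + average-linkage leaf order.

    Zero-variance samples yield NaN correlations (recorded as missing) and
    are placed last in the display order.
    """
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    expr = we.exprs if isinstance(we, WeightedExpression) else we
    if expr.shape[1] < 2:
        raise DesignError("need >= 2 samples")
    arr = expr.to_numpy()
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr.T)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    cdf = pd.DataFrame(corr, index=expr.columns, columns=expr.columns)

    good = np.flatnonzero(sd > 0)
    order: list = []
    if len(good) >= 2:
        sub = corr[np.ix_(good, good)]
        d = squareform(np.clip(1.0 - sub, 0.0, None), checks=False)
        z = average(d)
        order = [expr.columns[good[i]] for i in leaves_list(z)]
    order += [expr.columns[i] for i in range(len(sd)) if sd[i] == 0]
    return cdf, order


def classical_mds(
    data: pd.DataFrame | np.ndarray,
    dims: int = 2,
    is_distance: bool = False,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of samples.

    ``data`` is either a genes x samples expression frame (Euclidean
    distances over genes are computed) or a ready sample-distance matrix
    (``is_distance=True``).  Double-centres the squared distances and takes
    the top ``dims`` eigenpairs; for configurations that are exactly
    ``dims``-dimensional the embedding reproduces the input distances.
    Substantial negative eigenvalue mass (non-Euclidean input) triggers a
    warning.
    """
    if is_distance:
        D = np.asarray(data, dtype=float)
    else:
        X = (data.to_numpy() if isinstance(data, pd.DataFrame) else np.asarray(data)).T
        if X.shape[0] < 3:
            raise DesignError("need >= 3 samples")
        sq = (X ** 2).sum(axis=1)
        D2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
        D = np.sqrt(np.clip(D2, 0, None))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    neg_mass = -evals[evals < 0].sum()
    pos_mass = evals[evals > 0].sum()
    if pos_mass > 0 and neg_mass > tol * pos_mass and neg_mass > tol:
        warnings.warn(
            f"non-Euclidean distances: negative eigenvalue mass {neg_mass:.3g}",
            stacklevel=2,
        )
    lam = np.clip(evals[:dims], 0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)[None, :]
    return coords, evals


# --------------------------------------------------------------------------
# model / results surface


class GeneExpressionLM:
    """Per-gene weighted linear model over a factorial RNA-seq design.

    Built either from a prepared :class:`WeightedExpression` or directly from
    a count matrix (`from_counts`).  ``fit()`` runs the WLS + empirical-Bayes
    chain and returns a :class:`GeneExpressionLMResults`.
    """

    def __init__(self, we: WeightedExpression, sheet: pd.DataFrame,
                 design: pd.DataFrame | None = None):
        self.we = we
        self.sheet = sheet
        self.design = cell_means_design(sheet) if design is None else design
        # align design rows to expression columns
        self.design = self.design.loc[list(we.exprs.columns)]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, sheet: pd.DataFrame,
                    **voom_kwargs) -> "GeneExpressionLM":
        design = cell_means_design(sheet)
        design = design.loc[list(counts.columns)]
        we = precision_weighted_logcpm(counts, design=design, **voom_kwargs)
        return cls(we, sheet, design=design)

    def fit(self, moderate: bool = True) -> "GeneExpressionLMResults":
        fit = fit_gene_models(self.we, self.design)
        moderation = (
            empirical_bayes_moderate(fit)
            if moderate
            else ModerationParams(d0=0.0, s0_2=float(np.nanmedian(fit.s2)),
                                  s2_post=fit.s2.copy())
        )
        return GeneExpressionLMResults(self, fit, moderation)


class GeneExpressionLMResults:
    """Fitted per-gene models with moderated variances and contrast tests."""

    def __init__(self, model: GeneExpressionLM, fit: LinearModelFit,
                 moderation: ModerationParams):
        self.model = model
        self.fit_ = fit
        self.moderation = moderation

    @property
    def coef(self) -> pd.DataFrame:
        return self.fit_.coef

    def contrast(self, spec, name: str = "contrast") -> ModeratedTestResult:
        return contrast_test(self.fit_, self.moderation, spec, name)

    def heat_contrast(self, genotype: str, timepoint: str) -> ModeratedTestResult:
        return heat_contrast(self.fit_, self.moderation, genotype, timepoint)

    def interaction_contrast(
        self, genoA: str, genoB: str, timepoint: str
    ) -> ModeratedTestResult:
        return interaction_contrast(
            self.fit_, self.moderation, genoA, genoB, timepoint
        )

    def decide_global(self, results, alpha: float = 0.05, lfc: float = 0.0):
        return decide_global(results, alpha=alpha, lfc=lfc)

    def summary(self) -> str:
        fit = self.fit_
        lines = [
            "Gene-wise weighted linear model",
            f"  genes: {fit.coef.shape[0]}, samples: {fit.design.shape[0]}, "
            f"coefficients: {fit.coef.shape[1]}",
            f"  residual df per gene: {fit.df_resid[0]:.0f}",
            f"  prior df d0: {self.moderation.d0:.4g}, "
            f"prior variance s0^2: {self.moderation.s0_2:.4g}",
            f"  median residual variance: {np.nanmedian(fit.s2):.4g}, "
            f"median posterior variance: {np.nanmedian(self.moderation.s2_post):.4g}",
        ]
        return "\n".join(lines)
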