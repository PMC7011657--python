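"""Conditioning-based decomposition of expression variability.

The central idea: allele-specific (intrinsic) variability is uncorrelated
between genes, while cell-state (extrinsic) variability is shared.  Fitting
each gene with an ordinary multiple linear regression on measured cell-state
features and replacing counts by residuals-plus-gene-mean ("conditioning
with mean add-back") removes the shared component; what remains is judged by
its dispersion (Fano factor = variance / mean; 1 at the Poisson limit) and
by its covariance structure (gene-gene correlations and the variance
explained by the first principal components, compared with a
per-gene-shuffled baseline).  Unmeasured shared factors are recovered as the
leading principal components of the conditioned matrix and conditioned out
in a final stage.

The model is deliberately plain OLS on untransformed counts — including its
small-count imperfections — with no generalized-linear or technical-noise
correction.  Counts can be pre-transformed via the ``transform`` hook of
:class:`VarianceDecomposition` if desired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "MLRFit",
    "ConditionedMatrix",
    "CorrelationSummary",
    "StageResult",
    "DecompositionResults",
    "VarianceDecomposition",
    "fit_gene_mlr",
    "condition_expression",
    "sequential_decomposition",
    "dispersion_stats",
    "correlation_structure",
    "category_explained_variance",
    "calcium_feature_significance",
    "DEFAULT_STAGE_PLAN",
]


def _as_matrix(x) -> tuple[np.ndarray, list]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    arr = np.asarray(x, dtype=float)
    return arr, [f"col_{i}" for i in range(arr.shape[1])]


def _design(features: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    n = features.shape[0]
    X = np.column_stack([np.ones(n), features])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cur = X[:, :1]
        for j in range(features.shape[1]):
            cand = np.column_stack([cur, features[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                collinear.append(feature_names[j])
            else:
                cur = cand
        raise ValueError(f"design matrix is rank deficient; collinear features: {collinear}")
    return X


@dataclass
class MLRFit:
    """Per-gene OLS fit: intercept-first coefficients, R^2 and residuals."""

    coef: pd.DataFrame  # (1 + n_features) x genes
    r_squared: pd.Series  # per gene
    residuals: pd.DataFrame  # cells x genes
    fitted: pd.DataFrame  # cells x genes


def fit_gene_mlr(counts, features) -> MLRFit:
    """Ordinary least squares of every gene on the shared feature matrix.

    An intercept is always included.  R^2 = 1 - SS_res / SS_tot (zero for
    genes with zero total variance).  Requires n_cells > n_features + 1 and
    a full-rank design; collinear features are named in the error.
    """
    Y, gene_names = _as_matrix(counts)
    F, feat_names = _as_matrix(features)
    if Y.shape[0] != F.shape[0]:
        raise ValueError("counts and features disagree on cell count")
    if Y.shape[0] <= F.shape[1] + 1:
        raise ValueError(
            f"need n_cells > n_features + 1 ({Y.shape[0]} cells, {F.shape[1]} features)"
        )
    X = _design(F, feat_names)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    resid = Y - fitted
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    idx = pd.Index(["intercept"] + list(feat_names))
    cells = counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(Y.shape[0])
    return MLRFit(
        coef=pd.DataFrame(beta, index=idx, columns=gene_names),
        r_squared=pd.Series(r2, index=gene_names, name="r_squared"),
        residuals=pd.DataFrame(resid, index=cells, columns=gene_names),
        fitted=pd.DataFrame(fitted, index=cells, columns=gene_names),
    )


@dataclass
class ConditionedMatrix:
    """Residuals plus per-gene raw mean ("the gene conditioned on ...").

    Mean add-back keeps every gene's mean identical to the raw mean, so
    dispersion statistics stay on the raw count scale.  Negative values are
    legitimate and preserved; clipping would bias the Fano factor downward.
    """

    values: pd.DataFrame  # cells x genes
    provenance: tuple[str, ...]  # ordered feature names conditioned on
    r_squared: pd.Series

    @property
    def gene_means(self) -> pd.Series:
        return self.values.mean(axis=0)


def condition_expression(counts, features, provenance: tuple[str, ...] | None = None) -> ConditionedMatrix:
    """Condition counts on features: OLS residuals + per-gene raw mean."""
    counts_df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    if features is None or (hasattr(features, "shape") and features.shape[1] == 0):
        r2 = pd.Series(0.0, index=counts_df.columns)
        return ConditionedMatrix(values=counts_df.astype(float), provenance=(), r_squared=r2)
    fit = fit_gene_mlr(counts_df, features)
    conditioned = fit.residuals + counts_df.mean(axis=0)
    if provenance is None:
        provenance = tuple(features.columns) if isinstance(features, pd.DataFrame) else ()
    return ConditionedMatrix(values=conditioned, provenance=provenance, r_squared=fit.r_squared)


def dispersion_stats(conditioned, raw_means) -> pd.DataFrame:
    """Per-gene Fano factor and CV^2 of a (conditioned) expression matrix.

    Fano = Var / raw mean and CV^2 = Var / raw mean^2, with the unbiased
    (ddof = 1) variance estimator.  The denominator is the raw gene mean —
    identical to the conditioned mean under mean add-back.
    """
    values = conditioned.values if isinstance(conditioned, ConditionedMatrix) else conditioned
    mat, genes = _as_matrix(values)
    means = np.asarray(raw_means, dtype=float)
    if np.any(means == 0):
        bad = [g for g, m in zip(genes, means) if m == 0]
        raise ValueError(f"zero raw mean for genes {bad}; dispersion undefined")
    var = mat.var(axis=0, ddof=1)
    return pd.DataFrame(
        {"mean": means, "fano": var / means, "cv2": var / means**2},
        index=pd.Index(genes, name="gene"),
    )


@dataclass
class CorrelationSummary:
    """Gene-gene Pearson matrix and leading-PC explained variance."""

    correlation: pd.DataFrame
    pc_explained_variance: float  # fraction of total variance in first k PCs
    k: int
    shuffled_pc_explained_variance: float | None = None
    excluded_genes: tuple[str, ...] = ()


def _pc_explained(mat: np.ndarray, k: int, standardize: bool) -> float:
    x = mat - mat.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        x = x / sd
    pca = PCA(n_components=min(k, x.shape[1], x.shape[0] - 1), svd_solver="full")
    pca.fit(x)
    return float(pca.explained_variance_ratio_.sum())


def correlation_structure(
    matrix,
    k: int = 2,
    shuffle_seed: int | None = None,
    standardize: bool = True,
) -> CorrelationSummary:
    """Pearson correlation matrix plus first-k-PC explained variance.

    PCA runs on per-gene z-scored data by default (correlation PCA), making
    the explained-variance fraction a pure covariance-structure statistic
    independent of expression-magnitude differences between genes.  When
    ``shuffle_seed`` is given, the same statistic is recomputed after
    independently permuting each gene across cells — the no-shared-structure
    baseline.  Zero-variance genes are excluded with a warning.
    """
    mat, genes = _as_matrix(matrix)
    if mat.shape[1] < 2 or mat.shape[0] < 3:
        raise ValueError("need at least 2 genes and 3 cells")
    sd = mat.std(axis=0, ddof=1)
    excluded = tuple(g for g, s in zip(genes, sd) if s == 0)
    if excluded:
        warnings.warn(f"excluding zero-variance genes: {list(excluded)}")
        keep = sd > 0
        mat = mat[:, keep]
        genes = [g for g, k_ in zip(genes, keep) if k_]
    corr = np.corrcoef(mat, rowvar=False)
    pc_var = _pc_explained(mat, k, standardize)
    shuffled = None
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        shuf = np.column_stack([rng.permutation(mat[:, j]) for j in range(mat.shape[1])])
        shuffled = _pc_explained(shuf, k, standardize)
    gi = pd.Index(genes, name="gene")
    return CorrelationSummary(
        correlation=pd.DataFrame(corr, index=gi, columns=gi),
        pc_explained_variance=pc_var,
        k=k,
        shuffled_pc_explained_variance=shuffled,
        excluded_genes=excluded,
    )


# ---------------------------------------------------------------------------
# Sequential (staged) decomposition
# ---------------------------------------------------------------------------

#: Stage plan mirroring the analysis: volume first, then cell cycle,
#: then the remaining observed features, then the inferred hidden factors.
DEFAULT_STAGE_PLAN = (
    ("raw", ()),
    ("volume", ("volume",)),
    (
        "volume+cycle",
        ("volume", "s_score", "g2m_score"),
    ),
    (
        "all_observed",
        (
            "volume",
            "s_score",
            "g2m_score",
            "diff_marker_1",
            "diff_marker_2",
            "ca_n_peaks_low",
            "ca_n_peaks_high",
            "ca_decay_time",
            "ca_fwhm",
            "ca_auc_low",
            "ca_auc_high",
            "ca_max_value",
            "ca_time_of_max",
        ),
    ),
)


@dataclass
class StageResult:
    name: str
    feature_names: tuple[str, ...]
    conditioned: ConditionedMatrix
    dispersion: pd.DataFrame  # per-gene mean / fano / cv2
    correlation: CorrelationSummary

    @property
    def median_fano(self) -> float:
        return float(self.dispersion["fano"].median())

    @property
    def median_r_squared(self) -> float:
        return float(self.conditioned.r_squared.median())


@dataclass
class DecompositionResults:
    """Results of a staged variance decomposition.

    ``stages`` holds one :class:`StageResult` per conditioning stage in
    order (raw counts first when the plan starts with an empty feature
    set; the hidden-factor stage last).  ``hidden_factors`` are the
    per-cell scores of the principal components appended in the final
    stage.
    """

    stages: list[StageResult]
    hidden_factors: pd.DataFrame | None
    category_r2: pd.DataFrame | None = None
    model: "VarianceDecomposition | None" = None

    def __getitem__(self, name: str) -> StageResult:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(name)

    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]

    @property
    def final(self) -> StageResult:
        return self.stages[-1]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.stages:
            rows.append(
                {
                    "stage": st.name,
                    "n_features": len(st.feature_names),
                    "median_r2": st.median_r_squared,
                    "median_fano": st.median_fano,
                    "pc12_explained_variance": st.correlation.pc_explained_variance,
                    "shuffled_pc12": st.correlation.shuffled_pc_explained_variance,
                    "mean_abs_offdiag_corr": _mean_abs_offdiag(st.correlation.correlation),
                }
            )
        return pd.DataFrame(rows).set_index("stage")

    def summary(self) -> str:
        df = self.summary_frame()
        lines = ["Variance decomposition", "=" * 70]
        lines.append(df.to_string(float_format=lambda v: f"{v:.4f}"))
        final = self.final
        lines.append("-" * 70)
        lines.append(
            f"final stage '{final.name}': median Fano "
            f"{final.median_fano:.3f} (Poisson limit = 1), PC1+2 variance "
            f"{final.correlation.pc_explained_variance:.3%}"
        )
        if final.correlation.shuffled_pc_explained_variance is not None:
            lines.append(
                f"shuffled-baseline PC1+2 variance "
                f"{final.correlation.shuffled_pc_explained_variance:.3%}"
            )
        return "\n".join(lines)

    # ---- plotting -------------------------------------------------------
    def plot_fano(self, ax=None):
        """Boxplots of per-gene Fano factors across stages."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.stages) + 2, 4))
        data = [st.dispersion["fano"].to_numpy() for st in self.stages]
        ax.boxplot(data, tick_labels=self.stage_names, whis=1.5)
        ax.axhline(1.0, ls="--", color="gray", lw=1, label="Poisson limit")
        ax.set_ylabel("Fano factor")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def plot_pc_variance(self, ax=None):
        """Explained variance of the first two PCs per stage vs shuffled."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.stages) + 2, 4))
        vals = [st.correlation.pc_explained_variance for st in self.stages]
        ax.plot(self.stage_names, vals, "o-", label="PC1+2 explained variance")
        shuf = self.final.correlation.shuffled_pc_explained_variance
        if shuf is not None:
            ax.axhline(shuf, ls=":", color="k", label="shuffled baseline")
        ax.set_ylabel("fraction of variance")
        ax.legend()
        return ax

    def plot_cv2_vs_mean(self, stage: str | None = None, ax=None):
        """CV^2 against mean on log-log axes with the Poisson line."""
        import matplotlib.pyplot as plt

        st = self[stage] if stage else self.final
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        d = st.dispersion
        ax.loglog(d["mean"], d["cv2"], ".", alpha=0.7)
        grid = np.geomspace(d["mean"].min(), d["mean"].max(), 50)
        ax.loglog(grid, 1.0 / grid, "--", color="gray", label="Poisson (CV$^2$ = 1/mean)")
        ax.set_xlabel("mean counts")
        ax.set_ylabel("CV$^2$")
        ax.legend()
        return ax


def _mean_abs_offdiag(corr: pd.DataFrame) -> float:
    c = corr.to_numpy()
    n = c.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.abs(c[mask]).mean())


def _validate_nested(plan) -> list[tuple[str, tuple[str, ...]]]:
    out = []
    prev: set = set()
    for name, feats in plan:
        feats = tuple(feats)
        if not prev <= set(feats):
            raise ValueError(
                f"stage plan is not nested: stage {name!r} does not contain "
                f"all previous features"
            )
        prev = set(feats)
        out.append((name, feats))
    return out


def sequential_decomposition(
    counts,
    features,
    stage_plan=DEFAULT_STAGE_PLAN,
    n_hidden: int = 2,
    shuffle_seed: int | None = 0,
    standardize_pca: bool = True,
) -> DecompositionResults:
    """Run the staged conditioning analysis.

    Each stage conditions the raw counts on a nested, growing feature set
    and records residual dispersion and covariance summaries.  When
    ``n_hidden`` > 0 a final stage appends that many "hidden" features —
    the leading principal components of the per-gene z-scored conditioned
    matrix of the last planned stage — and re-conditions, capturing shared
    cell-state variation the measured features missed.
    """
    counts_df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    plan = _validate_nested(stage_plan)
    raw_means = counts_df.mean(axis=0)

    stages: list[StageResult] = []
    last_cond: ConditionedMatrix | None = None
    for name, feats in plan:
        sub = features[list(feats)] if feats else None
        cond = condition_expression(counts_df, sub, provenance=feats)
        stages.append(_summarize_stage(name, feats, cond, raw_means, shuffle_seed, standardize_pca))
        last_cond = cond

    hidden_df = None
    if n_hidden > 0 and last_cond is not None:
        vals = last_cond.values.to_numpy()
        centered = vals - vals.mean(axis=0)
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        pca = PCA(n_components=n_hidden, svd_solver="full")
        scores = pca.fit_transform(centered / sd)
        hidden_df = pd.DataFrame(
            scores,
            index=counts_df.index,
            columns=[f"hidden_pc{i + 1}" for i in range(n_hidden)],
        )
        feats = plan[-1][1]
        aug = pd.concat(
            [features[list(feats)].set_axis(counts_df.index), hidden_df], axis=1
        ) if feats else hidden_df
        cond = condition_expression(counts_df, aug, provenance=tuple(aug.columns))
        stages.append(
            _summarize_stage(
                "hidden", tuple(aug.columns), cond, raw_means, shuffle_seed, standardize_pca
            )
        )
    return DecompositionResults(stages=stages, hidden_factors=hidden_df)


def _summarize_stage(name, feats, cond, raw_means, shuffle_seed, standardize_pca) -> StageResult:
    disp = dispersion_stats(cond, raw_means)
    corr = correlation_structure(
        cond.values, k=2, shuffle_seed=shuffle_seed, standardize=standardize_pca
    )
    return StageResult(
        name=name,
        feature_names=tuple(feats),
        conditioned=cond,
        dispersion=disp,
        correlation=corr,
    )


# ---------------------------------------------------------------------------
# Category-wise attribution of explained variance
# ---------------------------------------------------------------------------

DEFAULT_CATEGORY_ORDER = ("volume", "cell_cycle", "differentiation", "calcium")


def category_explained_variance(
    counts,
    features: pd.DataFrame,
    categories: dict[str, str],
    order: Sequence[str] = DEFAULT_CATEGORY_ORDER,
    average_orders: bool = False,
) -> pd.DataFrame:
    """Split each gene's full-model R^2 across feature categories.

    Categories must partition the feature columns.  Attribution is
    incremental R^2: categories are added in the fixed ``order`` and each
    category's share is the increase in R^2 at its addition, so shares
    telescope exactly to the full-model R^2.  With ``average_orders`` the
    incremental shares are averaged over all category orderings
    (a Shapley-style attribution that removes the order dependence).
    """
    cats = {c: [f for f in features.columns if categories.get(f) == c] for c in order}
    assigned = [f for fs in cats.values() for f in fs]
    if sorted(assigned) != sorted(features.columns):
        missing = set(features.columns) - set(assigned)
        raise ValueError(
            f"categories must partition the features; unassigned or overlapping: {sorted(missing)}"
        )

    def incremental(order_seq):
        shares = {}
        prev_r2 = None
        used: list[str] = []
        for c in order_seq:
            used.extend(cats[c])
            r2 = fit_gene_mlr(counts, features[used]).r_squared
            shares[c] = r2 if prev_r2 is None else r2 - prev_r2
            prev_r2 = r2
        return pd.DataFrame(shares)

    if not average_orders:
        return incremental(order)

    from itertools import permutations

    frames = [incremental(p) for p in permutations(order)]
    out = frames[0].copy()
    for f in frames[1:]:
        out += f
    return out / len(frames)


# ---------------------------------------------------------------------------
# Permutation significance of calcium features
# ---------------------------------------------------------------------------

def calcium_feature_significance(
    volume_adjusted_counts,
    calcium_features: pd.DataFrame,
    n_resamples: int = 1600,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Permutation test for each (gene, calcium feature) slope.

    Volume-adjusted counts (counts conditioned on volume alone) are fitted
    with an OLS model on all calcium features; the observed slope of each
    feature is compared with a null distribution of slopes from
    ``n_resamples`` refits in which only that feature's column is permuted
    across cells.  Reported per (gene, feature): observed slope, null mean
    and SD, z-score, a two-sided empirical p-value on |slope| floored at
    1 / n_resamples, the Bonferroni-adjusted p over all gene x feature
    tests, and the significance flag at adjusted p < alpha.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples < 100 gives an unstable null SD")
    Y, gene_names = _as_matrix(volume_adjusted_counts)
    F, feat_names = _as_matrix(calcium_features)
    n, n_feat = F.shape
    X = np.column_stack([np.ones(n), F])
    obs_beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    obs_slopes = obs_beta[1:, :]  # (n_feat, genes)

    rng = np.random.default_rng(seed)
    null = np.empty((n_feat, n_resamples, Y.shape[1]))
    for f in range(n_feat):
        Xp = X.copy()
        for b in range(n_resamples):
            Xp[:, f + 1] = F[rng.permutation(n), f]
            beta, *_ = np.linalg.lstsq(Xp, Y, rcond=None)
            null[f, b, :] = beta[f + 1, :]

    null_mean = null.mean(axis=1)
    null_sd = null.std(axis=1, ddof=1)
    z = (obs_slopes - null_mean) / null_sd
    exceed = (np.abs(null) >= np.abs(obs_slopes)[:, None, :]).mean(axis=1)
    p = np.maximum(exceed, 1.0 / n_resamples)
    n_tests = p.size
    p_adj = np.minimum(1.0, p * n_tests)

    rows = []
    for f, fname in enumerate(feat_names):
        for g, gname in enumerate(gene_names):
            rows.append(
                {
                    "gene": gname,
                    "feature": fname,
                    "slope": obs_slopes[f, g],
                    "null_mean": null_mean[f, g],
                    "null_sd": null_sd[f, g],
                    "z": z[f, g],
                    "p_value": p[f, g],
                    "p_adjusted": p_adj[f, g],
                    "significant": p_adj[f, g] < alpha,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_resamples"] = n_resamples
    out.attrs["n_tests"] = n_tests
    return out


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class VarianceDecomposition:
    """Staged MLR variance-decomposition model for a counts matrix.

    Parameters
    ----------
    counts : DataFrame (cells x genes)
        Raw (untransformed) molecule counts.
    features : DataFrame (cells x features)
        Measured cell-state features.
    categories : dict, optional
        feature name -> category label (used by
        :meth:`category_explained_variance`).
    stage_plan : sequence of (name, feature-name tuple)
        Nested conditioning stages; defaults to raw -> volume -> volume +
        cell cycle -> all observed features.
    n_hidden : int
        Hidden features (leading PCs of the last stage's residuals) to
        append in a final stage.
    transform : callable, optional
        Applied to the counts before fitting (e.g. ``np.sqrt``); the
        default is the identity.

    Examples
    --------
    >>> model = VarianceDecomposition.from_dataset(dataset)   # doctest: +SKIP
    >>> results = model.fit()                                  # doctest: +SKIP
    >>> print(results.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        features: pd.DataFrame,
        categories: dict[str, str] | None = None,
        stage_plan=None,
        n_hidden: int = 2,
        shuffle_seed: int | None = 0,
        standardize_pca: bool = True,
        transform: Callable | None = None,
    ):
        self.counts = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
        self.features = features
        self.categories = categories
        if stage_plan is None:
            available = set(features.columns)
            stage_plan = [
                (name, tuple(f for f in feats if f in available))
                for name, feats in DEFAULT_STAGE_PLAN
            ]
        self.stage_plan = stage_plan
        self.n_hidden = n_hidden
        self.shuffle_seed = shuffle_seed
        self.standardize_pca = standardize_pca
        self.transform = transform

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "VarianceDecomposition":
        """Build from a :class:`~statefish.simulate.SyntheticDataset`."""
        return cls(
            counts=dataset.expression,
            features=dataset.features,
            categories=dataset.feature_categories,
            **kwargs,
        )

    def fit(self, compute_category_r2: bool = False) -> DecompositionResults:
        counts = self.counts
        if self.transform is not None:
            counts = counts.apply(self.transform)
        results = sequential_decomposition(
            counts,
            self.features,
            stage_plan=self.stage_plan,
            n_hidden=self.n_hidden,
            shuffle_seed=self.shuffle_seed,
            standardize_pca=self.standardize_pca,
        )
        if compute_category_r2 and self.categories is not None:
            results.category_r2 = category_explained_variance(
                counts, self.features, self.categories
            )
        results.model = self
        return results
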