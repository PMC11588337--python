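"""Single-trial stimulus-azimuth decoding.

The decoder is a naive Bayes classifier whose class-conditional densities
P(X_j | Y = k) are one-dimensional kernel density estimates fitted per
unit and per azimuth class; the posterior over the 13 azimuth classes is

    P(Y = k | X_1..X_p) ∝ pi(Y = k) * prod_j P(X_j | Y = k)

with priors pi taken as the class frequencies of the training set and the
class chosen by the maximum a posteriori rule. All data-dependent choices
(feature ranking, PCA loadings, bandwidths) are refit inside every
leave-one-out fold so that nothing leaks from the held-out trial.

Decoding quality is judged against a paradigm-specific chance model: the
error distribution obtained by enumerating all 169 (true, predicted)
azimuth pairs of the 13-point grid with equal weight. Observed error
distributions are compared to it with two-sided two-sample
Kolmogorov-Smirnov tests, Sidak-corrected over the number of model sizes
examined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import (
    AnalysisConfig,
    AzimuthGrid,
    ErrorDistribution,
    KERNELS,
    ResponseDataset,
)
from .unit_stats import chi2_dependency, rank_units, _chi2_one_unit

__all__ = [
    "DecoderModel",
    "ChanceModel",
    "PerformanceCurve",
    "LooResult",
    "FoldRecord",
    "ChanceComparison",
    "fit_bayes",
    "predict_bayes",
    "tune_bayes",
    "fit_pca",
    "PcaModel",
    "loo_decode",
    "knn_decode",
    "chance_error_distribution",
    "compare_to_chance",
    "sidak",
    "performance_curve",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kernels and bandwidths


def _kernel_density(u: np.ndarray, kernel: str) -> np.ndarray:
    """Density of the scaled kernel at standardized distances ``u``."""
    if kernel == "gaussian":
        return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)
    a = np.abs(u)
    if kernel == "epanechnikov":
        return np.where(a < 1.0, 0.75 * (1.0 - u * u), 0.0)
    if kernel == "uniform":
        return np.where(a < 1.0, 0.5, 0.0)
    if kernel == "triangular":
        return np.where(a < 1.0, 1.0 - a, 0.0)
    raise ValueError(f"unknown kernel {kernel!r}")


def _silverman_bandwidths(vk: np.ndarray) -> np.ndarray:
    """Per-unit rule-of-thumb bandwidths 0.9 * min(sd, iqr/1.34) * n^(-1/5)
    for one class's (n_k, p) training block.

    Falls back to the sample SD when the IQR collapses (heavily tied
    data), and to a small positive constant when the values are constant
    (the density then degenerates to a narrow bump at that value).
    """
    n = vk.shape[0]
    sd = vk.std(axis=0, ddof=1) if n > 1 else np.zeros(vk.shape[1])
    q75, q25 = np.percentile(vk, [75, 25], axis=0)
    iqr = q75 - q25
    scale = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
    h = 0.9 * scale * n ** (-0.2)
    fallback = 1e-6 + 1e-3 * np.abs(vk[0])
    return np.where(scale > 0, h, fallback)


def _bandwidth_matrix(
    class_values: list[np.ndarray], bandwidth: str | float
) -> np.ndarray:
    """Per-(class, unit) bandwidths. ``bandwidth`` is 'silverman' or a
    float multiplier of each unit's pooled training SD."""
    n_classes = len(class_values)
    p = class_values[0].shape[1]
    h = np.empty((n_classes, p))
    if bandwidth == "silverman":
        for k, vk in enumerate(class_values):
            h[k] = _silverman_bandwidths(vk)
    else:
        pooled = np.concatenate(class_values, axis=0)
        sd = pooled.std(axis=0, ddof=1)
        sd[sd <= 0] = 1e-6
        h[:] = float(bandwidth) * sd
    return h


# ---------------------------------------------------------------------------
# naive Bayes decoder


@dataclass
class DecoderModel:
    """Kernel-density naive Bayes model for azimuth classification."""

    classes: np.ndarray  # (K,) stimulus labels
    priors: np.ndarray  # (K,) class frequencies, sum to 1
    class_values: list  # K arrays (n_k, p) of training responses
    bandwidths: np.ndarray  # (K, p)
    kernel: str = "gaussian"
    density_floor: float = 1e-300
    grid: AzimuthGrid = field(default_factory=AzimuthGrid)

    @property
    def n_units(self) -> int:
        return self.class_values[0].shape[1]

    def log_class_conditionals(self, x: np.ndarray) -> np.ndarray:
        """(K, p) matrix of log max(P(x_j | Y = k), floor)."""
        x = np.asarray(x, dtype=float)
        out = np.empty((self.classes.size, x.size))
        for k, vk in enumerate(self.class_values):
            u = (x[None, :] - vk) / self.bandwidths[k][None, :]
            dens = _kernel_density(u, self.kernel).mean(axis=0) / self.bandwidths[k]
            out[k] = np.log(np.maximum(dens, self.density_floor))
        return out


def _fit_bayes_arrays(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str,
    bandwidth: str | float,
    grid: AzimuthGrid,
    density_floor: float = 1e-300,
) -> DecoderModel:
    classes = np.unique(y)
    class_values = []
    priors = np.empty(classes.size)
    for k, c in enumerate(classes):
        vk = X[y == c]
        if vk.shape[0] == 0:
            raise ValueError(f"class {c} has no training trials")
        class_values.append(vk)
        priors[k] = vk.shape[0] / X.shape[0]
    h = _bandwidth_matrix(class_values, bandwidth)
    return DecoderModel(
        classes=classes,
        priors=priors,
        class_values=class_values,
        bandwidths=h,
        kernel=kernel,
        density_floor=density_floor,
        grid=grid,
    )


def fit_bayes(
    train: ResponseDataset,
    kernel: str = "gaussian",
    bandwidth: str | float = "silverman",
) -> DecoderModel:
    """Fit the kernel-density naive Bayes decoder on a training dataset.

    One KDE per (unit, class) over that class's training responses;
    priors are the relative class frequencies of the training set.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    if not isinstance(bandwidth, str) and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return _fit_bayes_arrays(
        train.responses, train.labels, kernel, bandwidth, train.grid
    )


def _map_choice(classes: np.ndarray, scores: np.ndarray, grid: AzimuthGrid) -> float:
    """Argmax with deterministic tie-breaking: smallest |azimuth| first,
    then the more contralateral angle."""
    best = scores.max()
    tied = classes[scores >= best - 1e-12]
    if tied.size == 1:
        return float(tied[0])
    key = sorted(tied, key=lambda a: (abs(a), -grid.contralateral_sign * a))
    return float(key[0])


def predict_bayes(model: DecoderModel, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior over azimuth classes and the MAP azimuth for one trial.

    Scores are accumulated in log space; if every class-conditional
    product bottoms out at the density floor the posterior falls back to
    the priors alone (with a logged warning).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_units,):
        raise ValueError(
            f"response vector has {x.size} entries, model expects {model.n_units}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("response vector must be finite")
    log_cond = model.log_class_conditionals(x)
    floor_log = np.log(model.density_floor)
    if np.all(log_cond <= floor_log):
        logger.warning(
            "all class-conditional densities at the floor; posterior reduces "
            "to the priors"
        )
    scores = np.log(model.priors) + log_cond.sum(axis=1)
    scores -= scores.max()
    posterior = np.exp(scores)
    posterior /= posterior.sum()
    return posterior, _map_choice(model.classes, scores, model.grid)


def tune_bayes(
    train: ResponseDataset,
    kernels: tuple[str, ...] = KERNELS,
    bandwidths: np.ndarray | None = None,
    folds: int = 3,
    seed: int = 0,
) -> tuple[str, float]:
    """Select (kernel, bandwidth multiplier) by exhaustive grid search
    with stratified inner cross-validation, minimizing mean absolute
    decoding error. Ties prefer the smaller bandwidth, then the kernel
    order uniform, epanechnikov, gaussian, triangular.
    """
    if bandwidths is None:
        bandwidths = np.geomspace(0.05, 2.0, 10)
    bandwidths = np.asarray(bandwidths, dtype=float)
    if bandwidths.size == 0 or not kernels:
        raise ValueError("hyperparameter grid must be non-empty")
    classes, counts = np.unique(train.labels, return_counts=True)
    if folds < 2 or folds > counts.min():
        raise ValueError("folds must be >= 2 and <= the smallest class count")

    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(train.responses, train.labels))

    best: tuple[float, float, int] | None = None  # (error, bandwidth, kernel rank)
    best_pair: tuple[str, float] | None = None
    for kernel in kernels:
        rank = KERNELS.index(kernel)
        for bw in bandwidths:
            errors = []
            skip = False
            for tr_idx, te_idx in splits:
                y_tr = train.labels[tr_idx]
                if np.unique(y_tr).size < classes.size:
                    warnings.warn(
                        f"candidate ({kernel}, {bw:.3g}) skipped: class absent "
                        "from an inner training fold"
                    )
                    skip = True
                    break
                model = _fit_bayes_arrays(
                    train.responses[tr_idx], y_tr, kernel, float(bw), train.grid
                )
                for t in te_idx:
                    _, pred = predict_bayes(model, train.responses[t])
                    errors.append(abs(train.labels[t] - pred))
            if skip:
                continue
            key = (float(np.mean(errors)), float(bw), rank)
            if best is None or key < best:
                best = key
                best_pair = (kernel, float(bw))
    if best_pair is None:
        raise ValueError("no feasible hyperparameter candidate")
    return best_pair


# ---------------------------------------------------------------------------
# PCA feature reduction


@dataclass
class PcaModel:
    """Column-centered PCA with deterministic component signs."""

    mean: np.ndarray  # (p,)
    loadings: np.ndarray  # (p, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        L = self.loadings if k is None else self.loadings[:, :k]
        return (np.atleast_2d(X) - self.mean) @ L


def fit_pca(train: np.ndarray) -> PcaModel:
    """PCA of a trial x unit matrix via SVD of the centered data.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive; explained-variance fractions sum to 1.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 trials")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = (Xc**2).sum()
    if total_var <= 0:
        raise ValueError("PCA input has zero variance")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt.T
    # deterministic sign: largest-|loading| entry of each component positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])] < 0
    loadings[:, flip] *= -1.0
    evr = s**2 / (s**2).sum()
    return PcaModel(mean=mean, loadings=loadings, explained_variance_ratio=evr)


# ---------------------------------------------------------------------------
# KNN alternative


def knn_decode(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    k: int,
    grid: AzimuthGrid | None = None,
) -> float:
    """Majority label among the k Euclidean nearest training trials.

    Ties in the vote go to the class with the smallest mean distance
    among its voting neighbours, then to the MAP tie-break rule
    (smallest |azimuth|, then most contralateral).
    """
    grid = grid or AzimuthGrid()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train_X.shape[0]:
        raise ValueError("k exceeds the number of training trials")
    d = np.linalg.norm(train_X - np.asarray(test_x, dtype=float)[None, :], axis=1)
    nn = np.argsort(d, kind="stable")[:k]
    votes, counts = np.unique(train_y[nn], return_counts=True)
    top = votes[counts == counts.max()]
    if top.size > 1:
        mean_d = np.array([d[nn][train_y[nn] == c].mean() for c in top])
        top = top[mean_d <= mean_d.min() + 1e-12]
    scores = np.zeros(top.size)
    return _map_choice(top, scores, grid)


# ---------------------------------------------------------------------------
# chance model and KS comparisons


@dataclass
class ChanceModel:
    """Error distribution of the stimulation paradigm itself: all 169
    (true, predicted) azimuth pairs enumerated with equal weight."""

    grid: AzimuthGrid
    pairs: np.ndarray  # (K*K, 2)
    errors: np.ndarray  # (K*K,)

    @property
    def median(self) -> float:
        return float(np.median(self.errors))

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))

    def p_error(self, e: float) -> float:
        return float(np.mean(np.abs(self.errors - e) < 1e-9))

    def cdf(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_1d(values)
        return np.array([np.mean(self.errors <= v + 1e-9) for v in values])


def chance_error_distribution(grid: AzimuthGrid | None = None) -> ChanceModel:
    grid = grid or AzimuthGrid()
    a = np.asarray(grid.angles)
    true_, pred = np.meshgrid(a, a, indexing="ij")
    pairs = np.column_stack([true_.ravel(), pred.ravel()])
    return ChanceModel(grid=grid, pairs=pairs, errors=np.abs(pairs[:, 0] - pairs[:, 1]))


def sidak(p: float, m: int) -> float:
    """Sidak-adjusted p-value for m comparisons: 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if p >= 1.0:
        return 1.0
    return float(-np.expm1(m * np.log1p(-p)))


@dataclass
class ChanceComparison:
    ks_statistic: float
    pvalue: float
    pvalue_adjusted: float
    direction: str  # 'better' | 'worse' | 'none'
    observed_median: float
    reference_median: float


def compare_to_chance(
    observed: ErrorDistribution | np.ndarray,
    chance: ChanceModel,
    m_comparisons: int = 1,
) -> ChanceComparison:
    """Two-sided two-sample KS test of observed errors against the chance
    multiset, Sidak-corrected for ``m_comparisons``. Direction is
    'better' when the observed errors shift toward smaller values."""
    errors = observed.errors if isinstance(observed, ErrorDistribution) else observed
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("observed error distribution is empty")
    res = stats.ks_2samp(errors, chance.errors, alternative="two-sided")
    obs_med = float(np.median(errors))
    diff = chance.median - obs_med
    direction = "better" if diff > 0 else ("worse" if diff < 0 else "none")
    return ChanceComparison(
        ks_statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        pvalue_adjusted=sidak(float(res.pvalue), m_comparisons),
        direction=direction,
        observed_median=obs_med,
        reference_median=chance.median,
    )


# ---------------------------------------------------------------------------
# leave-one-out decoding


@dataclass
class FoldRecord:
    """Provenance of one leave-one-out fold: everything that was derived
    from the training fold, stored for leakage auditing."""

    test_index: int
    selected_units: np.ndarray | None = None
    ranking_pvalues: np.ndarray | None = None
    ranking_statistics: np.ndarray | None = None
    pca_mean: np.ndarray | None = None
    pca_loadings: np.ndarray | None = None
    bandwidths: np.ndarray | None = None
    kernel: str | None = None


@dataclass
class LooResult:
    errors: ErrorDistribution
    predictions: np.ndarray
    true_labels: np.ndarray
    folds: list
    selector: str
    classifier: str


def _parse_selector(selector: str) -> tuple[str, int | None]:
    if selector == "none":
        return "none", None
    for prefix in ("pca", "top_ranked"):
        if selector.startswith(prefix + ":"):
            size = int(selector.split(":", 1)[1])
            if size < 1:
                raise ValueError(f"selector size must be >= 1: {selector!r}")
            return prefix, size
    raise ValueError(
        f"selector {selector!r} must be 'none', 'pca:k' or 'top_ranked:m'"
    )


def _rank_training_fold(
    X: np.ndarray, y: np.ndarray, classes: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square dependency p-values and statistics on a training fold."""
    class_idx = np.searchsorted(classes, y)
    p = np.empty(X.shape[1])
    s = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        p[j], s[j], _, _, _ = _chi2_one_unit(X[:, j], class_idx, classes.size, n_bins)
    return p, s


def loo_decode(
    dataset: ResponseDataset,
    selector: str = "none",
    classifier: str = "bayes",
    config: AnalysisConfig | None = None,
    store_provenance: bool = True,
) -> LooResult:
    """Leave-one-out cross-validated decoding of single-trial responses.

    For every held-out trial the whole data-dependent chain — chi-square
    unit ranking (``top_ranked:m``), PCA loadings (``pca:k``), kernel
    bandwidths — is recomputed from the remaining trials only, the
    classifier is fitted on them and the held-out trial is decoded.
    """
    config = config or AnalysisConfig()
    if classifier not in ("bayes", "knn"):
        raise ValueError("classifier must be 'bayes' or 'knn'")
    kind, size = _parse_selector(selector)
    n = dataset.n_trials
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ValueError(
            f"class {bad} has fewer than 2 trials; a training fold would "
            "lose it entirely"
        )
    if kind == "top_ranked" and size > dataset.n_units:
        raise ValueError(
            f"selector top_ranked:{size} needs {size} units, dataset has "
            f"{dataset.n_units}"
        )
    if kind == "pca" and size > min(n - 1, dataset.n_units):
        raise ValueError(f"selector pca:{size} infeasible for this dataset")

    X = dataset.responses
    y = dataset.labels
    predictions = np.empty(n)
    folds: list[FoldRecord] = []
    for t in range(n):
        mask = np.ones(n, dtype=bool)
        mask[t] = False
        X_tr, y_tr = X[mask], y[mask]
        x_te = X[t]
        record = FoldRecord(test_index=t)

        if kind == "top_ranked":
            p, s = _rank_training_fold(X_tr, y_tr, classes, config.chi2_bins)
            sel = rank_units(p, s, alpha=config.alpha).top(size)
            X_tr_f, x_te_f = X_tr[:, sel], x_te[sel]
            if store_provenance:
                record.selected_units = sel
                record.ranking_pvalues = p
                record.ranking_statistics = s
        elif kind == "pca":
            pca = fit_pca(X_tr)
            X_tr_f = pca.transform(X_tr, size)
            x_te_f = pca.transform(x_te, size)[0]
            if store_provenance:
                record.pca_mean = pca.mean
                record.pca_loadings = pca.loadings[:, :size]
        else:
            X_tr_f, x_te_f = X_tr, x_te

        if classifier == "bayes":
            model = _fit_bayes_arrays(
                X_tr_f,
                y_tr,
                config.kernel,
                config.bandwidth,
                dataset.grid,
                config.density_floor,
            )
            _, pred = predict_bayes(model, x_te_f)
            if store_provenance:
                record.bandwidths = model.bandwidths
                record.kernel = model.kernel
        else:
            k = min(config.knn_k, X_tr_f.shape[0])
            pred = knn_decode(X_tr_f, y_tr, x_te_f, k, dataset.grid)
        predictions[t] = pred
        folds.append(record)

    errors = np.abs(y - predictions)
    return LooResult(
        errors=ErrorDistribution(errors, provenance="observed", grid=dataset.grid),
        predictions=predictions,
        true_labels=y.copy(),
        folds=folds,
        selector=selector,
        classifier=classifier,
    )


# ---------------------------------------------------------------------------
# performance across model sizes


@dataclass
class PerformanceCurve:
    sizes: np.ndarray
    error_distributions: list
    medians: np.ndarray
    pvalues: np.ndarray
    pvalues_adjusted: np.ndarray
    alpha: float
    smallest_significant: int | None
    overfitting: bool

    def significant(self) -> np.ndarray:
        return self.pvalues_adjusted < self.alpha


def performance_curve(
    dataset: ResponseDataset,
    selector_family: str,
    sizes,
    classifier: str = "bayes",
    config: AnalysisConfig | None = None,
) -> PerformanceCurve:
    """Decoding performance as a function of model size (number of first
    PCs or of top-ranked units), with Sidak correction over the sizes
    tested. Flags the smallest size beating chance and whether
    significance is lost again at the largest size (overfitting).
    """
    if selector_family not in ("pca", "top_ranked"):
        raise ValueError("selector_family must be 'pca' or 'top_ranked'")
    config = config or AnalysisConfig()
    sizes = np.asarray(sorted(int(s) for s in sizes), dtype=int)
    if sizes.size == 0 or np.unique(sizes).size != sizes.size:
        raise ValueError("sizes must be a non-empty strictly increasing list")
    chance = chance_error_distribution(dataset.grid)
    m = int(sizes.size)
    dists, medians, pvals, padj = [], [], [], []
    for s in sizes:
        res = loo_decode(
            dataset,
            selector=f"{selector_family}:{s}",
            classifier=classifier,
            config=config,
            store_provenance=False,
        )
        cmp_ = compare_to_chance(res.errors, chance, m_comparisons=m)
        dists.append(res.errors)
        medians.append(res.errors.median)
        pvals.append(cmp_.pvalue)
        padj.append(cmp_.pvalue_adjusted)
    medians = np.asarray(medians)
    pvals = np.asarray(pvals)
    padj = np.asarray(padj)
    sig = padj < config.alpha
    smallest = int(sizes[sig.argmax()]) if sig.any() else None
    overfit = bool(sig.any() and not sig[-1])
    return PerformanceCurve(
        sizes=sizes,
        error_distributions=dists,
        medians=medians,
        pvalues=pvals,
        pvalues_adjusted=padj,
        alpha=config.alpha,
        smallest_significant=smallest,
        overfitting=overfit,
    )
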