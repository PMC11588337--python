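"""Per-unit response statistics.

Covers the unit-level characterization stages: neuronal signal-to-noise
(inverse coefficient of variation at the best stimulus), Kruskal-Wallis
azimuth tuning, chi-square response-dependency ranking used for
top-ranked-unit selection, frequency dependence for pure-tone blocks, and
the best-frequency versus azimuth-significance correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ResponseDataset

__all__ = [
    "SnrTable",
    "TuningResult",
    "Chi2Result",
    "UnitRanking",
    "FrequencyResult",
    "neuronal_snr",
    "kruskal_wallis_tuning",
    "chi2_dependency",
    "rank_units",
    "frequency_dependence",
    "bf_azimuth_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class SnrTable:
    """Per-unit neuronal S/N (mean / sample SD at the best stimulus)."""

    snr: np.ndarray
    best_azimuth: np.ndarray
    undefined: np.ndarray  # mean <= 0 after baseline subtraction
    infinite: np.ndarray  # zero SD across best-stimulus trials
    condition: str = "stimulus"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snr": self.snr,
                "best_azimuth": self.best_azimuth,
                "undefined": self.undefined,
                "infinite": self.infinite,
            }
        )

    @property
    def defined(self) -> np.ndarray:
        """nS/N values usable in histograms (finite and defined)."""
        return self.snr[~self.undefined & ~self.infinite]


@dataclass
class TuningResult:
    """Kruskal-Wallis test of median response tuning, per unit."""

    pvalues: np.ndarray
    statistics: np.ndarray
    tuned: np.ndarray
    alpha: float

    @property
    def fraction_tuned(self) -> float:
        return float(np.mean(self.tuned))


@dataclass
class Chi2Result:
    """Chi-square response-dependency test, per unit."""

    pvalues: np.ndarray
    statistics: np.ndarray
    dof: np.ndarray
    non_informative: np.ndarray  # single occupied response bin
    n_bins: int


@dataclass
class UnitRanking:
    """Units ordered by ascending dependency p-value."""

    pvalues: np.ndarray
    statistics: np.ndarray
    order: np.ndarray
    significant: np.ndarray
    alpha: float

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.significant))

    def top(self, m: int) -> np.ndarray:
        if m > self.order.size:
            raise ValueError(
                f"requested {m} top-ranked units but only {self.order.size} exist"
            )
        return self.order[:m]


@dataclass
class FrequencyResult:
    """Chi-square frequency dependence and best frequency, per unit."""

    pvalues: np.ndarray
    statistics: np.ndarray
    best_frequency: np.ndarray  # kHz
    non_informative: np.ndarray


def neuronal_snr(
    dataset: ResponseDataset,
    baseline: np.ndarray | None = None,
    condition: str = "stimulus",
) -> SnrTable:
    """Neuronal signal-to-noise per unit.

    The best stimulus is the label whose trials evoke the largest mean
    response; nS/N is the mean over those trials divided by their sample
    standard deviation (ddof=1), i.e. the inverse coefficient of
    variation. When ``baseline`` (same shape as the responses) is given it
    is subtracted trial-by-trial first. Zero SD flags the unit as
    infinite; a non-positive mean flags it undefined.
    """
    if baseline is None:
        baseline = dataset.baseline
    values = dataset.responses
    if baseline is not None:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != values.shape:
            raise ValueError("baseline must align with the response matrix")
        values = values - baseline

    classes = dataset.classes
    masks = [dataset.labels == c for c in classes]
    # sort within each class so the result is invariant to trial order
    # (within-class permutations must not perturb the statistics)
    class_means = np.stack(
        [np.sort(values[m], axis=0).mean(axis=0) for m in masks]
    )  # (K, p)
    best_idx = np.argmax(class_means, axis=0)

    n_units = dataset.n_units
    snr = np.full(n_units, np.nan)
    undefined = np.zeros(n_units, dtype=bool)
    infinite = np.zeros(n_units, dtype=bool)
    for j in range(n_units):
        v = np.sort(values[masks[best_idx[j]], j])
        if v.size < 2:
            raise ValueError("need >= 2 trials at the best stimulus")
        mean = v.mean()
        sd = v.std(ddof=1)
        if mean <= 0:
            undefined[j] = True
        elif sd == 0:
            infinite[j] = True
            snr[j] = np.inf
        else:
            snr[j] = mean / sd
    return SnrTable(
        snr=snr,
        best_azimuth=classes[best_idx],
        undefined=undefined,
        infinite=infinite,
        condition=condition,
    )


def kruskal_wallis_tuning(dataset: ResponseDataset, alpha: float = 0.05) -> TuningResult:
    """Kruskal-Wallis test of response medians across stimulus classes.

    The H statistic is tie-corrected and referred to its chi-square
    approximation with (n_classes - 1) degrees of freedom. Responses tied
    across every trial yield H = 0, p = 1.
    """
    classes = dataset.classes
    masks = [dataset.labels == c for c in classes]
    for c, m in zip(classes, masks):
        if m.sum() < 2:
            raise ValueError(f"stimulus {c} has fewer than 2 trials")
    n_units = dataset.n_units
    pvalues = np.ones(n_units)
    statistics = np.zeros(n_units)
    for j in range(n_units):
        groups = [dataset.responses[m, j] for m in masks]
        try:
            h, p = stats.kruskal(*groups)
        except ValueError:
            # all responses identical: no evidence of tuning
            h, p = 0.0, 1.0
        statistics[j], pvalues[j] = h, p
    return TuningResult(
        pvalues=pvalues,
        statistics=statistics,
        tuned=pvalues < alpha,
        alpha=alpha,
    )


def _chi2_one_unit(
    values: np.ndarray, class_idx: np.ndarray, n_classes: int, n_bins: int
) -> tuple[float, float, int, bool, bool]:
    """(p, stat, dof, non_informative, sparse) for one unit.

    Responses are discretized into ``n_bins`` equal-width bins over their
    observed range; empty bins are dropped before computing the
    independence statistic on the bins x classes contingency table.
    """
    lo, hi = values.min(), values.max()
    if lo == hi:
        return 1.0, 0.0, 0, True, False
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    table = np.zeros((n_bins, n_classes))
    np.add.at(table, (bins, class_idx), 1.0)
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        return 1.0, 0.0, 0, True, False
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (n_classes - 1)
    p = float(stats.chi2.sf(stat, dof))
    sparse = bool(np.mean(expected < 5) > 0.2)
    return p, stat, dof, False, sparse


def chi2_dependency(dataset: ResponseDataset, n_bins: int = 10) -> Chi2Result:
    """Chi-square test of statistical dependence between each unit's
    single-trial responses and the stimulus class.

    More sensitive than the median-based Kruskal-Wallis test on
    zero-inflated responses, because any change in the response
    distribution across classes (not just a median shift) contributes.
    Asymptotic p-values are used even with sparse cells; a warning is
    logged when more than 20% of expected counts fall below 5.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    classes = dataset.classes
    class_idx = np.searchsorted(classes, dataset.labels)
    n_units = dataset.n_units
    pvalues = np.ones(n_units)
    statistics = np.zeros(n_units)
    dof = np.zeros(n_units, dtype=int)
    flagged = np.zeros(n_units, dtype=bool)
    n_sparse = 0
    for j in range(n_units):
        p, s, d, flag, sparse = _chi2_one_unit(
            dataset.responses[:, j], class_idx, classes.size, n_bins
        )
        pvalues[j], statistics[j], dof[j], flagged[j] = p, s, d, flag
        n_sparse += sparse
    if n_sparse:
        logger.warning(
            "chi2_dependency: %d/%d units had >20%% expected counts < 5; "
            "asymptotic p-values may be approximate",
            n_sparse,
            n_units,
        )
    return Chi2Result(
        pvalues=pvalues,
        statistics=statistics,
        dof=dof,
        non_informative=flagged,
        n_bins=n_bins,
    )


def rank_units(
    pvals: np.ndarray, statistics: np.ndarray, alpha: float = 0.05
) -> UnitRanking:
    """Order units by descending significance.

    Ascending p-value; ties broken by descending test statistic, then by
    ascending unit index, so the ordering is deterministic.
    """
    pvals = np.asarray(pvals, dtype=float)
    statistics = np.asarray(statistics, dtype=float)
    if pvals.shape != statistics.shape or pvals.ndim != 1:
        raise ValueError("p-values and statistics must be aligned 1-D vectors")
    order = np.lexsort((np.arange(pvals.size), -statistics, pvals))
    return UnitRanking(
        pvalues=pvals,
        statistics=statistics,
        order=order,
        significant=pvals < alpha,
        alpha=alpha,
    )


def frequency_dependence(
    tone_dataset: ResponseDataset, n_bins: int = 10
) -> FrequencyResult:
    """Chi-square frequency dependence and best frequency per unit.

    Best frequency is the pure-tone label evoking the largest mean
    response (argmax of the empirical tuning curve).
    """
    if tone_dataset.block != "frequency":
        raise ValueError("frequency_dependence expects a frequency-block dataset")
    res = chi2_dependency(tone_dataset, n_bins=n_bins)
    classes = tone_dataset.classes
    means = np.stack(
        [tone_dataset.responses_for(c).mean(axis=0) for c in classes]
    )  # (K, p)
    best = classes[np.argmax(means, axis=0)]
    return FrequencyResult(
        pvalues=res.pvalues,
        statistics=res.statistics,
        best_frequency=best,
        non_informative=res.non_informative,
    )


def bf_azimuth_correlation(
    best_freq: np.ndarray, azimuth_logp: np.ndarray
) -> float:
    """Pearson correlation between log best frequency and azimuth
    dependence significance (-log p of the chi-square test) across units
    that depend on both stimulus dimensions.

    Returns NaN when either vector has zero variance (flagged undefined).
    """
    bf = np.asarray(best_freq, dtype=float)
    lp = np.asarray(azimuth_logp, dtype=float)
    if bf.shape != lp.shape or bf.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    if bf.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(bf)) and np.all(np.isfinite(lp))):
        raise ValueError("inputs must be finite")
    if np.any(bf <= 0):
        raise ValueError("best frequencies must be positive (kHz)")
    if np.all(bf == bf[0]) or np.all(lp == lp[0]):
        return float("nan")
    x = np.log10(bf)
    return float(np.corrcoef(x, lp)[0, 1])
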