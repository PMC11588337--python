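"""Synthetic correlated population responses.

Generates :class:`~popazi.data_model.ResponseDataset` objects with the
statistical structure the analysis stages assume: a minority of
stimulus-dependent units with contralateral or central selectivity, low
neuronal signal-to-noise with frequent zero-response trials, and positive
pairwise noise correlations imposed through a Gaussian copula.

The copula construction draws a latent multivariate normal vector per
trial with correlation matrix ``R``, maps each coordinate through the
standard-normal CDF to a uniform variate, and inverts the per-unit
marginal CDF (gamma for imaging-like continuous responses, negative
binomial for ephys-like counts). Because the transform is monotone, the
latent correlation ``r`` fixes the Kendall tau of continuous marginals
exactly at ``(2/pi) * arcsin(r)``; response failures (a Bernoulli mask)
attenuate it toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .data_model import AzimuthGrid, ResponseDataset, DEFAULT_GRID

__all__ = [
    "PopulationSpec",
    "make_tuning_curves",
    "sample_dataset",
    "spec_presets",
    "dependent_units",
    "correlation_scenario",
    "DEFAULT_TONE_FREQS_KHZ",
]

#: pure-tone stimulus grid: 4-48 kHz, 3.5 octaves in quarter-octave steps
DEFAULT_TONE_FREQS_KHZ = tuple(float(f) for f in 4.0 * 2.0 ** (np.arange(14) / 4.0))


@dataclass
class PopulationSpec:
    """Parameters of one simulated recording session.

    fraction_dependent : proportion of stimulus-dependent units (defaults
        mirror the typical dependent fractions of imaging-like sessions).
    tuning_family : response profile of the dependent units; ``"mixed"``
        assigns each dependent unit a sigmoid-contralateral or a
        gaussian-on-azimuth profile with equal probability.
    dispersion : gamma shape (imaging) or negative-binomial size (ephys);
        smaller values mean noisier, more overdispersed responses.
    p_fail : probability that a (trial, unit) response fails outright and
        is recorded as zero.
    latent_corr : ``None`` (independent units), a float (constant
        off-diagonal latent correlation) or a full unit x unit matrix.
    """

    n_units: int = 21
    fraction_dependent: float = 0.32
    reps_per_azimuth: int = 14
    tuning_family: str = "mixed"  # sigmoid | gaussian | flat | mixed
    peak_rate: tuple[float, float] = (1.0, 0.5)  # lognormal (log-mean, log-sd)
    baseline_rate: float = 0.08
    tuning_width: tuple[float, float] = (30.0, 10.0)  # degrees, gaussian family
    noise_family: str = "gamma"  # gamma (imaging) | nbinom (ephys)
    dispersion: float = 1.5
    p_fail: float = 0.3
    latent_corr: float | np.ndarray | None = None
    correlated_failures: bool = False
    block: str = "azimuth"
    stimuli: tuple[float, ...] | None = None
    grid: AzimuthGrid = field(default_factory=AzimuthGrid)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 <= self.fraction_dependent <= 1.0:
            raise ValueError("fraction_dependent must lie in [0, 1]")
        if self.reps_per_azimuth < 2:
            raise ValueError("reps_per_azimuth must be >= 2")
        if not 0.0 <= self.p_fail <= 1.0:
            raise ValueError("p_fail must lie in [0, 1]")
        if self.tuning_family not in ("sigmoid", "gaussian", "flat", "mixed"):
            raise ValueError("unknown tuning family")
        if self.noise_family not in ("gamma", "nbinom"):
            raise ValueError("noise family must be 'gamma' or 'nbinom'")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.block not in ("azimuth", "frequency"):
            raise ValueError("block must be 'azimuth' or 'frequency'")
        if self.stimuli is None:
            self.stimuli = (
                tuple(self.grid.angles)
                if self.block == "azimuth"
                else DEFAULT_TONE_FREQS_KHZ
            )

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def n_dependent(self) -> int:
        return int(round(self.fraction_dependent * self.n_units))

    @property
    def modality(self) -> str:
        return "imaging" if self.noise_family == "gamma" else "ephys"

    def correlation_matrix(self) -> np.ndarray:
        """Materialize and validate the latent correlation matrix."""
        p = self.n_units
        if self.latent_corr is None:
            return np.eye(p)
        if np.isscalar(self.latent_corr):
            r = float(self.latent_corr)
            R = np.full((p, p), r)
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(self.latent_corr, dtype=float)
        if R.shape != (p, p):
            raise ValueError(f"latent correlation matrix must be {p} x {p}")
        if not np.allclose(R, R.T):
            raise ValueError("latent correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("latent correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(R)
        if w[0] < -1e-10:
            raise ValueError(
                f"latent correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w[0]:.3e})"
            )
        return R


def dependent_units(spec: PopulationSpec) -> np.ndarray:
    """Indices of the planted stimulus-dependent units (the leading block)."""
    return np.arange(spec.n_dependent)


def make_tuning_curves(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw per-unit mean-response curves, one row per unit.

    Dependent units (the first ``spec.n_dependent`` rows) get non-constant
    curves of the requested family; the remainder are flat. All means are
    non-negative. Sigmoid units saturate toward the contralateral side;
    gaussian units peak at central-to-contralateral azimuths, echoing the
    contralateral/central selectivity typical of midbrain populations.
    """
    rng = rng or np.random.default_rng(spec.seed)
    stimuli = np.asarray(spec.stimuli, dtype=float)
    x = np.log2(stimuli) if spec.block == "frequency" else stimuli
    curves = np.empty((spec.n_units, stimuli.size))
    log_mu, log_sd = spec.peak_rate
    peaks = rng.lognormal(mean=np.log(log_mu), sigma=log_sd, size=spec.n_units)
    n_dep = spec.n_dependent
    contra = spec.grid.contralateral_sign
    for j in range(spec.n_units):
        if j >= n_dep or spec.tuning_family == "flat":
            curves[j] = spec.baseline_rate + 0.5 * peaks[j]
            continue
        family = spec.tuning_family
        if family == "mixed":
            family = "sigmoid" if rng.random() < 0.5 else "gaussian"
        if spec.block == "frequency" or family == "gaussian":
            if spec.block == "frequency":
                center = rng.uniform(x.min(), x.max())
                width = rng.uniform(0.5, 1.5)  # octaves
            else:
                # peak at central-to-contralateral azimuths
                center = contra * rng.uniform(-15.0, 90.0)
                width = max(5.0, rng.normal(*spec.tuning_width))
            curves[j] = spec.baseline_rate + peaks[j] * np.exp(
                -0.5 * ((x - center) / width) ** 2
            )
        else:  # sigmoid saturating toward the contralateral side
            midpoint = rng.uniform(-30.0, 30.0)
            slope = rng.uniform(10.0, 25.0)
            curves[j] = spec.baseline_rate + peaks[j] / (
                1.0 + np.exp(-contra * (x - midpoint) / slope)
            )
    return curves


def sample_dataset(
    spec: PopulationSpec,
    tuning: np.ndarray | None = None,
    seed: int | None = None,
) -> ResponseDataset:
    """Sample one balanced session: ``reps_per_azimuth`` trials per
    stimulus in seed-randomized order, with copula-imposed correlations
    and independent response failures.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if tuning is None:
        tuning = make_tuning_curves(spec, rng)
    tuning = np.asarray(tuning, dtype=float)
    if tuning.shape != (spec.n_units, spec.n_stimuli):
        raise ValueError(
            f"tuning must have shape {(spec.n_units, spec.n_stimuli)}, "
            f"got {tuning.shape}"
        )
    if np.any(tuning < 0):
        raise ValueError("tuning means must be non-negative")
    R = spec.correlation_matrix()

    stimuli = np.asarray(spec.stimuli, dtype=float)
    class_idx = np.repeat(np.arange(spec.n_stimuli), spec.reps_per_azimuth)
    rng.shuffle(class_idx)
    labels = stimuli[class_idx]
    n_trials = labels.size

    # latent MVN -> uniform via the normal CDF (Gaussian copula)
    if spec.latent_corr is None:
        z = rng.standard_normal((n_trials, spec.n_units))
    else:
        w, V = np.linalg.eigh(R)
        factor = V * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((n_trials, spec.n_units)) @ factor.T
    u = ndtr(z)
    # keep quantiles strictly inside (0, 1) for the inverse CDFs
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    mu = tuning[:, class_idx].T  # (n_trials, n_units)
    responses = np.zeros_like(mu)
    pos = mu > 0
    if spec.noise_family == "gamma":
        a = spec.dispersion
        responses[pos] = stats.gamma.ppf(u[pos], a, scale=mu[pos] / a)
    else:
        r = spec.dispersion
        p = r / (r + mu[pos])
        responses[pos] = stats.nbinom.ppf(u[pos], r, p)

    if spec.p_fail > 0:
        if spec.correlated_failures:
            # silence tied to the latent variable: low quantiles fail
            mask = u >= spec.p_fail
        else:
            mask = rng.random((n_trials, spec.n_units)) >= spec.p_fail
        responses *= mask

    return ResponseDataset(
        responses=responses,
        labels=labels,
        modality=spec.modality,
        block=spec.block,
        grid=spec.grid,
    )


def correlation_scenario(name: str) -> tuple[PopulationSpec, np.ndarray]:
    """Constructed populations whose noise correlations have a known,
    opposite-signed effect on decoding error.

    Both scenarios couple the units through a near-unity shared
    multiplicative gain (latent correlation r = 0.995) acting on
    exponential azimuth tuning; what differs is the tuning geometry:

    - ``"shared-gain-pair"``: two units with *opposed* exponential tuning.
      The shared gain cancels in the contrast between the two units, so
      the correlated data decode well; within-class shuffling breaks the
      cancellation and increases the error (correlations reduce error).
    - ``"shared-gain-population"``: many units with *identical*
      exponential tuning. A common gain fluctuation shifts every unit the
      same way an azimuth change would, confusing the decoder; shuffling
      averages the gain out across units and decreases the error
      (correlations increase error).

    Returns the population spec and the tuning matrix to pass to
    :func:`sample_dataset`.
    """
    angles = np.asarray(AzimuthGrid().angles)
    if name == "shared-gain-pair":
        # two opposed pairs; the gain is shared within each pair only
        pair = np.array([[1.0, 0.995], [0.995, 1.0]])
        R = np.zeros((4, 4))
        R[:2, :2] = pair
        R[2:, 2:] = pair
        spec = PopulationSpec(
            n_units=4,
            fraction_dependent=1.0,
            reps_per_azimuth=30,
            noise_family="gamma",
            dispersion=0.3,
            p_fail=0.0,
            latent_corr=R,
        )
        contrast = np.stack(
            [0.5 * np.exp(angles / 100.0), 0.5 * np.exp(-angles / 100.0)]
        )
        tuning = np.vstack([contrast, contrast])
    elif name == "shared-gain-population":
        n = 20
        spec = PopulationSpec(
            n_units=n,
            fraction_dependent=1.0,
            reps_per_azimuth=30,
            noise_family="gamma",
            dispersion=0.8,
            p_fail=0.0,
            latent_corr=0.995,
        )
        tuning = np.tile(0.5 * np.exp(angles / 115.0), (n, 1))
    else:
        raise ValueError(
            "unknown scenario; choose 'shared-gain-pair' or "
            "'shared-gain-population'"
        )
    return spec, tuning


def spec_presets(name: str, **overrides) -> PopulationSpec:
    """Named study-condition presets.

    - ``imaging-like``: large simultaneously imaged population, 14
      repetitions per azimuth, continuous zero-inflated gamma responses.
    - ``ephys-like``: ~21 single units, 20 repetitions per azimuth
      (260 azimuth trials), negative-binomial spike counts.
    - ``tone-ephys``: frequency block, 14 pure tones x 10 repetitions.
    - ``null``: flat tuning, identity latent correlation; everything any
      significance test finds here is a false positive.
    """
    presets = {
        "imaging-like": dict(
            n_units=600,
            fraction_dependent=0.32,
            reps_per_azimuth=14,
            noise_family="gamma",
            dispersion=1.5,
            p_fail=0.35,
            latent_corr=0.15,
        ),
        "ephys-like": dict(
            n_units=21,
            fraction_dependent=0.40,
            reps_per_azimuth=20,
            noise_family="nbinom",
            dispersion=2.0,
            p_fail=0.25,
            latent_corr=0.15,
        ),
        "tone-ephys": dict(
            n_units=21,
            fraction_dependent=0.42,
            reps_per_azimuth=10,
            noise_family="nbinom",
            dispersion=2.0,
            p_fail=0.25,
            latent_corr=None,
            block="frequency",
        ),
        "null": dict(
            n_units=100,
            fraction_dependent=0.0,
            reps_per_azimuth=20,
            tuning_family="flat",
            noise_family="gamma",
            dispersion=1.5,
            p_fail=0.3,
            latent_corr=None,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return PopulationSpec(**params)
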