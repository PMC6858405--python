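"""Transition-matrix model of mutation accumulation under purifying selection.

A new mutation enters a haploid Wright-Fisher population of ``N`` chromosomes
as a single copy.  Each generation, deterministic selection moves its
frequency from ``f`` to ``f' = (1-s) f / (1 - s f)`` (mutant fitness ``1-s``)
and binomial drift then resamples ``N`` chromosomes.  Tracking the full
probability distribution over copy number 0..N (loss and fixation absorbing)
gives the expected divergence of a sampled lineage from its ancestor after
``t`` generations, and hence the accumulation rate of selected mutations
relative to neutral ones:

    D(N, s, t) = sum_{v=1..t} sum_{x=1..N} P(N, x, s, v) * x / N
    A(N, s, t) = D(N, s, t) / D(N, 0, t),        D(N, 0, t) = t / N.

``P(., v=1)`` is the initial single-copy distribution, so ``D(N, s, 1) = 1/N``
for any ``s``.  ``A`` declines with sampling time because selection purges
deleterious variants; with fitness effects drawn from a gamma distribution
this produces the characteristic time-dependence of rate estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FrequencySpectrum",
    "DFESpec",
    "AccumulationCurve",
    "selection_map",
    "binomial_kernel",
    "transition_matrix",
    "new_mutation",
    "propagate",
    "expected_divergence",
    "relative_rate",
    "relative_rate_curve",
    "dfe_relative_rate",
    "monte_carlo_divergence",
]

_CONSERVATION_TOL = 1e-12


def _check_s(s: float) -> float:
    s = float(s)
    if not 0.0 <= s < 1.0:
        raise ValueError(f"selection coefficient s must be in [0, 1), got {s}")
    return s


def selection_map(f, s):
    """Frequency after one round of selection, f' = (1-s)f / (1-sf).

    ``f`` may be a scalar or array of frequencies in [0, 1]; ``s`` is the
    selection coefficient against the mutant (fitness 1-s), 0 <= s < 1.
    """
    s = _check_s(s)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("frequency must lie in [0, 1]")
    out = (1.0 - s) * f / (1.0 - s * f)
    return float(out) if out.ndim == 0 else out


def binomial_kernel(N: int, x: int, i: int, s: float) -> float:
    """P(x copies next generation | i copies now) with selection then drift."""
    N = int(N)
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= x <= N and 0 <= i <= N):
        raise ValueError("copy numbers must lie in 0..N")
    p = selection_map(i / N, s)
    return float(stats.binom.pmf(x, N, p))


def transition_matrix(N: int, s: float) -> np.ndarray:
    """(N+1) x (N+1) column-stochastic matrix M[x, i] = B(N, x, i, s).

    Columns i = 0 and i = N are absorbing (selection maps 0 -> 0 and 1 -> 1),
    so probability mass at loss and fixation is retained exactly.
    """
    N = int(N)
    if N < 1:
        raise ValueError("N must be >= 1")
    p = selection_map(np.arange(N + 1) / N, s)
    x = np.arange(N + 1)
    # broadcast: rows are offspring copy number, columns current copy number
    return stats.binom.pmf(x[:, None], N, p[None, :])


@dataclass
class FrequencySpectrum:
    """Probability distribution over copy number 0..N of a mutation.

    ``probs[x]`` is the probability the mutation is present in ``x`` copies;
    index 0 is loss and index N fixation (both absorbing).
    """

    N: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.N + 1,):
            raise ValueError("probs must have length N + 1")
        if np.any(self.probs < -_CONSERVATION_TOL):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def mean_frequency(self) -> float:
        return float(self.probs @ np.arange(self.N + 1)) / self.N


def new_mutation(N: int) -> FrequencySpectrum:
    """Spectrum of a mutation just introduced as a single copy."""
    probs = np.zeros(int(N) + 1)
    probs[1] = 1.0
    return FrequencySpectrum(int(N), probs)


def propagate(spec: FrequencySpectrum, s: float, generations: int) -> FrequencySpectrum:
    """Advance a frequency spectrum by ``generations`` rounds of selection+drift."""
    generations = int(generations)
    if generations < 0:
        raise ValueError("generation count must be >= 0")
    if generations == 0:
        return FrequencySpectrum(spec.N, spec.probs.copy())
    M = transition_matrix(spec.N, s)
    probs = spec.probs.copy()
    for _ in range(generations):
        probs = M @ probs
    return FrequencySpectrum(spec.N, probs)


def _mean_frequency_series(N: int, s: float, t_max: int) -> np.ndarray:
    """E[x/N] at generations v = 1..t_max; v=1 is the initial single copy."""
    if t_max < 1:
        raise ValueError("t must be >= 1")
    M = transition_matrix(N, s)
    x_over_N = np.arange(N + 1) / N
    probs = np.zeros(N + 1)
    probs[1] = 1.0
    means = np.empty(t_max)
    means[0] = 1.0 / N
    for v in range(1, t_max):
        probs = M @ probs
        means[v] = probs @ x_over_N
    return means


def expected_divergence(N: int, s: float, t: int) -> float:
    """Expected divergence per introduced mutation after ``t`` generations.

    D(N, s, t) = sum over generations of the expected mutant frequency;
    neutrally D(N, 0, t) = t/N (the mean frequency is a martingale).
    """
    return float(_mean_frequency_series(int(N), s, int(t)).sum())


def relative_rate(N: int, s: float, t: int) -> float:
    """Accumulation rate of selected relative to neutral mutations, Eq. A = D/D0."""
    N, t = int(N), int(t)
    return expected_divergence(N, s, t) / (t / N)


def relative_rate_curve(N: int, s: float, times) -> "AccumulationCurve":
    """A(N, s, t) evaluated at each t in ``times`` (single shared recursion)."""
    times = np.asarray(times, dtype=int)
    if np.any(times < 1):
        raise ValueError("times must be >= 1")
    series = _mean_frequency_series(int(N), s, int(times.max()))
    D = np.cumsum(series)
    values = D[times - 1] / (times / N)
    return AccumulationCurve(times=times, values=values, N=int(N))


@dataclass
class DFESpec:
    """Gamma distribution of deleterious fitness effects.

    ``mean_Ns`` is the mean selection coefficient scaled by population size,
    so draws have mean ``s = mean_Ns / N``.  Draws with s >= 1 (impossible
    fitness) are capped at 1 - 1e-6, i.e. treated as effectively lethal.
    """

    shape: float
    mean_Ns: float
    n_samples: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.mean_Ns < 0:
            raise ValueError("mean_Ns must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def sample_s(self, N: int) -> np.ndarray:
        """Draw ``n_samples`` selection coefficients for population size N."""
        if self.mean_Ns == 0:
            return np.zeros(self.n_samples)
        rng = np.random.default_rng(self.seed)
        mean_s = self.mean_Ns / N
        scale = mean_s / self.shape
        draws = rng.gamma(self.shape, scale, size=self.n_samples)
        n_capped = int(np.sum(draws >= 1.0))
        if n_capped > 0.5 * self.n_samples:
            warnings.warn(
                f"{n_capped}/{self.n_samples} DFE draws had s >= 1 and were "
                "capped at 1 - 1e-6; mean_Ns is large relative to N",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.minimum(draws, 1.0 - 1e-6)


@dataclass
class AccumulationCurve:
    """Relative accumulation rate A as a function of sampling time.

    ``times`` are generations; ``times_in_N`` reports them in units of N.
    """

    times: np.ndarray
    values: np.ndarray
    N: int

    @property
    def times_in_N(self) -> np.ndarray:
        return np.asarray(self.times) / self.N

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "t_in_N": self.times_in_N, "A": self.values}
        )


def geometric_times(N: int, max_gen_in_N: float = 4.0, n_points: int = 25) -> np.ndarray:
    """Geometric grid of generation counts from 1 to max_gen_in_N * N."""
    t_max = max(1, int(round(max_gen_in_N * N)))
    grid = np.unique(np.geomspace(1, t_max, n_points).round().astype(int))
    return grid


def dfe_relative_rate(N: int, dfe: DFESpec, times) -> AccumulationCurve:
    """Relative accumulation rate averaged over a gamma DFE.

    Divergence is computed for each sampled selection coefficient and averaged
    across mutations before dividing by the neutral expectation t/N.
    """
    N = int(N)
    times = np.asarray(times, dtype=int)
    if np.any(times < 1):
        raise ValueError("times must be >= 1")
    t_max = int(times.max())
    draws = dfe.sample_s(N)
    D_acc = np.zeros(t_max)
    for s in draws:
        D_acc += np.cumsum(_mean_frequency_series(N, float(s), t_max))
    D_mean = D_acc / len(draws)
    values = D_mean[times - 1] / (times / N)
    return AccumulationCurve(times=times, values=values, N=N)


def monte_carlo_divergence(
    N: int, s: float, t: int, replicates: int, seed: int | None = None
) -> tuple[float, float]:
    """Forward-simulation estimate of D(N, s, t) with its standard error.

    Independent oracle for :func:`expected_divergence`: single-copy
    trajectories are simulated under the same selection-then-binomial scheme
    and the per-generation frequencies summed.  Returns ``(estimate, se)``;
    ``se`` is NaN when ``replicates == 1``.
    """
    N, t, replicates = int(N), int(t), int(replicates)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if t < 1:
        raise ValueError("t must be >= 1")
    s = _check_s(s)
    rng = np.random.default_rng(seed)
    x = np.ones(replicates, dtype=np.int64)
    totals = np.full(replicates, 1.0 / N)  # generation v = 1: single copy
    for _ in range(t - 1):
        p = (1.0 - s) * (x / N) / (1.0 - s * (x / N))
        x = rng.binomial(N, p)
        totals += x / N
    est = float(totals.mean())
    se = float(totals.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else float("nan")
    return est, se
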