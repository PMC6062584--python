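"""Summary statistics for larval trajectories.

Navigation indices, 30-degree-binned heading distributions, the RMS
distance between such distributions, saturating stimulus-response fits,
and the comparison statistics used on tracking data (Welch's t, the
one-sample t, Benjamini-Hochberg correction).

All functions are duck-typed over trajectories: anything exposing
``positions`` (in consistent length units), ``path_length``,
``displacements`` and ``headings_deg`` works, simulated or loaded from a
track file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import BinMismatchError, ConvergenceError, EmptyTrajectoryError

__all__ = [
    "navigation_index",
    "ensemble_navigation_index",
    "AngularDistribution",
    "angular_distribution",
    "rms_angular_deviation",
    "SaturatingFit",
    "fit_saturating_curve",
    "welch_test",
    "one_sample_t",
    "bh_adjust",
]

_AXES = {"x": 0, "y": 1}


def navigation_index(trajectory, axis: str = "x") -> float:
    """Net displacement along ``axis`` divided by the stratified path length.

    NI = -1 for ballistic motion in the negative axis direction, 0 for an
    unbiased random walk.  The triangle inequality bounds |NI| by 1, with
    equality only for a perfectly straight path along the axis.
    """
    try:
        col = _AXES[axis]
    except KeyError:
        raise ValueError("axis must be 'x' or 'y'") from None
    s = trajectory.path_length
    if trajectory.n_accepted < 1 or s == 0.0:
        raise EmptyTrajectoryError("navigation index needs at least one step")
    delta = float(trajectory.positions[-1, col] - trajectory.positions[0, col])
    return delta / s


def ensemble_navigation_index(trajectories, axis: str = "x", pooled: bool = False) -> float:
    """Ensemble NI: mean of per-larva indices (default) or the pooled ratio.

    ``pooled=True`` divides the summed displacement of all larvae by their
    summed path length instead of averaging per-larva ratios.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise EmptyTrajectoryError("empty ensemble")
    if pooled:
        col = _AXES[axis]
        delta = sum(float(t.positions[-1, col] - t.positions[0, col]) for t in trajectories)
        s = sum(t.path_length for t in trajectories)
        if s == 0.0:
            raise EmptyTrajectoryError("zero total path length")
        return delta / s
    return float(np.mean([navigation_index(t, axis) for t in trajectories]))


@dataclass(frozen=True)
class AngularDistribution:
    """Heading probabilities over [0, 180] degrees in fixed-width bins."""

    probabilities: np.ndarray
    bin_deg: float = 30.0
    n_steps: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        n_bins = int(round(180.0 / self.bin_deg))
        if not np.isclose(n_bins * self.bin_deg, 180.0):
            raise ValueError("bin width must divide 180 degrees")
        if p.shape != (n_bins,):
            raise ValueError(f"expected {n_bins} bin probabilities, got {p.shape}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("bin probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, 180.0 + self.bin_deg / 2, self.bin_deg)


def angular_distribution(trajectories, bin_deg: float = 30.0) -> AngularDistribution:
    """Pool per-step headings over trajectories into a binned distribution.

    Headings are folded to [0, 180] (mirror symmetry about the source
    axis).  Bin edges follow half-open convention [lo, hi) except the last
    bin, which includes 180 exactly.
    """
    if hasattr(trajectories, "headings_deg"):
        trajectories = [trajectories]
    headings = [np.atleast_1d(t.headings_deg) for t in trajectories]
    if not headings or sum(h.size for h in headings) == 0:
        raise EmptyTrajectoryError("no steps to bin")
    pooled = np.concatenate(headings)
    n_bins = int(round(180.0 / bin_deg))
    counts, _ = np.histogram(pooled, bins=n_bins, range=(0.0, 180.0))
    return AngularDistribution(
        probabilities=counts / counts.sum(), bin_deg=bin_deg, n_steps=int(counts.sum())
    )


def rms_angular_deviation(p: AngularDistribution, q: AngularDistribution) -> float:
    """Root-mean-squared deviation between two equally-binned distributions."""
    if p.bin_deg != q.bin_deg or p.probabilities.shape != q.probabilities.shape:
        raise BinMismatchError("distributions must share the same binning")
    diff = p.probabilities - q.probabilities
    return float(np.sqrt(np.mean(diff**2)))


@dataclass(frozen=True)
class SaturatingFit:
    """Least-squares fit of NI(u) = A * (1 - exp(-u / s)).

    ``A`` is the saturation amplitude (NI units) and ``s`` the stimulus
    scale in the regressor's units; NI(0) = 0 by construction.  Used as a
    curve to guide the eye, with no inferential claim attached.
    """

    amplitude: float
    scale: float
    rss: float

    def predict(self, u):
        u = np.asarray(u, dtype=float)
        out = self.amplitude * (1.0 - np.exp(-u / self.scale))
        return float(out) if out.ndim == 0 else out


def fit_saturating_curve(pairs) -> SaturatingFit:
    """Fit the saturating interpolation to (stimulus, NI) pairs.

    Raises
    ------
    ConvergenceError
        If the optimizer fails or the data are degenerate (fewer than 3
        distinct stimulus values, or responses indistinguishable from 0).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (stimulus, NI)")
    u, ni = arr[:, 0], arr[:, 1]
    if len(np.unique(u)) < 3:
        raise ConvergenceError("need at least 3 distinct stimulus values")
    if np.allclose(ni, 0.0):
        raise ConvergenceError("all responses are zero; amplitude is degenerate")
    a0 = ni[np.argmax(np.abs(u))]
    if a0 == 0.0:
        a0 = ni[np.argmax(np.abs(ni))]
    s0 = max(float(np.median(np.abs(u[u != 0]))), 1e-6)

    def model(uu, a, s):
        return a * (1.0 - np.exp(-uu / s))

    try:
        popt, _ = optimize.curve_fit(
            model, u, ni, p0=(a0, s0),
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise ConvergenceError(f"saturating fit failed: {exc}") from exc
    resid = ni - model(u, *popt)
    return SaturatingFit(amplitude=float(popt[0]), scale=float(popt[1]),
                         rss=float(resid @ resid))


def _check_sample(sample, name: str) -> np.ndarray:
    a = np.asarray(sample, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def welch_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Two-sided Welch unpaired t-test: (t, Welch-Satterthwaite dof, p)."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_sample_t(sample, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against ``mu0``: (t, p)."""
    a = _check_sample(sample, "sample")
    if a.var(ddof=1) == 0.0:
        raise ValueError("sample has zero variance")
    res = stats.ttest_1samp(a, mu0)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
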