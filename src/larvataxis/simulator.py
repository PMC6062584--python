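"""The biased Markov chain at the heart of the model.

A simulated larva performs a discrete-time, continuous-space random walk:
step proposals are isotropic bivariate Gaussians (standard deviation
sigma, about 0.1 mm, roughly a tenth of a body length), and each proposal
r -> r' is accepted with the generalized Metropolis-Hastings probability

    P = 1                  if W(r -> r') <= 0
    P = exp(-W / T)        if W(r -> r') >  0

where the step weight combines the change in light intensity along the
step with a directionality term carrying the bearing of the light source:

    W(r -> r') = dI(r -> r') + beta * <I> * f(alpha(r -> r'))

``f`` is a decreasing angular function of the heading alpha relative to
the source direction (f(0) = 1 toward the source, f(180) = 0 away from
it); by default f(alpha) = 1 - (alpha/180)^4.  The effective temperature
T (irradiance units) sets how often weight-increasing, "risky" moves are
taken.  Larvae start at the origin and are absorbed once an accepted
position reaches 1150 sigma (~11.5 cm, the plate boundary).

Positions are handled internally in sigma units; fields are evaluated in
cm, with the single conversion ``sigma_cm`` applied at the simulator
boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from . import metrics
from .errors import CapExceededWarning, DomainError, ZeroStepError
from .light_fields import LinearLightField, mean_intensity

__all__ = [
    "ModelParams",
    "Trajectory",
    "EnsembleResult",
    "angular_weight",
    "step_angle",
    "step_weight",
    "propose_step",
    "acceptance_probability",
    "effective_beta",
    "simulate_larva",
    "simulate_ensemble",
]

#: proposals drawn per vectorised batch inside simulate_larva
_CHUNK = 8192


def angular_weight(alpha_deg, n: int = 4, family: str = "power"):
    """Directional weight f(alpha) in [0, 1].

    ``power``  family: f = 1 - (alpha/180)^n
    ``cosine`` family: f = ((1 + cos alpha)/2)^n

    Both satisfy f(0) = 1, f(180) = 0 and decrease monotonically, so the
    weight always favours headings away from the source.  (A raw cos^n
    would violate f(180) = 0 for even n, hence the half-angle form.)
    """
    a = np.asarray(alpha_deg, dtype=float)
    if np.any(a < 0) or np.any(a > 180):
        raise DomainError("heading angle must lie in [0, 180] degrees")
    if n < 1 or int(n) != n:
        raise ValueError("angular exponent n must be a positive integer")
    if family == "power":
        out = 1.0 - (a / 180.0) ** n
    elif family == "cosine":
        out = ((1.0 + np.cos(np.radians(a))) / 2.0) ** n
    else:
        raise ValueError(f"unknown angular family {family!r}")
    return float(out) if out.ndim == 0 else out


def step_angle(r, r_prime, source_direction=(1.0, 0.0)) -> float:
    """Unsigned heading of the step r -> r' relative to the source bearing.

    Returns degrees in [0, 180]; 0 points toward the light source, 180
    directly away.  The angle is folded (mirror-symmetric about the
    source axis).
    """
    d = np.asarray(r_prime, dtype=float) - np.asarray(r, dtype=float)
    norm = float(np.hypot(*d))
    if norm == 0.0:
        raise ZeroStepError("cannot define a heading for a zero-length step")
    s = np.asarray(source_direction, dtype=float)
    s = s / np.hypot(*s)
    cos_a = np.clip(float(d @ s) / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_a)))


def acceptance_probability(W, T: float):
    """Metropolis acceptance probability: 1 for W <= 0, exp(-W/T) otherwise."""
    if T <= 0:
        raise ValueError("effective temperature T must be positive")
    w = np.asarray(W, dtype=float)
    out = np.where(w <= 0, 1.0, np.exp(-np.maximum(w, 0.0) / T))
    return float(out) if out.ndim == 0 else out


def effective_beta(beta_prime: float, theta_deg: float) -> float:
    """Project the raw directionality weight onto the plate: beta = beta' cos(theta).

    An overhead source (theta = 90 deg) has no in-plane bearing, so the
    directionality term vanishes.
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta_deg must lie in [0, 90]")
    return float(beta_prime * math.cos(math.radians(theta_deg)))


def propose_step(rng: np.random.Generator, sigma: float = 1.0, size=None):
    """Draw Gaussian step proposals: independent N(0, sigma^2) x and y deviates.

    With ``size=None`` returns a single (2,) displacement; with an integer
    returns (size, 2).
    """
    if size is None:
        return rng.normal(0.0, sigma, size=2)
    return rng.normal(0.0, sigma, size=(size, 2))


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the biased-chain model.

    T : effective temperature, irradiance units (W/m^2), > 0.
    beta : directionality weight (dimensionless, >= 0).  Ignored when
        ``beta_prime`` is given, in which case the effective value
        beta_prime * cos(theta) is taken from the field's zenith angle.
    n, angular_family : exponent and family of the angular weight f.
    sigma_cm : proposal standard deviation in cm (0.01 cm = 0.1 mm).
    boundary_radius_sigma : absorbing radius in sigma units (1150 ~ 11.5 cm).
    max_accepted_steps / max_proposals : safety caps per larva.
    seed : master RNG seed (child streams are spawned per replicate/larva).
    delta_sign : +1 for dI = I(r') - I(r) (the behaviourally consistent
        convention); -1 flips the intensity term, producing positive
        phototaxis, and exists for fidelity experiments only.
    """

    T: float
    beta: float = 0.0
    beta_prime: float | None = None
    n: int = 4
    angular_family: str = "power"
    sigma_cm: float = 0.01
    boundary_radius_sigma: float = 1150.0
    max_accepted_steps: int = 20000
    max_proposals: int = 1_000_000
    seed: int | None = None
    delta_sign: int = 1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.T) and self.T > 0):
            raise ValueError("T must be positive and finite")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.sigma_cm <= 0:
            raise ValueError("sigma_cm must be positive")
        if self.boundary_radius_sigma <= 0:
            raise ValueError("boundary_radius_sigma must be positive")
        if self.max_accepted_steps < 1 or self.max_proposals < 1:
            raise ValueError("step and proposal caps must be positive")
        if self.delta_sign not in (1, -1):
            raise ValueError("delta_sign must be +1 or -1")
        angular_weight(0.0, self.n, self.angular_family)  # validates n / family

    def resolved_beta(self, field: LinearLightField) -> float:
        """Effective directionality weight for ``field``'s source geometry."""
        if self.beta_prime is not None:
            return effective_beta(self.beta_prime, field.theta_deg)
        return float(self.beta)


def step_weight(field: LinearLightField, params: ModelParams, r, r_prime) -> float:
    """Metropolis-Hastings weight W for a step given in sigma units.

    W = delta_sign * dI + beta * <I> * f(alpha), with the positions
    converted to cm before the field is evaluated.
    """
    r = np.asarray(r, dtype=float)
    rp = np.asarray(r_prime, dtype=float)
    d = (rp - r)[None, :]
    return float(_step_weights(field, params, d)[0])


def _step_weights(field: LinearLightField, params: ModelParams, disp: np.ndarray):
    """Vectorised W for an (n, 2) array of displacements in sigma units.

    For a *linear* field the intensity change over a step depends only on
    the displacement, never on the current position, so the weight (and
    hence the acceptance decision) is a function of the proposal alone.
    """
    if np.any(np.all(disp == 0.0, axis=1)):
        raise ZeroStepError("zero-length proposal")
    d_cm = disp * params.sigma_cm
    d_i = field.a1x * d_cm[:, 0] + field.a1y * d_cm[:, 1]
    beta = params.resolved_beta(field)
    w = params.delta_sign * d_i
    if beta != 0.0:
        s = np.asarray(field.source_direction)
        norm = np.hypot(disp[:, 0], disp[:, 1])
        cos_a = np.clip((disp @ s) / norm, -1.0, 1.0)
        alpha = np.degrees(np.arccos(cos_a))
        w = w + beta * mean_intensity(field) * angular_weight(
            alpha, params.n, params.angular_family
        )
    return w


@dataclass(frozen=True)
class Trajectory:
    """Accepted positions of one simulated larva, in sigma units.

    ``positions`` has shape (n_accepted + 1, 2) and starts at the origin.
    ``termination`` is one of ``boundary`` (absorbed at the plate edge),
    ``step_cap``, ``proposal_cap`` or ``loaded`` (read from a track file).
    """

    positions: np.ndarray
    n_proposals: int
    termination: str
    source_direction: tuple[float, float] = (1.0, 0.0)

    @property
    def n_accepted(self) -> int:
        return len(self.positions) - 1

    @property
    def displacements(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    @property
    def step_lengths(self) -> np.ndarray:
        d = self.displacements
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def path_length(self) -> float:
        """Total polyline (stratified-path) length s."""
        return float(self.step_lengths.sum())

    @property
    def headings_deg(self) -> np.ndarray:
        """Per-step headings folded to [0, 180] relative to the source bearing."""
        d = self.displacements
        norm = np.hypot(d[:, 0], d[:, 1])
        s = np.asarray(self.source_direction)
        cos_a = np.clip((d @ s) / norm, -1.0, 1.0)
        return np.degrees(np.arccos(cos_a))

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposals if self.n_proposals else float("nan")


def simulate_larva(
    field: LinearLightField, params: ModelParams, rng: np.random.Generator | None = None
) -> Trajectory:
    """Run one larva from the origin until absorption or a cap.

    Proposals are drawn in batches; because the field is linear the
    weight of each proposal is independent of the current position, so a
    whole batch can be scored and accepted at once and the accepted
    displacements accumulated — exactly equivalent to the one-at-a-time
    algorithm, including the RNG draw order (a Gaussian pair and one
    uniform per proposal within each batch).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    radius2 = params.boundary_radius_sigma**2
    pos_blocks = [np.zeros((1, 2))]
    current = np.zeros(2)
    n_acc = 0
    n_prop = 0
    termination = None
    while termination is None:
        m = min(_CHUNK, params.max_proposals - n_prop)
        if m <= 0:
            termination = "proposal_cap"
            warnings.warn(
                "max_proposals reached before boundary or step cap",
                CapExceededWarning,
                stacklevel=2,
            )
            break
        disp = propose_step(rng, 1.0, size=m)
        w = _step_weights(field, params, disp)
        u = rng.random(m)
        accepted = u < acceptance_probability(w, params.T)
        acc_idx = np.nonzero(accepted)[0]
        k_room = params.max_accepted_steps - n_acc
        take = acc_idx[:k_room]
        if take.size:
            steps = disp[take]
            pos = current + np.cumsum(steps, axis=0)
            hit = np.nonzero((pos**2).sum(axis=1) >= radius2)[0]
            if hit.size:
                j = hit[0]
                pos = pos[: j + 1]
                take = take[: j + 1]
                termination = "boundary"
            pos_blocks.append(pos)
            current = pos[-1]
            n_acc += len(pos)
        if termination == "boundary":
            n_prop += int(take[-1]) + 1
        elif take.size < acc_idx.size:
            # step cap reached inside this batch; count proposals up to
            # the last accepted step actually taken
            n_prop += int(take[-1]) + 1 if take.size else 0
            termination = "step_cap"
        elif n_acc >= params.max_accepted_steps:
            # cap filled exactly at a batch acceptance: proposals after the
            # final accepted one never happen in the sequential algorithm
            n_prop += int(take[-1]) + 1 if take.size else m
            termination = "step_cap"
        else:
            n_prop += m
    return Trajectory(
        positions=np.concatenate(pos_blocks, axis=0),
        n_proposals=n_prop,
        termination=termination,
        source_direction=field.source_direction,
    )


@dataclass(frozen=True)
class EnsembleResult:
    """Navigation indices and trajectories of a replicated ensemble.

    Per replicate, the ensemble index is the mean over larvae of each
    larva's navigation index; the reported ``ni_x``/``ni_y`` are means
    over replicates and ``sd_x``/``sd_y`` the standard deviations across
    replicate means (ddof=1; 0 for a single replicate).
    """

    trajectories: list  # list (replicates) of lists (larvae) of Trajectory
    replicate_ni_x: np.ndarray
    replicate_ni_y: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)

    @property
    def ni_x(self) -> float:
        return float(self.replicate_ni_x.mean())

    @property
    def ni_y(self) -> float:
        return float(self.replicate_ni_y.mean())

    @property
    def sd_x(self) -> float:
        return float(self.replicate_ni_x.std(ddof=1)) if self.n_replicates > 1 else 0.0

    @property
    def sd_y(self) -> float:
        return float(self.replicate_ni_y.std(ddof=1)) if self.n_replicates > 1 else 0.0

    @property
    def se_x(self) -> float:
        """Standard error of ni_x across replicates."""
        return self.sd_x / math.sqrt(self.n_replicates)

    @property
    def se_y(self) -> float:
        return self.sd_y / math.sqrt(self.n_replicates)

    @property
    def all_trajectories(self) -> list:
        return [t for rep in self.trajectories for t in rep]

    @property
    def acceptance_rate(self) -> float:
        trajs = self.all_trajectories
        return sum(t.n_accepted for t in trajs) / sum(t.n_proposals for t in trajs)

    def termination_counts(self) -> dict:
        counts: dict[str, int] = {}
        for t in self.all_trajectories:
            counts[t.termination] = counts.get(t.termination, 0) + 1
        return counts

    def pooled_angular_distribution(self, bin_deg: float = 30.0):
        return metrics.angular_distribution(self.all_trajectories, bin_deg=bin_deg)


def simulate_ensemble(
    field: LinearLightField,
    params: ModelParams,
    n_larvae: int = 30,
    n_replicates: int = 30,
) -> EnsembleResult:
    """Simulate ``n_replicates`` independent ensembles of ``n_larvae`` larvae.

    Child RNG streams are spawned deterministically from ``params.seed``
    (one per replicate, then one per larva), so results are reproducible
    and independent of evaluation order.
    """
    if n_larvae < 1 or n_replicates < 1:
        raise ValueError("n_larvae and n_replicates must be >= 1")
    master = np.random.SeedSequence(params.seed)
    rep_seeds = master.spawn(n_replicates)
    trajectories = []
    rep_ni_x = np.empty(n_replicates)
    rep_ni_y = np.empty(n_replicates)
    for i, rep_seed in enumerate(rep_seeds):
        larvae = [
            simulate_larva(field, params, np.random.default_rng(s))
            for s in rep_seed.spawn(n_larvae)
        ]
        trajectories.append(larvae)
        rep_ni_x[i] = np.mean([metrics.navigation_index(t, "x") for t in larvae])
        rep_ni_y[i] = np.mean([metrics.navigation_index(t, "y") for t in larvae])
    return EnsembleResult(
        trajectories=trajectories,
        replicate_ni_x=rep_ni_x,
        replicate_ni_y=rep_ni_y,
        provenance={
            "field": field,
            "params": params,
            "n_larvae": n_larvae,
            "n_replicates": n_replicates,
        },
    )
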