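"""Calibration of the model's free parameters against target navigation indices.

The three free parameters are fitted the way the behavioural study
determines them:

* the effective temperature T is tuned so the simulated ensemble
  navigation index matches a measured value (stochastic bisection on
  log T with common random numbers across evaluations);
* the directionality weight beta is obtained from a "tilted" pattern in
  which the intensity gradient lies along y while the source bearing lies
  along x, decoupling the two weight terms: first T is fitted to the
  y-index with beta = 0, then beta is fitted to the x-index, and finally
  both are jointly refined by alternating updates;
* the angular exponent n (and family) is selected by simulating candidate
  models and ranking them by the RMS deviation of their pooled heading
  distributions from reference distributions.

Every evaluation uses a fixed ensemble size and a fixed evaluation seed,
so the objective seen by the root-finder is a deterministic function of
the parameter and the Monte-Carlo noise cancels between evaluations.
Calibration evaluations cap trajectories at ``step_cap`` accepted steps
(the navigation index is stationary well before the boundary is reached
at the biases of interest), which keeps the stochastic search tractable;
reporting ensembles should be run with the full boundary rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .errors import (
    BinMismatchError,
    CapExceededWarning,
    NonConvergenceWarning,
    UnreachableTargetError,
)
from .light_fields import LinearLightField, mean_intensity
from .metrics import AngularDistribution, rms_angular_deviation
from .simulator import ModelParams, _step_weights, simulate_ensemble

__all__ = [
    "CalibrationResult",
    "AngularModelScore",
    "greedy_limit_ni",
    "fit_temperature",
    "fit_beta_tilted",
    "joint_refine",
    "calibrate_tilted",
    "select_angular_model",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a stochastic parameter fit.

    ``trace`` records every ensemble evaluation as a dict with the
    parameter values tried and the navigation indices (with sd) they
    produced, for auditability.
    """

    params: dict
    achieved: dict
    sd: dict
    trace: list = dc_field(default_factory=list)
    converged: bool = False
    tol: float = 0.01


@dataclass(frozen=True)
class AngularModelScore:
    """RMS score of one candidate angular model against the references."""

    family: str
    n: int
    rms: float


def _eval_seed(params: ModelParams) -> int:
    # one fixed evaluation seed per calibration run: common random numbers
    return int(np.random.SeedSequence(params.seed).generate_state(1)[0] % (2**31))


def _eval(field, params, T, beta, axis, seed, n_larvae, n_replicates, step_cap):
    # the proposal budget bounds the cost of pathological (low-acceptance)
    # parameter points probed during bracketing; CapExceededWarning from
    # such probes is routine here, not a user-facing condition
    p = replace(
        params, T=T, beta=beta, beta_prime=None, seed=seed,
        max_accepted_steps=step_cap, max_proposals=25 * step_cap,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CapExceededWarning)
        ens = simulate_ensemble(field, p, n_larvae=n_larvae, n_replicates=n_replicates)
    ni = ens.ni_x if axis == "x" else ens.ni_y
    sd = ens.sd_x if axis == "x" else ens.sd_y
    return ni, sd, ens


def greedy_limit_ni(
    field: LinearLightField,
    params: ModelParams,
    axis: str = "x",
    n_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Navigation index in the greedy (T -> 0) limit.

    As T -> 0 only weight-decreasing proposals are accepted, so the
    per-step acceptance indicator is 1{W <= 0}.  Because the weight of a
    proposal is position-independent for a linear field, the limiting NI
    equals E[d_axis 1{W<=0}] / E[|d| 1{W<=0}] over the proposal
    distribution, estimated here by plain Monte Carlo.  This is the
    practical reachability bound for temperature fitting.
    """
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_samples, 2))
    w = _step_weights(field, params, d)
    keep = w <= 0
    if not np.any(keep):
        return 0.0
    col = 0 if axis == "x" else 1
    ell = np.hypot(d[:, 0], d[:, 1])
    return float(d[keep, col].sum() / ell[keep].sum())


def _expand_bracket(h, x0, target_mag, grow=4.0, max_expand=30):
    """Find [lo, hi] with h(lo) >= target_mag >= h(hi), h decreasing in x.

    ``h`` returns (magnitude, payload).  When expanding toward stronger
    bias the magnitude must keep growing; if it turns over (the objective
    is only locally monotone, as the y-index is in T once the
    directionality term is on), the target is declared unreachable
    instead of walking into ever-costlier parameter regions.
    """
    lo = hi = x0
    m0, _ = h(x0)
    if m0 >= target_mag:
        for _ in range(max_expand):
            hi = hi * grow
            m, _ = h(hi)
            if m <= target_mag:
                return lo, hi
        raise UnreachableTargetError(
            "could not bracket the target from above (bias never weak enough)"
        )
    m_prev = m0
    for _ in range(max_expand):
        lo = lo / grow
        m, _ = h(lo)
        if m >= target_mag:
            return lo, hi
        if m <= m_prev:
            raise UnreachableTargetError(
                f"objective peaks at {m_prev:.4f} below the target magnitude "
                f"{target_mag:.4f}; no stronger bias is attainable"
            )
        m_prev = m
    raise UnreachableTargetError(
        "could not bracket the target from below (bias never strong enough)"
    )


def fit_temperature(
    field: LinearLightField,
    params: ModelParams,
    target_ni: float,
    axis: str = "x",
    tol: float = 0.01,
    max_iter: int = 60,
    n_larvae: int = 30,
    n_replicates: int = 30,
    step_cap: int = 4000,
    xtol_rel: float = 0.05,
) -> CalibrationResult:
    """Fit T so the ensemble navigation index along ``axis`` matches ``target_ni``.

    Monotone bracketing followed by bisection on log T; ``params.T`` is
    the initial guess, ``params.beta`` (or ``beta_prime``) is held fixed.
    Bisection continues until the bracket has shrunk to ``xtol_rel`` in
    log width even after the index residual drops below ``tol`` — near a
    flat part of the response curve an early stop would leave T resolved
    only to the coarse bracketing grid.

    Raises
    ------
    UnreachableTargetError
        If ``target_ni`` is 0 (W/T and hence the chain is independent of
        T for an unbiased chain, so T is not identifiable), has the wrong
        sign, or exceeds the greedy (T -> 0) limit.
    """
    if target_ni == 0.0:
        raise UnreachableTargetError(
            "target NI of 0 corresponds to an unbiased chain; T is not identifiable"
        )
    beta = params.resolved_beta(field)
    if beta == 0.0:
        # pure gradient drive: |ni| is monotone in T and the T -> 0 limit is
        # its supremum, so the greedy bound is an exact reachability check
        greedy = greedy_limit_ni(field, params, axis=axis)
        if greedy == 0.0 or np.sign(greedy) != np.sign(target_ni):
            raise UnreachableTargetError(
                f"target ni_{axis}={target_ni:+.3f} has the wrong sign for this "
                f"field (greedy limit {greedy:+.3f})"
            )
        if abs(target_ni) >= abs(greedy):
            raise UnreachableTargetError(
                f"target ni_{axis}={target_ni:+.3f} exceeds the greedy limit "
                f"{greedy:+.3f}"
            )
    seed = _eval_seed(params)
    trace: list[dict] = []

    def h(T):
        ni, sd, _ = _eval(field, params, T, beta, axis, seed, n_larvae, n_replicates, step_cap)
        trace.append({"T": T, "beta": beta, f"ni_{axis}": ni, "sd": sd})
        return abs(ni), (ni, sd)

    mag0, (ni0, sd0) = h(params.T)
    if mag0 > max(3.0 * sd0, tol) and np.sign(ni0) != np.sign(target_ni):
        raise UnreachableTargetError(
            f"simulated ni_{axis}={ni0:+.3f} at T={params.T:g} has the opposite "
            f"sign of the target {target_ni:+.3f}"
        )

    def h_cached(T, _first=[True]):
        if _first[0] and T == params.T:
            _first[0] = False
            return mag0, (ni0, sd0)
        return h(T)

    lo, hi = _expand_bracket(h_cached, params.T, abs(target_ni))
    best = min(trace, key=lambda e: abs(e[f"ni_{axis}"] - target_ni))
    it = len(trace)
    while it < max_iter and np.log(hi / lo) > xtol_rel:
        mid = float(np.sqrt(lo * hi))
        mag, (ni, sd) = h(mid)
        it += 1
        if mag > abs(target_ni):
            lo = mid
        else:
            hi = mid
        if abs(ni - target_ni) < abs(best[f"ni_{axis}"] - target_ni):
            best = trace[-1]
    converged = abs(best[f"ni_{axis}"] - target_ni) <= tol
    return CalibrationResult(
        params={"T": best["T"]},
        achieved={axis: best[f"ni_{axis}"]},
        sd={axis: best["sd"]},
        trace=trace,
        converged=converged,
        tol=tol,
    )


def _fit_beta(
    field, params, target_ni_x, tol, max_iter, n_larvae, n_replicates, step_cap,
    beta_init=None, xtol_rel=0.05,
):
    """Monotone search on beta so ni_x matches the target, T held fixed."""
    seed = _eval_seed(params)
    trace: list[dict] = []

    def eval_beta(b):
        ni, sd, _ = _eval(field, params, params.T, b, "x", seed, n_larvae, n_replicates, step_cap)
        trace.append({"T": params.T, "beta": b, "ni_x": ni, "sd": sd})
        return ni, sd

    ni0, sd0 = eval_beta(0.0)
    if abs(ni0 - target_ni_x) <= tol:
        return CalibrationResult(
            params={"beta": 0.0}, achieved={"x": ni0}, sd={"x": sd0},
            trace=trace, converged=True, tol=tol,
        )
    # directionality only pushes ni_x toward the greedy (away-from-source)
    # direction, i.e. away from the beta=0 value
    away = -float(np.sign(field.source_direction[0])) or -1.0
    if np.sign(target_ni_x - ni0) != away:
        raise UnreachableTargetError(
            f"target ni_x={target_ni_x:+.3f} is on the wrong side of the "
            f"gradient-only index {ni0:+.3f}; no beta >= 0 can reach it"
        )

    def h(b):
        ni, sd = eval_beta(b)
        # distance past the target in the away direction, as a decreasing
        # function of 1/b -> use |ni| toward away direction
        return away * (ni - ni0), (ni, sd)

    b0 = beta_init if beta_init else 0.014
    target_mag = away * (target_ni_x - ni0)
    # h is increasing in b; reuse the decreasing-bracket helper on 1/b
    lo_inv, hi_inv = _expand_bracket(lambda x: h(1.0 / x), 1.0 / b0, target_mag)
    lo, hi = 1.0 / hi_inv, 1.0 / lo_inv  # h(lo) <= target_mag <= h(hi)
    best = min(trace[1:], key=lambda e: abs(e["ni_x"] - target_ni_x))
    it = len(trace)
    while it < max_iter and np.log(hi / lo) > xtol_rel:
        mid = float(np.sqrt(lo * hi))
        mag, (ni, sd) = h(mid)
        it += 1
        if mag < target_mag:
            lo = mid
        else:
            hi = mid
        if abs(ni - target_ni_x) < abs(best["ni_x"] - target_ni_x):
            best = trace[-1]
    converged = abs(best["ni_x"] - target_ni_x) <= tol
    return CalibrationResult(
        params={"beta": best["beta"]}, achieved={"x": best["ni_x"]},
        sd={"x": best["sd"]}, trace=trace, converged=converged, tol=tol,
    )


def fit_beta_tilted(
    field: LinearLightField,
    params: ModelParams,
    target_ni_x: float,
    target_ni_y: float,
    tol: float = 0.01,
    max_iter: int = 60,
    n_larvae: int = 30,
    n_replicates: int = 30,
    step_cap: int = 4000,
) -> CalibrationResult:
    """Two-step calibration on a tilted pattern: T from ni_y, then beta from ni_x.

    Step 1 assumes only the intensity term acts (beta = 0) and fits T to
    the y-index, which the artificial y-gradient dominates.  Step 2 holds
    that T and fits beta so the x-index (dominated by directionality)
    matches.  Follow with :func:`joint_refine` to absorb the small
    coupling between the two terms.
    """
    try:
        res_t = fit_temperature(
            field, replace(params, beta=0.0, beta_prime=None), target_ni_y,
            axis="y", tol=tol, max_iter=max_iter,
            n_larvae=n_larvae, n_replicates=n_replicates, step_cap=step_cap,
        )
    except UnreachableTargetError as exc:
        raise UnreachableTargetError(f"stage 1 (temperature from ni_y): {exc}") from exc
    T = res_t.params["T"]
    try:
        res_b = _fit_beta(
            field, replace(params, T=T, beta=0.0, beta_prime=None), target_ni_x,
            tol, max_iter, n_larvae, n_replicates, step_cap,
        )
    except UnreachableTargetError as exc:
        raise UnreachableTargetError(f"stage 2 (beta from ni_x): {exc}") from exc
    return CalibrationResult(
        params={"beta": res_b.params["beta"], "T": T},
        achieved={"x": res_b.achieved["x"], "y": res_t.achieved["y"]},
        sd={"x": res_b.sd["x"], "y": res_t.sd["y"]},
        trace=res_t.trace + res_b.trace,
        converged=res_t.converged and res_b.converged,
        tol=tol,
    )


def joint_refine(
    field: LinearLightField,
    params: ModelParams,
    beta0: float,
    T0: float,
    targets: tuple[float, float],
    tol: float = 0.01,
    max_sweeps: int = 30,
    damping: float = 0.7,
    n_larvae: int = 30,
    n_replicates: int = 30,
    step_cap: int = 4000,
) -> CalibrationResult:
    """Joint refinement of (beta, T) against (target ni_x, target ni_y).

    Once the directionality term is on, the two indices couple: beta
    amplifies |ni_y| as well, so the two-step estimates are biased.  Each
    sweep runs one ensemble at the current (beta, T) and applies damped
    multiplicative updates exploiting the local response shape
    (|ni_y| roughly proportional to 1/T at fixed beta, |ni_x| increasing
    in beta at fixed T):

        T    <- T    * (|ni_y| / |target_y|) ** damping
        beta <- beta * (|target_x| / |ni_x|) ** damping

    Stops when both residuals are within ``tol``; issues a
    :class:`NonConvergenceWarning` and returns the best visited point
    after ``max_sweeps`` sweeps.

    Raises
    ------
    UnreachableTargetError
        When a target is identically 0 on the y-axis, or the iteration
        diverges (a parameter runs away by more than x300), which is how
        contradictory target pairs manifest.
    """
    target_x, target_y = targets
    if target_y == 0.0:
        raise UnreachableTargetError(
            "target ni_y of 0 leaves the effective temperature unidentifiable"
        )
    seed = _eval_seed(params)
    beta, T = float(beta0), float(T0)
    beta_scale = max(abs(beta), 1e-4)
    trace: list[dict] = []
    converged = False
    best = None
    for _sweep in range(max_sweeps):
        p = replace(params, T=T, beta=beta, beta_prime=None, seed=seed,
                    max_accepted_steps=step_cap, max_proposals=25 * step_cap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CapExceededWarning)
            ens = simulate_ensemble(field, p, n_larvae=n_larvae, n_replicates=n_replicates)
        entry = {"T": T, "beta": beta, "ni_x": ens.ni_x, "ni_y": ens.ni_y,
                 "sd_x": ens.sd_x, "sd_y": ens.sd_y}
        trace.append(entry)
        miss = max(abs(ens.ni_x - target_x), abs(ens.ni_y - target_y))
        if best is None or miss < best[0]:
            best = (miss, entry)
        if abs(ens.ni_x - target_x) <= tol and abs(ens.ni_y - target_y) <= tol:
            converged = True
            break
        if abs(ens.ni_y) > 0:
            T = T * (abs(ens.ni_y) / abs(target_y)) ** damping
        if target_x != 0.0 and beta > 0.0 and abs(ens.ni_x) > 0:
            beta = beta * (abs(target_x) / abs(ens.ni_x)) ** damping
        if not (T0 / 300 <= T <= T0 * 300) or beta > beta_scale * 300:
            raise UnreachableTargetError(
                f"joint refinement diverged (T={T:.3g}, beta={beta:.3g}); "
                f"the target pair ({target_x:+.3f}, {target_y:+.3f}) appears "
                f"unattainable for this field"
            )
    if not converged:
        warnings.warn(
            f"joint refinement stopped with residual {best[0]:.4f} > tol {tol} "
            f"(sweep cap, stalled parameters, or marginally unattainable target)",
            NonConvergenceWarning,
            stacklevel=2,
        )
        entry = best[1]
    return CalibrationResult(
        params={"beta": entry["beta"], "T": entry["T"]},
        achieved={"x": entry["ni_x"], "y": entry["ni_y"]},
        sd={"x": entry["sd_x"], "y": entry["sd_y"]},
        trace=trace,
        converged=converged,
        tol=tol,
    )


def calibrate_tilted(
    field: LinearLightField,
    params: ModelParams,
    target_ni_x: float,
    target_ni_y: float,
    tol: float = 0.01,
    max_iter: int = 60,
    max_sweeps: int = 30,
    n_larvae: int = 30,
    n_replicates: int = 30,
    step_cap: int = 4000,
) -> CalibrationResult:
    """Full tilted-pattern calibration: two-step fit followed by joint refinement."""
    sizes = dict(n_larvae=n_larvae, n_replicates=n_replicates, step_cap=step_cap)
    two_step = fit_beta_tilted(
        field, params, target_ni_x, target_ni_y, tol=tol, max_iter=max_iter, **sizes
    )
    refined = joint_refine(
        field, params, two_step.params["beta"], two_step.params["T"],
        (target_ni_x, target_ni_y), tol=tol, max_sweeps=max_sweeps, **sizes,
    )
    return replace(refined, trace=two_step.trace + refined.trace)


def select_angular_model(
    reference_dists,
    field,
    params: ModelParams,
    candidates,
    n_larvae: int = 30,
    n_replicates: int = 30,
    step_cap: int = 4000,
    seed: int | None = None,
) -> list[AngularModelScore]:
    """Rank candidate angular models by mean RMS deviation from references.

    ``reference_dists`` is one :class:`AngularDistribution` or a sequence
    of them (one per illumination condition); ``field`` correspondingly a
    single field or a matched sequence.  ``candidates`` is a sequence of
    ``(family, n)`` pairs.  Every candidate is simulated with the same
    seed (common random numbers), so ranking differences reflect the
    angular model, not Monte-Carlo luck.  Ties break toward smaller n,
    then the power family.
    """
    if isinstance(reference_dists, AngularDistribution):
        reference_dists = [reference_dists]
    reference_dists = list(reference_dists)
    if not reference_dists:
        raise ValueError("need at least one reference distribution")
    if isinstance(field, LinearLightField):
        fields = [field] * len(reference_dists)
    else:
        fields = list(field)
        if len(fields) != len(reference_dists):
            raise ValueError("need one field per reference distribution")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    bins = {d.bin_deg for d in reference_dists}
    if len(bins) > 1:
        raise BinMismatchError("reference distributions use mixed bin widths")
    bin_deg = bins.pop()
    sim_seed = seed if seed is not None else _eval_seed(params)
    scores = []
    for family, n in candidates:
        p = replace(params, n=n, angular_family=family, seed=sim_seed,
                    max_accepted_steps=step_cap)
        rms_vals = []
        for ref, fld in zip(reference_dists, fields):
            ens = simulate_ensemble(fld, p, n_larvae=n_larvae, n_replicates=n_replicates)
            sim_dist = ens.pooled_angular_distribution(bin_deg=bin_deg)
            rms_vals.append(rms_angular_deviation(ref, sim_dist))
        scores.append(AngularModelScore(family=family, n=n, rms=float(np.mean(rms_vals))))
    return sorted(scores, key=lambda s: (s.rms, s.n, s.family != "power"))
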