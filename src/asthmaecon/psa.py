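"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated through the decision tree by Monte
Carlo simulation: per-state costs follow Gamma distributions matched to
their (mean, sd) by moments, and the three-state probability vector
follows a Dirichlet with the observed visit counts as concentration (so
each marginal is Beta and every draw lies on the simplex).  Utilities are
fixed by default.  Each iteration re-evaluates both strategies and stores
the incremental pair (dC, dU); the cloud summarises as a
cost-effectiveness plane (with a normal-theory confidence ellipse) and a
cost-effectiveness acceptability curve (CEAC) over a willingness-to-pay
grid.

Seeding: one root seed is split into independent per-parameter streams
keyed by a CRC-32 of the parameter's name, so adding or removing one
parameter does not reshuffle the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cua import evaluate_strategy
from .parameters import StrategyParams
from .states import N_STATES

__all__ = [
    "ParamDistribution",
    "StrategyDistributions",
    "PSAResult",
    "EllipseSummary",
    "fit_gamma_from_moments",
    "dirichlet_from_counts",
    "run_psa",
    "ceac",
    "ce_plane_summary",
]


@dataclass(frozen=True)
class ParamDistribution:
    """Prior for one model parameter.

    ``kind`` is one of ``gamma_cost`` (moments-matched Gamma on a cost),
    ``dirichlet_probs`` (Dirichlet on the state-probability vector),
    ``beta_probs`` (independent per-state Betas, renormalized) or
    ``fixed`` (degenerate at ``value``).
    """

    kind: str
    mean: float | None = None
    sd: float | None = None
    shape: float | None = None
    scale: float | None = None
    counts: tuple[float, ...] | None = None
    value: tuple[float, ...] | float | None = None

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "gamma_cost":
            return rng.gamma(self.shape, self.scale, size=size)
        if self.kind == "dirichlet_probs":
            return rng.dirichlet(self.counts, size=size)
        if self.kind == "beta_probs":
            total = float(sum(self.counts))
            cols = [
                rng.beta(c, total - c, size=size) if 0 < c < total
                else np.full(size, c / total)
                for c in self.counts
            ]
            p = np.column_stack(cols)
            return p / p.sum(axis=1, keepdims=True)
        if self.kind == "fixed":
            v = np.asarray(self.value, dtype=float)
            return np.broadcast_to(v, (size,) + v.shape).copy()
        raise ValueError(f"unknown distribution kind {self.kind!r}")


def fit_gamma_from_moments(mean: float, sd: float) -> ParamDistribution:
    """Gamma prior matched to a cost's mean and standard deviation.

    shape = (mean/sd)^2, scale = sd^2/mean, so the fitted distribution
    reproduces the input mean and variance exactly.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moments must be positive")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return ParamDistribution(kind="gamma_cost", mean=mean, sd=sd, shape=shape, scale=scale)


def dirichlet_from_counts(counts: Sequence[float]) -> ParamDistribution:
    """Dirichlet prior on the state-probability simplex.

    The visit counts act as the concentration vector: the marginal of
    state *i* is Beta(count_i, total - count_i) with mean count_i/total,
    and every draw sums to one.  Zero counts are rejected; add a small
    offset upstream if a state was never observed.
    """
    c = tuple(float(x) for x in counts)
    if len(c) != N_STATES:
        raise ValueError(f"need exactly {N_STATES} counts")
    if any(x <= 0 for x in c):
        raise ValueError("zero count: Dirichlet concentration must be positive")
    return ParamDistribution(kind="dirichlet_probs", counts=c)


@dataclass(frozen=True)
class StrategyDistributions:
    """Per-strategy priors: one per state cost, one for the probability vector."""

    params: StrategyParams
    cost_dists: tuple[ParamDistribution, ...]
    prob_dist: ParamDistribution
    utility_dist: ParamDistribution

    @classmethod
    def from_params(
        cls,
        params: StrategyParams,
        cost_sds: Sequence[float] | None = None,
        cv: float = 0.3,
        counts: Sequence[float] | None = None,
        prob_mode: str = "dirichlet",
        vary_probs: bool = True,
        vary_costs: bool = True,
    ) -> "StrategyDistributions":
        """Build priors around a strategy's point estimates.

        Cost sds default to ``cv * mean`` when no published sd is given;
        a zero sd pins that cost (degenerate prior).  Probabilities need
        the underlying visit ``counts``; without them (or with
        ``vary_probs=False``) the vector is fixed.  Utilities are always
        fixed here (the base-case PSA varies costs and probabilities only).
        """
        cds = []
        for i, mean in enumerate(params.state_costs):
            sd = cost_sds[i] if cost_sds is not None else cv * mean
            if not vary_costs or sd == 0 or mean == 0:
                cds.append(ParamDistribution(kind="fixed", value=mean))
            else:
                cds.append(fit_gamma_from_moments(mean, sd))
        if vary_probs and counts is not None:
            if prob_mode == "dirichlet":
                pd_ = dirichlet_from_counts(counts)
            elif prob_mode == "beta":
                pd_ = ParamDistribution(
                    kind="beta_probs", counts=tuple(float(x) for x in counts)
                )
            else:
                raise ValueError(f"unknown prob_mode {prob_mode!r}")
        else:
            pd_ = ParamDistribution(kind="fixed", value=params.state_probs)
        ud = ParamDistribution(kind="fixed", value=params.state_utilities)
        return cls(params=params, cost_dists=tuple(cds), prob_dist=pd_, utility_dist=ud)


@dataclass
class PSAResult:
    """Paired incremental draws from the Monte Carlo simulation."""

    ref_label: str
    alt_label: str
    delta_cost: np.ndarray
    delta_utility: np.ndarray
    seed: int
    n_iterations: int
    ceac_grid: np.ndarray | None = field(default=None)
    ceac_prob: np.ndarray | None = field(default=None)

    @property
    def draws(self) -> np.ndarray:
        """(n, 2) array of (dC, dU) pairs."""
        return np.column_stack([self.delta_cost, self.delta_utility])


def _param_rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream for one named parameter under one root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _sample_strategy(
    dists: StrategyDistributions, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n,) expected costs and utilities under the strategy's priors."""
    label = dists.params.label
    costs = np.column_stack(
        [
            d.sample(_param_rng(seed, f"{label}/cost/{i}"), n)
            for i, d in enumerate(dists.cost_dists)
        ]
    )
    probs = dists.prob_dist.sample(_param_rng(seed, f"{label}/probs"), n)
    utils = dists.utility_dist.sample(_param_rng(seed, f"{label}/utilities"), n)
    if utils.ndim == 1:
        utils = np.broadcast_to(utils[None, :], probs.shape)
    return (probs * costs).sum(axis=1), (probs * utils).sum(axis=1)


def run_psa(
    ref: StrategyDistributions,
    alt: StrategyDistributions,
    n: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo PSA of ``alt`` against ``ref``.

    Every iteration draws all costs and probability vectors from their
    priors, re-evaluates both decision trees and records
    (dC, dU) = alt - ref.  Runs are bit-reproducible for a given seed,
    and the draw mean converges to the deterministic base case when the
    priors are centred on it.
    """
    if ref.params.cost_basis != alt.params.cost_basis:
        raise ValueError("mismatched cost basis between PSA arms")
    if n < 1:
        raise ValueError("need at least one iteration")
    ref_c, ref_u = _sample_strategy(ref, n, seed)
    alt_c, alt_u = _sample_strategy(alt, n, seed)
    return PSAResult(
        ref_label=ref.params.label,
        alt_label=alt.params.label,
        delta_cost=alt_c - ref_c,
        delta_utility=alt_u - ref_u,
        seed=seed,
        n_iterations=n,
    )


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each threshold lambda the curve is the fraction of draws with
    positive incremental net benefit, ``lambda * dU - dC > 0``.  At
    lambda = 0 this is the fraction of cost-saving draws; as lambda grows
    it tends to the fraction of utility-gaining draws.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    nb = grid[:, None] * result.delta_utility[None, :] - result.delta_cost[None, :]
    prob = (nb > 0).mean(axis=1)
    result.ceac_grid = grid
    result.ceac_prob = prob
    return grid, prob


@dataclass(frozen=True)
class EllipseSummary:
    """Normal-theory confidence ellipse on the (dC, dU) cloud."""

    center: tuple[float, float]
    axes: tuple[float, float]          # semi-axis lengths
    angle_deg: float                   # orientation of the major axis
    confidence: float
    inside_fraction: float
    quadrant_shares: dict[str, float]  # NE/NW/SE/SW shares of draws
    degenerate: bool = False


def ce_plane_summary(result: PSAResult, confidence: float = 0.95) -> EllipseSummary:
    """Confidence ellipse and quadrant shares of the incremental cloud.

    The ellipse is the bivariate-normal region at the requested
    confidence on (dC, dU); for normally distributed draws the fraction
    of points inside approaches the nominal level.  Quadrants are labeled
    on the cost-effectiveness plane with dU on the x-axis and dC on the
    y-axis (NE: dU > 0, dC > 0 — the tradeoff quadrant; SE: dU > 0,
    dC <= 0 — alt dominates).
    """
    if result.n_iterations < 3:
        raise ValueError("need at least 3 draws for an ellipse")
    xy = np.column_stack([result.delta_utility, result.delta_cost])
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    q = stats.chi2.ppf(confidence, df=2)
    degenerate = bool(np.linalg.matrix_rank(cov) < 2)
    if degenerate:
        inside = float(np.all(xy == xy[0]))
        evals = np.zeros(2)
        angle = 0.0
    else:
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        centered = xy - center
        d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(cov), centered)
        inside = float((d2 <= q).mean())
    du, dc = result.delta_utility, result.delta_cost
    n = result.n_iterations
    shares = {
        "NE": float(np.count_nonzero((du > 0) & (dc > 0)) / n),
        "SE": float(np.count_nonzero((du > 0) & (dc <= 0)) / n),
        "NW": float(np.count_nonzero((du <= 0) & (dc > 0)) / n),
        "SW": float(np.count_nonzero((du <= 0) & (dc <= 0)) / n),
    }
    return EllipseSummary(
        center=(float(center[0]), float(center[1])),
        axes=(float(np.sqrt(q * evals[0])), float(np.sqrt(q * evals[1]))),
        angle_deg=angle,
        confidence=confidence,
        inside_fraction=inside,
        quadrant_shares=shares,
        degenerate=degenerate,
    )


def deterministic_delta(ref: StrategyParams, alt: StrategyParams) -> tuple[float, float]:
    """Base-case (dC, dU) used as the convergence target of the PSA mean."""
    r, a = evaluate_strategy(ref), evaluate_strategy(alt)
    return a.expected_cost - r.expected_cost, a.expected_utility - r.expected_utility
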