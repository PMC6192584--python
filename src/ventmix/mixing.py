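"""Bayesian stable-isotope mixing model for diet proportions.

The model follows the single-observation form of the SIAR family of mixing
models.  A consumer's tissue value for isotope j is

    X_j ~ Normal(m_j, s_j^2)
    m_j   = sum_k p_k (mu_jk + D_jk)
    s_j^2 = sum_k p_k^2 (omega_jk^2 + tau_jk^2)

where p is the diet-proportion vector on the K-simplex, mu_jk / omega_jk are
the source means / SDs, and D_jk / tau_jk the trophic discrimination factor
(TDF) means / SDs.  The prior on p is Dirichlet(alpha), flat by default.
With concentration dependence enabled the mixture weights become
p_k q_jk / sum_k p_k q_jk for elemental concentrations q_jk.

Inference is by adaptive random-walk Metropolis on the isometric log-ratio
(ILR) transform of p (Jacobian-corrected), run as several independent chains;
``grid_posterior_mean`` provides a deterministic simplex-lattice quadrature
oracle for small K, and ``analytic_two_source_point`` the closed-form
single-isotope two-source mass balance.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .core import (
    ISOTOPES,
    CapabilityError,
    ConsumerObservation,
    DegenerateModelError,
    SourcePool,
    TDFSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MixingProblem",
    "MixingResult",
    "log_unnormalized_posterior",
    "fit_mixing",
    "grid_posterior_mean",
    "analytic_two_source_point",
    "ilr",
    "ilr_inv",
]

_SIMPLEX_TOL = 1e-8


# ---------------------------------------------------------------------------
# Problem definition
# ---------------------------------------------------------------------------

@dataclass
class MixingProblem:
    """Consumers, candidate sources, TDFs and prior: the unit of inference.

    ``tdf`` may be a single :class:`TDFSet` applied to every source (the
    default guild-based convention) or a per-source sequence.
    """

    sources: Sequence[SourcePool]
    tdf: TDFSet | Sequence[TDFSet]
    consumers: Sequence[ConsumerObservation]
    alpha: Optional[Sequence[float]] = None
    concentration_dependent: bool = False

    def __post_init__(self) -> None:
        self.sources = list(self.sources)
        self.consumers = list(self.consumers)
        K = len(self.sources)
        if K < 2:
            raise ValidationError(f"need at least 2 sources, got {K}")
        if len(self.consumers) < 1:
            raise ValidationError("need at least one consumer")
        names = [s.name for s in self.sources]
        if len(set(names)) != K:
            raise ValidationError(f"source names must be unique, got {names}")
        for s in self.sources:
            for iso in ISOTOPES:
                if s.sd(iso) is None:
                    raise ValidationError(
                        f"source {s.name!r} has an undefined SD for {iso}; "
                        "single-replicate sources need an explicit SD"
                    )
        if isinstance(self.tdf, TDFSet):
            self._tdfs = [self.tdf] * K
        else:
            self._tdfs = list(self.tdf)
            if len(self._tdfs) != K:
                raise ValidationError(
                    f"per-source TDF list has length {len(self._tdfs)}, "
                    f"expected {K}"
                )
        if self.alpha is None:
            self.alpha = np.ones(K)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (K,) or np.any(self.alpha <= 0):
            raise ValidationError(
                "prior concentration alpha must be length-K with all entries > 0"
            )

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


class _Packed:
    """Dense arrays for the likelihood; isotope axis ordered as ISOTOPES."""

    def __init__(self, problem: MixingProblem):
        K = problem.n_sources
        J = len(ISOTOPES)
        self.mu = np.empty((J, K))
        self.var_src = np.empty((J, K))  # omega^2
        self.dlt = np.empty((J, K))
        self.var_tdf = np.empty((J, K))  # tau^2
        self.q = np.ones((J, K))
        for k, (src, tdf) in enumerate(zip(problem.sources, problem._tdfs)):
            for j, iso in enumerate(ISOTOPES):
                self.mu[j, k] = src.mean(iso)
                self.var_src[j, k] = src.sd(iso) ** 2
                self.dlt[j, k] = tdf.mean(iso)
                self.var_tdf[j, k] = tdf.sd(iso) ** 2
                if src.concentration is not None:
                    self.q[j, k] = src.concentration[iso]
        self.shifted = self.mu + self.dlt              # (J, K)
        self.total_var = self.var_src + self.var_tdf   # (J, K)
        if np.any(self.total_var.sum(axis=1) == 0.0):
            raise DegenerateModelError(
                "every source has zero variance on at least one isotope; "
                "the mixture variance would be identically zero"
            )
        X = np.array(
            [[c.value(iso) for iso in ISOTOPES] for c in problem.consumers]
        )  # (I, J)
        self.n_obs = X.shape[0]
        self.sum_x = X.sum(axis=0)          # (J,)
        self.sum_x2 = (X ** 2).sum(axis=0)  # (J,)
        self.X = X
        self.conc = problem.concentration_dependent
        self.alpha = np.asarray(problem.alpha, dtype=float)
        # Dirichlet normalizing constant (for the exact log posterior).
        self.log_dir_norm = float(
            gammaln(self.alpha.sum()) - gammaln(self.alpha).sum()
        )


def _moments(P: np.ndarray, packed: _Packed) -> tuple[np.ndarray, np.ndarray]:
    """Mixture mean (n, J) and variance (n, J) for proportion rows P (n, K)."""
    if packed.conc:
        # weights w_jk = p_k q_jk / sum_k p_k q_jk, per isotope
        pw = P[:, None, :] * packed.q[None, :, :]        # (n, J, K)
        W = pw / pw.sum(axis=2, keepdims=True)
        m = np.einsum("njk,jk->nj", W, packed.shifted)
        s2 = np.einsum("njk,jk->nj", W ** 2, packed.total_var)
    else:
        m = P @ packed.shifted.T
        s2 = (P ** 2) @ packed.total_var.T
    return m, s2


_LOG_2PI = math.log(2.0 * math.pi)


def _log_post_rows(P: np.ndarray, packed: _Packed) -> np.ndarray:
    """Log posterior density (up to the evidence) for each proportion row."""
    m, s2 = _moments(P, packed)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = packed.sum_x2[None, :] - 2.0 * m * packed.sum_x[None, :] \
            + packed.n_obs * m ** 2
        ll = -0.5 * packed.n_obs * (_LOG_2PI + np.log(s2)) - sse / (2.0 * s2)
        ll = np.where(s2 > 0.0, ll, -np.inf).sum(axis=1)
        prior = xlogy(packed.alpha - 1.0, P).sum(axis=1)
    bad = np.any(P < 0.0, axis=1) | np.isnan(prior)
    out = packed.log_dir_norm + prior + ll
    out[bad] = -np.inf
    return out


def log_unnormalized_posterior(p: Sequence[float], problem: MixingProblem) -> float:
    """Log of prior × likelihood at a single simplex point ``p``.

    Includes all normalizing constants except the model evidence, so the value
    equals ``log Dirichlet(p | alpha) + sum_ij log Normal(X_ij | m_ij, s_ij^2)``.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (problem.n_sources,):
        raise ValidationError(
            f"p has shape {p.shape}, expected ({problem.n_sources},)"
        )
    if np.any(p < -_SIMPLEX_TOL) or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValidationError(f"p is not on the simplex: {p}")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    packed = _Packed(problem)
    _, s2 = _moments(p[None, :], packed)
    if np.any(s2 == 0.0):
        raise DegenerateModelError(
            "mixture variance is zero at this p; the likelihood is degenerate"
        )
    return float(_log_post_rows(p[None, :], packed)[0])


# ---------------------------------------------------------------------------
# ILR transform (Helmert orthonormal basis)
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=None)
def _helmert_basis_cached(K: int) -> np.ndarray:
    return _helmert_basis_build(K)


def _helmert_basis_build(K: int) -> np.ndarray:
    """Orthonormal (K, K-1) basis of the hyperplane orthogonal to 1."""
    V = np.zeros((K, K - 1))
    for i in range(1, K):
        norm = math.sqrt(i * (i + 1))
        V[:i, i - 1] = 1.0 / norm
        V[i, i - 1] = -i / norm
    return V


def ilr(p: np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates of composition rows (…, K) → (…, K−1)."""
    p = np.asarray(p, dtype=float)
    V = _helmert_basis_cached(p.shape[-1])
    logp = np.log(p)
    clr = logp - logp.mean(axis=-1, keepdims=True)
    return clr @ V


def ilr_inv(z: np.ndarray) -> np.ndarray:
    """Composition rows from ILR coordinates: softmax of the basis expansion."""
    z = np.asarray(z, dtype=float)
    V = _helmert_basis_cached(z.shape[-1] + 1)
    logits = z @ V.T
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MixingResult:
    """Posterior draws and summaries of diet proportions.

    ``draws`` is (n_draws, K) pooled over chains; ``chain_draws`` keeps the
    (chains, kept, K) layout used for split-chain convergence checks.
    """

    source_names: list[str]
    draws: np.ndarray
    chain_draws: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    quantiles: pd.DataFrame  # rows: 2.5%, 50%, 97.5%; columns: sources
    acceptance_rate: np.ndarray  # per chain
    rhat: np.ndarray  # per source
    seed: int
    iterations: int
    burn_in: int
    thin: int
    chains: int
    out_of_polygon: bool
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Per-source posterior mean, SD and credible-interval table."""
        return pd.DataFrame(
            {
                "source": self.source_names,
                "mean": self.mean,
                "sd": self.sd,
                "q2.5": self.quantiles.loc[2.5].to_numpy(),
                "q50": self.quantiles.loc[50.0].to_numpy(),
                "q97.5": self.quantiles.loc[97.5].to_numpy(),
            }
        )


def _out_of_polygon(packed: _Packed) -> bool:
    """Bounding-box screen: any consumer outside the range of TDF-shifted
    source means on either isotope axis cannot be an interior mixture."""
    lo = packed.shifted.min(axis=1)
    hi = packed.shifted.max(axis=1)
    return bool(np.any((packed.X < lo[None, :]) | (packed.X > hi[None, :])))


def fit_mixing(
    problem: MixingProblem,
    iterations: int = 500_000,
    burn_in: Optional[int] = None,
    thin: int = 15,
    chains: int = 4,
    seed: int = 0,
) -> MixingResult:
    """Sample the diet-proportion posterior by adaptive random-walk Metropolis.

    ``iterations`` is the total number of MCMC steps summed over ``chains``
    (the study ran 500,000).  Each chain discards ``burn_in`` steps (default:
    50,000, capped at half the chain length) and keeps every ``thin``-th draw
    afterwards.  The proposal is an isotropic Gaussian step in ILR coordinates
    whose scale adapts toward ~30% acceptance during burn-in and is frozen
    afterwards.  Identical seed and inputs give identical draws.
    """
    import arviz as az

    packed = _Packed(problem)
    K = problem.n_sources
    d = K - 1
    if chains < 1:
        raise ValidationError("need at least one chain")
    n_steps = iterations // chains
    if burn_in is None:
        burn_in = min(50_000, n_steps // 2)
    if not (0 <= burn_in < n_steps):
        raise ValidationError(
            f"burn_in ({burn_in}) must be < per-chain steps ({n_steps})"
        )
    if thin < 1:
        raise ValidationError("thin must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # Overdispersed inits: one chain per prior draw.
    P0 = rng.dirichlet(np.asarray(problem.alpha), size=chains)
    P0 = np.clip(P0, 1e-10, None)
    P0 /= P0.sum(axis=1, keepdims=True)
    Z = ilr(P0)

    def target(Zb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        P = ilr_inv(Zb)
        # +sum(log p): Jacobian of the ILR parameterization.
        return _log_post_rows(P, packed) + np.log(P).sum(axis=1), P

    logp, Pcur = target(Z)
    scale = np.full(chains, 2.38 / math.sqrt(d))
    n_kept = (n_steps - burn_in + thin - 1) // thin
    kept = np.empty((chains, n_kept, K))
    acc_post = np.zeros(chains)
    n_post = 0
    k_idx = 0
    target_acc = 0.30

    for t in range(n_steps):
        eps = rng.standard_normal((chains, d))
        Zprop = Z + scale[:, None] * eps
        lp_prop, P_prop = target(Zprop)
        logr = lp_prop - logp
        accept = np.log(rng.random(chains)) < logr
        Z[accept] = Zprop[accept]
        logp[accept] = lp_prop[accept]
        Pcur[accept] = P_prop[accept]
        if t < burn_in:
            gamma = 1.0 / (t + 10.0) ** 0.6
            acc_prob = np.exp(np.minimum(logr, 0.0))
            scale *= np.exp(gamma * (acc_prob - target_acc))
        else:
            acc_post += accept
            n_post += 1
            if (t - burn_in) % thin == 0:
                kept[:, k_idx, :] = Pcur
                k_idx += 1
    kept = kept[:, :k_idx, :]

    acc_rate = acc_post / max(n_post, 1)
    draws = kept.reshape(-1, K)
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    qs = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    quantiles = pd.DataFrame(
        qs, index=[2.5, 50.0, 97.5], columns=problem.source_names
    )

    if chains >= 2 and k_idx >= 4:
        rhat_ds = az.rhat(az.convert_to_dataset(kept))
        rhat = np.asarray(rhat_ds["x"])
    else:  # split-chain statistic on a single chain
        rhat_ds = az.rhat(az.convert_to_dataset(kept))
        rhat = np.asarray(rhat_ds["x"])

    result_warnings: list[str] = []
    if np.any(rhat > 1.05):
        msg = (
            f"convergence warning: split-chain R-hat max {np.nanmax(rhat):.3f} "
            "> 1.05; consider more iterations"
        )
        result_warnings.append(msg)
        logger.warning(msg)
        _warnings.warn(msg, RuntimeWarning, stacklevel=2)
    oop = _out_of_polygon(packed)
    if oop:
        msg = (
            "out-of-polygon consumer: tissue value outside the range of "
            "TDF-shifted source means on at least one isotope axis"
        )
        result_warnings.append(msg)
        logger.warning(msg)

    logger.info(
        "fit_mixing: K=%d, iterations=%d, chains=%d, seed=%d, "
        "acceptance=%s, rhat=%s",
        K, iterations, chains, seed,
        np.round(acc_rate, 3), np.round(rhat, 4),
    )
    return MixingResult(
        source_names=problem.source_names,
        draws=draws,
        chain_draws=kept,
        mean=mean,
        sd=sd,
        quantiles=quantiles,
        acceptance_rate=acc_rate,
        rhat=rhat,
        seed=seed,
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        chains=chains,
        out_of_polygon=oop,
        warnings=result_warnings,
    )


# ---------------------------------------------------------------------------
# Deterministic oracles
# ---------------------------------------------------------------------------

def _compositions(total: int, parts: int) -> np.ndarray:
    """All nonnegative integer vectors of length ``parts`` summing to ``total``."""
    if parts == 1:
        return np.array([[total]], dtype=np.int64)
    blocks = []
    for first in range(total + 1):
        sub = _compositions(total - first, parts - 1)
        blocks.append(
            np.column_stack([np.full(len(sub), first, dtype=np.int64), sub])
        )
    return np.vstack(blocks)


def grid_posterior_mean(
    problem: MixingProblem, resolution: float = 0.005
) -> np.ndarray:
    """Posterior mean of p by exhaustive simplex-lattice quadrature.

    Enumerates the lattice with step ``resolution``, weights each node by the
    unnormalized posterior density, and returns the normalized expectation.
    Only feasible for K ≤ 4.  Lattice nodes on the simplex boundary are
    dropped when any ``alpha != 1`` (where the Dirichlet density diverges or
    vanishes).
    """
    K = problem.n_sources
    if K > 4:
        raise CapabilityError(
            f"grid enumeration supports K <= 4 sources, got {K}"
        )
    if not (0.0 < resolution <= 0.02):
        raise ValidationError(
            f"resolution must be in (0, 0.02], got {resolution}"
        )
    packed = _Packed(problem)
    N = int(round(1.0 / resolution))
    P = _compositions(N, K).astype(float) / N
    if np.any(packed.alpha != 1.0):
        P = P[np.all(P > 0.0, axis=1)]
    logw = _log_post_rows(P, packed)
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegenerateModelError("posterior weights vanished on the grid")
    return (w[:, None] * P).sum(axis=0) / total


def analytic_two_source_point(
    consumer: ConsumerObservation,
    source1: SourcePool,
    source2: SourcePool,
    tdf: TDFSet,
    isotope: str,
) -> float:
    """Single-isotope two-source mass balance, solved for source1's fraction.

    f = (X − Δ − μ2) / (μ1 − μ2), deliberately unclipped: values outside
    [0, 1] signal a consumer outside the two-source mixing interval.
    """
    mu1 = source1.mean(isotope)
    mu2 = source2.mean(isotope)
    if mu1 == mu2:
        raise ValidationError(
            f"sources {source1.name!r} and {source2.name!r} have equal "
            f"{isotope} means ({mu1}); the mass balance is undefined"
        )
    x = consumer.value(isotope)
    return (x - tdf.mean(isotope) - mu2) / (mu1 - mu2)
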