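"""Bulk-isotope statistics, isotopic-niche ellipses, and diet mixing model.

The mixing model estimates the dietary proportions ``p`` of K food sources
from J-isotope consumer data under the marginalized Gaussian formulation:
for consumer i and isotope j,

    x_ij ~ Normal( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k² (ω_jk² + τ_j²) + σ_j² )

with source means/SDs (μ, ω), trophic enrichment mean/SD (λ, τ) per isotope,
a Dirichlet(α) prior on the proportion simplex, and half-Cauchy residual
scales σ_j.  Sampling is random-walk Metropolis on a softmax
reparameterization of ``p`` (last logit pinned to zero) and on ``log σ``,
with step-size adaptation during burn-in.  The softmax map contributes a
log-Jacobian of ``Σ_k ln p_k``; the log transform of σ contributes ``ln σ``.

The standard ellipse area (SEA) of a bivariate isotope scatter is
``π √(λ₁ λ₂)`` over the covariance eigenvalues; SEAc applies the
small-sample correction ``(n−1)/(n−2)`` and requires n ≥ 3.
"""
from __future__ import annotations

import dataclasses
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SourceDistribution",
    "TrophicEnrichment",
    "EllipseMetrics",
    "MixingPosterior",
    "TEFComparison",
    "group_stats",
    "validate_isotope_table",
    "seac",
    "MixingModel",
    "fit_mixing",
    "tef_alternatives",
]

ISOTOPE_COLUMNS = ("d13C", "d15N", "D14C")


@dataclass(frozen=True)
class SourceDistribution:
    """Per-isotope mean/SD of one candidate food source (end-member)."""

    name: str
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"source {self.name}: sd[{iso}] must be >= 0")


@dataclass(frozen=True)
class TrophicEnrichment:
    """Per-isotope mean/SD of the diet-to-tissue trophic enrichment factor."""

    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"TEF sd[{iso}] must be >= 0")


def validate_isotope_table(df: pd.DataFrame) -> list[str]:
    """Sanity-check isotope values; returns warnings (never raises).

    Typical marine ranges: −40 < δ¹³C < 0 and −5 < δ¹⁵N < 25.  Values
    outside these bounds are flagged as suspicious, not rejected.
    """
    notes: list[str] = []
    if "d13C" in df and ((df["d13C"] <= -40) | (df["d13C"] >= 0)).any():
        notes.append("d13C values outside the typical marine range (-40, 0)")
    if "d15N" in df and ((df["d15N"] <= -5) | (df["d15N"] >= 25)).any():
        notes.append("d15N values outside the typical marine range (-5, 25)")
    for note in notes:
        _warnings.warn(note, stacklevel=2)
    return notes


def group_stats(df: pd.DataFrame, isotopes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-group mean/SD/n for each isotope column.

    SDs use the n−1 denominator; groups with a single sample report the SD
    as missing (NaN) rather than zero so downstream variance math stays
    honest.
    """
    if df.empty:
        raise ValueError("no isotope samples to summarize")
    if isotopes is None:
        isotopes = [c for c in ISOTOPE_COLUMNS if c in df.columns]
    rows = {}
    for group, grp in df.groupby("group", sort=True):
        row: dict[str, float] = {}
        for iso in isotopes:
            vals = grp[iso].dropna().to_numpy()
            row[f"{iso}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{iso}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            row[f"{iso}_n"] = int(vals.size)
        rows[group] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


@dataclass(frozen=True)
class EllipseMetrics:
    sea: float  # permil^2
    seac: float  # permil^2
    a: float  # semi-axis (permil), a >= b
    b: float
    orientation: float  # radians
    n: int
    degenerate: bool = False


def seac(points: np.ndarray | Sequence[Sequence[float]]) -> EllipseMetrics:
    """Standard ellipse area of a bivariate isotope scatter.

    The ellipse is the 1-SD contour of the sample covariance (n−1
    denominator); SEA = π√(λ₁λ₂) over its eigenvalues and
    SEAc = SEA · (n−1)/(n−2).  Fewer than 3 points is an error (the niche
    of such groups is conventionally not reported); an exactly singular
    covariance (collinear points) gives zero area with a degenerate flag.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("seac expects an (n, 2) array of (d13C, d15N) points")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"SEAc requires at least 3 samples, got {n}")
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam2, lam1 = float(max(eigvals[0], 0.0)), float(eigvals[1])
    degenerate = lam2 <= 1e-12 * max(lam1, 1.0)
    sea = 0.0 if degenerate else float(np.pi * np.sqrt(lam1 * lam2))
    major = eigvecs[:, 1]
    return EllipseMetrics(
        sea=sea,
        seac=sea * (n - 1) / (n - 2),
        a=float(np.sqrt(lam1)),
        b=0.0 if degenerate else float(np.sqrt(lam2)),
        orientation=float(np.arctan2(major[1], major[0])),
        n=n,
        degenerate=degenerate,
    )


@dataclass
class MixingPosterior:
    """Posterior draws of diet proportions and residual scales."""

    p_draws: pd.DataFrame  # one column per source, one row per retained draw
    sigma_draws: pd.DataFrame  # one column per isotope (sigma_<iso>)
    acceptance_rate: float
    ess: dict[str, float]
    summary: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_proportions(self) -> pd.Series:
        return self.p_draws.mean()


def _ess_1d(x: np.ndarray) -> float:
    import arviz as az

    out = az.ess(np.asarray(x, dtype=float)[None, :])
    if np.isscalar(out) or isinstance(out, np.generic):
        return float(out)
    return float(next(iter(out.data_vars.values())).values)


def _softmax_full(z: np.ndarray) -> np.ndarray:
    """Map K−1 free logits (last pinned at 0) to the K-simplex."""
    full = np.append(z, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


class MixingModel(BaseEstimator):
    """Bayesian two-isotope diet mixing model (scikit-learn style estimator).

    Parameters
    ----------
    sources : sequence of SourceDistribution
        End-members with per-isotope means and SDs.
    tef : TrophicEnrichment
        Trophic enrichment mean/SD per isotope.
    isotopes : sequence of str
        Isotope columns shared by consumers, sources, and TEF.
    prior_alpha : float
        Symmetric Dirichlet concentration on the proportions (1 = uniform).
    n_iter, burn_in, thin : int
        Total Metropolis iterations, discarded burn-in, thinning stride.
    sigma_prior_scale : float
        Half-Cauchy scale (‰) of the residual SDs.
    target_accept : float
        Acceptance rate targeted by the burn-in step adaptation.
    random_state : int, numpy Generator, or None
        Seed; identical seeds give identical draws.

    Attributes (after ``fit``)
    --------------------------
    source_names_, draws_p_, draws_sigma_, acceptance_rate_, ess_,
    summary_, warnings_, posterior_
    """

    def __init__(
        self,
        sources: Sequence[SourceDistribution] | None = None,
        tef: TrophicEnrichment | None = None,
        isotopes: Sequence[str] = ("d13C", "d15N"),
        prior_alpha: float = 1.0,
        n_iter: int = 40_000,
        burn_in: int = 10_000,
        thin: int = 10,
        sigma_prior_scale: float = 5.0,
        target_accept: float = 0.3,
        random_state=None,
    ):
        self.sources = sources
        self.tef = tef
        self.isotopes = isotopes
        self.prior_alpha = prior_alpha
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.sigma_prior_scale = sigma_prior_scale
        self.target_accept = target_accept
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate(self, X) -> np.ndarray:
        if not self.sources:
            raise ValueError("at least one source is required")
        if self.tef is None:
            raise ValueError("a TrophicEnrichment is required")
        isos = list(self.isotopes)
        for src in self.sources:
            missing = [j for j in isos if j not in src.means or j not in src.sds]
            if missing:
                raise ValueError(
                    f"source {src.name!r} lacks isotopes {missing}: "
                    "consumer/source/TEF isotope sets must match"
                )
        missing = [j for j in isos if j not in self.tef.means or j not in self.tef.sds]
        if missing:
            raise ValueError(f"TEF lacks isotopes {missing}")
        if isinstance(X, pd.DataFrame):
            absent = [j for j in isos if j not in X.columns]
            if absent:
                raise ValueError(f"consumer table lacks isotope columns {absent}")
            X = X[isos].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(isos):
            raise ValueError(
                f"consumer data must be (n, {len(isos)}) for isotopes {isos}"
            )
        if X.shape[0] < 1:
            raise ValueError("at least one consumer sample is required")
        if not np.all(np.isfinite(X)):
            raise ValueError("consumer isotope values must be finite")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        return X

    def _log_post(self, z, logsig, consts):
        n, xbar, S, mu, om2, lam, tau2, alpha, hc_scale = consts
        p = _softmax_full(z)
        sig = np.exp(logsig)
        m = (mu + lam[:, None]) @ p
        v = (om2 + tau2[:, None]) @ (p**2) + sig**2
        loglik = float(
            np.sum(-0.5 * n * np.log(2.0 * np.pi * v) - (S + n * (xbar - m) ** 2) / (2.0 * v))
        )
        # Dirichlet prior + softmax Jacobian
        logprior = float(np.sum((alpha - 1.0) * np.log(p)) + np.sum(np.log(p)))
        # half-Cauchy prior on sigma + log-transform Jacobian
        logprior += float(
            np.sum(
                np.log(2.0 / (np.pi * hc_scale * (1.0 + (sig / hc_scale) ** 2)))
                + logsig
            )
        )
        return loglik + logprior

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None):
        """Sample the posterior given consumer isotope data ``X``."""
        X = self._validate(X)
        isos = list(self.isotopes)
        names = [s.name for s in self.sources]
        K, J, n = len(names), len(isos), X.shape[0]
        rng = np.random.default_rng(self.random_state)

        xbar = X.mean(axis=0)
        S = ((X - xbar) ** 2).sum(axis=0)
        mu = np.array([[s.means[j] for s in self.sources] for j in isos])
        om2 = np.array([[s.sds[j] ** 2 for s in self.sources] for j in isos])
        lam = np.array([self.tef.means[j] for j in isos])
        tau2 = np.array([self.tef.sds[j] ** 2 for j in isos])
        consts = (n, xbar, S, mu, om2, lam, tau2, self.prior_alpha, self.sigma_prior_scale)

        resid_sd = np.sqrt(np.maximum(S / max(n - 1, 1), 0.01))
        z = np.zeros(K - 1)
        logsig = np.log(resid_sd)
        lp = self._log_post(z, logsig, consts)

        # Metropolis-within-Gibbs: the proportion logits and the residual
        # log-scales form separate blocks with independently adapted steps.
        steps = np.array([0.5, 0.5])
        keep = (self.n_iter - self.burn_in) // self.thin
        draws_p = np.empty((keep, K))
        draws_sig = np.empty((keep, J))
        accepted_post = 0
        post_steps = 0
        acc_window = np.zeros(2)
        kept = 0
        for it in range(self.n_iter):
            if K > 1:  # block 1: proportions
                z_new = z + steps[0] * rng.standard_normal(K - 1)
                lp_new = self._log_post(z_new, logsig, consts)
                if np.log(rng.uniform()) < lp_new - lp:
                    z, lp = z_new, lp_new
                    acc_window[0] += 1
                    if it >= self.burn_in:
                        accepted_post += 1
            # block 2: residual scales
            logsig_new = logsig + steps[1] * rng.standard_normal(J)
            lp_new = self._log_post(z, logsig_new, consts)
            if np.log(rng.uniform()) < lp_new - lp:
                logsig, lp = logsig_new, lp_new
                acc_window[1] += 1
                if it >= self.burn_in:
                    accepted_post += 1
            if it >= self.burn_in:
                post_steps += 2 if K > 1 else 1
                offset = it - self.burn_in
                if offset % self.thin == 0 and kept < keep:
                    draws_p[kept] = _softmax_full(z)
                    draws_sig[kept] = np.exp(logsig)
                    kept += 1
            elif (it + 1) % 50 == 0:  # burn-in step adaptation per block
                rates = acc_window / 50.0
                steps *= np.exp(0.5 * (rates - self.target_accept))
                steps = np.clip(steps, 1e-3, 10.0)
                acc_window[:] = 0

        draws_p = draws_p[:kept]
        draws_sig = draws_sig[:kept]
        self.source_names_ = names
        self.isotopes_ = isos
        self.n_consumers_ = n
        self.draws_p_ = draws_p
        self.draws_sigma_ = draws_sig
        self.acceptance_rate_ = accepted_post / max(post_steps, 1)
        self.step_sizes_ = steps

        ess = {}
        warnings_list: list[str] = []
        for k, name in enumerate(names):
            ess[name] = _ess_1d(draws_p[:, k]) if K > 1 else float(len(draws_p))
            if ess[name] < 100:
                msg = f"effective sample size {ess[name]:.0f} < 100 for p[{name}]"
                warnings_list.append(msg)
                _warnings.warn(msg, stacklevel=2)
        for j, iso in enumerate(isos):
            ess[f"sigma_{iso}"] = _ess_1d(draws_sig[:, j])
        self.ess_ = ess
        self.warnings_ = warnings_list

        cols = {name: draws_p[:, k] for k, name in enumerate(names)}
        cols.update({f"sigma_{iso}": draws_sig[:, j] for j, iso in enumerate(isos)})
        all_draws = pd.DataFrame(cols)
        q = all_draws.quantile([0.025, 0.5, 0.975]).T
        q.columns = ["q2.5", "q50", "q97.5"]
        summary = pd.DataFrame(
            {"mean": all_draws.mean(), "sd": all_draws.std(ddof=1)}
        ).join(q)
        summary["ess"] = pd.Series(ess)
        self.summary_ = summary
        self.posterior_ = MixingPosterior(
            p_draws=all_draws[names],
            sigma_draws=all_draws[[f"sigma_{iso}" for iso in isos]],
            acceptance_rate=self.acceptance_rate_,
            ess=ess,
            summary=summary,
            warnings=warnings_list,
        )
        return self


def fit_mixing(
    consumers,
    sources: Sequence[SourceDistribution],
    tef: TrophicEnrichment,
    prior_alpha: float = 1.0,
    n_iter: int = 40_000,
    burn_in: int = 10_000,
    thin: int = 10,
    seed=None,
    **kwargs,
) -> MixingPosterior:
    """Functional wrapper around :class:`MixingModel`; returns the posterior."""
    model = MixingModel(
        sources=sources,
        tef=tef,
        prior_alpha=prior_alpha,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        random_state=seed,
        **kwargs,
    )
    return model.fit(consumers).posterior_


@dataclass
class TEFComparison:
    posteriors: dict[str, MixingPosterior]
    shifts: pd.DataFrame | None  # posterior-mean change vs the first scenario


def tef_alternatives(
    consumers,
    sources: Sequence[SourceDistribution],
    tef_scenarios: Mapping[str, TrophicEnrichment],
    seed=None,
    **kwargs,
) -> TEFComparison:
    """Fit the mixing model under alternative TEF scenarios.

    The shift table reports, per scenario and source, the change in the
    posterior mean proportion relative to the first scenario.  With a single
    source the proportions are fixed at 1 and shifts are reported absent.
    """
    if not tef_scenarios:
        raise ValueError("at least one TEF scenario is required")
    # common random numbers across scenarios: the comparison is paired, and
    # identical scenarios yield exactly identical posteriors
    posteriors = {
        name: fit_mixing(consumers, sources, tef, seed=seed, **kwargs)
        for name, tef in tef_scenarios.items()
    }
    if len(sources) < 2:
        return TEFComparison(posteriors=posteriors, shifts=None)
    means = pd.DataFrame(
        {name: post.mean_proportions for name, post in posteriors.items()}
    ).T
    shifts = means - means.iloc[0]
    return TEFComparison(posteriors=posteriors, shifts=shifts)
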