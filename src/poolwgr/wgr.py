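"""Whole-genome regression models: BayesA and the multilevel partial-pooling model.

Both models regress standardized phenotypes on centered marker genotypes,

    y_i ~ N(mu_i, sigma_e^2),    mu_i = beta_0 + sum_k z_ik u_k        (BayesA)
    y_ij ~ N(mu_ij, sigma_e^2),  mu_ij = beta_0 + sum_k z_ijk u_jk     (multilevel)

where in the multilevel model the population-specific effects are shrunk
toward overall effects through the hierarchy

    u_jk ~ N(u_k, gamma_k^2),    u_k ~ N(0, sigma_k^2),
    sigma_k^2 ~ scaled-inv-chi^2(4.001, S^2),    gamma_k ~ N(m, d^2)+,

with Uniform(0.001, 0.5) hyperpriors on S^2, m and d, and a Uniform(0, 1)
prior on sigma_e.  A specific effect u_jk is only estimated when marker k is
polymorphic in population j; otherwise it is pinned to zero and treated as a
constant.  The posterior mean of the truncated-Normal mean of N(m, d^2)+ — the
"typical" deviation of specific from overall effects — quantifies how much the
populations' marker effects diverge.

BayesA keeps the classical conjugate prior stack (u_k ~ N(0, sigma_k^2),
sigma_k^2 ~ scaled-inv-chi^2(4.001, S^2)) with, by default, a Gamma(1.1, 1.1)
hyperprior on S^2 and an improper scaled-inv-chi^2(-1, 0) prior on the
residual variance.

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn tooling; :func:`fit_bayesa` and :func:`fit_multilevel` are thin
functional wrappers returning the posterior objects directly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import _samplers
from .diagnostics import effective_sample_size, truncated_normal_mean
from .popgen import CenteredGenotypes

__all__ = [
    "ChainSettings",
    "BayesAPosterior",
    "MultilevelPosterior",
    "BayesARegressor",
    "MultilevelRegressor",
    "fit_bayesa",
    "fit_multilevel",
]

_PRESETS = {
    # chain length settings used for the reported analyses
    "paper": dict(n_samples=1000, burn_in=10_000, thin=500),
    # short chains for interactive work and the test suite
    "desk": dict(n_samples=500, burn_in=2000, thin=10),
}


@dataclass(frozen=True)
class ChainSettings:
    """Single-chain MCMC run lengths: retained samples, burn-in and thinning."""

    n_samples: int = 500
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("need n_samples >= 1, burn_in >= 0, thin >= 1")
        if self.total_iterations >= 2**31:
            raise ValueError("chain length overflows the iteration counter")

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.n_samples * self.thin

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0) -> "ChainSettings":
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        return cls(seed=seed, **_PRESETS[preset])


def _as_matrix(Z):
    if isinstance(Z, CenteredGenotypes):
        return np.ascontiguousarray(Z.values, dtype=float), Z.marker_ids
    Z = np.ascontiguousarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (lines x markers)")
    return Z, None


def _check_y(y, n):
    y = np.ascontiguousarray(y, dtype=float).ravel()
    if y.size != n:
        raise ValueError("phenotype length must match genotype rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes contain non-finite values")
    if abs(y.mean()) > 0.01 or abs(y.std() - 1.0) > 0.05:
        warnings.warn(
            "phenotypes do not look standardized (mean 0, unit variance); "
            "the priors assume a standardized scale",
            UserWarning,
            stacklevel=3,
        )
    return y


def _ess_safe(x):
    try:
        return effective_sample_size(x)
    except ValueError:
        return float("nan")


@dataclass(frozen=True)
class BayesAPosterior:
    """Retained BayesA samples, posterior means and per-parameter ESS."""

    beta0: np.ndarray  # (S,)
    u: np.ndarray  # (S, K)
    sigma_k2: np.ndarray  # (S, K)
    scale: np.ndarray  # (S,) S^2
    sigma_e2: np.ndarray  # (S,)
    settings: ChainSettings
    seed: int

    @property
    def n_retained(self) -> int:
        return int(self.beta0.size)

    @property
    def effect_means(self) -> np.ndarray:
        return self.u.mean(axis=0)

    @property
    def intercept_mean(self) -> float:
        return float(self.beta0.mean())

    def ess(self, include_effects: bool = True) -> dict[str, float]:
        out = {
            "beta0": _ess_safe(self.beta0),
            "S2": _ess_safe(self.scale),
            "sigma_e2": _ess_safe(self.sigma_e2),
        }
        if include_effects:
            for k in range(self.u.shape[1]):
                out[f"u[{k}]"] = _ess_safe(self.u[:, k])
                out[f"sigma_k2[{k}]"] = _ess_safe(self.sigma_k2[:, k])
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {"beta0": self.beta0, "S2": self.scale, "sigma_e2": self.sigma_e2}
        for k in range(self.u.shape[1]):
            cols[f"u[{k}]"] = self.u[:, k]
        for k in range(self.u.shape[1]):
            cols[f"sigma_k2[{k}]"] = self.sigma_k2[:, k]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "model": "bayesa",
            "n_retained": self.n_retained,
            "settings": {
                "n_samples": self.settings.n_samples,
                "burn_in": self.settings.burn_in,
                "thin": self.settings.thin,
            },
            "seed": int(self.seed),
            "posterior_means": {
                "beta0": self.intercept_mean,
                "S2": float(self.scale.mean()),
                "sigma_e2": float(self.sigma_e2.mean()),
                "u": self.effect_means.tolist(),
            },
            "ess": self.ess(include_effects=False),
        }


@dataclass(frozen=True)
class MultilevelPosterior:
    """Retained multilevel samples, posterior means, ESS and the divergence metric."""

    beta0: np.ndarray  # (S,)
    u_overall: np.ndarray  # (S, K)
    u_specific: np.ndarray  # (S, P, K)
    sigma_k2: np.ndarray  # (S, K)
    gamma: np.ndarray  # (S, K)
    m: np.ndarray  # (S,)
    d: np.ndarray  # (S,)
    scale: np.ndarray  # (S,) S^2
    sigma_e: np.ndarray  # (S,)
    estimated: np.ndarray  # (P, K) bool
    populations: np.ndarray  # (P,) labels
    settings: ChainSettings
    seed: int
    gamma_pinned: float | None = None
    divergence: np.ndarray = field(init=False)

    def __post_init__(self):
        # per-draw divergence metric: mean of N(m, d^2)+ (the "typical"
        # deviation of specific from overall marker effects)
        object.__setattr__(self, "divergence", truncated_normal_mean(self.m, self.d))

    @property
    def n_retained(self) -> int:
        return int(self.beta0.size)

    @property
    def active_markers(self) -> np.ndarray:
        return self.estimated.any(axis=0)

    @property
    def overall_effect_means(self) -> np.ndarray:
        return self.u_overall.mean(axis=0)

    @property
    def specific_effect_means(self) -> np.ndarray:
        return self.u_specific.mean(axis=0)

    @property
    def divergence_mean(self) -> float:
        return float(self.divergence.mean())

    def ess(self, include_effects: bool = True) -> dict[str, float]:
        pinned = self.gamma_pinned is not None
        out = {
            "beta0": _ess_safe(self.beta0),
            "S2": _ess_safe(self.scale),
            "sigma_e": _ess_safe(self.sigma_e),
        }
        if not pinned:
            out["m"] = _ess_safe(self.m)
            out["d"] = _ess_safe(self.d)
            out["divergence"] = _ess_safe(self.divergence)
        if include_effects:
            active = self.active_markers
            for k in np.flatnonzero(active):
                out[f"u[{k}]"] = _ess_safe(self.u_overall[:, k])
                out[f"sigma_k2[{k}]"] = _ess_safe(self.sigma_k2[:, k])
                if not pinned:
                    out[f"gamma[{k}]"] = _ess_safe(self.gamma[:, k])
                for j in range(self.estimated.shape[0]):
                    if self.estimated[j, k]:
                        out[f"u[{self.populations[j]},{k}]"] = _ess_safe(
                            self.u_specific[:, j, k]
                        )
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "beta0": self.beta0,
            "m": self.m,
            "d": self.d,
            "S2": self.scale,
            "sigma_e": self.sigma_e,
            "divergence": self.divergence,
        }
        K = self.u_overall.shape[1]
        for k in range(K):
            cols[f"u[{k}]"] = self.u_overall[:, k]
        for j, p in enumerate(self.populations):
            for k in range(K):
                if self.estimated[j, k]:
                    cols[f"u[{p},{k}]"] = self.u_specific[:, j, k]
        for k in range(K):
            cols[f"gamma[{k}]"] = self.gamma[:, k]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "model": "multilevel",
            "n_retained": self.n_retained,
            "settings": {
                "n_samples": self.settings.n_samples,
                "burn_in": self.settings.burn_in,
                "thin": self.settings.thin,
            },
            "seed": int(self.seed),
            "posterior_means": {
                "beta0": float(self.beta0.mean()),
                "m": float(self.m.mean()),
                "d": float(self.d.mean()),
                "S2": float(self.scale.mean()),
                "sigma_e": float(self.sigma_e.mean()),
                "divergence": self.divergence_mean,
                "u_overall": self.overall_effect_means.tolist(),
            },
            "ess": self.ess(include_effects=False),
        }


class BayesARegressor(BaseEstimator, RegressorMixin):
    """BayesA whole-genome regression (conjugate single-chain Gibbs sampler).

    Parameters
    ----------
    n_samples, burn_in, thin : chain run lengths (ignored if ``preset`` given).
    preset : ``"paper"`` (1000 / 10000 / 500) or ``"desk"`` (500 / 2000 / 10).
    df : prior degrees of freedom of the scaled-inv-chi^2 on sigma_k^2.
    s2_prior : ``"gamma"`` for the conjugate Gamma(s2_shape, s2_rate)
        hyperprior on S^2, or ``"uniform"`` for a Uniform(hyper_lower,
        hyper_upper) prior sampled by slice sampling (the multilevel model's
        choice).
    random_state : integer seed of the chain.

    Fitted attributes: ``coef_`` (posterior-mean marker effects),
    ``intercept_``, ``posterior_`` (full :class:`BayesAPosterior`).
    """

    def __init__(
        self,
        n_samples: int = 500,
        burn_in: int = 2000,
        thin: int = 10,
        preset: str | None = None,
        df: float = 4.001,
        s2_prior: str = "gamma",
        s2_shape: float = 1.1,
        s2_rate: float = 1.1,
        hyper_lower: float = 0.001,
        hyper_upper: float = 0.5,
        intercept_prior_variance: float = 1e6,
        slice_width: float = 0.1,
        max_stepout: int = 50,
        random_state: int = 0,
    ):
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.thin = thin
        self.preset = preset
        self.df = df
        self.s2_prior = s2_prior
        self.s2_shape = s2_shape
        self.s2_rate = s2_rate
        self.hyper_lower = hyper_lower
        self.hyper_upper = hyper_upper
        self.intercept_prior_variance = intercept_prior_variance
        self.slice_width = slice_width
        self.max_stepout = max_stepout
        self.random_state = random_state

    def _settings(self) -> ChainSettings:
        seed = int(self.random_state) % (2**31)
        if self.preset is not None:
            return ChainSettings.from_preset(self.preset, seed=seed)
        return ChainSettings(self.n_samples, self.burn_in, self.thin, seed)

    def fit(self, X, y):
        Z, marker_ids = _as_matrix(X)
        y = _check_y(y, Z.shape[0])
        if self.s2_prior not in ("gamma", "uniform"):
            raise ValueError("s2_prior must be 'gamma' or 'uniform'")
        st = self._settings()
        beta0, u, sig2, scale, sige2 = _samplers.bayesa_chain(
            Z,
            y,
            st.n_samples,
            st.burn_in,
            st.thin,
            st.seed,
            float(self.df),
            self.s2_prior == "uniform",
            float(self.s2_shape),
            float(self.s2_rate),
            float(self.hyper_lower),
            float(self.hyper_upper),
            float(self.intercept_prior_variance),
            float(self.slice_width),
            int(self.max_stepout),
        )
        self.posterior_ = BayesAPosterior(beta0, u, sig2, scale, sige2, st, st.seed)
        self.coef_ = self.posterior_.effect_means
        self.intercept_ = self.posterior_.intercept_mean
        self.marker_ids_ = marker_ids
        self.n_features_in_ = Z.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")
        Z, marker_ids = _as_matrix(X)
        if Z.shape[1] != self.n_features_in_:
            raise ValueError("marker count differs from the fitted model")
        if (
            marker_ids is not None
            and self.marker_ids_ is not None
            and np.any(marker_ids != self.marker_ids_)
        ):
            raise ValueError("marker ids differ from the fitted model")
        return self.intercept_ + Z @ self.coef_


class MultilevelRegressor(BaseEstimator, RegressorMixin):
    """Bayesian multilevel whole-genome regression for partial pooling.

    ``fit`` requires per-line population labels.  Specific effects u_jk are
    estimated only where marker k is polymorphic in population j; markers
    monomorphic in the entire training set are excluded from the hierarchy and
    their effects pinned to zero.

    ``pin_gamma`` fixes every gamma_k at a constant (skipping the gamma, m and
    d updates) — a diagnostic mode in which the model collapses toward BayesA
    as ``pin_gamma`` tends to zero.

    Fitted attributes: ``coef_overall_`` (posterior-mean u_k, used to predict
    lines from populations absent from training), ``coef_specific_``
    (populations x markers posterior-mean u_jk), ``divergence_`` (posterior
    mean of the truncated-Normal mean of N(m, d^2)+), ``posterior_``.
    """

    def __init__(
        self,
        n_samples: int = 500,
        burn_in: int = 2000,
        thin: int = 10,
        preset: str | None = None,
        df: float = 4.001,
        hyper_lower: float = 0.001,
        hyper_upper: float = 0.5,
        sigma_e_upper: float = 1.0,
        intercept_prior_variance: float = 1e6,
        pin_gamma: float | None = None,
        slice_width: float = 0.1,
        max_stepout: int = 50,
        random_state: int = 0,
    ):
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.thin = thin
        self.preset = preset
        self.df = df
        self.hyper_lower = hyper_lower
        self.hyper_upper = hyper_upper
        self.sigma_e_upper = sigma_e_upper
        self.intercept_prior_variance = intercept_prior_variance
        self.pin_gamma = pin_gamma
        self.slice_width = slice_width
        self.max_stepout = max_stepout
        self.random_state = random_state

    def _settings(self) -> ChainSettings:
        seed = int(self.random_state) % (2**31)
        if self.preset is not None:
            return ChainSettings.from_preset(self.preset, seed=seed)
        return ChainSettings(self.n_samples, self.burn_in, self.thin, seed)

    def fit(self, X, y, populations=None):
        if populations is None:
            raise ValueError("fit requires per-line population labels")
        Z, marker_ids = _as_matrix(X)
        y = _check_y(y, Z.shape[0])
        labels = np.asarray(populations, dtype=np.int64).ravel()
        if labels.size != Z.shape[0]:
            raise ValueError("one population label per line is required")

        order = np.argsort(labels, kind="stable")
        Zs, ys, ls = Z[order], y[order], labels[order]
        pops, starts = np.unique(ls, return_index=True)
        pop_start = starts.astype(np.int64)
        pop_end = np.append(pop_start[1:], ls.size).astype(np.int64)

        P, K = pops.size, Z.shape[1]
        est = np.zeros((P, K), dtype=np.uint8)
        for j in range(P):
            block = Zs[pop_start[j] : pop_end[j]]
            est[j] = (block.max(axis=0) - block.min(axis=0)) > 1e-12
        if np.any(est.sum(axis=1) == 0):
            bad = pops[np.flatnonzero(est.sum(axis=1) == 0)]
            raise ValueError(f"population(s) {bad.tolist()} have no polymorphic marker")

        st = self._settings()
        pin = -1.0 if self.pin_gamma is None else float(self.pin_gamma)
        if self.pin_gamma is not None and pin <= 0:
            raise ValueError("pin_gamma must be positive")
        out = _samplers.multilevel_chain(
            np.ascontiguousarray(Zs),
            np.ascontiguousarray(ys),
            pop_start,
            pop_end,
            est,
            st.n_samples,
            st.burn_in,
            st.thin,
            st.seed,
            float(self.df),
            float(self.hyper_lower),
            float(self.hyper_upper),
            float(self.sigma_e_upper),
            float(self.intercept_prior_variance),
            pin,
            float(self.slice_width),
            int(self.max_stepout),
        )
        beta0, u, ujk, sig2, gamma, m, d, scale, sige = out
        self.posterior_ = MultilevelPosterior(
            beta0,
            u,
            ujk,
            sig2,
            gamma,
            m,
            d,
            scale,
            sige,
            est.astype(bool),
            pops,
            st,
            st.seed,
            gamma_pinned=self.pin_gamma,
        )
        self.populations_ = pops
        self.coef_overall_ = self.posterior_.overall_effect_means
        self.coef_specific_ = self.posterior_.specific_effect_means
        self.intercept_ = float(beta0.mean())
        self.divergence_ = self.posterior_.divergence_mean
        self.marker_ids_ = marker_ids
        self.n_features_in_ = K
        return self

    def predict(self, X, populations=None):
        """GEBVs from posterior-mean effects.

        Lines whose population was in the training set use its specific
        effects u_jk; lines without a label (or from a new population) use the
        overall effects u_k.
        """
        if not hasattr(self, "coef_overall_"):
            raise AttributeError("estimator is not fitted")
        Z, marker_ids = _as_matrix(X)
        if Z.shape[1] != self.n_features_in_:
            raise ValueError("marker count differs from the fitted model")
        if (
            marker_ids is not None
            and self.marker_ids_ is not None
            and np.any(marker_ids != self.marker_ids_)
        ):
            raise ValueError("marker ids differ from the fitted model")
        yhat = self.intercept_ + Z @ self.coef_overall_
        if populations is not None:
            labels = np.asarray(populations, dtype=np.int64).ravel()
            if labels.size != Z.shape[0]:
                raise ValueError("one population label per line is required")
            row = {int(p): j for j, p in enumerate(self.populations_)}
            for p in np.unique(labels):
                if int(p) in row:
                    rows = labels == p
                    yhat[rows] = self.intercept_ + Z[rows] @ self.coef_specific_[row[int(p)]]
        return yhat


def fit_bayesa(y, Z, settings: ChainSettings | None = None, **params) -> BayesAPosterior:
    """Fit BayesA to standardized phenotypes; returns the posterior."""
    st = settings or ChainSettings()
    est = BayesARegressor(
        n_samples=st.n_samples,
        burn_in=st.burn_in,
        thin=st.thin,
        random_state=st.seed,
        **params,
    )
    est.fit(Z, y)
    return est.posterior_


def fit_multilevel(
    y, Z, population_labels, settings: ChainSettings | None = None, **params
) -> MultilevelPosterior:
    """Fit the multilevel partial-pooling model; returns the posterior."""
    st = settings or ChainSettings()
    est = MultilevelRegressor(
        n_samples=st.n_samples,
        burn_in=st.burn_in,
        thin=st.thin,
        random_state=st.seed,
        **params,
    )
    est.fit(Z, y, populations=population_labels)
    return est.posterior_
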