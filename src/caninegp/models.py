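"""Whole-genome regression models for genomic prediction.

Two models are implemented, both with sex and breed as fixed effects:

* :class:`GBLUP` — the mixed linear model ``y = mu + X beta + Z g + e`` with
  ``g ~ N(0, K sigma_g^2)`` for a genomic relationship matrix K and
  ``e ~ N(0, I sigma_e^2)``. Fitted either exactly (Henderson's mixed-model
  equations at given variance components, or REML-estimated components via
  the eigendecomposition of K) or by a Gibbs sampler in the eigenbasis of K.

* :class:`BayesC` — marker-effect regression ``y = mu + X beta + W alpha + e``
  where each effect alpha_j has a spike-and-slab prior: a point mass at zero
  with probability 1 - pi and N(0, sigma_a^2) with probability pi. Fitted by
  a single-site Gibbs sampler with scaled-inverse-chi-square priors on the
  variances and a Beta full conditional for pi.

Both fits return results objects carrying estimates, posterior summaries and
a ``summary()`` table, statsmodels-style. Binary traits are fitted with the
same Gaussian likelihood on the 0/1 coding (no threshold/probit link);
predictions for binary traits are continuous scores to be ranked (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data import GenotypeMatrix, PhenotypeVector
from .design import FixedEffectsDesign, build_design
from .kinship import KinshipMatrix, centered_dosages

__all__ = [
    "VarianceComponents", "ChainConfig", "BayesCPriors",
    "GBLUP", "GBLUPResults", "BayesC", "BayesCResults",
    "fit_gblup_closed_form", "fit_gblup_gibbs", "fit_bayesc",
]

_EIG_TOL = 1e-10  # relative eigenvalue threshold for the K-range basis


class DegeneratePhenotypeError(ValueError):
    """Constant phenotype: variance components are unidentifiable."""


class MarkerAlignmentError(ValueError):
    """Validation marker set does not match the training panel."""


@dataclass(frozen=True)
class VarianceComponents:
    """Genetic and residual variances; ``h2 = sigma_g2 / (sigma_g2 + sigma_e2)``."""

    sigma_g2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0")

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings (defaults are deliberately longer than common
    shipped defaults, which are too short for stable posterior means)."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def kept(self) -> np.ndarray:
        return np.arange(self.burn_in, self.n_iter, self.thin)


@dataclass(frozen=True)
class BayesCPriors:
    """Hyperparameters of the BayesC spike-and-slab sampler.

    ``pi0``/``pi_weight`` parameterize the Beta prior on the inclusion
    probability (counts ``pi0*pi_weight`` and ``(1-pi0)*pi_weight``);
    ``r2`` is the prior proportion of phenotypic variance attributed to
    markers, used to set the scaled-inverse-chi-square scales so the prior
    modes split var(y) accordingly. ``fix_*`` pin a parameter at its
    starting value (used for the ridge-regression limit pi = 1).
    """

    pi0: float = 0.5
    pi_weight: float = 10.0
    df_e: float = 5.0
    df_a: float = 5.0
    r2: float = 0.5
    fix_pi: bool = False
    fix_sigma_a2: float | None = None
    fix_sigma_e2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in (0, 1]")


def _scaled_inv_chi2(rng: np.random.Generator, df: float, ss: float) -> float:
    """Draw from ScaledInvChi2(df, ss/df), i.e. ss / chi2(df)."""
    return ss / rng.chisquare(df)


# ===========================================================================
# GBLUP


class GBLUP:
    """Genomic BLUP model over a fixed sample set.

    Parameters
    ----------
    y : PhenotypeVector or array aligned with ``kinship.sample_ids``.
    kinship : KinshipMatrix over *all* samples (training and any dogs to be
        predicted later); prediction for non-training dogs uses the
        conditional expectation through the joint kinship.
    breed, sex : optional per-sample factors fitted as fixed effects
        (treatment coding, reference = alphabetically first training level).
    train_idx : indices of the samples used for fitting; defaults to all
        samples with an observed phenotype.
    """

    def __init__(self, y, kinship: KinshipMatrix, breed=None, sex=None,
                 train_idx=None):
        if isinstance(y, PhenotypeVector):
            vals, miss = y.values, y.missing
            self.trait_name = y.trait_name
        else:
            vals = np.asarray(y, dtype=np.float64)
            miss = np.isnan(vals)
            self.trait_name = "y"
        if vals.shape[0] != kinship.n:
            raise ValueError("phenotype length does not match kinship dimension")
        self.y = vals
        self.kinship = kinship
        self.breed = None if breed is None else np.asarray(breed, dtype=object)
        self.sex = None if sex is None else np.asarray(sex, dtype=object)
        if train_idx is None:
            train_idx = np.flatnonzero(~miss)
        self.train_idx = np.asarray(train_idx, dtype=np.intp)
        if miss[self.train_idx].any():
            raise ValueError("training samples include missing phenotypes")
        if self.train_idx.size < 3:
            raise ValueError("need at least 3 training samples")

        if self.breed is not None and self.sex is not None:
            self.design = build_design(self.breed[self.train_idx],
                                       self.sex[self.train_idx])
            self._names = ["intercept"] + list(self.design.effect_names)
        else:
            self.design = None
            self._names = ["intercept"]

        self._yt = self.y[self.train_idx]
        self._Xt = self._X_rows(self.train_idx)
        if np.ptp(self._yt) == 0:
            raise DegeneratePhenotypeError("training phenotype is constant")
        self._Kt = kinship.submatrix(self.train_idx)

    def _X_rows(self, idx: np.ndarray) -> np.ndarray:
        """Design rows (intercept first) for samples ``idx``, encoded with
        training levels; raises on factor levels unseen in training."""
        idx = np.asarray(idx, dtype=np.intp)
        ones = np.ones((idx.size, 1))
        if self.design is None or self.design.n_effects == 0:
            return ones
        return np.hstack([ones, self.design.encode(
            {"breed": self.breed[idx], "sex": self.sex[idx]})])

    # -- closed form ------------------------------------------------------

    def _rotated(self):
        """Eigendecomposition of the training kinship and rotated data."""
        d = self._Kt.eigenvalues
        U = self._Kt.eigenvectors
        return d, U, U.T @ self._yt, U.T @ self._Xt

    def _gls(self, d, Uy, UX, vc: VarianceComponents):
        """Exact (beta, g, residual diag) at fixed variance components."""
        v = vc.sigma_g2 * d + vc.sigma_e2
        XtVX = (UX.T / v) @ UX
        XtVy = (UX.T / v) @ Uy
        cond = np.linalg.cond(XtVX)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError(
                f"singular fixed-effects system (cond={cond:.2e}); "
                f"confounded columns among: {self._names}"
            )
        c, low = linalg.cho_factor(XtVX)
        beta = linalg.cho_solve((c, low), XtVy)
        r = Uy - UX @ beta
        g_rot = vc.sigma_g2 * d / v * r
        return beta, g_rot, r, v

    def fit(self, variance_components: VarianceComponents | None = None) -> "GBLUPResults":
        """Exact mixed-model solve; REML variance components if not supplied.

        The REML profile restricted likelihood is maximized over h2 on the
        eigendecomposed model (deterministic; no MCMC involved).
        """
        d, U, Uy, UX = self._rotated()
        n, K = self._Xt.shape

        if variance_components is None:
            def neg_restricted_ll(h2: float) -> float:
                vc = VarianceComponents(h2, 1.0 - h2)
                beta, _, r, v = self._gls(d, Uy, UX, vc)
                rss = float(np.sum(r * r / v))
                sigma_p2 = rss / (n - K)
                XtVX = (UX.T / v) @ UX
                sign, logdet = np.linalg.slogdet(XtVX)
                return ((n - K) * np.log(sigma_p2) + np.sum(np.log(v)) + logdet) / 2.0

            res = optimize.minimize_scalar(
                neg_restricted_ll, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
                options={"xatol": 1e-8},
            )
            h2 = float(res.x)
            vc_unit = VarianceComponents(h2, 1.0 - h2)
            beta, _, r, v = self._gls(d, Uy, UX, vc_unit)
            sigma_p2 = float(np.sum(r * r / v)) / (n - K)
            variance_components = VarianceComponents(h2 * sigma_p2, (1.0 - h2) * sigma_p2)

        beta, g_rot, _, _ = self._gls(d, Uy, UX, variance_components)
        g = U @ g_rot
        return GBLUPResults(
            model=self, method="closed_form", beta=beta, vc=variance_components,
            g_train=g,
        )

    # -- Gibbs sampler ------------------------------------------------------

    def fit_gibbs(self, chain: ChainConfig = ChainConfig(), seed: int = 0,
                  prior_df: float = 5.0, prior_r2: float | None = None) -> "GBLUPResults":
        """Gibbs sampler in the eigenbasis of the training kinship.

        Transformed genetic effects a_i (with prior N(0, sigma_g2 * d_i) on
        the positive-eigenvalue components), fixed effects (flat prior) and
        both variances (scaled-inverse-chi-square full conditionals) are
        sampled; posterior means are reported. Reproducible given ``seed``.

        The variance priors have ``prior_df`` degrees of freedom each, with
        scales whose modes split var(y) into a genetic share ``prior_r2``
        and a residual share 1 - prior_r2. By default ``prior_r2`` is set
        from a preliminary REML fit (an empirical-Bayes centering that avoids
        biasing the posterior toward any fixed heritability); pass an
        explicit value (e.g. 0.5) for a data-independent prior.
        """
        rng = np.random.default_rng(seed)
        d_all, U_all, _, _ = self._rotated()
        keep = d_all > _EIG_TOL * d_all.max()
        d, U = d_all[keep], U_all[:, keep]
        y, X = self._yt, self._Xt
        n, K = X.shape
        m = d.size

        vy = float(np.var(y))
        if vy == 0:
            raise DegeneratePhenotypeError("training phenotype is constant")
        if prior_r2 is None:
            prior_r2 = min(max(self.fit().vc.h2, 0.05), 0.95)
        df_g = df_e = prior_df
        mean_diag = float(np.mean(np.diag(self._Kt.matrix)))
        S_g = vy * prior_r2 * (df_g + 2.0) / df_g / max(mean_diag, 1e-12)
        S_e = vy * (1.0 - prior_r2) * (df_e + 2.0) / df_e
        r2 = prior_r2

        XtX = X.T @ X
        cX, lowX = linalg.cho_factor(XtX)
        Rx = linalg.cholesky(XtX, lower=False)
        UTy = U.T @ y
        UTX = U.T @ X

        a = np.zeros(m)
        beta = linalg.cho_solve((cX, lowX), X.T @ y)
        sigma_g2, sigma_e2 = vy * r2 / max(mean_diag, 1e-12), vy * (1.0 - r2)

        kept_iters = set(chain.kept().tolist())
        sums = {k: 0.0 for k in ("sigma_g2", "sigma_e2", "h2")}
        sums2 = {k: 0.0 for k in ("sigma_g2", "sigma_e2", "h2")}
        beta_sum = np.zeros(K)
        g_sum = np.zeros(n)
        n_kept = 0

        for it in range(chain.n_iter):
            # fixed effects | a (flat prior)
            resid_fx = y - U @ a
            mean_b = linalg.cho_solve((cX, lowX), X.T @ resid_fx)
            beta = mean_b + np.sqrt(sigma_e2) * linalg.solve_triangular(
                Rx, rng.standard_normal(K), lower=False)
            # transformed genetic effects | beta (independent given rotation)
            r_rot = UTy - UTX @ beta
            prec = 1.0 / sigma_e2 + 1.0 / (sigma_g2 * d)
            mu_a = (r_rot / sigma_e2) / prec
            a = mu_a + rng.standard_normal(m) / np.sqrt(prec)
            # variances
            sigma_g2 = _scaled_inv_chi2(rng, df_g + m, df_g * S_g + float(np.sum(a * a / d)))
            e = y - X @ beta - U @ a
            sigma_e2 = _scaled_inv_chi2(rng, df_e + n, df_e * S_e + float(e @ e))

            if it in kept_iters:
                n_kept += 1
                beta_sum += beta
                g_sum += U @ a
                for k, val in (("sigma_g2", sigma_g2), ("sigma_e2", sigma_e2),
                               ("h2", sigma_g2 / (sigma_g2 + sigma_e2))):
                    sums[k] += val
                    sums2[k] += val * val

        post = {k: sums[k] / n_kept for k in sums}
        post_sd = {k: np.sqrt(max(sums2[k] / n_kept - post[k] ** 2, 0.0)) for k in sums}
        vc = VarianceComponents(post["sigma_g2"], post["sigma_e2"])
        return GBLUPResults(
            model=self, method="gibbs", beta=beta_sum / n_kept, vc=vc,
            g_train=g_sum / n_kept, chain=chain, seed=seed,
            posterior_h2=post["h2"], posterior_sd=post_sd,
        )


@dataclass
class GBLUPResults:
    """Fitted GBLUP: fixed effects, variance components, genetic values."""

    model: GBLUP
    method: str
    beta: np.ndarray           # intercept first
    vc: VarianceComponents
    g_train: np.ndarray
    chain: ChainConfig | None = None
    seed: int | None = None
    posterior_h2: float | None = None
    posterior_sd: dict = field(default_factory=dict)

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    @property
    def h2(self) -> float:
        return self.posterior_h2 if self.posterior_h2 is not None else self.vc.h2

    def fitted_values(self) -> np.ndarray:
        """Linear predictor mu + X beta + g on the training samples."""
        m = self.model
        return m._Xt @ self.beta + self.g_train

    def predict(self, idx=None) -> np.ndarray:
        """Predict mu + X beta + g for kinship samples ``idx`` (default all).

        Training samples get their fitted genetic value; held-out samples get
        the conditional expectation K[new, train] K[train, train]^-1 g_train,
        with a small ridge (1e-6 * tr(K)/n) stabilizing the inverse.
        """
        m = self.model
        if idx is None:
            idx = np.arange(m.kinship.n)
        idx = np.asarray(idx, dtype=np.intp)
        Ktt = m._Kt.matrix
        nt = Ktt.shape[0]
        ridge = 1e-6 * np.trace(Ktt) / nt
        w = linalg.solve(Ktt + ridge * np.eye(nt), self.g_train, assume_a="pos")
        g = m.kinship.cross(idx, m.train_idx) @ w
        # exact fitted genetic values on training rows
        pos_in_train = {s: i for i, s in enumerate(m.train_idx)}
        for out_i, sample in enumerate(idx):
            j = pos_in_train.get(int(sample))
            if j is not None:
                g[out_i] = self.g_train[j]
        return m._X_rows(idx) @ self.beta + g

    def mme_residual(self) -> float:
        """Max norm of the mixed-model normal-equation residuals.

        Checks X'(y - X beta - g) = 0 and K (y - X beta - g) = lambda g with
        lambda = sigma_e2 / sigma_g2 (the K-multiplied form of Henderson's
        second equation block, valid for singular K as well).
        """
        m = self.model
        r = m._yt - m._Xt @ self.beta - self.g_train
        r1 = m._Xt.T @ r
        lam = self.vc.sigma_e2 / self.vc.sigma_g2
        r2 = m._Kt.matrix @ r - lam * self.g_train
        scale = max(1.0, float(np.abs(m._yt).max()))
        return float(max(np.abs(r1).max(), np.abs(r2).max()) / scale)

    def summary(self) -> str:
        lines = [
            f"GBLUP fit ({self.method}) — trait {self.model.trait_name!r}, "
            f"n_train={self.model.train_idx.size}",
            f"  sigma_g2 = {self.vc.sigma_g2:.6g}   sigma_e2 = {self.vc.sigma_e2:.6g}"
            f"   h2 = {self.h2:.4f}",
        ]
        if self.posterior_sd:
            lines.append(
                "  posterior SD: "
                + "  ".join(f"{k}={v:.4g}" for k, v in self.posterior_sd.items())
            )
        for name, b in zip(self.model._names, self.beta):
            lines.append(f"  {name:<20s} {b: .6g}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-training-sample genetic values as a tidy frame."""
        m = self.model
        return pd.DataFrame({
            "sample_id": m.kinship.sample_ids[m.train_idx],
            "genetic_value": self.g_train,
        })


# ===========================================================================
# BayesC


class BayesC:
    """Spike-and-slab whole-genome regression fitted by Gibbs sampling.

    Marker columns are centered by their training means (2 * allele
    frequency); the centering constants are reused at prediction time.
    Monomorphic training markers keep a zero effect throughout.
    """

    def __init__(self, y, genotypes: GenotypeMatrix, breed=None, sex=None,
                 priors: BayesCPriors = BayesCPriors(), train_idx=None):
        if isinstance(y, PhenotypeVector):
            vals, miss = y.values, y.missing
            self.trait_name = y.trait_name
        else:
            vals = np.asarray(y, dtype=np.float64)
            miss = np.isnan(vals)
            self.trait_name = "y"
        if genotypes.n_markers == 0:
            raise ValueError("empty marker panel")
        if vals.shape[0] != genotypes.n_samples:
            raise ValueError("phenotype length does not match genotype matrix")
        self.genotypes = genotypes
        self.priors = priors
        self.y = vals
        self.breed = None if breed is None else np.asarray(breed, dtype=object)
        self.sex = None if sex is None else np.asarray(sex, dtype=object)
        if train_idx is None:
            train_idx = np.flatnonzero(~miss)
        self.train_idx = np.asarray(train_idx, dtype=np.intp)
        if miss[self.train_idx].any():
            raise ValueError("training samples include missing phenotypes")

        gt = genotypes.take_samples(self.train_idx)
        if gt.missing_mask.any():
            raise ValueError("missing dosages in training panel; filter first")
        M = gt.dosages.astype(np.float64)
        self.center = M.mean(axis=0)
        self._W = M - self.center
        self._yt = vals[self.train_idx]

        if self.breed is not None and self.sex is not None:
            self.design = build_design(self.breed[self.train_idx], self.sex[self.train_idx])
            self._Xt = np.hstack([np.ones((len(self.train_idx), 1)),
                                  self.design.matrix])
            self._names = ["intercept"] + list(self.design.effect_names)
        else:
            self.design = None
            self._Xt = np.ones((len(self.train_idx), 1))
            self._names = ["intercept"]

    def fit(self, chain: ChainConfig = ChainConfig(), seed: int = 0) -> "BayesCResults":
        pri = self.priors
        rng = np.random.default_rng(seed)
        y, X, W = self._yt, self._Xt, self._W
        n, K = X.shape
        L = W.shape[1]
        WT = np.ascontiguousarray(W.T)
        cjj = np.einsum("ij,ij->i", WT, WT)  # per-marker sum of squares
        active = np.flatnonzero(cjj > 0)

        vy = float(np.var(y))
        if vy == 0:
            raise DegeneratePhenotypeError("training phenotype is constant")
        msx = float(cjj.sum() / n)
        S_e = vy * (1.0 - pri.r2) * (pri.df_e + 2.0) / pri.df_e
        S_a = vy * pri.r2 * (pri.df_a + 2.0) / (pri.df_a * pri.pi0 * max(msx, 1e-12))

        cXtX, lowX = linalg.cho_factor(X.T @ X)
        Rx = linalg.cholesky(X.T @ X, lower=False)

        alpha = np.zeros(L)
        delta = np.zeros(L, dtype=bool)
        beta = linalg.cho_solve((cXtX, lowX), X.T @ y)
        pi = pri.pi0
        sigma_a2 = pri.fix_sigma_a2 if pri.fix_sigma_a2 is not None else vy * pri.r2 / max(msx * pri.pi0, 1e-12)
        sigma_e2 = pri.fix_sigma_e2 if pri.fix_sigma_e2 is not None else vy * (1.0 - pri.r2)
        e = y - X @ beta  # alpha starts at zero

        kept_iters = set(chain.kept().tolist())
        n_kept = 0
        alpha_sum = np.zeros(L)
        incl_sum = np.zeros(L)
        beta_sum = np.zeros(K)
        scalars = {"pi": 0.0, "sigma_a2": 0.0, "sigma_e2": 0.0, "h2": 0.0}

        for it in range(chain.n_iter):
            # fixed effects (flat prior)
            r_fx = e + X @ beta
            mean_b = linalg.cho_solve((cXtX, lowX), X.T @ r_fx)
            beta = mean_b + np.sqrt(sigma_e2) * linalg.solve_triangular(
                Rx, rng.standard_normal(K), lower=False)
            e = r_fx - X @ beta

            # single-site updates of (delta_j, alpha_j)
            lam = sigma_e2 / sigma_a2
            log_odds_prior = np.log(pi) - np.log1p(-pi) if pi < 1.0 else np.inf
            for j in active:
                wj = WT[j]
                old = alpha[j]
                rj = float(wj @ e) + cjj[j] * old
                v = cjj[j] + lam
                if pi >= 1.0:
                    include = True
                else:
                    log_bf = 0.5 * (np.log(lam) - np.log(v)) + rj * rj / (2.0 * sigma_e2 * v)
                    p_in = 1.0 / (1.0 + np.exp(-(log_odds_prior + log_bf)))
                    include = rng.random() < p_in
                if include:
                    new = rj / v + np.sqrt(sigma_e2 / v) * rng.standard_normal()
                    delta[j] = True
                else:
                    new = 0.0
                    delta[j] = False
                if new != old:
                    e -= wj * (new - old)
                alpha[j] = new

            m_in = int(delta.sum())
            if pri.fix_sigma_a2 is None:
                ss_a = float(np.sum(alpha[delta] ** 2)) + pri.df_a * S_a
                sigma_a2 = _scaled_inv_chi2(rng, pri.df_a + m_in, ss_a)
            if pri.fix_sigma_e2 is None:
                sigma_e2 = _scaled_inv_chi2(rng, pri.df_e + n, float(e @ e) + pri.df_e * S_e)
            if not pri.fix_pi:
                pi = rng.beta(pri.pi0 * pri.pi_weight + m_in,
                              (1.0 - pri.pi0) * pri.pi_weight + (active.size - m_in))
                pi = min(max(pi, 1e-6), 1.0 - 1e-6)

            if it in kept_iters:
                n_kept += 1
                alpha_sum += alpha
                incl_sum += delta
                beta_sum += beta
                g_var = float(np.var(W @ alpha))
                scalars["pi"] += pi
                scalars["sigma_a2"] += sigma_a2
                scalars["sigma_e2"] += sigma_e2
                scalars["h2"] += g_var / (g_var + sigma_e2)

        post = {k: v / n_kept for k, v in scalars.items()}
        return BayesCResults(
            model=self, beta=beta_sum / n_kept, alpha=alpha_sum / n_kept,
            inclusion_prob=incl_sum / n_kept, pi=post["pi"],
            vc=VarianceComponents(max(post["sigma_a2"] * msx * post["pi"], 0.0),
                                  post["sigma_e2"]),
            posterior_h2=post["h2"], chain=chain, seed=seed,
        )


@dataclass
class BayesCResults:
    """Fitted BayesC: posterior-mean effects and inclusion probabilities."""

    model: BayesC
    beta: np.ndarray
    alpha: np.ndarray
    inclusion_prob: np.ndarray
    pi: float
    vc: VarianceComponents
    posterior_h2: float
    chain: ChainConfig
    seed: int

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    @property
    def h2(self) -> float:
        return self.posterior_h2

    def fitted_values(self) -> np.ndarray:
        m = self.model
        return m._Xt @ self.beta + m._W @ self.alpha

    def _align_markers(self, newg: GenotypeMatrix) -> np.ndarray:
        train_ids = self.model.genotypes.marker_ids
        if newg.n_markers == train_ids.size and (newg.marker_ids == train_ids).all():
            return newg.dosages.astype(np.float64)
        pos = {mid: j for j, mid in enumerate(newg.marker_ids)}
        missing = [mid for mid in train_ids if mid not in pos]
        if missing:
            raise MarkerAlignmentError(
                f"{len(missing)} training markers absent from validation panel, "
                f"e.g. {missing[:5]}"
            )
        cols = [pos[mid] for mid in train_ids]
        return newg.dosages[:, cols].astype(np.float64)

    def predict(self, newg: GenotypeMatrix | None = None, breed=None, sex=None,
                idx=None) -> np.ndarray:
        """mu + X beta + (M_new - training centering) alpha.

        Either pass ``idx`` into the training genotype object's samples, or a
        new :class:`GenotypeMatrix` whose markers match the training panel.
        """
        m = self.model
        if newg is None:
            if idx is None:
                idx = np.arange(m.genotypes.n_samples)
            idx = np.asarray(idx, dtype=np.intp)
            M = m.genotypes.dosages[idx].astype(np.float64)
            breed = None if m.breed is None else m.breed[idx]
            sex = None if m.sex is None else m.sex[idx]
        else:
            M = self._align_markers(newg)
            if breed is None:
                breed, sex = newg.breed, newg.sex
        if np.isnan(M).any() or (M < 0).any():
            raise ValueError("missing dosages in prediction panel")
        Wn = M - m.center
        if m.design is not None:
            X = np.hstack([np.ones((M.shape[0], 1)),
                           m.design.encode({"breed": breed, "sex": sex})])
        else:
            X = np.ones((M.shape[0], 1))
        return X @ self.beta + Wn @ self.alpha

    def effects_frame(self) -> pd.DataFrame:
        g = self.model.genotypes
        return pd.DataFrame({
            "marker_id": g.marker_ids, "chrom": g.chrom, "pos_bp": g.pos_bp,
            "alpha": self.alpha, "inclusion_prob": self.inclusion_prob,
        })

    def export_effects_tsv(self, path) -> None:
        self.effects_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        top = self.effects_frame().nlargest(5, "inclusion_prob")
        lines = [
            f"BayesC fit — trait {self.model.trait_name!r}, "
            f"n_train={self.model.train_idx.size}, L={self.alpha.size}",
            f"  posterior pi = {self.pi:.4f}   sigma_e2 = {self.vc.sigma_e2:.6g}"
            f"   h2 = {self.posterior_h2:.4f}",
            "  top markers by inclusion probability:",
        ]
        for _, row in top.iterrows():
            lines.append(
                f"    {row.marker_id:<16s} P(incl)={row.inclusion_prob:.3f} "
                f"alpha={row.alpha: .4g}"
            )
        return "\n".join(lines)


# ===========================================================================
# Functional wrappers mirroring the operation-level surface


def fit_gblup_closed_form(y, kin: KinshipMatrix, vc: VarianceComponents,
                          breed=None, sex=None, train_idx=None) -> GBLUPResults:
    """Exact mixed-model solve at supplied variance components."""
    return GBLUP(y, kin, breed=breed, sex=sex, train_idx=train_idx).fit(vc)


def fit_gblup_gibbs(y, kin: KinshipMatrix, chain: ChainConfig = ChainConfig(),
                    seed: int = 0, breed=None, sex=None, train_idx=None) -> GBLUPResults:
    return GBLUP(y, kin, breed=breed, sex=sex, train_idx=train_idx).fit_gibbs(chain, seed)


def fit_bayesc(y, genotypes: GenotypeMatrix, priors: BayesCPriors = BayesCPriors(),
               chain: ChainConfig = ChainConfig(), seed: int = 0,
               breed=None, sex=None, train_idx=None) -> BayesCResults:
    return BayesC(y, genotypes, breed=breed, sex=sex, priors=priors,
                  train_idx=train_idx).fit(chain, seed)
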