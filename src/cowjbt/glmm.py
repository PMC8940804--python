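"""Mixed models for trial-level JBT responses, fitted by Laplace ML.

Two model families are provided, mirroring how the training-phase
responses are analysed:

* :class:`MixedLogit` -- a Bernoulli GLMM with logit link for binary
  outcomes (correct/incorrect responses, NoGo indicators), with
  independent Gaussian random intercepts for one or more grouping factors
  (e.g. sessions nested within cows nested within groups, coded as one
  intercept per nesting level);
* :class:`BetaMixedRegression` -- a beta-distributed GLMM with logit mean
  link and common precision ``phi`` for proportions in (0, 1) (the
  non-zero remaining latencies);
* :class:`HurdleBetaModel` -- the two-part model combining a MixedLogit
  for the probability ``p`` of a zero (NoGo) with a BetaMixedRegression
  for the positive part, so a record contributes ``log p`` when y = 0 and
  ``log(1-p) + log Beta(y; mu phi, (1-mu) phi)`` otherwise.  The two parts
  share no parameters and factorise exactly.

Estimation maximises the marginal likelihood with the random-intercept
integrals approximated by the Laplace method: an inner Fisher-scoring
problem finds the joint mode of the random effects, and the outer
quasi-Newton optimisation runs over fixed effects, log random-effect
standard deviations and (for the beta family) log precision.  Standard
errors come from the numerically differentiated observed information of
the outer objective, so fixed-effect uncertainty accounts for variance
-parameter uncertainty.

The API follows the statsmodels convention: a model object built from a
DataFrame, ``fit()`` returning a results object that carries estimates,
covariance, Wald tests, estimated marginal means and a ``summary()``
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.special import digamma, expit, gammaln, polygamma

__all__ = [
    "FixedEffectsDesign",
    "MixedLogit",
    "BetaMixedRegression",
    "HurdleBetaModel",
    "ModelSpec",
    "fit_model",
    "hurdle_beta_loglik",
]

#: Numerical guard for beta responses near the open-interval bounds.
BETA_EPS = 1e-6
#: Lower bound on log sigma in the outer optimisation; below ~1e-3 the
#: component is reported as a boundary (zero-variance) estimate.
LOG_SIGMA_MIN = -8.0
LOG_SIGMA_MAX = 4.0
SIGMA_BOUNDARY = 1e-3


class ConvergenceError(RuntimeError):
    """The outer optimisation did not converge."""


class FixedEffectsDesign:
    """Treatment-coded design for categorical fixed effects.

    ``factors`` are column names treated as categorical (first sorted level
    is the reference); ``interactions`` are pairs of factor names whose
    dummy products are appended.  The design remembers the levels so new
    prediction grids (for marginal means) are coded consistently.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        factors: Sequence[str],
        interactions: Sequence[tuple[str, str]] = (),
    ):
        self.factors = list(factors)
        self.interactions = [tuple(i) for i in interactions]
        for a, b in self.interactions:
            if a not in self.factors or b not in self.factors:
                raise ValueError("interaction terms require both main effects present")
        self.levels = {f: sorted(map(str, pd.unique(data[f].astype(str)))) for f in self.factors}
        for f, levs in self.levels.items():
            if len(levs) < 1:
                raise ValueError(f"factor {f} has no levels")
        self.columns: list[tuple] = [("Intercept",)]
        for f in self.factors:
            for lev in self.levels[f][1:]:
                self.columns.append((f, lev))
        for a, b in self.interactions:
            for la in self.levels[a][1:]:
                for lb in self.levels[b][1:]:
                    self.columns.append((f"{a}:{b}", la, lb))

    @property
    def names(self) -> list[str]:
        out = []
        for col in self.columns:
            if col == ("Intercept",):
                out.append("Intercept")
            elif len(col) == 2:
                out.append(f"{col[0]}[{col[1]}]")
            else:
                a, b = col[0].split(":")
                out.append(f"{a}[{col[1]}]:{b}[{col[2]}]")
        return out

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        X = np.zeros((n, len(self.columns)))
        dummies = {}
        for f in self.factors:
            vals = data[f].astype(str).to_numpy()
            unknown = set(vals) - set(self.levels[f])
            if unknown:
                raise ValueError(f"unseen level(s) {sorted(unknown)} for factor {f}")
            for lev in self.levels[f][1:]:
                dummies[(f, lev)] = (vals == lev).astype(float)
        for j, col in enumerate(self.columns):
            if col == ("Intercept",):
                X[:, j] = 1.0
            elif len(col) == 2:
                X[:, j] = dummies[col]
            else:
                a, b = col[0].split(":")
                X[:, j] = dummies[(a, col[1])] * dummies[(b, col[2])]
        return X

    def term_indices(self, term: str) -> list[int]:
        """Column indices belonging to a term, e.g. ``"punisher"`` or
        ``"punisher:cue"``."""
        idx = [j for j, col in enumerate(self.columns) if col[0] == term]
        if not idx:
            raise KeyError(f"term {term!r} not in design (have {sorted({c[0] for c in self.columns})})")
        return idx


# ---------------------------------------------------------------------------
# observation-level log-likelihood families


class _BernoulliFamily:
    """logit-link Bernoulli: l, score and Fisher weight w.r.t. eta."""

    n_extra = 0

    @staticmethod
    def loglik(y, eta, extra):
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def score_weight(y, eta, extra):
        p = expit(eta)
        return y - p, np.clip(p * (1.0 - p), 1e-10, None)


class _BetaFamily:
    """logit-mean beta regression; ``extra = [log phi]``."""

    n_extra = 1

    @staticmethod
    def loglik(y, eta, extra):
        phi = np.exp(extra[0])
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        a = mu * phi
        b = (1.0 - mu) * phi
        return (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )

    @staticmethod
    def score_weight(y, eta, extra):
        phi = np.exp(extra[0])
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        dmu = mu * (1.0 - mu)
        ystar = np.log(y) - np.log1p(-y)
        mustar = digamma(mu * phi) - digamma((1.0 - mu) * phi)
        score = phi * (ystar - mustar) * dmu
        # expected information w.r.t. eta (always positive)
        w = phi**2 * (polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)) * dmu**2
        return score, np.clip(w, 1e-10, None)


# ---------------------------------------------------------------------------


class _LaplaceMixedModel:
    """Shared machinery: Laplace-approximated marginal likelihood with
    independent Gaussian random intercepts per grouping factor."""

    family = None
    _default_extra: list[float] = []

    def __init__(
        self,
        endog,
        exog: np.ndarray,
        exog_names: Sequence[str],
        groups: Mapping[str, Sequence] | None = None,
        design: Optional[FixedEffectsDesign] = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (nobs, k) aligned with endog")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {self.exog.shape[1]} columns)"
            )
        self.exog_names = list(exog_names)
        self.design = design
        self.group_names: list[str] = []
        self.group_codes: list[np.ndarray] = []
        self.group_sizes: list[int] = []
        for name, labels in (groups or {}).items():
            codes, uniques = pd.factorize(np.asarray(labels))
            if len(labels) != len(self.endog):
                raise ValueError(f"grouping factor {name} misaligned with endog")
            self.group_names.append(name)
            self.group_codes.append(codes.astype(np.int64))
            self.group_sizes.append(len(uniques))
        self.k_fe = self.exog.shape[1]
        self.n_groups = len(self.group_names)
        self._Z = self._build_z()

    def _build_z(self):
        if not self.group_names:
            return None
        n = len(self.endog)
        cols = []
        offset = 0
        rows = np.arange(n)
        data, ridx, cidx = [], [], []
        for codes, size in zip(self.group_codes, self.group_sizes):
            ridx.append(rows)
            cidx.append(codes + offset)
            data.append(np.ones(n))
            offset += size
        Z = sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(ridx), np.concatenate(cidx))),
            shape=(n, offset),
        )
        return Z

    # -- Laplace objective ---------------------------------------------------

    def _eta(self, beta, u):
        eta = self.exog @ beta
        if u is not None:
            offset = 0
            for codes, size in zip(self.group_codes, self.group_sizes):
                eta = eta + u[offset : offset + size][codes]
                offset += size
        return eta

    def _inner_mode(self, beta, sigmas, extra, u0=None, tol=1e-10, maxiter=100):
        """Fisher-scoring for the joint random-effect mode; returns
        (u_hat, eta_hat, penalised loglik at mode, log|H|)."""
        q = sum(self.group_sizes)
        prec = np.concatenate(
            [np.full(size, 1.0 / max(s, 1e-12) ** 2) for size, s in zip(self.group_sizes, sigmas)]
        )
        u = np.zeros(q) if u0 is None else u0.copy()
        # factors with (near-)zero variance are pinned at 0
        active = np.concatenate(
            [np.full(size, s > SIGMA_BOUNDARY) for size, s in zip(self.group_sizes, sigmas)]
        )
        act = np.where(active)[0]
        u[~active] = 0.0
        prec = np.where(active, prec, 0.0)
        single = self.n_groups == 1
        codes = self.group_codes[0] if single else None
        xb = self.exog @ beta
        if act.size == 0:
            eta = xb
            pen = float(np.sum(self.family.loglik(self.endog, eta, extra)))
            return u, eta, pen, 0.0
        for _ in range(maxiter):
            eta = self._eta(beta, u)
            score, w = self.family.score_weight(self.endog, eta, extra)
            if single:
                g = np.bincount(codes, weights=score, minlength=q) - u * prec
                h = np.bincount(codes, weights=w, minlength=q) + prec
                step = g / h
            else:
                g = (self._Z.T @ score - u * prec)[act]
                H = (self._Z.T @ sparse.diags(w) @ self._Z).toarray()[np.ix_(act, act)]
                H[np.diag_indices_from(H)] += prec[act]
                step_act = np.linalg.solve(H, g)
                step = np.zeros(q)
                step[act] = step_act
            step = np.where(active, step, 0.0)
            # damped update for robustness on flat starts
            lam = 1.0
            pen0 = float(np.sum(self.family.loglik(self.endog, eta, extra)) - 0.5 * np.sum(prec * u * u))
            for _ in range(30):
                u_new = u + lam * step
                eta_new = xb + (self._Z @ u_new if not single else u_new[codes])
                pen = float(
                    np.sum(self.family.loglik(self.endog, eta_new, extra))
                    - 0.5 * np.sum(prec * u_new * u_new)
                )
                if pen >= pen0 - 1e-12:
                    break
                lam *= 0.5
            u = u + lam * step
            if np.max(np.abs(lam * step)) < tol:
                break
        eta = self._eta(beta, u)
        _, w = self.family.score_weight(self.endog, eta, extra)
        if single:
            h = np.bincount(codes, weights=w, minlength=q) + prec
            logdet = float(np.sum(np.log(h[act])))
        else:
            H = (self._Z.T @ sparse.diags(w) @ self._Z).toarray()[np.ix_(act, act)]
            H[np.diag_indices_from(H)] += prec[act]
            sign, logdet = np.linalg.slogdet(H)
            if sign <= 0:
                raise FloatingPointError("random-effect Hessian not positive definite")
        pen = float(np.sum(self.family.loglik(self.endog, eta, extra)) - 0.5 * np.sum(prec * u * u))
        return u, eta, pen, logdet

    def loglike(self, beta, sigmas, extra, u0=None):
        """Laplace-approximated marginal log-likelihood."""
        if not self.group_names:
            eta = self.exog @ beta
            return float(np.sum(self.family.loglik(self.endog, eta, extra))), None
        u, eta, pen, logdet = self._inner_mode(beta, sigmas, extra, u0=u0)
        # prior normalisation net of the Laplace (2 pi)^{q/2} factor; factors
        # pinned at the zero-variance boundary contribute nothing
        ll = pen - 0.5 * logdet
        for size, s in zip(self.group_sizes, sigmas):
            if s > SIGMA_BOUNDARY:
                ll -= size * np.log(s)
        return float(ll), u

    # -- fitting ---------------------------------------------------------------

    def _start_beta(self):
        import statsmodels.api as sm

        fam = sm.families.Binomial()
        y = self.endog
        if isinstance(self.family, _BetaFamily) or self.family is _BetaFamily:
            # quasi-likelihood start: treat proportions as binomial means
            y = np.clip(y, 1e-3, 1 - 1e-3)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, self.exog, family=fam).fit()
            return np.asarray(res.params)
        except Exception:
            return np.zeros(self.k_fe)

    def fit(self, start_params=None, maxiter=200, gtol=1e-5, sigma_fixed=None):
        """Maximise the Laplace marginal likelihood.

        ``sigma_fixed`` optionally maps grouping-factor names to fixed
        standard deviations (0 removes the component), which are then
        excluded from the outer optimisation.
        """
        sigma_fixed = dict(sigma_fixed or {})
        free_groups = [i for i, nm in enumerate(self.group_names) if nm not in sigma_fixed]
        k = self.k_fe
        n_extra = self.family.n_extra

        if start_params is None:
            beta0 = self._start_beta()
        else:
            beta0 = np.asarray(start_params, dtype=float)[:k]
        x0 = np.concatenate(
            [beta0, np.full(len(free_groups), np.log(0.5)), np.array(self._default_extra)]
        )
        bounds = (
            [(None, None)] * k
            + [(LOG_SIGMA_MIN, LOG_SIGMA_MAX)] * len(free_groups)
            + [(-4.0, 12.0)] * n_extra
        )

        warm = {"u": None}

        def unpack(x):
            beta = x[:k]
            sigmas = np.empty(self.n_groups)
            for i, nm in enumerate(self.group_names):
                if nm in sigma_fixed:
                    sigmas[i] = float(sigma_fixed[nm])
            for j, i in enumerate(free_groups):
                sigmas[i] = np.exp(x[k + j])
            extra = x[k + len(free_groups) :]
            return beta, sigmas, extra

        def negll(x):
            beta, sigmas, extra = unpack(x)
            try:
                ll, u = self.loglike(beta, sigmas, extra, u0=warm["u"])
            except FloatingPointError:
                return 1e10
            warm["u"] = u
            return -ll

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimize.minimize(
                negll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol, "maxcor": 25},
            )
        if not opt.success and "ABNORMAL" in str(opt.message):
            raise ConvergenceError(f"outer optimisation failed: {opt.message}")

        xhat = opt.x
        beta, sigmas, extra = unpack(xhat)
        llf = -float(opt.fun)

        # observed information of the outer objective by central differences
        nfree = k + len(free_groups) + n_extra
        hess = np.zeros((nfree, nfree))
        steps = 1e-4 * (1.0 + np.abs(xhat))
        f0 = opt.fun
        fp = np.zeros(nfree)
        fm = np.zeros(nfree)
        for i in range(nfree):
            e = np.zeros(nfree)
            e[i] = steps[i]
            fp[i] = negll(xhat + e)
            fm[i] = negll(xhat - e)
            hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
        for i in range(nfree):
            for j in range(i + 1, nfree):
                e = np.zeros(nfree)
                e[i] = steps[i]
                e[j] = steps[j]
                fpp = negll(xhat + e)
                hess[i, j] = hess[j, i] = (
                    fpp - fp[i] - fp[j] + f0
                ) / (steps[i] * steps[j])
        try:
            cov_all = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(hess)
        cov_fe = cov_all[:k, :k]
        # guard against tiny negative variances from finite differencing
        d = np.diag(cov_fe).copy()
        if np.any(d < 0):
            cov_fe = cov_fe + np.eye(k) * (1e-12 - min(d.min(), 0))

        grad = optimize.approx_fprime(xhat, negll, 1e-6 * (1.0 + np.abs(xhat)))
        vc = {}
        for i, nm in enumerate(self.group_names):
            s = sigma_fixed.get(nm, sigmas[i])
            vc[nm] = 0.0 if s <= SIGMA_BOUNDARY else float(s)
        return MixedResults(
            model=self,
            params=beta,
            cov_params_arr=cov_fe,
            vc=vc,
            extra=np.asarray(extra),
            llf=llf,
            converged=bool(opt.success),
            niter=int(opt.nit),
            grad_norm=float(np.max(np.abs(grad))),
        )


class MixedLogit(_LaplaceMixedModel):
    """Binary logit GLMM with independent random intercepts (Laplace ML)."""

    family = _BernoulliFamily
    _default_extra: list[float] = []

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        factors: Sequence[str],
        groups: Sequence[str],
        interactions: Sequence[tuple[str, str]] = (),
    ) -> "MixedLogit":
        design = FixedEffectsDesign(data, factors, interactions)
        X = design.matrix(data)
        grp = {g: data[g].to_numpy() for g in groups}
        return cls(data[response].to_numpy(), X, design.names, grp, design=design)


class BetaMixedRegression(_LaplaceMixedModel):
    """Beta GLMM (logit mean link, common precision phi) for responses in (0, 1)."""

    family = _BetaFamily
    _default_extra = [np.log(5.0)]

    def __init__(self, endog, exog, exog_names, groups=None, design=None):
        endog = np.asarray(endog, dtype=float)
        if np.any(endog <= 0) or np.any(endog >= 1):
            raise ValueError("beta responses must lie strictly in (0, 1); clip first")
        super().__init__(endog, exog, exog_names, groups, design)

    @classmethod
    def from_dataframe(cls, data, response, factors, groups, interactions=()):
        design = FixedEffectsDesign(data, factors, interactions)
        X = design.matrix(data)
        grp = {g: data[g].to_numpy() for g in groups}
        y = np.clip(data[response].to_numpy(dtype=float), BETA_EPS, 1 - BETA_EPS)
        return cls(y, X, design.names, grp, design=design)


# ---------------------------------------------------------------------------
# results


@dataclass
class MixedResults:
    """Estimates and inference for one fitted mixed model."""

    model: _LaplaceMixedModel
    params: np.ndarray
    cov_params_arr: np.ndarray
    vc: dict
    extra: np.ndarray
    llf: float
    converged: bool
    niter: int
    grad_norm: float

    @property
    def exog_names(self):
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_arr))

    @property
    def phi(self) -> Optional[float]:
        return float(np.exp(self.extra[0])) if self.extra.size else None

    def cov_params(self) -> np.ndarray:
        return self.cov_params_arr

    def wald_test(self, term) -> "WaldTest":
        """Wald chi-square test that a term's coefficients are all zero.

        ``term`` is a term name from the design (e.g. ``"punisher"`` or
        ``"punisher:cue"``), a coefficient name, or a list of coefficient
        names.
        """
        if isinstance(term, str):
            if self.model.design is not None and any(
                c[0] == term for c in self.model.design.columns
            ):
                idx = self.model.design.term_indices(term)
            elif term in self.exog_names:
                idx = [self.exog_names.index(term)]
            else:
                raise KeyError(f"unknown term or coefficient {term!r}")
        else:
            idx = [self.exog_names.index(t) for t in term]
        b = self.params[idx]
        V = self.cov_params_arr[np.ix_(idx, idx)]
        if np.linalg.matrix_rank(V) < len(idx):
            raise ValueError("singular covariance block for the requested term")
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return WaldTest(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))

    # -- estimated marginal means -------------------------------------------

    def _emm_vectors(self, factor: str, within: Optional[tuple[str, str]] = None):
        design = self.model.design
        if design is None:
            raise ValueError("marginal means need a FixedEffectsDesign-built model")
        if factor not in design.factors:
            raise KeyError(f"{factor!r} is not a fixed factor")
        if len(design.levels[factor]) < 2:
            raise ValueError(f"factor {factor!r} has a single level")
        others = [f for f in design.factors if f != factor]
        fixed = {}
        if within is not None:
            wf, wl = within
            if wf == factor:
                raise ValueError("'within' must name a different factor")
            fixed[wf] = [str(wl)]
        grids = {f: fixed.get(f, design.levels[f]) for f in others}
        out = {}
        for lev in design.levels[factor]:
            rows = []
            for combo in product(*(grids[f] for f in others)):
                row = {factor: lev}
                row.update(dict(zip(others, combo)))
                rows.append(row)
            # equal weights over the other factors' level combinations
            L = design.matrix(pd.DataFrame(rows)).mean(axis=0)
            out[lev] = L
        return out

    def emm_pairwise(self, factor: str, within: Optional[tuple[str, str]] = None) -> pd.DataFrame:
        """Pairwise contrasts of estimated marginal means on the logit scale.

        Marginal means average the linear predictor over the other fixed
        factors' levels with equal weights; ``within=(other_factor, level)``
        restricts the averaging to one level of another factor.  Returns a
        DataFrame with logit differences, odds ratios, 95% Wald CIs and
        Bonferroni-adjusted p-values over the set of pairwise contrasts.
        """
        from cowjbt.nonparam import bonferroni_adjust

        emms = self._emm_vectors(factor, within)
        levels = list(emms)
        rows = []
        pairs = list(combinations(levels, 2))
        for la, lb in pairs:
            L = emms[la] - emms[lb]
            est = float(L @ self.params)
            se = float(np.sqrt(L @ self.cov_params_arr @ L))
            z = est / se if se > 0 else np.inf * np.sign(est)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
            rows.append(
                {
                    "contrast": f"{la} - {lb}",
                    "estimate": est,
                    "se": se,
                    "odds_ratio": float(np.exp(est)),
                    "or_ci_low": float(np.exp(est - 1.959963984540054 * se)),
                    "or_ci_high": float(np.exp(est + 1.959963984540054 * se)),
                    "z": z,
                    "p_raw": p,
                }
            )
        df = pd.DataFrame(rows)
        df["p_adj"] = bonferroni_adjust(df["p_raw"].to_numpy(), len(pairs))
        return df

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} (Laplace ML)",
            f"  nobs: {len(self.model.endog)}   logLik: {self.llf:.3f}   "
            f"converged: {self.converged} (iter {self.niter}, |grad| {self.grad_norm:.2e})",
            "  Fixed effects (logit scale):",
        ]
        for name, b, se in zip(self.exog_names, self.params, self.bse):
            z = b / se if se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"    {name:<30s} {b: 9.4f}  (se {se:.4f}, z {z: 6.2f}, p {p:.4g})")
        if self.vc:
            lines.append("  Random-intercept standard deviations:")
            for nm, s in self.vc.items():
                lines.append(f"    {nm:<30s} {s:.4f}")
        if self.phi is not None:
            lines.append(f"  Beta precision phi: {self.phi:.4f}")
        return "\n".join(lines)


@dataclass
class WaldTest:
    chi2: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# hurdle model


def hurdle_beta_loglik(y, p_zero, mu, phi) -> float:
    """Exact hurdle-beta log-likelihood given per-record parameters.

    ``y`` holds remaining latencies in [0, 1): a zero (NoGo) contributes
    ``log p_zero``; a positive value contributes ``log(1 - p_zero)`` plus
    the log beta density with mean ``mu`` and precision ``phi``.  Values
    within ``1e-6`` of the interval bounds are clipped before the beta
    part.
    """
    y = np.asarray(y, dtype=float)
    p_zero = np.broadcast_to(np.asarray(p_zero, dtype=float), y.shape)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if np.any((y < 0) | (y >= 1)):
        raise ValueError("responses must lie in [0, 1)")
    if not phi > 0:
        raise ValueError("phi must be positive")
    zero = y == 0
    ll = float(np.sum(np.log(p_zero[zero])))
    yp = np.clip(y[~zero], BETA_EPS, 1 - BETA_EPS)
    mup = mu[~zero]
    a = mup * phi
    b = (1.0 - mup) * phi
    ll += float(
        np.sum(
            np.log1p(-p_zero[~zero])
            + gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(yp)
            + (b - 1.0) * np.log1p(-yp)
        )
    )
    return ll


class HurdleBetaModel:
    """Two-part mixed model for censored remaining latencies.

    The NoGo part models ``P(y = 0)`` with a :class:`MixedLogit`
    (default: punisher and cue-type fixed effects, cow random intercept,
    no interaction); the positive part models ``y | y > 0`` with a
    :class:`BetaMixedRegression` (default: batch, punisher, cue type and
    punisher x cue interaction, with session-within-cow-within-group
    random intercepts).  The parts share nothing, so joint ML factorises
    into the two separate fits.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "remaining",
        zero_factors: Sequence[str] = ("punisher", "cue"),
        zero_groups: Sequence[str] = ("cow_id",),
        zero_interaction: bool = False,
        positive_factors: Sequence[str] = ("batch", "punisher", "cue"),
        positive_groups: Sequence[str] = ("group_id", "cow_id", "cow_session"),
        positive_interactions: Sequence[tuple[str, str]] = (("punisher", "cue"),),
    ):
        self.data = data.copy()
        y = self.data[response].to_numpy(dtype=float)
        if np.any((y < 0) | (y >= 1)):
            raise ValueError("remaining latencies must lie in [0, 1)")
        self.response = response
        self.data["_is_zero"] = (y == 0).astype(float)
        zi = list(zero_factors)
        z_inter = [("punisher", "cue")] if zero_interaction else []
        self.nogo_model = MixedLogit.from_dataframe(
            self.data, "_is_zero", zi, zero_groups, interactions=z_inter
        )
        pos = self.data[y > 0].copy()
        self.positive_model = BetaMixedRegression.from_dataframe(
            pos, response, list(positive_factors), list(positive_groups),
            interactions=list(positive_interactions),
        )

    def fit(self, **kwargs) -> "HurdleBetaResults":
        nogo = self.nogo_model.fit(**kwargs)
        positive = self.positive_model.fit(**kwargs)
        return HurdleBetaResults(nogo=nogo, positive=positive)


@dataclass
class HurdleBetaResults:
    nogo: MixedResults
    positive: MixedResults

    @property
    def llf(self) -> float:
        return self.nogo.llf + self.positive.llf

    def summary(self) -> str:
        return (
            "Hurdle beta mixed model\n== NoGo part (P[y=0]) ==\n"
            + self.nogo.summary()
            + "\n== Positive part (y | y>0) ==\n"
            + self.positive.summary()
        )


# ---------------------------------------------------------------------------
# spec-style front door


@dataclass
class ModelSpec:
    """Declarative description of one of the two trial-level models."""

    response: str  # "binary_correct" or "hurdle_remaining_latency"
    binary_column: str = "correct"
    remaining_column: str = "remaining"
    include_interaction: bool = True
    nogo_interaction: bool = False


def fit_model(spec: ModelSpec, data: pd.DataFrame):
    """Fit the model described by ``spec`` on a trial-level DataFrame.

    The DataFrame needs columns ``batch``, ``punisher``, ``cue``,
    ``group_id``, ``cow_id``, ``cow_session`` plus the response column.
    """
    inter = [("punisher", "cue")] if spec.include_interaction else []
    if spec.response == "binary_correct":
        model = MixedLogit.from_dataframe(
            data,
            spec.binary_column,
            ["batch", "punisher", "cue"],
            ["group_id", "cow_id", "cow_session"],
            interactions=inter,
        )
        return model.fit()
    if spec.response == "hurdle_remaining_latency":
        model = HurdleBetaModel(
            data,
            response=spec.remaining_column,
            zero_interaction=spec.nogo_interaction,
            positive_interactions=inter,
        )
        return model.fit()
    raise ValueError(f"unknown response kind {spec.response!r}")
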