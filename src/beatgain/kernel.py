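"""Psychophysical-kernel estimation: probit regression of choice on tones.

The observer model is

    P(high) = Phi( sum_k g_tar_k * f_tar_k + sum_k g_dis_k * f_dis_k + b )

where ``f`` are tone frequencies in base-2 log distance from the reference,
``g`` are per-position sensory gains, ``b`` is an additive response bias and
``Phi`` the cumulative normal.  Fitting this across trials by maximum
likelihood recovers the weight each tone position carried in the decision
(psychophysical reverse correlation).  Gains are pooled across positions,
separately for targets and distractors, by arithmetic mean.

The link is probit; a logit option is exposed but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import IntegrityError
from .sequences import ROLE_DISTRACTOR, ROLE_TARGET, trials_to_table

__all__ = [
    "build_design", "fit_probit", "pool_gains", "influence_by_distance",
    "ChoiceKernelModel", "ChoiceKernelResults", "GainEstimate",
]


def _as_tones_table(tones) -> pd.DataFrame:
    if isinstance(tones, pd.DataFrame):
        return tones
    return trials_to_table(list(tones))


def _as_choices_table(choices) -> pd.DataFrame:
    if isinstance(choices, pd.DataFrame):
        return choices
    rows = [(c.trial_id, c.choice) for c in choices]
    return pd.DataFrame(rows, columns=["trial_id", "choice"])


def _role_matrix(tones: pd.DataFrame, role: str, prefix: str,
                 trial_ids: pd.Index) -> pd.DataFrame:
    sub = tones[tones["role"] == role]
    mat = sub.pivot_table(index="trial_id", columns="index_in_role",
                          values="f_log2", aggfunc="first")
    mat = mat.reindex(trial_ids)
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise IntegrityError(
            f"missing {role} tones for trial(s) {bad[:5]}"
            + ("..." if len(bad) > 5 else ""))
    mat.columns = [f"{prefix}_{int(k)}" for k in mat.columns]
    return mat


def build_design(tones, choices) -> tuple[pd.DataFrame, pd.Series]:
    """Build the trial-by-regressor matrix and binary response vector.

    One row per trial; one column per target position (``g_tar_k``), per
    distractor position (``g_dis_k``), plus an intercept (the response
    bias).  The response is 1 for a "high" choice.

    Raises
    ------
    IntegrityError
        if any trial lacks a choice or any expected tone position, naming
        the offending trial(s).
    """
    tones = _as_tones_table(tones)
    ch = _as_choices_table(choices)
    if ch["trial_id"].duplicated().any():
        dup = ch.loc[ch["trial_id"].duplicated(), "trial_id"].tolist()
        raise IntegrityError(f"duplicate choices for trial(s) {dup[:5]}")
    trial_ids = pd.Index(sorted(tones["trial_id"].unique()), name="trial_id")
    ch = ch.set_index("trial_id")
    missing = trial_ids.difference(ch.index)
    if len(missing):
        raise IntegrityError(f"no choice recorded for trial(s) "
                             f"{missing.tolist()[:5]}")
    X = pd.concat([
        _role_matrix(tones, ROLE_TARGET, "g_tar", trial_ids),
        _role_matrix(tones, ROLE_DISTRACTOR, "g_dis", trial_ids),
    ], axis=1)
    X["bias"] = 1.0
    y = (ch.loc[trial_ids, "choice"] == "high").astype(int)
    y.name = "choice_high"
    return X, y


class ChoiceKernelModel:
    """Probit (or logit) choice model with per-tone-position gain weights.

    Parameters
    ----------
    endog : binary response (1 = "high" choice), one entry per trial.
    exog : design matrix with named columns; the column named ``bias`` (or
        the last column) is the intercept.
    link : "probit" (the model as specified) or "logit".
    ridge : optional L2 penalty weight on the gain coefficients (never on
        the bias); 0 disables it.
    """

    def __init__(self, endog, exog, link: str = "probit", ridge: float = 0.0):
        if link not in ("probit", "logit"):
            raise ValueError(f"link must be 'probit' or 'logit', got {link!r}")
        self.exog = pd.DataFrame(exog)
        self.endog = pd.Series(endog).astype(int)
        if not self.endog.isin((0, 1)).all():
            raise ValueError("responses must be binary (0/1)")
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        self.link = link
        self.ridge = float(ridge)
        n, k = self.exog.shape
        if n < 10 * k:
            warnings.warn(
                f"only {n} trials for {k} parameters (<10x); estimates may "
                "be unstable", stacklevel=2)

    @classmethod
    def from_tables(cls, tones, choices, link: str = "probit",
                    ridge: float = 0.0) -> "ChoiceKernelModel":
        X, y = build_design(tones, choices)
        return cls(y, X, link=link, ridge=ridge)

    # -- likelihood machinery (used directly only on the ridge path) -------

    def _cdf(self, z):
        if self.link == "probit":
            return scipy.special.ndtr(z)
        return scipy.special.expit(z)

    def loglik(self, params: np.ndarray) -> float:
        """Unpenalized Bernoulli log-likelihood at ``params``."""
        z = self.exog.to_numpy() @ np.asarray(params, dtype=float)
        p = np.clip(self._cdf(z), 1e-12, 1 - 1e-12)
        y = self.endog.to_numpy()
        return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    def _penalty_mask(self) -> np.ndarray:
        return np.array([c != "bias" for c in self.exog.columns], dtype=float)

    def fit(self, tol: float = 1e-8, maxiter: int = 200) -> "ChoiceKernelResults":
        """Maximum-likelihood fit; flags (not raises on) perfect separation."""
        y, X = self.endog, self.exog
        if y.nunique() < 2:
            return self._separated(
                f"all responses are {'high' if y.iloc[0] else 'low'}; "
                "the likelihood has no interior maximum")
        if self.ridge > 0:
            return self._fit_ridge(tol, maxiter)
        fam = sm.Probit if self.link == "probit" else sm.Logit
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fam(y.to_numpy(), X.to_numpy()).fit(
                    method="newton", maxiter=maxiter, tol=tol, disp=0,
                    warn_convergence=False)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            return self._separated(f"fit failed ({exc}); data are likely "
                                   "perfectly separated")
        params = pd.Series(res.params, index=X.columns)
        if np.abs(params).max() > 50:
            return self._separated(
                "diverging coefficients (|beta| > 50); data are likely "
                "perfectly separated")
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        return ChoiceKernelResults(
            model=self, params=params, cov=cov, llf=float(res.llf),
            converged=bool(res.mle_retvals.get("converged", False)))

    def _fit_ridge(self, tol, maxiter):
        y = self.endog.to_numpy().astype(float)
        Xm = self.exog.to_numpy()
        mask = self._penalty_mask()
        alpha = self.ridge

        def negloglik(beta):
            return -self.loglik(beta) + alpha * np.sum(mask * beta ** 2)

        def grad(beta):
            z = Xm @ beta
            p = np.clip(self._cdf(z), 1e-12, 1 - 1e-12)
            if self.link == "probit":
                phi = np.exp(-0.5 * z ** 2) / np.sqrt(2 * np.pi)
                w = (y - p) * phi / (p * (1 - p))
            else:
                w = y - p
            return -Xm.T @ w + 2 * alpha * mask * beta

        beta0 = np.zeros(Xm.shape[1])
        opt = scipy.optimize.minimize(negloglik, beta0, jac=grad,
                                      method="BFGS",
                                      options={"gtol": tol, "maxiter": maxiter})
        params = pd.Series(opt.x, index=self.exog.columns)
        # curvature of the penalized objective, by finite differences of grad
        H = scipy.optimize.approx_fprime(opt.x, grad, 1e-6)
        H = 0.5 * (H + H.T)
        cov = pd.DataFrame(np.linalg.pinv(H), index=self.exog.columns,
                           columns=self.exog.columns)
        return ChoiceKernelResults(model=self, params=params, cov=cov,
                                   llf=self.loglik(opt.x),
                                   converged=bool(opt.success))

    def _separated(self, message: str) -> "ChoiceKernelResults":
        nan = pd.Series(np.nan, index=self.exog.columns)
        cov = pd.DataFrame(np.nan, index=self.exog.columns,
                           columns=self.exog.columns)
        return ChoiceKernelResults(model=self, params=nan, cov=cov,
                                   llf=np.nan, converged=False,
                                   separation=True, diagnostic=message)


@dataclass
class ChoiceKernelResults:
    """Fitted psychophysical kernel: gains, bias, uncertainties, diagnostics."""

    model: ChoiceKernelModel
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool
    separation: bool = False
    diagnostic: str = ""

    # -- named views --------------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def _role_params(self, prefix: str) -> pd.Series:
        cols = [c for c in self.params.index if c.startswith(prefix)]
        return self.params[cols]

    @property
    def g_target_by_pos(self) -> pd.Series:
        return self._role_params("g_tar_")

    @property
    def g_distractor_by_pos(self) -> pd.Series:
        return self._role_params("g_dis_")

    @property
    def bias(self) -> float:
        return float(self.params["bias"])

    @property
    def g_target_pooled(self) -> float:
        return float(self.g_target_by_pos.mean())

    @property
    def g_distractor_pooled(self) -> float:
        return float(self.g_distractor_by_pos.mean())

    def pooled_se(self, role: str = "target") -> float:
        """Delta-method s.e. of the pooled (mean) gain for a role."""
        prefix = "g_tar_" if role == "target" else "g_dis_"
        cols = [c for c in self.params.index if c.startswith(prefix)]
        w = np.zeros(len(self.params))
        idx = [self.params.index.get_loc(c) for c in cols]
        w[idx] = 1.0 / len(cols)
        return float(np.sqrt(w @ self.cov.to_numpy() @ w))

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def to_dict(self) -> dict:
        return {
            "link": self.model.link,
            "ridge": self.model.ridge,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "llf": None if np.isnan(self.llf) else self.llf,
            "converged": self.converged,
            "separation": self.separation,
            "diagnostic": self.diagnostic,
            "nobs": self.nobs,
            "g_target_pooled": None if self.separation else self.g_target_pooled,
            "g_distractor_pooled": None if self.separation else self.g_distractor_pooled,
        }

    def summary(self) -> str:
        lines = [
            "Psychophysical kernel (choice ~ tone frequencies)",
            f"  link: {self.model.link}   n trials: {self.nobs}   "
            f"loglik: {self.llf:.3f}   converged: {self.converged}",
        ]
        if self.separation:
            lines.append(f"  SEPARATION: {self.diagnostic}")
            return "\n".join(lines)
        lines.append(f"  {'param':<10}{'coef':>10}{'s.e.':>10}")
        for name, val in self.params.items():
            lines.append(f"  {name:<10}{val:>10.4f}{self.bse[name]:>10.4f}")
        lines.append(f"  pooled target gain:     {self.g_target_pooled:.4f} "
                     f"(s.e. {self.pooled_se('target'):.4f})")
        lines.append(f"  pooled distractor gain: {self.g_distractor_pooled:.4f} "
                     f"(s.e. {self.pooled_se('distractor'):.4f})")
        return "\n".join(lines)

    def plot_gains(self, ax=None):
        """Bar plot of per-position gains, targets vs distractors."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        gt, gd = self.g_target_by_pos, self.g_distractor_by_pos
        ax.bar(np.arange(len(gt)) - 0.2, gt.to_numpy(), width=0.4,
               label="targets")
        ax.bar(np.arange(len(gd)) + 0.2, gd.to_numpy(), width=0.4,
               label="distractors")
        ax.set_xlabel("position in role")
        ax.set_ylabel("sensory gain")
        ax.legend()
        return ax


#: Domain-named alias: a fitted kernel is the gain estimate.
GainEstimate = ChoiceKernelResults


def fit_probit(design, responses, tol: float = 1e-8,
               link: str = "probit", ridge: float = 0.0) -> ChoiceKernelResults:
    """Fit the per-position gain model to a prebuilt design matrix."""
    return ChoiceKernelModel(responses, design, link=link, ridge=ridge).fit(tol=tol)


def pool_gains(est: ChoiceKernelResults) -> tuple[float, float]:
    """Arithmetic means of the per-position gains, (target, distractor)."""
    return est.g_target_pooled, est.g_distractor_pooled


def influence_by_distance(tones, choices, n_bins: int = 4) -> pd.DataFrame:
    """Influence of tones on choice as a function of |f_log2|.

    Tones of each role are binned by the absolute log-frequency distance
    from the reference (quantile bins).  For each role x bin, the regressor
    is the per-trial sum of sign(f) over tones falling in the bin; a probit
    regression of choice on all role-bin regressors (plus intercept) gives
    the per-bin influence weights.  For a probit observer, influence grows
    with |f| for gained roles and is flat for zero-gain roles.

    Returns a frame with columns (role, bin, absf_center, weight, se, n_tones).
    """
    tones = _as_tones_table(tones)
    ch = _as_choices_table(choices)
    trial_ids = pd.Index(sorted(tones["trial_id"].unique()), name="trial_id")
    y = (ch.set_index("trial_id").loc[trial_ids, "choice"] == "high").astype(int)

    cols = {}
    meta = []
    for role, prefix in ((ROLE_TARGET, "tar"), (ROLE_DISTRACTOR, "dis")):
        sub = tones[tones["role"] == role].copy()
        if len(sub) < n_bins:
            raise IntegrityError(f"fewer {role} tones ({len(sub)}) than bins")
        absf = sub["f_log2"].abs()
        binned = pd.qcut(absf, n_bins, labels=False, duplicates="drop")
        n_eff = int(binned.max()) + 1
        if n_eff < n_bins:
            warnings.warn(f"{role}: merged {n_bins - n_eff} empty |f| bins",
                          stacklevel=2)
        sub["bin"] = binned
        sub["signf"] = np.sign(sub["f_log2"])
        for b in range(n_eff):
            g = sub[sub["bin"] == b]
            s = g.groupby("trial_id")["signf"].sum().reindex(trial_ids).fillna(0.0)
            cols[f"{prefix}_bin{b}"] = s
            meta.append((role, b, float(g["f_log2"].abs().mean()), len(g)))
    X = pd.DataFrame(cols, index=trial_ids)
    X["bias"] = 1.0
    res = ChoiceKernelModel(y, X).fit()
    rows = []
    for (role, b, center, n_tones) in meta:
        name = f"{'tar' if role == ROLE_TARGET else 'dis'}_bin{b}"
        rows.append((role, b, center, float(res.params[name]),
                     float(res.bse[name]), n_tones))
    return pd.DataFrame(rows, columns=["role", "bin", "absf_center",
                                       "weight", "se", "n_tones"])
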