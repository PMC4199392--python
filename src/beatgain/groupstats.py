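"""Group-level inference on per-participant estimates.

Per-participant fitting happens first (kernel / phase modules); the
functions here operate on the resulting per-participant effect values:
standard parametric tests (t-tests, Pearson correlation, 2x2
repeated-measures ANOVA), a Watson-Williams test for the equality of mean
directions of circular samples (preferred phases), and an AIC-based Bayes
factor contrasting a zero-mean Gaussian account of the per-participant
effects against one with a free mean.

For the Bayes factor, with sigma0^2 the mean square about zero and sigma1^2
the ML variance about the sample mean,

    BF = exp((AIC_null - AIC_effect) / 2) = e^-1 * (sigma0^2 / sigma1^2)^(n/2),

so BF > 1 favours the effect model; a sample whose mean is exactly zero
gives BF = e^-1.  BF < 1/3 is read as substantial evidence for the null,
BF > 3 as substantial evidence for the effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DegenerateSampleError

__all__ = [
    "EffectSample", "BayesFactorResult", "TestResult", "aic_bayes_factor",
    "watson_williams", "paired_t", "one_sample_t", "two_sample_t",
    "pearson_r", "rm_anova_2x2", "write_report", "format_report",
]


@dataclass(frozen=True)
class EffectSample:
    """Per-participant values of one within-subject effect."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("an effect sample needs at least 2 participants")
        if not np.all(np.isfinite(v)):
            raise ValueError("effect values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p: float
    name: str = ""
    warning: str = ""

    def to_dict(self) -> dict:
        return {"name": self.name, "statistic": self.statistic,
                "df": self.df, "p": self.p,
                **({"warning": self.warning} if self.warning else {})}


@dataclass(frozen=True)
class BayesFactorResult:
    bf: float
    aic_null: float
    aic_effect: float
    loglik_null: float
    loglik_effect: float
    n: int

    @property
    def verdict(self) -> str:
        if self.bf < 1.0 / 3.0:
            return "favors_null"
        if self.bf > 3.0:
            return "favors_effect"
        return "inconclusive"

    def to_dict(self) -> dict:
        return {"bf": self.bf, "aic_null": self.aic_null,
                "aic_effect": self.aic_effect, "verdict": self.verdict,
                "n": self.n}


def _gaussian_ml_loglik(n: int, sigma2: float) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def aic_bayes_factor(sample: EffectSample | np.ndarray) -> BayesFactorResult:
    """AIC-based Bayes factor: free-mean vs zero-mean Gaussian.

    Both models are fitted by maximum likelihood in closed form: the null
    fixes the mean at 0 (1 free parameter, the s.d.), the effect model frees
    it (2 parameters).  AIC = 2k - 2*loglik and
    BF = exp((AIC_null - AIC_effect)/2).
    """
    if not isinstance(sample, EffectSample):
        sample = EffectSample(np.asarray(sample, dtype=float))
    v, n = sample.values, sample.n
    if n < 3:
        raise ValueError("need at least 3 participants for the Bayes factor")
    sigma2_null = float(np.mean(v ** 2))
    sigma2_eff = float(np.mean((v - v.mean()) ** 2))
    if sigma2_eff <= 0.0 or sigma2_null <= 0.0:
        raise DegenerateSampleError("sample variance is zero; the Gaussian "
                                    "likelihood is degenerate")
    ll0 = _gaussian_ml_loglik(n, sigma2_null)
    ll1 = _gaussian_ml_loglik(n, sigma2_eff)
    aic0, aic1 = 2.0 * 1 - 2.0 * ll0, 2.0 * 2 - 2.0 * ll1
    return BayesFactorResult(bf=float(np.exp((aic0 - aic1) / 2.0)),
                             aic_null=aic0, aic_effect=aic1,
                             loglik_null=ll0, loglik_effect=ll1, n=n)


# ---------------------------------------------------------------------------
# circular: Watson-Williams
# ---------------------------------------------------------------------------

def _kappa_from_rbar(rbar: float) -> float:
    """Fisher's approximation to the von Mises concentration."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def _resultant_length(phases: np.ndarray) -> float:
    return float(np.hypot(np.sum(np.cos(phases)), np.sum(np.sin(phases))))


def watson_williams(phases_a, phases_b) -> TestResult:
    """Watson-Williams F test for equal mean directions of two samples.

    Phases in radians.  Uses the standard F statistic with the von Mises
    concentration correction factor 1 + 3/(8*kappa); df = (1, n_a+n_b-2).
    The test assumes reasonably concentrated samples — a mean resultant
    length below ~0.45 sets a validity warning on the result.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 phases")
    n = a.size + b.size
    ra, rb = _resultant_length(a), _resultant_length(b)
    r_all = _resultant_length(np.concatenate([a, b]))
    rw = (ra + rb) / n
    warning = ""
    if rw < 0.45:
        warning = (f"mean resultant length {rw:.2f} < 0.45; samples too "
                   "dispersed for a reliable Watson-Williams test")
    kappa = _kappa_from_rbar(rw)
    g = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = n - (ra + rb)
    if denom <= 0:
        F = 0.0
    else:
        F = float(g * (n - 2) * max(0.0, ra + rb - r_all) / denom)
    p = float(scipy.stats.f.sf(F, 1, n - 2))
    return TestResult(statistic=F, df=(1, n - 2), p=p,
                      name="watson_williams", warning=warning)


# ---------------------------------------------------------------------------
# standard parametric tests
# ---------------------------------------------------------------------------

def paired_t(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have matching lengths")
    return one_sample_t(a - b, 0.0, name="paired_t")


def one_sample_t(a, popmean: float = 0.0, name: str = "one_sample_t") -> TestResult:
    a = np.asarray(a, float)
    if np.ptp(a) == 0.0 and a[0] == popmean:
        # identical values at the null mean: no evidence either way
        return TestResult(0.0, int(a.size - 1), 1.0, name)
    res = scipy.stats.ttest_1samp(a, popmean)
    return TestResult(float(res.statistic), int(a.size - 1),
                      float(res.pvalue), name)


def two_sample_t(a, b) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = scipy.stats.ttest_ind(a, b)
    return TestResult(float(res.statistic), int(a.size + b.size - 2),
                      float(res.pvalue), "two_sample_t")


def pearson_r(x, y) -> TestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("correlation samples must have matching lengths")
    res = scipy.stats.pearsonr(x, y)
    return TestResult(float(res.statistic), int(x.size - 2),
                      float(res.pvalue), "pearson_r")


def rm_anova_2x2(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                 factor_a: str = "a", factor_b: str = "b") -> dict[str, TestResult]:
    """2x2 repeated-measures ANOVA from within-subject contrasts.

    ``data`` is long-format with a subject column and two two-level factor
    columns; replicates within a cell are averaged.  For a 2x2 within
    design each effect has df = (1, n-1) and its F is exactly the square of
    the one-sample t on the corresponding per-subject contrast, which is how
    it is computed here (no sphericity correction is needed at df = 1).

    Returns {"a": ..., "b": ..., "interaction": ...}.
    """
    for col in (dv, subject, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    cells = data.groupby([subject, factor_a, factor_b])[dv].mean().unstack(
        [factor_a, factor_b])
    if cells.shape[1] != 4 or cells.isna().any().any():
        raise ValueError("incomplete 2x2 within-subject cells")
    a_levels = sorted({c[0] for c in cells.columns})
    b_levels = sorted({c[1] for c in cells.columns})
    m = {(ai, bi): cells[(ai, bi)].to_numpy()
         for ai in a_levels for bi in b_levels}
    n = len(cells)
    contrasts = {
        "a": (m[a_levels[0], b_levels[0]] + m[a_levels[0], b_levels[1]]
              - m[a_levels[1], b_levels[0]] - m[a_levels[1], b_levels[1]]) / 2,
        "b": (m[a_levels[0], b_levels[0]] - m[a_levels[0], b_levels[1]]
              + m[a_levels[1], b_levels[0]] - m[a_levels[1], b_levels[1]]) / 2,
        "interaction": (m[a_levels[0], b_levels[0]] - m[a_levels[0], b_levels[1]]
                        - m[a_levels[1], b_levels[0]]
                        + m[a_levels[1], b_levels[1]]),
    }
    out = {}
    for name, c in contrasts.items():
        t = scipy.stats.ttest_1samp(c, 0.0)
        out[name] = TestResult(float(t.statistic ** 2), (1, n - 1),
                               float(t.pvalue), f"rm_anova_{name}")
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def format_report(contrasts: dict) -> str:
    """Human-readable summary of a dict of TestResult / BayesFactorResult."""
    lines = [f"{'contrast':<36}{'statistic':>12}{'df':>12}{'p / verdict':>16}"]
    for name, res in contrasts.items():
        if isinstance(res, BayesFactorResult):
            lines.append(f"{name:<36}{'BF=' + format(res.bf, '.3f'):>12}"
                         f"{res.n:>12}{res.verdict:>16}")
        else:
            df = (f"({res.df[0]},{res.df[1]})" if isinstance(res.df, tuple)
                  else str(res.df))
            lines.append(f"{name:<36}{res.statistic:>12.3f}{df:>12}"
                         f"{res.p:>16.4f}")
            if res.warning:
                lines.append(f"    ! {res.warning}")
    return "\n".join(lines)


def write_report(contrasts: dict, json_path, text_path=None) -> None:
    """Serialize contrasts as structured JSON plus an optional text table."""
    import json
    payload = {name: res.to_dict() for name, res in contrasts.items()}
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(format_report(contrasts) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {obj!r}")
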