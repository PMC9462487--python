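"""Inverse-variance random-effects meta-analysis of per-study log odds ratios.

The model is y_i = mu + u_i + e_i with u_i ~ N(0, tau2) between-study
heterogeneity and e_i ~ N(0, v_i) known within-study variances.  tau2 is
estimated by restricted maximum likelihood (bracketed 1-D maximization of
the REML criterion, clamped at 0), the pooled effect by weighted least
squares with weights 1/(v_i + tau2), and inference is a Wald-type normal
test on the pooled coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import InputError


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio with its within-study variance (SE^2)."""

    study: str
    y: float
    v: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise InputError(f"study {self.study}: variance must be > 0, got {self.v}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled log-OR with between-study variance and Wald inference."""

    mu: float
    se_mu: float
    tau2: float
    z: float
    p: float
    k: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.mu))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for the pooled OR."""
        zq = norm.ppf(0.5 + level / 2)
        return (float(np.exp(self.mu - zq * self.se_mu)),
                float(np.exp(self.mu + zq * self.se_mu)))


def _reml_criterion(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(-0.5 * np.sum(np.log(v + tau2)) - 0.5 * np.log(np.sum(w))
                 - 0.5 * np.sum(w * (y - mu) ** 2))


def _reml_score(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """d/d tau2 of the REML criterion (envelope theorem: mu held at mu-hat)."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    e2 = (y - mu) ** 2
    return float(0.5 * (-np.sum(w) + np.sum(w ** 2) / np.sum(w)
                        + np.sum(w ** 2 * e2)))


def reml_tau2(effects: list[StudyEffect]) -> float:
    """REML estimate of the between-study variance tau2.

    Maximizes the REML criterion over tau2 >= 0 on the bracket
    [0, 10 * max(v_i) + 2 var(y)]: the score equation is solved by Brent
    root-finding in every sign-change interval of a coarse scan, the
    candidates (plus both endpoints) are compared on the criterion, and
    the winner is returned, clamped at 0.  A single study carries no
    between-study information: tau2 = 0 with a warning.
    """
    if len(effects) < 2:
        warnings.warn("fewer than 2 studies: tau2 set to 0", stacklevel=2)
        return 0.0
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    # bracket must contain any plausible optimum: the REML tau2 is bounded
    # by roughly the sample variance of y (for k = 2 equal variances it is
    # exactly var(y, ddof=1) - v), so twice that plus a generous multiple
    # of the largest within-study variance is safe
    hi = 10.0 * v.max() + 2.0 * float(np.var(y, ddof=1)) + 1e-12
    grid = np.linspace(0.0, hi, 257)
    scores = np.array([_reml_score(t, y, v) for t in grid])
    candidates = [0.0, hi]
    for a, b, sa, sb in zip(grid[:-1], grid[1:], scores[:-1], scores[1:]):
        if sa == 0.0:
            candidates.append(float(a))
        elif sa * sb < 0:
            candidates.append(float(brentq(_reml_score, a, b, args=(y, v),
                                           xtol=1e-14, rtol=8.9e-16)))
    best = max(candidates, key=lambda t: _reml_criterion(t, y, v))
    return max(best, 0.0)


def wald_p(mu: float, se_mu: float) -> float:
    """Two-sided Wald p: 2 * (1 - Phi(|mu / se_mu|))."""
    if not se_mu > 0:
        raise InputError(f"se_mu must be > 0, got {se_mu}")
    return float(2.0 * norm.sf(abs(mu / se_mu)))


def combine(effects: list[StudyEffect]) -> MetaResult:
    """Pool study effects with inverse-variance weights 1/(v_i + tau2)."""
    if not effects:
        raise InputError("no studies to combine")
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    tau2 = reml_tau2(effects) if len(effects) >= 2 else 0.0
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = mu / se
    return MetaResult(mu=mu, se_mu=se, tau2=tau2, z=z, p=wald_p(mu, se), k=len(effects))


def read_effects_tsv(path, approx_se_from_p: bool = False) -> list[StudyEffect]:
    """Read per-study effects from a TSV.

    Expected columns are (study, log_or, se); alternatively (study, or, p)
    when ``approx_se_from_p`` is set, in which case the SE is back-derived
    as |log OR| / Phi^-1(1 - p/2) — a crude inversion that is only valid
    if the study p came from a Wald test, hence the explicit opt-in and
    warning.
    """
    frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    if "log_or" in cols and "se" in cols:
        return [StudyEffect(str(r[cols.get("study", frame.columns[0])]),
                            float(r[cols["log_or"]]), float(r[cols["se"]]) ** 2)
                for _, r in frame.iterrows()]
    if approx_se_from_p and "or" in cols and "p" in cols:
        warnings.warn("approximating SE from (OR, p); valid only for Wald-derived p",
                      stacklevel=2)
        out = []
        for _, r in frame.iterrows():
            log_or = float(np.log(float(r[cols["or"]])))
            zq = norm.isf(float(r[cols["p"]]) / 2)
            if zq <= 0:
                raise InputError(f"cannot derive SE from p = {r[cols['p']]}")
            out.append(StudyEffect(str(r[cols.get("study", frame.columns[0])]),
                                   log_or, (abs(log_or) / zq) ** 2))
        return out
    raise InputError("effects TSV needs (study, log_or, se) columns, or "
                     "(study, or, p) with approx_se_from_p=True")
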