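"""Functional-site identification from stability vs evolutionary fitness.

Per domain, normalized stability (f in [-1, 0]) is modelled as a sigmoid of
an evolutionary fitness score s:

    f_hat = -1 + 1 / (1 + exp(-(s - xmid) / scal))

Mutations whose evolutionary fitness is lower than their stability effect
explains sit above the curve (positive residual); significant positive
residuals mark functional mutations, and residues with large
inverse-variance-weighted mean residuals are called functional sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import bh_fdr
from .datatypes import PredictorScore
from .qc import NormalizedFitness


def sigmoid(s: np.ndarray, xmid: float, scal: float) -> np.ndarray:
    return -1.0 + 1.0 / (1.0 + np.exp(-(s - xmid) / scal))


def stability_fit_weights(f: np.ndarray) -> np.ndarray:
    """Fit weights prioritizing low-stability variants:
    w_i = (max(f) - min(f) - (f_i + 1))^2."""
    f = np.asarray(f, float)
    return (f.max() - f.min() - (f + 1.0)) ** 2


class SigmoidStabilityCurve(BaseEstimator, RegressorMixin):
    """Weighted sigmoid regression of normalized stability on an
    evolutionary fitness score.

    Parameters
    ----------
    n_restarts : int
        Jittered re-initializations tried after a failed fit.
    random_state : int
        Seed for the jittered restarts.

    Attributes
    ----------
    xmid_ : float
        Sigmoid midpoint on the score axis (f_hat(xmid_) = -0.5).
    scal_ : float
        Steepness, in score units; constrained positive.
    converged_ : bool
    """

    def __init__(self, n_restarts: int = 5, random_state: int = 0,
                 maxfev: int = 10000):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.maxfev = maxfev

    def fit(self, X, y, sample_weight=None):
        s = np.asarray(X, float).reshape(-1)
        f = np.asarray(y, float)
        if s.size != f.size:
            raise ValueError("X and y must have the same length")
        if sample_weight is None:
            sample_weight = stability_fit_weights(f)
        w = np.asarray(sample_weight, float)
        # curve_fit takes per-point sigma: w = 1/sigma^2
        cf_sigma = 1.0 / np.sqrt(np.maximum(w, 1e-12))
        p5, p95 = np.percentile(s, [5, 95])
        inits = [(float(np.median(s)), max((p95 - p5) / 10.0, 1e-3))]
        rng = np.random.default_rng(self.random_state)
        for _ in range(self.n_restarts):
            inits.append(
                (
                    float(rng.uniform(p5, p95)),
                    float(np.exp(rng.uniform(np.log(1e-2),
                                             np.log(max(p95 - p5, 1.0))))),
                )
            )
        self.converged_ = False
        self.xmid_ = np.nan
        self.scal_ = np.nan
        for x0 in inits:
            try:
                popt, _ = curve_fit(
                    sigmoid, s, f, p0=x0, sigma=cf_sigma,
                    bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                    maxfev=self.maxfev,
                )
            except RuntimeError:
                continue
            if np.all(np.isfinite(popt)):
                self.xmid_, self.scal_ = float(popt[0]), float(popt[1])
                self.converged_ = True
                break
        return self

    def predict(self, X):
        check_is_fitted(self, "xmid_")
        return sigmoid(np.asarray(X, float).reshape(-1), self.xmid_,
                       self.scal_)


@dataclass
class SigmoidFit:
    """A fitted stability-vs-evolutionary-fitness curve with residuals."""

    domain_id: str
    xmid: float
    scal: float
    converged: bool
    keys: list[tuple] = field(default_factory=list)
    positions: np.ndarray | None = None
    f_norm: np.ndarray | None = None
    scores: np.ndarray | None = None
    sigma_norm: np.ndarray | None = None
    predicted: np.ndarray | None = None
    weights: np.ndarray | None = None
    residuals: np.ndarray | None = None


@dataclass
class VarianceExplained:
    r_xy: float
    r_xx: float
    R_xy: float
    fraction: float
    r_xy_rank: float = np.nan
    R_xy_rank: float = np.nan


def check_eligibility(
    normalized: list[NormalizedFitness],
    scores: list[PredictorScore],
    max_wt_exceed_fraction: float = 0.30,
    min_score_range: float = 10.0,
    min_variants: int = 20,
) -> tuple[bool, list[str]]:
    """Eligibility of a domain for the sigmoid decomposition.

    (1) the wild type must lie within the top 30% of the fitness
    distribution: the fraction of variants strictly fitter than the wild
    type (f_norm > 0) must be < 0.30; (2) the 5th-95th percentile range of
    the evolutionary score must exceed ``min_score_range``.
    """
    score_by_key = {s.key: s.score for s in scores}
    joint = [v for v in normalized if v.key in score_by_key
             and v.variant_class == "missense"]
    reasons: list[str] = []
    if len(joint) < min_variants:
        return False, [f"fewer than {min_variants} joint variants"]
    f = np.array([v.f_norm for v in joint])
    frac_above = float(np.mean(f > 0))
    if frac_above >= max_wt_exceed_fraction:
        reasons.append(
            f"wild type not among the fittest variants "
            f"({100 * frac_above:.0f}% of variants above wild type)"
        )
    s = np.array([score_by_key[v.key] for v in joint])
    p5, p95 = np.percentile(s, [5, 95])
    if not (p95 - p5 > min_score_range):
        reasons.append(
            f"evolutionary score range {p95 - p5:.2f} <= {min_score_range}"
        )
    return (not reasons), reasons


def fit_sigmoid(
    normalized: list[NormalizedFitness],
    scores: list[PredictorScore],
    seed: int = 0,
) -> SigmoidFit:
    """Fit the weighted sigmoid for one domain and record residuals.

    Only missense variants with both a normalized fitness and a score are
    used. Residual r_i = f_i - f_hat_i: positive residual = observed
    stability above the curve.
    """
    score_by_key = {s.key: s.score for s in scores}
    joint = [v for v in normalized if v.key in score_by_key
             and v.variant_class == "missense"]
    if len(joint) < 20:
        raise ValueError("fit_sigmoid needs >= 20 joint variants")
    domain_id = joint[0].domain_id
    f = np.array([v.f_norm for v in joint])
    s = np.array([score_by_key[v.key] for v in joint])
    sig = np.array([v.sigma_norm for v in joint])
    w = stability_fit_weights(f)
    est = SigmoidStabilityCurve(random_state=seed).fit(s, f, sample_weight=w)
    fit = SigmoidFit(
        domain_id=domain_id,
        xmid=est.xmid_,
        scal=est.scal_,
        converged=est.converged_,
        keys=[v.key for v in joint],
        positions=np.array([v.position for v in joint]),
        f_norm=f,
        scores=s,
        sigma_norm=sig,
        weights=w,
    )
    if est.converged_:
        fit.predicted = est.predict(s)
        fit.residuals = f - fit.predicted
    return fit


def call_functional_mutations(
    fit: SigmoidFit,
    fdr: float = 0.1,
    residual_cut: float = 0.3,
) -> pd.DataFrame:
    """Flag mutations whose evolutionary fitness loss exceeds what
    stability explains.

    z = residual / sigma_norm, two-tailed normal p, BH-FDR within the
    domain; functional iff q < fdr AND residual > residual_cut.
    """
    if not fit.converged:
        raise ValueError(f"{fit.domain_id}: sigmoid fit did not converge")
    z = fit.residuals / fit.sigma_norm
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    functional = (q < fdr) & (fit.residuals > residual_cut)
    return pd.DataFrame(
        {
            "domain_id": fit.domain_id,
            "position": fit.positions,
            "wt_aa": [k[2] for k in fit.keys],
            "mut_aa": [k[3] for k in fit.keys],
            "f_norm": fit.f_norm,
            "score": fit.scores,
            "predicted": fit.predicted,
            "residual": fit.residuals,
            "z": z,
            "p": p,
            "q": q,
            "functional": functional,
        }
    )


def call_functional_sites(
    fit: SigmoidFit,
    site_cut: float = 0.3,
    min_substitutions: int = 3,
) -> pd.DataFrame:
    """Per-residue functional-site calls from weighted mean residuals.

    Residual means are weighted by the inverse variance of the normalized
    fitness (1/sigma_norm^2); a residue is a site iff its weighted mean
    residual exceeds ``site_cut``. Residues with fewer than
    ``min_substitutions`` measured substitutions get no call.
    """
    if not fit.converged:
        raise ValueError(f"{fit.domain_id}: sigmoid fit did not converge")
    rows = []
    for pos in np.unique(fit.positions):
        mask = fit.positions == pos
        n = int(mask.sum())
        if n < min_substitutions:
            rows.append(
                {"domain_id": fit.domain_id, "position": int(pos), "n": n,
                 "weighted_mean_residual": np.nan, "is_site": False,
                 "reason": f"fewer than {min_substitutions} substitutions"}
            )
            continue
        w = 1.0 / fit.sigma_norm[mask] ** 2
        wm = float(np.sum(w * fit.residuals[mask]) / np.sum(w))
        rows.append(
            {"domain_id": fit.domain_id, "position": int(pos), "n": n,
             "weighted_mean_residual": wm, "is_site": wm > site_cut,
             "reason": ""}
        )
    return pd.DataFrame(rows)


def variance_explained(
    f_norm: np.ndarray,
    scores: np.ndarray,
    rep_corr: float,
) -> VarianceExplained:
    """Fraction of evolutionary fitness variance explained by stability,
    disattenuated for measurement noise: R_xy = r_xy / sqrt(r_xx).

    Both the Pearson and rank (Spearman) versions are computed; the linear
    version is reported as the headline fraction (R_xy^2, clipped at 1).
    """
    if not (0 < rep_corr <= 1):
        raise ValueError(f"replicate correlation must be in (0, 1], "
                         f"got {rep_corr}")
    f = np.asarray(f_norm, float)
    s = np.asarray(scores, float)
    r_xy = float(np.corrcoef(f, s)[0, 1])
    r_rank = float(stats.spearmanr(f, s).statistic)
    R_xy = r_xy / np.sqrt(rep_corr)
    R_rank = r_rank / np.sqrt(rep_corr)
    fraction = R_xy ** 2
    if fraction > 1.0:
        warnings.warn(
            f"disattenuation overcorrects (R_xy = {R_xy:.3f}); "
            "fraction clipped at 1", stacklevel=2,
        )
        fraction = 1.0
    return VarianceExplained(
        r_xy=r_xy, r_xx=float(rep_corr), R_xy=float(R_xy),
        fraction=float(fraction), r_xy_rank=r_rank, R_xy_rank=float(R_rank),
    )
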