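"""Two-state thermodynamic (Boltzmann) energy models of domain families.

The model assumes every mutation causes the same folding free-energy change
(ddG) in all homologous domains and that energies combine additively:

    dG(variant) = b0 + sum_c U[c, wt_aa(c)] + D[c_mut, mut_aa]
    p_f = 1 / (1 + exp(dG))            (fraction folded, RT = 1)
    fitness = gamma0 + gamma1 * p_f    (affine output map, gamma1 > 0)

U holds per-(alignment column, amino acid) wild-type composition energies
(so each homologue's baseline stability is determined by its sequence), D
the shared mutation energies. The model is fitted by weighted least squares
with per-variant measurement errors and a small ridge penalty, evaluated by
tenfold cross-validation and leave-one-homologue-out, and can predict
variants in homologues never measured.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import bh_fdr
from .datatypes import (
    AA_INDEX,
    AMINO_ACIDS,
    GAP,
    FamilyAlignment,
    VariantFitness,
)

N_AA = len(AMINO_ACIDS)


@dataclass
class FamilyEncoding:
    """Design-matrix description of one family's variants.

    Wild-type identity features live in the composition matrix ``comp``
    (one row per homologue over L x 20 one-hot columns); each missense
    variant additionally activates one shared mutation feature
    (column, mutant amino acid), indexed as (column-1) * 20 + aa_index.
    """

    family_id: str
    n_columns: int
    hom_ids: list[str]
    comp: np.ndarray                 # (n_hom, L*20) 0/1 wt composition
    hom_idx: np.ndarray              # (n,) homologue index per variant
    mut_feat: np.ndarray             # (n,) mutation feature, -1 = wild type
    fitness: np.ndarray              # (n,)
    sigma: np.ndarray                # (n,)
    keys: list[tuple] = field(default_factory=list)
    replicates: np.ndarray | None = None   # (n, k) growth rates, optional
    columns: np.ndarray | None = None      # (n,) 1-based alignment column

    @property
    def n_variants(self) -> int:
        return len(self.fitness)

    @property
    def n_homologues(self) -> int:
        return len(self.hom_ids)

    def subset(self, mask: np.ndarray) -> "FamilyEncoding":
        return FamilyEncoding(
            family_id=self.family_id,
            n_columns=self.n_columns,
            hom_ids=self.hom_ids,
            comp=self.comp,
            hom_idx=self.hom_idx[mask],
            mut_feat=self.mut_feat[mask],
            fitness=self.fitness[mask],
            sigma=self.sigma[mask],
            keys=[k for k, m in zip(self.keys, mask) if m],
            replicates=None if self.replicates is None
            else self.replicates[mask],
            columns=None if self.columns is None else self.columns[mask],
        )


def moderate_errors(sigma: np.ndarray, n_replicates: int,
                    prior_df: float = 6.0) -> np.ndarray:
    """Shrink per-variant replicate errors toward the pooled error.

    Standard errors estimated from few replicates are chi-distributed with
    k-1 degrees of freedom and make inverse-variance weights unstable; the
    moderated variance ((k-1) s_i^2 + d0 s0^2) / (k-1 + d0) with the pooled
    variance s0^2 stabilizes them (empirical-Bayes style).
    """
    k = n_replicates
    s2 = np.asarray(sigma, float) ** 2 * k
    s0 = s2.mean()
    return np.sqrt((((k - 1) * s2 + prior_df * s0) / ((k - 1) + prior_df))
                   / k)


def encode_family(
    alignment: FamilyAlignment,
    variants: list[VariantFitness],
    min_mean_count: float | None = None,
    error_moderation_df: float | None = 6.0,
) -> FamilyEncoding:
    """Recode variants onto alignment coordinates as model features.

    Nonsense variants are excluded from the energy model; synonymous
    variants carry no mutation feature (wild-type trait). A variant whose
    position maps to a gapped column is a hard error; a mutation equal to
    the homologue's wild type after mapping is treated as synonymous with a
    warning. ``min_mean_count`` applies the upstream read-count filter;
    ``error_moderation_df`` shrinks the few-replicate error estimates
    toward the family-pooled error before they are used as fit weights
    (None disables).
    """
    hom_ids = sorted(alignment.rows)
    hom_index = {d: i for i, d in enumerate(hom_ids)}
    L = alignment.columns
    comp = np.zeros((len(hom_ids), L * N_AA))
    for d, row in alignment.rows.items():
        for c, aa in enumerate(row):
            if aa != GAP and aa in AA_INDEX:
                comp[hom_index[d], c * N_AA + AA_INDEX[aa]] = 1.0

    hom_idx, mut_feat, fitness, sigma, keys, cols, reps = \
        [], [], [], [], [], [], []
    for v in variants:
        if v.variant_class == "nonsense":
            continue
        if v.domain_id not in hom_index:
            raise ValueError(f"variant domain {v.domain_id} not in "
                             f"alignment {alignment.family_id}")
        if min_mean_count is not None and v.counts.size and \
                v.counts.mean() <= min_mean_count:
            continue
        cmap = alignment.column_map[v.domain_id]
        if v.position not in cmap:
            raise ValueError(
                f"{v.domain_id} position {v.position} maps to a gapped "
                f"alignment column"
            )
        col = cmap[v.position]
        row = alignment.rows[v.domain_id]
        wt_at_col = row[col - 1]
        if v.variant_class == "synonymous":
            feat = -1
        elif v.mut_aa == wt_at_col:
            warnings.warn(
                f"{v.domain_id} {v.wt_aa}{v.position}{v.mut_aa}: mutation "
                "equals the wild type at alignment level; treated as "
                "synonymous", stacklevel=2,
            )
            feat = -1
        else:
            feat = (col - 1) * N_AA + AA_INDEX[v.mut_aa]
        hom_idx.append(hom_index[v.domain_id])
        mut_feat.append(feat)
        fitness.append(v.fitness)
        sigma.append(v.sigma)
        keys.append(v.key)
        cols.append(col)
        reps.append(v.growth_rates)
    k = min(len(r) for r in reps) if reps else 0
    sigma_arr = np.array(sigma, dtype=float)
    if error_moderation_df is not None and k > 1:
        sigma_arr = moderate_errors(sigma_arr, k, error_moderation_df)
    return FamilyEncoding(
        family_id=alignment.family_id,
        n_columns=L,
        hom_ids=hom_ids,
        comp=comp,
        hom_idx=np.array(hom_idx, dtype=int),
        mut_feat=np.array(mut_feat, dtype=int),
        fitness=np.array(fitness, dtype=float),
        sigma=sigma_arr,
        keys=keys,
        replicates=np.array([r[:k] for r in reps]) if k else None,
        columns=np.array(cols, dtype=int),
    )


class FamilyEnergyRegressor(BaseEstimator, RegressorMixin):
    """Additive two-state energy model of a domain family.

    Minimizes sum_i (f_i - gamma0 - gamma1 * p_f(dG_i))^2 / sigma_i^2
    + lambda * (||U||^2 + ||D||^2) with L-BFGS and an analytic gradient.
    After fitting, fully covered alignment columns of U are centred over
    the residues observed at that column, absorbing the shift into ``b0_``
    (the gauge-fixing step that makes the parameterization unique).

    Parameters
    ----------
    lambda_reg : float
        Ridge penalty on U and D. Keeps energies with little curvature
        (mutations invisible within the assay's dynamic range, e.g.
        stabilizing changes on an already folded background) pinned near
        zero instead of drifting; 0 reproduces the unregularized model.
    transform : str
        "boltzmann" (fraction folded) or "linear" (discarded variant kept
        for invariance checks only).
    """

    def __init__(
        self,
        lambda_reg: float = 0.1,
        max_iter: int = 5000,
        tol: float = 1e-9,
        n_restarts: int = 5,
        random_state: int = 0,
        init_scale: float = 0.1,
        transform: str = "boltzmann",
    ):
        self.lambda_reg = lambda_reg
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.init_scale = init_scale
        self.transform = transform

    # -- parameter vector layout: [b0, U (L*20), D (L*20), gamma0, gamma1]
    def _unpack(self, theta: np.ndarray, L: int):
        nf = L * N_AA
        b0 = theta[0]
        U = theta[1:1 + nf]
        D = theta[1 + nf:1 + 2 * nf]
        gamma0, gamma1 = theta[-2], theta[-1]
        return b0, U, D, gamma0, gamma1

    def _energies(self, enc: FamilyEncoding, b0, U, D) -> np.ndarray:
        base = enc.comp @ U
        dG = b0 + base[enc.hom_idx]
        has_mut = enc.mut_feat >= 0
        dG = dG + np.where(has_mut, D[np.maximum(enc.mut_feat, 0)], 0.0)
        return dG

    def _loss_grad(self, theta, enc, w):
        L = enc.n_columns
        b0, U, D, gamma0, gamma1 = self._unpack(theta, L)
        dG = self._energies(enc, b0, U, D)
        if self.transform == "boltzmann":
            p = expit(-dG)
            dp_ddG = -p * (1.0 - p)
        else:  # linear (discarded variant, kept for invariance checks)
            p = -dG
            dp_ddG = -np.ones_like(dG)
        pred = gamma0 + gamma1 * p
        err = enc.fitness - pred
        loss = float(np.sum(w * err ** 2)) + self.lambda_reg * (
            float(U @ U) + float(D @ D)
        )
        # gradient
        t = -2.0 * w * err * gamma1 * dp_ddG     # dLoss/ddG_i
        grad = np.zeros_like(theta)
        grad[0] = t.sum()
        # U: through per-homologue baselines
        t_h = np.bincount(enc.hom_idx, weights=t,
                          minlength=enc.n_homologues)
        grad[1:1 + L * N_AA] = enc.comp.T @ t_h + 2 * self.lambda_reg * U
        # D: through mutation features
        has_mut = enc.mut_feat >= 0
        gD = np.bincount(enc.mut_feat[has_mut], weights=t[has_mut],
                         minlength=L * N_AA)
        grad[1 + L * N_AA:1 + 2 * L * N_AA] = gD + 2 * self.lambda_reg * D
        grad[-2] = float(np.sum(-2.0 * w * err))
        grad[-1] = float(np.sum(-2.0 * w * err * p))
        return loss, grad

    def _smart_init(self, enc: FamilyEncoding) -> np.ndarray:
        """Linearized starting point: invert the Boltzmann map on clipped
        fitness, alternate-solve per-homologue baselines and shared D,
        then ridge-solve U from the baselines (minimum-norm)."""
        L = enc.n_columns
        nf = L * N_AA
        f = enc.fitness
        gamma0 = float(np.percentile(f, 1))
        gamma1 = max(float(np.percentile(f, 99) - gamma0), 1e-3)
        p = np.clip((f - gamma0) / gamma1, 2e-3, 1 - 2e-3)
        g = np.log(1.0 / p - 1.0)  # target energies, clipped by p bounds

        beta = np.zeros(enc.n_homologues)
        D = np.zeros(nf)
        has_mut = enc.mut_feat >= 0
        feats = enc.mut_feat[has_mut]
        n_h = np.bincount(enc.hom_idx, minlength=enc.n_homologues)
        n_m = np.bincount(feats, minlength=nf)
        for _ in range(8):
            resid = g - np.where(has_mut, D[np.maximum(enc.mut_feat, 0)],
                                 0.0)
            beta = np.bincount(enc.hom_idx, weights=resid,
                               minlength=enc.n_homologues) / \
                np.maximum(n_h, 1)
            resid = (g - beta[enc.hom_idx])[has_mut]
            D = np.bincount(feats, weights=resid, minlength=nf) / \
                np.maximum(n_m, 1)
        b0 = float(beta.mean())
        # minimum-norm U with comp @ U ~= beta - b0
        C = enc.comp
        gram = C @ C.T + 1e-6 * np.eye(enc.n_homologues)
        U = C.T @ np.linalg.solve(gram, beta - b0)

        theta0 = np.zeros(3 + 2 * nf)
        theta0[0] = b0
        theta0[1:1 + nf] = U
        theta0[1 + nf:1 + 2 * nf] = D
        theta0[-2] = gamma0
        theta0[-1] = gamma1
        return theta0

    def fit(self, X: FamilyEncoding, y=None):
        """Fit the family model. ``X`` is a :class:`FamilyEncoding`;
        ``y`` optionally overrides its fitness vector."""
        enc = X
        fitness = enc.fitness if y is None else np.asarray(y, float)
        enc = enc if y is None else FamilyEncoding(
            family_id=enc.family_id, n_columns=enc.n_columns,
            hom_ids=enc.hom_ids, comp=enc.comp, hom_idx=enc.hom_idx,
            mut_feat=enc.mut_feat, fitness=fitness, sigma=enc.sigma,
            keys=enc.keys, replicates=enc.replicates, columns=enc.columns,
        )
        w = 1.0 / enc.sigma ** 2
        L = enc.n_columns
        nf = L * N_AA
        rng = np.random.default_rng(self.random_state)
        f_min, f_max = float(enc.fitness.min()), float(enc.fitness.max())
        span = max(f_max - f_min, 1e-6)

        bounds = [(None, None)] * (1 + 2 * nf) + \
            [(None, None), (1e-6, None)]  # gamma1 > 0
        best = None
        theta_smart = self._smart_init(enc)
        for attempt in range(1 + self.n_restarts):
            if attempt == 0:
                theta0 = theta_smart
            else:
                theta0 = theta_smart + np.concatenate(
                    [rng.normal(0.0, self.init_scale, 1 + 2 * nf),
                     [0.0, 0.0]]
                )
                theta0[-2] = f_min
                theta0[-1] = span
            res = minimize(
                self._loss_grad, theta0, args=(enc, w), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.tol,
                         "gtol": 1e-8},
            )
            if res.x[-1] > 1e-5 and (best is None or res.fun < best.fun):
                best = res
                break  # first healthy solution wins; restarts are fallback
        if best is None:
            raise RuntimeError(
                f"{enc.family_id}: gamma1 collapsed to <= 0 in all "
                f"{1 + self.n_restarts} seeded restarts"
            )
        b0, U, D, gamma0, gamma1 = self._unpack(best.x, L)
        U = U.reshape(L, N_AA).copy()
        D = D.reshape(L, N_AA).copy()

        # gauge fixing: centre U columns observed in every homologue
        observed = enc.comp.reshape(enc.n_homologues, L, N_AA)
        b0 = float(b0)
        for c in range(L):
            present = observed[:, c, :].sum(axis=0) > 0
            if observed[:, c, :].sum() == enc.n_homologues and present.any():
                m = U[c, present].mean()
                U[c, present] -= m
                b0 += m

        self.family_id_ = enc.family_id
        self.n_columns_ = L
        self.hom_ids_ = list(enc.hom_ids)
        self.b0_ = b0
        self.U_ = U
        self.D_ = D
        self.gamma0_ = float(gamma0)
        self.gamma1_ = float(gamma1)
        self.converged_ = bool(best.success or
                               best.status == 1)  # 1 = maxiter
        self.n_iter_ = int(best.nit)
        self.loss_ = float(best.fun)
        # per-mutation-feature curvature for downstream inference errors
        self._feature_curvature(enc, w)
        return self

    def _feature_curvature(self, enc: FamilyEncoding, w: np.ndarray):
        """Diagonal Gauss-Newton curvature of the D block; the approximate
        standard error of D[m] is 1/sqrt(curvature[m])."""
        dG = self.dG(enc)
        if self.transform == "boltzmann":
            p = expit(-dG)
            dpred = self.gamma1_ * p * (1.0 - p)
        else:
            dpred = np.full_like(dG, self.gamma1_)
        has_mut = enc.mut_feat >= 0
        curv = np.bincount(
            enc.mut_feat[has_mut],
            weights=(w * dpred ** 2)[has_mut],
            minlength=self.n_columns_ * N_AA,
        ) + 2 * self.lambda_reg
        self.feature_curvature_ = curv

    def dG(self, X: FamilyEncoding) -> np.ndarray:
        check_is_fitted(self, "U_")
        return self._energies(
            X, self.b0_, self.U_.reshape(-1), self.D_.reshape(-1)
        )

    def fraction_folded(self, X: FamilyEncoding) -> np.ndarray:
        return expit(-self.dG(X))

    def predict(self, X: FamilyEncoding) -> np.ndarray:
        if self.transform == "boltzmann":
            return self.gamma0_ + self.gamma1_ * self.fraction_folded(X)
        return self.gamma0_ + self.gamma1_ * (-self.dG(X))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "U_")
        cfg = self.get_params()
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {
            "family_id": self.family_id_,
            "n_columns": self.n_columns_,
            "amino_acids": AMINO_ACIDS,
            "hom_ids": self.hom_ids_,
            "seed": self.random_state,
            "config": cfg,
            "config_hash": cfg_hash,
            "b0": self.b0_,
            "U": self.U_.tolist(),
            "D": self.D_.tolist(),
            "gamma0": self.gamma0_,
            "gamma1": self.gamma1_,
            "converged": self.converged_,
            "feature_curvature": self.feature_curvature_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FamilyEnergyRegressor":
        try:
            model = cls(**payload["config"])
            model.family_id_ = payload["family_id"]
            model.n_columns_ = payload["n_columns"]
            model.hom_ids_ = payload["hom_ids"]
            model.b0_ = float(payload["b0"])
            model.U_ = np.array(payload["U"], dtype=float)
            model.D_ = np.array(payload["D"], dtype=float)
            model.gamma0_ = float(payload["gamma0"])
            model.gamma1_ = float(payload["gamma1"])
            model.converged_ = bool(payload["converged"])
            model.feature_curvature_ = np.array(
                payload["feature_curvature"], dtype=float
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"truncated or invalid model payload: {exc}")
        if model.U_.shape != (model.n_columns_, N_AA) or \
                model.D_.shape != (model.n_columns_, N_AA):
            raise ValueError("truncated parameter block in model payload")
        return model


@dataclass
class CrossValReport:
    family_id: str
    fold_assignment: np.ndarray
    per_fold_r: list[float]
    pooled_r: float
    explainable_fraction: float
    predictions: np.ndarray
    failed_folds: list[int] = field(default_factory=list)


@dataclass
class LohoResult:
    domain_id: str
    r: float
    n_variants: int
    mean_hamming: float
    mean_blosum_dist: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def replicate_r_squared(enc: FamilyEncoding) -> float:
    """Mean squared Pearson correlation between replicate growth rates."""
    if enc.replicates is None or enc.replicates.shape[1] < 2:
        return np.nan
    from itertools import combinations

    reps = enc.replicates
    rs = [
        _pearson(reps[:, i], reps[:, j]) ** 2
        for i, j in combinations(range(reps.shape[1]), 2)
    ]
    return float(np.mean(rs))


def tenfold_cv(
    enc: FamilyEncoding,
    model: FamilyEnergyRegressor | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValReport:
    """Held-out performance by seeded variant-level cross-validation.

    Each fold is predicted by a model trained on the other folds; reports
    per-fold and pooled held-out Pearson r and the explainable fraction
    R^2(obs, pred) / R^2(replicate pairs).
    """
    model = model or FamilyEnergyRegressor(random_state=seed)
    rng = np.random.default_rng(seed)
    n = enc.n_variants
    folds = rng.permutation(n) % n_folds
    predictions = np.full(n, np.nan)
    per_fold_r: list[float] = []
    failed: list[int] = []
    for fold in range(n_folds):
        test = folds == fold
        if not test.any():
            continue
        try:
            fitted = FamilyEnergyRegressor(
                **model.get_params()
            ).fit(enc.subset(~test))
            predictions[test] = fitted.predict(enc.subset(test))
            per_fold_r.append(
                _pearson(enc.fitness[test], predictions[test])
            )
        except RuntimeError:
            failed.append(fold)
            per_fold_r.append(np.nan)
    ok = np.isfinite(predictions)
    pooled = _pearson(enc.fitness[ok], predictions[ok])
    rep_r2 = replicate_r_squared(enc)
    explainable = pooled ** 2 / rep_r2 if np.isfinite(rep_r2) else np.nan
    if np.isfinite(explainable) and explainable > 1.05:
        warnings.warn(
            f"{enc.family_id}: explainable fraction {explainable:.3f} "
            "exceeds 1.05", stacklevel=2,
        )
    return CrossValReport(
        family_id=enc.family_id,
        fold_assignment=folds,
        per_fold_r=per_fold_r,
        pooled_r=pooled,
        explainable_fraction=float(explainable),
        predictions=predictions,
        failed_folds=failed,
    )


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def alignment_distances(
    alignment: FamilyAlignment, left_out: str, training: list[str]
) -> tuple[float, float]:
    """Mean Hamming and BLOSUM62-derived distance of one row to others.

    Both are computed over mutually non-gap columns; the BLOSUM62 distance
    of residues a, b is (blosum(a,a) + blosum(b,b))/2 - blosum(a,b), a
    non-negative per-column dissimilarity.
    """
    bl = _blosum62()
    row = alignment.rows[left_out]
    hams, blos = [], []
    for other in training:
        orow = alignment.rows[other]
        ham = 0
        blo = 0.0
        for a, b in zip(row, orow):
            if a == GAP or b == GAP:
                continue
            if a != b:
                ham += 1
            blo += (bl[a, a] + bl[b, b]) / 2.0 - bl[a, b]
        hams.append(ham)
        blos.append(blo)
    return float(np.mean(hams)), float(np.mean(blos))


def loho(
    enc: FamilyEncoding,
    alignment: FamilyAlignment,
    model: FamilyEnergyRegressor | None = None,
    min_homologues: int = 10,
    seed: int = 0,
) -> list[LohoResult]:
    """Leave-one-homologue-out evaluation.

    The left-out domain's baseline energy is predicted purely from its
    wild-type composition through U; the shared D supplies its mutation
    effects. Columns whose wild-type residue was never observed in
    training contribute the column-centred mean (0) with a warning.
    """
    if enc.n_homologues < min_homologues:
        raise ValueError(
            f"loho needs >= {min_homologues} homologues, family has "
            f"{enc.n_homologues}"
        )
    model = model or FamilyEnergyRegressor(random_state=seed)
    results = []
    for h, domain_id in enumerate(enc.hom_ids):
        test = enc.hom_idx == h
        fitted = FamilyEnergyRegressor(**model.get_params()).fit(
            enc.subset(~test)
        )
        # coverage check: wt residues of the left-out homologue unseen in
        # training carry only the regularized (near-zero) U entry
        train_obs = enc.comp[np.arange(enc.n_homologues) != h].sum(axis=0)
        unseen = (enc.comp[h] > 0) & (train_obs == 0)
        if unseen.any():
            warnings.warn(
                f"{domain_id}: {int(unseen.sum())} wild-type residues "
                "never observed in training; their U contribution is the "
                "column-centred mean (0)", stacklevel=2,
            )
        pred = fitted.predict(enc.subset(test))
        r = _pearson(enc.fitness[test], pred)
        ham, blo = alignment_distances(
            alignment, domain_id,
            [d for d in enc.hom_ids if d != domain_id],
        )
        results.append(
            LohoResult(
                domain_id=domain_id, r=r, n_variants=int(test.sum()),
                mean_hamming=ham, mean_blosum_dist=blo,
            )
        )
    return results


def rescale_energies(
    model: FamilyEnergyRegressor,
    enc: FamilyEncoding | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rescale mutation energies to the wt = 0 / 2.5th percentile scale.

    The signed, fitness-oriented energy distribution (destabilizing =
    negative, like fitness) over observed mutation features sets the scale:
    its 2.5th percentile maps to magnitude 1. The returned table uses the
    positive = destabilizing orientation, so scaled ddG > 0.3 marks strong
    destabilization; the orientation flip is recorded in the metadata.
    """
    check_is_fitted(model, "D_")
    D = model.D_
    if enc is not None:
        observed = np.zeros(model.n_columns_ * N_AA, dtype=bool)
        feats = enc.mut_feat[enc.mut_feat >= 0]
        observed[np.unique(feats)] = True
        observed = observed.reshape(model.n_columns_, N_AA)
    else:
        observed = np.ones_like(D, dtype=bool)
    values = D[observed]
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("degenerate energy distribution; cannot rescale")
    fitness_oriented = -values
    p25 = float(np.percentile(fitness_oriented, 2.5))
    scale = abs(p25)
    if scale == 0:
        raise ValueError("degenerate energy distribution; cannot rescale")
    rows = []
    for c in range(model.n_columns_):
        for a, aa in enumerate(AMINO_ACIDS):
            if not observed[c, a]:
                continue
            rows.append(
                {
                    "column": c + 1,
                    "mut_aa": aa,
                    "ddG": D[c, a],
                    "scaled_ddG": D[c, a] / scale,
                }
            )
    meta = {
        "scale_constant": scale,
        "orientation": "positive = destabilizing",
        "percentile_rule": "2.5th percentile of the fitness-oriented "
                           "(sign-flipped) energy distribution = -1",
    }
    return pd.DataFrame(rows), meta


def predict_new_homologue(
    model: FamilyEnergyRegressor,
    aligned_row: str,
    mutations: list[tuple[int, str]],
    fdr_threshold: float = 0.1,
    scale_constant: float | None = None,
) -> pd.DataFrame:
    """Predict fitness, scaled ddG and destabilization calls for a
    homologue aligned to the family's columns.

    ``mutations`` are (1-based alignment column, mutant amino acid) pairs;
    a pair whose mutant equals the wild type is a wild-type "variant" with
    scaled ddG 0, never called destabilizing. Calls use the approximate
    parameter standard errors from the weighted least-squares curvature
    (one-tailed test for ddG > 0, BH-FDR over the prediction set).
    """
    check_is_fitted(model, "U_")
    row = aligned_row.upper().replace(".", GAP)
    if len(row) != model.n_columns_:
        raise ValueError(
            f"aligned row length {len(row)} != family columns "
            f"{model.n_columns_}"
        )
    baseline = model.b0_
    for c, aa in enumerate(row):
        if aa != GAP and aa in AA_INDEX:
            baseline += model.U_[c, AA_INDEX[aa]]
    if scale_constant is None:
        table, meta = rescale_energies(model)
        scale_constant = meta["scale_constant"]

    recs = []
    for col, mut_aa in mutations:
        wt_aa = row[col - 1]
        if wt_aa == GAP:
            raise ValueError(f"column {col} is gapped in the aligned row")
        if mut_aa == wt_aa:
            ddG, se = 0.0, np.nan
        else:
            feat = (col - 1) * N_AA + AA_INDEX[mut_aa]
            ddG = float(model.D_[col - 1, AA_INDEX[mut_aa]])
            se = float(1.0 / np.sqrt(model.feature_curvature_[feat]))
        dG = baseline + ddG
        pf = expit(-dG)
        recs.append(
            {
                "column": col,
                "wt_aa": wt_aa,
                "mut_aa": mut_aa,
                "dG": dG,
                "predicted_fitness": model.gamma0_ + model.gamma1_ * pf,
                "ddG": ddG,
                "scaled_ddG": ddG / scale_constant,
                "se_scaled_ddG": se / scale_constant if np.isfinite(se)
                else np.nan,
            }
        )
    df = pd.DataFrame(recs)
    z = np.where(
        np.isfinite(df["se_scaled_ddG"]) & (df["se_scaled_ddG"] > 0),
        df["scaled_ddG"] / df["se_scaled_ddG"],
        0.0,
    )
    p = stats.norm.sf(z)  # one-tailed: only ddG > 0 can be significant
    df["q"] = bh_fdr(p)
    df["destabilizing"] = (df["q"] < fdr_threshold) & (df["scaled_ddG"] > 0)
    return df
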