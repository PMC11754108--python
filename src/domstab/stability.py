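"""Destabilization calling, stability-class summaries and clinical
classifier evaluation.

Variants are tested with a one-tailed z-test on the normalized fitness
scale (only fitness below the wild type can be significant), corrected by
Benjamini-Hochberg FDR over the declared analysis set. Destabilizing:
FDR < 0.1 and f_norm < 0; strongly destabilizing additionally requires
f_norm < -0.3. Classifier performance on clinical labels is measured with
the Matthews correlation coefficient (errors by measurement-noise
resampling) and ROC/AUC for continuous scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .datatypes import ClinicalAnnotation
from .qc import NormalizedFitness

VariantKey = tuple[str, int, str, str]


@dataclass
class StabilityCall:
    domain_id: str
    position: int
    wt_aa: str
    mut_aa: str
    f_norm: float
    sigma_norm: float
    z: float
    p: float
    q: float
    stability_class: str  # stable | mild | strong

    @property
    def key(self) -> VariantKey:
        return (self.domain_id, self.position, self.wt_aa, self.mut_aa)

    @property
    def destabilizing(self) -> bool:
        return self.stability_class in ("mild", "strong")


@dataclass
class ClassifierEval:
    positive_label: str
    threshold_rule: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    mcc: float = np.nan
    mcc_sd: float = np.nan
    roc_points: np.ndarray | None = None
    auc: float = np.nan
    reason: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def call_destabilizing(
    normalized: list[NormalizedFitness],
    fdr_threshold: float = 0.1,
    strong_cut: float = -0.3,
) -> list[StabilityCall]:
    """One-tailed z-test destabilization calls with BH-FDR.

    z = f_norm / sigma_norm; p = Phi(z), the probability of a fitness this
    low under the null of no destabilization. The BH correction is applied
    over all variants passed in (one batch = the declared analysis set).
    """
    if not normalized:
        return []
    sig = np.array([v.sigma_norm for v in normalized])
    if np.any(sig <= 0):
        bad = normalized[int(np.argmax(sig <= 0))]
        raise ValueError(f"sigma_norm must be > 0 for all variants "
                         f"(offending variant: {bad.key})")
    f = np.array([v.f_norm for v in normalized])
    z = f / sig
    p = stats.norm.cdf(z)
    q = bh_fdr(p)
    calls = []
    for v, zi, pi, qi in zip(normalized, z, p, q):
        if qi < fdr_threshold and v.f_norm < 0:
            cls = "strong" if v.f_norm < strong_cut else "mild"
        else:
            cls = "stable"
        calls.append(
            StabilityCall(
                domain_id=v.domain_id, position=v.position, wt_aa=v.wt_aa,
                mut_aa=v.mut_aa, f_norm=v.f_norm, sigma_norm=v.sigma_norm,
                z=float(zi), p=float(pi), q=float(qi), stability_class=cls,
            )
        )
    return calls


def summarize_stability_classes(
    calls: list[StabilityCall],
    annotations: list[ClinicalAnnotation],
    af_floor: float = 1e-5,
) -> pd.DataFrame:
    """Counts and percentages per stability class for each clinical label.

    Population variants are reported only above the allele-frequency floor.
    Percentages over {stable, mild, strong} sum to 100 per label.
    """
    by_key = {c.key: c for c in calls}
    rows = []
    labels = ("pathogenic", "benign", "vus", "population")
    for label in labels:
        group = [a for a in annotations if a.label == label]
        if label == "population":
            group = [a for a in group if a.allele_frequency is not None
                     and a.allele_frequency > af_floor]
        matched = [by_key[a.key] for a in group if a.key in by_key]
        n = len(matched)
        counts = {
            cls: sum(c.stability_class == cls for c in matched)
            for cls in ("stable", "mild", "strong")
        }
        row = {"label": label, "n": n, **{f"n_{k}": v
                                          for k, v in counts.items()}}
        row["n_destabilizing"] = counts["mild"] + counts["strong"]
        if n > 0:
            for k, v in counts.items():
                row[f"pct_{k}"] = 100.0 * v / n
            row["pct_destabilizing"] = 100.0 * row["n_destabilizing"] / n
        else:
            for k in counts:
                row[f"pct_{k}"] = np.nan
            row["pct_destabilizing"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def fisher_or(
    table: np.ndarray | list[list[int]],
) -> tuple[float, float, tuple[float, float]]:
    """Two-tailed Fisher's exact test with a sample (cross-product) OR.

    The Haldane-Anscombe 0.5 correction is applied to the OR (and its CI)
    only when a cell is zero; the exact p-value always uses the raw table.
    Returns (odds_ratio, p_two_tailed, (ci_low, ci_high)).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("fisher_or expects a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    t = np.round(t).astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    tc = t.astype(float)
    if (tc == 0).any():
        tc = tc + 0.5
    orr = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    se_log = float(np.sqrt((1.0 / tc).sum()))
    ci = (
        float(np.exp(np.log(orr) - 1.959963984540054 * se_log)),
        float(np.exp(np.log(orr) + 1.959963984540054 * se_log)),
    )
    return float(orr), float(p), ci


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table."""
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return np.nan
    return float(num / np.sqrt(den))


def _clinical_sets(
    annotations: list[ClinicalAnnotation], af_floor: float
) -> tuple[set[VariantKey], set[VariantKey]]:
    """Positive (pathogenic) and negative (benign + common population)
    variant keys."""
    pos = {a.key for a in annotations if a.label == "pathogenic"}
    neg = {
        a.key
        for a in annotations
        if a.label == "benign"
        or (a.label == "population" and a.allele_frequency is not None
            and a.allele_frequency > af_floor)
    }
    return pos, neg - pos


def evaluate_classifier(
    calls_or_scores: list[StabilityCall] | dict[VariantKey, float],
    annotations: list[ClinicalAnnotation],
    af_floor: float = 1e-5,
    positive_rule: str = "strong",
) -> ClassifierEval:
    """Evaluate how well destabilization (or any score) separates
    pathogenic from benign variants.

    With stability calls the prediction is class membership
    (``positive_rule``: "strong" or "destabilizing") and MCC is reported;
    with a continuous score dict, ROC points and AUC are reported instead.
    Population variants above ``af_floor`` count as benign.
    """
    pos, neg = _clinical_sets(annotations, af_floor)
    ev = ClassifierEval(positive_label="pathogenic",
                        threshold_rule=positive_rule)
    if not pos or not neg:
        ev.reason = "need at least one pathogenic and one benign variant"
        return ev

    if isinstance(calls_or_scores, dict):
        keys = [k for k in calls_or_scores if k in pos or k in neg]
        if not keys:
            ev.reason = "no scored clinical variants"
            return ev
        y = np.array([k in pos for k in keys], dtype=int)
        if y.min() == y.max():
            ev.reason = "single-class labels after joining scores"
            return ev
        s = np.array([calls_or_scores[k] for k in keys], dtype=float)
        from sklearn.metrics import roc_auc_score, roc_curve

        fpr, tpr, _ = roc_curve(y, s)
        ev.roc_points = np.column_stack([fpr, tpr])
        ev.auc = float(roc_auc_score(y, s))
        return ev

    for call in calls_or_scores:
        if call.key not in pos and call.key not in neg:
            continue
        if positive_rule == "strong":
            pred = call.stability_class == "strong"
        elif positive_rule == "destabilizing":
            pred = call.destabilizing
        else:
            raise ValueError(f"unknown positive_rule {positive_rule!r}")
        actual = call.key in pos
        if pred and actual:
            ev.tp += 1
        elif pred and not actual:
            ev.fp += 1
        elif not pred and actual:
            ev.fn += 1
        else:
            ev.tn += 1
    if (ev.tp + ev.fn) == 0 or (ev.fp + ev.tn) == 0:
        ev.reason = "single-class labels among called variants"
        return ev
    ev.mcc = mcc_from_counts(ev.tp, ev.fp, ev.tn, ev.fn)
    return ev


def resample_mcc(
    normalized: list[NormalizedFitness],
    annotations: list[ClinicalAnnotation],
    n: int = 10,
    seed: int = 0,
    fdr_threshold: float = 0.1,
    strong_cut: float = -0.3,
    af_floor: float = 1e-5,
    positive_rule: str = "strong",
) -> float:
    """Standard deviation of the MCC under measurement-noise resampling.

    Each resample draws f_norm* ~ Normal(f_norm, sigma_norm) per variant,
    re-runs the destabilization caller and recomputes the MCC.
    """
    if n < 2:
        raise ValueError("resample_mcc needs n >= 2 resamples")
    rng = np.random.default_rng(seed)
    mccs = []
    for _ in range(n):
        jittered = [
            NormalizedFitness(
                domain_id=v.domain_id, position=v.position, wt_aa=v.wt_aa,
                mut_aa=v.mut_aa, variant_class=v.variant_class,
                f_norm=float(rng.normal(v.f_norm, v.sigma_norm)),
                sigma_norm=v.sigma_norm,
                scale_factor=v.scale_factor, offset=v.offset,
            )
            for v in normalized
        ]
        calls = call_destabilizing(jittered, fdr_threshold, strong_cut)
        ev = evaluate_classifier(calls, annotations, af_floor, positive_rule)
        mccs.append(ev.mcc)
    return float(np.nanstd(mccs))


def calls_table(calls: list[StabilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_id": c.domain_id, "position": c.position,
                "wt_aa": c.wt_aa, "mut_aa": c.mut_aa, "f_norm": c.f_norm,
                "sigma_norm": c.sigma_norm, "z": c.z, "p": c.p, "q": c.q,
                "stability_class": c.stability_class,
            }
            for c in calls
        ]
    )
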