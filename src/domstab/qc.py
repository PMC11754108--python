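"""Per-domain quality control, PCA ranking/filtering and fitness
normalization.

Four per-domain quality metrics (wild-type position in the fitness
distribution, replicate correlation, fitness-vs-burial correlation and
fitness-vs-hydrophobicity correlation) are combined by PCA into a single
quality rank; retained domains are then normalized so that the wild type
maps to 0 and the 2.5th percentile of missense-plus-wild-type growth rates
maps to -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import DomainRecord, VariantFitness

# Kyte-Doolittle hydropathy; any 20-value scale may be supplied instead.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass
class QualityMetrics:
    domain_id: str
    wt_position: float = np.nan     # (f_wt - p95) / (p95 - p5)
    rep_corr: float = np.nan        # replicate Pearson r, missense only
    sasa_corr: float = np.nan       # fitness vs residue rSASA
    hyd_corr: float = np.nan        # fitness vs mutant hydrophobicity
    coverage: float = np.nan        # fraction of variants with enough counts
    pc1_score: float = np.nan
    rank: int = 0                   # 1 = best
    retained: bool = False
    reasons: list[str] = field(default_factory=list)


@dataclass
class NormalizedFitness:
    """A variant's fitness on the wild-type = 0 / 2.5th pct = -1 scale."""

    domain_id: str
    position: int
    wt_aa: str
    mut_aa: str
    variant_class: str
    f_norm: float
    sigma_norm: float
    scale_factor: float
    offset: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.domain_id, self.position, self.wt_aa, self.mut_aa)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def compute_quality_metrics(
    domain: DomainRecord,
    variants: list[VariantFitness],
    hydrophobicity_scale: dict[str, float] | None = None,
    min_counts: int = 10,
) -> QualityMetrics:
    """Compute the four per-domain quality metrics plus variant coverage.

    ``wt_position`` is (f_wt - p95)/(p95 - p5) over the domain's fitness
    distribution (0 when the wild type sits at the 95th percentile, -1 at
    the 5th); replicate correlation is averaged over replicate pairs when
    more than two replicates are present.
    """
    scale = hydrophobicity_scale or KYTE_DOOLITTLE
    qm = QualityMetrics(domain_id=domain.domain_id)
    dv = [v for v in variants if v.domain_id == domain.domain_id]
    missense = [v for v in dv if v.variant_class == "missense"]
    fitness_all = np.array([v.fitness for v in dv])
    if len(missense) < 20:
        qm.reasons.append("fewer than 20 missense variants")
        return qm

    p95, p5 = np.percentile(fitness_all, [95, 5])
    if p95 == p5:
        qm.reasons.append("zero fitness range")
        return qm
    qm.wt_position = float((domain.wt_growth_rate - p95) / (p95 - p5))

    reps = np.array([v.growth_rates for v in missense])
    pair_rs = [
        _pearson(reps[:, i], reps[:, j])
        for i, j in combinations(range(reps.shape[1]), 2)
    ]
    qm.rep_corr = float(np.nanmean(pair_rs)) if pair_rs else np.nan

    rsasa = np.array([domain.rsasa[v.position - 1] for v in missense])
    qm.sasa_corr = _pearson(np.array([v.fitness for v in missense]), rsasa)

    hyd = np.array([scale.get(v.mut_aa, np.nan) for v in missense])
    qm.hyd_corr = _pearson(np.array([v.fitness for v in missense]), hyd)

    covered = sum((v.counts >= min_counts).any() for v in dv)
    qm.coverage = covered / len(dv)
    return qm


def classify_foldedness(domain: DomainRecord) -> tuple[str, list[str]]:
    """Exclude domains without a hydrophobic core or with low confidence.

    A domain is kept as ``folded`` iff at least 10% of residues are buried
    (rSASA < 25%) and the mean per-residue confidence (pLDDT) is >= 50.
    """
    reasons: list[str] = []
    if domain.rsasa is None or len(domain.rsasa) == 0 or \
            domain.plddt is None or len(domain.plddt) == 0:
        return "excluded", ["missing structural features"]
    core_fraction = float(np.mean(domain.rsasa < 0.25))
    if core_fraction < 0.10:
        reasons.append(f"core fraction {core_fraction:.3f} < 0.10")
    if float(np.mean(domain.plddt)) < 50:
        reasons.append(f"mean pLDDT {np.mean(domain.plddt):.1f} < 50")
    return ("excluded", reasons) if reasons else ("folded", [])


METRIC_COLUMNS = ("wt_position", "rep_corr", "sasa_corr", "hyd_corr")


def rank_and_filter(
    metrics: list[QualityMetrics],
    max_rank: int | None = None,
    min_rep_corr: float = 0.485,
    min_coverage: float = 0.5,
    manual_exclusions: set[str] | None = None,
) -> tuple[list[QualityMetrics], float]:
    """Combine the quality metrics by PCA and apply the retention rules.

    The four metrics are standardized before PCA and the first component is
    oriented so that higher scores track higher replicate correlation.
    Retained iff rank <= max_rank AND rep_corr > min_rep_corr (strict) AND
    coverage > min_coverage; a manual exclusion list is honoured afterwards.
    Returns the updated metrics and the PC1 variance share.
    """
    complete = [
        m for m in metrics
        if all(np.isfinite(getattr(m, c)) for c in METRIC_COLUMNS)
    ]
    if len(complete) < 3:
        raise ValueError("rank_and_filter needs >= 3 domains with complete "
                         "metrics")
    if max_rank is None:
        max_rank = len(metrics)

    X = np.array([[getattr(m, c) for c in METRIC_COLUMNS] for m in complete])
    keep_cols = X.std(axis=0) > 0
    if not keep_cols.all():
        dropped = [c for c, k in zip(METRIC_COLUMNS, keep_cols) if not k]
        warnings.warn(f"constant metric column(s) dropped from PCA: "
                      f"{dropped}", stacklevel=2)
        X = X[:, keep_cols]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(n_components=1)
    pc1 = pca.fit_transform(Xs)[:, 0]
    rep = np.array([m.rep_corr for m in complete])
    if np.corrcoef(pc1, rep)[0, 1] < 0:
        pc1 = -pc1
    variance_share = float(pca.explained_variance_ratio_[0])

    for m, s in zip(complete, pc1):
        m.pc1_score = float(s)
    # rank by pc1 descending; ties broken by domain_id lexicographic order
    order = sorted(complete, key=lambda m: (-m.pc1_score, m.domain_id))
    for r, m in enumerate(order, start=1):
        m.rank = r
    excluded = manual_exclusions or set()
    for m in metrics:
        m.retained = False
        if m not in complete:
            m.reasons.append("incomplete quality metrics")
            continue
        if m.rank > max_rank:
            m.reasons.append(f"rank {m.rank} > {max_rank}")
        if not (m.rep_corr > min_rep_corr):
            m.reasons.append(
                f"replicate r {m.rep_corr:.3f} <= {min_rep_corr}"
            )
        if not (m.coverage > min_coverage):
            m.reasons.append(f"coverage {m.coverage:.3f} <= {min_coverage}")
        if m.domain_id in excluded:
            m.reasons.append("manual exclusion")
        m.retained = not m.reasons
    return metrics, variance_share


def normalize_fitness(
    domain: DomainRecord,
    variants: list[VariantFitness],
    min_missense: int = 40,
) -> list[NormalizedFitness]:
    """Affinely rescale a domain's fitness to wt = 0, 2.5th percentile = -1.

    The percentile is computed over missense variants plus the wild type;
    nonsense variants are carried through the same map but excluded from the
    percentile. Errors are scaled by the same factor.
    """
    dv = [v for v in variants if v.domain_id == domain.domain_id]
    missense = [v for v in dv if v.variant_class == "missense"]
    if len(missense) < min_missense:
        warnings.warn(
            f"{domain.domain_id}: only {len(missense)} missense variants; "
            "2.5th percentile is unstable", stacklevel=2,
        )
    f_wt = domain.wt_growth_rate
    pool = np.array([v.fitness for v in missense] + [f_wt])
    p25 = float(np.percentile(pool, 2.5))  # linear interpolation rule
    if p25 >= f_wt:
        raise ValueError(
            f"{domain.domain_id}: non-positive dynamic range "
            f"(2.5th percentile {p25:.4f} >= wild type {f_wt:.4f})"
        )
    scale_factor = 1.0 / (f_wt - p25)
    offset = -f_wt * scale_factor
    return [
        NormalizedFitness(
            domain_id=v.domain_id, position=v.position, wt_aa=v.wt_aa,
            mut_aa=v.mut_aa, variant_class=v.variant_class,
            f_norm=v.fitness * scale_factor + offset,
            sigma_norm=v.sigma * scale_factor,
            scale_factor=scale_factor, offset=offset,
        )
        for v in dv
    ]


def metrics_table(metrics: list[QualityMetrics]) -> pd.DataFrame:
    """QC report with one row per domain."""
    return pd.DataFrame(
        [
            {
                "domain_id": m.domain_id,
                **{c: getattr(m, c) for c in METRIC_COLUMNS},
                "coverage": m.coverage,
                "pc1_score": m.pc1_score,
                "rank": m.rank,
                "retained": m.retained,
                "reasons": ";".join(m.reasons),
            }
            for m in metrics
        ]
    )
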