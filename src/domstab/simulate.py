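"""Synthetic families of homologous domains with known energetics.

The generator runs the two-state thermodynamic model forwards: shared
per-column mutation energies and wild-type composition energies (RT = 1)
determine each variant's folding energy, the Boltzmann fraction folded
p_f = 1/(1+exp(dG)) maps affinely to a growth rate, and replicate
measurement noise produces per-variant fitness means and errors. Planted
functional sites, epistatic deviations and clinical labels give every
downstream stage a ground-truth surface to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .datatypes import (
    AA_INDEX,
    AMINO_ACIDS,
    STOP,
    ClinicalAnnotation,
    DomainRecord,
    FamilyAlignment,
    PredictorScore,
    VariantFitness,
)


def fraction_folded(dG: np.ndarray | float) -> np.ndarray | float:
    """Boltzmann two-state occupancy of the folded state, RT = 1."""
    return expit(-np.asarray(dG, dtype=float)) if np.ndim(dG) else \
        float(expit(-dG))


@dataclass
class SimulationConfig:
    """Generator settings; defaults define the package's study conditions.

    Energies are in RT units; growth rates in h^-1. The default family size
    (12 homologues x 40 columns) keeps a full model fit in the minutes range
    on one CPU while leaving ~19 observations per shared mutation energy.
    """

    n_replicates: int = 3
    core_fraction: float = 0.4          # fraction of buried alignment columns
    dG_wt_mean: float = -2.5            # mean wild-type folding energy (RT)
    u_scale: float = 0.25               # sd of per-(column, aa) wt energies
    softmax_temperature: float = 0.1    # wt sampling temperature over -U
    wt_dG_halfwidth: float | None = 1.0  # band of wild-type stabilities
    # around the family median (RT); emulates the assay retaining only
    # domains whose wild types are comparably well-behaved
    core_ddg_mean: float = 5.0          # core mutation ddG ~ N(mean, sd), RT
    core_ddg_sd: float = 2.0
    surface_ddg_mean: float = 1.0       # surface mutation ddG ~ N(mean, sd)
    surface_ddg_sd: float = 0.8
    gamma0: float = 0.05                # growth rate of the unfolded state
    gamma1: float = 0.35                # growth-rate gain per fraction folded
    noise_sigma: float = 0.05           # per-variant fitness noise (h^-1)
    sigma_floor: float = 1e-4           # lower bound on reported errors
    mean_count: float = 100.0           # Poisson mean of input read counts
    include_nonsense: bool = True
    include_synonymous: bool = True
    nonsense_dG: float = 15.0           # stop variants are fully unfolded
    # functional sites
    functional_fraction: float = 0.1    # fraction of columns with function
    functional_penalty: float = 12.0    # evolutionary-score penalty at sites
    s_max: float = 0.0                  # evolutionary score of a wt-like variant
    s_min: float = -20.0                # score of a fully unfolded variant
    score_noise: float = 0.5
    # epistasis injection
    core_bias: float = 0.0              # 0 = uniform; >0 favours core columns
    # optional divergent homologue (index) sampled at a higher temperature,
    # used to study distance-dependence of cross-homologue prediction
    divergent_homologue: int | None = None
    divergence_temperature: float = 2.0
    # clinical label generation
    pathogenic_rate: float = 0.3        # P(pathogenic) at maximal deleteriousness
    benign_rate: float = 0.15           # sampling rate among near-neutral variants
    population_rate: float = 0.15
    vus_rate: float = 0.02
    neutral_cut: float = 0.2            # deleteriousness below which a variant
    functional_weight: float = 0.8      # counts as near-neutral; site weight

    def __post_init__(self) -> None:
        if self.gamma1 <= 0:
            raise ValueError("gamma1 must be > 0: fitness must increase "
                             "with folding")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted parameters, stored losslessly for recovery tests."""

    family_id: str
    U_true: np.ndarray                  # (L, 20) wt composition energies
    D_true: np.ndarray                  # (L, 20) mutation energies (ddG)
    b0: float
    gamma0: float
    gamma1: float
    dG_wt: dict[str, float]             # per-homologue wild-type energy
    core_columns: set[int]              # 1-based
    functional_columns: set[int]        # 1-based
    functional_penalty: float
    epistatic_set: dict[tuple, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0
    dG_variant: dict[tuple, float] = field(default_factory=dict)

    def pf_wt(self, domain_id: str) -> float:
        return float(fraction_folded(self.dG_wt[domain_id]))


@dataclass
class SyntheticFamily:
    """Bundle of one simulated family; supports tuple unpacking."""

    domains: dict[str, DomainRecord]
    variants: list[VariantFitness]
    alignment: FamilyAlignment
    truth: SyntheticTruth
    config: SimulationConfig

    def __iter__(self):
        return iter((self.domains, self.variants, self.alignment, self.truth))


def _measure(rng: np.random.Generator, true_rate: float,
             config: SimulationConfig) -> tuple[np.ndarray, float, float]:
    """Replicate growth rates, their mean and the floored standard error.

    Per-replicate noise is inflated by sqrt(k) so that the replicate mean has
    standard deviation ``noise_sigma`` regardless of the replicate count.
    """
    k = config.n_replicates
    eps = rng.normal(0.0, config.noise_sigma * np.sqrt(k), size=k)
    reps = true_rate + eps
    fitness = float(reps.mean())
    sem = float(reps.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    return reps, fitness, max(sem, config.sigma_floor)


def simulate_family(
    n_homologues: int = 12,
    n_columns: int = 40,
    config: SimulationConfig | None = None,
    seed: int = 0,
    family_id: str = "FAM0001",
) -> SyntheticFamily:
    """Simulate a family of homologous domains with every missense variant.

    Wild-type sequences are drawn per column from a softmax over the negated
    composition energies, guaranteeing folded wild types; variant fitness is
    the replicate mean of gamma0 + gamma1 * p_f + noise. Deterministic under
    ``seed``.
    """
    if n_homologues < 2:
        raise ValueError("n_homologues must be >= 2")
    if n_columns < 5:
        raise ValueError("n_columns must be >= 5")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    L, A = n_columns, len(AMINO_ACIDS)

    n_core = max(1, round(config.core_fraction * L))
    core_cols = {int(c) + 1 for c in rng.choice(L, size=n_core, replace=False)}
    surface_cols = [c for c in range(1, L + 1) if c not in core_cols]

    U = rng.normal(0.0, config.u_scale, size=(L, A))
    D = np.empty((L, A))
    for c in range(L):
        if (c + 1) in core_cols:
            D[c] = rng.normal(config.core_ddg_mean, config.core_ddg_sd, A)
        else:
            D[c] = rng.normal(config.surface_ddg_mean,
                              config.surface_ddg_sd, A)

    # wild types favour low-energy residues per column
    def draw_sequence(temp: float) -> np.ndarray:
        logits = -U / temp
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        return np.array([rng.choice(A, p=probs[c]) for c in range(L)])

    seq_idx = np.empty((n_homologues, L), dtype=int)
    for h in range(n_homologues):
        temp = config.softmax_temperature
        if config.divergent_homologue == h:
            temp = config.divergence_temperature
        seq_idx[h] = draw_sequence(temp)

    if config.wt_dG_halfwidth is not None:
        # condition wild-type stabilities into a band around the family
        # median: the assay only retains comparably well-behaved wild types
        sums = np.array(
            [U[np.arange(L), seq_idx[h]].sum() for h in range(n_homologues)]
        )
        target = float(np.median(sums))
        for h in range(n_homologues):
            temp = config.softmax_temperature
            if config.divergent_homologue == h:
                temp = config.divergence_temperature
            best, best_dist = seq_idx[h], abs(sums[h] - target)
            for _ in range(100):
                if best_dist <= config.wt_dG_halfwidth:
                    break
                cand = draw_sequence(temp)
                dist = abs(U[np.arange(L), cand].sum() - target)
                if dist < best_dist:
                    best, best_dist = cand, dist
            seq_idx[h] = best

    sum_U = np.array(
        [U[np.arange(L), seq_idx[h]].sum() for h in range(n_homologues)]
    )
    b0 = float(config.dG_wt_mean - sum_U.mean())

    n_fun = max(1, round(config.functional_fraction * L))
    fun_pool = surface_cols if len(surface_cols) >= n_fun else list(
        range(1, L + 1))
    functional_columns = set(
        int(c) for c in rng.choice(fun_pool, size=n_fun, replace=False)
    )

    domain_ids = [f"{family_id}_D{h:02d}" for h in range(n_homologues)]
    truth = SyntheticTruth(
        family_id=family_id,
        U_true=U,
        D_true=D,
        b0=b0,
        gamma0=config.gamma0,
        gamma1=config.gamma1,
        dG_wt={d: float(b0 + sum_U[h]) for h, d in enumerate(domain_ids)},
        core_columns=core_cols,
        functional_columns=functional_columns,
        functional_penalty=config.functional_penalty,
        noise_sigma=config.noise_sigma,
        seed=seed,
    )

    # per-column burial, shared across homologues with a small jitter
    col_rsasa = np.empty(L)
    for c in range(L):
        if (c + 1) in core_cols:
            col_rsasa[c] = rng.uniform(0.02, 0.20)
        else:
            col_rsasa[c] = rng.uniform(0.30, 0.90)

    domains: dict[str, DomainRecord] = {}
    variants: list[VariantFitness] = []
    for h, domain_id in enumerate(domain_ids):
        sequence = "".join(AMINO_ACIDS[i] for i in seq_idx[h])
        jitter = rng.uniform(-0.03, 0.03, size=L)
        rsasa = np.clip(col_rsasa + jitter, 0.01, 0.99)
        in_core = np.array([(c + 1) in core_cols for c in range(L)])
        rsasa[in_core] = np.clip(rsasa[in_core], 0.01, 0.245)
        rsasa[~in_core] = np.clip(rsasa[~in_core], 0.27, 0.99)
        plddt = rng.uniform(75.0, 95.0, size=L)
        dG_wt = truth.dG_wt[domain_id]
        wt_rate = config.gamma0 + config.gamma1 * fraction_folded(dG_wt)
        domains[domain_id] = DomainRecord(
            domain_id=domain_id,
            family_id=family_id,
            sequence=sequence,
            rsasa=rsasa,
            plddt=plddt,
            alignment_row=sequence,
            wt_growth_rate=float(wt_rate),
        )
        if config.include_synonymous:
            wt_aa = sequence[0]
            reps, fitness, sigma = _measure(rng, wt_rate, config)
            variants.append(
                VariantFitness(
                    domain_id=domain_id, position=1, wt_aa=wt_aa,
                    mut_aa=wt_aa,
                    growth_rates=reps,
                    counts=rng.poisson(config.mean_count,
                                       config.n_replicates),
                    fitness=fitness, sigma=sigma,
                )
            )
        for c in range(L):
            wt_aa = sequence[c]
            for mut_aa in AMINO_ACIDS:
                if mut_aa == wt_aa:
                    continue
                dG = dG_wt + D[c, AA_INDEX[mut_aa]]
                truth.dG_variant[(domain_id, c + 1, wt_aa, mut_aa)] = float(dG)
                rate = config.gamma0 + config.gamma1 * fraction_folded(dG)
                reps, fitness, sigma = _measure(rng, rate, config)
                variants.append(
                    VariantFitness(
                        domain_id=domain_id, position=c + 1, wt_aa=wt_aa,
                        mut_aa=mut_aa,
                        growth_rates=reps,
                        counts=rng.poisson(config.mean_count,
                                           config.n_replicates),
                        fitness=fitness, sigma=sigma,
                    )
                )
            if config.include_nonsense:
                rate = config.gamma0 + config.gamma1 * fraction_folded(
                    config.nonsense_dG)
                reps, fitness, sigma = _measure(rng, rate, config)
                variants.append(
                    VariantFitness(
                        domain_id=domain_id, position=c + 1, wt_aa=wt_aa,
                        mut_aa=STOP,
                        growth_rates=reps,
                        counts=rng.poisson(config.mean_count,
                                           config.n_replicates),
                        fitness=fitness, sigma=sigma,
                    )
                )

    alignment = FamilyAlignment(
        family_id=family_id,
        columns=L,
        rows={d: domains[d].alignment_row for d in domain_ids},
    )
    return SyntheticFamily(domains, variants, alignment, truth, config)


def inject_epistasis(
    family: SyntheticFamily,
    fraction: float,
    delta_magnitude: float | None = None,
    seed: int = 0,
    hotspot_column: int | None = None,
    hotspot_fraction: float = 0.0,
    delta_sigmas: float = 5.0,
) -> SyntheticFamily:
    """Plant energetic deviations on a subset of missense variants.

    A uniformly chosen subset (without replacement) of (homologue, variant)
    pairs has its folding energy shifted before the fitness is regenerated,
    and the shifted energies recorded in ``truth.epistatic_set``. Two
    deviation semantics are supported:

    * ``delta_magnitude`` (RT units): a fixed-size energy shift whose
      direction is chosen toward the observable side of the assay's
      dynamic range (folded backgrounds destabilized, unfolded ones
      stabilized), so every planted deviation moves the growth rate;
    * ``delta_sigmas`` (default, 5): a per-variant energy shift sized so
      the expected growth rate moves by ``delta_sigmas`` times the
      measurement noise (capped by the dynamic range near the transition
      midpoint) — deviations calibrated against the assay noise.

    ``config.core_bias`` > 0 preferentially samples buried columns;
    ``hotspot_column`` concentrates ``hotspot_fraction`` of the planted
    set at one alignment column.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return family
    config = family.config
    rng = np.random.default_rng(seed)
    missense = [v for v in family.variants if v.variant_class == "missense"]
    n_plant = round(fraction * len(missense))
    idx = np.arange(len(missense))

    weights = np.ones(len(missense))
    if config.core_bias > 0:
        core = family.truth.core_columns
        for i, v in enumerate(missense):
            if v.position in core:
                weights[i] *= 1.0 + config.core_bias
    chosen: list[int] = []
    if hotspot_column is not None and hotspot_fraction > 0:
        hot = [i for i in idx if missense[i].position == hotspot_column]
        n_hot = min(len(hot), round(hotspot_fraction * n_plant))
        chosen.extend(rng.choice(hot, size=n_hot, replace=False).tolist())
    remaining = np.setdiff1d(idx, np.array(chosen, dtype=int))
    w = weights[remaining] / weights[remaining].sum()
    n_rest = n_plant - len(chosen)
    chosen.extend(
        rng.choice(remaining, size=n_rest, replace=False, p=w).tolist()
    )

    truth = replace(
        family.truth,
        dG_variant=dict(family.truth.dG_variant),
        epistatic_set=dict(family.truth.epistatic_set),
    )
    new_variants = list(family.variants)
    lookup = {id(v): j for j, v in enumerate(family.variants)}
    noise = config.noise_sigma if config.noise_sigma > 0 else 0.01
    for i in chosen:
        v = missense[i]
        dG = truth.dG_variant[v.key]
        pf0 = fraction_folded(dG)
        if delta_magnitude is not None:
            delta = delta_magnitude if pf0 >= 0.5 else -delta_magnitude
        else:
            # shift sized to move the expected rate by delta_sigmas * noise
            target = delta_sigmas * noise / config.gamma1
            up, dn = pf0 + target, pf0 - target
            if dn >= 1e-3 and (up > 0.999 or pf0 >= 0.5):
                pf_new = dn       # destabilize a folded background
            elif up <= 0.999:
                pf_new = up       # stabilize an unfolded background
            else:                 # capped near the transition midpoint
                pf_new = 0.999 if (0.999 - pf0) > (pf0 - 1e-3) else 1e-3
            delta = float(np.log(1.0 / pf_new - 1.0)) - dG
        dG_new = dG + delta
        truth.epistatic_set[v.key] = float(delta)
        truth.dG_variant[v.key] = float(dG_new)
        rate = config.gamma0 + config.gamma1 * fraction_folded(dG_new)
        reps, fitness, sigma = _measure(rng, rate, config)
        new_variants[lookup[id(v)]] = replace(
            v, growth_rates=reps, fitness=fitness, sigma=sigma
        )
    return SyntheticFamily(family.domains, new_variants, family.alignment,
                           truth, config)


def simulate_evolutionary_scores(
    truth: SyntheticTruth,
    variants: list[VariantFitness],
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[PredictorScore]:
    """Emulate an evolutionary (language-model-like) fitness score.

    score = s_max + (s_min - s_max) * (1 - p_f / p_f,wt), clipped to
    [s_min, s_max], minus ``functional_penalty`` at planted functional
    columns, plus Gaussian noise. The default range (s_max - s_min = 20)
    keeps every domain above the >10-range eligibility rule downstream.
    """
    if truth is None:
        raise ValueError("simulate_evolutionary_scores requires truth")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    scores: list[PredictorScore] = []
    for v in variants:
        if v.variant_class == "nonsense":
            continue
        if v.variant_class == "synonymous":
            base = config.s_max
        else:
            pf = fraction_folded(truth.dG_variant[v.key])
            pf_wt = truth.pf_wt(v.domain_id)
            base = config.s_max + (config.s_min - config.s_max) * (
                1.0 - pf / pf_wt
            )
            base = float(np.clip(base, config.s_min, config.s_max))
        if v.position in truth.functional_columns and \
                v.variant_class == "missense":
            base -= truth.functional_penalty
        noise = rng.normal(0.0, config.score_noise) if config.score_noise \
            else 0.0
        scores.append(
            PredictorScore(
                domain_id=v.domain_id, position=v.position, wt_aa=v.wt_aa,
                mut_aa=v.mut_aa, score=base + noise,
                predictor_name="synthetic-evo",
            )
        )
    return scores


def simulate_clinical_labels(
    truth: SyntheticTruth,
    variants: list[VariantFitness],
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[ClinicalAnnotation]:
    """Sample clinical labels conditioned on combined deleteriousness.

    Deleteriousness combines the destabilization fraction (1 - p_f/p_f,wt)
    and a planted functional-site effect; pathogenic labels are sampled with
    probability increasing in it, benign/population labels from near-neutral
    variants, with population allele frequencies log-uniform in
    [1e-6, 1e-2]. Deterministic under ``seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    annotations: list[ClinicalAnnotation] = []
    for v in variants:
        if v.variant_class != "missense":
            continue
        pf = fraction_folded(truth.dG_variant[v.key])
        pf_wt = truth.pf_wt(v.domain_id)
        destab = float(np.clip(1.0 - pf / pf_wt, 0.0, 1.0))
        func = config.functional_weight if (
            v.position in truth.functional_columns
            and truth.functional_penalty > 0
        ) else 0.0
        delet = min(1.0, destab + func)
        u = rng.uniform()
        label: str | None = None
        af = None
        if u < config.pathogenic_rate * delet ** 2:
            label = "pathogenic"
        elif delet < config.neutral_cut:
            u2 = rng.uniform()
            if u2 < config.benign_rate:
                label = "benign"
            elif u2 < config.benign_rate + config.population_rate:
                label = "population"
                af = float(10 ** rng.uniform(-6.0, -2.0))
        if label is None and rng.uniform() < config.vus_rate:
            label = "vus"
        if label is not None:
            annotations.append(
                ClinicalAnnotation(
                    domain_id=v.domain_id, position=v.position,
                    wt_aa=v.wt_aa, mut_aa=v.mut_aa,
                    label=label, allele_frequency=af,
                )
            )
    return annotations
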