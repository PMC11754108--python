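"""End-to-end orchestration: simulate -> qc -> normalize -> stability ->
sites -> energymodel -> epistasis, with deterministic sub-seeding and an
artifact manifest.

Every stochastic stage receives a sub-seed derived from a stable hash of
(master seed, stage name), so adding stages never perturbs existing ones.
Stages communicate only through the declared output files / returned
tables; the manifest lists every output with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import epistasis as epi
from . import io, qc, simulate, sites, stability
from .energy import (
    FamilyEnergyRegressor,
    encode_family,
    loho,
    rescale_energies,
    tenfold_cv,
)

logger = logging.getLogger("domstab")

ALL_STAGES = ("simulate", "qc", "normalize", "stability", "sites",
              "energymodel", "epistasis")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed from (master seed, stage name), < 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    outdir: str = "domstab_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_homologues: int = 12
    n_columns: int = 40
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    epistasis_fraction: float = 0.05
    epistasis_delta: float = 5.0
    fdr_threshold: float = 0.1
    strong_cut: float = -0.3
    residual_cut: float = 0.3
    site_cut: float = 0.3
    epistasis_magnitude_cut: float = 0.05
    af_floor: float = 1e-5
    min_rep_corr: float = 0.485
    max_rank: int | None = None      # defaults to n_domains for synthetic runs


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest.

    A stage failure raises after writing the partial manifest; toggled-off
    upstream stages disable their dependents with an explicit warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": config.seed, "outputs": {}}
    stages = set(config.stages)
    if "energymodel" not in stages and "epistasis" in stages:
        logger.warning(
            "epistasis depends on energymodel; skipping epistasis"
        )
        stages.discard("epistasis")

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _hash_file(path)
        }

    try:
        family = simulate.simulate_family(
            config.n_homologues, config.n_columns, config.sim,
            seed=stage_seed(config.seed, "simulate"),
        )
        if config.epistasis_fraction > 0:
            family = simulate.inject_epistasis(
                family, config.epistasis_fraction, config.epistasis_delta,
                seed=stage_seed(config.seed, "simulate.epistasis"),
            )
        scores = simulate.simulate_evolutionary_scores(
            family.truth, family.variants, config.sim,
            seed=stage_seed(config.seed, "simulate.scores"),
        )
        annotations = simulate.simulate_clinical_labels(
            family.truth, family.variants, config.sim,
            seed=stage_seed(config.seed, "simulate.clinical"),
        )
        if "simulate" in stages:
            io.write_variant_table(outdir / "variants.tsv", family.variants)
            io.write_alignment(outdir / "alignment.fasta", family.alignment)
            io.write_score_table(outdir / "scores.tsv", scores)
            io.write_clinical_table(outdir / "clinical.tsv", annotations)
            record("variants", outdir / "variants.tsv")
            record("alignment", outdir / "alignment.fasta")
            record("scores", outdir / "scores.tsv")
            record("clinical", outdir / "clinical.tsv")
            logger.info("simulate: %d variants in %d homologues",
                        len(family.variants), config.n_homologues)

        metrics = None
        if "qc" in stages:
            metrics = [
                qc.compute_quality_metrics(d, family.variants)
                for d in family.domains.values()
            ]
            metrics, pc1_share = qc.rank_and_filter(
                metrics,
                max_rank=config.max_rank or len(metrics),
                min_rep_corr=config.min_rep_corr,
            )
            qc.metrics_table(metrics).to_csv(
                outdir / "qc_report.tsv", sep="\t", index=False
            )
            record("qc_report", outdir / "qc_report.tsv")
            logger.info("qc: %d/%d domains retained (PC1 share %.2f)",
                        sum(m.retained for m in metrics), len(metrics),
                        pc1_share)

        normalized = []
        if "normalize" in stages:
            retained_ids = (
                {m.domain_id for m in metrics if m.retained}
                if metrics is not None else set(family.domains)
            )
            for d in family.domains.values():
                if d.domain_id in retained_ids:
                    normalized.extend(
                        qc.normalize_fitness(d, family.variants)
                    )
            import pandas as pd

            pd.DataFrame(
                [
                    {"domain_id": v.domain_id, "position": v.position,
                     "wt_aa": v.wt_aa, "mut_aa": v.mut_aa,
                     "f_norm": v.f_norm, "sigma_norm": v.sigma_norm}
                    for v in normalized
                ]
            ).to_csv(outdir / "normalized.tsv", sep="\t", index=False)
            record("normalized", outdir / "normalized.tsv")

        if "stability" in stages and normalized:
            tested = [v for v in normalized
                      if v.variant_class == "missense"]
            calls = stability.call_destabilizing(
                tested, config.fdr_threshold, config.strong_cut
            )
            stability.calls_table(calls).to_csv(
                outdir / "stability_calls.tsv", sep="\t", index=False
            )
            record("stability_calls", outdir / "stability_calls.tsv")
            summary = stability.summarize_stability_classes(
                calls, annotations, config.af_floor
            )
            summary.to_csv(outdir / "stability_summary.tsv", sep="\t",
                           index=False)
            record("stability_summary", outdir / "stability_summary.tsv")

        if "sites" in stages and normalized:
            import pandas as pd

            frames_mut, frames_site, fit_rows = [], [], []
            for domain_id in family.domains:
                dn = [v for v in normalized if v.domain_id == domain_id]
                ds = [s for s in scores if s.domain_id == domain_id]
                if not dn:
                    continue
                eligible, reasons = sites.check_eligibility(dn, ds)
                if not eligible:
                    fit_rows.append({"domain_id": domain_id,
                                     "eligible": False,
                                     "reasons": ";".join(reasons)})
                    continue
                fit = sites.fit_sigmoid(
                    dn, ds, seed=stage_seed(config.seed, "sites")
                )
                fit_rows.append(
                    {"domain_id": domain_id, "eligible": True,
                     "xmid": fit.xmid, "scal": fit.scal,
                     "converged": fit.converged, "reasons": ""}
                )
                if fit.converged:
                    frames_mut.append(sites.call_functional_mutations(
                        fit, config.fdr_threshold, config.residual_cut))
                    frames_site.append(sites.call_functional_sites(
                        fit, config.site_cut))
            if frames_mut:
                pd.concat(frames_mut).to_csv(
                    outdir / "functional_mutations.tsv", sep="\t",
                    index=False)
                record("functional_mutations",
                       outdir / "functional_mutations.tsv")
            if frames_site:
                pd.concat(frames_site).to_csv(
                    outdir / "functional_sites.tsv", sep="\t", index=False)
                record("functional_sites", outdir / "functional_sites.tsv")
            pd.DataFrame(fit_rows).to_csv(
                outdir / "sigmoid_fits.tsv", sep="\t", index=False)
            record("sigmoid_fits", outdir / "sigmoid_fits.tsv")

        model = None
        enc = None
        if "energymodel" in stages:
            enc = encode_family(family.alignment, family.variants)
            model = FamilyEnergyRegressor(
                random_state=stage_seed(config.seed, "energymodel")
            ).fit(enc)
            io.write_model(outdir / "energy_model.json", model)
            record("energy_model", outdir / "energy_model.json")
            cv = tenfold_cv(enc, model,
                            seed=stage_seed(config.seed, "energymodel.cv"))
            scaled, meta = rescale_energies(model, enc)
            scaled.to_csv(outdir / "scaled_ddG.tsv", sep="\t", index=False)
            record("scaled_ddG", outdir / "scaled_ddG.tsv")
            manifest["cv_pooled_r"] = cv.pooled_r
            manifest["cv_explainable_fraction"] = cv.explainable_fraction
            manifest["energy_scale"] = meta
            logger.info("energymodel: pooled held-out r = %.3f",
                        cv.pooled_r)
            if enc.n_homologues >= 10:
                results = loho(
                    enc, family.alignment, model,
                    seed=stage_seed(config.seed, "energymodel.loho"),
                )
                import pandas as pd

                pd.DataFrame(
                    [vars(r) for r in results]
                ).to_csv(outdir / "loho.tsv", sep="\t", index=False)
                record("loho", outdir / "loho.tsv")

        if "epistasis" in stages and model is not None:
            calls = epi.call_epistatic(
                model, enc, config.epistasis_magnitude_cut,
                config.fdr_threshold,
            )
            epi.epistasis_table(calls).to_csv(
                outdir / "epistasis_calls.tsv", sep="\t", index=False)
            record("epistasis_calls", outdir / "epistasis_calls.tsv")
            site_classes = epi.classify_sites(family.alignment,
                                              family.domains)
            if any(c.is_epistatic for c in calls):
                enrich, summary = epi.site_enrichment(calls, site_classes)
                enrich.to_csv(outdir / "epistasis_sites.tsv", sep="\t",
                              index=False)
                record("epistasis_sites", outdir / "epistasis_sites.tsv")
                manifest["epistasis_summary"] = {
                    k: (float(v) if isinstance(v, (int, float, np.floating))
                        else v)
                    for k, v in summary.items()
                }
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
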