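"""Epistasis detection: variants deviating from the family energy model.

Residuals of observed fitness to the additive family model are tested with
a two-tailed z-test (z = residual / measurement error, BH-FDR per family);
epistatic variants require FDR < 0.1 and |residual| > 0.05 h^-1 in growth
rate units. Alignment sites enriched for epistatic variants (log2 OR > 1.5,
Fisher FDR < 0.05) are epistatic sites, and columns are classified as
core / surface / changing by the burial of the homologous residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .datatypes import DomainRecord, FamilyAlignment
from .energy import FamilyEncoding, FamilyEnergyRegressor
from .stability import fisher_or


@dataclass
class EpistasisCall:
    domain_id: str
    position: int
    wt_aa: str
    mut_aa: str
    column: int
    residual: float
    z: float
    q: float
    is_epistatic: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.domain_id, self.position, self.wt_aa, self.mut_aa)


def call_epistatic(
    model: FamilyEnergyRegressor,
    enc: FamilyEncoding,
    magnitude_cut: float = 0.05,
    fdr: float = 0.1,
    residual_units: str = "growth_rate",
) -> list[EpistasisCall]:
    """Flag variants whose fitness deviates from the additive family model.

    Residuals and ``magnitude_cut`` must be in the same declared units
    (growth rate, h^-1, by default — matching a 0.05 h^-1 cut). When the
    model was fitted on normalized fitness, pass
    ``residual_units="normalized"`` with a cut on that scale; a mismatch is
    a hard error rather than a guess.
    """
    if residual_units not in ("growth_rate", "normalized"):
        raise ValueError(
            f"unknown residual_units {residual_units!r}; declare "
            "'growth_rate' or 'normalized'"
        )
    pred = model.predict(enc)
    residuals = enc.fitness - pred
    z = residuals / enc.sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    calls = []
    for i, key in enumerate(enc.keys):
        calls.append(
            EpistasisCall(
                domain_id=key[0], position=key[1], wt_aa=key[2],
                mut_aa=key[3],
                column=int(enc.columns[i]) if enc.columns is not None
                else key[1],
                residual=float(residuals[i]), z=float(z[i]), q=float(q[i]),
                is_epistatic=bool(
                    q[i] < fdr and abs(residuals[i]) > magnitude_cut
                ),
            )
        )
    return calls


def classify_sites(
    alignment: FamilyAlignment,
    domains: dict[str, DomainRecord],
    core_rsasa: float = 0.25,
    majority: float = 0.75,
) -> pd.DataFrame:
    """Classify alignment columns as core, surface or changing.

    Core: rSASA < 25% in at least 75% of (non-gap) homologues; surface:
    rSASA > 25% in at least 75%; changing: the rest. Columns with fewer
    than two non-gap homologues are "changing" with a low-coverage flag.
    """
    pos_of_col = {
        d: {c: p for p, c in alignment.column_map[d].items()}
        for d in alignment.rows
    }
    rows = []
    for col in range(1, alignment.columns + 1):
        burials = []
        for d in alignment.rows:
            p = pos_of_col[d].get(col)
            if p is None or d not in domains:
                continue
            burials.append(domains[d].rsasa[p - 1])
        low_coverage = len(burials) < 2
        if low_coverage:
            cls = "changing"
        else:
            burials = np.array(burials)
            frac_core = np.mean(burials < core_rsasa)
            frac_surface = np.mean(burials > core_rsasa)
            if frac_core >= majority:
                cls = "core"
            elif frac_surface >= majority:
                cls = "surface"
            else:
                cls = "changing"
        rows.append(
            {"column": col, "site_class": cls, "n_homologues": len(burials),
             "low_coverage": low_coverage}
        )
    return pd.DataFrame(rows)


def site_enrichment(
    calls: list[EpistasisCall],
    site_classes: pd.DataFrame,
    log2_or_cut: float = 1.5,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-column enrichment of epistatic variants, plus the family-level
    core-vs-surface odds ratio.

    For each column a 2x2 table (epistatic vs not) x (at column vs
    elsewhere) is tested with Fisher's exact test, BH-corrected over
    columns; epistatic sites require log2(OR) > 1.5 and FDR < 0.05.
    """
    if not any(c.is_epistatic for c in calls):
        raise ValueError("site_enrichment needs at least one epistatic call")
    total_epi = sum(c.is_epistatic for c in calls)
    total = len(calls)
    class_of = dict(zip(site_classes["column"], site_classes["site_class"]))
    rows = []
    for col in sorted({c.column for c in calls}):
        at_col = [c for c in calls if c.column == col]
        epi_here = sum(c.is_epistatic for c in at_col)
        non_here = len(at_col) - epi_here
        epi_there = total_epi - epi_here
        non_there = (total - len(at_col)) - epi_there
        table = [[epi_here, non_here], [epi_there, non_there]]
        orr, p, _ = fisher_or(table)
        rows.append(
            {
                "column": col,
                "n_at_column": len(at_col),
                "n_epistatic": epi_here,
                "odds_ratio": orr,
                "log2_or": np.log2(orr),
                "p": p,
                "site_class": class_of.get(col, "changing"),
                "zero_margin": min(epi_here + non_here,
                                   epi_here + epi_there) == 0,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["is_epistatic_site"] = (df["log2_or"] > log2_or_cut) & \
        (df["q"] < fdr)

    # family-level core vs surface enrichment of epistatic variants
    core_epi = sum(
        c.is_epistatic for c in calls if class_of.get(c.column) == "core"
    )
    core_non = sum(
        (not c.is_epistatic) for c in calls
        if class_of.get(c.column) == "core"
    )
    surf_epi = sum(
        c.is_epistatic for c in calls if class_of.get(c.column) == "surface"
    )
    surf_non = sum(
        (not c.is_epistatic) for c in calls
        if class_of.get(c.column) == "surface"
    )
    if (core_epi + core_non) and (surf_epi + surf_non):
        core_or, core_p, _ = fisher_or(
            [[core_epi, core_non], [surf_epi, surf_non]]
        )
    else:
        core_or, core_p = np.nan, np.nan
    summary = {
        "core_vs_surface_or": core_or,
        "core_vs_surface_p": core_p,
        "n_epistatic": total_epi,
        "n_variants": total,
    }
    return df, summary


def epistasis_table(calls: list[EpistasisCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_id": c.domain_id, "position": c.position,
                "wt_aa": c.wt_aa, "mut_aa": c.mut_aa, "column": c.column,
                "residual": c.residual, "z": c.z, "q": c.q,
                "is_epistatic": c.is_epistatic,
            }
            for c in calls
        ]
    )
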