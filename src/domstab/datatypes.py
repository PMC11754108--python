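"""Shared domain types for the stability-analysis pipeline.

Conventions used throughout the package:

* residue positions are 1-based and inclusive; alignment columns are 1-based;
* energies are dimensionless (RT = 1) until explicitly rescaled;
* fitness is a growth-rate-derived score in h^-1 before normalization, and on
  the wild-type = 0 / 2.5th-percentile = -1 scale after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
STOP: str = "*"
GAP: str = "-"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def classify_variant(wt_aa: str, mut_aa: str) -> str:
    """Classify a substitution as synonymous, missense or nonsense."""
    if mut_aa == STOP:
        return "nonsense"
    if mut_aa == wt_aa:
        return "synonymous"
    return "missense"


@dataclass
class VariantFitness:
    """One amino-acid substitution with its growth-rate measurements.

    ``fitness`` is the mean growth-rate-derived score across replicates and
    ``sigma`` its measurement error in the same units (h^-1).
    """

    domain_id: str
    position: int          # 1-based residue index within the domain
    wt_aa: str
    mut_aa: str
    growth_rates: np.ndarray  # per-replicate selection growth rates (h^-1)
    counts: np.ndarray        # per-replicate input read counts
    fitness: float
    sigma: float
    variant_class: str = ""

    def __post_init__(self) -> None:
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.counts = np.asarray(self.counts)
        if not self.variant_class:
            self.variant_class = classify_variant(self.wt_aa, self.mut_aa)
        if self.position < 1:
            raise ValueError(
                f"position must be >= 1, got {self.position} "
                f"({self.domain_id})"
            )
        if not (self.sigma > 0):
            raise ValueError(
                f"sigma must be > 0, got {self.sigma} "
                f"({self.domain_id} {self.wt_aa}{self.position}{self.mut_aa})"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.domain_id, self.position, self.wt_aa, self.mut_aa)


@dataclass
class DomainRecord:
    """A domain's sequence, family membership and per-residue features."""

    domain_id: str
    family_id: str
    sequence: str
    rsasa: np.ndarray        # per-residue relative SASA, fraction in [0, 1]
    plddt: np.ndarray        # per-residue model confidence, 0-100
    alignment_row: str       # gapped row over the family alignment columns
    wt_growth_rate: float    # h^-1
    uniprot_id: str | None = None

    def __post_init__(self) -> None:
        self.rsasa = np.asarray(self.rsasa, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = len(self.sequence)
        if len(self.rsasa) != n or len(self.plddt) != n:
            raise ValueError(
                f"{self.domain_id}: rsasa/plddt length must equal sequence "
                f"length {n}"
            )
        ungapped = self.alignment_row.replace(GAP, "").replace(".", "")
        if ungapped != self.sequence:
            raise ValueError(
                f"{self.domain_id}: ungapped alignment_row does not "
                f"reproduce the sequence"
            )


@dataclass
class FamilyAlignment:
    """A family multiple sequence alignment with per-domain column maps."""

    family_id: str
    columns: int
    rows: dict[str, str]                       # domain_id -> gapped row
    column_map: dict[str, dict[int, int]] = field(default_factory=dict)
    # column_map[domain_id]: 1-based residue position -> 1-based column

    def __post_init__(self) -> None:
        if not self.column_map:
            self.column_map = {
                d: build_column_map(row) for d, row in self.rows.items()
            }
        for d, row in self.rows.items():
            if len(row) != self.columns:
                raise ValueError(
                    f"{self.family_id}: row {d} has length {len(row)}, "
                    f"expected {self.columns}"
                )
            cmap = self.column_map[d]
            if len(set(cmap.values())) != len(cmap):
                raise ValueError(f"{self.family_id}: column_map for {d} "
                                 "is not injective")


def build_column_map(row: str) -> dict[int, int]:
    """Map 1-based residue positions of a gapped row to 1-based columns."""
    cmap: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch not in (GAP, "."):
            pos += 1
            cmap[pos] = col
    return cmap


CLINICAL_LABELS = ("pathogenic", "benign", "vus", "population")


@dataclass
class ClinicalAnnotation:
    """Clinical label for one substitution."""

    domain_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: str
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.label not in CLINICAL_LABELS:
            raise ValueError(f"unknown clinical label {self.label!r}")
        has_af = self.allele_frequency is not None
        if (self.label == "population") != has_af:
            raise ValueError(
                "allele_frequency must be present iff label == 'population' "
                f"({self.domain_id} {self.wt_aa}{self.position}{self.mut_aa})"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.domain_id, self.position, self.wt_aa, self.mut_aa)


@dataclass
class PredictorScore:
    """External predictor score (e.g. a protein-language-model fitness)."""

    domain_id: str
    position: int
    wt_aa: str
    mut_aa: str
    score: float
    predictor_name: str = "evo"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.domain_id, self.position, self.wt_aa, self.mut_aa)
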