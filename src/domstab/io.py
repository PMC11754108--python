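"""Readers and writers for the standard formats the pipeline touches.

Variant tables are TSV with a header; alignments are aligned FASTA or
Stockholm; fitted models round-trip through a self-describing JSON text
serialization. Parsing is locale-independent (decimal points only).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .datatypes import (
    GAP,
    ClinicalAnnotation,
    DomainRecord,
    FamilyAlignment,
    PredictorScore,
    VariantFitness,
    classify_variant,
)

MODEL_FORMAT_VERSION = 1

REQUIRED_VARIANT_COLUMNS = (
    "domain_id",
    "position",
    "wt_aa",
    "mut_aa",
    "fitness",
    "sigma",
)


class TableFormatError(ValueError):
    """A table is structurally unusable (missing columns, ragged rows)."""


def _replicate_columns(columns: Sequence[str], prefix: str) -> list[str]:
    reps = [c for c in columns if c.startswith(prefix)]
    return sorted(reps, key=lambda c: int(c[len(prefix):]))


def read_variant_table(
    path: str | Path,
    dialect_config: dict | None = None,
    domains: dict[str, DomainRecord] | None = None,
) -> list[VariantFitness]:
    """Read a per-variant fitness TSV into :class:`VariantFitness` records.

    ``dialect_config`` may rename required columns (mapping canonical name ->
    file column name) and set the replicate-column prefixes
    (``growth_rate_prefix``, ``count_prefix``). When ``domains`` is given,
    each row's wild-type amino acid is validated against the domain sequence.
    """
    cfg = dict(dialect_config or {})
    gr_prefix = cfg.pop("growth_rate_prefix", "growth_rate_")
    ct_prefix = cfg.pop("count_prefix", "count_")
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str})
    rename = {v: k for k, v in cfg.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in REQUIRED_VARIANT_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(
                f"{path}: missing required column {col!r}"
            )
    gr_cols = _replicate_columns(df.columns, gr_prefix)
    ct_cols = _replicate_columns(df.columns, ct_prefix)

    records: list[VariantFitness] = []
    errors: list[str] = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            fitness = float(row["fitness"])
            sigma = float(row["sigma"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric fitness/sigma")
            continue
        position = int(row["position"])
        wt_aa = str(row["wt_aa"])
        mut_aa = str(row["mut_aa"])
        domain_id = str(row["domain_id"])
        if domains is not None and domain_id in domains:
            seq = domains[domain_id].sequence
            if position > len(seq):
                errors.append(
                    f"line {line}: position {position} beyond domain "
                    f"{domain_id} length {len(seq)}"
                )
                continue
            if seq[position - 1] != wt_aa:
                errors.append(
                    f"line {line}: wt_aa {wt_aa} disagrees with sequence of "
                    f"{domain_id} at position {position} "
                    f"({seq[position - 1]})"
                )
                continue
        records.append(
            VariantFitness(
                domain_id=domain_id,
                position=position,
                wt_aa=wt_aa,
                mut_aa=mut_aa,
                growth_rates=np.array([float(row[c]) for c in gr_cols]),
                counts=np.array([int(row[c]) for c in ct_cols]),
                fitness=fitness,
                sigma=sigma,
                variant_class=classify_variant(wt_aa, mut_aa),
            )
        )
    if errors:
        raise TableFormatError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return records


def write_variant_table(path: str | Path,
                        variants: Iterable[VariantFitness]) -> None:
    rows = []
    for v in variants:
        row = {
            "domain_id": v.domain_id,
            "position": v.position,
            "wt_aa": v.wt_aa,
            "mut_aa": v.mut_aa,
            "variant_class": v.variant_class,
            "fitness": v.fitness,
            "sigma": v.sigma,
        }
        for i, g in enumerate(v.growth_rates, start=1):
            row[f"growth_rate_{i}"] = g
        for i, c in enumerate(v.counts, start=1):
            row[f"count_{i}"] = int(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path, family_id: str | None = None,
                   fmt: str | None = None) -> FamilyAlignment:
    """Read an aligned FASTA or Stockholm file into a FamilyAlignment.

    Gap characters '-' and '.' are both accepted and normalized to '-'.
    The format is inferred from the file content unless ``fmt`` is given.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows: dict[str, str] = {}
    lengths = set()
    for rec in aln:
        if rec.id in rows:
            raise TableFormatError(f"{path}: duplicate row id {rec.id!r}")
        seq = str(rec.seq).upper().replace(".", GAP)
        rows[rec.id] = seq
        lengths.add(len(seq))
    if len(lengths) > 1:
        raise TableFormatError(f"{path}: ragged alignment rows {lengths}")
    ncol = lengths.pop() if lengths else 0
    return FamilyAlignment(
        family_id=family_id or path.stem, columns=ncol, rows=rows
    )


def write_alignment(path: str | Path, alignment: FamilyAlignment) -> None:
    with open(path, "w") as fh:
        for domain_id, row in alignment.rows.items():
            fh.write(f">{domain_id}\n{row}\n")


def write_model(path: str | Path, model) -> None:
    """Serialize a fitted FamilyEnergyRegressor to self-describing JSON."""
    payload = {
        "format": "domstab-family-energy-model",
        "version": MODEL_FORMAT_VERSION,
    }
    payload.update(model.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_model(path: str | Path):
    """Load a model written by :func:`write_model` at full precision."""
    from .energy import FamilyEnergyRegressor

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "domstab-family-energy-model":
        raise TableFormatError(f"{path}: not a domstab model file")
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise TableFormatError(
            f"{path}: model format version {version} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return FamilyEnergyRegressor.from_dict(payload)


def read_clinical_table(path: str | Path) -> list[ClinicalAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str})
    out = []
    for row in df.itertuples(index=False):
        af = getattr(row, "allele_frequency", None)
        if af is not None and (isinstance(af, float) and np.isnan(af)):
            af = None
        out.append(
            ClinicalAnnotation(
                domain_id=str(row.domain_id),
                position=int(row.position),
                wt_aa=str(row.wt_aa),
                mut_aa=str(row.mut_aa),
                label=str(row.label),
                allele_frequency=af,
            )
        )
    return out


def write_clinical_table(path: str | Path,
                         annotations: Iterable[ClinicalAnnotation]) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "domain_id": a.domain_id,
                "position": a.position,
                "wt_aa": a.wt_aa,
                "mut_aa": a.mut_aa,
                "label": a.label,
                "allele_frequency": (
                    "" if a.allele_frequency is None else a.allele_frequency
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path,
                     predictor_name: str = "evo") -> list[PredictorScore]:
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str})
    return [
        PredictorScore(
            domain_id=str(r.domain_id),
            position=int(r.position),
            wt_aa=str(r.wt_aa),
            mut_aa=str(r.mut_aa),
            score=float(r.score),
            predictor_name=getattr(r, "predictor_name", predictor_name),
        )
        for r in df.itertuples(index=False)
    ]


def write_score_table(path: str | Path,
                      scores: Iterable[PredictorScore]) -> None:
    pd.DataFrame(
        [
            {
                "domain_id": s.domain_id,
                "position": s.position,
                "wt_aa": s.wt_aa,
                "mut_aa": s.mut_aa,
                "score": s.score,
                "predictor_name": s.predictor_name,
            }
            for s in scores
        ]
    ).to_csv(path, sep="\t", index=False)


def merge_clinical_sources(
    *sources: Iterable[ClinicalAnnotation],
) -> list[ClinicalAnnotation]:
    """Merge clinical annotation sources; conflicting labels drop to VUS."""
    import warnings

    merged: dict[tuple, ClinicalAnnotation] = {}
    for source in sources:
        for ann in source:
            prev = merged.get(ann.key)
            if prev is None:
                merged[ann.key] = ann
            elif prev.label != ann.label:
                warnings.warn(
                    f"conflicting clinical labels for {ann.key}: "
                    f"{prev.label} vs {ann.label}; dropping to VUS",
                    stacklevel=2,
                )
                merged[ann.key] = ClinicalAnnotation(
                    domain_id=ann.domain_id,
                    position=ann.position,
                    wt_aa=ann.wt_aa,
                    mut_aa=ann.mut_aa,
                    label="vus",
                )
    return list(merged.values())
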