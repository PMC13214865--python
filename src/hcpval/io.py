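"""Readers and writers for peptide tables, FASTA databases, and result tables.

Search-engine exports differ only in column naming; a *dialect* maps the
required logical columns (sequence, accessions, run id, intensity, q-value)
onto the export's own headers.  Two presets are shipped; any mapping can be
supplied directly.  Design coordinates are carried in a separate
run-annotation table keyed by ``run_id`` because raw exports do not encode
the validation design.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    AssayPlan,
    PeptideObservation,
    ReplicateBlock,
    SpikeLevel,
    ValidationDesign,
)

__all__ = [
    "DIALECTS",
    "read_peptide_table",
    "read_fasta",
    "read_run_annotations",
    "read_design",
    "write_design",
    "write_blocks",
    "read_blocks",
    "write_table",
]


class FormatError(ValueError):
    """A required column or field is missing or unparsable."""


#: Logical column -> export header, per search-engine dialect.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "sequence": "sequence",
        "accessions": "accessions",
        "run_id": "run_id",
        "intensity": "intensity",
        "q_value": "q_value",
        "is_heavy": "is_heavy",
    },
    "spectromine": {
        "sequence": "PEP.StrippedSequence",
        "accessions": "PG.ProteinAccessions",
        "run_id": "R.FileName",
        "intensity": "PEP.Quantity",
        "q_value": "PEP.QValue",
        "is_heavy": "PEP.IsHeavy",
    },
    "fragpipe": {
        "sequence": "Peptide",
        "accessions": "Mapped Proteins",
        "run_id": "Spectrum File",
        "intensity": "Intensity",
        "q_value": "PeptideProphet Probability",
        "is_heavy": "Heavy",
    },
}

_REQUIRED = ("sequence", "accessions", "run_id", "intensity", "q_value")


def read_peptide_table(
    path: str | Path,
    dialect: str | Mapping[str, str] = "generic",
    run_annotations: Mapping[str, dict] | None = None,
    sep: str = "\t",
) -> list[PeptideObservation]:
    """Read a peptide-level TSV/CSV into :class:`PeptideObservation` rows.

    ``run_annotations`` maps run_id -> dict with keys ``assay``, ``level``,
    ``preparation``, ``injection``; unmapped runs keep empty coordinates.
    """
    colmap = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, sep=sep)
    for logical in _REQUIRED:
        if colmap[logical] not in df.columns:
            raise FormatError(
                f"required column {colmap[logical]!r} (for {logical!r}) missing from {path}"
            )
    heavy_col = colmap.get("is_heavy")
    out: list[PeptideObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = dict(zip(df.columns, row))
        try:
            intensity = float(rec[colmap["intensity"]])
            q_value = float(rec[colmap["q_value"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} line {i}: unparsable intensity/q-value") from exc
        accs = tuple(str(rec[colmap["accessions"]]).replace(",", ";").split(";"))
        run_id = str(rec[colmap["run_id"]])
        coords = (run_annotations or {}).get(run_id, {})
        is_heavy = bool(rec[heavy_col]) if heavy_col and heavy_col in df.columns else False
        out.append(
            PeptideObservation(
                sequence=str(rec[colmap["sequence"]]),
                accessions=tuple(a.strip() for a in accs if a.strip()),
                run_id=run_id,
                assay=str(coords.get("assay", "")),
                level=str(coords.get("level", "")),
                preparation=int(coords.get("preparation", 0)),
                injection=int(coords.get("injection", 0)),
                intensity=intensity,
                q_value=q_value,
                is_heavy=is_heavy,
            )
        )
    return out


def read_run_annotations(path: str | Path, sep: str = "\t") -> dict[str, dict]:
    """Read the run-annotation map (run_id -> design coordinates)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("run_id", "assay", "level", "preparation", "injection"):
        if col not in df.columns:
            raise FormatError(f"run-annotation table missing column {col!r}")
    return {
        str(r.run_id): {
            "assay": r.assay,
            "level": r.level,
            "preparation": int(r.preparation),
            "injection": int(r.injection),
        }
        for r in df.itertuples(index=False)
    }


def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    # UniProt pipe convention: db|ACCESSION|ENTRY_NAME
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA database into an accession -> uppercase-sequence map."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(record.description)
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for accession {acc!r}")
        if acc in out:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        out[acc] = seq
    return out


def read_design(path: str | Path) -> ValidationDesign:
    """Load a validation design from YAML/JSON."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    levels = tuple(SpikeLevel(d["label"], float(d["nominal_ng"])) for d in cfg["levels"])
    layout = {
        str(a): AssayPlan(
            levels=tuple(p["levels"]),
            n_preparations=int(p.get("n_preparations", 3)),
            n_injections=int(p.get("n_injections", 3)),
        )
        for a, p in cfg["assay_layout"].items()
    }
    kwargs = {
        k: cfg[k]
        for k in (
            "beta",
            "acceptance_limit_aggregate",
            "acceptance_limit_stratified",
            "mab_mass_per_injection_mg",
        )
        if k in cfg
    }
    return ValidationDesign(levels=levels, assay_layout=layout, **kwargs)


def write_design(design: ValidationDesign, path: str | Path) -> None:
    cfg = {
        "levels": [{"label": lv.label, "nominal_ng": lv.nominal_ng} for lv in design.levels],
        "assay_layout": {
            a: {
                "levels": list(p.levels),
                "n_preparations": p.n_preparations,
                "n_injections": p.n_injections,
            }
            for a, p in design.assay_layout.items()
        },
        "beta": design.beta,
        "acceptance_limit_aggregate": design.acceptance_limit_aggregate,
        "acceptance_limit_stratified": design.acceptance_limit_stratified,
        "mab_mass_per_injection_mg": design.mab_mass_per_injection_mg,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_blocks(blocks: list[ReplicateBlock], path: str | Path) -> None:
    """Write replicate-block reportables as TSV (full float precision)."""
    df = pd.DataFrame(
        {
            "assay": [b.assay for b in blocks],
            "level": [b.level for b in blocks],
            "block": [b.block for b in blocks],
            "reportable_ng": [repr(b.reportable_ng) for b in blocks],
            "nominal_ng": [repr(b.nominal_ng) for b in blocks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path) -> list[ReplicateBlock]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        ReplicateBlock(
            assay=str(r.assay),
            level=str(r.level),
            block=int(r.block),
            reportable_ng=float(r.reportable_ng),
            nominal_ng=float(r.nominal_ng),
        )
        for r in df.itertuples(index=False)
    ]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with round-trippable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
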