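"""Shared data model and file formats for the EHR pharmacogenetics pipeline.

Two longitudinal streams drive everything: biomarker measurements and drug
prescriptions, both keyed by an opaque ``person_id`` and an integer ``date``
counted in days from an arbitrary study epoch.  Tabular formats are
tab-separated with fixed headers; the QC audit and run manifest are JSON.

Dates use half-open intervals ``[a, b)`` throughout the pipeline, except the
baseline window whose "+7 days after treatment start" boundary is inclusive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKER_UNITS",
    "CodeEntry",
    "CodeMap",
    "MEASURE_COLUMNS",
    "PRESCRIPTION_COLUMNS",
    "MalformedInputError",
    "QCAudit",
    "default_code_map",
    "read_association_table",
    "read_audit",
    "read_code_map",
    "read_dosages",
    "read_dosages_vcf",
    "read_measures",
    "read_prescriptions",
    "read_weights",
    "write_association_table",
    "write_audit",
    "write_code_map",
    "write_manifest",
    "write_table",
]

#: Closed set of biomarkers and the units accepted for each.
BIOMARKER_UNITS: dict[str, set[str]] = {
    "LDL": {"mmol_L", "mg_dL"},
    "HDL": {"mmol_L", "mg_dL"},
    "TC": {"mmol_L", "mg_dL"},
    "HBA1C": {"mmol_per_mol", "percent"},
    "SBP": {"mmHg"},
    "HR": {"bpm"},
}

MEASURE_COLUMNS = ["person_id", "date", "biomarker", "value", "unit", "source"]
PRESCRIPTION_COLUMNS = ["person_id", "date", "code", "description", "quantity"]
WEIGHT_COLUMNS = ["variant_id", "effect_allele", "weight"]
ASSOC_COLUMNS = ["variant_id", "model", "mode", "beta", "se", "p", "n", "eaf"]


class MalformedInputError(ValueError):
    """A row failed hard parsing; carries file, line and column context."""


# ---------------------------------------------------------------------------
# Drug code map (toy stand-in for real prescription vocabularies)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeEntry:
    """Resolution of one drug code.

    ``primary`` names the primary-medication group the code belongs to
    (e.g. ``statin``) or ``None`` for other members of the broad class.
    Combination products (single item containing the primary medication plus
    another same-class agent) carry ``is_combination=True``.
    """

    broad_class: str
    primary: str | None
    ingredient: str
    dose_mg: float | None = None
    is_combination: bool = False


class CodeMap:
    """Mapping drug code -> :class:`CodeEntry`."""

    def __init__(self, entries: dict[str, CodeEntry]):
        primaries: dict[str, str] = {}
        for code, e in entries.items():
            if e.primary is not None:
                seen = primaries.setdefault(e.primary, e.broad_class)
                if seen != e.broad_class:
                    raise ValueError(
                        f"primary medication {e.primary!r} spans broad classes "
                        f"{seen!r} and {e.broad_class!r} (code {code!r})"
                    )
        self.entries = dict(entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> CodeEntry:
        return self.entries[code]

    def get(self, code: str) -> CodeEntry | None:
        return self.entries.get(code)

    def codes_for_primary(self, primary: str) -> list[str]:
        return [c for c, e in self.entries.items() if e.primary == primary]

    def __len__(self) -> int:
        return len(self.entries)


def default_code_map() -> CodeMap:
    """Toy code map covering the lipid and antidiabetic broad classes."""
    E = CodeEntry
    return CodeMap(
        {
            # lipid-regulating class
            "STA1": E("lipid", "statin", "simvastatin"),
            "STA2": E("lipid", "statin", "atorvastatin"),
            "STA3": E("lipid", "statin", "rosuvastatin"),
            "EZE1": E("lipid", None, "ezetimibe"),
            "FIB1": E("lipid", None, "fenofibrate"),
            "CMB1": E("lipid", "statin", "simvastatin_ezetimibe", is_combination=True),
            # antidiabetic class
            "MET1": E("antidiabetic", "metformin", "metformin"),
            "SUL1": E("antidiabetic", None, "gliclazide"),
            "SUL2": E("antidiabetic", None, "glimepiride"),
            "CMB2": E("antidiabetic", "metformin", "metformin_gliclazide", is_combination=True),
            # antihypertensive class
            "ACE1": E("antihypertensive", "acei", "ramipril"),
            "CCB1": E("antihypertensive", "ccb", "amlodipine"),
        }
    )


def write_code_map(code_map: CodeMap, path: str | Path) -> None:
    rows = [
        {
            "code": c,
            "broad_class": e.broad_class,
            "primary": e.primary if e.primary is not None else "",
            "ingredient": e.ingredient,
            "dose_mg": "" if e.dose_mg is None else e.dose_mg,
            "is_combination": int(e.is_combination),
        }
        for c, e in code_map.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_code_map(path: str | Path) -> CodeMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = {}
    for _, r in df.iterrows():
        entries[r["code"]] = CodeEntry(
            broad_class=r["broad_class"],
            primary=r["primary"] or None,
            ingredient=r["ingredient"],
            dose_mg=float(r["dose_mg"]) if r["dose_mg"] else None,
            is_combination=bool(int(r["is_combination"])),
        )
    return CodeMap(entries)


# ---------------------------------------------------------------------------
# Longitudinal streams
# ---------------------------------------------------------------------------


def _parse_typed(df: pd.DataFrame, path: str | Path, column: str, kind: str) -> pd.Series:
    """Coerce a column, raising MalformedInputError naming file/line/column."""
    raw = df[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # 1-based plus header line
        raise MalformedInputError(
            f"{path}: line {line}, column {column!r}: cannot parse {raw[bad.idxmax()]!r} as {kind}"
        )
    if kind == "int":
        frac = converted.dropna() % 1 != 0
        if frac.any():
            line = int(frac.idxmax()) + 2
            raise MalformedInputError(
                f"{path}: line {line}, column {column!r}: expected integer"
            )
        return converted.astype("Int64")
    return converted


def read_measures(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read measures.tsv -> (accepted records, rejects with reasons).

    Unknown biomarker codes, units outside the biomarker's allowed set,
    missing units, negative dates and non-finite values are quarantined in the
    rejects table rather than silently dropped.  Hard parse failures raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if df.empty:
        empty = df.reindex(columns=MEASURE_COLUMNS)
        return empty.assign(date=pd.Series(dtype=int), value=pd.Series(dtype=float)), _empty_rejects()

    df = df.copy()
    df["date"] = _parse_typed(df, path, "date", "int")
    df["value"] = _parse_typed(df, path, "value", "float")

    reasons = pd.Series("", index=df.index)
    reasons[~df["biomarker"].isin(BIOMARKER_UNITS)] = "unknown_biomarker"
    unit_ok = [
        (b in BIOMARKER_UNITS and u in BIOMARKER_UNITS[b])
        for b, u in zip(df["biomarker"], df["unit"])
    ]
    reasons[(reasons == "") & (df["unit"].str.strip() == "")] = "missing_unit"
    reasons[(reasons == "") & ~pd.Series(unit_ok, index=df.index)] = "invalid_unit"
    reasons[(reasons == "") & ~np.isfinite(df["value"].astype(float))] = "nonfinite_value"
    reasons[(reasons == "") & (df["date"] < 0)] = "negative_date"

    rejected = reasons != ""
    rejects = df.loc[rejected, MEASURE_COLUMNS].assign(reason=reasons[rejected])
    accepted = df.loc[~rejected, MEASURE_COLUMNS].copy()
    accepted["date"] = accepted["date"].astype(int)
    accepted["value"] = accepted["value"].astype(float)
    return accepted.reset_index(drop=True), rejects.reset_index(drop=True)


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=[*MEASURE_COLUMNS, "reason"])


def read_prescriptions(
    path: str | Path, code_map: CodeMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read prescriptions.tsv -> (accepted, rejects).

    With a code map, codes it cannot resolve are quarantined.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PRESCRIPTION_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if df.empty:
        return df.reindex(columns=PRESCRIPTION_COLUMNS), pd.DataFrame(
            columns=[*PRESCRIPTION_COLUMNS, "reason"]
        )
    df = df.copy()
    df["date"] = _parse_typed(df, path, "date", "int")
    qty = df["quantity"].replace("", np.nan)
    df["quantity"] = pd.to_numeric(qty, errors="coerce")

    reasons = pd.Series("", index=df.index)
    reasons[df["date"] < 0] = "negative_date"
    if code_map is not None:
        reasons[(reasons == "") & ~df["code"].isin(code_map.entries)] = "unknown_code"
    rejected = reasons != ""
    rejects = df.loc[rejected, PRESCRIPTION_COLUMNS].assign(reason=reasons[rejected])
    accepted = df.loc[~rejected, PRESCRIPTION_COLUMNS].copy()
    accepted["date"] = accepted["date"].astype(int)
    return accepted.reset_index(drop=True), rejects.reset_index(drop=True)


def read_dosages(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a plain dosage matrix (rows persons, columns variants, values [0,2]).

    Returns (dosage frame indexed by person_id, list of monomorphic variants).
    Monomorphic columns are accepted but flagged so downstream association can
    refuse to fit them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str})
    if "person_id" not in df.columns:
        raise MalformedInputError(f"{path}: missing column 'person_id'")
    df = df.set_index("person_id")
    values = df.to_numpy(dtype=float)
    if values.size and (np.nanmin(values) < 0 or np.nanmax(values) > 2):
        raise MalformedInputError(f"{path}: dosages must lie in [0, 2]")
    monomorphic = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    return df.astype(float), monomorphic


def read_dosages_vcf(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Extract a dosage matrix from a VCF (DS format field, else GT allele count)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            data[vid] = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            data[vid] = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
    df = pd.DataFrame(data, index=pd.Index(samples, name="person_id"))
    monomorphic = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    return df, monomorphic


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "effect_allele": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise MalformedInputError(f"{path}: duplicate variant_id {dup!r}")
    if not np.isfinite(df["weight"].to_numpy(dtype=float)).all():
        raise MalformedInputError(f"{path}: non-finite weight")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_association_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df.reindex(columns=ASSOC_COLUMNS), path)


def read_association_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str, "model": str, "mode": str})


# ---------------------------------------------------------------------------
# QC audit and run manifest
# ---------------------------------------------------------------------------


@dataclass
class QCAudit:
    """Auditable record of every exclusion in the cohort-emulation cascade.

    Each excluded person is counted at the first stage it fails, so
    ``n_input == n_final + sum(removed.values())`` holds exactly.
    """

    stages: list[str]
    removed: dict[str, int]
    first_failing: dict[str, str]
    n_input: int
    n_final: int
    cohort_size_warning: bool = False

    def conserved(self) -> bool:
        return self.n_input == self.n_final + sum(self.removed.values())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCAudit":
        return cls(
            stages=list(d["stages"]),
            removed={k: int(v) for k, v in d["removed"].items()},
            first_failing=dict(d["first_failing"]),
            n_input=int(d["n_input"]),
            n_final=int(d["n_final"]),
            cohort_size_warning=bool(d["cohort_size_warning"]),
        )


def write_audit(audit: QCAudit, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(audit.to_dict(), indent=2))


def read_audit(path: str | Path) -> QCAudit:
    return QCAudit.from_dict(json.loads(Path(path).read_text()))


def write_manifest(config: dict, seed: int, path: str | Path) -> None:
    """Echo the effective configuration and master seed of a run."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({"seed": int(seed), "config": config}, indent=2, default=str))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
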