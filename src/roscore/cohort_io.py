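"""Cohort input/output: expression matrices, clinical tables, gene panels.

File conventions (all plain text, TSV or CSV):
  * expression: genes in rows, first column = gene symbol, header = sample
    ids, cells numeric or NA. Gene symbols are upper-cased for matching.
  * clinical: one row per sample; arbitrary headers are renamed to the
    canonical fields via a column map. Canonical columns: ``sample_id``,
    ``os_years``, ``os_event``, ``age``, ``stage``, ``grade``,
    ``residual_mm``; any extra columns are carried through as strata.
  * panel: three columns (gene, direction in {high, low}, p). The packaged
    ``table1`` fixture is the published 25-gene panel.

Residual disease is recoded at the 10 mm boundary: <= 10 mm residual is
"optimal" debulking, >= 11 mm "suboptimal". Gene-symbol matching is
case-insensitive exact match; no alias resolution. Median dichotomization
is invariant under monotone per-gene transforms, so any monotone expression
scale (intensity, log-count, -dCt) is acceptable and no unit is enforced.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from roscore._panel_data import BUILTIN_PANELS

logger = logging.getLogger("roscore")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GenePanel",
    "PanelEntry",
    "AlignedCohort",
    "HIGH_GOOD",
    "LOW_GOOD",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "load_panel",
    "write_panel",
    "align_cohort",
]

HIGH_GOOD = "high_good"
LOW_GOOD = "low_good"

STAGES = ("I", "II", "III", "IV")
GRADES = ("1", "2", "3", "other")

CANONICAL_CLINICAL = (
    "sample_id",
    "os_years",
    "os_event",
    "age",
    "stage",
    "grade",
    "residual_mm",
)


def _sep_for(path, fmt=None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "csv"):
            raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
        return "\t" if fmt == "tsv" else ","
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample continuous expression values.

    ``frame`` is indexed by upper-cased gene symbol with sample-id columns;
    missing values are NaN (explicitly marked, never silently zero).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        if f.shape[0] == 0 or f.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        f.index = f.index.astype(str).str.upper()
        f.index.name = "gene"
        f.columns = f.columns.astype(str)
        dup = f.index[f.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene id(s) after case-normalization: {', '.join(dup)}")
        dup = f.columns[f.columns.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate sample id(s): {', '.join(dup)}")
        vals = f.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        bad = np.isinf(vals)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at gene {f.index[g]!r}, sample {f.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def values_for(self, gene: str) -> np.ndarray:
        return self.frame.loc[gene.upper()].to_numpy(dtype=float)

    def has_gene(self, gene: str) -> bool:
        return gene.upper() in self.frame.index

    def missing_summary(self) -> pd.Series:
        """Count of missing values per gene (genes with any NA only)."""
        na = self.frame.isna().sum(axis=1)
        return na[na > 0]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[:, list(sample_ids)].copy())


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows expression table (TSV/CSV, NA = missing)."""
    path = Path(path)
    sep = _sep_for(path, format)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_hdr = {h for h in header if header.count(h) > 1}
    if dup_hdr:
        raise ValueError(f"{path}: duplicate sample id(s) in header: {', '.join(sorted(dup_hdr))}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    na_tokens = {"", "NA", "NAN", "NaN", "nan", "na", "N/A", "null", "NULL"}
    numeric = raw.apply(lambda col: pd.to_numeric(col.where(~col.isin(na_tokens)), errors="coerce"))
    bad = numeric.isna() & ~raw.isin(na_tokens)
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    em = ExpressionMatrix(numeric)
    n_missing = int(em.frame.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "%s: %d missing expression value(s) across %d gene(s)",
            path,
            n_missing,
            len(em.missing_summary()),
        )
    return em


def write_expression(em: ExpressionMatrix, path, format: str | None = None) -> None:
    sep = _sep_for(path, format)
    em.frame.to_csv(path, sep=sep, na_rep="NA")


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

_EVENT_MAP = {
    "0": 0, "1": 1, "0.0": 0, "1.0": 1,
    "alive": 0, "living": 0, "censored": 0, "no": 0, "false": 0,
    "dead": 1, "deceased": 1, "death": 1, "yes": 1, "true": 1,
}

_ROMAN = {"i": "I", "ii": "II", "iii": "III", "iv": "IV"}
_ARABIC = {"1": "I", "2": "II", "3": "III", "4": "IV"}


def _norm_stage(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "unknown", "nx"):
        return np.nan
    s = re.sub(r"^(figo\s*)?(stage\s*)?", "", s)
    m = re.match(r"(iv|iii|ii|i)[abc]?$", s)
    if m:
        return _ROMAN[m.group(1)]
    m = re.match(r"([1-4])[abc]?$", s)
    if m:
        return _ARABIC[m.group(1)]
    raise ValueError(f"unparseable stage value {value!r}")


def _norm_grade(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower().removeprefix("g")
    if s in ("", "na", "nan", "unknown", "gx", "x"):
        return np.nan
    if s in ("1", "2", "3", "1.0", "2.0", "3.0"):
        return s[0]
    return "other"


def _norm_event(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    key = str(value).strip().lower()
    if key in ("", "na", "nan"):
        return np.nan
    if key not in _EVENT_MAP:
        raise ValueError(f"unmappable event coding {value!r} (expected 0/1, alive/dead, ...)")
    return _EVENT_MAP[key]


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus clinical covariates.

    ``frame`` is indexed by sample id with columns ``os_years`` (> 0),
    ``os_event`` (1 = death observed, 0 = right-censored), ``age``,
    ``stage`` (I..IV), ``grade`` (1/2/3/other), ``residual_mm`` and the
    derived ``residual`` (optimal <= 10 mm / suboptimal >= 11 mm).
    Covariates may be missing (NaN); outcome columns may not.
    Extra columns (molecular subtype, regimen, ...) are kept as strata.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        f.index = f.index.astype(str)
        f.index.name = "sample_id"
        dup = f.index[f.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate sample id(s): {', '.join(dup)}")
        for col in ("os_years", "os_event"):
            if col not in f.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        if f["os_years"].isna().any() or f["os_event"].isna().any():
            bad = f.index[f["os_years"].isna() | f["os_event"].isna()]
            raise ValueError(f"missing survival outcome for sample(s): {', '.join(bad)}")
        nonpos = f.index[f["os_years"] <= 0]
        if len(nonpos):
            raise ValueError(f"os_years must be > 0; offending sample(s): {', '.join(nonpos)}")
        if not f["os_event"].isin((0, 1)).all():
            raise ValueError("os_event must be coded 0/1")
        f["os_event"] = f["os_event"].astype(int)
        if "residual_mm" in f.columns and "residual" not in f.columns:
            recoded = pd.Series(
                np.where(f["residual_mm"] <= 10.0, "optimal", "suboptimal"),
                index=f.index,
                dtype=object,
            )
            f["residual"] = recoded.where(f["residual_mm"].notna())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def os_years(self) -> np.ndarray:
        return self.frame["os_years"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.frame["os_event"].to_numpy(dtype=int)

    @property
    def extra_columns(self) -> list[str]:
        known = set(CANONICAL_CLINICAL) | {"residual"}
        return [c for c in self.frame.columns if c not in known]

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(sample_ids)].copy())


def read_clinical(
    path,
    column_map: dict | None = None,
    format: str | None = None,
    residual_unit: str = "mm",
) -> ClinicalTable:
    """Read and validate a clinical table.

    ``column_map`` maps canonical field names to the file's headers, e.g.
    ``{"sample_id": "bcr_patient_barcode", "os_years": "OS.years"}``;
    canonical names already present need not be listed. ``residual_unit``
    ("mm" or "cm") rescales the residual-disease column to millimetres
    before the optimal (<= 10 mm) / suboptimal recoding.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    column_map = dict(column_map or {})
    rename = {}
    for canonical, source in column_map.items():
        if canonical not in CANONICAL_CLINICAL:
            raise ValueError(f"unknown canonical clinical field {canonical!r}")
        if source not in raw.columns:
            raise ValueError(f"{path}: mapped column {source!r} not found")
        rename[source] = canonical
    raw = raw.rename(columns=rename)
    if "sample_id" not in raw.columns:
        raise ValueError(f"{path}: no sample_id column (use column_map)")
    for col in ("os_years", "os_event"):
        if col not in raw.columns:
            raise ValueError(f"{path}: no {col} column (use column_map)")

    out = pd.DataFrame(index=raw["sample_id"].astype(str))
    out["os_years"] = pd.to_numeric(raw["os_years"].values, errors="raise")
    out["os_event"] = [_norm_event(v) for v in raw["os_event"].values]
    if "age" in raw.columns:
        out["age"] = pd.to_numeric(raw["age"].values, errors="coerce")
    if "stage" in raw.columns:
        out["stage"] = [_norm_stage(v) for v in raw["stage"].values]
    if "grade" in raw.columns:
        out["grade"] = [_norm_grade(v) for v in raw["grade"].values]
    if "residual_mm" in raw.columns:
        mm = pd.to_numeric(raw["residual_mm"].values, errors="coerce")
        if residual_unit == "cm":
            mm = mm * 10.0
        elif residual_unit != "mm":
            raise ValueError(f"residual_unit must be 'mm' or 'cm', got {residual_unit!r}")
        out["residual_mm"] = mm
    used = set(rename) | set(CANONICAL_CLINICAL)
    for col in raw.columns:
        if col not in used:
            out[col] = raw[col].where(~raw[col].isin(("", "NA", "nan")), np.nan).values
    ct = ClinicalTable(out)
    logger.info(
        "%s: %d samples, %d events, %d censored",
        path,
        ct.n_samples,
        int(ct.os_event.sum()),
        int((1 - ct.os_event).sum()),
    )
    return ct


def write_clinical(ct: ClinicalTable, path, format: str | None = None) -> None:
    sep = _sep_for(path, format)
    ct.frame.to_csv(path, sep=sep, na_rep="NA")


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    direction: str  # high_good / low_good
    p: float

    def __post_init__(self):
        if self.direction not in (HIGH_GOOD, LOW_GOOD):
            raise ValueError(f"invalid direction {self.direction!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"screen p out of [0, 1]: {self.p}")


@dataclass
class GenePanel:
    """Ordered list of scored genes with direction-of-effect labels.

    ``high_good`` genes earn a point for above-median expression,
    ``low_good`` genes for at-or-below-median expression.
    """

    entries: list[PanelEntry]

    def __post_init__(self):
        if len(self.entries) < 1:
            raise ValueError("a gene panel needs at least one entry")
        genes = [e.gene.upper() for e in self.entries]
        if len(set(genes)) != len(genes):
            seen, dup = set(), set()
            for g in genes:
                (dup if g in seen else seen).add(g)
            raise ValueError(f"duplicate panel gene(s): {', '.join(sorted(dup))}")
        self.entries = [
            PanelEntry(gene=e.gene.upper(), direction=e.direction, p=e.p) for e in self.entries
        ]

    @property
    def K(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def directions(self) -> dict[str, str]:
        return {e.gene: e.direction for e in self.entries}

    def flipped(self) -> "GenePanel":
        """Panel with every direction label inverted (for audits/tests)."""
        inv = {HIGH_GOOD: LOW_GOOD, LOW_GOOD: HIGH_GOOD}
        return GenePanel([PanelEntry(e.gene, inv[e.direction], e.p) for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "direction": ["high" if e.direction == HIGH_GOOD else "low" for e in self.entries],
                "p": [e.p for e in self.entries],
            }
        )


_DIRECTION_TOKENS = {
    "high": HIGH_GOOD,
    "high_good": HIGH_GOOD,
    "low": LOW_GOOD,
    "low_good": LOW_GOOD,
}


def load_panel(source) -> GenePanel:
    """Load a gene panel from a 3-column TSV/CSV or a builtin fixture name.

    Builtin names: ``table1`` (the packaged 25-gene panel).
    """
    if isinstance(source, str) and source in BUILTIN_PANELS:
        return GenePanel(
            [PanelEntry(g, _DIRECTION_TOKENS[d], p) for g, p, d in BUILTIN_PANELS[source]]
        )
    path = Path(source)
    if not path.exists():
        raise ValueError(
            f"panel source {source!r} is neither a builtin name "
            f"({', '.join(sorted(BUILTIN_PANELS))}) nor an existing file"
        )
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("gene", "direction", "p") if c not in cols]
    if missing:
        raise ValueError(f"{path}: panel file lacks column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty panel file")
    entries = []
    for _, row in df.iterrows():
        token = str(row[cols["direction"]]).strip().lower()
        if token not in _DIRECTION_TOKENS:
            raise ValueError(f"{path}: unknown direction token {row[cols['direction']]!r}")
        entries.append(
            PanelEntry(
                gene=str(row[cols["gene"]]).strip(),
                direction=_DIRECTION_TOKENS[token],
                p=float(row[cols["p"]]),
            )
        )
    return GenePanel(entries)


def write_panel(panel: GenePanel, path, format: str | None = None) -> None:
    sep = _sep_for(path, format)
    panel.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    dropped_expression: list[str] = field(default_factory=list)
    dropped_clinical: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable) -> AlignedCohort:
    """Restrict both tables to the shared samples, in the expression order.

    Idempotent: aligning an already-aligned cohort drops nothing.
    """
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"expression and clinical tables share only {len(shared)} sample(s); need >= 2"
        )
    dropped_e = [s for s in expr.sample_ids if s not in set(shared)]
    dropped_c = [s for s in clin.sample_ids if s not in set(shared)]
    if dropped_e or dropped_c:
        logger.info(
            "align_cohort: %d dropped from expression, %d from clinical",
            len(dropped_e),
            len(dropped_c),
        )
    return AlignedCohort(
        expression=expr.subset_samples(shared),
        clinical=clin.subset(shared),
        dropped_expression=dropped_e,
        dropped_clinical=dropped_c,
    )
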