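"""Cohort container, variable catalog and the Categorize step.

The 3C strategy starts from a subject x variable table of mixed clinical
and biological measurements together with a knowledge-driven catalog that
assigns every variable to one of three roles:

``DX``
    the assigned diagnosis, a single crude ordinal label (e.g. the
    CN < SMC < EMCI < LMCI < AD staging of an Alzheimer's cohort);
``CM``
    clinical measurements describing the patient's manifest condition
    (cognitive test scores, questionnaires, co-morbidities, demographics);
``PBM``
    potential biomarkers: biological measures (CSF, genetics, imaging
    volumetry) whose clinical meaning is not asserted up front.

Categorization is deliberately knowledge-driven: the catalog is an input,
never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CATEGORIES = ("DX", "CM", "PBM")
VARTYPES = ("continuous", "ordinal", "categorical")
DIRECTIONS = ("higher_worse", "higher_better", "none")

#: Ordered diagnosis levels used by the synthetic generator (least to most
#: severe), mirroring the ADNI-style five-level staging.
DX_LEVELS = ("CN", "SMC", "EMCI", "LMCI", "AD")

CATALOG_COLUMNS = ("variable", "category", "vartype", "direction", "domain")


class CatalogError(ValueError):
    """Raised when a variable catalog violates its schema."""


@dataclass
class VariableCatalog:
    """Per-variable metadata: category, type, severity direction, domain tag.

    Wraps a DataFrame with columns ``variable, category, vartype, direction,
    domain`` (one row per variable).  Exactly one variable must carry the
    ``DX`` category.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "VariableCatalog":
        df = pd.DataFrame(list(records))
        for col in CATALOG_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col == "domain" else None
        return cls(df[list(CATALOG_COLUMNS)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "VariableCatalog":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns and c != "domain"]
        if missing:
            raise CatalogError(f"catalog missing required columns: {missing}")
        if "domain" not in df.columns:
            df["domain"] = ""
        return cls(df[list(CATALOG_COLUMNS)])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        errors: list[str] = []
        if t["variable"].duplicated().any():
            dups = t.loc[t["variable"].duplicated(), "variable"].tolist()
            errors.append(f"duplicate variable entries: {dups}")
        for i, row in t.iterrows():
            if row["category"] not in CATEGORIES:
                errors.append(f"line {i + 2}: bad category {row['category']!r} "
                              f"for {row['variable']!r}")
            if row["vartype"] not in VARTYPES:
                errors.append(f"line {i + 2}: bad vartype {row['vartype']!r} "
                              f"for {row['variable']!r}")
            if row["direction"] not in DIRECTIONS:
                errors.append(f"line {i + 2}: bad direction {row['direction']!r} "
                              f"for {row['variable']!r}")
        n_dx = int((t["category"] == "DX").sum())
        if n_dx != 1:
            errors.append(f"catalog must designate exactly one DX variable, found {n_dx}")
        cm_no_dir = t[(t["category"] == "CM") & (t["direction"] == "none")]
        if len(cm_no_dir):
            errors.append("CM variables must carry a severity direction: "
                          f"{cm_no_dir['variable'].tolist()}")
        if errors:
            raise CatalogError("; ".join(errors))

    # -- accessors -------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return self.table["variable"].tolist()

    @property
    def dx_variable(self) -> str:
        return self.table.loc[self.table["category"] == "DX", "variable"].iloc[0]

    def names(self, category: str) -> list[str]:
        return self.table.loc[self.table["category"] == category, "variable"].tolist()

    def direction(self, variable: str) -> str:
        row = self.table.loc[self.table["variable"] == variable]
        if row.empty:
            raise CatalogError(f"variable {variable!r} not in catalog")
        return row["direction"].iloc[0]

    def vartype(self, variable: str) -> str:
        row = self.table.loc[self.table["variable"] == variable]
        if row.empty:
            raise CatalogError(f"variable {variable!r} not in catalog")
        return row["vartype"].iloc[0]

    def subset(self, variables: Iterable[str]) -> "VariableCatalog":
        keep = set(variables)
        return VariableCatalog(self.table[self.table["variable"].isin(keep)].copy())

    def add_variable(self, variable: str, category: str, vartype: str,
                     direction: str, domain: str = "") -> "VariableCatalog":
        row = pd.DataFrame([{"variable": variable, "category": category,
                             "vartype": vartype, "direction": direction,
                             "domain": domain}])
        return VariableCatalog(pd.concat([self.table, row], ignore_index=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Cohort:
    """A subject x variable table with its catalog.

    ``data`` is indexed by subject id; missing cells are NaN.  The catalog
    must cover every column (and nothing else).
    """

    data: pd.DataFrame
    catalog: VariableCatalog
    #: optional free-form provenance notes (filter reports etc.)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        cat = set(self.catalog.variables)
        if cols != cat:
            only_data = sorted(cols - cat)
            only_cat = sorted(cat - cols)
            raise CatalogError(
                f"catalog/data mismatch: columns without catalog entry {only_data}; "
                f"catalog entries without column {only_cat}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.data.isna()

    def is_complete(self) -> bool:
        return not bool(self.data.isna().values.any())

    # -- io ---------------------------------------------------------------
    def to_csv(self, data_path: str | Path, catalog_path: str | Path | None = None
               ) -> None:
        self.data.to_csv(data_path, index_label="subject_id")
        if catalog_path is not None:
            self.catalog.to_csv(catalog_path)

    @classmethod
    def from_csv(cls, data_path: str | Path, catalog_path: str | Path) -> "Cohort":
        catalog = VariableCatalog.from_csv(catalog_path)
        df = pd.read_csv(data_path, index_col="subject_id")
        # DX and categorical columns stay as strings; everything else numeric
        for var in df.columns:
            if var in set(catalog.variables) and \
                    catalog.vartype(var) in ("continuous", "ordinal") and \
                    catalog.table.set_index("variable").loc[var, "category"] != "DX":
                df[var] = pd.to_numeric(df[var], errors="coerce")
        return cls(df, catalog)

    def subset_variables(self, variables: Iterable[str]) -> "Cohort":
        variables = [v for v in self.data.columns if v in set(variables)]
        return Cohort(self.data[variables].copy(), self.catalog.subset(variables),
                      dict(self.meta))


def dx_severity_level(labels: pd.Series | np.ndarray,
                      order: tuple[str, ...] = DX_LEVELS) -> np.ndarray:
    """Map ordinal diagnosis labels to 0-based severity levels.

    Integer-coded labels pass through; string labels are looked up in
    ``order`` (least severe first).
    """
    arr = np.asarray(labels)
    if arr.dtype.kind in "iuf":
        return arr.astype(int)
    lookup = {lab: i for i, lab in enumerate(order)}
    try:
        return np.array([lookup[x] for x in arr], dtype=int)
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"unknown DX label {e.args[0]!r}; expected one of {order}")


def categorize(cohort: Cohort) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Split a cohort into (dx_labels, cm_block, pbm_block) by catalog category.

    The three views share the cohort's subject order.  The DX label must
    show at least two observed levels, otherwise screening against it is
    meaningless.
    """
    catalog = cohort.catalog
    dx_var = catalog.dx_variable
    dx = cohort.data[dx_var]
    if dx.dropna().nunique() < 2:
        raise CatalogError(
            f"DX variable {dx_var!r} has fewer than two observed levels")
    cm_block = cohort.data[catalog.names("CM")]
    pbm_block = cohort.data[catalog.names("PBM")]
    return dx, cm_block, pbm_block
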