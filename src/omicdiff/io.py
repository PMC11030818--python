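"""Tabular input/output for site, protein and metabolite tables.

All on-disk tables are tab-delimited text with a header row; lines
starting with ``#`` are treated as comments (the CLI writes provenance
headers this way).  Missing values are written as ``NA`` and read back
from ``NA`` or empty cells.  Intensities are non-negative; a literal 0
is kept as a value in the generic dialect but converted to missing in
the MaxQuant sites dialect, where 0 denotes non-detection.

In-memory conventions
---------------------
* Site tables: :class:`pandas.DataFrame` with a 4-level ``MultiIndex``
  ``(protein_id, residue, position, modification)`` and one float
  column per sample.
* Protein tables: DataFrame indexed by ``protein_id``.
* Metabolite tables: :class:`MetaboliteTable` (values + display name +
  optional lipid-class annotation).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SampleSheet",
    "MetaboliteTable",
    "SITE_INDEX",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_site_table",
    "write_site_table",
    "read_protein_table",
    "write_protein_table",
    "read_metabolite_table",
    "write_metabolite_table",
    "write_table",
]

SITE_INDEX = ["protein_id", "residue", "position", "modification"]

#: number formatting used by every writer; 17 significant digits make
#: the float -> text -> float round trip exact.
_FLOAT_FMT = "%.17g"
_NA_REP = "NA"


class FormatError(ValueError):
    """Raised when an input file violates the table contract."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Maps samples to groups and replicate pairings.

    ``frame`` has columns ``sample_id``, ``group``, ``replicate_index``
    and optionally ``channel`` (TMT reporter label); row order is
    preserved from the input file.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "replicate_index"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample_id: {sorted(set(dups))}")
        try:
            idx = self.frame["replicate_index"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError("replicate_index must be integer") from exc
        if (idx < 1).any():
            raise FormatError("replicate_index must be a positive integer")
        self.frame = self.frame.assign(replicate_index=idx).reset_index(drop=True)
        for grp, sub in self.frame.groupby("group", sort=False):
            if sub["replicate_index"].duplicated().any():
                raise FormatError(f"duplicate replicate_index within group {grp!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    def samples(self, group: str) -> list[str]:
        sel = self.frame.loc[self.frame["group"] == group, "sample_id"]
        if sel.empty:
            raise KeyError(f"no samples in group {group!r}")
        return list(sel)

    def paired_samples(self, group_a: str, group_b: str) -> list[tuple[str, str]]:
        """Samples of the two groups matched by ``replicate_index``.

        Unmatched replicate indices are dropped; pairs are returned in
        increasing replicate order.
        """
        a = self.frame[self.frame["group"] == group_a].set_index("replicate_index")
        b = self.frame[self.frame["group"] == group_b].set_index("replicate_index")
        shared = sorted(set(a.index) & set(b.index))
        return [(a.loc[i, "sample_id"], b.loc[i, "sample_id"]) for i in shared]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet from TSV or CSV (delimiter sniffed from header)."""
    path = Path(path)
    text = _read_text(path)
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(_io.StringIO(text), sep=sep, dtype={"sample_id": str, "group": str})
    known = ["sample_id", "group", "replicate_index", "channel"]
    extra = [c for c in frame.columns if c not in known]
    if extra:
        logger.warning("sample sheet %s: ignoring columns %s", path, extra)
        frame = frame.drop(columns=extra)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, header: str | None = None) -> None:
    _write(sheet.frame, path, header=header, index=False)


# ---------------------------------------------------------------------------
# site and protein tables
# ---------------------------------------------------------------------------

def read_site_table(
    path: str | Path,
    dialect: str = "generic",
    modification: str = "site",
) -> pd.DataFrame:
    """Read a site-level modified-peptide intensity table.

    Parameters
    ----------
    dialect
        ``generic``: header ``protein_id, residue, position,
        modification`` followed by one column per sample; empty/``NA``
        cells are missing.  ``maxquant_sites``: MaxQuant sites-table
        columns ``Protein``, ``Amino acid``, ``Position`` and
        ``Intensity <sample>``; intensity 0 is converted to missing.
    modification
        Modification tag stamped on every row of a ``maxquant_sites``
        file (the MaxQuant table carries it implicitly in the file name).
    """
    path = Path(path)
    if dialect == "generic":
        frame = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t",
                            na_values=[_NA_REP, ""], keep_default_na=False,
                        float_precision="round_trip",
                            dtype={"protein_id": str, "residue": str, "modification": str})
        missing = set(SITE_INDEX) - set(frame.columns)
        if missing:
            raise FormatError(f"{path}: missing site columns {sorted(missing)}")
    elif dialect == "maxquant_sites":
        raw = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t",
                          na_values=[_NA_REP, ""], keep_default_na=False,
                        float_precision="round_trip")
        required = {"Protein", "Amino acid", "Position"}
        if not required <= set(raw.columns):
            raise FormatError(f"{path}: missing columns {sorted(required - set(raw.columns))}")
        intensity_cols = [c for c in raw.columns if c.startswith("Intensity ")]
        if not intensity_cols:
            raise FormatError(f"{path}: no 'Intensity <sample>' columns")
        frame = pd.DataFrame({
            "protein_id": raw["Protein"].astype(str),
            "residue": raw["Amino acid"].astype(str),
            "position": raw["Position"],
            "modification": modification,
        })
        for col in intensity_cols:
            # MaxQuant writes 0 for sites not detected in a sample
            values = pd.to_numeric(raw[col], errors="coerce")
            frame[col.removeprefix("Intensity ")] = values.where(values != 0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    positions = pd.to_numeric(frame["position"], errors="coerce")
    if positions.isna().any() or (positions <= 0).any() or (positions % 1 != 0).any():
        raise FormatError(f"{path}: position must be a positive integer")
    frame["position"] = positions.astype(int)

    sample_cols = [c for c in frame.columns if c not in SITE_INDEX]
    if not sample_cols:
        raise FormatError(f"{path}: no intensity columns")
    table = frame.set_index(SITE_INDEX)[sample_cols].astype(float)
    _check_nonnegative(table, path)
    if table.index.duplicated().any():
        raise FormatError(f"{path}: duplicate site keys")
    return table


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read a protein-level intensity table (``protein_id`` + sample columns)."""
    path = Path(path)
    frame = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t",
                        na_values=[_NA_REP, ""], keep_default_na=False,
                        float_precision="round_trip",
                        dtype={"protein_id": str})
    if "protein_id" not in frame.columns:
        raise FormatError(f"{path}: missing protein_id column")
    table = frame.set_index("protein_id").astype(float)
    if table.shape[1] == 0:
        raise FormatError(f"{path}: no intensity columns")
    _check_nonnegative(table, path)
    if table.index.duplicated().any():
        raise FormatError(f"{path}: duplicate protein_id")
    return table


def write_site_table(table: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write(table.reset_index(), path, header=header, index=False)


def write_protein_table(table: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write(table.reset_index(), path, header=header, index=False)


# ---------------------------------------------------------------------------
# metabolite tables
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteTable:
    """Metabolite peak-area matrix with display names and optional classes.

    ``values`` is indexed by ``metabolite_id`` with one float column per
    sample; ``names`` maps id -> display name (used for lipid-class
    prefix matching); ``classes`` maps id -> curated class annotation
    and overrides name parsing when present.
    """

    values: pd.DataFrame
    names: pd.Series = field(default=None)  # type: ignore[assignment]
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate metabolite_id")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("negative peak area")
        if self.names is None:
            self.names = pd.Series(self.values.index, index=self.values.index, name="name")
        self.names = self.names.reindex(self.values.index)
        if self.classes is not None:
            self.classes = self.classes.reindex(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)


def read_metabolite_table(path: str | Path) -> MetaboliteTable:
    path = Path(path)
    frame = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t",
                        na_values=[_NA_REP, ""], keep_default_na=False,
                        float_precision="round_trip",
                        dtype={"metabolite_id": str})
    if "metabolite_id" not in frame.columns:
        raise FormatError(f"{path}: missing metabolite_id column")
    frame = frame.set_index("metabolite_id")
    names = frame.pop("name").astype(str) if "name" in frame.columns else None
    classes = None
    if "lipid_class" in frame.columns:
        classes = frame.pop("lipid_class").astype("string").astype(object)
    values = frame.astype(float)
    if values.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if (values.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative peak area")
    return MetaboliteTable(values=values, names=names, classes=classes)


def write_metabolite_table(table: MetaboliteTable, path: str | Path, header: str | None = None) -> None:
    out = table.values.reset_index()
    insert_at = 1
    if table.classes is not None:
        out.insert(insert_at, "lipid_class", table.classes.values)
    out.insert(insert_at, "name", table.names.values)
    _write(out, path, header=header, index=False)


def write_table(obj, path: str | Path, header: str | None = None) -> None:
    """Write any supported table type to tab-delimited text."""
    if isinstance(obj, MetaboliteTable):
        write_metabolite_table(obj, path, header)
    elif isinstance(obj, SampleSheet):
        write_sample_sheet(obj, path, header)
    elif isinstance(obj, pd.DataFrame):
        if isinstance(obj.index, pd.MultiIndex):
            write_site_table(obj, path, header)
        elif obj.index.name:
            _write(obj.reset_index(), path, header=header, index=False)
        else:
            _write(obj, path, header=header, index=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_text(path: Path) -> str:
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    return "\n".join(lines)


def _write(frame: pd.DataFrame, path: str | Path, header: str | None, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, na_rep=_NA_REP, float_format=_FLOAT_FMT)


def _check_nonnegative(table: pd.DataFrame, path: Path) -> None:
    with np.errstate(invalid="ignore"):
        if (table.to_numpy() < 0).any():
            raise FormatError(f"{path}: negative intensity")
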