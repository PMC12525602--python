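"""Data model and I/O for compound, docking-score, and assay tables.

The central container is :class:`DescriptorMatrix`: a compounds x descriptors
real matrix with an optional binary activity label per compound (1 = active,
0 = inactive) and a family tag per descriptor column (``rdkit``, ``drugtax``,
``fingerprint`` or ``other``).  Docking scores are binding energies in
kcal/mol (lower = stronger binding).  Concentrations are stored internally in
mol/L; readers accept a declared unit and convert on ingest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("rdkit", "drugtax", "fingerprint", "other")

#: multiplicative factors to mol/L
_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "mol/L": 1.0,
}


def to_molar(values, unit: str):
    """Convert concentration values in ``unit`` to mol/L."""
    try:
        factor = _UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; known: {sorted(_UNIT_TO_MOLAR)}"
        ) from None
    return np.asarray(values, dtype=float) * factor


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


@dataclass
class CompoundRecord:
    """A single compound: opaque id, optional structure, optional label."""

    compound_id: str
    smiles: str | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors matrix with labels and per-column family tags.

    Attributes
    ----------
    values : pandas.DataFrame
        Real matrix, index = compound ids (unique), columns = descriptor names
        (unique).  Row order is preserved across transformations unless an
        operation documents a sort.
    labels : pandas.Series or None
        Binary activity labels aligned to ``values.index``.
    families : dict
        Descriptor name -> family tag.  Missing names default to ``other``.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate compound ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate descriptor names: {dupes}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)
            bad = set(self.labels.dropna().unique()) - {0, 1}
            if bad:
                raise SchemaError(f"labels must be binary 0/1, got extra values {bad}")
            self.labels = self.labels.astype(int)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_compounds(self) -> int:
        return len(self.values.index)

    @property
    def n_descriptors(self) -> int:
        return len(self.values.columns)

    def family_of(self, name: str) -> str:
        return self.families.get(name, "other")

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.values.columns:
            counts[self.family_of(c)] = counts.get(self.family_of(c), 0) + 1
        return counts

    def subset_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise SchemaError(f"unknown descriptor columns: {missing}")
        return DescriptorMatrix(
            values=self.values.loc[:, list(names)].copy(),
            labels=None if self.labels is None else self.labels.copy(),
            families={n: self.family_of(n) for n in names},
        )

    def subset_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(
            values=self.values.loc[list(ids)].copy(),
            labels=None if self.labels is None else self.labels.loc[list(ids)].copy(),
            families=dict(self.families),
        )


@dataclass
class DockingScoreTable:
    """Per-compound docking scores for one or more protein targets.

    ``scores`` is indexed by compound id with one column per target; NaN marks
    an explicitly missing score.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise SchemaError("duplicate compound ids in docking table")
        # normalize the index name so tables round-trip through CSV unchanged
        self.scores = self.scores.rename_axis("compound_id")

    @property
    def targets(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


ASSAY_KINDS = ("dose_response", "kinetics", "quench", "sync_spectrum", "glucose_curve")


@dataclass
class AssayTable:
    """Long-format assay readout with a declared kind and per-column units.

    Concentrations must be non-negative, intensities/absorbances non-negative,
    temperatures in kelvin positive.  Units are recorded in ``units``
    (column name -> unit string) for provenance; conversion to internal units
    happens on read.
    """

    kind: str
    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ASSAY_KINDS:
            raise SchemaError(f"unknown assay kind {self.kind!r}; known: {ASSAY_KINDS}")
        for col in self.data.columns:
            low = col.lower()
            vals = self.data[col]
            if not np.issubdtype(vals.dtype, np.number):
                continue
            is_conc = (
                "conc" in low
                or low in ("s", "i", "q")
                or any(tok in low for tok in ("substrate", "inhibitor", "quencher"))
            )
            if is_conc and (vals < 0).any():
                raise SchemaError(f"negative concentrations in column {col!r}")
            if ("intensity" in low or "abs" in low) and (vals < 0).any():
                raise SchemaError(f"negative intensities/absorbances in column {col!r}")
            if "temp" in low and (vals <= 0).any():
                raise SchemaError(f"non-positive kelvin temperatures in column {col!r}")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV file, sniffing the delimiter from the header line."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_compound_table(
    path: str | Path,
    id_column: str = "compound_id",
    label_column: str | None = "label",
    family_map: Mapping[str, str] | None = None,
    require_labels: bool = False,
    impute: bool = True,
) -> DescriptorMatrix:
    """Read a delimited compound table into a :class:`DescriptorMatrix`.

    All columns other than the id and label columns are treated as
    descriptors.  Non-numeric descriptor cells and missing values are imputed
    by column median, with a logged count.

    Raises
    ------
    SchemaError
        On duplicate compound ids or a missing required label column.
    """
    df = _read_delimited(path)
    if id_column not in df.columns:
        raise SchemaError(f"id column {id_column!r} not in table")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate compound ids: {dupes}")

    labels = None
    if label_column is not None and label_column in df.columns:
        labels = pd.Series(df[label_column].values, index=ids.values, name="label")
    elif require_labels:
        raise SchemaError(f"label column {label_column!r} required but absent")

    desc_cols = [c for c in df.columns if c not in (id_column, label_column)]
    values = df[desc_cols].apply(pd.to_numeric, errors="coerce")
    values.index = ids.values
    n_bad = int(values.isna().sum().sum())
    if n_bad:
        if impute:
            logger.info("imputing %d non-numeric/missing descriptor cells by column median", n_bad)
            values = values.fillna(values.median())
        else:
            logger.warning("%d non-numeric/missing descriptor cells left as NaN", n_bad)

    families = dict(family_map) if family_map else {}
    return DescriptorMatrix(values=values, labels=labels, families=families)


def read_docking_scores(path: str | Path, id_column: str = "compound_id") -> DockingScoreTable:
    """Read a docking-score table: one row per compound, one column per target."""
    df = _read_delimited(path)
    if id_column not in df.columns:
        raise SchemaError(f"id column {id_column!r} not in table")
    df = df.set_index(id_column)
    df.index = df.index.astype(str)
    return DockingScoreTable(scores=df.apply(pd.to_numeric, errors="coerce"))


def read_assay_table(
    path: str | Path,
    kind: str,
    units: Mapping[str, str] | None = None,
    conc_columns: Sequence[str] = (),
) -> AssayTable:
    """Read an assay table, converting declared concentration columns to mol/L.

    ``units`` maps column name -> declared unit; columns listed in
    ``conc_columns`` whose unit is a concentration unit are converted.
    A JSON sidecar ``<path>.schema.json`` with ``{"units": {...}}`` is honored
    when ``units`` is not given.
    """
    path = Path(path)
    df = _read_delimited(path)
    if units is None:
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        if sidecar.exists():
            units = json.loads(sidecar.read_text()).get("units", {})
        else:
            units = {}
    units = dict(units)
    for col in conc_columns:
        unit = units.get(col)
        if unit and unit in _UNIT_TO_MOLAR:
            df[col] = to_molar(df[col].values, unit)
            units[col] = "mol/L"
    return AssayTable(kind=kind, data=df, units=units)


def write_table(obj, path: str | Path) -> None:
    """Write any table type to a delimited UTF-8 CSV with header row.

    Round-trip guarantee: reading the file back with the matching reader
    returns an equal object at the written precision (full ``repr``
    precision is used, so numeric round trips are exact).
    """
    path = Path(path)
    if isinstance(obj, DescriptorMatrix):
        df = obj.values.copy()
        if obj.labels is not None:
            df.insert(0, "label", obj.labels.values)
        df.insert(0, "compound_id", df.index)
        df.to_csv(path, index=False)
        if obj.families:
            sidecar = path.with_suffix(path.suffix + ".schema.json")
            sidecar.write_text(json.dumps({"families": obj.families}, indent=1))
    elif isinstance(obj, DockingScoreTable):
        df = obj.scores.copy()
        df.insert(0, "compound_id", df.index)
        df.to_csv(path, index=False)
    elif isinstance(obj, AssayTable):
        obj.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        sidecar.write_text(json.dumps({"kind": obj.kind, "units": obj.units}, indent=1))
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


class DescriptorToolkitError(RuntimeError):
    """Raised when descriptor computation is requested without the toolkit."""


def compute_descriptors(
    smiles_list: Iterable[str],
    families: Iterable[str] = ("rdkit",),
) -> DescriptorMatrix:
    """Compute descriptors from SMILES via the optional structure toolkit.

    Supported families: ``rdkit`` (physicochemical descriptors) and
    ``fingerprint`` (MACCS keys).  Invalid SMILES are reported and their rows
    dropped.  This adapter is optional: precomputed tables are the primary
    input path.

    Raises
    ------
    DescriptorToolkitError
        If RDKit is not installed; supply a precomputed descriptor table
        instead.
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Descriptors, MACCSkeys
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise DescriptorToolkitError(
            "RDKit is not available; supply a precomputed descriptor table "
            "via read_compound_table instead"
        ) from exc

    RDLogger.DisableLog("rdApp.*")
    families = set(families)
    unknown = families - {"rdkit", "fingerprint"}
    if unknown:
        raise ValueError(f"unsupported descriptor families: {sorted(unknown)}")

    rows: list[dict[str, float]] = []
    ids: list[str] = []
    fam_tags: dict[str, str] = {}
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("invalid SMILES %r: row dropped", smi)
            continue
        row: dict[str, float] = {}
        if "rdkit" in families:
            for name, fn in Descriptors.descList:
                try:
                    row[name] = float(fn(mol))
                except Exception:
                    row[name] = float("nan")
                fam_tags[name] = "rdkit"
        if "fingerprint" in families:
            fp = MACCSkeys.GenMACCSKeys(mol)
            for i in range(fp.GetNumBits()):
                key = f"MACCS_{i}"
                row[key] = float(fp.GetBit(i))
                fam_tags[key] = "fingerprint"
        rows.append(row)
        ids.append(smi)

    values = pd.DataFrame(rows, index=pd.Index(ids).astype(str))
    # duplicate SMILES would collide as ids; disambiguate deterministically
    if values.index.has_duplicates:
        values.index = [f"{s}#{i}" for i, s in enumerate(values.index)]
    return DescriptorMatrix(values=values, families=fam_tags)
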