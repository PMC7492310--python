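"""Readers/writers for descriptor tables, activity tables and model documents.

File conventions
----------------
Descriptor CSV   header ``Name,<desc1>,<desc2>,...``; UTF-8, comma
                 delimited, decimal point; one row per compound.
Activity CSV     header ``Name,IC50_uM`` (micromolar, converted on load)
                 or ``Name,pIC50``.
Model document   JSON object with keys ``descriptors`` (list of names),
                 ``coefficients`` (matching list of numbers),
                 ``intercept`` (number) and optional ``metadata``.

Missing or non-numeric cells are rejected at load, naming the offending
row and column; the pipeline has no imputation step.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from .core import (
    ActivitySeries,
    DescriptorTable,
    LinearModel,
    LoadError,
    pic50_from_ic50_uM,
)

Source = Union[str, Path, IO[str]]

__all__ = [
    "load_descriptor_table",
    "save_descriptor_table",
    "load_activity",
    "save_activity",
    "load_model",
    "save_model",
    "reference_model",
    "reference_y_randomization",
    "designed_compounds",
]


def _read_csv(source: Source) -> pd.DataFrame:
    try:
        # keep cells verbatim so "NA"/blank are rejected with their location
        return pd.read_csv(
            source,
            dtype=str,
            skipinitialspace=True,
            comment="#",
            keep_default_na=False,
            na_values=[],
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise LoadError(f"cannot parse CSV: {exc}") from exc


def _numeric_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Coerce every cell to float, naming the first offending cell."""
    out = {}
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals.fillna(np.nan))
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            cell = raw.loc[row, col]
            raise LoadError(
                f"non-numeric value {cell!r} for column {col!r} of compound {row!r}"
            )
        out[col] = vals
    return pd.DataFrame(out, index=raw.index)


def load_descriptor_table(source: Source) -> DescriptorTable:
    """Load a PaDEL-style descriptor CSV (first column = compound id)."""
    raw = _read_csv(source)
    if raw.shape[1] < 2:
        raise LoadError("descriptor CSV needs an id column plus >= 1 descriptor")
    raw = raw.set_index(raw.columns[0])
    if raw.index.isna().any() or raw.isna().any().any() or (raw == "").any().any():
        raise LoadError("descriptor CSV has missing cells (ragged or empty fields)")
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise LoadError(f"duplicate compound ids: {dupes}")
    return DescriptorTable(_numeric_frame(raw))


def save_descriptor_table(table: DescriptorTable, sink: Source) -> None:
    table.frame.to_csv(sink, index_label="Name")


def load_activity(source: Source) -> ActivitySeries:
    """Load an activity CSV; an ``IC50_uM`` column is converted to pIC50."""
    raw = _read_csv(source)
    cols = [c.strip() for c in raw.columns]
    raw.columns = cols
    if len(cols) != 2 or cols[0] != "Name":
        raise LoadError(f"activity CSV must have columns Name,IC50_uM or Name,pIC50; got {cols}")
    raw = raw.set_index("Name")
    frame = _numeric_frame(raw)
    if cols[1] == "IC50_uM":
        return ActivitySeries.from_ic50_uM(frame.index.tolist(), frame["IC50_uM"].to_numpy())
    if cols[1] == "pIC50":
        return ActivitySeries(frame["pIC50"])
    raise LoadError(f"unrecognised activity column {cols[1]!r}")


def save_activity(activity: ActivitySeries, sink: Source) -> None:
    activity.series.to_csv(sink, index_label="Name")


def load_model(source: Source) -> LinearModel:
    """Load a linear-model JSON document."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    if not isinstance(doc, dict):
        raise LoadError("model document must be a JSON object")
    for key in ("descriptors", "coefficients", "intercept"):
        if key not in doc:
            raise LoadError(f"model document missing {key!r}")
    names, coefs = doc["descriptors"], doc["coefficients"]
    if len(names) != len(coefs):
        raise LoadError(
            f"{len(coefs)} coefficients for {len(names)} descriptor names"
        )
    return LinearModel(
        descriptor_names=tuple(names),
        coefficients=tuple(coefs),
        intercept=doc["intercept"],
        metadata=doc.get("metadata", {}),
    )


def save_model(model: LinearModel, sink: Source) -> None:
    # json round-trips Python floats exactly (repr-based), so save->load
    # reproduces coefficients bit-identically
    if hasattr(sink, "write"):
        json.dump(model.to_dict(), sink, indent=2)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(model.to_dict(), fh, indent=2)
            fh.write("\n")


def _data(name: str):
    return resources.files("qsarkit.data").joinpath(name)


def reference_model() -> LinearModel:
    """The bundled five-descriptor cytotoxicity model for imidazol-5-ones.

    Published GFA-MLR equation linking pIC50 against the HCT116 cell
    line to the PaDEL descriptors nS, GATS5s, VR1_Dze, ETA_dBetaP, L3i.
    """
    with _data("eq2_model.json").open(encoding="utf-8") as fh:
        return load_model(fh)


def reference_y_randomization() -> pd.DataFrame:
    """Published Y-randomization records for the bundled reference model.

    One row per model (``original`` plus ten response-scrambled refits)
    with columns ``R``, ``R2``, ``Q2``.
    """
    with _data("y_randomization_reference.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh, index_col="model")


def designed_compounds() -> pd.DataFrame:
    """Predicted activities of the twelve designed imidazol-5-ones.

    The candidates (ids a..l) carry substituent annotations R1/R2/R3 and
    the published model predictions (pIC50 and the equivalent IC50 in
    micromolar); the row ``template`` is the parent compound they were
    derived from.  Their underlying descriptor rows are not distributed,
    so this table ships as a data fixture rather than being regenerated.
    """
    with _data("designed_compounds.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh, index_col="id")
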