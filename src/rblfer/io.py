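"""CSV readers/writers for residue tables and HX observation tables.

Canonical residue-table columns: ``residue_id``, ``K``, ``k_forward``,
``k_backward`` plus optional ``err_logK``, ``err_logk``, ``err_logkb``
and ``source``.  Tables may carry either K, or the two rates, or all
three; when all three are present the triad consistency K = k/k' is
checked (strict mode rejects, lenient mode warns).

HX tables: ``residue_id``, ``pH``, ``pulse_duration_s``, ``occupancy``
and optional ``err_occupancy``.  All files are UTF-8 CSV with a header.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import DomainError, HXObservation, ResidueExchangeRecord

__all__ = [
    "Dataset",
    "read_residue_table",
    "write_residue_table",
    "read_hx_table",
    "write_hx_table",
    "import_xlsx",
]

logger = logging.getLogger("rblfer")

ERR_COLUMNS = ("err_logK", "err_logk", "err_logkb")


@dataclass
class Dataset:
    """A named residue ensemble with free-form provenance metadata."""

    name: str
    records: list[ResidueExchangeRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.residue_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"duplicate residue_id values: {dupes}")


def _optional(row, col):
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_residue_table(path: str | Path, *, strict: bool = True,
                       triad_tol: float = 0.05, name: str | None = None) -> Dataset:
    """Read a residue-table CSV into a Dataset.

    If only the two rates are given, K is derived; if only K and one rate
    are given the table is rejected.  In strict mode a triad
    inconsistency beyond ``triad_tol`` log units raises, naming the
    residue; in lenient mode it is logged and K is kept as supplied.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "residue_id" not in df.columns:
        raise DomainError("missing required column(s): ['residue_id']")
    have_rates = {"k_forward", "k_backward"}.issubset(df.columns)
    have_K = "K" in df.columns
    if not have_K and not have_rates:
        raise DomainError(
            "missing required column(s): need 'K' and/or both "
            "'k_forward' and 'k_backward'"
        )
    if not have_rates:
        raise DomainError(
            "missing required column(s): ['k_forward', 'k_backward'] "
            "(a K-only table carries no rate information)"
        )

    records: list[ResidueExchangeRecord] = []
    for i, row in df.iterrows():
        rid = str(row["residue_id"])
        k_f, k_b = float(row["k_forward"]), float(row["k_backward"])
        for colname, value in (("k_forward", k_f), ("k_backward", k_b)):
            if not (value > 0) or not math.isfinite(value):
                raise DomainError(
                    f"row {i + 2}: non-positive {colname} = {value!r} "
                    f"(residue {rid!r})"
                )
        errs = {c: _optional(row, c) for c in ERR_COLUMNS}
        source = str(row["source"]) if "source" in df.columns and not pd.isna(row.get("source")) else ""
        if have_K and not pd.isna(row["K"]):
            K = float(row["K"])
            if not (K > 0):
                raise DomainError(f"row {i + 2}: non-positive K = {K!r} (residue {rid!r})")
            mismatch = abs(math.log10(K) - math.log10(k_f / k_b))
            if mismatch > triad_tol:
                msg = (f"residue {rid!r}: K = {K:g} inconsistent with k/k' = "
                       f"{k_f / k_b:g} (|log10 mismatch| = {mismatch:.3g} > {triad_tol:g})")
                if strict:
                    raise DomainError(msg)
                logger.warning("%s (lenient mode, keeping supplied K)", msg)
            rec = ResidueExchangeRecord(residue_id=rid, K=K, k_forward=k_f,
                                        k_backward=k_b, source=source,
                                        triad_tol=max(triad_tol, mismatch * (1 + 1e-9) + 1e-12),
                                        **errs)
        else:
            rec = ResidueExchangeRecord.from_rates(rid, k_f, k_b, source=source, **errs)
        records.append(rec)
    return Dataset(name=name or path.stem, records=records)


def write_residue_table(records: Sequence[ResidueExchangeRecord] | Dataset,
                        path: str | Path) -> None:
    """Write records to the canonical residue-table CSV (17 sig. digits)."""
    if isinstance(records, Dataset):
        records = records.records
    df = pd.DataFrame({
        "residue_id": [r.residue_id for r in records],
        "K": [r.K for r in records],
        "k_forward": [r.k_forward for r in records],
        "k_backward": [r.k_backward for r in records],
        "err_logK": [r.err_logK for r in records],
        "err_logk": [r.err_logk for r in records],
        "err_logkb": [r.err_logkb for r in records],
        "source": [r.source for r in records],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_hx_table(path: str | Path) -> list[HXObservation]:
    """Read an HX observation CSV."""
    df = pd.read_csv(path)
    required = ["residue_id", "pH", "pulse_duration_s", "occupancy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"missing required column(s): {missing}")
    return [
        HXObservation(
            residue_id=str(row["residue_id"]), pH=float(row["pH"]),
            pulse_duration=float(row["pulse_duration_s"]),
            occupancy=float(row["occupancy"]),
            err_occupancy=_optional(row, "err_occupancy"),
        )
        for _, row in df.iterrows()
    ]


def write_hx_table(observations: Sequence[HXObservation], path: str | Path) -> None:
    df = pd.DataFrame({
        "residue_id": [o.residue_id for o in observations],
        "pH": [o.pH for o in observations],
        "pulse_duration_s": [o.pulse_duration for o in observations],
        "occupancy": [o.occupancy for o in observations],
        "err_occupancy": [o.err_occupancy for o in observations],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def import_xlsx(path: str | Path, sheet: str | int = 0, *,
                out_csv: str | Path | None = None, strict: bool = False) -> Dataset:
    """Thin importer: first sheet of an XLSX with the canonical columns.

    Converts to the canonical CSV dialect (optionally written to
    ``out_csv``) and parses it with the standard reader, so the CSV path
    stays the single source of parsing truth.
    """
    import tempfile

    df = pd.read_excel(path, sheet_name=sheet)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
        return read_residue_table(out_csv, strict=strict, name=Path(path).stem)
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        df.to_csv(fh.name, index=False)
        tmp = fh.name
    try:
        return read_residue_table(tmp, strict=strict, name=Path(path).stem)
    finally:
        Path(tmp).unlink(missing_ok=True)
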