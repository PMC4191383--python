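"""Measurement-table and sequence I/O plus the calculation-trace report.

The package's tabular boundary is a long-form CSV with one row per
run x analyte x channel x replicate, produced upstream by chromatographic
peak integration (or by the built-in simulator).  All amounts are pmol
internally and in files; column names carry explicit unit suffixes.
"""
from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem import CANONICAL
from .quantify import QuantResult

__all__ = [
    "MEASUREMENT_COLUMNS",
    "SchemaError",
    "read_measurements",
    "write_measurements",
    "validate_measurements",
    "residue_counts",
    "format_report",
]

MEASUREMENT_COLUMNS = [
    "run_id", "session_id", "analyte", "channel", "peak_area", "level_pmol", "replicate",
]
CHANNELS = ("MS12", "MS13", "UV254")


class SchemaError(ValueError):
    """Measurement CSV violates the schema; message names row and column."""


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table against the schema.

    Checks: exact column set, known channels, non-negative areas, UV rows
    only for canonical nucleosides, and uniqueness of
    (run_id, analyte, channel, replicate).  Row numbers in error messages
    are 1-based data rows (header excluded).
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected columns: {extra}")
    bad = ~df["channel"].isin(CHANNELS)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise SchemaError(f"row {row + 1}, column 'channel': unknown channel {df['channel'].iloc[row]!r}")
    areas = pd.to_numeric(df["peak_area"], errors="coerce")
    bad = areas.isna() | (areas < 0)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise SchemaError(f"row {row + 1}, column 'peak_area': negative or non-numeric value")
    uv_bad = (df["channel"] == "UV254") & ~df["analyte"].isin(CANONICAL)
    if uv_bad.any():
        row = int(np.argmax(uv_bad.to_numpy()))
        raise SchemaError(
            f"row {row + 1}, column 'analyte': UV rows are only defined for canonical "
            f"nucleosides, got {df['analyte'].iloc[row]!r}"
        )
    dup = df.duplicated(subset=["run_id", "analyte", "channel", "replicate"], keep="first")
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise SchemaError(
            f"row {row + 1}: duplicate (run_id, analyte, channel, replicate) key "
            f"{tuple(df.loc[df.index[row], ['run_id', 'analyte', 'channel', 'replicate']])}"
        )
    out = df.copy()
    out["peak_area"] = areas
    out["level_pmol"] = pd.to_numeric(out["level_pmol"], errors="coerce")
    out["replicate"] = out["replicate"].astype(int)
    return out[MEASUREMENT_COLUMNS]


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a measurement-table CSV (UTF-8, decimal point)."""
    df = pd.read_csv(path, dtype={"run_id": str, "session_id": str, "analyte": str, "channel": str})
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement table at full float precision (lossless round-trip)."""
    validate_measurements(df).to_csv(path, index=False, float_format="%.17g")


def residue_counts(fasta_path) -> tuple[dict[str, int], str]:
    """Residue counts of the (single) sequence in a FASTA file.

    RNA or DNA alphabets are accepted; T is normalized to U and counting
    is on the given strand only.  Returns ({A,C,G,U} counts, sequence id).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one sequence, found {len(records)}")
    seq = str(records[0].seq).upper().replace("T", "U")
    unknown = set(seq) - set("ACGU")
    if unknown:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(unknown)}")
    return {b: seq.count(b) for b in "ACGU"}, records[0].id


def format_report(result: QuantResult, sample_name: str = "sample") -> str:
    """Human-readable calculation trace of one absolute quantification:
    isotopomer ratio -> pmol -> UV-based RNA amount -> yields."""
    buf = _io.StringIO()
    w = buf.write
    w(f"Absolute quantification report: {sample_name}\n")
    w("=" * (34 + len(sample_name)) + "\n\n")
    if result.rna_pmol is not None:
        w("Injected RNA (UV-based, internal-standard-corrected):\n")
        w(f"  RNA amount = {result.rna_pmol:.3f} pmol")
        if result.rna_se is not None:
            w(f"  (se {result.rna_se:.3f})")
        w("\n\n")
    w("Modified nucleosides (amount = NIF / rRFN):\n")
    for nuc, pmol in sorted(result.amounts.items()):
        se = result.amount_se.get(nuc)
        w(f"  {nuc:>6s}: {pmol:.4f} pmol")
        if se is not None and np.isfinite(se):
            w(f" (se {se:.4f})")
        y = result.yields.get(nuc)
        if y is not None:
            w(f" | per molecule {y.per_molecule:.4f}")
            if y.occupancy is not None:
                w(f" | occupancy {100 * y.occupancy:.1f}%")
            if y.pct_of_parent is not None:
                w(f" | {y.pct_of_parent:.2f}% of parent")
            if y.mol_pct is not None:
                w(f" | {y.mol_pct:.3f} mol%")
        f = result.flags.get(nuc, {})
        marks = [k for k in ("below_loq", "above_valid_range", "background") if f.get(k)]
        if marks:
            w("  [" + ", ".join(marks) + "]")
        w("\n")
    return buf.getvalue()
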