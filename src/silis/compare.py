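"""Relative quantification: doubly normalized levels and fold changes.

For sample comparison each modified nucleoside's MS signal is first
divided by the signal of its 13C isotopomer (cancelling instrumental and
sample parameters) and then by the UV-area sum of the four canonical
nucleosides (cancelling differences in the amount of RNA injected).  The
ratio of those normalized levels between two samples is the fold change
in the modification level.  When absolute calibration is available the
per-molecule levels are used to flag fold changes that are mere ratios of
background noise.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import RFTable
from .chem import CANONICAL
from .quantify import rna_amount_from_uv
from .simulate import SILIS_REF_RUN

__all__ = [
    "normalized_level",
    "fold_change",
    "flag_background",
    "compare_tables",
    "DEFAULT_BACKGROUND_THRESHOLD",
]

#: Below this per-molecule level (mol modification / mol RNA) in every
#: compared sample, a nucleoside is treated as background.
DEFAULT_BACKGROUND_THRESHOLD = 0.01


def normalized_level(signal_12c: float, signal_13c: float, uv_canonical_sum: float) -> float:
    """Loading- and drift-invariant modification level:
    (12C / 13C) / sum(UV areas of C, U, G, A)."""
    if signal_13c <= 0:
        raise ValueError("13C internal-standard signal must be > 0")
    if uv_canonical_sum <= 0:
        raise ValueError("canonical UV sum must be > 0")
    return (signal_12c / signal_13c) / uv_canonical_sum


def fold_change(level_1: float, level_2: float) -> float:
    """Ratio of normalized levels, sample 1 over sample 2.

    Values below 1 mean the modification is higher in sample 2.  A zero
    reference level makes the ratio undefined and is reported as NaN (to
    be flagged), never as infinity.
    """
    if level_2 < 0 or level_1 < 0:
        raise ValueError("levels must be >= 0")
    if level_2 == 0:
        return float("nan")
    return level_1 / level_2


def flag_background(abs_levels: dict[str, list[float]], threshold: float = DEFAULT_BACKGROUND_THRESHOLD) -> dict[str, bool]:
    """Background = per-molecule level below ``threshold`` in ALL samples.

    Fold changes of background nucleosides are kept but marked
    not-interpretable: a ratio of two noise levels is an artifact.
    """
    return {
        nuc: bool(len(levels) > 0 and all(v < threshold for v in levels))
        for nuc, levels in abs_levels.items()
    }


def _sample_levels(df: pd.DataFrame, silis_ref_run: str) -> tuple[dict[str, float], float]:
    """Median normalized level per modified nucleoside, plus the canonical UV sum.

    The internal standard's own UV contribution is subtracted per canonical
    when a standard-only reference injection is present — the sum must scale
    with the injected sample for levels to be loading-invariant; without a
    reference run the raw sum is used (exact for equal loadings).
    """
    runs = [r for r in df["run_id"].unique() if r != silis_ref_run]
    sub = df[df["run_id"].isin(runs)]
    ref = df[df["run_id"] == silis_ref_run]
    uv_sum = 0.0
    for nuc in CANONICAL:
        uv = sub[(sub["analyte"] == nuc) & (sub["channel"] == "UV254")]
        if uv.empty:
            raise ValueError(f"missing UV rows for canonical nucleoside {nuc!r}")
        area = float(uv["peak_area"].median())
        ref_uv = ref[(ref["analyte"] == nuc) & (ref["channel"] == "UV254")]
        if not ref_uv.empty:
            area = max(area - float(ref_uv["peak_area"].median()), 0.0)
        uv_sum += area
    if uv_sum <= 0:
        raise ValueError("canonical UV sum is zero after internal-standard correction")
    levels = {}
    for nuc in sorted(sub.loc[sub["channel"] == "MS12", "analyte"].unique()):
        if nuc in CANONICAL:
            continue
        wide = sub[(sub["analyte"] == nuc) & sub["channel"].isin(["MS12", "MS13"])].pivot_table(
            index=["run_id", "replicate"], columns="channel", values="peak_area", aggfunc="first"
        )
        if "MS13" not in wide.columns or wide["MS13"].isna().any():
            raise ValueError(f"{nuc}: MS13 internal-standard rows missing")
        ratios = wide["MS12"] / wide["MS13"]
        levels[nuc] = normalized_level(float(ratios.median()), 1.0, uv_sum)
    return levels, uv_sum


def _per_molecule(df, rf_table, sequence_counts, reference, silis_ref_run):
    runs = [r for r in df["run_id"].unique() if r != silis_ref_run]
    sub = df[df["run_id"].isin(runs)]
    total = float(sub[(sub["analyte"] == reference) & (sub["channel"] == "UV254")]["peak_area"].median())
    silis_rows = df[(df["run_id"] == silis_ref_run) & (df["analyte"] == reference) & (df["channel"] == "UV254")]
    silis = float(silis_rows["peak_area"].median()) if not silis_rows.empty else 0.0
    rna = rna_amount_from_uv(total, silis, rf_table.uvf[reference], sequence_counts[reference])
    out = {}
    for nuc in sorted(sub.loc[sub["channel"] == "MS12", "analyte"].unique()):
        if nuc in CANONICAL or nuc not in rf_table.rrfn:
            continue
        wide = sub[(sub["analyte"] == nuc) & sub["channel"].isin(["MS12", "MS13"])].pivot_table(
            index=["run_id", "replicate"], columns="channel", values="peak_area", aggfunc="first"
        )
        nif = float((wide["MS12"] / wide["MS13"]).median())
        out[nuc] = (nif / rf_table.rrfn[nuc].slope) / rna
    return out


def compare_tables(
    tables: list[pd.DataFrame],
    rf_table: RFTable | None = None,
    sequence_counts: dict[str, int] | None = None,
    reference_sample: int | None = None,
    reference_nucleoside: str = "G",
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    silis_ref_run: str = SILIS_REF_RUN,
) -> pd.DataFrame:
    """Fold-change table for two or more samples.

    Fold changes are reported against the 1-based ``reference_sample``
    (the denominator); by default the second sample for a pair — so the
    pairwise fold change is level_1 / level_2 and values < 1 mean higher
    in sample 2 — and the first sample otherwise.  With an RFTable and
    residue counts, absolute
    per-molecule levels are added and background nucleosides flagged.
    Output columns mirror the pairwise report: nucleoside, level_i,
    fold_change_i (sample i vs reference), abs_i, background_flag.
    """
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    if reference_sample is None:
        reference_sample = 2 if len(tables) == 2 else 1
    if not 1 <= reference_sample <= len(tables):
        raise ValueError("reference_sample out of range")
    levels = [_sample_levels(t, silis_ref_run)[0] for t in tables]
    nucs = sorted(set().union(*levels))

    abs_levels: dict[str, list[float]] = {}
    backgrounds: dict[str, bool] = {}
    if rf_table is not None and sequence_counts is not None:
        per_mol = [
            _per_molecule(t, rf_table, sequence_counts, reference_nucleoside, silis_ref_run)
            for t in tables
        ]
        abs_levels = {nuc: [pm.get(nuc, 0.0) for pm in per_mol] for nuc in nucs}
        backgrounds = flag_background(abs_levels, background_threshold)

    ref = reference_sample - 1
    rows = []
    for nuc in nucs:
        row = {"nucleoside": nuc}
        for i, lv in enumerate(levels, start=1):
            row[f"level_{i}"] = lv.get(nuc, 0.0)
        ref_level = levels[ref].get(nuc, 0.0)
        for i, lv in enumerate(levels, start=1):
            if i - 1 == ref:
                continue
            row[f"fold_change_{i}" if len(tables) > 2 else "fold_change"] = fold_change(
                lv.get(nuc, 0.0), ref_level
            )
        for i in range(1, len(tables) + 1):
            if abs_levels:
                row[f"abs_{i}"] = abs_levels[nuc][i - 1]
        row["background_flag"] = backgrounds.get(nuc, False)
        row["undefined_flag"] = ref_level == 0.0
        rows.append(row)
    return pd.DataFrame(rows)
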