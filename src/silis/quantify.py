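"""Absolute quantification from isotopomer pairs and the UV channel.

amount (pmol) = NIF / rRFN = signal(12C) / (rRFN * signal(13C internal
standard)); the amount of injected RNA comes from the UV area of a
canonical reference nucleoside (guanosine by default) after subtracting
the internal standard's UV contribution; the two combine into
modification yields (site occupancy, % of parent, mol%) and enzymatic
turnover efficiencies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import RFTable, compute_nif
from .chem import CANONICAL
from .simulate import SILIS_REF_RUN

__all__ = [
    "QuantResult",
    "YieldResult",
    "MissingCalibrationError",
    "absolute_amount",
    "rna_amount_from_uv",
    "modification_yield",
    "spike_check",
    "quantify_table",
]


class MissingCalibrationError(KeyError):
    """Quantification requested for nucleosides without an rRFN."""

    def __init__(self, nucleosides):
        self.nucleosides = sorted(nucleosides)
        super().__init__(
            "no external calibration (rRFN) available for: " + ", ".join(self.nucleosides)
        )


def absolute_amount(signal_12c, signal_13c, rrfn: float) -> float | tuple[float, float]:
    """Eq.-of-the-method amount: NIF / rRFN, in pmol.

    Scalars return a pmol value; arrays of replicate signals return
    (mean pmol, standard error over replicates).
    """
    if rrfn <= 0:
        raise ValueError("rrfn must be > 0")
    s12 = np.asarray(signal_12c, dtype=float)
    s13 = np.asarray(signal_13c, dtype=float)
    if s12.ndim == 0:
        return compute_nif(float(s12), float(s13)) / rrfn
    if np.any(s13 <= 0):
        raise ValueError("13C internal-standard signal must be > 0 (SIL-IS missing from run?)")
    amounts = (s12 / s13) / rrfn
    se = float(np.std(amounts, ddof=1) / np.sqrt(len(amounts))) if len(amounts) > 1 else float("nan")
    return float(amounts.mean()), se


def rna_amount_from_uv(
    uv_area_total: float, uv_area_silis: float, uvf: float, n_residues: int
) -> float:
    """Injected RNA amount (pmol molecules) from the UV area of one
    canonical reference nucleoside.

    The internal standard contributes to the UV peak and is subtracted
    first; the corrected area over UVF gives pmol of the canonical, which
    over its residue count per molecule gives pmol of RNA.
    """
    if uv_area_silis < 0:
        raise ValueError("uv_area_silis must be >= 0")
    if uv_area_total < uv_area_silis:
        raise ValueError(
            "total UV area smaller than the internal-standard area "
            "(overspiked SIL-IS or integration fault)"
        )
    if uvf <= 0:
        raise ValueError("uvf must be > 0")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return (uv_area_total - uv_area_silis) / (uvf * n_residues)


@dataclass
class YieldResult:
    """Modification yield of one nucleoside in one RNA sample."""

    per_molecule: float               # mol modification per mol RNA
    occupancy: float | None = None    # per_molecule / site count
    pct_of_parent: float | None = None  # 100 * mod / (rna * parent residues)
    mol_pct: float | None = None      # 100 * per_molecule / total residues


def modification_yield(
    mod_pmol: float,
    rna_pmol: float,
    sites: int | None = None,
    parent_count: int | None = None,
    total_residues: int | None = None,
) -> YieldResult:
    """Express an absolute modification amount as a yield.

    per_molecule = mod/rna is always computed; occupancy divides by the
    number of candidate sites; pct_of_parent normalizes to the parent
    canonical's residue count; mol% normalizes to the full sequence length
    (and therefore requires the sequence).
    """
    if rna_pmol <= 0:
        raise ValueError("rna_pmol must be > 0")
    if mod_pmol < 0:
        raise ValueError("mod_pmol must be >= 0")
    per_molecule = mod_pmol / rna_pmol
    occ = None
    if sites is not None:
        if sites < 1:
            raise ValueError("sites must be >= 1")
        occ = per_molecule / sites
    pct_parent = None
    if parent_count is not None:
        if parent_count < 1:
            raise ValueError("parent_count must be >= 1")
        pct_parent = 100.0 * mod_pmol / (rna_pmol * parent_count)
    mol_pct = None
    if total_residues is not None:
        if total_residues < 1:
            raise ValueError("total_residues must be >= 1")
        mol_pct = 100.0 * per_molecule / total_residues
    return YieldResult(per_molecule, occ, pct_parent, mol_pct)


@dataclass
class QuantResult:
    """Absolute quantification of one sample."""

    amounts: dict[str, float]                       # pmol
    amount_se: dict[str, float] = field(default_factory=dict)
    rna_pmol: float | None = None
    rna_se: float | None = None
    yields: dict[str, YieldResult] = field(default_factory=dict)
    flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nuc, pmol in sorted(self.amounts.items()):
            y = self.yields.get(nuc)
            f = self.flags.get(nuc, {})
            rows.append({
                "nucleoside": nuc,
                "amount_pmol": pmol,
                "amount_se_pmol": self.amount_se.get(nuc, np.nan),
                "per_molecule": y.per_molecule if y else np.nan,
                "occupancy": (y.occupancy if y and y.occupancy is not None else np.nan),
                "pct_of_parent": (y.pct_of_parent if y and y.pct_of_parent is not None else np.nan),
                "mol_pct": (y.mol_pct if y and y.mol_pct is not None else np.nan),
                "below_loq": f.get("below_loq", False),
                "above_valid_range": f.get("above_valid_range", False),
                "background": f.get("background", False),
                "rna_pmol": self.rna_pmol if self.rna_pmol is not None else np.nan,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def spike_check(
    sample_result: QuantResult,
    spiked_result: QuantResult,
    spike_pmol: float,
    nucleoside: str,
    tolerance: float = 0.05,
) -> tuple[float, bool]:
    """Recovery of a known spike: (spiked - unspiked) / spike.

    Returns (recovery fraction, pass flag); the check passes when the
    recovery is within ``tolerance`` of 1.
    """
    if spike_pmol <= 0:
        raise ValueError("spike_pmol must be > 0")
    for res in (sample_result, spiked_result):
        if nucleoside not in res.amounts:
            raise KeyError(f"{nucleoside!r} not quantified in both results")
    recovery = (spiked_result.amounts[nucleoside] - sample_result.amounts[nucleoside]) / spike_pmol
    return recovery, abs(recovery - 1.0) <= tolerance


def _uv_area(df: pd.DataFrame, run_ids, nucleoside: str) -> float:
    sub = df[
        df["run_id"].isin(run_ids)
        & (df["analyte"] == nucleoside)
        & (df["channel"] == "UV254")
    ]
    if sub.empty:
        raise ValueError(f"no UV rows for {nucleoside!r}")
    return float(sub["peak_area"].median())


def quantify_table(
    df: pd.DataFrame,
    rf_table: RFTable,
    sequence_counts: dict[str, int] | None = None,
    sites: dict[str, int] | None = None,
    reference: str = "G",
    silis_ref_run: str = SILIS_REF_RUN,
    registry=None,
) -> QuantResult:
    """Quantify one sample measurement table end to end.

    Every analyte with isotopomer-pair MS rows is converted to pmol via
    its rRFN; nucleosides lacking an rRFN raise MissingCalibrationError
    listing them.  With ``sequence_counts`` (residue counts of the RNA,
    e.g. from a FASTA) the injected RNA amount is determined from the UV
    area of the ``reference`` canonical (internal-standard area from the
    ``silis_ref_run`` injection subtracted, scaled by replicate count 1)
    and yields are derived.  ``reference="mean"`` averages the RNA
    estimate over all four canonicals.
    """
    sample_runs = [r for r in df["run_id"].unique() if r != silis_ref_run]
    ms = df[df["run_id"].isin(sample_runs)]
    analytes = sorted(ms.loc[ms["channel"] == "MS12", "analyte"].unique())
    analytes = [a for a in analytes if a not in CANONICAL]
    missing = [a for a in analytes if a not in rf_table.rrfn]
    if missing:
        raise MissingCalibrationError(missing)

    amounts, ses, flags = {}, {}, {}
    for nuc in analytes:
        sub = ms[(ms["analyte"] == nuc) & ms["channel"].isin(["MS12", "MS13"])]
        wide = sub.pivot_table(
            index=["run_id", "replicate"], columns="channel", values="peak_area", aggfunc="first"
        )
        if "MS13" not in wide.columns or wide["MS13"].isna().any():
            raise ValueError(f"{nuc}: MS13 internal-standard rows missing")
        value = absolute_amount(
            wide["MS12"].to_numpy(), wide["MS13"].to_numpy(), rf_table.rrfn[nuc].slope
        )
        amount, se = value if isinstance(value, tuple) else (value, float("nan"))
        amounts[nuc], ses[nuc] = amount, se
        lo, hi = rf_table.valid_range.get(nuc, (np.nan, np.nan))
        flags[nuc] = {
            "below_loq": bool(np.isfinite(lo) and amount < lo),
            "above_valid_range": bool(np.isfinite(hi) and amount > hi),
            "background": False,
        }

    result = QuantResult(amounts=amounts, amount_se=ses, flags=flags)
    if sequence_counts is None:
        return result

    refs = list(CANONICAL) if reference == "mean" else [reference]
    estimates = []
    for ref in refs:
        if ref not in rf_table.uvf:
            raise ValueError(f"no UVF for reference nucleoside {ref!r}")
        n_res = sequence_counts.get(ref, 0)
        if n_res < 1:
            raise ValueError(f"sequence contains no {ref!r} residues")
        total = _uv_area(df, sample_runs, ref)
        silis = (
            _uv_area(df, [silis_ref_run], ref)
            if (df["run_id"] == silis_ref_run).any()
            else 0.0
        )
        estimates.append(rna_amount_from_uv(total, silis, rf_table.uvf[ref], n_res))
    result.rna_pmol = float(np.mean(estimates))
    result.rna_se = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates))) if len(estimates) > 1 else None

    total_residues = int(sum(sequence_counts.values()))
    for nuc in analytes:
        parent = registry[nuc].parent if registry is not None and nuc in registry else None
        parent_count = sequence_counts.get(parent) if parent else None
        result.yields[nuc] = modification_yield(
            amounts[nuc],
            result.rna_pmol,
            sites=(sites or {}).get(nuc),
            parent_count=parent_count,
            total_residues=total_residues,
        )
    return result
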