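"""Calibration: linear dynamic range, LOD/LOQ, isotope-normalized response
factors (rRFN), UV response factors (UVF) and cross-session stability.

The central quantity is the nucleoside-isotope factor (NIF), the ratio of
the 12C analyte signal to its co-measured 13C internal-standard signal.
Because both isotopomers are suppressed and drift identically, the NIF is
proportional to the injected amount far beyond where the raw signal
saturates; its slope versus amount is the relative response factor rRFN
(pmol^-1) that converts a measured NIF into pmol.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem import CANONICAL

__all__ = [
    "CalibrationModel",
    "RFTable",
    "RrfnFit",
    "LinearRangeError",
    "compute_nif",
    "nif_by_level",
    "fit_linear_range",
    "estimate_lod_loq",
    "fit_rrfn",
    "fit_uvf",
    "session_stability",
    "calibrate_table",
    "rrfn_by_session",
]

DEFAULT_TOL_MID = 0.15   # back-calculated accuracy, interior levels
DEFAULT_TOL_EDGE = 0.20  # back-calculated accuracy, window edges


class LinearRangeError(ValueError):
    """No acceptable linear window; carries the best window found."""

    def __init__(self, msg, best_window=None):
        super().__init__(msg)
        self.best_window = best_window


@dataclass
class CalibrationModel:
    """One fitted calibration curve on its linear window."""

    nucleoside: str
    channel: str              # "MS12", "NIF" or "UV"
    slope: float              # signal (or NIF) per pmol
    intercept: float
    r2: float
    linear_lo: float          # pmol
    linear_hi: float          # pmol
    lod: float = float("nan")  # pmol
    loq: float = float("nan")  # pmol

    def __post_init__(self):
        if not self.linear_lo < self.linear_hi:
            raise ValueError("linear_lo must be < linear_hi")
        if np.isfinite(self.lod) and np.isfinite(self.loq) and self.lod > self.loq:
            raise ValueError("lod must be <= loq")

    @property
    def decades(self) -> float:
        """Span of the linear window in orders of magnitude."""
        return float(np.log10(self.linear_hi / self.linear_lo))


@dataclass
class RrfnFit:
    slope: float  # rRFN, pmol^-1
    r2: float
    se: float
    degenerate: bool = False  # all-zero NIFs: slope 0, r2 undefined-as-0

    def __iter__(self):  # allow tuple unpacking (rrfn, r2, se)
        return iter((self.slope, self.r2, self.se))


def compute_nif(signal_12c: float, signal_13c: float) -> float:
    """Nucleoside-isotope factor: 12C signal over 13C internal-standard signal."""
    if signal_13c <= 0:
        raise ValueError("13C internal-standard signal must be > 0 (SIL-IS missing from run?)")
    return signal_12c / signal_13c


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    resid = y - np.asarray(yhat, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def _aggregate_median(levels, responses):
    df = pd.DataFrame({"level": np.asarray(levels, float), "y": np.asarray(responses, float)})
    agg = df.groupby("level", sort=True)["y"].median()
    return agg.index.to_numpy(), agg.to_numpy()


def _wls(x, y, weights, through_origin):
    X = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.WLS(y, X, weights=weights).fit()
    if through_origin:
        return 0.0, float(res.params[0]), res
    return float(res.params[0]), float(res.params[1]), res


def fit_linear_range(
    levels,
    responses,
    tol_mid: float = DEFAULT_TOL_MID,
    tol_edge: float = DEFAULT_TOL_EDGE,
    through_origin: bool = False,
    nucleoside: str = "",
    channel: str = "MS12",
    min_levels: int = 4,
) -> CalibrationModel:
    """Find the longest contiguous run of calibration levels that is linear.

    Replicates are aggregated by median per level; blanks (level 0) are
    ignored here.  For every candidate window a 1/x-weighted least-squares
    line is fitted in linear space and each level is back-calculated
    through it; the window is accepted when interior levels are accurate
    to ±tol_mid and the terminal levels to ±tol_edge.  The longest
    accepted window wins, ties broken toward higher R².
    """
    x_all, y_all = _aggregate_median(levels, responses)
    pos = x_all > 0
    x_all, y_all = x_all[pos], y_all[pos]
    if len(x_all) < 5:
        raise ValueError("need >= 5 distinct positive levels")

    best = None         # (length, r2, model)
    best_failed = None  # best window even if tolerance not met, for the error
    n = len(x_all)
    for i in range(n):
        for j in range(i + min_levels - 1, n):
            x, y = x_all[i : j + 1], y_all[i : j + 1]
            a, b, _ = _wls(x, y, 1.0 / x, through_origin)
            if b <= 0:
                continue
            back = (y - a) / b
            rel = np.abs(back / x - 1.0)
            tol = np.full(len(x), tol_mid)
            tol[0] = tol[-1] = tol_edge
            ok = bool(np.all(rel <= tol))
            r2 = _r2(y, a + b * x)
            cand = (j - i + 1, r2, CalibrationModel(nucleoside, channel, b, a, r2, x[0], x[-1]))
            if ok:
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
            frac_ok = float(np.mean(rel <= tol))
            key = (frac_ok * (j - i + 1), r2)
            if best_failed is None or key > best_failed[0]:
                best_failed = (key, cand[2])
    if best is None:
        raise LinearRangeError(
            f"no window of >= {min_levels} levels meets ±{tol_mid:.0%}/{tol_edge:.0%} "
            "back-calculated accuracy",
            best_window=None if best_failed is None else best_failed[1],
        )
    return best[2]


def estimate_lod_loq(blank_signals, slope: float) -> tuple[float, float]:
    """LOD = 3·sd(blanks)/slope, LOQ = 10·sd(blanks)/slope (pmol)."""
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 3:
        raise ValueError("need >= 3 blank measurements")
    if slope <= 0:
        raise ValueError("slope must be > 0")
    sd = float(np.std(blanks, ddof=1))
    if sd == 0:
        warnings.warn("zero blank variance; LOD/LOQ reported as 0", stacklevel=2)
        return 0.0, 0.0
    return 3.0 * sd / slope, 10.0 * sd / slope


def fit_rrfn(amounts, nifs) -> RrfnFit:
    """Relative response factor: 1/x-weighted through-origin slope of NIF
    versus injected amount.  R² is computed on the fitted points."""
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(nifs, dtype=float)
    if np.any(y < 0):
        raise ValueError("NIF values must be >= 0")
    if np.any(x <= 0):
        raise ValueError("amounts must be > 0")
    if len(x) < 2:
        raise ValueError("need >= 2 points")
    if np.all(y == 0):
        return RrfnFit(slope=0.0, r2=0.0, se=0.0, degenerate=True)
    _, b, res = _wls(x, y, 1.0 / x, through_origin=True)
    se = float(res.bse[0])
    return RrfnFit(slope=b, r2=_r2(y, b * x), se=se)


def fit_uvf(amounts, uv_areas, nucleoside: str) -> float:
    """UV response factor (area per pmol): through-origin OLS slope.

    Defined only for the four canonical nucleosides — the operational form
    of the 254 nm extinction coefficient.
    """
    if nucleoside not in CANONICAL:
        raise ValueError(f"UVF is defined only for canonical nucleosides, not {nucleoside!r}")
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(uv_areas, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 points")
    return float(np.sum(x * y) / np.sum(x * x))


def session_stability(rrfn_by_session_map) -> float:
    """% RSD (sample sd over mean) of per-session response-factor values."""
    values = np.asarray(list(rrfn_by_session_map.values())
                        if hasattr(rrfn_by_session_map, "values") else rrfn_by_session_map,
                        dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 sessions")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean response factor is 0; RSD undefined")
    return float(100.0 * np.std(values, ddof=1) / mean)


# ---------------------------------------------------------------------------
# Table-level drivers

def _pivot_ms(df: pd.DataFrame, nucleoside: str) -> pd.DataFrame:
    sub = df[(df["analyte"] == nucleoside) & df["channel"].isin(["MS12", "MS13"])]
    wide = sub.pivot_table(
        index=["session_id", "run_id", "level_pmol", "replicate"],
        columns="channel", values="peak_area", aggfunc="first",
    ).reset_index()
    if "MS13" not in wide or wide["MS13"].isna().any():
        raise ValueError(f"{nucleoside}: MS13 internal-standard rows missing")
    return wide


def _blank_corrected(wide: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-session median blank 12C area before forming NIFs.

    The additive integration baseline shifts the tiny 12C signals near the
    LOD but is negligible on the large 13C internal-standard signal; blank
    subtraction is what makes NIF(0) = 0 hold in practice, so the
    through-origin NIF fit stays valid down to the noise floor.
    """
    blanks = (
        wide[wide["level_pmol"] == 0]
        .groupby("session_id")["MS12"]
        .median()
        .rename("blank12")
    )
    out = wide.merge(blanks, on="session_id", how="left")
    out["blank12"] = out["blank12"].fillna(0.0)
    out["ms12_corr"] = (out["MS12"] - out["blank12"]).clip(lower=0.0)
    return out


def nif_by_level(df: pd.DataFrame, nucleoside: str) -> pd.DataFrame:
    """Per-injection blank-corrected NIFs (positive levels only)."""
    wide = _blank_corrected(_pivot_ms(df, nucleoside))
    wide = wide[wide["level_pmol"] > 0].copy()
    wide["nif"] = wide["ms12_corr"] / wide["MS13"]
    return wide[["session_id", "level_pmol", "replicate", "nif"]]


def _median_nif_per_level(wide: pd.DataFrame):
    agg = wide.groupby("level_pmol", sort=True)["nif"].median()
    return agg.index.to_numpy(), agg.to_numpy()


def rrfn_by_session(
    df: pd.DataFrame, nucleoside: str, window: tuple[float, float] | None = None
) -> dict[str, RrfnFit]:
    """Fit one rRFN per session, restricted to the given amount window."""
    out = {}
    for session, sub in nif_by_level(df, nucleoside).groupby("session_id"):
        x, y = _median_nif_per_level(sub)
        if window is not None:
            keep = (x >= window[0]) & (x <= window[1])
            x, y = x[keep], y[keep]
        out[str(session)] = fit_rrfn(x, y)
    return out


@dataclass
class RFTable:
    """Fitted response factors: rRFN per modified nucleoside (with R², SE,
    validity window and cross-session RSD) and UVF per canonical."""

    rrfn: dict[str, RrfnFit]
    uvf: dict[str, float]
    valid_range: dict[str, tuple[float, float]]
    session_rsd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for nuc, fit in sorted(self.rrfn.items()):
            lo, hi = self.valid_range.get(nuc, (np.nan, np.nan))
            rows.append({
                "nucleoside": nuc,
                "rrfn_pmol_inv": fit.slope,
                "r2": fit.r2,
                "se": fit.se,
                "valid_lo_pmol": lo,
                "valid_hi_pmol": hi,
                "session_rsd_pct": self.session_rsd.get(nuc, np.nan),
            })
        for nuc, uvf in sorted(self.uvf.items()):
            rows.append({
                "nucleoside": f"UV:{nuc}",
                "rrfn_pmol_inv": uvf,
                "r2": np.nan, "se": np.nan,
                "valid_lo_pmol": np.nan, "valid_hi_pmol": np.nan,
                "session_rsd_pct": np.nan,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RFTable":
        df = pd.read_csv(path)
        rrfn, uvf, valid, rsd = {}, {}, {}, {}
        for _, row in df.iterrows():
            name = row["nucleoside"]
            if isinstance(name, str) and name.startswith("UV:"):
                uvf[name[3:]] = float(row["rrfn_pmol_inv"])
            else:
                rrfn[name] = RrfnFit(float(row["rrfn_pmol_inv"]), float(row["r2"]), float(row["se"]))
                valid[name] = (float(row["valid_lo_pmol"]), float(row["valid_hi_pmol"]))
                rsd[name] = float(row["session_rsd_pct"])
        return cls(rrfn=rrfn, uvf=uvf, valid_range=valid, session_rsd=rsd)


def calibrate_table(
    df: pd.DataFrame,
    tol_mid: float = DEFAULT_TOL_MID,
    tol_edge: float = DEFAULT_TOL_EDGE,
) -> tuple[RFTable, dict[str, dict[str, CalibrationModel]]]:
    """Full calibration of a measurement table.

    For every nucleoside with isotopomer-pair rows: LOD/LOQ from the blank
    12C injections, the raw-signal and NIF linear windows, the rRFN fitted
    within the NIF window, and (when several sessions are present) the
    cross-session rRFN RSD.  Canonical nucleosides with UV rows get a UVF
    from the SIL-IS-corrected UV areas.

    Returns the RFTable plus the per-nucleoside calibration models
    ({nucleoside: {"MS12": ..., "NIF": ...}}).
    """
    rrfn, valid, rsd, uvf = {}, {}, {}, {}
    models: dict[str, dict[str, CalibrationModel]] = {}
    for nuc in sorted(df.loc[df["channel"] == "MS13", "analyte"].unique()):
        wide = _blank_corrected(_pivot_ms(df, nuc))
        blanks = wide.loc[wide["level_pmol"] == 0, "MS12"].to_numpy()
        pos = wide[wide["level_pmol"] > 0].copy()
        pos["nif"] = pos["ms12_corr"] / pos["MS13"]

        raw = fit_linear_range(
            pos["level_pmol"], pos["MS12"], tol_mid, tol_edge, nucleoside=nuc, channel="MS12",
        )
        if blanks.size >= 3:
            raw.lod, raw.loq = estimate_lod_loq(blanks, raw.slope)
        nifm = fit_linear_range(
            pos["level_pmol"], pos["nif"], tol_mid, tol_edge,
            through_origin=True, nucleoside=nuc, channel="NIF",
        )
        models[nuc] = {"MS12": raw, "NIF": nifm}

        x, y = _median_nif_per_level(pos)
        keep = (x >= nifm.linear_lo) & (x <= nifm.linear_hi)
        rrfn[nuc] = fit_rrfn(x[keep], y[keep])
        valid[nuc] = (nifm.linear_lo, nifm.linear_hi)
        if pos["session_id"].nunique() >= 2:
            per_session = rrfn_by_session(df, nuc, window=valid[nuc])
            rsd[nuc] = session_stability({s: f.slope for s, f in per_session.items()})

    for nuc in CANONICAL:
        uv = df[(df["analyte"] == nuc) & (df["channel"] == "UV254") & df["level_pmol"].notna()]
        if uv.empty:
            continue
        agg = uv.groupby("level_pmol")["peak_area"].median()
        if 0.0 not in agg.index or (agg.index > 0).sum() < 2:
            continue
        silis_area = agg.loc[0.0]  # blank level: internal-standard-only UV area
        x = agg.index.to_numpy()
        pos_mask = x > 0
        uvf[nuc] = fit_uvf(x[pos_mask], agg.to_numpy()[pos_mask] - silis_area, nuc)
    return RFTable(rrfn=rrfn, uvf=uvf, valid_range=valid, session_rsd=rsd), models
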