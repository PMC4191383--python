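"""Synthetic LC-MS/MS instrument for isotopomer-pair measurements.

Generates the long-form peak-area tables the rest of the package consumes,
with the signal structure that makes isotope-dilution calibration work and
plain external calibration fail:

* a saturating MS response — co-eluting 12C analyte and 13C internal
  standard share one ion-suppression factor, so their *ratio* is exact
  even deep inside saturation;
* a multiplicative inter-session drift factor applied identically to both
  isotopomer channels of a nucleoside (detector tuning, spray condition),
  which is what ruins raw response factors across weeks;
* proportional + additive per-injection noise, independent per channel;
* a linear, quiet UV channel for the canonical nucleosides.

Everything is seeded and byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import CANONICAL

__all__ = [
    "InstrumentModel",
    "SampleTruth",
    "default_model",
    "default_levels",
    "expected_signals",
    "simulate_calibration",
    "simulate_digest",
    "SILIS_REF_RUN",
    "DEFAULT_SILIS_PMOL",
]

#: run_id used for the internal-standard-only UV reference injection.
SILIS_REF_RUN = "SILIS_REF"

#: Default internal-standard spike per injection, pmol of each 13C isotopomer.
DEFAULT_SILIS_PMOL = 0.1

MEASUREMENT_COLUMNS = [
    "run_id", "session_id", "analyte", "channel", "peak_area", "level_pmol", "replicate",
]


@dataclass
class InstrumentModel:
    """Ground-truth instrument parameters for the simulator.

    rf         MS response factor per nucleoside, signal counts per pmol,
               shared by the 12C and 13C isotopomers of that nucleoside.
    k_sat      suppression capacity in pmol (scalar or per nucleoside): the
               co-eluting amount at which the response has dropped to half.
    sigma_add  additive baseline noise sd, counts.
    baseline   mean blank area, counts (defaults to 3*sigma_add so that
               integrated blank areas stay positive like a real integrator's).
    cv_prop    proportional per-injection noise CV, independent per channel.
    drift_cv   lognormal inter-session drift CV (scalar or per nucleoside),
               applied to rf of BOTH channels of a nucleoside per session.
    uvf_true   UV area per pmol for the canonical nucleosides.
    uv_cv      proportional noise CV of the UV channel.
    """

    rf: dict[str, float]
    k_sat: float | dict[str, float] = 5.0
    sigma_add: float = 3.0
    baseline: float | None = None
    cv_prop: float = 0.01
    drift_cv: float | dict[str, float] = 0.24
    uvf_true: dict[str, float] = field(
        default_factory=lambda: {"C": 540.0, "U": 600.0, "G": 800.0, "A": 900.0}
    )
    uv_cv: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in self.rf.items():
            if v <= 0:
                raise ValueError(f"rf[{name}] must be positive")
        for v in (list(self.k_sat.values()) if isinstance(self.k_sat, dict) else [self.k_sat]):
            if v <= 0:
                raise ValueError("k_sat must be positive")
        for name, v in self.uvf_true.items():
            if v <= 0:
                raise ValueError(f"uvf_true[{name}] must be positive")
        if not 0 <= self.cv_prop < 1:
            raise ValueError("cv_prop must be in [0, 1)")
        for v in (list(self.drift_cv.values()) if isinstance(self.drift_cv, dict) else [self.drift_cv]):
            if not 0 <= v < 1:
                raise ValueError("drift_cv must be in [0, 1)")
        if self.baseline is None:
            self.baseline = 3.0 * self.sigma_add

    def k_sat_of(self, nucleoside: str) -> float:
        return self.k_sat[nucleoside] if isinstance(self.k_sat, dict) else self.k_sat

    def drift_cv_of(self, nucleoside: str) -> float:
        return self.drift_cv[nucleoside] if isinstance(self.drift_cv, dict) else self.drift_cv


@dataclass
class SampleTruth:
    """True composition of one injected sample digest.

    amounts_12c     pmol of each (modified) 12C nucleoside injected.
    silis_amounts   pmol of each 13C isotopomer injected (constant per batch).
    sequence_counts residue counts per canonical nucleoside of the RNA.
    rna_pmol        true amount of RNA molecules injected.
    """

    amounts_12c: dict[str, float]
    silis_amounts: dict[str, float]
    sequence_counts: dict[str, int] | None = None
    rna_pmol: float | None = None

    def __post_init__(self) -> None:
        if (self.sequence_counts is None) != (self.rna_pmol is None):
            raise ValueError("sequence_counts and rna_pmol must be given together")
        for name, v in self.amounts_12c.items():
            if v < 0:
                raise ValueError(f"amounts_12c[{name}] must be >= 0")
        for name, v in self.silis_amounts.items():
            if v <= 0:
                raise ValueError(f"silis_amounts[{name}] must be > 0")

    @classmethod
    def from_occupancy(
        cls,
        rna_pmol: float,
        sequence_counts: dict[str, int],
        occupancy: dict[str, tuple[int, float]],
        silis_amounts: dict[str, float],
    ) -> "SampleTruth":
        """Build truth from per-modification (site count, occupancy) pairs:
        the injected amount of a modification is rna_pmol * sites * occupancy."""
        amounts = {
            name: rna_pmol * sites * occ for name, (sites, occ) in occupancy.items()
        }
        return cls(
            amounts_12c=amounts,
            silis_amounts=silis_amounts,
            sequence_counts=dict(sequence_counts),
            rna_pmol=rna_pmol,
        )


def default_model(nucleosides=("Am",), rf: float = 1.0e6, seed: int = 0, **kwargs) -> InstrumentModel:
    """An instrument model with the package's reference study conditions."""
    return InstrumentModel(rf={n: rf for n in nucleosides}, seed=seed, **kwargs)


def default_levels() -> np.ndarray:
    """The default external-calibration grid: a blank plus 15 half-decade
    levels from 0.01 fmol to 100 pmol injected."""
    return np.concatenate([[0.0], np.logspace(-5, 2, 15)])


def expected_signals(
    model: InstrumentModel, a12: float, a13: float, nucleoside: str
) -> tuple[float, float]:
    """Noise-free mean MS signals of the co-eluting isotopomer pair.

    Both channels share the suppression factor
    ``phi = 1 / (1 + (a12 + a13) / k_sat)``, so the mean 12C/13C ratio is
    exactly a12/a13 at every load — the mechanism that makes the
    isotope-normalized response saturation-proof.
    """
    if a12 < 0 or a13 < 0:
        raise ValueError("amounts must be >= 0")
    rf = model.rf[nucleoside]
    phi = 1.0 / (1.0 + (a12 + a13) / model.k_sat_of(nucleoside))
    return rf * a12 * phi, rf * a13 * phi


def _session_drifts(model, nucleosides, n_sessions, rng):
    """One shared lognormal drift factor per (session, nucleoside), mean 1."""
    out = {}
    for nuc in nucleosides:
        cv = model.drift_cv_of(nuc)
        if cv == 0:
            out[nuc] = np.ones(n_sessions)
        else:
            s2 = np.log1p(cv**2)
            out[nuc] = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=n_sessions)
    return out


def _noisy(mean, model, rng):
    eps_prop = rng.normal(0.0, model.cv_prop) if model.cv_prop > 0 else 0.0
    eps_add = rng.normal(model.baseline, model.sigma_add) if model.sigma_add > 0 else model.baseline
    return max(mean * (1.0 + eps_prop) + eps_add, 0.0)


def simulate_calibration(
    model: InstrumentModel,
    levels=None,
    silis_pmol: float | dict[str, float] = DEFAULT_SILIS_PMOL,
    n_replicates: int = 3,
    n_sessions: int = 1,
    nucleosides=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an external-calibration series with constant SIL-IS spike.

    Each session draws one drift factor per nucleoside applied to the
    response of BOTH isotopomer channels; each injection then gets
    independent proportional + additive noise per channel.  Levels must be
    ascending and non-negative; a level of 0 is a blank.  Canonical
    nucleosides additionally get UV rows (linear, drift-free channel).
    """
    if levels is None:
        levels = default_levels()
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    if np.any(levels < 0) or np.any(np.diff(levels) < 0):
        raise ValueError("levels must be ascending and >= 0")
    if nucleosides is None:
        nucleosides = list(model.rf)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    drifts = _session_drifts(model, nucleosides, n_sessions, rng)

    rows = []
    for s in range(n_sessions):
        session_id = f"S{s + 1}"
        for nuc in nucleosides:
            a13 = silis_pmol[nuc] if isinstance(silis_pmol, dict) else silis_pmol
            d = drifts[nuc][s]
            for i, level in enumerate(levels):
                m12, m13 = expected_signals(model, level, a13, nuc)
                for r in range(1, n_replicates + 1):
                    run_id = f"{session_id}_L{i:02d}_R{r}"
                    rows.append(
                        (run_id, session_id, nuc, "MS12", _noisy(m12 * d, model, rng), level, r)
                    )
                    rows.append(
                        (run_id, session_id, nuc, "MS13", _noisy(m13 * d, model, rng), level, r)
                    )
                    if nuc in CANONICAL and nuc in model.uvf_true:
                        area = model.uvf_true[nuc] * (level + a13)
                        area *= 1.0 + (rng.normal(0.0, model.uv_cv) if model.uv_cv > 0 else 0.0)
                        rows.append(
                            (run_id, session_id, nuc, "UV254", max(area, 0.0), level, r)
                        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def simulate_digest(
    model: InstrumentModel,
    truth: SampleTruth,
    n_replicates: int = 3,
    seed: int | None = None,
    run_prefix: str = "SAMPLE",
    session_id: str = "S1",
    include_silis_ref: bool = True,
) -> pd.DataFrame:
    """Simulate the measurement of one full sample digest.

    MS rows are produced for every nucleoside with an internal-standard
    spike; UV rows for every canonical nucleoside present in the sequence,
    with the internal standard contributing to the UV area exactly as it
    does in a real run (to be subtracted downstream).  When
    ``include_silis_ref`` is set, an internal-standard-only reference
    injection (run_id ``SILIS_REF``) is appended so the UV subtraction can
    use a measured, not theoretical, standard area.
    """
    for nuc in list(truth.amounts_12c) + list(truth.silis_amounts):
        if nuc not in model.rf and nuc not in CANONICAL:
            raise ValueError(f"nucleoside {nuc!r} has no response factor in the model")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    drifts = _session_drifts(model, list(model.rf), 1, rng)

    rows = []
    for r in range(1, n_replicates + 1):
        run_id = f"{run_prefix}_R{r}"
        for nuc, a13 in truth.silis_amounts.items():
            if nuc in CANONICAL and nuc not in model.rf:
                continue
            a12 = truth.amounts_12c.get(nuc, 0.0)
            if nuc in CANONICAL and truth.sequence_counts is not None:
                a12 += truth.rna_pmol * truth.sequence_counts.get(nuc, 0)
            m12, m13 = expected_signals(model, a12, a13, nuc)
            d = drifts[nuc][0]
            rows.append((run_id, session_id, nuc, "MS12", _noisy(m12 * d, model, rng), np.nan, r))
            rows.append((run_id, session_id, nuc, "MS13", _noisy(m13 * d, model, rng), np.nan, r))
        if truth.sequence_counts is not None:
            for nuc in CANONICAL:
                count = truth.sequence_counts.get(nuc, 0)
                if count == 0 and nuc not in truth.silis_amounts:
                    continue
                pmol = truth.rna_pmol * count + truth.silis_amounts.get(nuc, 0.0)
                area = model.uvf_true[nuc] * pmol
                area *= 1.0 + (rng.normal(0.0, model.uv_cv) if model.uv_cv > 0 else 0.0)
                rows.append((run_id, session_id, nuc, "UV254", max(area, 0.0), np.nan, r))
    if include_silis_ref and truth.sequence_counts is not None:
        for nuc in CANONICAL:
            if nuc not in truth.silis_amounts:
                continue
            area = model.uvf_true[nuc] * truth.silis_amounts[nuc]
            area *= 1.0 + (rng.normal(0.0, model.uv_cv) if model.uv_cv > 0 else 0.0)
            rows.append((SILIS_REF_RUN, session_id, nuc, "UV254", max(area, 0.0), np.nan, 1))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def truth_table(truth: SampleTruth, run_prefix: str = "SAMPLE") -> pd.DataFrame:
    """Sidecar table of true injected amounts, for recovery tests."""
    rows = [(run_prefix, nuc, pmol) for nuc, pmol in sorted(truth.amounts_12c.items())]
    if truth.rna_pmol is not None:
        rows.append((run_prefix, "RNA", truth.rna_pmol))
    return pd.DataFrame(rows, columns=["run_id", "nucleoside", "true_pmol"])
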