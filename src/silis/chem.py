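"""Nucleoside chemistry: registry, isotopologue math and MRM transitions.

The internal standard used throughout this package is a digest of uniformly
13C-labeled total RNA, so every analyte has a co-eluting isotopomer whose
[M+H]+ is shifted up by exactly one mass unit per carbon atom.  This module
owns that bookkeeping: elemental formulas, protonated monoisotopic masses,
binomial isotopologue distributions at arbitrary 13C incorporation, the
ribose-loss MRM transitions, and the inverse problem of estimating the
labeling efficiency from an observed isotopologue ratio.
"""
from __future__ import annotations

import csv
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
from pyteomics import mass as _pmass
from scipy import stats as _stats

__all__ = [
    "NucleosideSpec",
    "IsotopologuePattern",
    "RegistryError",
    "TransitionError",
    "CANONICAL",
    "NATURAL_13C_ABUNDANCE",
    "PROTON_MASS",
    "C13_SHIFT",
    "RIBOSE_LOSS",
    "METHYLRIBOSE_LOSS",
    "parse_formula",
    "protonated_mz",
    "mrm_transition",
    "isotopologue_pattern",
    "estimate_labeling_efficiency",
    "load_registry",
    "default_registry",
    "export_transitions",
]

#: The four canonical ribonucleosides (UV-quantifiable majors).
CANONICAL = ("C", "U", "G", "A")

#: Natural abundance of 13C (the ~1.1% satellite seen on unlabeled spectra).
NATURAL_13C_ABUNDANCE = 0.011

PROTON_MASS = _pmass.nist_mass["H+"][0][0]  # 1.0072765
C13_SHIFT = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]

#: Neutral losses monitored in the MRM transitions: the N-glycosidic bond
#: cleaves off the sugar, C5H8O4 for ribose, C6H10O4 for 2'-O-methylribose.
RIBOSE_LOSS = _pmass.calculate_mass(formula="C5H8O4")  # 132.0423
METHYLRIBOSE_LOSS = _pmass.calculate_mass(formula="C6H10O4")  # 146.0579


class RegistryError(ValueError):
    """A nucleoside definition is malformed (bad formula, duplicate name...)."""


class TransitionError(ValueError):
    """An MRM transition cannot be derived and no override was supplied."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``"C11H15N5O4"``.

    Every element symbol is checked against the isotope mass table; an
    unknown symbol is a configuration error, not a silent zero.
    """
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises its own error type
        raise RegistryError(f"cannot parse formula {formula!r}: {exc}") from exc
    for element in comp:
        bare = element.split("[")[0]
        if bare not in _pmass.nist_mass:
            raise RegistryError(f"unknown element {element!r} in formula {formula!r}")
    if not comp:
        raise RegistryError(f"empty formula {formula!r}")
    return dict(comp)


@dataclass(frozen=True)
class NucleosideSpec:
    """Chemistry and MRM identity of one (canonical or modified) nucleoside.

    ``formula`` is the neutral elemental formula; ``parent`` names the
    canonical nucleoside the modification derives from (needed for yield
    calculations); ``two_prime_methyl`` switches the MRM neutral loss to
    methylribose; ``c_glycoside`` marks species such as pseudouridine whose
    base-sugar bond does not fragment like an N-glycoside, so their
    transition must be supplied explicitly via ``transition_override``.
    """

    short_name: str
    formula: str
    full_name: str = ""
    parent: str | None = None
    rt_window: tuple[float, float] | None = None
    transition_override: tuple[float, float] | None = None
    two_prime_methyl: bool = False
    c_glycoside: bool = False
    no_external_calibration: bool = False
    composition: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition", parse_formula(self.formula))

    @property
    def n_carbon(self) -> int:
        return int(self.composition.get("C", 0))

    @property
    def is_canonical(self) -> bool:
        return self.short_name in CANONICAL


@dataclass(frozen=True)
class IsotopologuePattern:
    """Relative abundances of the 13C isotopologues of one nucleoside.

    ``intensities`` maps the integer mass offset (= number of 13C atoms)
    to relative abundance; offsets run from 0 to the carbon count and the
    abundances sum to one.
    """

    base_mz: float
    intensities: Mapping[int, float]
    p13: float

    def ratio(self, offset_a: int, offset_b: int) -> float:
        """Intensity ratio I(offset_a) / I(offset_b)."""
        return self.intensities[offset_a] / self.intensities[offset_b]


def _neutral_mass(spec: NucleosideSpec) -> float:
    return _pmass.calculate_mass(formula=spec.formula)


def protonated_mz(spec: NucleosideSpec, uniform_13c: bool = False) -> float:
    """Monoisotopic [M+H]+ m/z; with ``uniform_13c`` every carbon is 13C.

    The labeled-minus-unlabeled difference is exactly
    ``n_carbon * (m(13C) - m(12C))``, i.e. one mass unit per carbon at
    unit resolution.
    """
    if "H" not in spec.composition:
        raise RegistryError(f"{spec.short_name}: formula {spec.formula!r} has no hydrogen")
    mz = _neutral_mass(spec) + PROTON_MASS
    if uniform_13c:
        mz += spec.n_carbon * C13_SHIFT
    return mz


def mrm_transition(spec: NucleosideSpec) -> tuple[float, float]:
    """(precursor m/z, product m/z) for the nucleoside's MRM transition.

    Ordinary N-glycosides lose the ribose (132.0423); 2'-O-methylated
    species lose the methylated ribose (146.0579), so the product ion is
    the protonated base either way.  C-glycosides (pseudouridine) do not
    fragment by sugar loss and must carry a ``transition_override``.
    """
    if spec.transition_override is not None:
        return tuple(spec.transition_override)
    if spec.c_glycoside:
        raise TransitionError(
            f"{spec.short_name}: C-glycosidic fragmentation is not derivable from the "
            "ribose-loss rule; supply transition_override"
        )
    precursor = protonated_mz(spec)
    loss = METHYLRIBOSE_LOSS if spec.two_prime_methyl else RIBOSE_LOSS
    return (precursor, precursor - loss)


def isotopologue_pattern(spec: NucleosideSpec, p13: float) -> IsotopologuePattern:
    """Binomial isotopologue distribution at per-atom 13C probability ``p13``.

    Each of the ``n_carbon`` carbons is independently 13C with probability
    p13, so the intensity at mass offset k is the Binomial(n_carbon, p13)
    probability of exactly k heavy atoms.  p13 = 0.011 gives the natural
    satellite pattern of an unlabeled compound; p13 near 1 gives the
    biosynthetic internal standard with its small M-1 residual.
    """
    if not 0.0 <= p13 <= 1.0:
        raise ValueError(f"p13 must be in [0, 1], got {p13}")
    n = spec.n_carbon
    ks = np.arange(n + 1)
    pmf = _stats.binom.pmf(ks, n, p13)
    pmf = pmf / pmf.sum()
    return IsotopologuePattern(
        base_mz=protonated_mz(spec),
        intensities={int(k): float(v) for k, v in zip(ks, pmf)},
        p13=float(p13),
    )


def estimate_labeling_efficiency(ratio_mminus1_to_m: float, n_carbon: int) -> float:
    """Per-atom 13C probability from the observed I(M-1)/I(M) ratio.

    For a binomial pattern the ratio of the (n-1)-labeled to the fully
    labeled isotopologue is ``n * (1 - p) / p``, hence
    ``p = n / (n + ratio)``.  A ratio of zero means no residual 12C
    (p = 1); e.g. an 11-carbon nucleoside with an M-1 peak one ninth of
    the main peak is 99% labeled.
    """
    if ratio_mminus1_to_m < 0:
        raise ValueError("intensity ratio must be non-negative")
    if n_carbon < 1:
        raise ValueError("n_carbon must be >= 1")
    return n_carbon / (n_carbon + ratio_mminus1_to_m)


# ---------------------------------------------------------------------------
# Registry I/O

def _spec_from_table(name: str, tbl: Mapping) -> NucleosideSpec:
    known = {
        "formula", "full_name", "parent", "rt_window", "transition_override",
        "two_prime_methyl", "c_glycoside", "no_external_calibration",
    }
    extra = set(tbl) - known
    if extra:
        raise RegistryError(f"{name}: unknown registry keys {sorted(extra)}")
    if "formula" not in tbl:
        raise RegistryError(f"{name}: missing formula")
    rt = tbl.get("rt_window")
    trans = tbl.get("transition_override")
    return NucleosideSpec(
        short_name=name,
        formula=tbl["formula"],
        full_name=tbl.get("full_name", name),
        parent=tbl.get("parent"),
        rt_window=tuple(rt) if rt is not None else None,
        transition_override=tuple(trans) if trans is not None else None,
        two_prime_methyl=bool(tbl.get("two_prime_methyl", False)),
        c_glycoside=bool(tbl.get("c_glycoside", False)),
        no_external_calibration=bool(tbl.get("no_external_calibration", False)),
    )


def load_registry(path) -> dict[str, NucleosideSpec]:
    """Load a TOML nucleoside registry (one table per nucleoside)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    registry: dict[str, NucleosideSpec] = {}
    for name, tbl in data.items():
        if name in registry:  # tomllib already rejects duplicate tables
            raise RegistryError(f"duplicate nucleoside {name!r}")
        registry[name] = _spec_from_table(name, tbl)
    _validate_registry(registry)
    return registry


def _validate_registry(registry: Mapping[str, NucleosideSpec]) -> None:
    for name, spec in registry.items():
        if spec.short_name != name:
            raise RegistryError(f"registry key {name!r} != short_name {spec.short_name!r}")
        if not spec.is_canonical and spec.parent is None:
            raise RegistryError(f"{name}: modified nucleoside without parent")
        if spec.parent is not None and spec.parent not in CANONICAL:
            raise RegistryError(f"{name}: parent {spec.parent!r} not canonical")


def default_registry() -> dict[str, NucleosideSpec]:
    """The built-in registry: the 18 externally calibratable nucleosides
    plus the five detectable-only species (D, m3C, m2A, m1G, m2G) flagged
    ``no_external_calibration``."""
    ref = resources.files("silis.data").joinpath("registry.toml")
    with resources.as_file(ref) as path:
        return load_registry(path)


def export_transitions(registry: Mapping[str, NucleosideSpec], path) -> None:
    """Write a dMRM-style transition list CSV.

    Columns: name, precursor_mz, product_mz, rt_window_start, rt_window_end.
    Species whose transition cannot be derived and that carry no override
    (C-glycosides) are a hard error, so an exported method is always complete.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "precursor_mz", "product_mz", "rt_window_start", "rt_window_end"])
        for name, spec in registry.items():
            prec, prod = mrm_transition(spec)
            lo, hi = spec.rt_window if spec.rt_window is not None else ("", "")
            writer.writerow([name, f"{prec:.4f}", f"{prod:.4f}", lo, hi])
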