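"""Monoisotopic mass arithmetic for peptides, modifications, and m/z.

All arithmetic is monoisotopic: peptide neutral mass is the sum of residue
(dehydrated) masses plus one water, a modification contributes its delta mass,
and m/z follows the proton-adduct convention.  Residue and elemental masses
come from :mod:`pyteomics.mass`; the water and proton constants used in the
field's search-engine conventions are centralized here.

The probe-remnant registry (vinyl sulfone, vinyl methyl ester, propargylamide,
the vinyl pentynyl sulfone probe with cleavable DADPS or DDE linker, plus the
standard carbamidomethyl / oxidation / Gly-Gly search modifications) is packaged
as a TSV and loaded by :func:`load_modification_registry`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _pt_mass

WATER_MASS = 18.010565
PROTON_MASS = 1.007276

#: Canonical residue letter -> monoisotopic residue (dehydrated) mass, Da.
RESIDUE_MASSES: Mapping[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)


class UnknownResidueError(ValueError):
    """A sequence contains a letter outside the 20 canonical amino acids."""


@dataclass(frozen=True)
class Modification:
    """A named monoisotopic mass shift attached to specific residues.

    Parameters
    ----------
    name : str
        Registry name, e.g. ``"vps_dadps"`` for the vinyl pentynyl sulfone
        probe remnant left after acid cleavage of the DADPS linker.
    delta_mass : float
        Monoisotopic mass shift in Da.
    targets : frozenset of str
        Residue letters the modification may occupy.
    kind : str
        ``"fixed"`` or ``"variable"`` (search-engine convention).
    """

    name: str
    delta_mass: float
    targets: frozenset = field(default_factory=frozenset)
    kind: str = "variable"

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no target residues")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError(f"modification {self.name!r} delta_mass not finite")


@dataclass(frozen=True)
class MatchTolerance:
    """Precursor (ppm) and fragment (Da) match tolerances."""

    precursor_ppm: float = 50.0
    fragment_da: float = 0.8

    def __post_init__(self):
        if self.precursor_ppm <= 0 or self.fragment_da <= 0:
            raise ValueError("tolerances must be positive")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise UnknownResidueError(
            f"non-canonical residue(s) {sorted(bad)} in sequence; only the 20 "
            "canonical amino acids are supported"
        )


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[int, Modification]] = (),
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide.

    Parameters
    ----------
    sequence : str
        Peptide sequence over the 20 canonical residues.
    mods : sequence of (position, Modification)
        0-based positions within ``sequence``; the residue at each position
        must be in the modification's target set.

    Returns
    -------
    float
        Sum of residue masses + water + sum of modification deltas, Da.
    """
    _check_sequence(sequence)
    total = sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER_MASS
    for pos, mod in mods:
        if not 0 <= pos < len(sequence):
            raise IndexError(f"modification position {pos} outside sequence")
        if sequence[pos] not in mod.targets:
            raise ValueError(
                f"modification {mod.name!r} targets {sorted(mod.targets)} but "
                f"position {pos} is {sequence[pos]!r}"
            )
        total += mod.delta_mass
    return total


def modification_mass_from_formula(formula: str) -> float:
    """Monoisotopic mass of an elemental formula over C, H, N, O, S.

    Used to validate registry deltas whose composition is known (e.g.
    carbamidomethyl = C2H3NO -> 57.0215 Da).
    """
    comp = _pt_mass.Composition(formula=formula)
    allowed = {"C", "H", "N", "O", "S"}
    bad = set(comp) - allowed
    if bad:
        raise ValueError(f"unknown element(s) {sorted(bad)}; allowed: {sorted(allowed)}")
    return _pt_mass.calculate_mass(composition=comp)


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at the given positive charge (proton adducts)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(observed_mz: float, charge: int) -> float:
    """Inverse of :func:`mz`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return observed_mz * charge - charge * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True when |ppm error| <= tolerance."""
    return abs(ppm_error(observed, theoretical)) <= tol_ppm


def _registry_path():
    return importlib.resources.files("probescout.data") / "modifications.tsv"


def load_modification_registry(path=None) -> dict[str, Modification]:
    """Load the packaged modification registry (or a user TSV of the same shape).

    The TSV has columns ``name, delta_mass, targets, kind[, formula]``;
    ``targets`` is a string of residue letters.
    """
    src = path if path is not None else _registry_path()
    df = pd.read_csv(src, sep="\t", comment="#")
    registry: dict[str, Modification] = {}
    for row in df.itertuples(index=False):
        registry[row.name] = Modification(
            name=row.name,
            delta_mass=float(row.delta_mass),
            targets=frozenset(str(row.targets)),
            kind=str(row.kind),
        )
    return registry


def registry_formula_table(path=None) -> pd.DataFrame:
    """Registry rows that declare an elemental formula, with recomputed deltas.

    Returns a frame with columns ``name, delta_mass, formula, computed_mass``;
    the probe remnants whose post-cleavage composition is not public carry no
    formula and are excluded.
    """
    src = path if path is not None else _registry_path()
    df = pd.read_csv(src, sep="\t", comment="#")
    df = df.dropna(subset=["formula"]).copy()
    df["computed_mass"] = [
        modification_mass_from_formula(f) for f in df["formula"]
    ]
    return df[["name", "delta_mass", "formula", "computed_mass"]]


def merge_registries(
    base: Mapping[str, Modification], extra: Mapping[str, Modification]
) -> dict[str, Modification]:
    """Merge a user registry over the packaged one (user entries win)."""
    merged = dict(base)
    merged.update(extra)
    return merged
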