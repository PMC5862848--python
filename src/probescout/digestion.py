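"""In-silico proteolysis and the sequential on-bead digestion workflow.

The wet-lab workflow being modeled: probe-labeled proteins are captured on
streptavidin beads through a cleavable biotin linker attached to the probe at
the labeled Cys.  A first protease digest releases unlabeled peptides (the
"on-bead digestion fraction", used for protein identification) while labeled
peptides stay bead-bound.  Optionally a second protease shortens the retained
peptides (sub-peptides without the labeled Cys are washed away), and finally
acid cleavage of the linker releases the labeled peptides — the "cleaved
fraction" — each carrying the probe-remnant mass at the labeled Cys.

Proteases are modeled with C-terminal cleavage rules (cleave after a residue
set, suppressed when the next residue is blocked — the usual search-engine
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .masses import Modification, peptide_mass


@dataclass(frozen=True)
class Enzyme:
    """A protease with C-terminal-side cleavage specificity.

    ``cleave_after`` is the residue set after which the backbone is cut;
    cleavage is suppressed when the following residue is in ``blocked_by_next``.
    """

    name: str
    cleave_after: frozenset
    blocked_by_next: frozenset = frozenset()

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError(f"enzyme {self.name!r} has empty cleave_after set")


# Cleavage rules: trypsin after K/R not before P; Lys-C after K (unblocked);
# chymotrypsin after F/W/Y/L not before P; Glu-C after E in ammonium
# bicarbonate buffer (E+D cleavage available as glu_c_de).
TRYPSIN = Enzyme("trypsin", frozenset("KR"), frozenset("P"))
LYS_C = Enzyme("lysC", frozenset("K"))
CHYMOTRYPSIN = Enzyme("chymotrypsin", frozenset("FWYL"), frozenset("P"))
GLU_C = Enzyme("gluC", frozenset("E"))
GLU_C_DE = Enzyme("gluC_DE", frozenset("ED"))

ENZYMES: Mapping[str, Enzyme] = {
    e.name: e for e in (TRYPSIN, LYS_C, CHYMOTRYPSIN, GLU_C, GLU_C_DE)
}


@dataclass(frozen=True)
class PeptideInterval:
    """A peptide as a half-open 0-based interval on its parent protein."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval")

    def __len__(self):
        return self.end - self.start


@dataclass(frozen=True)
class DigestionScheme:
    """Ordered protease steps plus the linker-cleavage remnant modification."""

    name: str
    step1_enzymes: tuple
    remnant: Modification
    step1_max_missed: int = 2
    step2_enzyme: Enzyme | None = None
    step2_max_missed: int = 2

    def __post_init__(self):
        if self.step1_max_missed < 0 or self.step2_max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if "C" not in self.remnant.targets:
            raise ValueError("remnant modification must target Cys")


@dataclass
class FractionResult:
    """Output fractions of the sequential on-bead digestion of one protein.

    ``onbead_fraction``: step-1 peptides without a labeled Cys (identification
    fraction).  ``washed``: step-2 sub-peptides without a labeled Cys.
    ``cleaved_fraction``: labeled peptides released by linker cleavage, as
    ``(PeptideInterval, mods)`` with the remnant at each labeled Cys.
    """

    protein_id: str
    onbead_fraction: list = field(default_factory=list)
    washed: list = field(default_factory=list)
    cleaved_fraction: list = field(default_factory=list)


def cut_sites(sequence: str, enzymes: Iterable[Enzyme]) -> list[int]:
    """Positions i such that the bond between residue i-1 and i is cut.

    A position qualifies if residue i-1 is in some enzyme's cleave_after set
    and residue i is not in that same enzyme's blocked set.
    """
    sites = set()
    for enz in enzymes:
        for i in range(1, len(sequence)):
            if sequence[i - 1] in enz.cleave_after and sequence[i] not in enz.blocked_by_next:
                sites.add(i)
    return sorted(sites)


def digest(
    sequence: str,
    enzymes: Iterable[Enzyme] | Enzyme,
    max_missed: int = 0,
    protein_id: str = "",
    offset: int = 0,
) -> list[PeptideInterval]:
    """Digest a sequence, returning all peptides with <= max_missed missed cuts.

    Returns fully-cleaved peptides plus every concatenation spanning at most
    ``max_missed`` internal cut sites, ordered by (start, end).  ``offset``
    shifts reported coordinates (used when re-digesting a sub-peptide so that
    intervals stay in parent-protein coordinates).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    boundaries = [0] + cut_sites(sequence, enzymes) + [len(sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            peptides.append(
                PeptideInterval(
                    protein_id=protein_id,
                    start=start + offset,
                    end=end + offset,
                    sequence=sequence[start:end],
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def _tile(sequence: str, enzymes, protein_id: str = "", offset: int = 0):
    """Fully-cleaved (zero missed cleavage) tiling of the sequence."""
    return digest(sequence, enzymes, 0, protein_id=protein_id, offset=offset)


def sequential_onbead_digest(
    protein_id: str,
    sequence: str,
    labeled_positions: Iterable[int],
    scheme: DigestionScheme,
) -> FractionResult:
    """Simulate the sequential on-bead digestion of one labeled protein.

    ``labeled_positions`` are 0-based indices of probe-labeled Cys residues.
    Fractionation uses the fully-cleaved tiling so that each residue lands in
    exactly one output peptide (the partition invariant); missed-cleavage
    variants matter for search-space generation, not for fraction membership.
    """
    labeled = sorted(set(labeled_positions))
    for pos in labeled:
        if not 0 <= pos < len(sequence):
            raise IndexError(f"labeled position {pos} outside protein")
        if sequence[pos] != "C":
            raise ValueError(f"labeled position {pos} is {sequence[pos]!r}, not Cys")

    result = FractionResult(protein_id=protein_id)
    labeled_set = set(labeled)

    retained = []
    for pep in _tile(sequence, scheme.step1_enzymes, protein_id):
        if labeled_set & set(range(pep.start, pep.end)):
            retained.append(pep)
        else:
            result.onbead_fraction.append(pep)

    if scheme.step2_enzyme is not None:
        step2_retained = []
        for pep in retained:
            for sub in _tile(
                pep.sequence, [scheme.step2_enzyme], protein_id, offset=pep.start
            ):
                if labeled_set & set(range(sub.start, sub.end)):
                    step2_retained.append(sub)
                else:
                    result.washed.append(sub)
        retained = step2_retained

    for pep in retained:
        mods = [(pos - pep.start, scheme.remnant) for pos in labeled
                if pep.start <= pos < pep.end]
        result.cleaved_fraction.append((pep, mods))
    return result


DEFAULT_WINDOW = {"min_length": 6, "max_length": 40,
                  "min_mass": 600.0, "max_mass": 6000.0}


def site_detectability(
    proteome: Mapping[str, str],
    annotated_sites: Sequence[tuple[str, int]],
    schemes: Sequence[DigestionScheme],
    window: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Which annotated Cys sites yield an observable cleaved-fraction peptide.

    ``annotated_sites`` are (protein_id, 0-based Cys index) pairs.  For each
    (site, scheme) the cleaved-fraction peptide containing the site is tested
    against the length/neutral-mass window; the returned frame has one row per
    pair with the peptide, its length and mass, and the detectable flag.
    """
    if not proteome:
        raise ValueError("empty proteome")
    win = dict(DEFAULT_WINDOW)
    if window:
        win.update(window)
    rows = []
    for protein_id, pos in annotated_sites:
        seq = proteome[protein_id]
        for scheme in schemes:
            frac = sequential_onbead_digest(protein_id, seq, [pos], scheme)
            pep, mods = next(
                (pm for pm in frac.cleaved_fraction
                 if pm[0].start <= pos < pm[0].end),
            )
            mass = peptide_mass(pep.sequence, mods)
            detectable = (
                win["min_length"] <= len(pep) <= win["max_length"]
                and win["min_mass"] <= mass <= win["max_mass"]
            )
            rows.append(
                {
                    "protein_id": protein_id,
                    "site": pos + 1,  # 1-based for reporting
                    "scheme": scheme.name,
                    "peptide": pep.sequence,
                    "length": len(pep),
                    "mass": mass,
                    "detectable": detectable,
                }
            )
    return pd.DataFrame(rows)


def coverage_summary(detectability: pd.DataFrame) -> pd.DataFrame:
    """Per-scheme and union coverage fractions from a detectability table."""
    n_sites = detectability.groupby(["protein_id", "site"]).ngroups
    rows = []
    for scheme, sub in detectability.groupby("scheme"):
        rows.append({"scheme": scheme,
                     "coverage": sub["detectable"].sum() / n_sites})
    union = (
        detectability.groupby(["protein_id", "site"])["detectable"].any().sum()
        / n_sites
    )
    rows.append({"scheme": "union", "coverage": union})
    return pd.DataFrame(rows)
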