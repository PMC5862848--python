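"""Spectrum-to-peptide matching, labeling-site localization, and two-tier FDR.

Scoring is a transparent matched-fragment-ion count: the number of theoretical
b/y ions that can be matched one-to-one to observed peaks within the fragment
tolerance.  Site localization uses the binomial Ascore idea: at a peak depth
of d peaks per 100 m/z, the probability that a site-determining ion is matched
by chance is d/100, so the evidence for a placement is the binomial survival
probability of its matched site-determining ion count, expressed on a
-10*log10 scale; the Ascore is the gap between the best and runner-up
placements.  Confidence filtering is target-decoy: identical searches against
reversed proteins estimate q-values at the peptide level (5%) and then the
protein level (2%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .digestion import PeptideInterval
from .masses import (
    MatchTolerance,
    Modification,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    mz,
    neutral_mass_from_mz,
    peptide_mass,
    ppm_error,
)

#: Sentinel Ascore for peptides with a single candidate Cys (no ambiguity).
ASCORE_UNAMBIGUOUS = 1000.0


@dataclass
class Spectrum:
    """An MS/MS spectrum: precursor plus a centroided peak list."""

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray  # (n, 2): m/z, intensity, sorted by m/z
    sample_id: str = ""
    replicate: str = ""
    digestion_condition: str = ""

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def neutral_mass(self) -> float:
        return neutral_mass_from_mz(self.precursor_mz, self.precursor_charge)


@dataclass
class LocalizationResult:
    """Best and runner-up labeling-site placements with the Ascore gap."""

    best_site: int  # 1-based within the peptide
    runner_up_site: int | None
    ascore: float

    def __post_init__(self):
        if self.ascore < 0:
            raise ValueError("ascore must be non-negative")


@dataclass
class PSM:
    """A peptide-spectrum match with its count-based score and FDR state."""

    spectrum_id: str
    protein_id: str
    peptide: PeptideInterval
    mods: tuple  # ((position_0based, Modification), ...)
    charge: int
    score: float
    is_decoy: bool = False
    sample_id: str = ""
    replicate: str = ""
    digestion_condition: str = ""
    localization: LocalizationResult | None = None
    #: per-site (position_1based_on_protein-relative peptide, ascore) pairs
    #: for PSMs carrying more than one remnant; 0-based within the peptide
    localized_sites: list | None = None
    q_value: float | None = None


def fragment_ions(
    sequence: str,
    mods: Sequence[tuple[int, Modification]] = (),
    max_fragment_charge: int = 1,
) -> list[tuple[str, int, float]]:
    """Theoretical b/y fragment ions of a modified peptide.

    Returns ``(label, charge, mz)`` triples for b_1..b_{n-1} and y_1..y_{n-1}
    at every charge up to ``max_fragment_charge``.  A modification shifts every
    fragment whose interval contains its position.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("fragments require a peptide of length >= 2")
    residue = np.array([RESIDUE_MASSES[aa] for aa in sequence])
    delta = np.zeros(n)
    for pos, mod in mods:
        delta[pos] += mod.delta_mass
    prefix = np.cumsum(residue + delta)
    total = prefix[-1] + WATER_MASS
    ions = []
    for i in range(1, n):
        b_neutral = prefix[i - 1]
        y_neutral = total - b_neutral
        for z in range(1, max_fragment_charge + 1):
            ions.append((f"b{i}", z, mz(b_neutral, z)))
            ions.append((f"y{n - i}", z, mz(y_neutral, z)))
    return ions


def count_matched_ions(
    theoretical_mz: Sequence[float],
    peaks_mz: Sequence[float],
    fragment_da: float,
) -> int:
    """Largest one-to-one assignment of theoretical ions to observed peaks.

    Each observed peak may explain at most one theoretical ion; an assignment
    is allowed when |observed - theoretical| <= fragment_da.  The maximum
    matching is computed exactly on the bipartite tolerance graph.
    """
    theo = np.asarray(theoretical_mz, dtype=float)
    obs = np.asarray(peaks_mz, dtype=float)
    if theo.size == 0 or obs.size == 0:
        return 0
    diff = np.abs(theo[:, None] - obs[None, :]) <= fragment_da
    if not diff.any():
        return 0
    graph = csr_matrix(diff)
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def match_spectrum(
    spectrum: Spectrum,
    candidates: Sequence[tuple[PeptideInterval, tuple, str]],
    tol: MatchTolerance = MatchTolerance(),
    max_fragment_charge: int = 1,
) -> PSM | None:
    """Score candidates against one spectrum and return the best PSM.

    ``candidates`` are ``(peptide, mods, protein_id)`` with mods already
    placed.  Candidates failing the precursor ppm filter are skipped.  Ties
    break toward fewer modifications, then lexicographic sequence.  Returns
    None when nothing survives the precursor filter.
    """
    obs_mass = spectrum.neutral_mass
    best = None
    best_key = None
    for peptide, mods, protein_id in candidates:
        theo_mass = peptide_mass(peptide.sequence, mods)
        if abs(ppm_error(obs_mass, theo_mass)) > tol.precursor_ppm:
            continue
        ions = fragment_ions(peptide.sequence, mods, max_fragment_charge)
        score = count_matched_ions(
            [m for _, _, m in ions], spectrum.peaks[:, 0], tol.fragment_da
        )
        key = (-score, len(mods), peptide.sequence)
        if best_key is None or key < best_key:
            best_key = key
            best = PSM(
                spectrum_id=spectrum.id,
                protein_id=protein_id,
                peptide=peptide,
                mods=tuple(mods),
                charge=spectrum.precursor_charge,
                score=score,
                sample_id=spectrum.sample_id,
                replicate=spectrum.replicate,
                digestion_condition=spectrum.digestion_condition,
            )
    return best


def _top_peaks_per_window(peaks: np.ndarray, depth: int, window: float = 100.0):
    """Keep the ``depth`` most intense peaks within each m/z window."""
    if peaks.shape[0] == 0:
        return peaks
    kept = []
    bins = np.floor(peaks[:, 0] / window).astype(int)
    for b in np.unique(bins):
        sub = peaks[bins == b]
        if sub.shape[0] > depth:
            order = np.argsort(sub[:, 1])[::-1][:depth]
            sub = sub[np.sort(order)]
        kept.append(sub)
    return np.vstack(kept)


def localize(
    spectrum: Spectrum,
    sequence: str,
    remnant: Modification,
    candidate_sites: Sequence[int],
    fixed_mods: Sequence[tuple[int, Modification]] = (),
    peak_depth: int = 10,
    fragment_da: float = 0.8,
) -> LocalizationResult:
    """Binomial Ascore-style localization of a single remnant on a peptide.

    ``candidate_sites`` are 0-based Cys positions within ``sequence``.  With a
    single candidate there is no ambiguity and the sentinel Ascore is
    returned.  Otherwise the spectrum is reduced to the top ``peak_depth``
    peaks per 100 m/z; for each placement, its site-determining singly-charged
    b/y ions (those not shared by every placement) are counted against the
    reduced peak list, and the placement evidence is
    -10*log10 P(X >= k; n, p=peak_depth/100).  The result is invariant to
    uniform intensity scaling.
    """
    for pos in candidate_sites:
        if sequence[pos] != "C":
            raise ValueError(f"candidate site {pos} is {sequence[pos]!r}, not Cys")
    sites = sorted(set(candidate_sites))
    if len(sites) == 1:
        return LocalizationResult(sites[0] + 1, None, ASCORE_UNAMBIGUOUS)

    peaks = _top_peaks_per_window(spectrum.peaks, peak_depth)
    p_chance = peak_depth / 100.0

    ion_sets = {}
    for pos in sites:
        mods = list(fixed_mods) + [(pos, remnant)]
        ion_sets[pos] = {round(m, 5) for _, _, m in fragment_ions(sequence, mods)}
    shared = set.intersection(*ion_sets.values())

    scores = {}
    for pos in sites:
        determining = sorted(ion_sets[pos] - shared)
        n = len(determining)
        k = count_matched_ions(determining, peaks[:, 0], fragment_da)
        if n == 0:
            scores[pos] = 0.0
        else:
            p_val = stats.binom.sf(k - 1, n, p_chance)  # P(X >= k)
            scores[pos] = min(-10.0 * np.log10(max(p_val, 1e-100)),
                              ASCORE_UNAMBIGUOUS)
    ranked = sorted(sites, key=lambda s: (-scores[s], s))
    best, second = ranked[0], ranked[1]
    ascore = max(scores[best] - scores[second], 0.0)
    return LocalizationResult(best + 1, second + 1, ascore)


def _placement_gap(
    peaks: np.ndarray,
    sequence: str,
    remnant: Modification,
    placement_a: frozenset,
    placement_b: frozenset,
    p_chance: float,
    fragment_da: float,
) -> float:
    """Binomial evidence gap (a minus b) between two remnant placements."""
    ions = {}
    for key, placement in (("a", placement_a), ("b", placement_b)):
        mods = [(pos, remnant) for pos in sorted(placement)]
        ions[key] = {round(m, 5) for _, _, m in fragment_ions(sequence, mods)}
    shared = ions["a"] & ions["b"]
    scores = {}
    for key in ("a", "b"):
        determining = sorted(ions[key] - shared)
        if not determining:
            scores[key] = 0.0
            continue
        k = count_matched_ions(determining, peaks[:, 0], fragment_da)
        p_val = stats.binom.sf(k - 1, len(determining), p_chance)
        scores[key] = min(-10.0 * np.log10(max(p_val, 1e-100)), ASCORE_UNAMBIGUOUS)
    return scores["a"] - scores["b"]


def localize_sites(
    spectrum: Spectrum,
    sequence: str,
    remnant: Modification,
    modified_sites: Sequence[int],
    candidate_sites: Sequence[int],
    peak_depth: int = 10,
    fragment_da: float = 0.8,
) -> list[tuple[int, float]]:
    """Per-site Ascores for a placement of one or more remnants.

    ``modified_sites`` is the matched placement (0-based), ``candidate_sites``
    every Cys in the peptide.  When every Cys carries a remnant there is no
    ambiguity and each site gets the sentinel score.  Otherwise each modified
    site is scored conservatively: the smallest evidence gap between the
    matched placement and any placement that relocates that one remnant to an
    unmodified Cys.  Returns ``[(site_0based, ascore), ...]``.
    """
    modified = frozenset(modified_sites)
    candidates = frozenset(candidate_sites)
    if not modified <= candidates:
        raise ValueError("modified sites must be candidate Cys positions")
    free = candidates - modified
    if not free:
        return [(pos, ASCORE_UNAMBIGUOUS) for pos in sorted(modified)]
    if len(modified) == 1:
        res = localize(
            spectrum, sequence, remnant, sorted(candidates),
            peak_depth=peak_depth, fragment_da=fragment_da,
        )
        return [(res.best_site - 1, res.ascore)]
    peaks = _top_peaks_per_window(spectrum.peaks, peak_depth)
    p_chance = peak_depth / 100.0
    out = []
    for pos in sorted(modified):
        gaps = [
            _placement_gap(
                peaks, sequence, remnant,
                modified, (modified - {pos}) | {alt},
                p_chance, fragment_da,
            )
            for alt in sorted(free)
        ]
        out.append((pos, max(min(gaps), 0.0)))
    return out


def _q_from_scores(target_scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """Target-decoy q-values, monotonized to be non-increasing in score."""
    target_scores = np.asarray(target_scores, dtype=float)
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    if target_scores.size == 0:
        raise ValueError("no target PSMs to assign q-values to")
    if decoy_scores.size == 0:
        warnings.warn("empty decoy set: q-values are uncalibrated zeros")
        return np.zeros_like(target_scores)
    order = np.argsort(target_scores)[::-1]  # descending score
    sorted_scores = target_scores[order]
    n_targets_ge = np.arange(1, sorted_scores.size + 1)
    # decoys with score >= s for each target threshold
    decoy_sorted = np.sort(decoy_scores)
    n_decoys_ge = decoy_sorted.size - np.searchsorted(
        decoy_sorted, sorted_scores, side="left"
    )
    fdr = n_decoys_ge / n_targets_ge
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(target_scores)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def assign_fdr(
    psms: Sequence[PSM],
    decoy_psms: Sequence[PSM],
    peptide_q: float = 0.05,
    protein_q: float = 0.02,
) -> list[PSM]:
    """Two-tier target-decoy filtering (peptide level, then protein level).

    Peptide-level q-values are assigned from the decoy score distribution and
    PSMs with q <= ``peptide_q`` are kept; each protein is then scored by its
    best retained peptide score, protein-level q-values are computed the same
    way against decoy proteins, and PSMs of proteins with q <= ``protein_q``
    are returned (with their peptide-level q filled in).
    """
    psms = list(psms)
    if not psms:
        raise ValueError("no target PSMs")
    q = _q_from_scores(
        np.array([p.score for p in psms]),
        np.array([p.score for p in decoy_psms]),
    )
    retained = []
    for psm, qi in zip(psms, q):
        psm.q_value = float(qi)
        if qi <= peptide_q:
            retained.append(psm)
    if not retained:
        return []

    def best_by_protein(items):
        best: dict[str, float] = {}
        for p in items:
            best[p.protein_id] = max(best.get(p.protein_id, -np.inf), p.score)
        return best

    target_best = best_by_protein(retained)
    decoy_best = best_by_protein(decoy_psms)
    proteins = sorted(target_best)
    prot_q = _q_from_scores(
        np.array([target_best[pid] for pid in proteins]),
        np.array(list(decoy_best.values())),
    )
    keep_proteins = {pid for pid, qi in zip(proteins, prot_q) if qi <= protein_q}
    return [p for p in retained if p.protein_id in keep_proteins]
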