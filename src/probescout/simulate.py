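"""Synthetic proteomes, labeling events, spectra, and feature-count matrices.

This module stands in for a raw chemoproteomics dataset while preserving the
statistical structure the pipeline assumes: a probe condition and a negative
control (an unrelated-recognition-element probe) across biological
replicates; probe-reactive Cys sites concentrated on a "DUB-like" protein
subset whose active-site Cys sits in a Lys/Arg-poor, Glu-containing window
(so the tryptic active-site peptide is long and a second Glu-C digestion
shortens it); overdispersed negative-binomial feature counts with a log2
enrichment effect on true targets; and fragment spectra with dropped ions
and uniform noise peaks.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import ProteinAnnotation
from .digestion import DigestionScheme, sequential_onbead_digest
from .masses import Modification, mz, peptide_mass
from .site_id import Spectrum

# Average amino-acid frequencies of a vertebrate proteome (Cys deliberately
# rare so that most labeled peptides carry a single candidate Cys).
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 3.6, 5.0, 4.0, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the modeled study: three biological replicates per
    condition, negative-binomial feature counts (mean 50, dispersion 0.2),
    a log2 enrichment effect of 3 on true probe targets, spectra with 70%
    fragment-ion retention and 5 noise peaks.
    """

    n_proteins: int = 40
    min_length: int = 80
    max_length: int = 240
    fraction_dub_like: float = 0.1
    probe_site_label_prob: float = 0.9
    background_label_prob: float = 0.05
    nb_mean: float = 50.0
    nb_dispersion: float = 0.2
    log2_effect: float = 3.0
    n_replicates: int = 3
    peak_retention: float = 0.7
    noise_peaks: int = 5
    precursor_jitter_ppm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.fraction_dub_like, self.probe_site_label_prob,
                  self.background_label_prob, self.peak_retention):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("NB mean and dispersion must be positive")
        if self.min_length < 60 or self.max_length < self.min_length:
            raise ValueError("infeasible protein length bounds (min >= 60)")


@dataclass
class GroundTruth:
    """Per-protein truth: class, reactive sites (0-based), enrichment effect."""

    class_label: dict = field(default_factory=dict)
    catalytic_sites: dict = field(default_factory=dict)  # id -> set of 0-based pos
    enriched: dict = field(default_factory=dict)  # id -> bool
    effect: dict = field(default_factory=dict)  # id -> log2 effect
    labeling_events: list = field(default_factory=list)  # planted (protein, pos, rep, cond)


# Active-site window: 45 residues free of K/R (long tryptic peptide) with Glu
# every ~8 residues (short Glu-C sub-peptides) and the catalytic Cys centered.
_WINDOW_LEN = 45
_WINDOW_E = (6, 14, 30, 38)
_WINDOW_C = 22


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


def _active_site_window(rng: np.random.Generator) -> str:
    pool = np.array([a for a in _AA if a not in "KRCE"])
    window = list(rng.choice(pool, size=_WINDOW_LEN))
    for pos in _WINDOW_E:
        window[pos] = "E"
    window[_WINDOW_C] = "C"
    return "".join(window)


def simulate_proteome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict, dict, GroundTruth]:
    """Generate a proteome with DUB-like and background proteins.

    Returns (proteome: id -> sequence, annotations: id -> ProteinAnnotation,
    truth).  DUB-like proteins carry a catalytic Cys inside the K/R-sparse,
    E-containing active-site window; they are the truly enriched targets.
    """
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_dub = int(round(config.fraction_dub_like * config.n_proteins))
    proteome: dict[str, str] = {}
    annotations: dict[str, ProteinAnnotation] = {}
    truth = GroundTruth()
    for i in range(config.n_proteins):
        is_dub = i < n_dub
        pid = f"{'DUB' if is_dub else 'BG'}{i:03d}"
        length = int(rng.integers(config.min_length, config.max_length + 1))
        seq = _random_sequence(rng, length)
        if is_dub:
            window = _active_site_window(rng)
            lo = 10
            hi = length - _WINDOW_LEN - 10
            start = int(rng.integers(lo, max(hi, lo + 1)))
            seq = seq[:start] + window + seq[start + _WINDOW_LEN:]
            cat = start + _WINDOW_C  # 0-based
            annotations[pid] = ProteinAnnotation(pid, "USP", frozenset({cat + 1}))
            truth.catalytic_sites[pid] = {cat}
            truth.class_label[pid] = "USP"
            truth.enriched[pid] = True
            truth.effect[pid] = config.log2_effect
        else:
            annotations[pid] = ProteinAnnotation(pid, "Other", frozenset())
            truth.catalytic_sites[pid] = set()
            truth.class_label[pid] = "Other"
            truth.enriched[pid] = False
            truth.effect[pid] = 0.0
        proteome[pid] = seq
    return proteome, annotations, truth


def simulate_labeling(
    proteome: Mapping[str, str],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
    condition: str,
    replicate: str,
) -> dict[str, list[int]]:
    """Draw labeled Cys positions for one replicate of one condition.

    Catalytic sites of enriched proteins are labeled with high probability in
    the probe condition only; every Cys can additionally pick up background
    labeling at the same low rate in both conditions (the control probe's
    electrophile is equally promiscuous).  Planted events are appended to
    ``truth.labeling_events``.
    """
    events: dict[str, list[int]] = {}
    for pid, seq in proteome.items():
        labeled = set()
        if condition == "probe":
            for pos in truth.catalytic_sites[pid]:
                if rng.random() < config.probe_site_label_prob:
                    labeled.add(pos)
        for pos, aa in enumerate(seq):
            if aa == "C" and pos not in labeled:
                if rng.random() < config.background_label_prob:
                    labeled.add(pos)
        if labeled:
            events[pid] = sorted(labeled)
            for pos in labeled:
                truth.labeling_events.append((pid, pos, replicate, condition))
    return events


def simulate_counts(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial feature-count matrix for probe vs control samples.

    Counts are NB(mean mu * 2^(effect * [enriched, probe sample]),
    dispersion phi) with variance mu + phi * mu^2.  Returns (counts frame
    proteins x samples, sample metadata frame).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    proteins = sorted(truth.class_label)
    samples, meta_rows = [], []
    for cond in ("probe", "control"):
        for r in range(1, config.n_replicates + 1):
            sid = f"{cond}_{r}"
            samples.append(sid)
            meta_rows.append(
                {"sample_id": sid, "condition": cond, "replicate": f"R{r}"}
            )
    phi = config.nb_dispersion
    size = 1.0 / phi
    data = np.zeros((len(proteins), len(samples)), dtype=int)
    for j, meta in enumerate(meta_rows):
        probe = meta["condition"] == "probe"
        for i, pid in enumerate(proteins):
            mu = config.nb_mean
            if probe and truth.enriched[pid]:
                mu = mu * 2.0 ** truth.effect[pid]
            p = size / (size + mu)
            data[i, j] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(data, index=proteins, columns=samples)
    return counts, pd.DataFrame(meta_rows)


def simulate_spectrum(
    peptide_sequence: str,
    mods: Sequence[tuple[int, Modification]],
    config: SimConfig,
    rng: np.random.Generator,
    spectrum_id: str,
    charge: int = 2,
    **spectrum_meta,
) -> Spectrum:
    """One fragment spectrum of a remnant-modified peptide.

    Singly-charged theoretical b/y ions are each retained with probability
    ``peak_retention``; ``noise_peaks`` uniform peaks are added over the ion
    m/z range; the precursor m/z is jittered within the configured ppm.
    """
    from .site_id import fragment_ions  # local import avoids cycle at import time

    ions = fragment_ions(peptide_sequence, mods, max_fragment_charge=1)
    mzs = np.array([m for _, _, m in ions])
    keep = rng.random(mzs.size) < config.peak_retention
    peaks = [(m, rng.uniform(0.4, 1.0)) for m in mzs[keep]]
    lo, hi = 100.0, float(mzs.max() + 200.0)
    for _ in range(config.noise_peaks):
        peaks.append((rng.uniform(lo, hi), rng.uniform(0.05, 0.6)))
    neutral = peptide_mass(peptide_sequence, mods)
    jitter = rng.uniform(-config.precursor_jitter_ppm, config.precursor_jitter_ppm)
    precursor = mz(neutral, charge) * (1.0 + jitter * 1e-6)
    peak_arr = (
        np.array(sorted(peaks)) if peaks else np.zeros((0, 2))
    )
    return Spectrum(
        id=spectrum_id,
        precursor_mz=precursor,
        precursor_charge=charge,
        peaks=peak_arr,
        **spectrum_meta,
    )


def simulate_experiment(
    config: SimConfig,
    scheme: DigestionScheme,
    rng: np.random.Generator | None = None,
) -> dict:
    """Full synthetic experiment: proteome, labeling, spectra, counts.

    For each (replicate, condition) a labeling draw is made, each labeled
    protein is run through the sequential on-bead digestion, and every
    cleaved-fraction peptide in the detectable length range (6-45, the
    practical LC-MS/MS window) yields one spectrum.  Returns a
    dict with proteome, annotations, truth, spectra (list of Spectrum), the
    planted evidence table, and the count matrix + metadata.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    proteome, annotations, truth = simulate_proteome(config, rng)
    spectra, evidence = [], []
    k = 0
    for r in range(1, config.n_replicates + 1):
        rep = f"R{r}"
        for cond in ("probe", "control"):
            labeling = simulate_labeling(proteome, truth, config, rng, cond, rep)
            for pid, positions in sorted(labeling.items()):
                frac = sequential_onbead_digest(pid, proteome[pid], positions, scheme)
                for pep, mods in frac.cleaved_fraction:
                    if not 6 <= len(pep) <= 45:
                        continue
                    k += 1
                    spec = simulate_spectrum(
                        pep.sequence,
                        mods,
                        config,
                        rng,
                        spectrum_id=f"scan{k:05d}",
                        sample_id=f"{cond}_{r}",
                        replicate=rep,
                        digestion_condition=scheme.name,
                    )
                    spectra.append(spec)
                    for off, _ in mods:
                        evidence.append(
                            {
                                "spectrum_id": spec.id,
                                "protein_id": pid,
                                "peptide": pep.sequence,
                                "start": pep.start + 1,
                                "end": pep.end,
                                "site": pep.start + off + 1,
                                "replicate": rep,
                                "condition": cond,
                                "scheme": scheme.name,
                            }
                        )
    counts, meta = simulate_counts(truth, config, rng)
    return {
        "proteome": proteome,
        "annotations": annotations,
        "truth": truth,
        "spectra": spectra,
        "evidence": pd.DataFrame(evidence),
        "counts": counts,
        "sample_metadata": meta,
    }
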