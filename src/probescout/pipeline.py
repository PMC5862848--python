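"""Search-space generation, identification, and the end-to-end pipeline.

`identify` is the stage that turns spectra into retained, localized PSMs:
candidate remnant-modified peptides are enumerated from the proteome (and a
reversed-sequence decoy proteome), matched per spectrum under the precursor
tolerance, scored by matched fragment ions, localized when the peptide has
more than one Cys, and filtered by the two-tier target-decoy FDR.
`run_pipeline` chains simulate -> identify -> aggregate -> enrich and writes
the report tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    aggregate_sites,
    classify_records,
    protein_identification_summary,
    summarize,
)
from .digestion import DigestionScheme, ENZYMES, digest
from .enrichment import FeatureEnrichment
from .masses import MatchTolerance, Modification, peptide_mass
from .site_id import PSM, Spectrum, assign_fdr, localize, localize_sites, match_spectrum
from .simulate import SimConfig, simulate_experiment
from . import io as psio

log = logging.getLogger("probescout")

DECOY_PREFIX = "rev_"


def reverse_proteome(proteome: Mapping[str, str]) -> dict[str, str]:
    """Whole-protein sequence reversal (decoy construction)."""
    return {DECOY_PREFIX + pid: seq[::-1] for pid, seq in proteome.items()}


@dataclass
class CandidateIndex:
    """Remnant-modified candidate peptides indexed by neutral mass."""

    masses: np.ndarray  # sorted
    candidates: list  # parallel: (PeptideInterval, mods, protein_id)

    def query(self, neutral_mass: float, ppm: float) -> list:
        half = neutral_mass * ppm * 1e-6
        lo = np.searchsorted(self.masses, neutral_mass - half, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + half, side="right")
        return self.candidates[lo:hi]


def build_candidate_index(
    proteome: Mapping[str, str],
    scheme: DigestionScheme,
    max_missed: int = 2,
    max_length: int = 60,
) -> CandidateIndex:
    """Enumerate Cys-containing peptides with remnant placements.

    Peptides come from a joint digest with every enzyme of the scheme (the
    cleaved-fraction boundaries are a refinement of these cut sites); every
    placement of 1-3 remnants on the peptide's Cys residues becomes a
    candidate (a bead-released peptide carries at least one label but may
    carry several).
    """
    from itertools import combinations

    enzymes = list(scheme.step1_enzymes)
    if scheme.step2_enzyme is not None:
        enzymes.append(scheme.step2_enzyme)
    entries = []
    for pid, seq in proteome.items():
        for pep in digest(seq, enzymes, max_missed, protein_id=pid):
            if len(pep) < 2 or len(pep) > max_length or "C" not in pep.sequence:
                continue
            cys = [off for off, aa in enumerate(pep.sequence) if aa == "C"]
            for k in range(1, min(len(cys), 3) + 1):
                for subset in combinations(cys, k):
                    mods = tuple((off, scheme.remnant) for off in subset)
                    entries.append(
                        (peptide_mass(pep.sequence, mods), (pep, mods, pid))
                    )
    entries.sort(key=lambda e: e[0])
    return CandidateIndex(
        masses=np.array([e[0] for e in entries]),
        candidates=[e[1] for e in entries],
    )


def identify(
    spectra: Sequence[Spectrum],
    proteome: Mapping[str, str],
    scheme: DigestionScheme,
    tol: MatchTolerance = MatchTolerance(),
    min_score: int = 1,
    peptide_q: float = 0.05,
    protein_q: float = 0.02,
    max_missed: int = 2,
) -> tuple[list[PSM], list[PSM], list[PSM]]:
    """Search spectra against target and decoy proteomes; filter by FDR.

    Target and decoy candidates compete per spectrum: the spectrum keeps its
    single best PSM (ties go to the target), so a decoy PSM estimates the
    chance that a random peptide outscores every true candidate.  Returns
    (retained_psms, all_target_psms, decoy_psms).  Each target PSM whose
    peptide carries more than one Cys gets a localization result; a
    single-Cys peptide is trivially localized.
    """
    target_index = build_candidate_index(proteome, scheme, max_missed)
    decoy_index = build_candidate_index(
        reverse_proteome(proteome), scheme, max_missed
    )
    target_psms, decoy_psms = [], []
    for spec in spectra:
        neutral = spec.neutral_mass
        t_cands = target_index.query(neutral, tol.precursor_ppm)
        d_cands = decoy_index.query(neutral, tol.precursor_ppm)
        t_best = match_spectrum(spec, t_cands, tol) if t_cands else None
        d_best = match_spectrum(spec, d_cands, tol) if d_cands else None
        if d_best is not None and (t_best is None or d_best.score > t_best.score):
            if d_best.score >= min_score:
                d_best.is_decoy = True
                decoy_psms.append(d_best)
        elif t_best is not None and t_best.score >= min_score:
            sites = [i for i, aa in enumerate(t_best.peptide.sequence) if aa == "C"]
            modified = [pos for pos, _ in t_best.mods]
            t_best.localized_sites = localize_sites(
                spec,
                t_best.peptide.sequence,
                scheme.remnant,
                modified,
                sites,
                fragment_da=tol.fragment_da,
            )
            if len(modified) == 1:
                t_best.localization = localize(
                    spec,
                    t_best.peptide.sequence,
                    scheme.remnant,
                    sites,
                    fragment_da=tol.fragment_da,
                )
            target_psms.append(t_best)
    if not target_psms:
        return [], [], decoy_psms
    retained = assign_fdr(target_psms, decoy_psms, peptide_q, protein_q)
    return retained, target_psms, decoy_psms


# ---------------------------------------------------------------------------
# digestion scheme construction


def make_scheme(
    name: str,
    step1: Sequence[str],
    remnant: Modification,
    step2: str | None = None,
    step1_max_missed: int = 2,
    step2_max_missed: int = 2,
) -> DigestionScheme:
    """Build a DigestionScheme from enzyme names (see ``digestion.ENZYMES``)."""
    return DigestionScheme(
        name=name,
        step1_enzymes=tuple(ENZYMES[e] for e in step1),
        remnant=remnant,
        step1_max_missed=step1_max_missed,
        step2_enzyme=ENZYMES[step2] if step2 else None,
        step2_max_missed=step2_max_missed,
    )


def default_schemes(remnant: Modification) -> list[DigestionScheme]:
    """The three digestion conditions of the modeled workflow."""
    return [
        make_scheme("trypsin_lysC", ("trypsin", "lysC"), remnant),
        make_scheme("trypsin_lysC_gluC", ("trypsin", "lysC"), remnant, step2="gluC"),
        make_scheme(
            "trypsin_lysC_chymo", ("trypsin", "lysC"), remnant, step2="chymotrypsin"
        ),
    ]


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(config: Mapping, out_dir) -> dict:
    """Simulate -> identify -> aggregate -> enrich; write all reports.

    ``config`` holds a ``simulation`` section (SimConfig fields), optional
    ``scheme`` (step1 enzymes / step2 enzyme), tolerances, FDR thresholds and
    a seed.  Returns the in-memory results dict and writes TSV/JSON reports
    under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim_cfg = SimConfig(**{**config.get("simulation", {}), "seed": seed})
    from .masses import load_modification_registry

    registry = load_modification_registry()
    remnant = registry[config.get("remnant", "vps_dadps")]
    scheme_cfg = config.get("scheme", {})
    scheme = make_scheme(
        scheme_cfg.get("name", "trypsin_lysC_gluC"),
        scheme_cfg.get("step1", ("trypsin", "lysC")),
        remnant,
        step2=scheme_cfg.get("step2", "gluC"),
    )
    tol = MatchTolerance(
        precursor_ppm=float(config.get("precursor_ppm", 50.0)),
        fragment_da=float(config.get("fragment_da", 0.8)),
    )

    stages = {}
    t0 = time.time()
    exp = simulate_experiment(sim_cfg, scheme)
    stages["simulate"] = {"seconds": time.time() - t0, "spectra": len(exp["spectra"])}
    log.info("simulate: %d spectra", len(exp["spectra"]))

    t0 = time.time()
    retained, targets, decoys = identify(
        exp["spectra"],
        exp["proteome"],
        scheme,
        tol,
        peptide_q=float(config.get("peptide_fdr", 0.05)),
        protein_q=float(config.get("protein_fdr", 0.02)),
    )
    stages["identify"] = {
        "seconds": time.time() - t0,
        "retained_psms": len(retained),
        "target_psms": len(targets),
        "decoy_psms": len(decoys),
    }

    t0 = time.time()
    records = aggregate_sites(retained)
    records = classify_records(records, exp["annotations"])
    summary = summarize(records, exp["annotations"])
    stages["aggregate"] = {"seconds": time.time() - t0, "site_records": len(records)}

    t0 = time.time()
    model = FeatureEnrichment(exp["counts"], exp["sample_metadata"])
    results = model.fit()
    hc = {r.protein_id: r.high_confidence for r in records}
    volcano = results.as_frame(site_flags=hc)
    stages["enrich"] = {"seconds": time.time() - t0, "proteins": len(volcano)}

    cfg = dict(config)
    psm_rows = pd.DataFrame(
        [
            {
                "spectrum_id": p.spectrum_id,
                "protein_id": p.protein_id,
                "peptide": p.peptide.sequence,
                "start": p.peptide.start + 1,
                "end": p.peptide.end,
                "site": p.peptide.start + p.localization.best_site
                if p.localization
                else None,
                "score": p.score,
                "ascore": p.localization.ascore if p.localization else None,
                "q": p.q_value,
                "replicate": p.replicate,
                "condition": p.digestion_condition,
            }
            for p in retained
        ]
    )
    site_rows = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "site": r.site,
                "n_replicates": len(r.replicates_observed),
                "high_confidence": r.high_confidence,
                "classification": r.classification,
            }
            for r in records
        ]
    )
    psio.write_table(psm_rows, out / "psms.tsv", cfg, seed)
    psio.write_table(site_rows, out / "sites.tsv", cfg, seed)
    psio.write_table(volcano, out / "volcano.tsv", cfg, seed)
    psio.write_table(
        protein_identification_summary(targets), out / "protein_ids.tsv", cfg, seed
    )
    with open(out / "summary.json", "w") as fh:
        json.dump({"summary": summary, "stages": stages}, fh, indent=2, default=str)
    return {
        "experiment": exp,
        "retained_psms": retained,
        "records": records,
        "summary": summary,
        "volcano": volcano,
        "stages": stages,
    }
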