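"""Aggregate retained PSMs into per-site records and summary counts.

A probe-labeling site is called high-confidence when it was observed in more
than one biological replicate (digestion conditions within one replicate do
not count toward this).  Sites on annotated proteins are classified as
catalytic (the annotated active-site Cys) or non-catalytic; everything else
is unannotated.  Protein-level identification uses the >= 3 unique peptides
rule, with a feature defined at the peptide-form level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .site_id import PSM

#: Ascore below which a PSM's site is considered ambiguously localized
#: (~ p-value gap of 0.05); such PSMs support protein evidence but not sites.
DEFAULT_MIN_ASCORE = 13.0

DUB_CLASSES = ("USP", "OTU", "UCH", "JOS")


@dataclass(frozen=True)
class ProteinAnnotation:
    """Protein class label plus its annotated catalytic Cys positions (1-based)."""

    protein_id: str
    protein_class: str = "Other"
    catalytic_cys: frozenset = frozenset()

    def __post_init__(self):
        if any(p < 1 for p in self.catalytic_cys):
            raise ValueError("catalytic positions are 1-based (must be >= 1)")


@dataclass
class SiteRecord:
    """An aggregated probe-labeling site on a protein."""

    protein_id: str
    site: int  # 1-based Cys position
    replicates_observed: set = field(default_factory=set)
    conditions_observed: set = field(default_factory=set)
    high_confidence: bool = False
    classification: str = "unannotated"


def aggregate_sites(
    retained_psms: Sequence[PSM],
    min_ascore: float = DEFAULT_MIN_ASCORE,
    min_replicates_high_confidence: int = 2,
) -> list[SiteRecord]:
    """Merge localized PSMs into one record per (protein, site).

    Only PSMs whose localization clears ``min_ascore`` contribute; replicate
    and condition sets are unioned across PSMs and the high-confidence flag
    requires observation in at least ``min_replicates_high_confidence``
    distinct biological replicates.  Output is sorted by (protein, site).
    """
    records: dict[tuple[str, int], SiteRecord] = {}
    for psm in retained_psms:
        if psm.localized_sites is not None:
            sites = [
                (psm.peptide.start + pos + 1, ascore)
                for pos, ascore in psm.localized_sites
            ]
        elif psm.localization is not None:
            sites = [
                (psm.peptide.start + psm.localization.best_site,
                 psm.localization.ascore)
            ]
        else:
            continue
        if not psm.replicate:
            raise ValueError(f"PSM {psm.spectrum_id} lacks a replicate id")
        for site, ascore in sites:
            if ascore < min_ascore:
                continue
            key = (psm.protein_id, site)
            rec = records.setdefault(key, SiteRecord(psm.protein_id, site))
            rec.replicates_observed.add(psm.replicate)
            if psm.digestion_condition:
                rec.conditions_observed.add(psm.digestion_condition)
    for rec in records.values():
        rec.high_confidence = (
            len(rec.replicates_observed) >= min_replicates_high_confidence
        )
    return [records[k] for k in sorted(records)]


def classify_site(
    record: SiteRecord, annotation: ProteinAnnotation | None
) -> str:
    """catalytic / non_catalytic / unannotated for one site record."""
    if annotation is None:
        return "unannotated"
    if record.site in annotation.catalytic_cys:
        return "catalytic"
    return "non_catalytic"


def classify_records(
    records: Iterable[SiteRecord],
    annotations: Mapping[str, ProteinAnnotation],
) -> list[SiteRecord]:
    """Fill the classification field of every record in place."""
    records = list(records)
    for rec in records:
        rec.classification = classify_site(rec, annotations.get(rec.protein_id))
    return records


def summarize(
    records: Sequence[SiteRecord],
    annotations: Mapping[str, ProteinAnnotation],
    class_filter: Sequence[str] | None = None,
    high_confidence_only: bool = True,
) -> dict:
    """Headline counts over aggregated site records.

    Returns proteins with >= 1 (high-confidence) site, proteins with >= 1
    (high-confidence) non-catalytic site, per-class breakdowns, and a
    sites-per-protein table.  ``class_filter`` restricts protein classes
    (e.g. the four Cys-protease deubiquitinase classes).
    """
    records = classify_records(records, annotations)
    rows = []
    for rec in records:
        ann = annotations.get(rec.protein_id)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "class": ann.protein_class if ann else "Other",
                "site": rec.site,
                "high_confidence": rec.high_confidence,
                "classification": rec.classification,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "class", "site", "high_confidence", "classification"],
    )
    df["high_confidence"] = df["high_confidence"].astype(bool)
    if class_filter is not None:
        df = df[df["class"].isin(class_filter)]
    eligible = df[df["high_confidence"]] if high_confidence_only else df

    proteins_with_site = eligible["protein_id"].nunique()
    noncat = eligible[eligible["classification"] == "non_catalytic"]
    per_class = (
        eligible.groupby("class")["protein_id"].nunique().to_dict()
        if not eligible.empty
        else {}
    )
    sites_per_protein = (
        df.groupby("protein_id")["site"].nunique().to_dict() if not df.empty else {}
    )
    return {
        "proteins_with_site": int(proteins_with_site),
        "proteins_with_noncatalytic_site": int(noncat["protein_id"].nunique()),
        "per_class": {k: int(v) for k, v in per_class.items()},
        "sites_per_protein": {k: int(v) for k, v in sites_per_protein.items()},
        "n_sites": int(len(eligible)),
    }


def protein_identification_summary(
    psms: Sequence[PSM], threshold: int = 3
) -> pd.DataFrame:
    """Per-(protein, sample) unique-peptide counts with the identification flag.

    Unique peptides are distinct (sequence, modification set) forms; a protein
    is identified in a sample when it has at least ``threshold`` of them.
    """
    forms: dict[tuple[str, str], set] = {}
    for psm in psms:
        mod_key = tuple(sorted((pos, mod.name) for pos, mod in psm.mods))
        forms.setdefault((psm.protein_id, psm.sample_id), set()).add(
            (psm.peptide.sequence, mod_key)
        )
    rows = [
        {
            "protein_id": pid,
            "sample_id": sid,
            "unique_peptide_count": len(s),
            "identified": len(s) >= threshold,
        }
        for (pid, sid), s in sorted(forms.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "sample_id", "unique_peptide_count", "identified"],
    )


def records_from_table(df: pd.DataFrame) -> list[SiteRecord]:
    """Build SiteRecords from a curated site table.

    Expects columns ``protein, class, site, high_confidence, non_catalytic``;
    replicate sets are synthesized to be consistent with the high-confidence
    flag (two pseudo-replicates for high-confidence sites, one otherwise).
    """
    records = []
    for row in df.itertuples(index=False):
        hc = bool(row.high_confidence)
        rec = SiteRecord(
            protein_id=str(row.protein),
            site=int(row.site),
            replicates_observed={"I", "II"} if hc else {"I"},
            high_confidence=hc,
        )
        records.append(rec)
    return sorted(records, key=lambda r: (r.protein_id, r.site))


def annotations_from_table(df: pd.DataFrame) -> dict[str, ProteinAnnotation]:
    """Derive per-protein annotations from a curated site table.

    For deubiquitinase-class proteins the catalytic Cys set is the sites not
    flagged non-catalytic; proteins of class Other use the dagger flag
    (catalytic residue of a non-DUB) where present.
    """
    anns = {}
    for pid, sub in df.groupby("protein"):
        cls = sub["class"].iloc[0]
        if cls in DUB_CLASSES:
            catalytic = frozenset(
                int(s) for s, nc in zip(sub["site"], sub["non_catalytic"]) if not nc
            )
        else:
            dag = sub.get("catalytic_of_non_dub")
            catalytic = (
                frozenset(int(s) for s, d in zip(sub["site"], dag) if d)
                if dag is not None
                else frozenset()
            )
        anns[str(pid)] = ProteinAnnotation(str(pid), str(cls), catalytic)
    return anns
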