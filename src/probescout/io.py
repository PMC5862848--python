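"""File I/O and packaged fixtures: FASTA, MGF, TSV tables, YAML config.

FASTA goes through Biopython, MGF through pyteomics; tables are plain TSV.
Every table written by the pipeline carries a header comment with the tool
version, a config hash, and the seed so runs are attributable.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from . import __version__
from .aggregation import ProteinAnnotation, SiteRecord, annotations_from_table, records_from_table
from .site_id import Spectrum


def read_fasta(path) -> dict[str, str]:
    """Read a proteome FASTA into an ordered id -> sequence mapping.

    The id is the first whitespace token of the header; sequences are
    upper-cased; duplicate ids raise.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        proteome[rec.id] = str(rec.seq).upper()
    return proteome


def write_fasta(proteome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF (BEGIN IONS / TITLE / PEPMASS / CHARGE blocks)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                    "sample": s.sample_id,
                    "replicate": s.replicate,
                    "condition": s.digestion_condition,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 2
            pepmass = params["pepmass"]
            spectra.append(
                Spectrum(
                    id=str(params.get("title", f"scan{len(spectra)}")),
                    precursor_mz=float(pepmass[0] if isinstance(pepmass, tuple) else pepmass),
                    precursor_charge=charge,
                    peaks=np.column_stack(
                        [entry["m/z array"], entry["intensity array"]]
                    )
                    if len(entry["m/z array"])
                    else np.zeros((0, 2)),
                    sample_id=str(params.get("sample", "")),
                    replicate=str(params.get("replicate", "")),
                    digestion_condition=str(params.get("condition", "")),
                )
            )
    return spectra


def read_annotations(path) -> dict[str, ProteinAnnotation]:
    """TSV of protein_id, class, catalytic sites (semicolon-joined, 1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    anns = {}
    for row in df.itertuples(index=False):
        sites = frozenset(
            int(s) for s in str(getattr(row, "catalytic_cys", "") or "").split(";") if s
        )
        anns[row.protein_id] = ProteinAnnotation(
            row.protein_id, getattr(row, "protein_class", "Other"), sites
        )
    return anns


# ---------------------------------------------------------------------------
# packaged curated site-table fixture


def table1_frame() -> pd.DataFrame:
    """The curated probe-labeling-site table packaged with the module."""
    src = importlib.resources.files("probescout.data") / "table1_sites.tsv"
    with importlib.resources.as_file(src) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_table1_fixture() -> tuple[list[SiteRecord], dict[str, ProteinAnnotation]]:
    """Site records + derived annotations from the curated site table."""
    df = table1_frame()
    return records_from_table(df), annotations_from_table(df)


# ---------------------------------------------------------------------------
# provenance-stamped table output


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path, config: Mapping | None = None, seed=None
) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# probescout {__version__}"
        f" config={config_hash(config) if config else 'n/a'} seed={seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
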