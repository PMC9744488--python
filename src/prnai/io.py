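"""TSV schemas and readers for the experiment tables.

All interchange files are plain tab-separated text:

* sample sheet   : sample_id, gene, treatment, stage_start_h, stage_end_h,
                   collection_date, bio_replicate
* amplicon sheet : name, gene, start, end, role in {qpcr, dsrna, reference}
* well table     : sample_id, amplicon, tech_replicate, cp, efficiency,
                   qc_pass
* raw curves     : sample_id, amplicon, tech_replicate, cycle, fluorescence
* collections    : treatment, start_dpi, end_dpi, wt_hatched, wt_unhatched,
                   phen_cat1, phen_cat2, nonspecific, empty
* cohort log     : day, females_alive, female_deaths, eggs
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .penetrance import CATEGORIES, CohortLog, CollectionRecord
from .qpcr import Amplicon, DsRnaRegion

SCHEMAS = {
    "samples": ["sample_id", "gene", "treatment", "stage_start_h",
                "stage_end_h", "collection_date", "bio_replicate"],
    "amplicons": ["name", "gene", "start", "end", "role"],
    "wells": ["sample_id", "amplicon", "tech_replicate", "cp", "efficiency"],
    "curves": ["sample_id", "amplicon", "tech_replicate", "cycle", "fluorescence"],
    "collections": ["treatment", "start_dpi", "end_dpi", *CATEGORIES],
    "cohort": ["day", "females_alive", "female_deaths", "eggs"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the interchange TSVs, checking its required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing {kind} columns {missing}")
    return df


def amplicons_from_sheet(sheet: pd.DataFrame) -> tuple[list[Amplicon], DsRnaRegion | None]:
    """Split an amplicon sheet into qPCR/reference amplicons and the dsRNA region."""
    amps = [
        Amplicon(r["name"], r["gene"], int(r["start"]), int(r["end"]))
        for _, r in sheet.iterrows() if r.get("role", "qpcr") != "dsrna"
    ]
    ds = sheet[sheet["role"] == "dsrna"] if "role" in sheet.columns else sheet.iloc[0:0]
    region = None
    if not ds.empty:
        row = ds.iloc[0]
        region = DsRnaRegion(row["gene"], int(row["start"]), int(row["end"]))
    return amps, region


def collections_from_table(df: pd.DataFrame) -> list[CollectionRecord]:
    return [
        CollectionRecord(
            treatment=r["treatment"], start_dpi=float(r["start_dpi"]),
            end_dpi=float(r["end_dpi"]),
            **{c: int(r[c]) for c in CATEGORIES},
        )
        for _, r in df.iterrows()
    ]


def cohort_from_table(df: pd.DataFrame) -> CohortLog:
    n_initial = int(df["females_alive"].iloc[0] + df["female_deaths"].iloc[0])
    return CohortLog(
        days=df["day"].to_numpy(),
        female_deaths=df["female_deaths"].to_numpy(),
        eggs=df["eggs"].to_numpy(),
        n_initial=n_initial,
    )
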