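"""Packaged reference fixtures: published differential-sialylation result lists.

Two small TSV tables ship with the package: the peptides with significantly
*increased* sialylated N-glycans in ST3GAL4-overexpressing gastric carcinoma
cells versus mock control, and the two with *decreased* sialylation.  They
are transcriptions of published result lists (peptide sequences carry ``de``
deamidation tags; fold changes are ST3GAL4/mock on the linear scale) and are
used as ground truth for the sequence parser, sequon logic and summary
operations — the raw MS data behind them are not redistributable, so the
statistical pipeline itself is validated on synthetic data instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .ingest import find_sequons, parse_modified_sequence

__all__ = [
    "load_increased_table",
    "load_decreased_table",
    "FixtureSummary",
    "summarize_fixture",
    "validate_fixture_sequons",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("sialoquant.data").joinpath(name).open("r") as fh:
        table = pd.read_csv(fh, sep="\t")
    table["fold_change"] = table["fold_change"].astype(float)
    table["p_value"] = table["p_value"].astype(float)
    return table


def load_increased_table() -> pd.DataFrame:
    """Peptides with significantly increased N-glycan sialylation (47 proteins)."""
    return _load("increased_sialylation.tsv")


def load_decreased_table() -> pd.DataFrame:
    """Peptides with significantly decreased N-glycan sialylation."""
    return _load("decreased_sialylation.tsv")


@dataclass(frozen=True)
class FixtureSummary:
    n_rows: int
    n_proteins: int
    max_fold_change: float
    min_fold_change: float
    min_p_value: float
    sequon_status_counts: dict


def summarize_fixture(table: pd.DataFrame) -> FixtureSummary:
    """Summary statistics computed purely from a packaged fixture table."""
    statuses: dict[str, int] = {}
    for status in validate_fixture_sequons(table)["best_status"]:
        statuses[status] = statuses.get(status, 0) + 1
    return FixtureSummary(
        n_rows=len(table),
        n_proteins=table["accession"].nunique(),
        max_fold_change=float(table["fold_change"].max()),
        min_fold_change=float(table["fold_change"].min()),
        min_p_value=float(table["p_value"].min()),
        sequon_status_counts=statuses,
    )


_STATUS_ORDER = {"valid": 0, "potential_NG": 1, "indeterminate_terminal": 2, "invalid": 3}


def validate_fixture_sequons(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row sequon validation of a fixture table.

    Each row's peptide is parsed and every deamidated Asn classified.  The
    printed site number cannot be located inside the peptide without the
    protein sequence, so a row validates through its *best* deamidated
    position: a row whose best status is ``valid`` or ``potential_NG``
    contains a bona fide glyco-candidate sequon, which is the sorting
    criterion the lists were built with.  All per-position statuses are
    returned alongside.
    """
    rows = []
    for _, rec in table.iterrows():
        pep = parse_modified_sequence(rec["sequence"])
        calls = find_sequons(pep)
        statuses = [c.status for c in calls]
        best = min(statuses, key=_STATUS_ORDER.__getitem__) if statuses else "invalid"
        rows.append(
            {
                "accession": rec["accession"],
                "sequence": rec["sequence"],
                "site": rec["site"],
                "positions": ";".join(str(c.position) for c in calls),
                "statuses": ";".join(statuses),
                "best_status": best,
                "is_glyco_candidate": best in ("valid", "potential_NG"),
            }
        )
    return pd.DataFrame(rows)
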