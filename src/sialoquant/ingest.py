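"""Identified-PSM ingestion, quality filtering and N-glycosequon detection.

The input is a table of identified spectra (PSMs) exported by the search
platform, with peptide sequences carrying ``de`` tags immediately after
deamidated residues (``ISVAGRNdeCSFQPER``).  PNGase F release of an N-glycan
converts the glycosylated Asn to Asp, which the search engine detects as
deamidation, so a deamidated Asn inside the N-glycosylation consensus motif
(sequon) N-X-[S/T/C] with X != P marks a former glycosite.  Deamidation also
happens spontaneously, most readily before glycine, so N-G-[S/T/C] sites are
only *potential* glycosites and are flagged as such.

PSM-level quality control applies the search-platform score thresholds:
Percolator q <= 0.01, rank 1 in both engines, SEQUEST HT deltaCn >= 0.1,
Mascot ion score >= 18, and charge-dependent XCorr strictly above
1.5 / 2.0 / 2.25 / 2.5 for 1+ .. 4+.  Boundary semantics follow the wording
those thresholds were published with: the Mascot cutoff is inclusive, the
XCorr cutoffs are strict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "XCORR_THRESHOLDS",
    "PSMRecord",
    "ParsedPeptide",
    "SequonCall",
    "SiteMapping",
    "FilterReport",
    "parse_modified_sequence",
    "render_modified_sequence",
    "psm_filter",
    "find_sequons",
    "map_site_to_protein",
    "read_psm_table",
    "read_fasta",
    "sequon_report",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Charge-state specific SEQUEST XCorr cutoffs (strict lower bounds).
XCORR_THRESHOLDS: Mapping[int, float] = {1: 1.5, 2: 2.0, 3: 2.25, 4: 2.5}

#: Filter rules in the order rejections are attributed.
FILTER_RULES: tuple[str, ...] = (
    "charge_unsupported",
    "percolator_q",
    "rank",
    "delta_cn",
    "mascot_score",
    "xcorr",
)


@dataclass(frozen=True)
class PSMRecord:
    """One identified spectrum with its engine scores and reporter intensities."""

    modified_sequence: str
    accession: str
    charge: int
    percolator_q: float
    mascot_rank: int
    sequest_rank: int
    delta_cn: float
    mascot_score: float
    xcorr: float
    reporter_intensities: tuple[float, ...]
    run_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.percolator_q <= 1):
            raise ValueError(f"q-value out of [0,1]: {self.percolator_q}")
        if any(x < 0 for x in self.reporter_intensities):
            raise ValueError("reporter intensities must be non-negative")


@dataclass(frozen=True)
class ParsedPeptide:
    """A peptide with its deamidation marks resolved to positions.

    ``deamidated`` holds 1-based positions of deamidated Asn; deamidation on
    Gln is chemically possible and parsed, but Gln cannot carry an N-glycan,
    so those positions are kept separately and ignored by sequon logic.
    """

    plain: str
    deamidated: frozenset[int] = frozenset()
    deamidated_q: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        illegal = set(self.plain) - AMINO_ACIDS
        if illegal:
            raise ValueError(f"non-standard residues {sorted(illegal)} in {self.plain!r}")
        for pos in self.deamidated:
            if not (1 <= pos <= len(self.plain)) or self.plain[pos - 1] != "N":
                raise ValueError(f"deamidated position {pos} is not an N in {self.plain!r}")
        for pos in self.deamidated_q:
            if not (1 <= pos <= len(self.plain)) or self.plain[pos - 1] != "Q":
                raise ValueError(f"deamidated position {pos} is not a Q in {self.plain!r}")


@dataclass(frozen=True)
class SequonCall:
    """Sequon status of one deamidated Asn within its peptide."""

    position: int  # 1-based in the plain peptide
    status: str  # valid | potential_NG | invalid | indeterminate_terminal
    protein_site: str | None = None  # e.g. "N844" once mapped


@dataclass(frozen=True)
class SiteMapping:
    sites: tuple[str, ...]
    ambiguous: bool


@dataclass
class FilterReport:
    kept: list[PSMRecord]
    rejected: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


def parse_modified_sequence(text: str) -> ParsedPeptide:
    """Strip ``de`` deamidation tags from a modified peptide string.

    Each ``de`` must directly follow the N (or Q) it modifies, as in
    ``TYNdeGTNdePDAASR`` -> plain ``TYNGTNPDAASR`` with Asn 3 and 6 deamidated.
    """
    if not text:
        raise ValueError("empty peptide string")
    plain: list[str] = []
    deamidated_n: set[int] = set()
    deamidated_q: set[int] = set()
    i = 0
    while i < len(text):
        if text.startswith("de", i):
            if not plain:
                raise ValueError(f"'de' tag at start of {text!r}")
            residue = plain[-1]
            if residue == "N":
                deamidated_n.add(len(plain))
            elif residue == "Q":
                deamidated_q.add(len(plain))
            else:
                raise ValueError(f"'de' tag follows {residue!r}, not N/Q, in {text!r}")
            i += 2
            continue
        ch = text[i]
        if ch not in AMINO_ACIDS:
            raise ValueError(f"illegal character {ch!r} in {text!r}")
        plain.append(ch)
        i += 1
    return ParsedPeptide("".join(plain), frozenset(deamidated_n), frozenset(deamidated_q))


def render_modified_sequence(pep: ParsedPeptide) -> str:
    """Inverse of :func:`parse_modified_sequence` (round-trips the tags)."""
    out = []
    marked = pep.deamidated | pep.deamidated_q
    for i, residue in enumerate(pep.plain, start=1):
        out.append(residue)
        if i in marked:
            out.append("de")
    return "".join(out)


def _first_failed_rule(rec: PSMRecord) -> str | None:
    if rec.charge not in XCORR_THRESHOLDS:
        return "charge_unsupported"
    if rec.percolator_q > 0.01:
        return "percolator_q"
    if rec.mascot_rank != 1 or rec.sequest_rank != 1:
        return "rank"
    if rec.delta_cn < 0.1:
        return "delta_cn"
    if rec.mascot_score < 18.0:
        return "mascot_score"
    if rec.xcorr <= XCORR_THRESHOLDS[rec.charge]:
        return "xcorr"
    return None


def psm_filter(records: Iterable[PSMRecord]) -> FilterReport:
    """Apply all PSM quality rules; attribute each rejection to its first failed rule."""
    report = FilterReport(kept=[], rejected={rule: 0 for rule in FILTER_RULES})
    for rec in records:
        rule = _first_failed_rule(rec)
        if rule is None:
            report.kept.append(rec)
        else:
            report.rejected[rule] += 1
    return report


def find_sequons(pep: ParsedPeptide) -> list[SequonCall]:
    """Classify every deamidated Asn of a peptide against the sequon motif.

    N-X-[S/T/C] with X != P is ``valid``; N-G-[S/T/C] is ``potential_NG``
    (spontaneous deamidation is frequent before Gly); a sequon running past
    the peptide's C-terminus is ``indeterminate_terminal`` because the next
    residues are unknown without the protein context.
    """
    calls = []
    seq = pep.plain
    for pos in sorted(pep.deamidated):
        if pos + 2 > len(seq):
            status = "indeterminate_terminal"
        else:
            x, third = seq[pos], seq[pos + 1]
            if x == "P" or third not in "STC":
                status = "invalid"
            elif x == "G":
                status = "potential_NG"
            else:
                status = "valid"
        calls.append(SequonCall(pos, status))
    return calls


def map_site_to_protein(pep: ParsedPeptide, position: int, protein_sequence: str) -> SiteMapping:
    """Locate a peptide in its protein and convert a peptide position to a site label.

    Returns all candidate sites (``N<residue number>``, 1-based over the
    supplied sequence) and flags ambiguity when the peptide occurs more than
    once.  Raises when the peptide is absent.
    """
    if not (1 <= position <= len(pep.plain)):
        raise ValueError(f"position {position} outside peptide of length {len(pep.plain)}")
    offsets = [m.start() for m in re.finditer(f"(?={re.escape(pep.plain)})", protein_sequence)]
    if not offsets:
        raise ValueError(f"peptide {pep.plain!r} not found in protein sequence")
    residue = pep.plain[position - 1]
    sites = tuple(f"{residue}{off + position}" for off in offsets)
    return SiteMapping(sites, ambiguous=len(offsets) > 1)


# ---------------------------------------------------------------------------
# File I/O

#: Required columns of a PSM table and their record fields.
PSM_COLUMNS: Mapping[str, str] = {
    "modified_sequence": "modified_sequence",
    "accession": "accession",
    "charge": "charge",
    "percolator_q": "percolator_q",
    "mascot_rank": "mascot_rank",
    "sequest_rank": "sequest_rank",
    "delta_cn": "delta_cn",
    "mascot_score": "mascot_score",
    "xcorr": "xcorr",
    "run_id": "run_id",
}


def read_psm_table(path, sep: str = "\t") -> list[PSMRecord]:
    """Read a delimited PSM table.

    Reporter intensities are taken from every column named ``reporter_*``
    (sorted by channel label); missing intensities may be blank and propagate
    as NaN.
    """
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table is missing columns: {missing}")
    reporter_cols = sorted(c for c in table.columns if c.startswith("reporter_"))
    if not reporter_cols:
        raise ValueError("PSM table has no reporter_* intensity columns")
    records = []
    for _, row in table.iterrows():
        intensities = tuple(float(row[c]) for c in reporter_cols)
        records.append(
            PSMRecord(
                modified_sequence=str(row["modified_sequence"]),
                accession=str(row["accession"]),
                charge=int(row["charge"]),
                percolator_q=float(row["percolator_q"]),
                mascot_rank=int(row["mascot_rank"]),
                sequest_rank=int(row["sequest_rank"]),
                delta_cn=float(row["delta_cn"]),
                mascot_score=float(row["mascot_score"]),
                xcorr=float(row["xcorr"]),
                reporter_intensities=intensities,
                run_id=str(row["run_id"]),
            )
        )
    return records


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by the first word of each FASTA header."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def sequon_report(records: Iterable[PSMRecord], proteins: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tabulate sequon calls for the deamidated peptides of a PSM set.

    One row per (accession, peptide, deamidated position); protein sites are
    resolved when the accession's sequence is supplied.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.accession, rec.modified_sequence)
        if key in seen:
            continue
        seen.add(key)
        pep = parse_modified_sequence(rec.modified_sequence)
        for call in find_sequons(pep):
            site, ambiguous = "", False
            if proteins and rec.accession in proteins:
                mapping = map_site_to_protein(pep, call.position, proteins[rec.accession])
                site, ambiguous = ";".join(mapping.sites), mapping.ambiguous
            rows.append(
                {
                    "accession": rec.accession,
                    "peptide": rec.modified_sequence,
                    "position": call.position,
                    "status": call.status,
                    "protein_site": site,
                    "ambiguous": ambiguous,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["accession", "peptide", "position", "status", "protein_site", "ambiguous"],
    )
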