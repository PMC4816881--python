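"""End-to-end differential-sialylation pipeline and run reporting.

Order of operations, mirroring the analysis this package reproduces:

1. ingest the identified-PSM table and apply the engine-score quality filter;
2. log2 + per-channel median normalization of reporter intensities;
3. rollup of PSMs to modified peptides (one-hit wonders allowed) and of
   unmodified unique peptides to proteins (>= 2 peptides required);
4. per-run mean centering of every feature, merging the replicate runs;
5. subtraction of the protein profile from each formerly sialylated
   glycopeptide (sialylation change net of protein abundance);
6. combined moderated-t / rank-product testing with Storey correction at
   FDR 0.05, then the biological gates: N-glycosylation sequon (NG sites
   flagged as only potential) and membrane association.

The pipeline is deterministic given the config seed.  A RunReport records
the feature counts at every stage so losses are auditable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ingest import (
    PSMRecord,
    FilterReport,
    find_sequons,
    map_site_to_protein,
    parse_modified_sequence,
    psm_filter,
    read_fasta,
    read_psm_table,
)
from .quant import (
    IntensityMatrix,
    center_runs,
    log2_median_normalize,
    merge_modified_peptides,
    normalize_glycopeptides_by_protein,
    protein_rollup,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_sialoproteome
from .stats import TestResult, differential_test, significance_filter

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineResult",
    "run_pipeline",
    "run_on_dataset",
    "evaluate_against_truth",
    "results_table",
    "load_config",
]

_STATUS_ORDER = {"valid": 0, "potential_NG": 1, "indeterminate_terminal": 2, "invalid": 3}

CASE_CONDITION = "ST3GAL4"
CONTROL_CONDITION = "mock"


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    min_per_condition: int = 2
    case: str = CASE_CONDITION
    control: str = CONTROL_CONDITION


@dataclass
class RunReport:
    """Stage-by-stage accounting of one pipeline run."""

    n_psm_input: int = 0
    n_psm_kept: int = 0
    psm_rejections: dict = field(default_factory=dict)
    n_modified_peptides: int = 0
    n_glyco_features: int = 0
    n_unmodified_peptides: int = 0
    n_proteins: int = 0
    dropped_proteins: list = field(default_factory=list)
    n_no_protein_reference: int = 0
    n_tested: int = 0
    n_untested: int = 0
    pi0: float = math.nan
    n_significant: int = 0
    n_increased: int = 0
    n_decreased: int = 0
    filter_counts: dict = field(default_factory=dict)
    max_fold_change: float = math.nan
    min_fold_change: float = math.nan
    min_p: float = math.nan
    min_q: float = math.nan
    config: dict = field(default_factory=dict)
    version: str = __version__
    seed: int | None = None


@dataclass
class PipelineResult:
    report: RunReport
    results: list[TestResult]
    increased: list[TestResult]
    decreased: list[TestResult]
    sequon_status: dict
    site_labels: dict
    glyco_matrix: IntensityMatrix
    protein_matrix: IntensityMatrix


def _build_raw_matrix(
    records: Sequence[PSMRecord],
    channels: Sequence[str],
    layout: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """PSM-level raw intensity table plus sample design and row keys."""
    runs = sorted({rec.run_id for rec in records})
    samples = [f"{run}:{chan}" for run in runs for chan in channels]
    design = pd.DataFrame(
        {
            "run": [s.split(":")[0] for s in samples],
            "condition": [layout[s.split(":")[1]] for s in samples],
            "channel": [s.split(":")[1] for s in samples],
        },
        index=samples,
    )
    col_of = {s: j for j, s in enumerate(samples)}
    values = np.full((len(records), len(samples)), np.nan)
    keys, index = [], []
    for i, rec in enumerate(records):
        if len(rec.reporter_intensities) != len(channels):
            raise ValueError(
                f"PSM {i} has {len(rec.reporter_intensities)} reporter intensities, "
                f"expected {len(channels)}"
            )
        for chan, value in zip(channels, rec.reporter_intensities):
            values[i, col_of[f"{rec.run_id}:{chan}"]] = value
        index.append(i)
        keys.append((rec.accession, rec.modified_sequence))
    raw = pd.DataFrame(values, index=index, columns=samples)
    return raw, design, pd.Series(keys, index=index)


def run_on_dataset(
    dataset: SyntheticDataset,
    pipe_cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on an in-memory synthetic dataset."""
    cfg = dataset.config
    records = _records_from_table(dataset.psm_table)
    proteins = _fasta_to_dict(dataset.protein_fasta)
    membrane = dict(
        zip(dataset.annotations["accession"], dataset.annotations["membrane"])
    )
    return _run(
        records,
        channels=cfg.channels,
        layout=cfg.layout,
        proteins=proteins,
        membrane=membrane,
        pipe_cfg=pipe_cfg or PipelineConfig(seed=cfg.seed),
    )


def run_pipeline(
    psm_path,
    layout: Mapping[str, str],
    fasta_path=None,
    annotation_path=None,
    pipe_cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the pipeline from files: PSM table, protein FASTA, annotation TSV.

    ``layout`` maps reporter channel labels to condition names; the
    annotation table needs ``accession`` and ``membrane`` columns.
    """
    records = read_psm_table(psm_path)
    if not records:
        raise ValueError("empty PSM table")
    channels = sorted(
        {c.split("_", 1)[1] for c in pd.read_csv(psm_path, sep="\t", nrows=0).columns if c.startswith("reporter_")}
    )
    proteins = read_fasta(fasta_path) if fasta_path else {}
    membrane: dict[str, bool] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t")
        for col in ("accession", "membrane"):
            if col not in ann.columns:
                raise ValueError(f"annotation table is missing column {col!r}")
        membrane = dict(zip(ann["accession"], ann["membrane"].astype(bool)))
    return _run(
        records,
        channels=channels,
        layout=layout,
        proteins=proteins,
        membrane=membrane,
        pipe_cfg=pipe_cfg or PipelineConfig(),
    )


def _records_from_table(table: pd.DataFrame) -> list[PSMRecord]:
    reporter_cols = sorted(c for c in table.columns if c.startswith("reporter_"))
    records = []
    for _, row in table.iterrows():
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
                reporter_intensities=tuple(float(row[c]) for c in reporter_cols),
                run_id=str(row["run_id"]),
            )
        )
    return records


def _fasta_to_dict(fasta: str) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    for line in fasta.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out


def _run(
    records: Sequence[PSMRecord],
    channels: Sequence[str],
    layout: Mapping[str, str],
    proteins: Mapping[str, str],
    membrane: Mapping[str, bool],
    pipe_cfg: PipelineConfig,
) -> PipelineResult:
    if not records:
        raise ValueError("empty PSM table")
    report = RunReport(config=dataclasses.asdict(pipe_cfg), seed=pipe_cfg.seed)
    report.n_psm_input = len(records)

    filt = psm_filter(records)
    report.n_psm_kept = len(filt.kept)
    report.psm_rejections = dict(filt.rejected)
    if not filt.kept:
        raise ValueError("no PSMs survive the quality filter")

    raw, design, keys = _build_raw_matrix(filt.kept, channels, layout)
    matrix = log2_median_normalize(raw, design)
    peptides = merge_modified_peptides(matrix, key=keys.to_dict())
    report.n_modified_peptides = len(peptides.data)

    # partition features into glyco-candidates and unmodified peptides
    parsed = {key: parse_modified_sequence(key[1]) for key in peptides.data.index}
    glyco_keys = [k for k, pep in parsed.items() if pep.deamidated]
    unmod_keys = [k for k, pep in parsed.items() if not pep.deamidated]
    report.n_glyco_features = len(glyco_keys)
    report.n_unmodified_peptides = len(unmod_keys)

    # unique-peptide -> protein map (shared plain sequences are excluded)
    plain_to_accs: dict[str, set[str]] = {}
    for acc, seq in unmod_keys:
        plain_to_accs.setdefault(seq, set()).add(acc)
    pep_to_protein = {
        (acc, seq): acc
        for acc, seq in unmod_keys
        if len(plain_to_accs[seq]) == 1
    }
    unmod = peptides.copy_with(peptides.data.loc[unmod_keys])
    prot_matrix, dropped = protein_rollup(unmod, pep_to_protein)
    report.n_proteins = len(prot_matrix.data)
    report.dropped_proteins = dropped

    glyco = peptides.copy_with(peptides.data.loc[glyco_keys])
    glyco = center_runs(glyco)
    prot_matrix = center_runs(prot_matrix)
    glyco_net = normalize_glycopeptides_by_protein(
        glyco, prot_matrix, {k: k[0] for k in glyco_keys}
    )
    report.n_no_protein_reference = sum(
        1 for v in glyco_net.flags.values() if v == "no_protein_reference"
    )

    # sequon status and protein-site labels per glyco feature
    sequon_status: dict = {}
    site_labels: dict = {}
    for key in glyco_keys:
        acc, _ = key
        pep = parsed[key]
        calls = find_sequons(pep)
        best = min(calls, key=lambda c: _STATUS_ORDER[c.status])
        sequon_status[key] = best.status
        if acc in proteins:
            try:
                mapping = map_site_to_protein(pep, best.position, proteins[acc])
                site_labels[key] = ";".join(mapping.sites)
            except ValueError:
                site_labels[key] = ""
        else:
            site_labels[key] = ""

    results, fit, rp, pi0 = differential_test(
        glyco_net,
        case=pipe_cfg.case,
        control=pipe_cfg.control,
        n_perm=pipe_cfg.n_perm,
        seed=pipe_cfg.seed,
        alpha=pipe_cfg.alpha,
    )
    report.n_tested = len(results)
    report.n_untested = len(fit.untested) + (len(fit.features) - len(results))
    report.pi0 = pi0.pi0
    report.n_significant = sum(r.significant for r in results)

    increased, decreased, counts = significance_filter(
        results,
        sequon_status,
        membrane,
        accession_of=lambda key: key[0],
        alpha=pipe_cfg.alpha,
    )
    report.filter_counts = counts
    report.n_increased = len(increased)
    report.n_decreased = len(decreased)
    final = increased + decreased
    if final:
        report.max_fold_change = max(r.fold_change for r in final)
        report.min_fold_change = min(r.fold_change for r in final)
        report.min_p = min(r.p_combined for r in final)
        report.min_q = min(r.q for r in final)
    return PipelineResult(
        report=report,
        results=results,
        increased=increased,
        decreased=decreased,
        sequon_status=sequon_status,
        site_labels=site_labels,
        glyco_matrix=glyco_net,
        protein_matrix=prot_matrix,
    )


def results_table(result: PipelineResult) -> pd.DataFrame:
    """Final result lists as a table mirroring the published column layout."""
    rows = []
    for direction, bucket in (("increased", result.increased), ("decreased", result.decreased)):
        for res in bucket:
            acc, seq = res.feature
            rows.append(
                {
                    "accession": acc,
                    "peptide": seq,
                    "site": result.site_labels.get(res.feature, ""),
                    "fold_change": round(res.fold_change, 2),
                    "p_combined": res.p_combined,
                    "q": res.q,
                    "direction": direction,
                    "caveat": res.caveat,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "peptide",
            "site",
            "fold_change",
            "p_combined",
            "q",
            "direction",
            "caveat",
        ],
    )


def evaluate_against_truth(
    result: PipelineResult, dataset: SyntheticDataset, alpha: float = 0.05
) -> dict:
    """Compare pipeline calls with simulator ground truth.

    Returns sensitivity (fraction of true-effect sites called at q <= alpha),
    the realized false-discovery proportion among those calls, and the
    fold-change errors of the detected true effects (log2).
    """
    truth = dataset.truth.glycosites.set_index(["accession", "peptide"])
    n_calls = n_false = n_true_effects = n_detected = 0
    fc_errors = []
    for res in result.results:
        key = res.feature
        if key not in truth.index:
            continue
        row = truth.loc[key]
        if res.q <= alpha:
            n_calls += 1
            if row["is_null"]:
                n_false += 1
            else:
                fc_errors.append(res.log2_fold_change - row["effect"])
    for _, row in truth.iterrows():
        if not row["is_null"]:
            n_true_effects += 1
    detected = n_calls - n_false
    return {
        "n_calls": n_calls,
        "n_false": n_false,
        "fdp": (n_false / n_calls) if n_calls else 0.0,
        "n_true_effects": n_true_effects,
        "sensitivity": (detected / n_true_effects) if n_true_effects else math.nan,
        "fc_errors": fc_errors,
    }


def load_config(path) -> tuple[SimulationConfig, PipelineConfig]:
    """Load simulation and pipeline settings from one YAML file.

    Top-level keys ``simulation`` and ``pipeline`` each hold the fields of
    the corresponding config dataclass; omitted fields keep their defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim_kwargs = dict(doc.get("simulation", {}))
    if "peptides_per_protein" in sim_kwargs:
        sim_kwargs["peptides_per_protein"] = tuple(sim_kwargs["peptides_per_protein"])
    if "psms_per_peptide" in sim_kwargs:
        sim_kwargs["psms_per_peptide"] = tuple(sim_kwargs["psms_per_peptide"])
    if "channels" in sim_kwargs:
        sim_kwargs["channels"] = tuple(str(c) for c in sim_kwargs["channels"])
    if "layout" in sim_kwargs:
        sim_kwargs["layout"] = {str(k): str(v) for k, v in sim_kwargs["layout"].items()}
    sim = SimulationConfig(**sim_kwargs)
    pipe = PipelineConfig(**doc.get("pipeline", {}))
    return sim, pipe
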