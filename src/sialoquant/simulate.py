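"""Synthetic sialoproteome and glycome generators with ground truth.

The proteomic generator emulates a 4-plex isobaric-label experiment run in
three replicate LC-MS runs over two conditions (mock vs ST3GAL4): log-normal
peptide intensities (additive on the log2 scale), per-run channel shifts that
median centering removes, run-level offsets that per-run mean centering
removes, a minority of glycopeptides carrying a true condition effect in the
ST3GAL4 channels only, and NG-motif decoy peptides whose deamidation is
spontaneous and condition-independent.  Every peptide is embedded at a known
offset in a generated protein sequence, so sequon detection and site mapping
are verifiable against ground truth, and engine scores are drawn so a
configurable fraction of PSMs fails each quality rule.

The glycomic generator emits peak lists at the theoretical negative-mode m/z
of a stated structure panel, before and after sialidase S / sialidase A
digestion, moving the intensity of each desialylated structure onto its
asialo composition according to the stated linkage truth.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glycans import (
    MonosaccharideComposition,
    Peak,
    PeakList,
    glycan_monoisotopic_mass,
    glycan_mz,
)
from .ingest import XCORR_THRESHOLDS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_sialoproteome",
    "simulate_glycan_run",
]

_RESIDUES = np.array(list("ACDEFGHIKLMNQSVWY"))  # no P/T/S ambiguity in linkers
_SEQON_THIRD = np.array(list("ST"))
_SEQON_X = np.array(list("ACDEFHIKLMQRSTVWY"))  # X != P, != G


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic 4-plex experiment.

    Defaults mirror the design being emulated — three biological replicate
    runs of a 4-plex labeling with two channels per condition, 1:1:1:1 mixing
    — at desk scale (tens of proteins, low hundreds of glycosites).  Effects
    are additive on the log2 scale; the default true effect is +1.5 log2
    units on 10% of glycosites with measurement noise sd 0.4.
    """

    n_proteins: int = 60
    peptides_per_protein: tuple[int, int] = (2, 4)
    n_glycosites: int = 150
    fraction_true_effects: float = 0.1
    effect_mean: float = 1.5
    effect_sd: float = 0.0
    noise_sd: float = 0.4
    channel_shift_sd: float = 0.5
    run_offset_sd: float = 1.0
    peptide_offset_sd: float = 1.0
    protein_mean: float = 20.0
    protein_sd: float = 2.0
    n_runs: int = 3
    channels: tuple[str, ...] = ("114", "115", "116", "117")
    #: channel -> condition assignment; the real channel map is unknown, so it
    #: is explicit configuration, never an assumption of the analysis.
    layout: Mapping[str, str] = field(
        default_factory=lambda: {
            "114": "mock",
            "115": "mock",
            "116": "ST3GAL4",
            "117": "ST3GAL4",
        }
    )
    fraction_ng_decoys: float = 0.1
    fraction_membrane: float = 0.8
    fraction_filter_fail: float = 0.05
    missing_rate: float = 0.05
    psms_per_peptide: tuple[int, int] = (1, 2)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "fraction_true_effects",
            "fraction_ng_decoys",
            "fraction_membrane",
            "fraction_filter_fail",
            "missing_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_proteins < 1 or self.n_glycosites < 0:
            raise ValueError("need at least one protein and a non-negative glycosite count")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if set(self.layout) != set(self.channels):
            raise ValueError("layout must assign every channel")
        if set(self.layout.values()) != {"mock", "ST3GAL4"}:
            raise ValueError("layout must use both conditions")


@dataclass
class GroundTruth:
    """What the generator actually put into the tables."""

    glycosites: pd.DataFrame  # site_id, accession, peptide, position, effect, is_null, sequon
    proteins: pd.DataFrame  # accession, membrane, length


@dataclass
class SyntheticDataset:
    psm_table: pd.DataFrame
    protein_fasta: str
    annotations: pd.DataFrame  # accession, membrane
    truth: GroundTruth
    config: SimulationConfig


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(_RESIDUES, size=length - 1))
    return body + str(rng.choice(["K", "R"]))


def _glyco_peptide(rng: np.random.Generator, ng_decoy: bool) -> tuple[str, int]:
    """A tryptic-like peptide containing one sequon; returns (plain, N position)."""
    length = int(rng.integers(8, 15))
    pos = int(rng.integers(1, length - 2))  # 0-based; leaves room for X and S/T
    pep = list(_random_peptide(rng, length))
    pep[pos] = "N"
    pep[pos + 1] = "G" if ng_decoy else str(rng.choice(_SEQON_X))
    pep[pos + 2] = str(rng.choice(_SEQON_THIRD))
    return "".join(pep), pos + 1  # 1-based


def _passing_scores(rng: np.random.Generator, charge: int) -> dict[str, float]:
    return {
        "percolator_q": float(rng.uniform(0.0, 0.01)),
        "mascot_rank": 1,
        "sequest_rank": 1,
        "delta_cn": float(rng.uniform(0.1, 0.6)),
        "mascot_score": float(rng.uniform(18.0, 120.0)),
        "xcorr": float(XCORR_THRESHOLDS[charge] + rng.uniform(0.05, 2.0)),
    }


def _fail_one_rule(rng: np.random.Generator, scores: dict[str, float], charge: int) -> None:
    rule = rng.choice(["percolator_q", "rank", "delta_cn", "mascot_score", "xcorr"])
    if rule == "percolator_q":
        scores["percolator_q"] = float(rng.uniform(0.011, 0.2))
    elif rule == "rank":
        scores[str(rng.choice(["mascot_rank", "sequest_rank"]))] = 2
    elif rule == "delta_cn":
        scores["delta_cn"] = float(rng.uniform(0.0, 0.099))
    elif rule == "mascot_score":
        scores["mascot_score"] = float(rng.uniform(0.0, 17.9))
    else:
        scores["xcorr"] = float(XCORR_THRESHOLDS[charge] - rng.uniform(0.01, 0.5))


def simulate_sialoproteome(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic experiment with ground truth.

    The PSM table carries one row per (peptide, run, PSM copy) with the four
    reporter intensities of that run; glycopeptides are ``Nde``-marked at
    their sequon position.  Proteins are built by joining their peptides with
    random linkers, so every peptide occurs at a recorded offset.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_sites = cfg.n_glycosites
    n_decoys = int(round(cfg.fraction_ng_decoys * n_sites))
    n_effects = int(round(cfg.fraction_true_effects * n_sites))

    # --- proteins and their unmodified peptides ---------------------------
    accessions = [f"SYN{i:04d}" for i in range(cfg.n_proteins)]
    membrane = rng.random(cfg.n_proteins) < cfg.fraction_membrane
    protein_abundance = rng.normal(cfg.protein_mean, cfg.protein_sd, cfg.n_proteins)

    peptide_rows = []  # (accession, plain, modified, is_glyco, position, effect, is_null, sequon)
    used_peptides: set[str] = set()
    lo, hi = cfg.peptides_per_protein
    for i, acc in enumerate(accessions):
        for _ in range(int(rng.integers(lo, hi + 1))):
            while True:
                pep = _random_peptide(rng, int(rng.integers(8, 16)))
                if pep not in used_peptides:
                    used_peptides.add(pep)
                    break
            peptide_rows.append((acc, pep, pep, False, 0, 0.0, True, ""))

    # --- glycosites -------------------------------------------------------
    site_meta = []
    decoy_flags = np.zeros(n_sites, dtype=bool)
    decoy_flags[:n_decoys] = True
    effects = np.zeros(n_sites)
    effect_idx = rng.choice(np.flatnonzero(~decoy_flags), size=n_effects, replace=False) \
        if n_effects and (~decoy_flags).sum() >= n_effects else np.array([], dtype=int)
    effects[effect_idx] = rng.normal(cfg.effect_mean, cfg.effect_sd, len(effect_idx)) \
        if cfg.effect_sd > 0 else cfg.effect_mean
    host = rng.integers(0, cfg.n_proteins, size=n_sites)
    for s in range(n_sites):
        while True:
            plain, pos = _glyco_peptide(rng, bool(decoy_flags[s]))
            if plain not in used_peptides:
                used_peptides.add(plain)
                break
        modified = plain[:pos] + "de" + plain[pos:]
        sequon = "potential_NG" if decoy_flags[s] else "valid"
        acc = accessions[host[s]]
        peptide_rows.append(
            (acc, plain, modified, True, pos, float(effects[s]), effects[s] == 0.0, sequon)
        )
        site_meta.append(
            {
                "site_id": f"site{s:04d}",
                "accession": acc,
                "peptide": modified,
                "plain": plain,
                "position": pos,
                "effect": float(effects[s]),
                "is_null": bool(effects[s] == 0.0),
                "sequon": sequon,
                "ng_decoy": bool(decoy_flags[s]),
            }
        )

    # --- protein sequences: peptides joined by linkers --------------------
    fasta_chunks = []
    offsets: dict[str, int] = {}
    lengths = {}
    by_protein: dict[str, list[str]] = {}
    for acc, plain, *_ in peptide_rows:
        by_protein.setdefault(acc, []).append(plain)
    for acc in accessions:
        seq_parts, cursor = [], 0
        linker = "".join(rng.choice(_RESIDUES, size=int(rng.integers(3, 8))))
        seq_parts.append(linker)
        cursor += len(linker)
        for plain in by_protein.get(acc, []):
            offsets[plain] = cursor
            seq_parts.append(plain)
            cursor += len(plain)
            linker = "".join(rng.choice(_RESIDUES, size=int(rng.integers(3, 8))))
            seq_parts.append(linker)
            cursor += len(linker)
        seq = "".join(seq_parts)
        lengths[acc] = len(seq)
        fasta_chunks.append(f">{acc}\n{seq}\n")
    fasta = "".join(fasta_chunks)

    for meta in site_meta:
        meta["protein_offset"] = offsets[meta["plain"]]
        meta["protein_site"] = f"N{offsets[meta['plain']] + meta['position']}"

    # --- intensities ------------------------------------------------------
    runs = [f"run{r + 1}" for r in range(cfg.n_runs)]
    channel_shift = rng.normal(0.0, cfg.channel_shift_sd, (cfg.n_runs, len(cfg.channels)))
    run_offset = rng.normal(0.0, cfg.run_offset_sd, cfg.n_runs)
    acc_index = {acc: i for i, acc in enumerate(accessions)}

    psm_records = []
    lo_psm, hi_psm = cfg.psms_per_peptide
    for acc, plain, modified, is_glyco, pos, effect, _, _ in peptide_rows:
        pep_offset = rng.normal(0.0, cfg.peptide_offset_sd)
        base = protein_abundance[acc_index[acc]] + pep_offset
        for r, run in enumerate(runs):
            for _ in range(int(rng.integers(lo_psm, hi_psm + 1))):
                charge = int(rng.integers(2, 5))
                scores = _passing_scores(rng, charge)
                if rng.random() < cfg.fraction_filter_fail:
                    _fail_one_rule(rng, scores, charge)
                intensities = []
                for c, chan in enumerate(cfg.channels):
                    value = (
                        base
                        + run_offset[r]
                        + channel_shift[r, c]
                        + rng.normal(0.0, cfg.noise_sd)
                    )
                    if is_glyco and cfg.layout[chan] == "ST3GAL4":
                        value += effect
                    if rng.random() < cfg.missing_rate:
                        intensities.append(np.nan)
                    else:
                        intensities.append(2.0**value)
                psm_records.append(
                    {
                        "modified_sequence": modified,
                        "accession": acc,
                        "charge": charge,
                        **scores,
                        **{
                            f"reporter_{chan}": intensities[c]
                            for c, chan in enumerate(cfg.channels)
                        },
                        "run_id": run,
                    }
                )

    psm_table = pd.DataFrame(psm_records)
    truth = GroundTruth(
        glycosites=pd.DataFrame(site_meta),
        proteins=pd.DataFrame(
            {
                "accession": accessions,
                "membrane": membrane,
                "length": [lengths[a] for a in accessions],
                "abundance": protein_abundance,
            }
        ),
    )
    annotations = truth.proteins[["accession", "membrane"]].copy()
    return SyntheticDataset(psm_table, fasta, annotations, truth, cfg)


# ---------------------------------------------------------------------------
# Glycome simulation


def simulate_glycan_run(
    structures: Sequence[tuple[str, MonosaccharideComposition, float]],
    linkage_truth: Mapping[str, str],
    noise_cv: float = 0.0,
    seed: int | None = None,
    reduced: bool = False,
    base_intensity: float = 1e6,
) -> dict[str, PeakList]:
    """Emit peak lists for untreated, sialidase-S and sialidase-A digests.

    ``structures`` is a list of (structure id, composition, true percent) with
    percents summing to 100.  Peaks appear at the theoretical [M-H]- and
    [M-2H]2- m/z with intensity proportional to the true percent under
    multiplicative log-normal noise of the given CV.  Sialidase S strips the
    NeuAc of "a2-3" structures, sialidase A strips "a2-3" and "a2-6/8"
    structures; the stripped intensity reappears on the asialo composition.
    """
    total = sum(pct for _, _, pct in structures)
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"true percents must sum to 100, got {total}")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def sample_intensity(pct: float) -> float:
        mean = base_intensity * pct / 100.0
        if sigma == 0.0:
            return mean
        return float(mean * np.exp(rng.normal(-0.5 * sigma**2, sigma)))

    def strip(sid: str, comp: MonosaccharideComposition, treatment: str) -> MonosaccharideComposition:
        if comp.neuac == 0:
            return comp
        linkage = linkage_truth.get(sid, "resistant")
        if treatment == "sialidase_S" and linkage == "a2-3":
            return comp.desialylated()
        if treatment == "sialidase_A" and linkage in ("a2-3", "a2-6/8"):
            return comp.desialylated()
        return comp

    out: dict[str, PeakList] = {}
    for treatment in ("none", "sialidase_S", "sialidase_A"):
        pooled: dict[MonosaccharideComposition, float] = {}
        for sid, comp, pct in structures:
            product = strip(sid, comp, treatment) if treatment != "none" else comp
            pooled[product] = pooled.get(product, 0.0) + sample_intensity(pct)
        peaks = []
        scan = 0
        for comp, intensity in pooled.items():
            mass = glycan_monoisotopic_mass(comp, reduced=reduced)
            for z in (1, 2):
                scan += 1
                peaks.append(Peak(glycan_mz(mass, z), intensity, scan))
        out[treatment] = PeakList(f"sim-{treatment}", peaks)
    return out
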