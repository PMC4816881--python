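"""Reporter-intensity normalization and peptide/protein rollup.

The quantitative unit is a features x samples matrix of log2 reporter
intensities from a multiplexed isobaric-label (iTRAQ 4-plex) experiment run
in several replicate LC-MS runs.  Each sample column is one reporter channel
of one run and carries (run, condition, channel) labels; which channels hold
which condition is part of the experimental design, never assumed.

Processing order mirrors the analysis this package reproduces:

1. log2 transform and per-column median centering (removes channel-level
   systematic shifts such as unequal mixing);
2. rollup of redundant rows into one profile per modified peptide
   (one-hit wonders allowed) and, for unmodified peptides, into one profile
   per protein (at least two unique peptides required);
3. per-run mean centering of each feature, which removes run-level offsets so
   the replicate runs can be merged;
4. subtraction of the protein profile from each glycopeptide profile, leaving
   a sialylation change net of protein-abundance change.

The rollup combination is "reference-free mean scaling": each contributing
row is centered on its own cross-sample mean, the centered rows are averaged
per sample, and the grand mean (mean of the row means) is restored.  Missing
values are skipped, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "log2_median_normalize",
    "merge_modified_peptides",
    "protein_rollup",
    "center_runs",
    "normalize_glycopeptides_by_protein",
]

DESIGN_FIELDS = ("run", "condition", "channel")


@dataclass
class IntensityMatrix:
    """Log2 intensities (features x samples) plus the sample design.

    ``data`` is indexed by feature key with one column per sample id;
    ``design`` is indexed by sample id with columns run / condition / channel.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    flags: dict[Hashable, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.design.index.is_unique:
            raise ValueError("sample ids must be unique")
        missing = [f for f in DESIGN_FIELDS if f not in self.design.columns]
        if missing:
            raise ValueError(f"design is missing fields: {missing}")
        unmatched = [c for c in self.data.columns if c not in self.design.index]
        if unmatched:
            raise ValueError(f"samples without design labels: {unmatched}")
        self.design = self.design.loc[list(self.data.columns)]

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def runs(self) -> list:
        return list(dict.fromkeys(self.design["run"]))

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.design["condition"]))

    def samples_for(self, *, run=None, condition=None) -> list:
        mask = pd.Series(True, index=self.design.index)
        if run is not None:
            mask &= self.design["run"] == run
        if condition is not None:
            mask &= self.design["condition"] == condition
        return list(self.design.index[mask])

    def copy_with(self, data: pd.DataFrame) -> "IntensityMatrix":
        return IntensityMatrix(data, self.design.copy(), dict(self.flags))

    # -- two-row-header TSV round trip --------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.data.columns]
            + [self.design[f].astype(str).values for f in DESIGN_FIELDS],
            names=["sample"] + list(DESIGN_FIELDS),
        )
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "IntensityMatrix":
        data = pd.read_csv(path, sep="\t", header=list(range(4)), index_col=0)
        samples = data.columns.get_level_values("sample")
        design = pd.DataFrame(
            {f: data.columns.get_level_values(f) for f in DESIGN_FIELDS},
            index=samples,
        )
        data.columns = samples
        return cls(data, design)


def log2_median_normalize(raw: pd.DataFrame, design: pd.DataFrame) -> IntensityMatrix:
    """log2-transform raw intensities and center each sample column on its median.

    Raw intensities must be positive where present (NaN marks a missing
    measurement); a non-positive cell is reported by feature and sample.
    After normalization the median of every column's non-missing values is 0,
    which makes the operation idempotent on already-log2 data only in the
    sense that re-centering changes nothing.
    """
    bad = (raw <= 0) & raw.notna()
    if bad.any().any():
        feature = bad.any(axis=1).idxmax()
        sample = bad.loc[feature].idxmax()
        raise ValueError(
            f"non-positive intensity at feature {feature!r}, sample {sample!r}: "
            f"{raw.loc[feature, sample]!r}"
        )
    log2 = np.log2(raw)
    centered = log2 - log2.median(axis=0, skipna=True)
    return IntensityMatrix(centered, design.copy())


def _rollup(data: pd.DataFrame, keys: pd.Series) -> pd.DataFrame:
    """Center-average-restore combination of row groups (vectorized).

    Each row is centered on its own cross-sample mean, the centered rows of a
    group are averaged per sample, and the grand mean (mean of the group's
    row means) is restored; single-row groups pass through unchanged.
    """
    codes, uniques = pd.factorize(keys.values, use_na_sentinel=False)
    row_means = data.mean(axis=1, skipna=True)
    centered = data.sub(row_means, axis=0)
    combined = centered.groupby(codes).mean()
    combined = combined.add(row_means.groupby(codes).mean(), axis=0)
    # keep composite (tuple) keys as flat scalars, not a MultiIndex
    combined.index = pd.Index(list(uniques), dtype=object, tupleize_cols=False)
    return combined


def merge_modified_peptides(
    matrix: IntensityMatrix,
    key: Callable[[Hashable], Hashable] | Mapping[Hashable, Hashable] | None = None,
) -> IntensityMatrix:
    """Roll redundant rows (e.g. repeated PSMs) up to one profile per modified peptide.

    ``key`` maps each input feature id to its modified-peptide key (default:
    the id itself).  Single-row groups — one-hit wonders — pass through
    unchanged, matching a rollup that allows them.
    """
    if key is None:
        keys = pd.Series(matrix.data.index, index=matrix.data.index)
    elif callable(key):
        keys = pd.Series([key(i) for i in matrix.data.index], index=matrix.data.index)
    else:
        keys = pd.Series([key[i] for i in matrix.data.index], index=matrix.data.index)
    return matrix.copy_with(_rollup(matrix.data, keys))


def protein_rollup(
    matrix: IntensityMatrix,
    peptide_to_protein: Mapping[Hashable, str],
) -> tuple[IntensityMatrix, list[str]]:
    """Roll unique unmodified peptides up to protein profiles.

    Only peptides mapping to exactly one accession are used; proteins backed
    by fewer than two unique peptide sequences are dropped (no one-hit
    wonders) and returned in the second element.
    """
    mapped = [pep for pep in matrix.data.index if pep in peptide_to_protein]
    data = matrix.data.loc[mapped]
    keys = pd.Series([peptide_to_protein[p] for p in mapped], index=data.index)
    # unique peptide sequences per protein
    n_unique: dict[str, set] = {}
    for pep, acc in keys.items():
        n_unique.setdefault(acc, set()).add(pep)
    dropped = sorted(acc for acc, peps in n_unique.items() if len(peps) < 2)
    keep = keys[~keys.isin(dropped)]
    rolled = _rollup(data.loc[keep.index], keep)
    return matrix.copy_with(rolled), dropped


def center_runs(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract each feature's per-run mean over that run's samples.

    Removes run-level offsets so the replicate iTRAQ runs are comparable;
    afterwards every (feature, run) mean over non-missing values is 0.  A
    feature entirely missing in a run stays missing there.
    """
    data = matrix.data.copy()
    for run in matrix.runs:
        cols = matrix.samples_for(run=run)
        block = data[cols]
        data[cols] = block.sub(block.mean(axis=1, skipna=True), axis=0)
    return matrix.copy_with(data)


def normalize_glycopeptides_by_protein(
    glyco: IntensityMatrix,
    proteins: IntensityMatrix,
    feature_to_protein: Mapping[Hashable, str],
) -> IntensityMatrix:
    """Subtract the protein profile from each glycopeptide profile, per sample.

    The result isolates the sialylation change from the underlying protein
    abundance change.  Glycopeptides whose protein is absent from the rolled-up
    protein matrix pass through unchanged, flagged ``no_protein_reference``.
    """
    if list(glyco.data.columns) != list(proteins.data.columns):
        raise ValueError("glycopeptide and protein matrices have different samples")
    flags = dict(glyco.flags)
    accs = [feature_to_protein.get(feat) for feat in glyco.data.index]
    has_ref = np.array(
        [acc is not None and acc in proteins.data.index for acc in accs]
    )
    ref = proteins.data.reindex(
        [acc if ok else None for acc, ok in zip(accs, has_ref)]
    ).to_numpy(dtype=float)
    ref[~has_ref] = 0.0
    data = pd.DataFrame(
        glyco.data.to_numpy(dtype=float) - ref,
        index=glyco.data.index,
        columns=glyco.data.columns,
    )
    for feat, ok in zip(glyco.data.index, has_ref):
        if not ok:
            flags[feat] = "no_protein_reference"
    return IntensityMatrix(data, glyco.design.copy(), flags)
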