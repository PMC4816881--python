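"""Glycan composition arithmetic and PGC-LC-MS glycomics quantification.

Masses are monoisotopic and derived from CODATA/AME atomic masses, so every
residue mass is an exact elemental sum rather than a hard-coded constant.
Glycans released by PNGase F are free reducing-end sugars; glycans released by
reductive beta-elimination are alditols (open ring, two hydrogens heavier).
Negative-ion mode throughout: ions are [M - zH]^z-.

Relative quantification follows the base-peak convention of PGC-LC-ESI-MS/MS
glycomics: the abundance of a structure is the maximum intensity of the
extracted ion chromatogram (XIC) at its theoretical m/z, expressed as percent
of the summed base-peak intensities of all structures in the sample.

Sialic acid linkage is assigned enzymatically: sialidase S removes only
alpha2-3-linked terminal NeuAc, sialidase A removes alpha2-3/6/8-linked
NeuAc; the differential loss of a structure between the two digests calls
its linkage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_FORMULA",
    "RESIDUE_MASS",
    "MonosaccharideComposition",
    "GlycanIon",
    "Peak",
    "PeakList",
    "CompositionMatch",
    "FoldChangeEntry",
    "parse_composition",
    "glycan_monoisotopic_mass",
    "glycan_mz",
    "match_mz",
    "xic_base_peak",
    "relative_abundance",
    "glycome_fold_change",
    "infer_sialic_linkage",
    "read_peak_list_tsv",
    "write_profile_tsv",
]

# CODATA-2018 / AME-2020 monoisotopic masses, Da.
ATOMIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

#: Mass of the proton (charge carrier in [M - zH]^z-), not the H atom.
PROTON_MASS: float = 1.007276466

# Elemental formulas of the glycosidically linked (dehydrated) residues.
RESIDUE_FORMULA: Mapping[str, Mapping[str, int]] = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dhex": {"C": 6, "H": 10, "O": 4},
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},
}


def _formula_mass(formula: Mapping[str, int]) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


RESIDUE_MASS: Mapping[str, float] = {
    name: _formula_mass(f) for name, f in RESIDUE_FORMULA.items()
}
WATER_MASS: float = _formula_mass({"H": 2, "O": 1})
_H2_MASS: float = 2 * ATOMIC_MASS["H"]


@dataclass(frozen=True, order=True)
class MonosaccharideComposition:
    """Integer counts of the four residue classes seen in this glycome.

    ``dhex`` counts deoxyhexose (fucose); ``neuac`` counts sialic acid.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name, count in self.counts().items():
            if count < 0:
                raise ValueError(f"negative residue count: {name}={count}")

    def counts(self) -> dict[str, int]:
        return {
            "hex": self.hex,
            "hexnac": self.hexnac,
            "dhex": self.dhex,
            "neuac": self.neuac,
        }

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neuac

    def is_empty(self) -> bool:
        return self.total_residues == 0

    def desialylated(self) -> "MonosaccharideComposition":
        """The composition with all sialic acids removed (exoglycosidase product)."""
        return MonosaccharideComposition(self.hex, self.hexnac, self.dhex, 0)

    def __add__(self, other: "MonosaccharideComposition") -> "MonosaccharideComposition":
        return MonosaccharideComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.dhex + other.dhex,
            self.neuac + other.neuac,
        )

    def __str__(self) -> str:
        parts = []
        for label, count in (
            ("Hex", self.hex),
            ("HexNAc", self.hexnac),
            ("dHex", self.dhex),
            ("NeuAc", self.neuac),
        ):
            if count:
                parts.append(f"{label}{count}")
        return "".join(parts) or "empty"


@dataclass(frozen=True)
class GlycanIon:
    """A glycan observed as a deprotonated negative ion [M - zH]^z-."""

    composition: MonosaccharideComposition
    charge: int = 1
    reduced: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge magnitude must be >= 1")

    @property
    def mass(self) -> float:
        return glycan_monoisotopic_mass(self.composition, reduced=self.reduced)

    @property
    def mz(self) -> float:
        return glycan_mz(self.mass, self.charge)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    scan: int = 0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class PeakList:
    """All centroided peaks of one LC-MS run of one sample.

    The scan number carries elution order as an ordinal retention index; it is
    stored for provenance but not used in matching (quantification is by XIC
    base peak only).
    """

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


_COMPOSITION_TOKEN = re.compile(r"([A-Za-z]+?)(\d+)")
_TOKEN_ALIASES = {
    "hex": "hex",
    "hexnac": "hexnac",
    "dhex": "dhex",
    "fuc": "dhex",
    "neuac": "neuac",
}


def parse_composition(text: str) -> MonosaccharideComposition:
    """Parse a composition string such as ``"Hex5HexNAc4NeuAc2"``.

    Recognised tokens are Hex, HexNAc, dHex (alias Fuc) and NeuAc, each
    followed by a positive multiplicity; unmentioned residues are zero.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty composition string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _COMPOSITION_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable composition segment {text[pos:m.start()]!r} in {text!r}")
        token, mult = m.group(1), int(m.group(2))
        key = _TOKEN_ALIASES.get(token.lower())
        if key is None:
            raise ValueError(f"unknown residue token {token!r} in {text!r}")
        if mult <= 0:
            raise ValueError(f"non-positive multiplicity for {token!r} in {text!r}")
        if key in counts:
            raise ValueError(f"residue {token!r} given twice in {text!r}")
        counts[key] = mult
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"trailing unparseable text {text[pos:]!r} in {text!r}")
    if not counts:
        raise ValueError(f"no residue tokens found in {text!r}")
    return MonosaccharideComposition(**counts)


def glycan_monoisotopic_mass(comp: MonosaccharideComposition, reduced: bool = False) -> float:
    """Neutral monoisotopic mass of a free glycan (Da).

    The mass is the sum of the dehydrated residue masses plus one water for
    the reducing (or formerly reducing) end.  ``reduced=True`` adds H2 for the
    open-ring alditol produced by reductive beta-elimination.
    """
    if comp.is_empty():
        raise ValueError("empty composition has no mass")
    mass = WATER_MASS + sum(
        count * RESIDUE_MASS[name] for name, count in comp.counts().items()
    )
    if reduced:
        mass += _H2_MASS
    return mass


def glycan_mz(mass: float, z: int) -> float:
    """m/z of the deprotonated ion [M - zH]^z- for charge magnitude ``z``."""
    if z < 1:
        raise ValueError("charge magnitude must be >= 1")
    return (mass - z * PROTON_MASS) / z


@dataclass(frozen=True)
class CompositionMatch:
    composition: MonosaccharideComposition
    theoretical_mz: float
    ppm_error: float


def match_mz(
    observed: float,
    z: int,
    candidates: Iterable[MonosaccharideComposition],
    reduced: bool = False,
    tol: float = 20.0,
) -> list[CompositionMatch]:
    """Candidates whose theoretical [M - zH]^z- lies within ``tol`` ppm.

    Returns matches sorted by absolute ppm error (empty list if none match).
    The default 20 ppm window suits ion-trap survey scans; tighten for
    orbitrap data.
    """
    if tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    matches = []
    for comp in candidates:
        theo = glycan_mz(glycan_monoisotopic_mass(comp, reduced=reduced), z)
        ppm = (observed - theo) / theo * 1e6
        if abs(ppm) <= tol:
            matches.append(CompositionMatch(comp, theo, ppm))
    matches.sort(key=lambda m: abs(m.ppm_error))
    return matches


def xic_base_peak(peaks: PeakList | Iterable[Peak], target: float, tol: float = 20.0) -> float:
    """Base-peak intensity of the XIC at ``target`` m/z (ppm window).

    The XIC collects every peak within ``tol`` ppm of the target across the
    run; its base peak is the single most intense of those.  Returns 0 when
    nothing falls in the window.
    """
    if tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    best = 0.0
    for peak in peaks:
        if abs(peak.mz - target) / target * 1e6 <= tol:
            best = max(best, peak.intensity)
    return best


def relative_abundance(intensities: Mapping[str, float]) -> dict[str, float]:
    """Convert per-structure base-peak intensities to percent of total.

    The output sums to 100 and is invariant to global intensity scaling.
    """
    if not intensities:
        raise ValueError("no structures to normalize")
    for sid, value in intensities.items():
        if value < 0:
            raise ValueError(f"negative intensity for structure {sid!r}")
    total = float(sum(intensities.values()))
    if total == 0:
        raise ValueError("all intensities are zero; relative abundance undefined")
    return {sid: 100.0 * value / total for sid, value in intensities.items()}


@dataclass(frozen=True)
class FoldChangeEntry:
    structure: str
    case_percent: float
    control_percent: float
    ratio: float | None  # None when the control abundance is zero
    flag: str  # "up", "down" or ""


def glycome_fold_change(
    case: Mapping[str, float],
    control: Mapping[str, float],
    highlight: float = 2.0,
) -> list[FoldChangeEntry]:
    """Ratio of case to control percent abundance with highlight flags.

    A structure is flagged "up" when ratio >= highlight and "down" when
    ratio <= 1/highlight; structures absent from either profile are skipped,
    and a zero control abundance yields an undefined (None) ratio.
    """
    if highlight <= 1:
        raise ValueError("highlight threshold must exceed 1")
    entries = []
    for sid in case:
        if sid not in control:
            continue
        c, r = float(case[sid]), float(control[sid])
        if r == 0:
            entries.append(FoldChangeEntry(sid, c, r, None, ""))
            continue
        ratio = c / r
        if ratio >= highlight:
            flag = "up"
        elif ratio <= 1.0 / highlight:
            flag = "down"
        else:
            flag = ""
        entries.append(FoldChangeEntry(sid, c, r, ratio, flag))
    return entries


def infer_sialic_linkage(
    untreated: Mapping[str, float],
    after_sialidase_s: Mapping[str, float],
    after_sialidase_a: Mapping[str, float],
    compositions: Mapping[str, MonosaccharideComposition],
    loss_fraction: float = 0.8,
) -> dict[str, str]:
    """Assign sialic acid linkage from differential sialidase digests.

    Sialidase S is alpha2-3 specific; sialidase A is broad (alpha2-3/6/8).
    For each NeuAc-bearing structure the relative abundance before and after
    each digest is compared: a drop of at least ``loss_fraction`` of the
    untreated abundance after S calls "a2-3"; survival of S but loss after A
    calls "a2-6/8"; survival of both is "resistant/uncertain".  Structures
    without NeuAc are "n/a".
    """
    if not (0 < loss_fraction <= 1):
        raise ValueError("loss_fraction must lie in (0, 1]")
    calls: dict[str, str] = {}
    for sid, comp in compositions.items():
        if sid not in untreated:
            raise KeyError(f"structure {sid!r} missing from untreated profile")
        if comp.neuac == 0:
            calls[sid] = "n/a"
            continue
        for profile, name in ((after_sialidase_s, "sialidase S"), (after_sialidase_a, "sialidase A")):
            if sid not in profile:
                raise KeyError(f"structure {sid!r} missing from {name} profile")
        base = float(untreated[sid])
        if base == 0:
            calls[sid] = "resistant/uncertain"
            continue
        lost_s = (base - float(after_sialidase_s[sid])) / base
        lost_a = (base - float(after_sialidase_a[sid])) / base
        if lost_s >= loss_fraction:
            calls[sid] = "a2-3"
        elif lost_a >= loss_fraction:
            calls[sid] = "a2-6/8"
        else:
            calls[sid] = "resistant/uncertain"
    return calls


def read_peak_list_tsv(path, sample_id: str | None = None) -> PeakList:
    """Read a 3-column TSV (mz, intensity, scan) into a PeakList."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in table.columns}
    for required in ("mz", "intensity"):
        if required not in cols:
            raise ValueError(f"peak list is missing column {required!r}")
    scan_col = cols.get("scan")
    peaks = [
        Peak(
            float(row[cols["mz"]]),
            float(row[cols["intensity"]]),
            int(row[scan_col]) if scan_col else 0,
        )
        for _, row in table.iterrows()
    ]
    return PeakList(sample_id or str(path), peaks)


def write_profile_tsv(profile: Mapping[str, float], path) -> None:
    """Write a relative-abundance profile as a two-column TSV."""
    import pandas as pd

    pd.DataFrame(
        {"structure": list(profile), "percent": [profile[s] for s in profile]}
    ).to_csv(path, sep="\t", index=False)
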