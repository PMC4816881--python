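"""Glycan composition arithmetic, m/z matching and profile quantification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sialoquant.glycans import (
    MonosaccharideComposition,
    Peak,
    PeakList,
    glycan_monoisotopic_mass,
    glycan_mz,
    glycome_fold_change,
    infer_sialic_linkage,
    match_mz,
    parse_composition,
    relative_abundance,
    xic_base_peak,
)

# Independent elemental oracle: accumulate the full molecular formula and sum
# atomic masses (values typed in here, not imported from the package).
_ATOM = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048, "O": 15.9949146196}
_RES = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dhex": {"C": 6, "H": 10, "O": 4},
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},
}


def oracle_mass(comp: MonosaccharideComposition, reduced: bool = False) -> float:
    formula = {"H": 2, "O": 1}  # water
    for name, count in comp.counts().items():
        for el, n in _RES[name].items():
            formula[el] = formula.get(el, 0) + n * count
    if reduced:
        formula["H"] += 2
    return sum(_ATOM[el] * n for el, n in formula.items())


comps = st.builds(
    MonosaccharideComposition,
    hex=st.integers(0, 10),
    hexnac=st.integers(0, 8),
    dhex=st.integers(0, 4),
    neuac=st.integers(0, 4),
).filter(lambda c: not c.is_empty())


class TestComposition:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Hex5HexNAc4NeuAc2", (5, 4, 0, 2)),
            ("Fuc1HexNAc1", (0, 1, 1, 0)),
            ("dHex2Hex3", (3, 0, 2, 0)),
        ],
    )
    def test_parse(self, text, expected):
        comp = parse_composition(text)
        assert (comp.hex, comp.hexnac, comp.dhex, comp.neuac) == expected

    @pytest.mark.parametrize("bad", ["Xyl2", "Hex0", "Hex", "", "Hex2Junk1", "Hex-1"])
    def test_parse_rejects(self, bad):
        with pytest.raises(ValueError):
            parse_composition(bad)


class TestMass:
    def test_disialylated_biantennary(self):
        # Hex5HexNAc4NeuAc2 = C84H136N6O61 as free glycan; frozen oracle value
        comp = parse_composition("Hex5HexNAc4NeuAc2")
        assert glycan_monoisotopic_mass(comp) == pytest.approx(2222.7830, abs=1e-4)
        assert glycan_mz(glycan_monoisotopic_mass(comp), 2) == pytest.approx(
            1110.3842, abs=1e-4
        )

    def test_sialylated_core_alditol(self):
        comp = parse_composition("Hex1HexNAc1NeuAc1")
        mass = glycan_monoisotopic_mass(comp, reduced=True)
        assert mass == pytest.approx(676.2538, abs=1e-4)
        assert glycan_mz(mass, 1) == pytest.approx(675.2466, abs=1e-4)

    @given(comps, st.booleans())
    def test_matches_elemental_oracle(self, comp, reduced):
        assert glycan_monoisotopic_mass(comp, reduced) == pytest.approx(
            oracle_mass(comp, reduced), abs=1e-4
        )

    @given(comps, comps)
    def test_mass_additivity(self, a, b):
        water = oracle_mass(MonosaccharideComposition(hex=1)) - sum(
            _ATOM[el] * n for el, n in _RES["hex"].items()
        )
        assert glycan_monoisotopic_mass(a + b) == pytest.approx(
            glycan_monoisotopic_mass(a) + glycan_monoisotopic_mass(b) - water,
            abs=1e-9,
        )

    @given(comps)
    def test_alditol_is_h2_heavier(self, comp):
        delta = glycan_monoisotopic_mass(comp, True) - glycan_monoisotopic_mass(comp, False)
        assert delta == pytest.approx(2.01565, abs=1e-5)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            glycan_monoisotopic_mass(MonosaccharideComposition())

    def test_mz_definition_at_z1(self):
        for m in (500.0, 675.2466, 2222.783):
            assert glycan_mz(m, 1) == pytest.approx(m - 1.007276466, abs=1e-9)
        with pytest.raises(ValueError):
            glycan_mz(500.0, 0)


class TestMatchMz:
    CANDIDATES = [
        parse_composition("Hex5HexNAc4NeuAc2"),
        parse_composition("Hex5HexNAc4NeuAc1"),
    ]

    def test_unique_match(self):
        hits = match_mz(1110.3842, 2, self.CANDIDATES, tol=10)
        assert [h.composition for h in hits] == [self.CANDIDATES[0]]

    def test_tiny_tolerance_excludes(self):
        assert match_mz(1110.3845, 2, self.CANDIDATES, tol=0.0001) == []

    def test_tied_duplicates(self):
        hits = match_mz(1110.3842, 2, [self.CANDIDATES[0]] * 2, tol=10)
        assert len(hits) == 2
        assert hits[0].ppm_error == hits[1].ppm_error

    @given(st.floats(500, 3000), st.integers(1, 3), st.floats(1, 50))
    def test_agrees_with_brute_force(self, observed, z, tol):
        candidates = [
            MonosaccharideComposition(hex=h, hexnac=n)
            for h in range(1, 8)
            for n in range(0, 5)
        ]
        hits = {str(h.composition) for h in match_mz(observed, z, candidates, tol=tol)}
        brute = {
            str(c)
            for c in candidates
            if abs(
                (observed - glycan_mz(glycan_monoisotopic_mass(c), z))
                / glycan_mz(glycan_monoisotopic_mass(c), z)
            )
            * 1e6
            <= tol
        }
        assert hits == brute


class TestQuantification:
    def test_base_peak_window(self):
        peaks = PeakList(
            "s",
            [Peak(1110.384, 500), Peak(1110.385, 900), Peak(900.0, 1e6)],
        )
        assert xic_base_peak(peaks, 1110.3842, tol=10) == 900

    def test_base_peak_empty(self):
        assert xic_base_peak(PeakList("s", []), 1110.0, tol=10) == 0

    def test_base_peak_order_free(self):
        peaks = [Peak(1000.0, i) for i in (3, 9, 1)]
        assert xic_base_peak(peaks, 1000.0, 5) == xic_base_peak(peaks[::-1], 1000.0, 5)

    def test_relative_abundance(self):
        assert relative_abundance({"A": 300, "B": 100}) == {"A": 75.0, "B": 25.0}
        assert relative_abundance({"A": 7}) == {"A": 100.0}

    @given(
        st.dictionaries(
            st.text("ABCDEF", min_size=1, max_size=3),
            st.floats(0, 1e6),
            min_size=1,
            max_size=8,
        ).filter(lambda d: sum(d.values()) > 1e-6),
        st.floats(0.001, 1000),
    )
    def test_profile_sums_to_100_and_scale_invariant(self, intensities, c):
        prof = relative_abundance(intensities)
        assert sum(prof.values()) == pytest.approx(100.0, abs=1e-6)
        scaled = relative_abundance({k: v * c for k, v in intensities.items()})
        for k in prof:
            assert scaled[k] == pytest.approx(prof[k], rel=1e-9, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance({"A": 0.0})


class TestFoldChange:
    def test_flags(self):
        entries = glycome_fold_change({"A": 4.0, "B": 1.0}, {"A": 1.0, "B": 1.6}, 2.0)
        by = {e.structure: e for e in entries}
        assert by["A"].ratio == pytest.approx(4.0) and by["A"].flag == "up"
        assert by["B"].flag == ""
        entries15 = glycome_fold_change({"B": 1.0}, {"B": 1.6}, 1.5)
        assert entries15[0].ratio == pytest.approx(0.625)
        assert entries15[0].flag == "down"

    def test_identity(self):
        prof = {"A": 60.0, "B": 40.0}
        for e in glycome_fold_change(prof, prof, 2.0):
            assert e.ratio == pytest.approx(1.0) and e.flag == ""

    @given(
        st.dictionaries(st.text("ABC", min_size=1, max_size=2), st.floats(0.01, 99), min_size=1),
        st.floats(1.1, 4),
    )
    def test_antisymmetric(self, case, threshold):
        control = {k: 100.0 - v for k, v in case.items()}
        fwd = {e.structure: e.flag for e in glycome_fold_change(case, control, threshold)}
        rev = {e.structure: e.flag for e in glycome_fold_change(control, case, threshold)}
        swap = {"up": "down", "down": "up", "": ""}
        assert rev == {k: swap[v] for k, v in fwd.items()}


class TestLinkage:
    COMPS = {
        "sia": parse_composition("Hex5HexNAc4NeuAc2"),
        "asialo": parse_composition("Hex3HexNAc2"),
    }

    def test_alpha23(self):
        calls = infer_sialic_linkage(
            {"sia": 10.0, "asialo": 90.0},
            {"sia": 0.5, "asialo": 99.5},
            {"sia": 0.2, "asialo": 99.8},
            self.COMPS,
        )
        assert calls["sia"] == "a2-3" and calls["asialo"] == "n/a"

    def test_alpha268(self):
        calls = infer_sialic_linkage(
            {"sia": 10.0, "asialo": 90.0},
            {"sia": 9.8, "asialo": 90.2},
            {"sia": 0.4, "asialo": 99.6},
            self.COMPS,
        )
        assert calls["sia"] == "a2-6/8"

    def test_resistant(self):
        calls = infer_sialic_linkage(
            {"sia": 10.0, "asialo": 90.0},
            {"sia": 9.9, "asialo": 90.1},
            {"sia": 9.7, "asialo": 90.3},
            self.COMPS,
        )
        assert calls["sia"] == "resistant/uncertain"

    def test_missing_structure_rejected(self):
        with pytest.raises(KeyError):
            infer_sialic_linkage(
                {"sia": 100.0}, {}, {"sia": 100.0}, {"sia": self.COMPS["sia"]}
            )
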