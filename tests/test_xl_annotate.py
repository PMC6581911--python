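"""Theoretical ion generation, spectrum annotation and XL filtering."""

import numpy as np
import pytest

from capri import chem
from capri.chem import PROTON, WATER, peptide_mono_mass
from capri.ptm_catalog import PtmAssignment
from capri.xl_annotate import (
    AnnotatedSpectrum,
    AnnotationConfig,
    CrosslinkedPeptide,
    annotate,
    filter_xl_candidates,
    summarize_xl,
    theoretical_ions,
)
from capri.fixtures import SpectrumNoise, synth_xl_spectrum


def make_xl(catalog_by_name, seq="VFIGNLNTLVVK", site=3, base="U", terminal=None, charge=2):
    residue = {site: catalog_by_name[f"{base}_base"]}
    terminals = {"N": catalog_by_name[terminal]} if terminal else {}
    return CrosslinkedPeptide(
        sequence=seq,
        assignment=PtmAssignment(seq, residue, terminals),
        charge=charge,
        protein_id="P1",
        start=18,
        end=18 + len(seq) - 1,
        carbamidomethyl_cys=False,
    )


NO_FLOOR = AnnotationConfig(lowest_mz=0.0)


def by_map(ions):
    return {
        (i.series, i.ordinal, i.charge): i.mz for i in ions if i.series in ("b", "y")
    }


def test_by_complementarity_with_site_mass(catalog_by_name):
    """b_i + y_{n-i} at charge 1 must equal peptide + base + 2 protons:
    exactly one of each complementary pair carries the crosslinked base."""
    xl = make_xl(catalog_by_name, site=5)
    ions = by_map(theoretical_ions(xl))
    n = len(xl.sequence)
    base_mass = catalog_by_name["U_base"].mass
    total = peptide_mono_mass(xl.sequence) + base_mass + 2 * PROTON
    for i in range(1, n):
        assert ions[("b", i, 1)] + ions[("y", n - i, 1)] == pytest.approx(total, abs=1e-9)


def test_terminal_adduct_not_on_fragments(catalog_by_name):
    plain = by_map(theoretical_ions(make_xl(catalog_by_name)))
    with_term = by_map(theoretical_ions(make_xl(catalog_by_name, terminal="A_plus_rest")))
    assert plain == pytest.approx(with_term)


def test_crosslink_site_move_changes_spanning_fragments(catalog_by_name):
    """Moving the site i -> j toggles the base mass on exactly the fragments
    that separate the two positions (brute-force containment oracle)."""
    seq = "ACDEFGHIKLMNPQR"
    n = len(seq)
    for i, j in [(2, 7), (1, 14), (5, 6)]:
        a = by_map(theoretical_ions(make_xl(catalog_by_name, seq=seq, site=i), NO_FLOOR))
        b = by_map(theoretical_ions(make_xl(catalog_by_name, seq=seq, site=j), NO_FLOOR))
        changed = {k for k in a if abs(a[k] - b[k]) > 1e-9}
        expected = set()
        for ordinal in range(1, n):
            # brute force: which prefix/suffix contains one site but not the other
            for series, residues in (("b", range(1, ordinal + 1)), ("y", range(n - ordinal + 1, n + 1))):
                if (i in residues) != (j in residues):
                    for z in (1,):
                        expected.add((series, ordinal, z))
        assert changed == expected


def test_marker_set_for_au_dinucleotide(catalog_by_name):
    xl = make_xl(catalog_by_name, terminal="A_plus_rest")
    markers = {i.label: i.mz for i in theoretical_ions(xl) if i.series == "marker"}
    assert markers["A_base+"] == pytest.approx(136.0618, abs=1e-4)
    assert markers["U_base+"] == pytest.approx(113.0346, abs=1e-4)
    assert markers["cAMP+"] == pytest.approx(330.0598, abs=1e-4)
    assert markers["cUMP+"] == pytest.approx(307.0326, abs=1e-4)
    assert markers["cAMP+-H2O"] == pytest.approx(312.0492, abs=1e-4)
    assert "cCMP+" not in markers  # no cytidine in the AU adduct


def test_second_water_loss_only_for_adenosine(catalog_by_name):
    xl = make_xl(catalog_by_name, base="C", terminal="U_plus_rest")
    labels = {i.label for i in theoretical_ions(xl) if i.series == "marker"}
    assert "cAMP+-H2O" not in labels
    assert {"C_base+", "U_base+", "cUMP+", "cCMP+"} <= labels


def test_precursor_neutral_loss_ladder_conservation(catalog_by_name):
    """The ladder starts at the intact precursor and descends by HPO3, the
    anhydro-ribose completing 'rest', or whole mononucleotides."""
    xl = make_xl(catalog_by_name, terminal="AU_plus_rest", charge=2)
    nl = sorted(
        (chem.neutral_mass(i.mz, i.charge) for i in theoretical_ions(xl)
         if i.series == "precursor_NL" and i.charge == 1),
        reverse=True,
    )
    assert nl[0] == pytest.approx(xl.precursor_neutral_mass, abs=1e-9)
    ribose_anhydro = chem.composition_mass(chem.ElementalComposition.from_formula("C5H8O4"))
    nmp = {
        nt: chem.composition_mass(c) + 212.008589
        for nt, c in __import__("capri.ptm_catalog", fromlist=["NUCLEOBASE_COMPOSITIONS"]).NUCLEOBASE_COMPOSITIONS.items()
    }
    allowed = [chem.HPO3, ribose_anhydro] + list(nmp.values())
    for hi, lo in zip(nl, nl[1:]):
        step = hi - lo
        assert any(abs(step - a) < 1e-6 for a in allowed), step
    # the ladder bottoms out at the peptide + base conjugate
    base_only = peptide_mono_mass(xl.sequence) + catalog_by_name["U_base"].mass
    assert nl[-1] == pytest.approx(base_only, abs=1e-6)


def test_invalid_assignment_rejected(catalog_by_name):
    bad = CrosslinkedPeptide(
        sequence="PEPTIDEK",
        assignment=PtmAssignment("PEPTIDEK", {}, {"N": catalog_by_name["rest"]}),
        carbamidomethyl_cys=False,
    )
    with pytest.raises(ValueError, match="no_base"):
        theoretical_ions(bad)


def test_annotation_floor_suppresses_low_mz(catalog_by_name):
    cfg = AnnotationConfig(lowest_mz=200.0)
    ions = theoretical_ions(make_xl(catalog_by_name, terminal="A_plus_rest"), cfg)
    assert all(i.mz >= 200.0 for i in ions)


class TestAnnotate:
    def test_noiseless_roundtrip(self, catalog_by_name):
        xl = make_xl(catalog_by_name, terminal="A_plus_rest")
        peaks, ions = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=0))
        ann = annotate(peaks, xl)
        assert len(ann.matches) == len(ions)
        assert max(abs(m.error_da) for m in ann.matches) < 1e-9
        assert ann.fragment_fraction == pytest.approx(1.0)

    def test_global_shift_beyond_tolerance_kills_matches(self, catalog_by_name):
        xl = make_xl(catalog_by_name)
        peaks, _ = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=0))
        shifted = peaks.copy()
        shifted[:, 0] += 0.05
        ann = annotate(shifted, xl, AnnotationConfig(fragment_tol_da=0.02))
        assert len(ann.matches) == 0

    def test_dinucleotide_base_peak_is_marker(self, catalog_by_name):
        xl = make_xl(catalog_by_name, terminal="A_plus_rest")
        peaks, _ = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=10))
        ann = annotate(peaks, xl)
        assert ann.base_peak_is_marker

    def test_permutation_and_rescaling_invariance(self, catalog_by_name, rng):
        xl = make_xl(catalog_by_name, terminal="A_plus_rest")
        peaks, _ = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=15), rng)
        ann1 = annotate(peaks, xl)
        shuffled = peaks[rng.permutation(len(peaks))]
        shuffled[:, 1] *= 3.7
        ann2 = annotate(shuffled, xl)
        key = lambda a: sorted((m.ion.label, m.ion.charge, round(m.observed_mz, 9)) for m in a.matches)
        assert key(ann1) == key(ann2)
        assert ann1.fragment_fraction == ann2.fragment_fraction

    def test_empty_spectrum_errors(self, catalog_by_name):
        with pytest.raises(ValueError, match="empty"):
            annotate(np.empty((0, 2)), make_xl(catalog_by_name))


class TestFilter:
    def test_rest_only_candidate_rejected(self, catalog_by_name):
        bad = CrosslinkedPeptide(
            sequence="PEPTIDEK",
            assignment=PtmAssignment("PEPTIDEK", {}, {"N": catalog_by_name["rest"]}),
            carbamidomethyl_cys=False,
        )
        spec = AnnotatedSpectrum(
            spectrum_id="s1", candidate=bad,
            peaks_mz=np.array([100.0]), peaks_intensity=np.array([1.0]),
        )
        accepted, rejected = filter_xl_candidates([spec])
        assert not accepted
        assert rejected[0][1] == "no_base"

    def test_noiseless_valid_candidate_accepted(self, catalog_by_name):
        xl = make_xl(catalog_by_name, terminal="A_plus_rest")
        peaks, _ = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=0))
        accepted, rejected = filter_xl_candidates([annotate(peaks, xl)])
        assert len(accepted) == 1 and not rejected

    def test_low_coverage_rejected(self, catalog_by_name):
        xl = make_xl(catalog_by_name)
        ions = theoretical_ions(xl)
        frag = [i for i in ions if i.series in ("b", "y")]
        keep = frag[: max(1, len(frag) // 10)]  # ~10% coverage
        peaks = np.array([[i.mz, 100.0] for i in keep])
        ann = annotate(peaks, xl)
        accepted, rejected = filter_xl_candidates([ann], AnnotationConfig(min_fragment_fraction=0.4))
        assert not accepted
        assert rejected[0][1] == "low_coverage"

    def test_decoy_only_spectrum_rejected(self, catalog_by_name, rng):
        xl = make_xl(catalog_by_name, terminal="A_plus_rest")
        decoys = np.column_stack([rng.uniform(400, 900, 30), np.full(30, 5.0)])
        ann = annotate(decoys, xl)
        accepted, rejected = filter_xl_candidates([ann])
        assert not accepted

    def test_missing_marker_rejected_for_dinucleotide(self, catalog_by_name):
        xl = make_xl(catalog_by_name, terminal="A_plus_rest")
        ions = theoretical_ions(xl)
        peaks = np.array([[i.mz, 100.0] for i in ions if i.series != "marker"])
        ann = annotate(peaks, xl)
        accepted, rejected = filter_xl_candidates([ann])
        assert rejected and rejected[0][1] == "missing_marker"


def test_summarize_counts(catalog_by_name):
    assert summarize_xl([]) == summarize_xl([])
    assert summarize_xl([]).crosslinks == 0

    def spec_for(seq, terminal, protein="P1"):
        xl = make_xl(catalog_by_name, seq=seq, terminal=terminal)
        xl.protein_id = protein
        peaks, _ = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=0))
        return annotate(peaks, xl)

    specs = [
        spec_for("VFIGNLNTLVVK", None),
        spec_for("VFIGNLNTLVVK", "A_plus_rest"),
        spec_for("VFIGNLNTLVVK", "A_plus_rest"),  # duplicate heteroconjugate
    ]
    summary = summarize_xl(specs)
    # naive de-dup oracle
    assert summary.crosslinks == 2
    assert summary.peptides == 1
    assert summary.proteins == 1


def test_mgf_roundtrip(tmp_path, catalog_by_name):
    from capri.fixtures import write_mgf
    from capri.xl_annotate import read_mgf

    xl = make_xl(catalog_by_name, terminal="A_plus_rest")
    peaks, ions = synth_xl_spectrum(xl, SpectrumNoise(n_decoys=5))
    path = tmp_path / "spectra.mgf"
    write_mgf(
        [{"id": "spec1", "pepmass": chem.mz(xl.precursor_neutral_mass, xl.charge), "charge": 2, "peaks": peaks}],
        path,
    )
    spectra = read_mgf(path)
    assert len(spectra) == 1
    assert spectra[0]["id"] == "spec1"
    assert spectra[0]["charge"] == 2
    np.testing.assert_allclose(spectra[0]["peaks"][:, 0], peaks[:, 0], atol=1e-5)
    ann = annotate(spectra[0]["peaks"], xl)
    assert len(ann.matches) == len(ions)
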