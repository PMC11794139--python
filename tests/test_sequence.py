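"""Sequence charge, composition and patterning metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasekit.exceptions import ConfigurationError, FormatError, ValidationError
from phasekit.sequence import (
    CANONICAL_RESIDUES,
    ChargeModel,
    ResidueSequence,
    aromatic_spacing,
    composition,
    ncpr_profile,
    net_charge,
    read_fasta,
)

random_protein = st.text(
    alphabet=sorted(CANONICAL_RESIDUES), min_size=1, max_size=200
)


class TestResidueSequence:
    def test_case_normalised(self):
        lower = ResidueSequence("x", "mnrmfvlaatlalvgmvfa")
        upper = ResidueSequence("x", "MNRMFVLAATLALVGMVFA")
        assert lower.residues == upper.residues

    def test_non_canonical_letter_names_position(self):
        with pytest.raises(ValidationError, match="position 3"):
            ResidueSequence("x", "GGBGG")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ResidueSequence("x", "")

    def test_fragment_is_one_based_inclusive(self, signal_peptide):
        frag = signal_peptide.fragment(1, 4)
        assert frag.residues == "MNRM"


class TestReadFasta:
    def test_reads_signal_peptide_record(self, tmp_fasta, signal_peptide):
        path = tmp_fasta({"sig": signal_peptide.residues})
        records = read_fasta(path)
        assert len(records) == 1
        assert len(records[0]) == 19

    def test_lowercase_equals_uppercase(self, tmp_fasta, signal_peptide):
        p1 = tmp_fasta({"a": signal_peptide.residues.lower()}, "lo.fasta")
        p2 = tmp_fasta({"a": signal_peptide.residues}, "up.fasta")
        assert read_fasta(p1)[0].residues == read_fasta(p2)[0].residues

    def test_invalid_letter_rejected(self, tmp_fasta):
        path = tmp_fasta({"bad": "MNBM"})
        with pytest.raises(ValidationError, match="position 3"):
            read_fasta(path)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(FormatError):
            read_fasta(path)


class TestComposition:
    def test_glycine_homopolymer(self):
        rep = composition(ResidueSequence("g", "GGGGG"))
        assert rep.category_fractions["glycine"] == 1.0
        assert rep.category_counts["glycine"] == 5

    def test_signal_peptide_alanine_count(self, signal_peptide):
        rep = composition(signal_peptide)
        assert rep.residue_counts["A"] == 4
        assert rep.residue_counts["A"] / rep.length == pytest.approx(4 / 19)

    def test_incomplete_category_map_rejected(self, signal_peptide):
        with pytest.raises(ConfigurationError, match="does not cover"):
            composition(signal_peptide, {"glycine": {"G"}})

    def test_overlapping_categories_rejected(self, signal_peptide):
        bad = {"a": set("ACDEFGHIKL"), "b": set("LMNPQRSTVWY"), "g": set("G")}
        with pytest.raises(ConfigurationError, match="overlap"):
            composition(signal_peptide, bad)

    @settings(max_examples=50, deadline=None)
    @given(residues=random_protein)
    def test_fractions_sum_to_one_and_counts_to_length(self, residues):
        rep = composition(ResidueSequence("r", residues))
        assert sum(rep.category_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(rep.category_counts.values()) == len(residues)


class TestNetCharge:
    def test_formal_balanced(self):
        q = net_charge(ResidueSequence("x", "EKRD"), model=ChargeModel(mode="formal"))
        assert q == 0

    def test_free_glycine_hh_closed_form(self):
        # single residue with only terminal groups: q = 1/(1+10^(pH-9.0))
        # - 1/(1+10^(3.55-pH)) evaluated at pH 7.4
        expected = 1 / (1 + 10 ** (7.4 - 9.0)) - 1 / (1 + 10 ** (3.55 - 7.4))
        q = net_charge(ResidueSequence("g", "G"), pH=7.4)
        assert q == pytest.approx(expected, abs=1e-12)
        assert q == pytest.approx(-0.024, abs=5e-4)

    def test_ph_out_of_range_rejected(self, signal_peptide):
        with pytest.raises(ValidationError):
            net_charge(signal_peptide, pH=15.0)

    @settings(max_examples=30, deadline=None)
    @given(residues=random_protein)
    def test_hh_charge_monotone_non_increasing_in_ph(self, residues):
        seq = ResidueSequence("r", residues)
        charges = [net_charge(seq, ph) for ph in np.linspace(0.0, 14.0, 29)]
        assert all(b <= a + 1e-12 for a, b in zip(charges, charges[1:]))

    @settings(max_examples=30, deadline=None)
    @given(residues=st.text(alphabet=sorted(set("GAKRDE")), min_size=1, max_size=80))
    def test_hh_approaches_formal_far_from_pkas(self, residues):
        # with H/C/Y absent and termini off, pH 7.4 sits >= ~3 units from
        # every relevant pKa only in a contrived table; instead evaluate at a
        # pH >= 6 units away from all pKas of the table
        seq = ResidueSequence("r", residues)
        pka = {"nterm": 13.5, "cterm": 0.5, "D": 0.6, "E": 0.7, "C": 13.6,
               "Y": 13.7, "H": 13.2, "K": 13.8, "R": 13.9}
        hh = ChargeModel(mode="henderson_hasselbalch", pka=pka, include_termini=False)
        formal = ChargeModel(mode="formal")
        assert net_charge(seq, 7.4, hh) == pytest.approx(
            net_charge(seq, 7.4, formal), abs=1e-5
        )


class TestNcprProfile:
    def test_lysine_homopolymer_all_positive(self):
        prof = ncpr_profile(ResidueSequence("k", "KKKKK"), window=3)
        assert np.allclose(prof.ncpr, 1.0)

    def test_alternating_ek_global_stats(self):
        prof = ncpr_profile(ResidueSequence("ek", "EKEKEKEK"), window=1)
        assert prof.global_ncpr == pytest.approx(0.0)
        assert prof.global_fcr == pytest.approx(1.0)

    def test_even_window_rejected(self, signal_peptide):
        with pytest.raises(ConfigurationError):
            ncpr_profile(signal_peptide, window=4)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            ncpr_profile(ResidueSequence("s", "GKG"), window=5)

    def test_edge_windows_truncated_not_padded(self):
        # KGGGG, window 3: first value averages positions 1-2 only
        prof = ncpr_profile(ResidueSequence("s", "KGGGG"), window=3)
        assert prof.ncpr[0] == pytest.approx(0.5)
        assert prof.ncpr[1] == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        ("residues", "region"),
        [
            ("G" * 20, "R1"),  # FCR 0
            ("KE" + "G" * 8, "R1"),  # FCR 0.2
            ("KKKEEE" + "G" * 14, "R2"),  # FCR 0.3
            ("KKEE" + "G" * 6, "R3"),  # f+ = f- = 0.2, FCR 0.4
            ("E" * 4 + "G" * 6, "R4"),  # f- = 0.4
            ("K" * 4 + "G" * 6, "R5"),  # f+ = 0.4
        ],
    )
    def test_das_pappu_regions(self, residues, region):
        assert ncpr_profile(ResidueSequence("r", residues)).das_pappu_region == region

    @settings(max_examples=50, deadline=None)
    @given(residues=random_protein)
    def test_fcr_and_ncpr_invariants(self, residues):
        prof = ncpr_profile(ResidueSequence("r", residues), window=1)
        assert prof.global_fcr == pytest.approx(
            prof.fraction_positive + prof.fraction_negative
        )
        assert abs(prof.global_ncpr) <= prof.global_fcr + 1e-12
        assert np.all(np.abs(prof.ncpr) <= 1 + 1e-12)


class TestAromaticSpacing:
    def test_regular_spacing(self):
        sp = aromatic_spacing(ResidueSequence("s", "FGGGFGGGF"))
        assert sp.gaps == (4, 4)
        assert sp.median_gap == 4

    def test_no_aromatics(self):
        sp = aromatic_spacing(ResidueSequence("s", "GGGG"))
        assert sp.gaps == ()
        assert sp.n_aromatic == 0
        assert sp.median_gap is None

    def test_single_aromatic_has_no_gaps(self):
        sp = aromatic_spacing(ResidueSequence("s", "GGWGG"))
        assert sp.n_aromatic == 1
        assert sp.gaps == ()

    def test_counts_on_signal_peptide(self, signal_peptide):
        # MNRMFVLAATLALVGMVFA has two phenylalanines (positions 5 and 18)
        sp = aromatic_spacing(signal_peptide)
        assert sp.n_aromatic == 2
        assert sp.aromatic_positions == (5, 18)
        assert sp.gaps == (13,)
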