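"""Alignment coordinate mapping and conservation inference."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from proforms.conservation import (
    Alignment,
    AlignmentError,
    FormSite,
    ModForm,
    ModSite,
    annotate_alignment,
    infer_form,
    read_alignment,
    site_conserved,
    write_alignment_fasta,
)
from proforms.synthetic import FROG, HUMAN, IDS, MOUSE


def random_alignment(seed, n_rows=3, n_cols=40):
    rng = random.Random(seed)
    rows = []
    for i in range(n_rows):
        row = "".join(
            "-" if rng.random() < 0.25 else rng.choice("ACDEFGHIKLMNPQRST")
            for _ in range(n_cols)
        )
        if row.strip("-") == "":  # keep at least one residue per row
            row = "A" + row[1:]
        rows.append((f"s{i}", row))
    return Alignment(rows)


class TestAlignmentContainer:
    def test_unequal_rows_rejected(self):
        with pytest.raises(AlignmentError, match="unequal"):
            Alignment([("a", "ACGT"), ("b", "ACG")])

    def test_ungapping_reproduces_input(self):
        aln = Alignment([("a", "AC-GT"), ("b", "ACTGT")])
        assert aln.ungapped("a") == "ACGT"
        assert aln.ungapped_length("b") == 5

    def test_fasta_round_trip(self, fx, tmp_path):
        p = tmp_path / "a.fasta"
        write_alignment_fasta(fx.alignment, p)
        again = read_alignment(p)
        assert again.rows == fx.alignment.rows


class TestMapPosition:
    def test_hand_countable_toy(self):
        aln = Alignment([("a", "AC-GT"), ("b", "ACTGT")])
        assert aln.map_position("a", 3, "b") == 4

    def test_gap_column_maps_to_none(self):
        aln = Alignment([("a", "ACGT"), ("b", "A-GT")])
        assert aln.map_position("a", 2, "b") is None

    def test_out_of_range_rejected(self):
        aln = Alignment([("a", "AC-GT"), ("b", "ACTGT")])
        with pytest.raises(AlignmentError):
            aln.map_position("a", 5, "b")
        with pytest.raises(AlignmentError):
            aln.map_position("zz", 1, "a")

    def test_fixture_reproduces_curated_correspondences(self, fx):
        a = fx.alignment
        assert a.map_position(HUMAN, 620, FROG) == 605
        assert a.map_position(HUMAN, 620, MOUSE) == 613
        assert a.map_position(HUMAN, 676, MOUSE) == 665
        assert a.map_position(HUMAN, 680, FROG) == 659
        assert a.map_position(HUMAN, 608, FROG) == 593
        assert a.map_position(HUMAN, 543, MOUSE) == 535
        assert a.map_position(HUMAN, 1043, MOUSE) == 1033
        assert a.map_position(HUMAN, 1043, FROG) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_on_non_gap_columns(self, seed):
        aln = random_alignment(seed)
        for pos in range(1, aln.ungapped_length("s0") + 1):
            mapped = aln.map_position("s0", pos, "s1")
            if mapped is not None:
                assert aln.map_position("s1", mapped, "s0") == pos

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_on_non_gap_columns(self, seed):
        aln = random_alignment(seed)
        mapped = [aln.map_position("s0", p, "s2")
                  for p in range(1, aln.ungapped_length("s0") + 1)]
        hits = [m for m in mapped if m is not None]
        assert hits == sorted(hits)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 200))
    def test_self_mapping_is_identity(self, seed, pos):
        aln = random_alignment(seed)
        n = aln.ungapped_length("s1")
        pos = 1 + (pos - 1) % n
        assert aln.map_position("s1", pos, "s1") == pos


class TestSiteConserved:
    def test_s670_conserved_in_frog(self, fx):
        site = ModSite(HUMAN, 670, "S")
        v = site_conserved(fx.alignment, site, FROG)
        assert v.conserved and v.mapped_position == 649 and v.mapped_residue == "S"

    def test_site_in_gap_column_not_conserved(self, fx):
        v = site_conserved(fx.alignment, ModSite(HUMAN, 1043, "S"), FROG)
        assert not v.conserved and v.mapped_position is None

    def test_residue_mismatch_not_conserved(self, fx):
        v = site_conserved(fx.alignment, ModSite(HUMAN, 543, "S"), FROG)
        assert not v.conserved and v.mapped_residue == "A"

    def test_st_equivalence_rule_flips_verdict(self):
        aln = Alignment([("a", "ASA"), ("b", "ATA")])
        site = ModSite("a", 2, "S")
        assert not site_conserved(aln, site, "b").conserved
        assert site_conserved(aln, site, "b", "st_equivalent").conserved

    def test_wrong_stated_residue_rejected(self, fx):
        with pytest.raises(AlignmentError, match="site says"):
            site_conserved(fx.alignment, ModSite(HUMAN, 620, "Y"), FROG)


class TestInferForm:
    def test_phos4_absent_in_frog(self, fx):
        form = next(f for f in fx.forms if f.form_id == IDS["p4"])
        call = infer_form(fx.alignment, form, FROG, fx.sites_corroborating)
        assert call.status == "absent"
        assert sum(v.conserved for v in call.site_verdicts if v.required) == 1

    def test_phos1_predicted_in_mouse_via_htp_site(self, fx):
        form = next(f for f in fx.forms if f.form_id == IDS["p1"])
        call = infer_form(fx.alignment, form, MOUSE, fx.sites_corroborating)
        assert call.status == "predicted"
        assert "target_htp_site" in call.evidence

    def test_conserved_without_corroboration_is_insufficient(self, fx):
        form = next(f for f in fx.forms if f.form_id == IDS["p1"])
        call = infer_form(fx.alignment, form, MOUSE)
        assert call.status == "insufficient_evidence"

    def test_registry_entry_wins(self, fx):
        form = next(f for f in fx.forms if f.form_id == IDS["p2"])
        call = infer_form(fx.alignment, form, FROG,
                          curated_registry=fx.registry_pairs())
        assert call.status == "curated"

    def test_kinase_tag_corroborates(self, fx):
        form = next(f for f in fx.forms if f.form_id == IDS["p2"])
        call = infer_form(fx.alignment, form, FROG,
                          evidence_tags=("analogous_kinase_demonstrated",))
        assert call.status == "predicted"

    def test_missing_reference_sequence_rejected(self, fx):
        form = ModForm("PR:1", "X", "BUB1B_rat",
                       (FormSite(ModSite("BUB1B_rat", 1, "S")),))
        with pytest.raises(AlignmentError, match="missing"):
            infer_form(fx.alignment, form, MOUSE)

    def test_adding_required_site_only_moves_toward_absent(self, fx):
        """Anti-monotonicity: growing the required-site set never turns an
        absent call into a predicted one."""
        order = {"absent": 0, "insufficient_evidence": 1, "predicted": 2,
                 "curated": 2}
        base_sites = [FormSite(ModSite(HUMAN, 670, "S"))]
        extra = [ModSite(HUMAN, 543, "S"), ModSite(HUMAN, 1043, "S"),
                 ModSite(HUMAN, 620, "T")]
        prev = None
        for i in range(len(extra) + 1):
            form = ModForm("PR:000035434", "BUB1B", HUMAN,
                           tuple(base_sites + [FormSite(s) for s in extra[:i]]))
            call = infer_form(fx.alignment, form, FROG,
                              fx.sites_corroborating,
                              evidence_tags=("analogous_kinase_demonstrated",))
            if prev is not None:
                assert order[call.status] <= order[prev]
            prev = call.status

    def test_form_requires_at_least_one_required_site(self):
        with pytest.raises(AlignmentError, match="required"):
            ModForm("PR:1", "X", HUMAN,
                    (FormSite(ModSite(HUMAN, 620, "T"), required=False),))


class TestAnnotateAlignment:
    def test_fixture_features_mark_experimental_and_predicted(self, fx):
        form = next(f for f in fx.forms if f.form_id == IDS["p1"])
        call = infer_form(fx.alignment, form, MOUSE, fx.sites_corroborating)
        text = annotate_alignment(fx.alignment, [call], fx.sites_experimental)
        lines = text.splitlines()
        assert any(f"\t{HUMAN}\t-1\t620\t620\texperimental_phosphosite" in ln
                   for ln in lines)
        assert any(f"\t{MOUSE}\t-1\t613\t613\tpredicted_phosphosite" in ln
                   for ln in lines)

    def test_no_sites_gives_header_only(self, fx):
        text = annotate_alignment(fx.alignment)
        assert text.splitlines() == ["experimental_phosphosite\t0000ff",
                                     "predicted_phosphosite\tff0000"]

    def test_every_feature_position_within_ungapped_sequence(self, fx):
        reg = fx.registry_pairs()
        calls = [
            infer_form(fx.alignment, f, target, fx.sites_corroborating, reg,
                       fx.evidence_tags.get((f.form_id, target), ()))
            for f in fx.forms for target in (FROG, MOUSE)
        ]
        text = annotate_alignment(fx.alignment, calls, fx.sites_experimental)
        for line in text.splitlines():
            cols = line.split("\t")
            if len(cols) != 6:
                continue  # colour header
            _, seq_id, _, start, end, _ = cols
            assert 1 <= int(start) == int(end)
            assert int(start) <= fx.alignment.ungapped_length(seq_id)
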