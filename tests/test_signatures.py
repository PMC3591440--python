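import pytest
from hypothesis import given, settings, strategies as st

from frdsig.core import ProteinRecord
from frdsig.refmap import PositionMap, build_position_map, global_align
from frdsig.signatures import (
    LABEL_AMBIGUOUS,
    LABEL_FRE,
    LABEL_NOX,
    LABEL_PRENOX,
    LABEL_YEDZ_STEAP,
    ResidueVector,
    SUBTYPE_STEAP24,
    SUBTYPE_YEDZ_STEAP1,
    classify,
    classify_msa,
    classify_record,
    default_signature_table,
    discover_signatures,
    extract_residue_vector,
    heme_histidine_count,
    identity_position_map,
    nox_call_positions,
)
from frdsig.conservation import profile_msa
from frdsig.synthetic import (
    EXPECTED_LABELS,
    GeneratorConfig,
    default_templates,
    generate_family,
)

POSITIONS = (101, 115, 119, 178, 179, 209, 222)


def vector(letters, query_id="q"):
    """Residue vector from a 7-tuple in position order (None = absent)."""
    return ResidueVector(
        query_id=query_id, residues=dict(zip(POSITIONS, letters))
    )


class TestExtraction:
    def test_nox2_against_itself_yields_the_printed_signature(self, nox2):
        ref = nox2.reference
        pmap = build_position_map(global_align(ref, ref))
        vec = extract_residue_vector(ref, pmap, reference=ref)
        assert [vec.residues[p] for p in POSITIONS] == ["H", "H", "H", "T", "G", "H", "H"]

    def test_position_aligned_to_gap_reports_absent(self, nox2):
        ref = nox2.reference
        # query lacking residue 119: reference position 119 must come out absent
        query = ProteinRecord(
            id="del119", sequence=ref.sequence[:118] + ref.sequence[119:]
        )
        pairs = [(i, i) for i in range(1, 119)] + [
            (i - 1, i) for i in range(120, len(ref.sequence) + 1)
        ]
        pmap = PositionMap(pairs=pairs, query_length=len(query.sequence), ref_length=len(ref.sequence))
        vec = extract_residue_vector(query, pmap, reference=ref)
        assert vec.residues[119] is None
        assert vec.residues[101] == "H" and vec.residues[178] == "T"

    def test_mismatched_reference_length_raises(self, nox2):
        pmap = PositionMap(pairs=[(1, 1)], query_length=1, ref_length=5)
        query = ProteinRecord(id="q", sequence="H")
        with pytest.raises(ValueError, match="reference"):
            extract_residue_vector(query, pmap, reference=nox2.reference)


class TestClassify:
    @pytest.mark.parametrize(
        "letters, label, subtype, heme",
        [
            (("H", "H", "H", "T", "G", "H", "H"), LABEL_NOX, None, 4),
            (("R", "H", "L", "S", "A", "Q", "H"), LABEL_YEDZ_STEAP, SUBTYPE_STEAP24, 2),
            (("R", "H", "L", "S", "A", "H", "H"), LABEL_YEDZ_STEAP, SUBTYPE_YEDZ_STEAP1, 3),
            (("H", "H", "F", "S", "A", "H", "H"), LABEL_FRE, None, 4),
            (("H", "H", "Y", "T", "G", "H", "H"), LABEL_PRENOX, None, 4),
            # green-algal variant: His-115 also missing, dipeptide intact
            (("H", "L", "Y", "T", "G", "H", "H"), LABEL_PRENOX, None, 3),
            # one mutated heme histidine tolerated for the NOX call
            (("H", "L", "H", "T", "G", "H", "H"), LABEL_NOX, None, 3),
            ((None,) * 7, LABEL_AMBIGUOUS, None, 0),
        ],
    )
    def test_rule_cascade(self, letters, label, subtype, heme):
        result = classify(vector(letters))
        assert (result.label, result.subtype) == (label, subtype)
        assert result.heme_histidine_count == heme

    def test_mutating_a_heme_histidine_in_tm5_does_not_break_the_nox_call(self):
        result = classify(vector(("H", "H", "H", "T", "G", "L", "H")))
        assert result.label == LABEL_NOX

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        st.tuples(
            *[st.sampled_from(["H", "R", "T", "G", "Q", "L", None]) for _ in range(7)]
        )
    )
    def test_total_and_deterministic(self, letters):
        first = classify(vector(letters))
        second = classify(vector(letters))
        assert first == second
        assert first.label in {
            LABEL_NOX, LABEL_PRENOX, LABEL_FRE, LABEL_YEDZ_STEAP, LABEL_AMBIGUOUS
        }

    def test_heme_count_only_counts_the_four_canonical_positions(self):
        vec = vector(("H", "H", "H", "H", "H", "H", "H"))
        assert heme_histidine_count(vec) == 4

    def test_nox_motif_has_four_positions_by_perturbation(self):
        assert nox_call_positions() == (101, 119, 178, 179)


class TestGeneratorRecovery:
    def test_full_accuracy_on_noise_free_templates(self):
        config = GeneratorConfig(seed=5, n_per_clade=10, substitution_rate=0.0, indel_rate=0.0)
        for i, template in enumerate(default_templates()):
            msa, _ = generate_family(template, config, stream_offset=i + 1)
            expected = EXPECTED_LABELS[template.name]
            for result in classify_msa(msa, offset=template.nterm_extension):
                assert (result.label, result.subtype) == expected

    def test_retained_heme_histidines_of_short_forms(self):
        config = GeneratorConfig(seed=5, n_per_clade=5, substitution_rate=0.0, indel_rate=0.0)
        counts = {}
        for i, template in enumerate(default_templates()):
            msa, _ = generate_family(template, config, stream_offset=i + 1)
            results = classify_msa(msa, offset=template.nterm_extension)
            counts[template.name] = {r.heme_histidine_count for r in results}
        assert counts["YedZ_STEAP1"] == {3}
        assert counts["STEAP2_4"] == {2}
        assert counts["NOX"] == {4}

    def test_high_accuracy_under_substitution_noise(self):
        config = GeneratorConfig(seed=9, n_per_clade=60, substitution_rate=0.05, indel_rate=0.01)
        correct = total = 0
        for i, template in enumerate(default_templates()):
            msa, _ = generate_family(template, config, stream_offset=i + 1)
            expected = EXPECTED_LABELS[template.name]
            for result in classify_msa(msa, offset=template.nterm_extension):
                total += 1
                correct += (result.label, result.subtype) == expected
        assert correct / total >= 0.95


class TestPipeline:
    def test_nox2_fixture_classifies_as_nox_group(self, nox2):
        result = classify_record(nox2.reference)
        assert result.label == LABEL_NOX
        assert result.heme_histidine_count == 4

    def test_extended_homolog_still_classifies_as_nox_group(self, nox2):
        query = ProteinRecord(id="ext", sequence="MSTAGKVLRE" + nox2.reference.sequence)
        assert classify_record(query).label == LABEL_NOX


class TestDiscovery:
    @staticmethod
    def _family(template, seed=7, n=30, rate=0.0, offset=1):
        config = GeneratorConfig(
            seed=seed, n_per_clade=n, substitution_rate=rate, indel_rate=0.0
        )
        msa, _ = generate_family(template, config, stream_offset=offset)
        return profile_msa(msa, template.name)

    def test_single_planted_difference_is_the_only_hit(self):
        templates = default_templates()
        nox = [t for t in templates if t.name == "NOX"][0]
        variant = default_templates()[0]
        variant.planted = {**nox.planted, 119: "Y"}
        profile_a = self._family(nox)
        profile_b = self._family(variant)
        pmap = identity_position_map(profile_a.n_columns)
        found = discover_signatures(profile_a, profile_b, pmap, pmap)
        assert [s.ref_pos for s in found] == [119]
        assert found[0].residue_a == "H" and found[0].freq_a == pytest.approx(1.0)

    def test_identical_clades_yield_nothing(self):
        nox = default_templates()[0]
        profile = self._family(nox)
        pmap = identity_position_map(profile.n_columns)
        assert discover_signatures(profile, profile, pmap, pmap) == []

    def test_nox_vs_fre_recovers_planted_motif_positions(self):
        templates = {t.name: t for t in default_templates()}
        profile_a = self._family(templates["NOX"], seed=7, n=50, rate=0.05, offset=1)
        profile_b = self._family(templates["FRE"], seed=7, n=50, rate=0.05, offset=3)
        pmap = identity_position_map(profile_a.n_columns)
        found = discover_signatures(profile_a, profile_b, pmap, pmap)
        assert [s.ref_pos for s in found] == [119, 178, 179]

    def test_swapping_clades_reports_the_same_positions(self):
        templates = {t.name: t for t in default_templates()}
        profile_a = self._family(templates["NOX"])
        profile_b = self._family(templates["FRE"])
        pmap = identity_position_map(profile_a.n_columns)
        forward = discover_signatures(profile_a, profile_b, pmap, pmap)
        backward = discover_signatures(profile_b, profile_a, pmap, pmap)
        assert [s.ref_pos for s in forward] == [s.ref_pos for s in backward]
        # roles exchanged: each side reports its own conserved residue
        for f, b in zip(forward, backward):
            assert f.residue_a != b.residue_a

    def test_non_separating_thresholds_raise(self):
        nox = default_templates()[0]
        profile = self._family(nox)
        pmap = identity_position_map(profile.n_columns)
        with pytest.raises(ValueError, match="separating"):
            discover_signatures(profile, profile, pmap, pmap, f_cons=0.3, f_bg=0.3)
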