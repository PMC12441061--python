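"""Detector tests: screening, counting, depth score, confidence, artifacts."""

import pytest
from hypothesis import given, strategies as st

from vntrscan.detect import (
    Confidence,
    DetectorConfig,
    VariantCall,
    build_anchor_positions,
    calls_to_tsv,
    classify_confidence,
    count_kmer_depths,
    depth_score,
    detect,
    filter_artifacts,
    screen_reads,
)
from vntrscan.errors import CatalogError, ParameterError, ValidationError
from vntrscan.io import SequenceRecord
from vntrscan.model import (
    InsertionSpec,
    KmerIndex,
    build_reference_kmer_index,
    enumerate_variant_kmers,
    render_allele,
    reverse_complement,
)
from vntrscan.simulate import SimulationConfig, simulate_genotype, simulate_short_reads

INS = InsertionSpec(9, 27, "C")


def mk_call(seq="C", score=0.5, alt=100.0, conf=Confidence.LOW):
    return VariantCall(
        inserted_sequence=seq,
        context="M:0",
        alt_depth=alt,
        total_depth=alt * (1 - score) / max(score, 1e-12) if score else 1.0,
        depth_score=score,
        confidence=conf,
    )


class TestDepthScore:
    def test_zero_alt_is_zero(self):
        assert depth_score(0.0, 123.0) == 0.0
        assert depth_score(0.0, 0.0) == 0.0

    def test_printed_threshold_arithmetic(self):
        assert depth_score(20, 3980) == pytest.approx(0.005)

    @given(x=st.floats(0.001, 1e6))
    def test_symmetry(self, x):
        assert depth_score(x, x) == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            depth_score(-1.0, 10.0)

    @given(
        alt=st.floats(0, 1e4), extra=st.floats(0.01, 1e3), total=st.floats(0.01, 1e4)
    )
    def test_monotone_in_alt_support(self, alt, extra, total):
        """More alt-supporting depth at fixed reference depth never lowers
        the score."""
        assert depth_score(alt + extra, total) >= depth_score(alt, total)


class TestConfidenceRule:
    @pytest.mark.parametrize(
        "score,alt,expected",
        [
            (0.00515, 21, Confidence.HIGH),  # both bounds exactly met
            (0.9, 20, Confidence.LOW),  # alt depth bound is strict
            (0.00514, 1000, Confidence.LOW),  # score bound is inclusive
            (0.00516, 20.5, Confidence.HIGH),
            (0.0, 0, Confidence.LOW),
        ],
    )
    def test_boundary_semantics(self, score, alt, expected):
        call = mk_call(score=score, alt=alt)
        assert classify_confidence(call, DetectorConfig()) is expected

    @given(
        s1=st.floats(0, 1), s2=st.floats(0, 1), a1=st.floats(0, 500), a2=st.floats(0, 500)
    )
    def test_classification_monotone(self, s1, s2, a1, a2):
        lo = classify_confidence(mk_call(score=min(s1, s2), alt=min(a1, a2)), DetectorConfig())
        hi = classify_confidence(mk_call(score=max(s1, s2), alt=max(a1, a2)), DetectorConfig())
        assert not (lo is Confidence.HIGH and hi is Confidence.LOW)


class TestArtifactRule:
    def test_low_conf_multibase_flagged(self):
        calls = filter_artifacts([mk_call("GGCT", conf=Confidence.LOW)], DetectorConfig())
        assert calls[0].artifact_flag

    def test_high_conf_single_base_not_flagged(self):
        calls = filter_artifacts([mk_call("C", conf=Confidence.HIGH)], DetectorConfig())
        assert not calls[0].artifact_flag

    def test_rule_is_a_conjunction(self):
        calls = filter_artifacts(
            [mk_call("GGCT", conf=Confidence.HIGH), mk_call("C", conf=Confidence.LOW)],
            DetectorConfig(),
        )
        assert not calls[0].artifact_flag and not calls[1].artifact_flag


class TestScreening:
    def test_random_read_discarded_vntr_read_kept(self, catalog):
        idx = build_reference_kmer_index(catalog, 25)
        cfg = DetectorConfig()
        unit = catalog.motifs[0].sequence
        vntr_read = SequenceRecord("v", (unit * 3)[10 : 10 + 80])
        junk = SequenceRecord("j", "ATATATATATATATATATATATATATATATATATATATAT")
        kept = screen_reads([junk, vntr_read], idx, cfg)
        assert kept == [vntr_read]

    def test_reverse_complement_retained(self, catalog):
        idx = build_reference_kmer_index(catalog, 25)
        unit = catalog.motifs[0].sequence
        rc = SequenceRecord("r", reverse_complement((unit * 2)[5:95]))
        assert screen_reads([rc], idx, DetectorConfig()) == [rc]

    def test_empty_index_is_an_error(self):
        with pytest.raises(CatalogError):
            screen_reads([], KmerIndex(25, {}), DetectorConfig())

    def test_mismatched_k_is_an_error(self, catalog):
        idx = build_reference_kmer_index(catalog, 21)
        with pytest.raises(ParameterError):
            screen_reads([], idx, DetectorConfig(k=25))


class TestCounting:
    def test_zero_reads_zero_counts(self, catalog):
        idx = build_reference_kmer_index(catalog, 25)
        counts = count_kmer_depths([], idx, [])
        assert set(counts.values()) == {0}

    def test_counts_both_orientations(self, catalog):
        idx = build_reference_kmer_index(catalog, 25)
        unit = catalog.motifs[0].sequence
        km = unit[:25]
        fwd = SequenceRecord("f", km)
        rev = SequenceRecord("r", reverse_complement(km))
        counts = count_kmer_depths([fwd, rev], idx, [])
        assert counts[km] == 2

    def test_error_free_noncarrier_has_zero_variant_counts(self, catalog):
        cfg = SimulationConfig(
            seed=21, repeat_count_range=(20, 30), mean_coverage=80.0,
            per_base_error_rate=0.0,
        )
        g = simulate_genotype(cfg, catalog)
        reads = simulate_short_reads(g, catalog, cfg)
        idx = build_reference_kmer_index(catalog, 25)
        diag = enumerate_variant_kmers(catalog, INS, 25, idx)
        counts = count_kmer_depths(reads, idx, [diag])
        assert all(counts[km] == 0 for km in diag)


class TestAnchors:
    def test_anchor_positions_cover_both_junctions(self, catalog):
        pos = build_anchor_positions(catalog, "A" * 40, "G" * 40, 25)
        assert len(pos) == 2 * 24
        assert all(len(p) == 1 for p in pos)  # single motif -> one k-mer each

    def test_short_flanks_rejected(self, catalog):
        with pytest.raises(ParameterError):
            build_anchor_positions(catalog, "A" * 10, "G" * 40, 25)


class TestDetectEndToEnd:
    def test_carrier_yields_single_high_conf_c_call(self, catalog):
        cfg = SimulationConfig(seed=22, repeat_count_range=(20, 30), mean_coverage=400.0)
        g = simulate_genotype(cfg, catalog, carrier=True, insertion=INS)
        reads = simulate_short_reads(g, catalog, cfg)
        res = detect(
            reads, catalog, flanks=(g.allele_a.flank_5p, g.allele_a.flank_3p)
        )
        assert len(res.calls) == 1
        call = res.calls[0]
        assert call.inserted_sequence == "C"
        assert call.confidence is Confidence.HIGH
        assert not call.artifact_flag
        assert call.alt_depth > 20

    def test_noncarrier_error_free_yields_no_calls(self, catalog):
        cfg = SimulationConfig(
            seed=23, repeat_count_range=(20, 30), mean_coverage=400.0,
            per_base_error_rate=0.0,
        )
        g = simulate_genotype(cfg, catalog)
        reads = simulate_short_reads(g, catalog, cfg)
        res = detect(reads, catalog, flanks=(g.allele_a.flank_5p, g.allele_a.flank_3p))
        assert res.calls == []
        assert res.report.n_screened > 0

    def test_ggct_carrier_low_coverage_is_flagged_artifact(self, catalog):
        """A multi-base insertion at depth too low for High confidence is
        reported but flagged by the artifact rule."""
        ggct = InsertionSpec(9, 27, "GGCT")
        cfg = SimulationConfig(seed=24, repeat_count_range=(20, 30), mean_coverage=30.0)
        g = simulate_genotype(cfg, catalog, carrier=True, insertion=ggct)
        reads = simulate_short_reads(g, catalog, cfg)
        res = detect(
            reads,
            catalog,
            DetectorConfig(candidate_insertions=("C", "GGCT")),
            flanks=(g.allele_a.flank_5p, g.allele_a.flank_3p),
        )
        ggct_calls = [c for c in res.calls if c.inserted_sequence == "GGCT"]
        assert ggct_calls and ggct_calls[0].confidence is Confidence.LOW
        assert ggct_calls[0].artifact_flag

    def test_detection_works_without_flanks(self, catalog):
        """Catalog-only mode: the depth score falls back to the aggregated
        repeat-k-mer denominator (copy-number dependent), but the call and
        its alt depth are unchanged."""
        cfg = SimulationConfig(seed=25, repeat_count_range=(20, 30), mean_coverage=400.0)
        g = simulate_genotype(cfg, catalog, carrier=True, insertion=INS)
        reads = simulate_short_reads(g, catalog, cfg)
        with_fl = detect(reads, catalog, flanks=(g.allele_a.flank_5p, g.allele_a.flank_3p))
        without = detect(reads, catalog)
        assert [c.inserted_sequence for c in without.calls] == ["C"]
        assert without.calls[0].alt_depth == pytest.approx(with_fl.calls[0].alt_depth)
        assert without.calls[0].total_depth > with_fl.calls[0].total_depth

    def test_tsv_rendering_round_trips_fields(self):
        text = calls_to_tsv([mk_call("C", score=0.25, alt=50.0, conf=Confidence.HIGH)])
        header, row = text.strip().split("\n")
        assert header.split("\t")[0] == "inserted_sequence"
        assert row.split("\t")[0] == "C"
        assert row.split("\t")[5] == "High"
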