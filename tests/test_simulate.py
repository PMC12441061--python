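"""Read-simulator tests: determinism, coverage calibration, error models."""

import numpy as np
import pytest

from vntrscan.errors import ParameterError, ValidationError
from vntrscan.model import (
    InsertionSpec,
    build_reference_kmer_index,
    enumerate_variant_kmers,
    render_allele,
    reverse_complement,
)
from vntrscan.simulate import (
    COVERAGE_PRESETS,
    DiploidGenotype,
    SimulationConfig,
    preset_config,
    simulate_genotype,
    simulate_long_reads,
    simulate_short_reads,
)

INS = InsertionSpec(9, 27, "C")


def small_cfg(**kw):
    kw.setdefault("repeat_count_range", (20, 30))
    kw.setdefault("mean_coverage", 60.0)
    return SimulationConfig(**kw)


class TestConfig:
    def test_presets_match_panel_medians(self):
        assert COVERAGE_PRESETS == {"broad_panel": 344.0, "adtkd_panel": 2424.0}
        assert preset_config("adtkd_panel").mean_coverage == 2424.0
        with pytest.raises(ParameterError):
            preset_config("nope")

    @pytest.mark.parametrize(
        "kw",
        [
            {"mean_coverage": 0.0},
            {"per_base_error_rate": 1.0},
            {"repeat_count_range": (30, 20)},
            {"read_length": 0},
            {"gc_bias_strength": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ParameterError):
            SimulationConfig(**kw)


class TestGenotype:
    def test_noncarrier_has_no_insertion(self, catalog):
        g = simulate_genotype(small_cfg(seed=1), catalog)
        assert not g.carrier
        assert all(a.insertion is None for a in g.alleles)

    def test_carrier_has_exactly_one_inserted_allele(self, catalog):
        g = simulate_genotype(small_cfg(seed=2), catalog, carrier=True, insertion=INS)
        assert g.carrier
        assert sum(a.insertion is not None for a in g.alleles) == 1

    def test_same_seed_bitwise_identical(self, catalog):
        a = simulate_genotype(small_cfg(seed=3), catalog, carrier=True, insertion=INS)
        b = simulate_genotype(small_cfg(seed=3), catalog, carrier=True, insertion=INS)
        assert a == b

    def test_repeat_counts_within_range(self, catalog):
        for seed in range(5):
            g = simulate_genotype(SimulationConfig(seed=seed), catalog)
            for a in g.alleles:
                assert 20 <= a.repeat_count <= 125

    def test_carrier_flag_consistency_enforced(self, catalog):
        g = simulate_genotype(small_cfg(seed=1), catalog)
        with pytest.raises(ValidationError):
            DiploidGenotype(g.allele_a, g.allele_b, carrier=True)

    def test_insertion_beyond_drawn_count_rejected(self, catalog):
        with pytest.raises(ValidationError):
            simulate_genotype(
                small_cfg(seed=4),
                catalog,
                carrier=True,
                insertion=InsertionSpec(500, 0, "C"),
            )


class TestShortReads:
    def test_deterministic_under_seed(self, catalog):
        cfg = small_cfg(seed=5)
        g = simulate_genotype(cfg, catalog)
        assert simulate_short_reads(g, catalog, cfg) == simulate_short_reads(g, catalog, cfg)

    def test_uniform_coverage_calibration(self, catalog):
        """With no GC bias the realized VNTR coverage tracks the target."""
        cfg = SimulationConfig(
            seed=6, repeat_count_range=(40, 50), mean_coverage=300.0,
            per_base_error_rate=0.0,
        )
        g = simulate_genotype(cfg, catalog)
        reads = simulate_short_reads(g, catalog, cfg)
        total_bases = sum(len(r.sequence) for r in reads)
        # interior per-base depth: reads start uniformly over L - rl + 1
        # positions, so expected depth is n*rl/(L - rl + 1) per allele
        span = sum(
            len(render_allele(a, catalog)) - cfg.read_length + 1 for a in g.alleles
        )
        assert 2 * total_bases / span == pytest.approx(300.0, rel=0.05)

    def test_error_free_reads_are_substrings_of_haplotypes(self, catalog):
        cfg = small_cfg(seed=7, per_base_error_rate=0.0)
        g = simulate_genotype(cfg, catalog)
        haps = [render_allele(a, catalog) for a in g.alleles]
        for r in simulate_short_reads(g, catalog, cfg)[:300]:
            assert any(
                r.sequence in h or reverse_complement(r.sequence) in h for h in haps
            )

    def test_preset_coverage_ratio(self, catalog):
        """The two panel regimes differ ~7.0x in realized depth."""
        ratios = []
        for seed in range(3):
            per = {}
            for preset in ("broad_panel", "adtkd_panel"):
                cfg = preset_config(preset, seed=seed, repeat_count_range=(25, 35))
                g = simulate_genotype(cfg, catalog)
                reads = simulate_short_reads(g, catalog, cfg)
                region = sum(len(render_allele(a, catalog)) for a in g.alleles) / 2
                per[preset] = sum(len(r.sequence) for r in reads) / region
            ratios.append(per["adtkd_panel"] / per["broad_panel"])
        assert np.mean(ratios) == pytest.approx(2424 / 344, rel=0.05)

    def test_gc_bias_shifts_read_composition(self, catalog):
        """GC down-weighting starves GC-rich (VNTR-internal) fragments."""
        cfg0 = small_cfg(seed=8, mean_coverage=120.0)
        cfgb = small_cfg(seed=8, mean_coverage=120.0, gc_bias_strength=6.0)
        g = simulate_genotype(cfg0, catalog)

        def mean_gc(reads):
            s = "".join(r.sequence for r in reads[:2000])
            return (s.count("G") + s.count("C")) / len(s)

        assert mean_gc(simulate_short_reads(g, catalog, cfgb)) < mean_gc(
            simulate_short_reads(g, catalog, cfg0)
        )

    def test_paired_mode_emits_mate_pairs(self, catalog):
        cfg = small_cfg(seed=9, paired=True)
        g = simulate_genotype(cfg, catalog)
        reads = simulate_short_reads(g, catalog, cfg)
        assert len(reads) % 2 == 0
        assert reads[0].name.endswith("/1") and reads[1].name.endswith("/2")
        assert all(len(r.sequence) == cfg.read_length for r in reads)

    def test_read_longer_than_allele_rejected(self, catalog):
        cfg = small_cfg(seed=10, read_length=5000, flank_length=30)
        g = simulate_genotype(cfg, catalog)
        with pytest.raises(ValidationError):
            simulate_short_reads(g, catalog, cfg)


class TestLongReads:
    def test_error_free_lengths_match_alleles_exactly(self, catalog):
        cfg = small_cfg(seed=11, long_read_error_rate=0.0, long_read_count=30)
        g = simulate_genotype(cfg, catalog, carrier=True, insertion=INS)
        lens = {len(render_allele(a, catalog)) for a in g.alleles}
        for r in simulate_long_reads(g, catalog, cfg):
            assert len(r.sequence) in lens

    def test_allele_sampling_is_fair(self, catalog):
        cfg = small_cfg(seed=12, long_read_count=200, long_read_error_rate=0.0)
        g = simulate_genotype(cfg, catalog)
        reads = simulate_long_reads(g, catalog, cfg)
        frac_a = np.mean(["allelea" in r.name for r in reads])
        # 200 draws at p=0.5: +/- 4 sigma
        assert abs(frac_a - 0.5) < 4 * 0.5 / np.sqrt(200)

    def test_carrier_reads_carry_diagnostic_kmers(self, catalog):
        cfg = small_cfg(seed=13, long_read_error_rate=0.0, long_read_count=40)
        g = simulate_genotype(cfg, catalog, carrier=True, insertion=INS)
        idx = build_reference_kmer_index(catalog, 25)
        diag = enumerate_variant_kmers(catalog, INS, 25, idx)
        carrier_len = len(
            render_allele(next(a for a in g.alleles if a.insertion), catalog)
        )
        for r in simulate_long_reads(g, catalog, cfg):
            fwd = r.sequence if any(k in r.sequence for k in diag) else reverse_complement(r.sequence)
            has_diag = any(k in fwd for k in diag)
            assert has_diag == (len(r.sequence) == carrier_len)

    def test_requires_flanks(self, catalog):
        cfg = small_cfg(seed=14, flank_length=0)
        with pytest.raises(ValidationError):
            g = simulate_genotype(cfg, catalog)
            simulate_long_reads(g, catalog, cfg)
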