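"""Synthetic diploid VNTR genotypes and sequencing reads.

This module is the package's study-condition generator: diploid alleles of
20-125 GC-rich 60-bp units, an optional heterozygous insertion (the
autosomal-dominant carrier model), Illumina-like short reads at a target
locus coverage with optional GC-dependent dropout, and error-prone long
amplicon reads spanning the whole repeat array flank to flank.

Two named coverage presets mirror the two targeted-panel regimes relevant
to MUC1 screening: a broad inherited-kidney-disease panel at a median VNTR
coverage of ~344x and a dedicated ADTKD panel at ~2,424x.

All outputs are pure functions of ``(config.seed, inputs)``; independent
random streams are derived from the seed per operation so that e.g. the
genotype does not change when the read simulation is re-run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError, ValidationError
from .io import SequenceRecord
from .model import (
    UNIT_LENGTH,
    InsertionSpec,
    MotifCatalog,
    RepeatMotif,
    VNTRAllele,
    render_allele,
    render_vntr,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space

# substreams derived from config.seed
_STREAM_GENOTYPE = 0
_STREAM_SHORT = 1
_STREAM_LONG = 2
_STREAM_CATALOG = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic sequencing experiment.

    ``mean_coverage`` is the target total (both-allele) per-base depth over
    the VNTR region.  ``gc_bias_strength`` g down-weights a fragment of GC
    fraction f by exp(-g*(f-0.5)) (clipped to [0,1]): 0 means uniform
    sampling, larger values starve GC-rich fragments the way GC-dependent
    capture/amplification dropout does.
    """

    seed: int = 0
    repeat_count_range: tuple[int, int] = (20, 125)
    read_length: int = 150
    paired: bool = False
    mean_coverage: float = 344.0
    per_base_error_rate: float = 0.001
    gc_bias_strength: float = 0.0
    long_read_error_rate: float = 0.002
    long_read_count: int = 60
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    flank_length: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.repeat_count_range
        if not (1 < lo <= hi < 1000):
            raise ParameterError("repeat_count_range must satisfy 1 < low <= high < 1000")
        if self.mean_coverage <= 0:
            raise ParameterError("mean_coverage must be > 0")
        for name in ("per_base_error_rate", "long_read_error_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.gc_bias_strength < 0:
            raise ParameterError("gc_bias_strength must be >= 0")
        if self.read_length <= 0:
            raise ParameterError("read_length must be positive")


#: Coverage presets named after the two panel regimes (median VNTR depth).
COVERAGE_PRESETS = {"broad_panel": 344.0, "adtkd_panel": 2424.0}


def preset_config(preset: str, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` at one of the named panel coverages."""
    if preset not in COVERAGE_PRESETS:
        raise ParameterError(
            f"unknown preset {preset!r}; choose from {sorted(COVERAGE_PRESETS)}"
        )
    return SimulationConfig(mean_coverage=COVERAGE_PRESETS[preset], **overrides)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode()


def random_catalog(
    seed: int, n_motifs: int = 1, gc: float = 0.72, prefix: str = "SYN"
) -> MotifCatalog:
    """A synthetic motif catalog of GC-rich 60-nt units.

    Stands in for the proprietary MUC1 motif inventory, which is not public;
    sequences are random with the stated GC content.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_CATALOG]))
    motifs = tuple(
        RepeatMotif(f"{prefix}{i + 1:02d}", _random_dna(rng, UNIT_LENGTH, gc))
        for i in range(n_motifs)
    )
    return MotifCatalog(motifs, source=f"synthetic(seed={seed}, gc={gc})")


@dataclass(frozen=True)
class DiploidGenotype:
    """Two haplotypes; in a carrier exactly one bears the insertion."""

    allele_a: VNTRAllele
    allele_b: VNTRAllele
    carrier: bool

    def __post_init__(self) -> None:
        n_ins = sum(a.insertion is not None for a in (self.allele_a, self.allele_b))
        if self.carrier != (n_ins == 1):
            raise ValidationError(
                "carrier flag must equal 'exactly one allele has an insertion'"
            )

    @property
    def alleles(self) -> tuple[VNTRAllele, VNTRAllele]:
        return (self.allele_a, self.allele_b)


def simulate_genotype(
    config: SimulationConfig,
    catalog: MotifCatalog,
    carrier: bool = False,
    insertion: Optional[InsertionSpec] = None,
) -> DiploidGenotype:
    """Draw a diploid genotype: uniform repeat counts, shared flanks.

    A carrier gets ``insertion`` on one randomly chosen allele (heterozygous,
    matching dominant inheritance).  Unit composition is drawn uniformly
    from the catalog per unit.
    """
    if carrier and insertion is None:
        raise ValidationError("carrier=True requires an insertion spec")
    rng = _rng(config, _STREAM_GENOTYPE)
    lo, hi = config.repeat_count_range
    counts = rng.integers(lo, hi + 1, size=2)
    flank_5p = _random_dna(rng, config.flank_length, gc=0.5)
    flank_3p = _random_dna(rng, config.flank_length, gc=0.5)
    ids = list(catalog.motif_ids)
    which = int(rng.integers(2)) if carrier else -1
    alleles = []
    for i, n in enumerate(counts):
        ins = insertion if (carrier and i == which) else None
        if ins is not None and ins.repeat_index >= n:
            raise ValidationError(
                f"insertion repeat_index {ins.repeat_index} >= drawn repeat count {n}"
            )
        units = tuple(rng.choice(ids, size=int(n)))
        alleles.append(
            VNTRAllele(units, insertion=ins, flank_5p=flank_5p, flank_3p=flank_3p)
        )
    return DiploidGenotype(alleles[0], alleles[1], carrier=carrier)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode_rows(mat: np.ndarray) -> list[str]:
    flat = _BASES[mat].tobytes().decode()
    w = mat.shape[1]
    return [flat[i : i + w] for i in range(0, len(flat), w)]


def _apply_substitutions(
    mat: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n:
        mat = mat.copy()
        # shift by 1..3 in code space: always a different base
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return mat


def _sample_starts_gc(
    seq_codes: np.ndarray,
    n: int,
    frag_len: int,
    gc_bias_strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fragment starts, uniform or GC-rejection-sampled at fixed count.

    Rejection keeps the total read count (hence overall coverage) at target
    while shifting which fragments survive, emulating GC dropout as a
    relative, not absolute, loss.
    """
    n_pos = len(seq_codes) - frag_len + 1
    if n_pos <= 0:
        raise ValidationError("fragment longer than template")
    if gc_bias_strength == 0:
        return rng.integers(0, n_pos, size=n)
    is_gc = np.concatenate([[0], np.cumsum((seq_codes == 1) | (seq_codes == 2))])
    accepted: list[np.ndarray] = []
    got = 0
    for _ in range(200):
        cand = rng.integers(0, n_pos, size=max(n, 1000))
        gc_frac = (is_gc[cand + frag_len] - is_gc[cand]) / frag_len
        w = np.minimum(1.0, np.exp(-gc_bias_strength * (gc_frac - 0.5)))
        keep = cand[rng.random(len(cand)) < w]
        accepted.append(keep)
        got += len(keep)
        if got >= n:
            break
    starts = np.concatenate(accepted)
    if len(starts) < n:
        raise ValidationError("GC bias too strong: could not sample enough fragments")
    return starts[:n]


def simulate_short_reads(
    genotype: DiploidGenotype,
    catalog: MotifCatalog,
    config: SimulationConfig,
) -> list[SequenceRecord]:
    """Illumina-like reads over both haplotypes at the target locus coverage.

    Each allele contributes half of ``mean_coverage`` in expectation.
    Errors are independent substitutions; strand is random.  Quality
    strings are constant Q30 (the detector ignores them).
    """
    rng = _rng(config, _STREAM_SHORT)
    rl = config.read_length
    reads: list[SequenceRecord] = []
    qual = "?" * rl
    for label, allele in zip("ab", genotype.alleles):
        seq = render_allele(allele, catalog)
        if len(seq) <= rl:
            raise ValidationError(
                f"rendered allele ({len(seq)} bp) must be longer than read_length"
            )
        codes = _encode(seq)
        n_span = len(seq) - rl + 1
        n_reads = int(round((config.mean_coverage / 2) * n_span / rl))
        if config.paired:
            n_frags = max(1, n_reads // 2)
            fl = np.clip(
                np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n_frags)),
                rl,
                len(seq),
            ).astype(int)
            mats = []
            names = []
            for j, L in enumerate(fl):
                s = _sample_starts_gc(codes, 1, int(L), config.gc_bias_strength, rng)[0]
                frag = codes[s : s + L]
                r1 = frag[:rl]
                r2 = _COMP_CODE[frag[-rl:]][::-1]
                mats.append(r1)
                mats.append(r2)
                names.append(f"sim_{label}_{j}/1")
                names.append(f"sim_{label}_{j}/2")
            mat = _apply_substitutions(np.array(mats), config.per_base_error_rate, rng)
            for name, s in zip(names, _decode_rows(mat)):
                reads.append(SequenceRecord(name, s, qual))
        else:
            starts = _sample_starts_gc(codes, n_reads, rl, config.gc_bias_strength, rng)
            mat = codes[starts[:, None] + np.arange(rl)]
            flip = rng.integers(0, 2, size=n_reads).astype(bool)
            if flip.any():
                mat[flip] = _COMP_CODE[mat[flip]][:, ::-1]
            mat = _apply_substitutions(mat, config.per_base_error_rate, rng)
            for j, s in enumerate(_decode_rows(mat)):
                reads.append(SequenceRecord(f"sim_{label}_{j}", s, qual))
    return reads


def simulate_long_reads(
    genotype: DiploidGenotype,
    catalog: MotifCatalog,
    config: SimulationConfig,
) -> list[SequenceRecord]:
    """Amplicon-style long reads, each spanning one whole haplotype.

    Alleles are drawn with equal probability; errors are independent
    substitutions at ``long_read_error_rate``; orientation is random.
    Flanks act as the primer anchors and must be non-empty.
    """
    for a in genotype.alleles:
        if not a.flank_5p or not a.flank_3p:
            raise ValidationError("long-read simulation requires non-empty flanks")
    rng = _rng(config, _STREAM_LONG)
    templates = [_encode(render_allele(a, catalog)) for a in genotype.alleles]
    picks = rng.integers(0, 2, size=config.long_read_count)
    out: list[SequenceRecord] = []
    for j, which in enumerate(picks):
        codes = templates[which][None, :]
        codes = _apply_substitutions(codes, config.long_read_error_rate, rng)[0]
        if rng.integers(2):
            codes = _COMP_CODE[codes][::-1]
        out.append(SequenceRecord(f"lr_{j}_allele{'ab'[which]}", _BASES[codes].tobytes().decode()))
    return out


def genotype_truth(genotype: DiploidGenotype, catalog: MotifCatalog) -> dict:
    """JSON-able ground-truth sidecar used by the validation harness."""
    alleles = []
    for a in genotype.alleles:
        ins = a.insertion
        alleles.append(
            {
                "repeat_count": a.repeat_count,
                "vntr_length": a.vntr_length(),
                "vntr_sequence": render_vntr(a, catalog),
                "insertion": None
                if ins is None
                else {
                    "repeat_index": ins.repeat_index,
                    "offset": ins.offset,
                    "inserted_sequence": ins.inserted_sequence,
                },
            }
        )
    return {"carrier": genotype.carrier, "alleles": alleles}
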