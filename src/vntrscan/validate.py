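"""In-silico validation of the detector against simulated truth.

Two designs mirror how a short-read VNTR caller is validated clinically:

1. carrier cohorts at a given panel coverage, scored against the
   simulator's ground truth (optionally cross-checked with the long-read
   reconstruction oracle as an independent truth channel);
2. non-carrier cohorts, to measure false-positive / low-confidence
   behaviour;

plus a coverage-sensitivity curve across panel depths, which probes the
false-negative regime at insufficient coverage.

By default a case counts as detected only on a High-confidence,
non-artifact call (low-confidence positives were false positives on
long-read validation in the clinical setting this mirrors);
``count_low_confidence`` flips that to a screening-first reading.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import binomtest

from .detect import Confidence, DetectorConfig, detect
from .errors import ValidationError
from .longread import reconstruct_alleles
from .model import InsertionSpec, MotifCatalog
from .simulate import (
    SimulationConfig,
    genotype_truth,
    preset_config,
    random_catalog,
    simulate_genotype,
    simulate_long_reads,
    simulate_short_reads,
)

#: default pathogenic lesion used by scenarios: one C inside an interior unit
DEFAULT_INSERTION = InsertionSpec(repeat_index=9, offset=27, inserted_sequence="C")


@dataclass
class CaseResult:
    case_id: str
    truth_carrier: bool
    called: bool
    confidence: Optional[str]
    artifact_flag: bool
    median_kmer_coverage: float
    n_calls: int = 0


@dataclass
class ConcordanceReport:
    n_cases: int
    true_positive: int
    false_negative: int
    false_positive: int
    true_negative: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    cases: list[CaseResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _score(cases: Sequence[CaseResult]) -> ConcordanceReport:
    tp = sum(c.truth_carrier and c.called for c in cases)
    fn = sum(c.truth_carrier and not c.called for c in cases)
    fp = sum(not c.truth_carrier and c.called for c in cases)
    tn = sum(not c.truth_carrier and not c.called for c in cases)
    return ConcordanceReport(
        n_cases=len(cases),
        true_positive=tp,
        false_negative=fn,
        false_positive=fp,
        true_negative=tn,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        cases=list(cases),
    )


def _case_detected(result, count_low_confidence: bool) -> tuple[bool, Optional[str], bool]:
    best = None
    for call in result.calls:
        if call.artifact_flag:
            continue
        if call.confidence == Confidence.HIGH or count_low_confidence:
            best = call
            break
        if best is None:
            best = call
    if best is None:
        return False, None, any(c.artifact_flag for c in result.calls)
    detected = best.confidence == Confidence.HIGH or count_low_confidence
    return detected, best.confidence.value, best.artifact_flag


def run_scenario(
    n_carriers: int,
    n_noncarriers: int,
    coverage_preset: str | float,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    detector_config: DetectorConfig = DetectorConfig(),
    catalog: Optional[MotifCatalog] = None,
    insertion: InsertionSpec = DEFAULT_INSERTION,
    count_low_confidence: bool = False,
    cross_check_longread: bool = False,
) -> ConcordanceReport:
    """Simulate a cohort, run the detector, and score the confusion matrix.

    Each case gets a reproducible sub-seed derived from ``seed`` by counter,
    so individual cases can be replayed.  ``coverage_preset`` is a preset
    name or an explicit mean coverage.  With ``cross_check_longread`` the
    long-read oracle is run per case and must agree with the simulator's
    sidecar truth on carrier status (a ValidationError otherwise).
    """
    if n_carriers < 0 or n_noncarriers < 0:
        raise ValidationError("cohort sizes must be >= 0")
    base = config or SimulationConfig()
    if isinstance(coverage_preset, str):
        base = dataclasses.replace(
            preset_config(coverage_preset), **_overridable(base)
        )
    else:
        base = dataclasses.replace(base, mean_coverage=float(coverage_preset))
    cat = catalog or random_catalog(seed)
    cases: list[CaseResult] = []
    for i in range(n_carriers + n_noncarriers):
        carrier = i < n_carriers
        case_cfg = dataclasses.replace(base, seed=_subseed(seed, i))
        genotype = simulate_genotype(
            case_cfg, cat, carrier=carrier, insertion=insertion if carrier else None
        )
        reads = simulate_short_reads(genotype, cat, case_cfg)
        result = detect(
            reads,
            cat,
            detector_config,
            flanks=(genotype.allele_a.flank_5p, genotype.allele_a.flank_3p),
        )
        called, conf, artifact = _case_detected(result, count_low_confidence)
        if cross_check_longread:
            lr = simulate_long_reads(genotype, cat, case_cfg)
            recs = reconstruct_alleles(
                lr, genotype.allele_a.flank_5p, genotype.allele_a.flank_3p, cat
            )
            lr_carrier = any(r.insertion_call is not None for r in recs)
            if lr_carrier != genotype.carrier:
                raise ValidationError(
                    f"long-read oracle disagrees with sidecar truth on case {i}"
                )
        cases.append(
            CaseResult(
                case_id=f"case_{i:04d}",
                truth_carrier=carrier,
                called=called,
                confidence=conf,
                artifact_flag=artifact,
                median_kmer_coverage=result.report.median_ref_kmer_depth,
                n_calls=len(result.calls),
            )
        )
    return _score(cases)


def _subseed(seed: int, counter: int) -> int:
    return (seed * 100_003 + counter) % (2**31 - 1)


def _overridable(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("mean_coverage")
    return d


def coverage_sensitivity_curve(
    coverages: Sequence[float],
    n_per_point: int,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    detector_config: DetectorConfig = DetectorConfig(),
    catalog: Optional[MotifCatalog] = None,
    insertion: InsertionSpec = DEFAULT_INSERTION,
) -> list[dict]:
    """Sensitivity per coverage with 95% Clopper-Pearson intervals.

    Carrier-only cohorts of ``n_per_point`` at each coverage; sub-seeds are
    offset per coverage so points are independent.
    """
    if any(c <= 0 for c in coverages):
        raise ValidationError("coverages must be positive")
    rows = []
    for j, cov in enumerate(coverages):
        rep = run_scenario(
            n_carriers=n_per_point,
            n_noncarriers=0,
            coverage_preset=float(cov),
            config=config,
            seed=_subseed(seed, 7919 * (j + 1)),
            detector_config=detector_config,
            catalog=catalog,
            insertion=insertion,
        )
        k = rep.true_positive
        ci = binomtest(k, n_per_point).proportion_ci(0.95) if n_per_point else None
        rows.append(
            {
                "coverage": float(cov),
                "n": n_per_point,
                "detected": k,
                "sensitivity": rep.sensitivity,
                "ci_low": float(ci.low) if ci else None,
                "ci_high": float(ci.high) if ci else None,
            }
        )
    return rows
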