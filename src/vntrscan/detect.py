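"""Mapping-free k-mer caller for frameshift insertions in the VNTR.

Reads are never aligned.  The caller screens reads for k-mer sharing with
the locus, counts how often each reference and each insertion-diagnostic
k-mer occurs (either strand), and converts the counts into per-candidate
insertion calls:

* ``alt_depth``  - mean count over the candidate's diagnostic k-mers,
* ``total_depth`` - mean count over the reference k-mers,
* ``depth_score`` - alt_depth / (alt_depth + total_depth),

classified **High** confidence iff depth_score >= 0.00515 AND
alt_depth > 20 ("at least" inclusive, "greater than" strict), otherwise
**Low**.  Multi-base Low-confidence insertions (the recurrent "GGCT"
pattern) are flagged as probable pipeline artifacts but kept in the
output.

Because every repeat k-mer recurs in all copies of the unit, its count
aggregates copy number and coverage into one number; the two are not
separable from repeat k-mers alone.  When the locus flank sequences are
supplied (they are fixed primer context), ``total_depth`` is therefore
measured on the single-copy flank-junction anchor k-mers, giving a
depth score that compares variant support with per-position locus
coverage and is invariant to repeat-array length.  Without flanks the
mean count over the repeat reference k-mers is used, which makes the
score scale like 1/(diploid copy sum).  The formula is isolated in
:func:`depth_score` so an alternative definition can be swapped in.
Calling is candidate-driven: a configured insertion alphabet is tested at
every unit offset.  De novo discovery of unknown motifs is out of scope,
mirroring the motif-reference limitation of k-mer VNTR callers.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import CatalogError, ParameterError, ValidationError
from .io import SequenceRecord
from .model import (
    UNIT_LENGTH,
    InsertionSpec,
    KmerIndex,
    MotifCatalog,
    build_reference_kmer_index,
    enumerate_variant_kmers,
    flank_junction_kmers,
    reverse_complement,
)

HIGH_CONF_DEPTH_SCORE = 0.00515
HIGH_CONF_ALT_DEPTH = 20


class Confidence(str, enum.Enum):
    HIGH = "High"
    LOW = "Low"


@dataclass(frozen=True)
class DetectorConfig:
    k: int = 25
    min_shared_kmers_to_screen: int = 3
    high_conf_depth_score: float = HIGH_CONF_DEPTH_SCORE
    high_conf_alt_depth: float = HIGH_CONF_ALT_DEPTH
    artifact_max_insertion_len: int = 1
    candidate_insertions: tuple[str, ...] = ("C",)
    alt_aggregate: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.high_conf_depth_score <= 0 or self.high_conf_alt_depth <= 0:
            raise ParameterError("confidence thresholds must be positive")
        if self.alt_aggregate not in ("mean", "median"):
            raise ParameterError("alt_aggregate must be 'mean' or 'median'")
        if not self.candidate_insertions:
            raise ParameterError("candidate_insertions must be non-empty")


@dataclass(frozen=True)
class Candidate:
    """One tested insertion hypothesis: sequence at (motif, offset)."""

    inserted_sequence: str
    motif_id: str
    offset: int
    kmers: frozenset[str]


@dataclass
class VariantCall:
    inserted_sequence: str
    context: str  # "<motif_id>:<offset>"
    alt_depth: float
    total_depth: float
    depth_score: float
    confidence: Confidence
    artifact_flag: bool = False
    supporting_kmers: int = 0


@dataclass
class DetectionReport:
    n_reads: int
    n_screened: int
    median_ref_kmer_depth: float
    estimated_base_coverage: float
    k: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class DetectionResult:
    calls: list[VariantCall]
    report: DetectionReport


# ---------------------------------------------------------------------------
# candidate enumeration


def build_candidates(
    catalog: MotifCatalog, config: DetectorConfig, ref_index: KmerIndex
) -> list[Candidate]:
    """Candidate insertions: every configured sequence at every unit offset.

    Candidates whose diagnostic k-mer set is empty (the insertion recreates
    reference context) or duplicates an earlier candidate's set (e.g. the
    same base inserted on either side of a homopolymer) are dropped, so each
    retained candidate is a distinct testable hypothesis.
    """
    seen: set[frozenset[str]] = set()
    out: list[Candidate] = []
    for seq in config.candidate_insertions:
        for motif in catalog:
            for offset in range(UNIT_LENGTH):
                kmers = enumerate_variant_kmers(
                    catalog,
                    InsertionSpec(0, offset, seq),
                    config.k,
                    ref_index,
                    motif_id=motif.motif_id,
                )
                if not kmers or kmers in seen:
                    continue
                seen.add(kmers)
                out.append(Candidate(seq, motif.motif_id, offset, kmers))
    return out


# ---------------------------------------------------------------------------
# flank-junction anchor k-mers (single-copy depth probes)


def build_anchor_positions(
    catalog: MotifCatalog, flank_5p: str, flank_3p: str, k: int
) -> list[frozenset[str]]:
    """Per junction position, the k-mers that could occupy it.

    A window overlapping the 5' flank/repeat junction (or the repeat/3'
    flank junction) occurs at most once per haplotype, so its read count
    measures per-position locus coverage directly.  The motif adjacent to
    a flank is unknown, so each of the ``2*(k-1)`` junction positions maps
    to the set of candidate k-mers over all motifs; summing their counts
    recovers that position's depth regardless of which motif is really
    there.
    """
    if len(flank_5p) < k - 1 or len(flank_3p) < k - 1:
        raise ParameterError("flanks must be at least k-1 nt to anchor junction k-mers")
    positions: list[set[str]] = [set() for _ in range(2 * (k - 1))]
    for motif in catalog:
        left = flank_5p[-(k - 1) :] + motif.sequence[: k - 1]
        for j in range(k - 1):
            positions[j].add(left[j : j + k])
        right = motif.sequence[-(k - 1) :] + flank_3p[: k - 1]
        for j in range(k - 1):
            positions[k - 1 + j].add(right[j : j + k])
    return [frozenset(p) for p in positions]


# ---------------------------------------------------------------------------
# screening and counting

def _both_strand_lookup(kmers: Iterable[str]) -> dict[str, object]:
    """kmer-or-its-reverse-complement -> slot id(s), for forward-only scans.

    Storing both orientations of every indexed k-mer lets read scanning run
    on the forward read only while still counting matches on either strand.
    The rare collision (one key serving two indexed k-mers) maps to a tuple
    of slots.
    """
    lookup: dict[str, object] = {}

    def add(key: str, slot: int) -> None:
        cur = lookup.get(key)
        if cur is None:
            lookup[key] = slot
        elif isinstance(cur, int):
            if cur != slot:
                lookup[key] = (cur, slot)
        elif slot not in cur:
            lookup[key] = cur + (slot,)

    for slot, kmer in enumerate(kmers):
        add(kmer, slot)
        add(reverse_complement(kmer), slot)
    return lookup


def screen_reads(
    reads: Sequence[SequenceRecord],
    index: KmerIndex,
    config: DetectorConfig,
) -> list[SequenceRecord]:
    """Recruit reads sharing >= ``min_shared_kmers_to_screen`` k-mers with
    the index in either orientation; order-preserving."""
    if len(index) == 0:
        raise CatalogError("cannot screen reads against an empty index")
    if index.k != config.k:
        raise ParameterError(f"index k={index.k} != config k={config.k}")
    members = set(index.entries)
    members.update(reverse_complement(k) for k in index.entries)
    k = config.k
    need = config.min_shared_kmers_to_screen
    kept = []
    for read in reads:
        seq = read.sequence
        hits = 0
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in members:
                hits += 1
                if hits >= need:
                    kept.append(read)
                    break
    return kept


def count_kmer_depths(
    reads: Sequence[SequenceRecord],
    ref_index: KmerIndex,
    variant_kmer_sets: Sequence[frozenset[str]],
) -> dict[str, int]:
    """Occurrences of every indexed k-mer across reads, both orientations.

    Returns counts keyed by the forward-orientation k-mer; a read window
    matching either the k-mer or its reverse complement increments it.
    """
    all_kmers = list(ref_index.entries)
    seen = set(all_kmers)
    for s in variant_kmer_sets:
        for km in s:
            if km not in seen:
                seen.add(km)
                all_kmers.append(km)
    lookup = _both_strand_lookup(all_kmers)
    counts = [0] * len(all_kmers)
    k = ref_index.k
    get = lookup.get
    for read in reads:
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            v = get(seq[i : i + k])
            if v is None:
                continue
            if type(v) is int:
                counts[v] += 1
            else:
                for s in v:
                    counts[s] += 1
    return dict(zip(all_kmers, counts))


def _aggregate(values: list[float], how: str) -> float:
    if not values:
        return 0.0
    if how == "median":
        return float(statistics.median(values))
    return float(sum(values) / len(values))


def depth_score(alt_depth: float, total_depth: float) -> float:
    """Alternate fraction of informative k-mer depth; 0 when both are 0."""
    if alt_depth < 0 or total_depth < 0:
        raise ValidationError("depths must be non-negative")
    denom = alt_depth + total_depth
    return alt_depth / denom if denom > 0 else 0.0


def classify_confidence(call: VariantCall, config: DetectorConfig) -> Confidence:
    """High iff depth_score >= threshold (inclusive) AND alt_depth > floor
    (strict); everything else is Low."""
    if (
        call.depth_score >= config.high_conf_depth_score
        and call.alt_depth > config.high_conf_alt_depth
    ):
        return Confidence.HIGH
    return Confidence.LOW


def filter_artifacts(
    calls: Sequence[VariantCall], config: DetectorConfig
) -> list[VariantCall]:
    """Flag probable artifacts: insertion longer than the single-base
    pathogenic pattern AND Low confidence.  Flagged calls stay in the
    output."""
    out = []
    for call in calls:
        flag = (
            len(call.inserted_sequence) > config.artifact_max_insertion_len
            and call.confidence == Confidence.LOW
        )
        out.append(replace(call, artifact_flag=flag))
    return out


def detect(
    reads: Sequence[SequenceRecord],
    catalog: MotifCatalog,
    config: DetectorConfig = DetectorConfig(),
    flanks: Optional[tuple[str, str]] = None,
) -> DetectionResult:
    """End-to-end call: screen -> count -> per-candidate calling -> classify
    -> artifact flagging.

    A candidate is considered when at least one of its diagnostic k-mers is
    observed.  Candidates for the same inserted sequence compete (offsets
    whose windows brush a real insertion share a few k-mers with it): only
    the best-supported context per inserted sequence is reported, ranked by
    fraction of diagnostic k-mers observed, then alt depth.

    ``flanks`` (5', 3' locus anchor sequences) switches ``total_depth`` to
    the single-copy flank-junction estimate (see module docstring).
    """
    ref_index = build_reference_kmer_index(catalog, config.k)
    candidates = build_candidates(catalog, config, ref_index)
    anchor_positions: list[frozenset[str]] = []
    if flanks is not None:
        # real junction windows can chance-spell an insertion pattern;
        # remove them from the diagnostic sets (and their rc matches)
        junction = flank_junction_kmers(catalog, flanks[0], flanks[1], config.k)
        junction = junction | {reverse_complement(km) for km in junction}
        candidates = [
            replace(c, kmers=kept)
            for c in candidates
            if (kept := c.kmers - junction)
        ]
        anchor_positions = build_anchor_positions(catalog, flanks[0], flanks[1], config.k)
        variant_kmers = {km for c in candidates for km in c.kmers}
        # an anchor k-mer that collides with repeat or variant context would
        # count multi-copy occurrences; drop it from the depth probes
        anchor_positions = [
            frozenset(
                km
                for km in pos
                if km not in ref_index.entries and km not in variant_kmers
            )
            for pos in anchor_positions
        ]
        anchor_positions = [p for p in anchor_positions if p]
    screen_index = KmerIndex(
        k=config.k,
        entries={
            **ref_index.entries,
            **{
                km: f"variant:{c.inserted_sequence}@{c.motif_id}:{c.offset}"
                for c in candidates
                for km in c.kmers
            },
            **{km: "anchor" for pos in anchor_positions for km in pos},
        },
        built_from=ref_index.built_from,
    )
    screened = screen_reads(reads, screen_index, config)
    counts = count_kmer_depths(
        screened, ref_index, [c.kmers for c in candidates] + anchor_positions
    )
    ref_counts = [counts[km] for km in ref_index.entries]
    total_depth = _aggregate([float(c) for c in ref_counts], "mean")
    if anchor_positions:
        position_depths = [
            float(sum(counts[km] for km in pos)) for pos in anchor_positions
        ]
        # anchors seeing no coverage while the repeat does means the flanks
        # do not match the data; keep the aggregated fallback in that case
        if sum(position_depths) > 0:
            total_depth = _aggregate(position_depths, "mean")
    median_kmer_depth = float(statistics.median(ref_counts)) if ref_counts else 0.0
    read_lengths = [len(r.sequence) for r in screened]
    if read_lengths and median_kmer_depth > 0:
        rl = statistics.median(read_lengths)
        est_cov = median_kmer_depth * rl / max(1.0, rl - config.k + 1)
    else:
        est_cov = 0.0

    best: dict[str, tuple[tuple[float, float], VariantCall]] = {}
    for cand in candidates:
        cand_counts = [float(counts[km]) for km in cand.kmers]
        supporting = sum(1 for c in cand_counts if c > 0)
        if supporting == 0:
            continue
        alt = _aggregate(cand_counts, config.alt_aggregate)
        call = VariantCall(
            inserted_sequence=cand.inserted_sequence,
            context=f"{cand.motif_id}:{cand.offset}",
            alt_depth=alt,
            total_depth=total_depth,
            depth_score=depth_score(alt, total_depth),
            confidence=Confidence.LOW,
            supporting_kmers=supporting,
        )
        call.confidence = classify_confidence(call, config)
        rank = (supporting / len(cand.kmers), alt)
        prev = best.get(cand.inserted_sequence)
        if prev is None or rank > prev[0]:
            best[cand.inserted_sequence] = (rank, call)

    calls = filter_artifacts([c for _, c in best.values()], config)
    calls.sort(key=lambda c: (-c.alt_depth, c.inserted_sequence))
    report = DetectionReport(
        n_reads=len(reads),
        n_screened=len(screened),
        median_ref_kmer_depth=median_kmer_depth,
        estimated_base_coverage=est_cov,
        k=config.k,
    )
    return DetectionResult(calls=calls, report=report)


def calls_to_tsv(calls: Sequence[VariantCall]) -> str:
    """VCF-like TSV rendering of a call list (header + one row per call)."""
    header = (
        "inserted_sequence\tcontext\talt_depth\ttotal_depth\t"
        "depth_score\tconfidence\tartifact_flag\tsupporting_kmers"
    )
    rows = [header]
    for c in calls:
        rows.append(
            f"{c.inserted_sequence}\t{c.context}\t{c.alt_depth:.3f}\t"
            f"{c.total_depth:.3f}\t{c.depth_score:.6f}\t{c.confidence.value}\t"
            f"{str(c.artifact_flag).lower()}\t{c.supporting_kmers}"
        )
    return "\n".join(rows) + "\n"
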