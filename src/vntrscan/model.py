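"""Domain model of a MUC1-type VNTR locus.

The locus is an array of 60-bp GC-rich repeat units drawn from a motif
catalog, flanked by non-repetitive anchor sequence.  Copy number is highly
variable (20-125 units in the canonical MUC1 range) and the pathogenic
lesion is a small insertion -- classically a single cytosine -- inside one
unit, which shifts the reading frame.

Two k-mer spaces are defined over a catalog:

* the *reference* space: every k-mer that can occur in any tandem
  arrangement of catalog units (within a unit or across any ordered
  unit-unit junction);
* the *variant-diagnostic* space for a candidate insertion: k-mers that
  span at least one inserted base and occur nowhere in the reference
  space.  Observing such a k-mer in reads is direct evidence for the
  insertion, with no read mapping involved.

Coordinates follow one convention throughout the package: insertions are
0-based, half-open, "insert before ``offset``" (``offset == 0`` prepends to
the unit, ``offset == 60`` appends after it).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import CatalogError, ParameterError, ValidationError

#: Length of one repeat unit (bp).  Fixed for the MUC1-type VNTR.
UNIT_LENGTH = 60

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    """Fraction of G/C bases in ``sequence`` (0 for the empty string)."""
    if not sequence:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def _check_dna(sequence: str, what: str) -> None:
    if not set(sequence) <= _DNA:
        bad = sorted(set(sequence) - _DNA)
        raise ValidationError(f"{what} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class RepeatMotif:
    """One canonical 60-nt repeat unit."""

    motif_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != UNIT_LENGTH:
            raise ValidationError(
                f"motif {self.motif_id!r}: unit length must be {UNIT_LENGTH}, "
                f"got {len(self.sequence)}"
            )
        _check_dna(self.sequence, f"motif {self.motif_id!r}")

    @property
    def gc_fraction(self) -> float:
        """GC content of the unit, recomputed from the sequence."""
        return gc_fraction(self.sequence)


@dataclass(frozen=True)
class MotifCatalog:
    """Ordered collection of repeat motifs defining the VNTR alphabet.

    The real MUC1 motif inventory is proprietary; catalogs are plain data
    supplied by the user (or generated synthetically for simulation).
    """

    motifs: tuple[RepeatMotif, ...]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate motif_ids in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self) -> Iterator[RepeatMotif]:
        return iter(self.motifs)

    @property
    def motif_ids(self) -> tuple[str, ...]:
        return tuple(m.motif_id for m in self.motifs)

    def get(self, motif_id: str) -> RepeatMotif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise CatalogError(f"motif {motif_id!r} not in catalog")

    # -- TSV round trip: columns motif_id, sequence; '#' lines are comments.

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "MotifCatalog":
        path = Path(path)
        motifs = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise CatalogError(f"{path}: malformed catalog row {row!r}")
                motifs.append(RepeatMotif(row[0].strip(), row[1].strip().upper()))
        return cls(tuple(motifs), source=source if source is not None else str(path))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# motif_id\tsequence\n")
            for m in self.motifs:
                fh.write(f"{m.motif_id}\t{m.sequence}\n")


@dataclass(frozen=True)
class InsertionSpec:
    """A small insertion inside one repeat unit.

    ``repeat_index`` addresses the unit within an allele's repeat array;
    ``offset`` is the 0-based position within that unit before which the
    sequence is inserted (0 <= offset <= 60).
    """

    repeat_index: int
    offset: int
    inserted_sequence: str

    def __post_init__(self) -> None:
        if self.repeat_index < 0:
            raise ValidationError("repeat_index must be >= 0")
        if not 0 <= self.offset <= UNIT_LENGTH:
            raise ValidationError(f"offset must be in [0, {UNIT_LENGTH}]")
        if not self.inserted_sequence:
            raise ValidationError("inserted_sequence must be non-empty")
        _check_dna(self.inserted_sequence, "inserted_sequence")


@dataclass(frozen=True)
class VNTRAllele:
    """One haplotype: an ordered repeat-unit array plus optional insertion."""

    repeat_units: tuple[str, ...]
    insertion: Optional[InsertionSpec] = None
    flank_5p: str = ""
    flank_3p: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.flank_5p, "flank_5p")
        _check_dna(self.flank_3p, "flank_3p")
        if not self.repeat_units:
            raise ValidationError("allele must contain at least one repeat unit")
        if self.insertion is not None and self.insertion.repeat_index >= len(
            self.repeat_units
        ):
            raise ValidationError(
                f"insertion repeat_index {self.insertion.repeat_index} out of "
                f"range for {len(self.repeat_units)} repeat units"
            )

    @property
    def repeat_count(self) -> int:
        return len(self.repeat_units)

    def vntr_length(self) -> int:
        extra = len(self.insertion.inserted_sequence) if self.insertion else 0
        return UNIT_LENGTH * self.repeat_count + extra

    def to_json(self) -> str:
        d = {
            "repeat_units": list(self.repeat_units),
            "insertion": None
            if self.insertion is None
            else {
                "repeat_index": self.insertion.repeat_index,
                "offset": self.insertion.offset,
                "inserted_sequence": self.insertion.inserted_sequence,
            },
            "flank_5p": self.flank_5p,
            "flank_3p": self.flank_3p,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "VNTRAllele":
        d = json.loads(text)
        ins = d.get("insertion")
        return cls(
            repeat_units=tuple(d["repeat_units"]),
            insertion=None
            if ins is None
            else InsertionSpec(ins["repeat_index"], ins["offset"], ins["inserted_sequence"]),
            flank_5p=d.get("flank_5p", ""),
            flank_3p=d.get("flank_3p", ""),
        )


def render_vntr(allele: VNTRAllele, catalog: MotifCatalog) -> str:
    """Repeat-array sequence of ``allele`` (no flanks), insertion spliced in."""
    units = [catalog.get(mid).sequence for mid in allele.repeat_units]
    ins = allele.insertion
    if ins is not None:
        u = units[ins.repeat_index]
        units[ins.repeat_index] = u[: ins.offset] + ins.inserted_sequence + u[ins.offset :]
    return "".join(units)


def render_allele(allele: VNTRAllele, catalog: MotifCatalog) -> str:
    """Full haplotype sequence: 5' flank + repeat array (+insertion) + 3' flank."""
    return allele.flank_5p + render_vntr(allele, catalog) + allele.flank_3p


# ---------------------------------------------------------------------------
# k-mer index construction


@dataclass(frozen=True)
class KmerIndex:
    """Map from k-mer to origin label.

    Labels are ``"reference"`` for k-mers of the insertion-free tandem
    sequence space and ``"variant:<descriptor>"`` for insertion-diagnostic
    k-mers.  Only the forward (coding) orientation is stored; read scanning
    handles both strands.
    """

    k: int
    entries: dict[str, str]
    built_from: str = ""

    def __post_init__(self) -> None:
        for kmer in self.entries:
            if len(kmer) != self.k:
                raise ValidationError(
                    f"index key {kmer!r} has length {len(kmer)}, expected k={self.k}"
                )

    @property
    def reference_kmers(self) -> frozenset[str]:
        return frozenset(k for k, v in self.entries.items() if v == "reference")

    def __len__(self) -> int:
        return len(self.entries)


def _kmers(sequence: str, k: int) -> Iterator[str]:
    for i in range(len(sequence) - k + 1):
        yield sequence[i : i + k]


def build_reference_kmer_index(catalog: MotifCatalog, k: int) -> KmerIndex:
    """Enumerate every k-mer of the insertion-free tandem sequence space.

    For k <= 60 a window in any tandem array of 60-nt units touches at most
    two adjacent units, so the k-mers of all ordered pairwise concatenations
    ``unitA + unitB`` (including A == B) cover the full space.  True unit
    order is unknown from short reads, so all ordered junctions are
    admitted; this is deliberately conservative and keeps junction k-mers
    out of the diagnostic set.
    """
    if len(catalog) == 0:
        raise CatalogError("cannot build a k-mer index from an empty catalog")
    if not 1 <= k <= UNIT_LENGTH:
        raise ParameterError(
            f"k must be in [1, {UNIT_LENGTH}] (windows spanning >2 units are "
            f"undefined under the tandem pair model); got {k}"
        )
    entries: dict[str, str] = {}
    for a in catalog:
        for b in catalog:
            for kmer in _kmers(a.sequence + b.sequence, k):
                entries[kmer] = "reference"
    return KmerIndex(k=k, entries=entries, built_from=catalog.source)


def flank_junction_kmers(
    catalog: MotifCatalog, flank_5p: str, flank_3p: str, k: int
) -> frozenset[str]:
    """Every k-mer of the flank-repeat junction context.

    Windows of ``flank_5p + unit`` and ``unit + flank_3p`` for each motif.
    These occur in real insertion-free haplotypes but not in the pure
    tandem reference space, so diagnostic k-mer sets must be screened
    against them: a flank whose first bases happen to spell an insertion
    pattern would otherwise mimic a variant.
    """
    out: set[str] = set()
    for m in catalog:
        for ctx in (flank_5p + m.sequence, m.sequence + flank_3p):
            out.update(_kmers(ctx, k))
    return frozenset(out)


def enumerate_variant_kmers(
    catalog: MotifCatalog,
    insertion: InsertionSpec,
    k: int,
    ref_index: KmerIndex,
    motif_id: str | None = None,
) -> frozenset[str]:
    """Diagnostic k-mers for an insertion at ``insertion.offset`` of one unit.

    The mutated unit is embedded between every ordered pair of catalog
    neighbours; windows overlapping at least one inserted base are
    collected and any k-mer already present in the reference space is
    discarded.  ``motif_id`` names the unit carrying the insertion and may
    be omitted for a single-motif catalog.

    The result can be empty when the insertion recreates reference context
    (e.g. duplicating a base of a homopolymer run).
    """
    if ref_index.k != k:
        raise ParameterError(f"ref_index has k={ref_index.k}, expected {k}")
    if motif_id is None:
        if len(catalog) != 1:
            raise CatalogError(
                "motif_id is required when the catalog has more than one motif"
            )
        motif_id = catalog.motifs[0].motif_id
    unit = catalog.get(motif_id).sequence
    mutated = unit[: insertion.offset] + insertion.inserted_sequence + unit[insertion.offset :]
    ins_len = len(insertion.inserted_sequence)
    ref = ref_index.entries
    out: set[str] = set()
    for left in catalog:
        for right in catalog:
            ctx = left.sequence + mutated + right.sequence
            ins_start = UNIT_LENGTH + insertion.offset
            ins_end = ins_start + ins_len
            lo = max(0, ins_start - k + 1)
            hi = min(len(ctx) - k, ins_end - 1)
            for i in range(lo, hi + 1):
                kmer = ctx[i : i + k]
                if kmer not in ref:
                    out.add(kmer)
    return frozenset(out)
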