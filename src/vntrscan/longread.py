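"""Ground-truth calling from long amplicon reads spanning the VNTR.

Each amplicon read covers the whole repeat array flank to flank.  The
pipeline anchors the two flanks (approximate match, <=10% edits), trims
the enclosed VNTR in coding orientation, clusters reads into alleles by
VNTR length, builds a per-column majority consensus per allele, and
decomposes the consensus into 60-nt units.  A consensus whose length is
not a multiple of 60 carries an insertion; its position is localized by
finding the deletion that restores an in-phase tiling of catalog units,
reported at the leftmost equivalent position (an insertion adjacent to an
identical base has several equivalent placements).

The reconstruction is also rendered 60 bases per line, the conventional
manual layout for repeat arrays, with the insertion-bearing line longer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .errors import ValidationError
from .io import SequenceRecord
from .model import UNIT_LENGTH, InsertionSpec, MotifCatalog, reverse_complement

#: maximum edit distance for a flank anchor, as a fraction of flank length
FLANK_MAX_EDIT_FRACTION = 0.10

#: clusters whose length centroids differ by less than half a unit merge
CLUSTER_MERGE_DISTANCE = 30


@dataclass
class AlleleReconstruction:
    consensus_sequence: str  # VNTR only, coding orientation
    repeat_count: int
    read_count: int
    allele_frequency: float
    insertion_call: Optional[InsertionSpec]
    layout_text: str


def _best_anchor(flank: str, read: str) -> Optional[tuple[int, int, int]]:
    """(start, end, distance) of the best infix match of flank in read."""
    max_dist = int(FLANK_MAX_EDIT_FRACTION * len(flank))
    res = edlib.align(flank, read, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def extract_vntr(read: str, flank_5p: str, flank_3p: str) -> Optional[str]:
    """VNTR substring between the flank anchors, in coding orientation.

    Tries the read as given and reverse-complemented; returns None when
    either anchor is missing (a non-spanning read).
    """
    if len(flank_5p) < 15 or len(flank_3p) < 15:
        raise ValidationError("flank anchors must be at least 15 nt")
    best: Optional[tuple[int, str]] = None
    for seq in (read, reverse_complement(read)):
        a5 = _best_anchor(flank_5p, seq)
        if a5 is None:
            continue
        a3 = _best_anchor(flank_3p, seq[a5[1] :])
        if a3 is None:
            continue
        dist = a5[2] + a3[2]
        vntr = seq[a5[1] : a5[1] + a3[0]]
        if best is None or dist < best[0]:
            best = (dist, vntr)
    return best[1] if best else None


def cluster_reads_into_alleles(vntr_substrings: Sequence[str]) -> list[list[str]]:
    """Partition VNTR substrings into one or two length clusters.

    Exact 1-D 2-means on length (best split of the sorted lengths); the two
    clusters merge when their centroids are closer than half a unit, so a
    homozygous-like sample and a carrier pair of equal repeat count each
    yield a single cluster.
    """
    if not vntr_substrings:
        raise ValidationError("no VNTR substrings to cluster")
    lengths = np.array([len(s) for s in vntr_substrings], dtype=float)
    order = np.argsort(lengths, kind="stable")
    sorted_len = lengths[order]
    n = len(sorted_len)
    if n == 1 or sorted_len[-1] - sorted_len[0] < CLUSTER_MERGE_DISTANCE:
        return [list(vntr_substrings)]
    # best split position by within-cluster sum of squares
    best_split, best_ss = None, np.inf
    csum = np.cumsum(sorted_len)
    csq = np.cumsum(sorted_len**2)
    for i in range(1, n):
        ss_left = csq[i - 1] - csum[i - 1] ** 2 / i
        ss_right = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        if ss_left + ss_right < best_ss:
            best_ss, best_split = ss_left + ss_right, i
    left_idx = order[:best_split]
    right_idx = order[best_split:]
    c_left = lengths[left_idx].mean()
    c_right = lengths[right_idx].mean()
    if abs(c_right - c_left) < CLUSTER_MERGE_DISTANCE:
        return [list(vntr_substrings)]
    return [
        [vntr_substrings[i] for i in sorted(left_idx)],
        [vntr_substrings[i] for i in sorted(right_idx)],
    ]


def _consensus(seqs: Sequence[str]) -> str:
    """Per-column majority over the reads of the modal length.

    Substitution noise leaves read lengths intact, so reads of the modal
    length are columnwise comparable; ties on length prefer the longer
    (insertion-bearing) group.
    """
    by_len = Counter(len(s) for s in seqs)
    top = max(by_len.items(), key=lambda kv: (kv[1], kv[0]))[0]
    rows = [s for s in seqs if len(s) == top]
    if len(rows) == 1:
        return rows[0]
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in rows])
    out = np.empty(mat.shape[1], dtype=np.uint8)
    for j in range(mat.shape[1]):
        vals, cnt = np.unique(mat[:, j], return_counts=True)
        out[j] = vals[np.argmax(cnt)]
    return out.tobytes().decode()


def _localize_insertion(
    consensus: str, catalog: MotifCatalog, ins_len: int
) -> InsertionSpec:
    """Leftmost deletion of ``ins_len`` bases restoring an in-phase tiling.

    Scans 60-nt blocks left to right for the first block that is not a
    catalog unit, then tries deletion positions around it; positions are
    verified by checking that every block of the restored sequence is a
    catalog motif.  Falls back to the minimum-mismatch position when noise
    prevents an exact restoration.
    """
    motif_set = {m.sequence for m in catalog}

    def in_phase(seq: str) -> bool:
        return all(
            seq[i : i + UNIT_LENGTH] in motif_set
            for i in range(0, len(seq), UNIT_LENGTH)
        )

    n_blocks = len(consensus) // UNIT_LENGTH
    first_bad = n_blocks
    for b in range(n_blocks):
        if consensus[b * UNIT_LENGTH : (b + 1) * UNIT_LENGTH] not in motif_set:
            first_bad = b
            break
    lo = max(0, first_bad * UNIT_LENGTH - ins_len)
    hi = min(len(consensus) - ins_len, (first_bad + 1) * UNIT_LENGTH + ins_len)
    fallback, fallback_score = None, np.inf
    for p in range(lo, hi + 1):
        restored = consensus[:p] + consensus[p + ins_len :]
        if in_phase(restored):
            return InsertionSpec(p // UNIT_LENGTH, p % UNIT_LENGTH, consensus[p : p + ins_len])
        mism = sum(
            restored[i : i + UNIT_LENGTH] not in motif_set
            for i in range(0, len(restored), UNIT_LENGTH)
        )
        if mism < fallback_score:
            fallback_score = mism
            fallback = InsertionSpec(
                p // UNIT_LENGTH, p % UNIT_LENGTH, consensus[p : p + ins_len]
            )
    assert fallback is not None
    return fallback


def canonical_insertion(spec: InsertionSpec, vntr_sequence: str) -> InsertionSpec:
    """Leftmost-equivalent representation of an insertion in a VNTR string.

    ``vntr_sequence`` is the mutated sequence containing the insertion.
    Sliding an inserted base left across identical bases yields the same
    string; comparisons between called and true specs use this normal form.
    """
    p = spec.repeat_index * UNIT_LENGTH + spec.offset
    L = len(spec.inserted_sequence)
    while p > 0 and vntr_sequence[p - 1] == vntr_sequence[p + L - 1]:
        p -= 1
    return InsertionSpec(p // UNIT_LENGTH, p % UNIT_LENGTH, vntr_sequence[p : p + L])


def _layout(consensus: str, insertion: Optional[InsertionSpec]) -> str:
    lines = []
    pos = 0
    unit = 0
    while pos < len(consensus):
        width = UNIT_LENGTH
        if insertion is not None and unit == insertion.repeat_index:
            width += len(insertion.inserted_sequence)
        lines.append(consensus[pos : pos + width])
        pos += width
        unit += 1
    return "\n".join(lines)


def decompose_and_call(
    cluster: Sequence[str], catalog: MotifCatalog
) -> AlleleReconstruction:
    """Consensus, repeat count, and direct insertion call for one cluster.

    ``read_count``/``allele_frequency`` are filled by the caller that knows
    the full read set; here they reflect the cluster alone.
    """
    if not cluster:
        raise ValidationError("cannot decompose an empty cluster")
    consensus = _consensus(cluster)
    repeat_count = len(consensus) // UNIT_LENGTH
    remainder = len(consensus) % UNIT_LENGTH
    insertion = None
    if remainder:
        insertion = _localize_insertion(consensus, catalog, remainder)
        insertion = canonical_insertion(insertion, consensus)
    return AlleleReconstruction(
        consensus_sequence=consensus,
        repeat_count=repeat_count,
        read_count=len(cluster),
        allele_frequency=1.0,
        insertion_call=insertion,
        layout_text=_layout(consensus, insertion),
    )


def reconstruct_alleles(
    reads: Sequence[SequenceRecord],
    flank_5p: str,
    flank_3p: str,
    catalog: MotifCatalog,
) -> list[AlleleReconstruction]:
    """Full oracle: extract, cluster, split carrier-mixed clusters, call.

    A length cluster holding two well-supported exact lengths (a carrier
    whose alleles have the same repeat count differs by the insertion
    length only) is split so both haplotypes are reconstructed.  Under the
    substitution-only error model read lengths are exact, which this split
    relies on; indel-noisy platforms would need length binning first.
    """
    vntrs = [v for r in reads if (v := extract_vntr(r.sequence, flank_5p, flank_3p))]
    if not vntrs:
        raise ValidationError("no read spans both flank anchors")
    clusters = cluster_reads_into_alleles(vntrs)
    subclusters: list[list[str]] = []
    for cluster in clusters:
        by_len = Counter(len(s) for s in cluster)
        major = [
            ln for ln, cnt in by_len.items() if cnt >= max(2, 0.2 * len(cluster))
        ]
        if len(major) >= 2:
            major_set = set(major)
            for ln in sorted(major_set):
                subclusters.append([s for s in cluster if len(s) == ln])
        else:
            subclusters.append(cluster)
    total = sum(len(c) for c in subclusters)
    out = []
    for cluster in subclusters:
        rec = decompose_and_call(cluster, catalog)
        rec.allele_frequency = len(cluster) / total
        out.append(rec)
    out.sort(key=lambda r: -r.read_count)
    return out


def reconstructions_to_tsv(recs: Sequence[AlleleReconstruction]) -> str:
    header = (
        "consensus_length\trepeat_count\tread_count\tallele_frequency\tinsertion_call"
    )
    rows = [header]
    for r in recs:
        ins = (
            "-"
            if r.insertion_call is None
            else f"{r.insertion_call.inserted_sequence}@"
            f"{r.insertion_call.repeat_index}:{r.insertion_call.offset}"
        )
        rows.append(
            f"{len(r.consensus_sequence)}\t{r.repeat_count}\t{r.read_count}\t"
            f"{r.allele_frequency:.4f}\t{ins}"
        )
    return "\n".join(rows) + "\n"
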