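"""Seed alignment construction for repeat families.

A repeat family's seed alignment is built from per-instance pairwise
alignments of genomic copies against a shared consensus sequence. This
module implements the curation rules applied before profile building:

* collapsing copies duplicated after transposition (near-identical
  flanking DNA on both sides),
* capping the seed at a maximum number of members, removing the most
  divergent quartile first and preferring near-full-length copies over
  fragments, with a depth top-up for poorly covered consensus regions,
* joining the surviving pairwise alignments into one multiple sequence
  alignment in consensus coordinates, with insertions relative to the
  consensus kept as lowercase insert columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "InstanceAlignment",
    "SeedAlignment",
    "join_to_msa",
    "dedupe_duplicated_copies",
    "sample_seed",
]

_GAPS = set("-.")

MAX_SEED_MEMBERS = 2000


def _degap(s: str) -> str:
    return "".join(c for c in s if c not in _GAPS)


@dataclass
class InstanceAlignment:
    """One genomic copy of a family, pairwise-aligned to the consensus.

    Coordinates are 1-based inclusive on the source sequence. ``divergence``
    is the fraction of aligned columns that are mismatches or indels;
    ``consensus_coverage`` is the fraction of the consensus length covered
    by this copy.
    """

    instance_id: str
    source_sequence_id: str
    start: int
    end: int
    strand: str
    aligned_instance: str
    aligned_consensus: str
    divergence: float
    consensus_coverage: float
    organism: str = ""

    def __post_init__(self) -> None:
        if len(self.aligned_instance) != len(self.aligned_consensus):
            raise ValueError(
                f"{self.instance_id}: aligned strings differ in length"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.instance_id}: strand must be + or -")
        n_res = len(_degap(self.aligned_instance))
        if n_res != self.end - self.start + 1:
            raise ValueError(
                f"{self.instance_id}: degapped length {n_res} != "
                f"end-start+1 ({self.end - self.start + 1})"
            )
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError(f"{self.instance_id}: divergence out of [0,1]")
        if not (0.0 <= self.consensus_coverage <= 1.0):
            raise ValueError(
                f"{self.instance_id}: consensus_coverage out of [0,1]"
            )


@dataclass
class SeedAlignment:
    """Multiple alignment of family members in consensus coordinates.

    Match columns correspond 1:1 to consensus positions; insert columns
    (lowercase residues, ``.`` padding) carry residues aligned opposite
    consensus gaps. ``rf`` marks match columns with ``x`` and insert
    columns with ``.``; ``column_counts[i]`` is the number of members with
    a residue in match column ``i``.
    """

    family_id: str
    consensus: str
    members: list[str]
    member_ids: list[str]
    rf: str
    column_counts: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = {len(m) for m in self.members}
        if len(widths) > 1:
            raise ValueError("member rows differ in aligned length")
        if self.members and len(self.members[0]) != len(self.rf):
            raise ValueError("rf length does not match alignment width")
        if len(self.members) > MAX_SEED_MEMBERS:
            raise ValueError(
                f"seed alignment has {len(self.members)} members "
                f"(cap is {MAX_SEED_MEMBERS}); run sample_seed first"
            )
        n_match = self.rf.count("x")
        if n_match != len(self.consensus):
            raise ValueError("match column count != consensus length")
        self.column_counts = np.asarray(self.column_counts, dtype=int)
        if len(self.column_counts) != n_match:
            raise ValueError("column_counts length != match column count")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def match_columns(self) -> np.ndarray:
        """Indices of match columns within the gapped alignment."""
        return np.flatnonzero(np.frombuffer(self.rf.encode(), dtype="S1") == b"x")


def _consensus_offset(inst: InstanceAlignment, consensus: str) -> int:
    """0-based start of this instance's consensus segment in the full consensus."""
    seg = _degap(inst.aligned_consensus).upper()
    off = consensus.upper().find(seg)
    if off < 0:
        raise ValueError(
            f"{inst.instance_id}: aligned consensus segment not found in consensus"
        )
    return off


def _walk(inst: InstanceAlignment, offset: int):
    """Yield per-column placements: match residues keyed by consensus position
    (0-based) and insert strings keyed by anchor (number of consensus
    positions strictly before the insertion)."""
    matches: dict[int, str] = {}
    inserts: dict[int, list[str]] = {}
    pos = offset
    for cc, ic in zip(inst.aligned_consensus, inst.aligned_instance):
        cons_gap = cc in _GAPS
        ins_gap = ic in _GAPS
        if not cons_gap:
            matches[pos] = "-" if ins_gap else ic.upper()
            pos += 1
        elif not ins_gap:
            inserts.setdefault(pos, []).append(ic.upper())
    return matches, {k: "".join(v) for k, v in inserts.items()}


def covered_positions(inst: InstanceAlignment, consensus: str) -> np.ndarray:
    """Boolean mask over consensus positions where this copy has a residue."""
    off = _consensus_offset(inst, consensus)
    matches, _ = _walk(inst, off)
    mask = np.zeros(len(consensus), dtype=bool)
    for p, c in matches.items():
        if c != "-":
            mask[p] = True
    return mask


def join_to_msa(
    alignments: list[InstanceAlignment],
    consensus: str,
    family_id: str = "family",
) -> SeedAlignment:
    """Join pairwise instance-vs-consensus alignments into one MSA.

    Instance residues aligned to a consensus position land in that match
    column; residues opposite consensus gaps become lowercase insert
    columns anchored after the preceding match column. Instances whose
    consensus segment cannot be located in ``consensus`` are rejected with
    a warning rather than silently dropped.
    """
    if not alignments:
        raise ValueError("no instance alignments supplied")
    consensus = consensus.upper()
    L = len(consensus)

    placed = []
    for inst in alignments:
        try:
            off = _consensus_offset(inst, consensus)
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        matches, inserts = _walk(inst, off)
        placed.append((inst, matches, inserts))
    if not placed:
        raise ValueError("no instance alignment matched the consensus")

    # width of the insert block after each anchor (0..L)
    ins_width = np.zeros(L + 1, dtype=int)
    for _, _, inserts in placed:
        for anchor, s in inserts.items():
            ins_width[anchor] = max(ins_width[anchor], len(s))

    rf_parts = []
    for p in range(L + 1):
        if p > 0:
            rf_parts.append("x")
        rf_parts.append("." * ins_width[p])
    rf = "".join(rf_parts)

    members, member_ids, provenance = [], [], []
    counts = np.zeros(L, dtype=int)
    for inst, matches, inserts in placed:
        row = []
        for p in range(L + 1):
            if p > 0:
                c = matches.get(p - 1, "-")
                row.append(c)
                if c != "-":
                    counts[p - 1] += 1
            ins = inserts.get(p, "").lower()
            row.append(ins + "." * (ins_width[p] - len(ins)))
        members.append("".join(row))
        member_ids.append(inst.instance_id)
        provenance.append(inst.organism)

    return SeedAlignment(
        family_id=family_id,
        consensus=consensus,
        members=members,
        member_ids=member_ids,
        rf=rf,
        column_counts=counts,
        provenance=provenance,
    )


def _fetch(store, seq_id: str, start: int, end: int) -> str:
    """Fetch [start, end] 1-based inclusive from a sequence store, clamped to
    the contig. Accepts a plain mapping of id -> string or any object with a
    pyfaidx-like ``store[seq_id][a:b]`` interface."""
    rec = store[seq_id]
    seq = rec if isinstance(rec, str) else str(rec[:])
    start = max(1, start)
    end = min(len(seq), end)
    if end < start:
        return ""
    return seq[start - 1 : end].upper()


def flank_identity(a: str, b: str) -> float:
    """Global-alignment identity between two flank sequences."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def dedupe_duplicated_copies(
    alignments: list[InstanceAlignment],
    flank_source,
    identity_threshold: float = 0.90,
    flank_len: int = 250,
) -> list[InstanceAlignment]:
    """Collapse copies that were duplicated after insertion.

    Instances whose flanking DNA (``flank_len`` bp on each side) exceeds
    ``identity_threshold`` pairwise on BOTH flanks are clustered by single
    linkage; one representative per cluster is kept (lowest divergence, ties
    by instance_id). Such pairs arise from segmental or tandem duplication
    of a region already containing the element, and would otherwise count
    one insertion twice.
    """
    if flank_source is None:
        warnings.warn("no flank source provided; skipping duplicate-copy dedupe")
        return list(alignments)
    n = len(alignments)
    if n <= 1:
        return list(alignments)

    flanks = []
    for inst in alignments:
        try:
            left = _fetch(flank_source, inst.source_sequence_id,
                          inst.start - flank_len, inst.start - 1)
            right = _fetch(flank_source, inst.source_sequence_id,
                           inst.end + 1, inst.end + flank_len)
        except KeyError:
            warnings.warn(
                f"{inst.instance_id}: source sequence missing from flank "
                "source; instance kept without dedupe"
            )
            left = right = None
        flanks.append((left, right))

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        if flanks[i][0] is None:
            continue
        for j in range(i + 1, n):
            if flanks[j][0] is None:
                continue
            if (
                flank_identity(flanks[i][0], flanks[j][0]) > identity_threshold
                and flank_identity(flanks[i][1], flanks[j][1]) > identity_threshold
            ):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    kept = []
    for idxs in clusters.values():
        best = min(idxs, key=lambda i: (alignments[i].divergence,
                                        alignments[i].instance_id))
        kept.append(best)
    kept.sort()
    return [alignments[i] for i in kept]


def sample_seed(
    alignments: list[InstanceAlignment],
    max_members: int = MAX_SEED_MEMBERS,
    long_coverage: float = 0.75,
    target_depth: int = 10,
    rng_seed: int = 0,
    *,
    consensus: str | None = None,
    supplementary: list[InstanceAlignment] | None = None,
) -> list[InstanceAlignment]:
    """Down-sample instances to at most ``max_members``.

    When over the cap, the most divergent quartile is removed first, then
    members are drawn at random (seeded), using near-full-length copies
    (consensus coverage > ``long_coverage``) before fragments. Afterwards,
    if any consensus position has depth < ``target_depth`` and room remains
    under the cap, fragments covering the lowest-depth position are added
    greedily from the unused pool and, if provided, from
    ``supplementary`` instances (e.g. copies from another organism).
    Requires ``consensus`` for the depth top-up step.
    """
    rng = np.random.default_rng(rng_seed)
    pool = list(alignments)

    if len(pool) > max_members:
        by_div = sorted(pool, key=lambda a: (a.divergence, a.instance_id))
        n_drop = len(by_div) // 4
        pool = by_div[: len(by_div) - n_drop]

    if len(pool) > max_members:
        longs = [a for a in pool if a.consensus_coverage > long_coverage]
        frags = [a for a in pool if a.consensus_coverage <= long_coverage]
        longs.sort(key=lambda a: a.instance_id)
        frags.sort(key=lambda a: a.instance_id)
        rng.shuffle(longs)
        rng.shuffle(frags)
        selected = longs[:max_members]
        if len(selected) < max_members:
            selected.extend(frags[: max_members - len(selected)])
        leftovers = longs[max_members:] + frags[max(0, max_members - len(longs)):]
    else:
        selected = pool
        leftovers = []

    def _mask(a: InstanceAlignment) -> np.ndarray:
        try:
            return covered_positions(a, consensus)
        except ValueError:
            return np.zeros(len(consensus), dtype=bool)

    extra_pool = leftovers + list(supplementary or [])
    if consensus is not None and extra_pool and len(selected) < max_members:
        selected = list(selected)
        depth = np.zeros(len(consensus), dtype=int)
        for a in selected:
            depth += _mask(a)
        masks = {id(a): _mask(a) for a in extra_pool}
        extra_pool = sorted(extra_pool,
                            key=lambda a: (a.divergence, a.instance_id))
        unsatisfiable = np.zeros(len(consensus), dtype=bool)
        while len(selected) < max_members:
            open_pos = np.flatnonzero((depth < target_depth) & ~unsatisfiable)
            if open_pos.size == 0 or not extra_pool:
                break
            pos = open_pos[np.argmin(depth[open_pos])]
            cand = next((a for a in extra_pool if masks[id(a)][pos]), None)
            if cand is None:
                unsatisfiable[pos] = True
                continue
            extra_pool.remove(cand)
            selected.append(cand)
            depth += masks[id(cand)]

    return selected
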