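"""Threshold application and redundant-hit adjudication.

Related family models match the same locus; annotation wants one "best"
family per region. After applying per-family GA or TC thresholds, hits on
a target are adjudicated greedily by descending score: a hit is accepted
iff its overlap with every already-accepted hit is within the tolerance.
Greedy is not guaranteed optimal (and is documented as such); ties break
deterministically by lower E-value, then longer hit, then model id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .hits import Hit

__all__ = [
    "AdjudicatedAnnotation",
    "apply_threshold",
    "resolve_redundant",
    "adjudicate",
]


@dataclass
class AdjudicatedAnnotation:
    hits: list[Hit] = field(default_factory=list)
    rejected: list[tuple[Hit, str]] = field(default_factory=list)


def apply_threshold(
    hits: list[Hit],
    thresholds: dict[str, dict[str, float]],
    mode: str = "GA",
    taxon: str | None = None,
) -> tuple[list[Hit], list[tuple[Hit, str]]]:
    """Keep hits scoring at or above their model's GA or TC threshold.

    ``thresholds`` maps model_id -> {"GA": bits, "TC": bits} or, with
    ``taxon`` given, model_id -> taxon -> {"GA","TC"}. A model without a
    threshold is an error (an uncalibrated model must not silently pass).
    """
    if mode not in ("GA", "TC"):
        raise ValueError("mode must be 'GA' or 'TC'")
    kept, rejected = [], []
    for h in hits:
        try:
            entry = thresholds[h.model_id]
            if taxon is not None:
                entry = entry[taxon]
            cut = entry[mode]
        except KeyError as exc:
            raise KeyError(
                f"no {mode} threshold for model {h.model_id!r}"
                + (f" taxon {taxon!r}" if taxon else "")
            ) from exc
        if h.score >= cut:
            kept.append(h)
        else:
            rejected.append((h, "below_threshold"))
    return kept, rejected


def _overlap(a: Hit, b: Hit) -> int:
    """Overlap between two hit envelopes, measured as the distance each
    encroaches past the other's boundary (so abutting hits, and hits
    sharing a single boundary base, count 0)."""
    return max(0, min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from))


def _sort_key(h: Hit):
    ev = h.evalue if math.isfinite(h.evalue) else math.inf
    return (-h.score, ev, -(h.ali_to - h.ali_from), h.model_id,
            h.ali_from, h.strand)


def resolve_redundant(hits: list[Hit],
                      max_overlap_bp: int = 0) -> AdjudicatedAnnotation:
    """Greedy score-descending adjudication of overlapping hits on one
    target sequence.

    Accepts a hit iff its overlap with every already-accepted hit is at
    most ``max_overlap_bp``. Deterministic and independent of input
    order; accepted + rejected partition the input."""
    targets = {h.target_id for h in hits}
    if len(targets) > 1:
        raise ValueError(
            "resolve_redundant expects hits on a single target; "
            f"got {sorted(targets)}"
        )
    result = AdjudicatedAnnotation()
    for h in sorted(hits, key=_sort_key):
        if all(_overlap(h, a) <= max_overlap_bp for a in result.hits):
            result.hits.append(h)
        else:
            result.rejected.append((h, "redundant_overlap"))
    result.hits.sort(key=lambda h: (h.ali_from, h.ali_to))
    return result


def adjudicate(
    hits: list[Hit],
    thresholds: dict[str, dict[str, float]],
    mode: str = "GA",
    max_overlap_bp: int = 0,
    taxon: str | None = None,
) -> AdjudicatedAnnotation:
    """Threshold then resolve redundancy, partitioning per target."""
    kept, rejected = apply_threshold(hits, thresholds, mode, taxon)
    result = AdjudicatedAnnotation(rejected=list(rejected))
    by_target: dict[str, list[Hit]] = {}
    for h in kept:
        by_target.setdefault(h.target_id, []).append(h)
    for target in sorted(by_target):
        sub = resolve_redundant(by_target[target], max_overlap_bp)
        result.hits.extend(sub.hits)
        result.rejected.extend(sub.rejected)
    return result
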