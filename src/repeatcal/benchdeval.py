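"""Benchmark evaluation: false hits, overextension, bp-level FDR split.

On a benchmark with planted truth, each annotation either has no truth
support (a false hit: all of its bases are false annotation) or matches a
planted fragment, in which case any bases beyond the bounds of that
fragment are *overextension* — the alignment correctly found a truncated
element but ran on into flanking non-homologous sequence. The bp-level
false discovery rate therefore splits into an FDR due to false hits and
an FDR due to overextension, and every annotated base is exactly one of
true / false-hit / overextended.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .hits import Hit
from .simbench import TruthInterval

__all__ = [
    "HitAssessment",
    "BenchmarkTotals",
    "classify_hits",
    "summarize",
    "overextension_histogram",
    "long_overextension_bp",
    "evaluate",
]


@dataclass
class HitAssessment:
    hit: Hit
    matched_truth: TruthInterval | None
    overlap_bp: int
    overext_bp: int

    @property
    def is_false(self) -> bool:
        return self.matched_truth is None

    @property
    def false_bp(self) -> int:
        return self.hit.length if self.is_false else 0

    @property
    def true_bp(self) -> int:
        return self.overlap_bp


@dataclass
class BenchmarkTotals:
    total_annotated_bp: int
    true_bp: int
    false_hit_bp: int
    overext_bp: int
    fdr_false_hits_pct: float
    fdr_overext_pct: float


def _overlap(a1: int, b1: int, a2: int, b2: int) -> int:
    return max(0, min(b1, b2) - max(a1, a2) + 1)


def classify_hits(hits: list[Hit], truth: list[TruthInterval],
                  min_overlap: int = 1) -> list[HitAssessment]:
    """Match each hit to the same-family truth interval of maximal overlap.

    Overlap below ``min_overlap`` bp (or a family absent from the truth
    catalog, or overlap only with another family's truth) makes the hit a
    false hit with every base counted false. Otherwise overext_bp is the
    number of hit bases outside the matched truth interval, left plus
    right. Ties on overlap go to the left-most truth interval.
    """
    by_family: dict[str, list[TruthInterval]] = {}
    for t in truth:
        by_family.setdefault(t.family_id, []).append(t)
    for lst in by_family.values():
        lst.sort(key=lambda t: (t.start, t.end))

    known = set(by_family)
    out = []
    for hit in hits:
        if hit.model_id not in known:
            warnings.warn(
                f"model {hit.model_id} absent from truth catalog; "
                "counted as a false hit"
            )
            out.append(HitAssessment(hit, None, 0, 0))
            continue
        best, best_ov = None, 0
        for t in by_family[hit.model_id]:
            ov = _overlap(hit.ali_from, hit.ali_to, t.start, t.end)
            if ov > best_ov:
                best, best_ov = t, ov
        if best is None or best_ov < min_overlap:
            out.append(HitAssessment(hit, None, 0, 0))
        else:
            out.append(HitAssessment(hit, best, best_ov,
                                     hit.length - best_ov))
    return out


def summarize(per_hit: list[HitAssessment],
              total_annotated_bp: int | None = None) -> BenchmarkTotals:
    """bp-level totals and the FDR split.

    The denominator is the total annotated bp (sum of hit lengths unless
    given explicitly); true + false-hit + overextended bp account for
    every annotated base exactly once."""
    if total_annotated_bp is None:
        total_annotated_bp = sum(a.hit.length for a in per_hit)
    if total_annotated_bp == 0:
        raise ValueError("zero annotated bp; FDR undefined")
    true_bp = sum(a.true_bp for a in per_hit)
    false_bp = sum(a.false_bp for a in per_hit)
    overext_bp = sum(a.overext_bp for a in per_hit)
    return BenchmarkTotals(
        total_annotated_bp=total_annotated_bp,
        true_bp=true_bp,
        false_hit_bp=false_bp,
        overext_bp=overext_bp,
        fdr_false_hits_pct=100.0 * false_bp / total_annotated_bp,
        fdr_overext_pct=100.0 * overext_bp / total_annotated_bp,
    )


def overextension_histogram(per_hit: list[HitAssessment]) -> dict[int, int]:
    """hit count per positive overextension length; the counts sum to the
    number of overextended hits."""
    return dict(Counter(a.overext_bp for a in per_hit
                        if not a.is_false and a.overext_bp > 0))


def long_overextension_bp(per_hit: list[HitAssessment],
                          min_len: int = 100) -> int:
    """Total overextended bp contributed by hits whose overextension
    exceeds ``min_len`` (long overextensions dominate the damage)."""
    return sum(a.overext_bp for a in per_hit
               if not a.is_false and a.overext_bp > min_len)


def evaluate(hits: list[Hit], truth: list[TruthInterval],
             min_overlap: int = 1):
    """classify + summarize + histogram in one call."""
    per_hit = classify_hits(hits, truth, min_overlap)
    return per_hit, summarize(per_hit), overextension_histogram(per_hit)
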