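"""Empirical GA/TC score-threshold calibration.

Per-family bit-score thresholds are set by comparing hits on genomic (or
planted-benchmark) sequence against hits on a simulated background of the
same size. Background hits stand in for false hits, so the empirical
false discovery rate at a threshold t is the background hit count at or
above t as a percentage of the genomic hit count at or above t.

* GA (gathering): the lowest score keeping FDR <= 0.2% with every
  accepted hit at E-value <= 100; used for organisms known to contain
  the family.
* TC (trusted cutoff): at least the score reaching E-value 1e-4, raised
  above every background hit; safe for annotating other organisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hits import Hit
from .profilecore import EValueModel

__all__ = [
    "CalibrationResult",
    "empirical_fdr",
    "choose_ga",
    "choose_tc",
    "calibrate_family",
]

DEFAULT_MAX_FDR = 0.2     # percent
DEFAULT_MAX_EVALUE = 100.0
DEFAULT_TC_EVALUE = 1e-4
TC_EPSILON = 0.1          # bits above the best background hit


def _scores(hits: list[Hit]) -> np.ndarray:
    return np.array([h.score for h in hits], dtype=float)


def empirical_fdr(genomic_hits: list[Hit], background_hits: list[Hit],
                  threshold: float) -> float:
    """Percent of genomic hits at or above ``threshold`` attributable to
    background, assuming equal search-space sizes. 0 when no background
    hit reaches the threshold; an error when no genomic hit does."""
    n_gen = int((_scores(genomic_hits) >= threshold).sum()) if genomic_hits else 0
    if n_gen == 0:
        raise ValueError(
            f"no genomic hits at or above threshold {threshold}; FDR undefined"
        )
    n_bg = int((_scores(background_hits) >= threshold).sum()) if background_hits else 0
    return 100.0 * n_bg / n_gen


def choose_ga(genomic_hits: list[Hit], background_hits: list[Hit],
              max_fdr: float = DEFAULT_MAX_FDR,
              max_evalue: float = DEFAULT_MAX_EVALUE) -> float:
    """Lowest score threshold with FDR <= ``max_fdr`` percent and all
    accepted hits at E-value <= ``max_evalue``.

    The FDR is a step function changing only at observed scores, so the
    scan over sorted genomic hit scores is exact. If no threshold
    satisfies both bounds, returns the lowest genomic score above every
    background hit (or just above the best background hit if none).
    """
    if not genomic_hits:
        raise ValueError("no genomic hits; cannot set GA")
    gen = sorted(genomic_hits, key=lambda h: h.score)
    bg_scores = _scores(background_hits)
    gen_scores = _scores(gen)
    gen_ev = np.array([h.evalue for h in gen], dtype=float)

    # max E-value among hits accepted at each candidate threshold
    suffix_max_ev = np.full(len(gen), -np.inf)
    running = -np.inf
    for i in range(len(gen) - 1, -1, -1):
        ev = gen_ev[i]
        if np.isfinite(ev):
            running = max(running, ev)
        suffix_max_ev[i] = running

    for i, t in enumerate(gen_scores):
        n_gen = len(gen) - i
        n_bg = int((bg_scores >= t).sum()) if bg_scores.size else 0
        fdr = 100.0 * n_bg / n_gen
        ev_ok = (suffix_max_ev[i] == -np.inf) or (suffix_max_ev[i] <= max_evalue)
        if fdr <= max_fdr and ev_ok:
            return float(t)

    best_bg = float(bg_scores.max()) if bg_scores.size else -np.inf
    above = gen_scores[gen_scores > best_bg]
    if above.size:
        return float(above.min())
    return best_bg + TC_EPSILON


def choose_tc(evalue_model: EValueModel, background_hits: list[Hit],
              evalue_target: float = DEFAULT_TC_EVALUE,
              search_space: float | None = None,
              epsilon: float = TC_EPSILON) -> float:
    """Trusted cutoff: max(score at the E-value target, best background
    score + epsilon). No background hit ever scores at or above TC."""
    if evalue_model is None:
        raise ValueError("E-value model required for TC")
    tc = evalue_model.score_at_evalue(evalue_target, search_space)
    if background_hits:
        tc = max(tc, max(h.score for h in background_hits) + epsilon)
    return float(tc)


@dataclass
class CalibrationResult:
    model_id: str
    taxon: str
    ga: float
    tc: float
    fdr_curve: list[tuple[float, int, int, float]] = field(default_factory=list)


def fdr_curve(genomic_hits: list[Hit],
              background_hits: list[Hit]) -> list[tuple[float, int, int, float]]:
    """(score, genomic >= score, background >= score, FDR%) at each
    observed genomic score."""
    gen_scores = np.sort(_scores(genomic_hits))
    bg_scores = _scores(background_hits)
    curve = []
    for i, t in enumerate(gen_scores):
        n_gen = len(gen_scores) - i
        n_bg = int((bg_scores >= t).sum()) if bg_scores.size else 0
        curve.append((float(t), n_gen, n_bg, 100.0 * n_bg / n_gen))
    return curve


def calibrate_family(
    model_id: str,
    genomic_hits: list[Hit],
    background_hits: list[Hit],
    evalue_model: EValueModel,
    taxon: str = "default",
    max_fdr: float = DEFAULT_MAX_FDR,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    tc_evalue: float = DEFAULT_TC_EVALUE,
) -> CalibrationResult:
    """Full GA + TC calibration for one family against one taxon."""
    ga = choose_ga(genomic_hits, background_hits, max_fdr, max_evalue)
    tc = choose_tc(evalue_model, background_hits, tc_evalue)
    tc = max(tc, ga)  # trusted cutoff is never below the gathering threshold
    return CalibrationResult(
        model_id=model_id, taxon=taxon, ga=ga, tc=tc,
        fdr_curve=fdr_curve(genomic_hits, background_hits),
    )
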