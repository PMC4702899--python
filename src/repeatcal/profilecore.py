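"""Position-specific scoring models with entropy weighting.

A family profile is built from a seed alignment by mixing per-column
observed counts with a Dirichlet prior. Deep alignments yield sharp
emission distributions whose average relative entropy (expected bits per
aligned residue) far exceeds what is wanted for sensitive, well-bounded
search, so observations are down-weighted until the model's average
relative entropy hits a target (default 0.62 bits/position):

* uniform weighting multiplies every column's counts by one factor m,
* exponential weighting replaces each column's total count k by k**s
  with a single exponent 0 <= s <= 1, so deep columns are down-weighted
  far more than shallow ones (every scaled total stays in [1, k]).

The module also provides a minimal local-alignment search over the
profile's log-odds scores and an empirical Gumbel-tail E-value fit, as
plumbing for threshold calibration and benchmark evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hits import Hit
from .seedforge import SeedAlignment

__all__ = [
    "PriorModel",
    "ProfileModel",
    "EValueModel",
    "relative_entropy",
    "column_posterior",
    "fit_exponential_scale",
    "fit_uniform_scale",
    "build_profile",
    "seed_counts",
    "search",
    "fit_evalue_model",
    "estimate_evalue",
]

ALPHABET = "ACGT"
DEFAULT_TARGET_RE = 0.62
_CODES = np.full(128, 4, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODES[ord(_c)] = _i
    _CODES[ord(_c.lower())] = _i

RE_TOL = 1e-4  # bisection tolerance on avg relative entropy, bits


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes (A,C,G,T -> 0..3; other -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PriorModel:
    """Symmetric-by-default Dirichlet pseudocounts over A,C,G,T."""

    alpha: np.ndarray = field(default_factory=lambda: np.ones(4))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (4,) or np.any(self.alpha <= 0):
            raise ValueError("prior alpha must be 4 positive components")


def relative_entropy(p, q) -> float:
    """Kullback-Leibler divergence D(p || q) in bits.

    This is the expected per-residue score of an emission distribution p
    against background q; it is >= 0, and 0 iff p == q.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("background distribution must be strictly positive")
    mask = p > 0
    # clamp tiny negative rounding residue: KL >= 0 mathematically
    return max(0.0, float(np.sum(p[mask] * np.log2(p[mask] / q[mask]))))


def column_posterior(counts, prior: PriorModel) -> np.ndarray:
    """Posterior mean emission probabilities for one column: (n + a) / sum."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    post = counts + prior.alpha
    return post / post.sum()


def _posterior_matrix(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    post = counts + alpha
    return post / post.sum(axis=1, keepdims=True)


def _re_rows(p: np.ndarray, background: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / background), 0.0)
    return np.maximum(terms.sum(axis=1), 0.0)


def _scaled_counts(counts: np.ndarray, scale: float, mode: str) -> np.ndarray:
    if mode == "exponential":
        k = counts.sum(axis=1, keepdims=True)
        factor = np.where(k > 0, k ** (scale - 1.0), 0.0)
        return counts * factor
    if mode == "uniform":
        return counts * scale
    raise ValueError(f"unknown weighting mode {mode!r}")


def average_relative_entropy(
    counts, prior: PriorModel, background, scale: float = 1.0,
    mode: str = "exponential",
) -> float:
    """Mean per-column relative entropy of the posterior model, in bits."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    background = np.asarray(background, dtype=float)
    p = _posterior_matrix(_scaled_counts(counts, scale, mode), prior.alpha)
    return float(_re_rows(p, background).mean())


def _fit_scale(counts, prior, background, target_re, mode,
               tol=RE_TOL, max_iter=100) -> float:
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[0] < 1:
        raise ValueError("need at least one column")

    def f(s: float) -> float:
        return average_relative_entropy(counts, prior, background, s, mode)

    if f(1.0) <= target_re:
        return 1.0
    lo, hi = 0.0, 1.0
    if f(lo) >= target_re:
        warnings.warn(
            f"target {target_re} bits below the relative entropy achievable "
            f"with zero observation weight; returning scale 0"
        )
        return 0.0
    # bisect well past the RE tolerance so the fitted scale itself is
    # resolved to ~1e-12, not just the achieved average RE
    mid = 0.5
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > target_re:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-12:
            break
    mid = 0.5 * (lo + hi)
    if abs(f(mid) - target_re) > tol:
        warnings.warn(
            f"bisection met the target only to {abs(f(mid) - target_re):.2e} "
            f"bits (tolerance {tol})"
        )
    return mid


def fit_exponential_scale(column_counts, prior: PriorModel, background,
                          target_re: float = DEFAULT_TARGET_RE) -> float:
    """Exponent s in [0,1] such that scaling each column total k to k**s
    brings the model's average relative entropy to the target.

    Per-letter counts within a column are scaled proportionally so the
    column total equals k**s; a column with k=1 is unchanged for every s.
    Returns 1 when the unweighted model is already at or below the target.
    """
    return _fit_scale(column_counts, prior, background, target_re, "exponential")


def fit_uniform_scale(column_counts, prior: PriorModel, background,
                      target_re: float = DEFAULT_TARGET_RE) -> float:
    """Single multiplier m in (0,1] applied to every column's counts so the
    average relative entropy reaches the target (HMMER's classic scheme)."""
    return _fit_scale(column_counts, prior, background, target_re, "uniform")


@dataclass
class ProfileModel:
    """Per-position emission model of a repeat family.

    ``log_odds`` is in bits against ``background``; ``per_position_re`` is
    the relative entropy of each match position; ``scale`` is the fitted
    entropy-weighting parameter (exponent s for exponential weighting,
    multiplier for uniform). ``thresholds`` maps a taxon tag to its GA
    (gathering) and TC (trusted cutoff) bit-score thresholds.
    """

    family_id: str
    emissions: np.ndarray
    background: np.ndarray
    target_re: float
    weighting: str
    scale: float
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != 4:
            raise ValueError("emissions must be (L, 4)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.emissions.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.emissions / self.background)

    @property
    def per_position_re(self) -> np.ndarray:
        return _re_rows(self.emissions, self.background)

    @property
    def avg_re(self) -> float:
        return float(self.per_position_re.mean())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.emissions.argmax(axis=1))

    def max_score(self) -> float:
        """Score of the gap-free maximum-scoring path over all positions."""
        return float(self.log_odds.max(axis=1).sum())


def seed_counts(seed: SeedAlignment) -> np.ndarray:
    """Observed A,C,G,T counts per match column of a seed alignment.

    Insert columns are excluded; ambiguous characters are ignored.
    """
    cols = seed.match_columns()
    rows = np.array([encode_sequence(m) for m in seed.members], dtype=np.int8)
    match = rows[:, cols] if rows.size else np.zeros((0, len(cols)), np.int8)
    counts = np.zeros((len(cols), 4), dtype=float)
    for x in range(4):
        counts[:, x] = (match == x).sum(axis=0)
    return counts


def build_profile(
    seed: SeedAlignment,
    target_re: float = DEFAULT_TARGET_RE,
    weighting: str = "exponential",
    background=None,
    prior: PriorModel | None = None,
) -> ProfileModel:
    """Build an entropy-weighted profile from a seed alignment.

    The fitted model's average relative entropy equals
    min(target_re, unweighted average) to within the bisection tolerance.
    Match columns with no observed residues are dropped with a warning.
    """
    if seed.n_members == 0:
        raise ValueError("empty seed alignment")
    prior = prior or PriorModel()
    background = (np.full(4, 0.25) if background is None
                  else np.asarray(background, dtype=float))

    counts = seed_counts(seed)
    keep = counts.sum(axis=1) > 0
    if not np.all(keep):
        warnings.warn(
            f"{(~keep).sum()} all-gap match column(s) dropped from "
            f"{seed.family_id}"
        )
        counts = counts[keep]
    if counts.shape[0] == 0:
        raise ValueError("no informative match columns in seed")

    if weighting == "none":
        scale = 1.0
        scaled = counts
    elif weighting == "exponential":
        scale = fit_exponential_scale(counts, prior, background, target_re)
        scaled = _scaled_counts(counts, scale, "exponential")
    elif weighting == "uniform":
        scale = fit_uniform_scale(counts, prior, background, target_re)
        scaled = _scaled_counts(counts, scale, "uniform")
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    emissions = _posterior_matrix(scaled, prior.alpha)
    return ProfileModel(
        family_id=seed.family_id,
        emissions=emissions,
        background=background,
        target_re=target_re,
        weighting=weighting,
        scale=scale,
    )


def _extract_hits(ends, starts, min_score, model_id, target_id, strand,
                  seq_len, evalue_model=None, search_space=None):
    order = np.flatnonzero(ends >= min_score)
    if order.size == 0:
        return []
    # strongest first; ties resolved by left-most end for determinism
    order = order[np.lexsort((order, -ends[order]))]
    occupied = np.zeros(seq_len, dtype=bool)
    hits = []
    for j in order:
        a, b = int(starts[j]), int(j) + 1  # 1-based inclusive envelope
        if occupied[a - 1 : b].any():
            continue
        occupied[a - 1 : b] = True
        if strand == "-":
            a, b = seq_len - b + 1, seq_len - a + 1
        score = float(ends[j])
        ev = (evalue_model.evalue(score, search_space)
              if evalue_model is not None else float("nan"))
        hits.append(Hit(model_id=model_id, target_id=target_id,
                        ali_from=a, ali_to=b, strand=strand,
                        score=score, evalue=ev))
    return hits


def search(
    profile: ProfileModel,
    sequence: str,
    target_id: str = "seq",
    min_score: float = 10.0,
    strand_both: bool = True,
    evalue_model: "EValueModel | None" = None,
    search_space: float | None = None,
) -> list[Hit]:
    """Local search of a profile against a nucleotide sequence.

    Dynamic programming over position-specific log-odds with affine gap
    costs (``profile.gap_open`` / ``profile.gap_extend`` bits), on both
    strands by default. Returns non-overlapping (per strand) hits with
    score >= ``min_score``, sorted by start coordinate; deterministic for
    fixed inputs. Sequences shorter than 10 bases yield no hits.
    """
    from ._kernels import local_align_ends

    if len(sequence) < 10:
        return []
    lo = np.ascontiguousarray(profile.log_odds)
    hits = []
    strands = ["+", "-"] if strand_both else ["+"]
    for strand in strands:
        seq = sequence if strand == "+" else revcomp(sequence)
        ends, starts = local_align_ends(
            lo, encode_sequence(seq), profile.gap_open, profile.gap_extend
        )
        hits.extend(
            _extract_hits(ends, starts, min_score, profile.family_id,
                          target_id, strand, len(sequence),
                          evalue_model, search_space)
        )
    hits.sort(key=lambda h: (h.ali_from, h.ali_to, h.strand))
    return hits


@dataclass
class EValueModel:
    """Gumbel right-tail model of null (background) bit scores.

    E(s) = P(S >= s) * (search_space / null_space): the tail probability
    under the fitted Gumbel, rescaled from the calibration search space to
    the query search space.
    """

    loc: float
    scale: float
    n_null: int
    null_space: float

    def evalue(self, score: float, search_space: float | None = None) -> float:
        space = self.null_space if search_space is None else search_space
        sf = stats.gumbel_r.sf(score, loc=self.loc, scale=self.scale)
        return float(sf * space / self.null_space)

    def score_at_evalue(self, evalue: float,
                        search_space: float | None = None) -> float:
        space = self.null_space if search_space is None else search_space
        p = min(max(evalue * self.null_space / space, 1e-300), 1.0 - 1e-12)
        return float(stats.gumbel_r.isf(p, loc=self.loc, scale=self.scale))


def fit_evalue_model(
    null_scores,
    null_space: float = 1.0,
    tail_fraction: float = 0.5,
) -> EValueModel:
    """Fit a Gumbel right tail to background search scores.

    Maximum likelihood on the top ``tail_fraction`` of scores, with the
    remainder entering the likelihood as left-censored at the cutoff so
    the fit is driven by the tail the E-values come from. Requires at
    least 100 scores and a non-degenerate distribution.
    """
    scores = np.asarray(null_scores, dtype=float)
    if scores.size < 100:
        raise ValueError(f"need >= 100 null scores, got {scores.size}")
    if np.std(scores) < 1e-9:
        raise ValueError("degenerate null score distribution")
    cutoff = float(np.quantile(scores, 1.0 - tail_fraction))
    upper = scores[scores >= cutoff]
    n_below = int((scores < cutoff).sum())
    if n_below:
        data = stats.CensoredData(uncensored=upper,
                                  left=np.full(n_below, cutoff))
    else:
        data = upper
    loc, scale = stats.gumbel_r.fit(data)
    return EValueModel(loc=float(loc), scale=float(scale),
                       n_null=int(scores.size), null_space=float(null_space))


def estimate_evalue(profile: ProfileModel, null_scores, score: float,
                    search_space: float, null_space: float = 1.0) -> float:
    """E-value of ``score`` given background scores from ``null_space`` bp."""
    model = fit_evalue_model(null_scores, null_space=null_space)
    return model.evalue(score, search_space)
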