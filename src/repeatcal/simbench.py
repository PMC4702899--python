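"""Composition-aware synthetic benchmark genomes with planted repeats.

False-positive and overextension rates for repeat-family models have to be
measured on sequence that contains no real repeats but looks like a
genome. This module trains a background model that captures large-scale
GC heterogeneity (isochores) and short-range k-mer structure: a Markov
chain over GC-content bins (default 6) emitting letters conditioned on
the previous ``context_len`` letters (default 3) with per-bin context
tables. On top of a simulated background it writes synthetically diverged
simple repeats at per-bin rates, and plants truncated, mutated fragments
of repeat-family consensi at GC-matched positions, recording exact truth
intervals for benchmarking.

Simple repeats and TE fragments are written over the background in place
(replacement rather than insertion) so truth coordinates never shift.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .profilecore import ALPHABET, ProfileModel, encode_sequence, revcomp
from .seedforge import SeedAlignment

__all__ = [
    "BackgroundModel",
    "TruthInterval",
    "SyntheticBenchmark",
    "SimpleRepeatMotif",
    "train_background",
    "simulate_background",
    "insert_simple_repeats",
    "plant_te_fragments",
    "mutate_sequence",
    "simulate_seed_alignment",
]

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _LETTERS[codes.astype(np.intp)].tobytes().decode("ascii")


@dataclass
class BackgroundModel:
    """GC-bin Markov chain with fixed-order context emission tables.

    ``bin_bounds`` are the GC-fraction breakpoints between the ``n_bins``
    bins; ``transitions[b1, b2]`` is the per-window-step probability of
    moving from bin b1 to bin b2; ``emissions[b, c]`` is the distribution
    of the next letter in bin b given integer-encoded context c (base-4
    encoding of the previous ``context_len`` letters).
    """

    n_bins: int
    bin_bounds: np.ndarray
    transitions: np.ndarray
    context_len: int
    emissions: np.ndarray
    window: int

    def __post_init__(self) -> None:
        self.bin_bounds = np.asarray(self.bin_bounds, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.transitions.shape != (self.n_bins, self.n_bins):
            raise ValueError("transition matrix shape mismatch")
        if self.emissions.shape != (self.n_bins, 4 ** self.context_len, 4):
            raise ValueError("emission table shape mismatch")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.emissions.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")

    def assign_bin(self, gc: float) -> int:
        return int(np.searchsorted(self.bin_bounds, gc, side="right"))

    def to_json(self, path) -> None:
        obj = {
            "n_bins": self.n_bins,
            "bin_bounds": self.bin_bounds.tolist(),
            "transitions": self.transitions.tolist(),
            "context_len": self.context_len,
            "emissions": self.emissions.tolist(),
            "window": self.window,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "BackgroundModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            n_bins=obj["n_bins"],
            bin_bounds=np.array(obj["bin_bounds"]),
            transitions=np.array(obj["transitions"]),
            context_len=obj["context_len"],
            emissions=np.array(obj["emissions"]),
            window=obj["window"],
        )


@dataclass(frozen=True)
class TruthInterval:
    """One planted element: 1-based inclusive genomic interval plus the
    model (consensus) region it was sampled from and its realized
    divergence."""

    kind: str  # te_fragment | simple_repeat
    family_id: str
    start: int
    end: int
    strand: str
    model_from: int
    model_to: int
    divergence: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticBenchmark:
    sequence: str
    truth: list[TruthInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for t in self.truth:
            if not (1 <= t.start <= t.end <= n):
                raise ValueError(f"truth interval {t} outside sequence bounds")
        te = sorted((t.start, t.end) for t in self.truth
                    if t.kind == "te_fragment")
        for (a1, b1), (a2, b2) in zip(te, te[1:]):
            if a2 <= b1:
                raise ValueError("te_fragment truth intervals overlap")


@dataclass
class SimpleRepeatMotif:
    """A tandem-repeat motif with per-GC-bin insertion rates.

    ``rates`` are expected insertions per Mb in each GC bin;
    ``mean_copies`` is the mean tandem copy number of an expansion."""

    motif: str
    rates: np.ndarray
    mean_copies: float = 20.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)


def _window_gc(codes: np.ndarray, window: int):
    """Per-window GC fraction and informative flag over non-overlapping
    windows; windows that are mostly N are flagged uninformative."""
    n_win = len(codes) // window
    gcs = np.empty(n_win)
    ok = np.empty(n_win, dtype=bool)
    for w in range(n_win):
        chunk = codes[w * window : (w + 1) * window]
        inf = chunk < 4
        n_inf = int(inf.sum())
        ok[w] = n_inf >= window // 2
        gc = ((chunk == 1) | (chunk == 2)).sum()
        gcs[w] = gc / n_inf if n_inf else 0.5
    return gcs, ok


def train_background(
    sequences,
    n_bins: int = 6,
    context_len: int = 3,
    window: int = 1000,
) -> BackgroundModel:
    """Train the GC-bin background model from genomic sequence.

    ``sequences`` is a string, a list of strings, or a mapping of id to
    string. Windows are assigned to bins by GC quantiles (equal
    occupancy); emission tables get +1 smoothing; bin transitions are
    counted between consecutive windows of each sequence.
    """
    if isinstance(sequences, str):
        seqs = [sequences]
    elif isinstance(sequences, dict):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    seqs = [s.upper() for s in seqs]
    if sum(len(s) for s in seqs) < window:
        raise ValueError("training sequence shorter than one window")

    coded = [encode_sequence(s) for s in seqs]
    all_gc, per_seq_bins = [], []
    for codes in coded:
        gcs, ok = _window_gc(codes, window)
        all_gc.append(gcs[ok])
        per_seq_bins.append((gcs, ok))
    gc_pool = np.concatenate(all_gc)
    if gc_pool.size == 0:
        raise ValueError("no informative windows in training sequence")
    bounds = np.quantile(gc_pool, np.arange(1, n_bins) / n_bins)

    n_ctx = 4 ** context_len
    mask = n_ctx - 1
    emit = np.ones((n_bins, n_ctx, 4))  # +1 smoothing
    trans = np.ones((n_bins, n_bins))
    for codes, (gcs, ok) in zip(coded, per_seq_bins):
        bins = np.searchsorted(bounds, gcs, side="right")
        prev_bin = -1
        for w in range(len(gcs)):
            if not ok[w]:
                prev_bin = -1
                continue
            b = int(bins[w])
            if prev_bin >= 0:
                trans[prev_bin, b] += 1
            prev_bin = b
            chunk = codes[w * window : (w + 1) * window]
            ctx, valid = 0, 0
            for x in chunk:
                if x == 4:
                    valid = 0
                    ctx = 0
                    continue
                if valid >= context_len:
                    emit[b, ctx, x] += 1
                ctx = ((ctx << 2) | int(x)) & mask
                valid += 1
    trans /= trans.sum(axis=1, keepdims=True)
    emit /= emit.sum(axis=2, keepdims=True)
    return BackgroundModel(
        n_bins=n_bins, bin_bounds=bounds, transitions=trans,
        context_len=context_len, emissions=emit, window=window,
    )


def simulate_background(model: BackgroundModel, length: int,
                        rng_seed: int = 0) -> str:
    """Simulate ``length`` bp of background: per-window bin states from the
    bin chain, letters from the bin's context table. Deterministic given
    the seed."""
    from ._kernels import emit_markov

    rng = np.random.default_rng(rng_seed)
    n_win = int(np.ceil(length / model.window))
    # stationary start so composition is unbiased from the first window
    evals, evecs = np.linalg.eig(model.transitions.T)
    i0 = int(np.argmin(np.abs(evals - 1.0)))
    stat = np.abs(np.real(evecs[:, i0]))
    stat /= stat.sum()
    states = np.empty(n_win, dtype=np.int64)
    states[0] = rng.choice(model.n_bins, p=stat)
    for w in range(1, n_win):
        states[w] = rng.choice(model.n_bins, p=model.transitions[states[w - 1]])
    bin_per_pos = np.repeat(states, model.window)[:length]

    cdf = np.cumsum(model.emissions, axis=2)
    cdf[:, :, -1] = 1.0
    init_ctx = 0
    for _ in range(model.context_len):
        init_ctx = (init_ctx << 2) | int(rng.integers(4))
    codes = emit_markov(bin_per_pos, cdf, model.context_len,
                        init_ctx, rng.random(length))
    return _decode(codes)


_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def mutate_sequence(
    seq: str,
    sub_rate: float,
    rng: np.random.Generator,
    ti_tv: float = 2.0,
    indel_frac: float = 0.1,
    indel_mean: float = 2.0,
) -> tuple[str, float]:
    """Mutate a sequence with substitutions and indels.

    Substitutions occur per base at ``sub_rate`` with a transition:
    transversion ratio of ``ti_tv``; indel events occur at
    ``indel_frac * sub_rate`` per base with geometric lengths of mean
    ``indel_mean``. Returns the mutated sequence and the realized
    divergence (mismatched + indel columns over alignment columns).
    """
    codes = list(encode_sequence(seq))
    n = len(codes)
    n_events = 0
    out: list[int] = []
    p_ti = ti_tv / (ti_tv + 1.0)
    ins_total = 0
    i = 0
    while i < n:
        x = codes[i]
        if rng.random() < sub_rate * indel_frac:
            ell = min(int(rng.geometric(1.0 / indel_mean)), max(1, n // 4))
            if rng.random() < 0.5:  # deletion
                n_events += min(ell, n - i)
                i += ell
                continue
            for _ in range(ell):  # insertion
                out.append(int(rng.integers(4)))
            n_events += ell
            ins_total += ell
        if rng.random() < sub_rate and x < 4:
            if rng.random() < p_ti:
                y = _TRANSITION[x]
            else:
                y = _TRANSITION[x]
                while y == x or y == _TRANSITION[x]:
                    y = int(rng.integers(4))
            out.append(y)
            n_events += 1
        else:
            out.append(x)
        i += 1
    div = n_events / max(1, n + ins_total)
    return _decode(np.array(out, dtype=np.int8)), div


def _overlaps(a: int, b: int, intervals: list[tuple[int, int]],
              pad: int = 0) -> bool:
    return any(a - pad <= e and s <= b + pad for s, e in intervals)


def insert_simple_repeats(
    sequence: str,
    catalog: list[SimpleRepeatMotif],
    model: BackgroundModel,
    divergence: float = 0.1,
    rng_seed: int = 0,
    avoid: list[tuple[int, int]] | None = None,
) -> tuple[str, list[TruthInterval]]:
    """Write diverged tandem expansions of catalog motifs over the sequence.

    Each genomic window's GC bin (from ``model``) sets the Poisson rate of
    insertions of each motif there; expansions are mutated to the given
    divergence. Empty catalog is a no-op."""
    if not catalog:
        return sequence, []
    rng = np.random.default_rng(rng_seed)
    seq = list(sequence)
    window = model.window
    gcs, ok = _window_gc(encode_sequence(sequence), window)
    bins = np.searchsorted(model.bin_bounds, gcs, side="right")
    occupied = list(avoid or [])
    truth: list[TruthInterval] = []
    for motif in catalog:
        if len(motif.rates) != model.n_bins:
            raise ValueError("motif rates must have one entry per GC bin")
        for w in range(len(gcs)):
            if not ok[w]:
                continue
            lam = motif.rates[bins[w]] * window / 1e6
            for _ in range(rng.poisson(lam)):
                copies = max(3, int(rng.geometric(1.0 / motif.mean_copies)))
                unit = motif.motif.upper()
                expanded, div = mutate_sequence(unit * copies, divergence, rng,
                                                indel_frac=0.0)
                ell = len(expanded)
                if ell >= window:
                    continue
                off = int(rng.integers(window - ell))
                start = w * window + off + 1  # 1-based
                end = start + ell - 1
                if end > len(seq) or _overlaps(start, end, occupied):
                    continue
                seq[start - 1 : end] = expanded
                occupied.append((start, end))
                truth.append(TruthInterval(
                    kind="simple_repeat", family_id=f"({unit})n",
                    start=start, end=end, strand="+",
                    model_from=1, model_to=ell, divergence=div,
                ))
    truth.sort(key=lambda t: t.start)
    return "".join(seq), truth


def _family_consensus(fam) -> str:
    if isinstance(fam, ProfileModel):
        return fam.consensus
    return str(fam).upper()


def plant_te_fragments(
    sequence: str,
    families: dict[str, object],
    n_per_family: int = 50,
    length_dist=None,
    divergence_dist=None,
    gc_preference: dict[str, np.ndarray] | None = None,
    model: BackgroundModel | None = None,
    rng_seed: int = 0,
    existing_truth: list[TruthInterval] | None = None,
    min_gap: int = 20,
) -> SyntheticBenchmark:
    """Plant truncated, mutated TE fragments into a benchmark sequence.

    ``families`` maps family_id to a consensus string or ProfileModel.
    Fragment lengths come from ``length_dist(rng, model_len)`` (default:
    half 5'-truncated with uniform retained fraction 0.2-1.0, half random
    internal windows); per-fragment substitution rates from
    ``divergence_dist(rng)`` (default uniform 0.05-0.25). Placement draws
    a GC bin from ``gc_preference[family]`` (requires ``model``) and a
    random position inside a window of that bin, avoiding existing truth
    intervals; if no position in the preferred bins can be found the
    fragment falls back to uniform placement with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    seq = list(sequence)
    n = len(seq)

    if length_dist is None:
        def length_dist(r, L):
            return max(30, int(L * r.uniform(0.2, 1.0)))
    if divergence_dist is None:
        def divergence_dist(r):
            return r.uniform(0.05, 0.25)

    window_bins = None
    if model is not None:
        gcs, ok = _window_gc(encode_sequence(sequence), model.window)
        bins = np.searchsorted(model.bin_bounds, gcs, side="right")
        window_bins = [
            np.flatnonzero(ok & (bins == b)) for b in range(model.n_bins)
        ]

    occupied = [(t.start, t.end) for t in (existing_truth or [])]
    truth = list(existing_truth or [])

    for fam_id in sorted(families):
        cons = _family_consensus(families[fam_id])
        L = len(cons)
        pref = None
        if gc_preference is not None and fam_id in gc_preference:
            if model is None:
                raise ValueError("gc_preference requires a background model")
            pref = np.asarray(gc_preference[fam_id], dtype=float)
            pref = pref / pref.sum()
        for _ in range(n_per_family):
            frag_len = min(length_dist(rng, L), L)
            if rng.random() < 0.5:
                m_from = L - frag_len + 1  # 5' truncation keeps the 3' end
            else:
                m_from = int(rng.integers(L - frag_len + 1)) + 1
            m_to = m_from + frag_len - 1
            frag = cons[m_from - 1 : m_to]
            sub_rate = divergence_dist(rng)
            mutated, div = mutate_sequence(frag, sub_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed_seq = mutated if strand == "+" else revcomp(mutated)
            ell = len(placed_seq)
            if ell >= n:
                continue

            start = None
            if pref is not None:
                for _try in range(200):
                    b = int(rng.choice(model.n_bins, p=pref))
                    wins = window_bins[b]
                    if wins.size == 0:
                        continue
                    w = int(wins[rng.integers(wins.size)])
                    off = int(rng.integers(model.window))
                    s = w * model.window + off + 1
                    e = s + ell - 1
                    if e <= n and not _overlaps(s, e, occupied, min_gap):
                        start = s
                        break
                if start is None:
                    warnings.warn(
                        f"{fam_id}: GC preference unsatisfiable; "
                        "falling back to uniform placement"
                    )
            if start is None:
                for _try in range(500):
                    s = int(rng.integers(n - ell)) + 1
                    e = s + ell - 1
                    if not _overlaps(s, e, occupied, min_gap):
                        start = s
                        break
            if start is None:
                warnings.warn(f"{fam_id}: no room left for fragment; skipped")
                continue
            end = start + ell - 1
            seq[start - 1 : end] = placed_seq
            occupied.append((start, end))
            truth.append(TruthInterval(
                kind="te_fragment", family_id=fam_id, start=start, end=end,
                strand=strand, model_from=m_from, model_to=m_to,
                divergence=div,
            ))

    truth.sort(key=lambda t: (t.start, t.end))
    return SyntheticBenchmark(sequence="".join(seq), truth=truth)


def simulate_seed_alignment(
    length: int = 300,
    depth: int = 100,
    identity: float = 0.85,
    family_id: str = "SYNFAM",
    fragmented: bool = False,
    rng_seed: int = 0,
) -> SeedAlignment:
    """Generate a synthetic seed alignment around a random consensus.

    Members are independent copies at the given identity to the consensus
    (substitutions only, so the alignment is gap-free and every column is
    a match column). With ``fragmented=True``, members cover random
    consensus windows instead of the full length, mimicking the ragged
    coverage of 5'-truncated element families.
    """
    rng = np.random.default_rng(rng_seed)
    cons_codes = rng.integers(4, size=length)
    consensus = _decode(cons_codes.astype(np.int8))
    members, ids = [], []
    counts = np.zeros(length, dtype=int)
    for m in range(depth):
        codes = cons_codes.copy()
        muts = rng.random(length) >= identity
        codes[muts] = (codes[muts] + rng.integers(1, 4, size=int(muts.sum()))) % 4
        row = _decode(codes.astype(np.int8))
        if fragmented:
            span = max(30, int(length * rng.uniform(0.2, 1.0)))
            s = int(rng.integers(length - span + 1))
            row = "-" * s + row[s : s + span] + "-" * (length - s - span)
            counts[s : s + span] += 1
        else:
            counts += 1
        members.append(row)
        ids.append(f"{family_id}_{m}")
    return SeedAlignment(
        family_id=family_id, consensus=consensus, members=members,
        member_ids=ids, rf="x" * length, column_counts=counts,
    )
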