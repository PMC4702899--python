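import numpy as np
import pytest

from repeatcal import (
    InstanceAlignment,
    simulate_seed_alignment,
    train_background,
)

BASES = "ACGT"


def make_instance(
    instance_id,
    aligned_instance,
    aligned_consensus,
    source="chr1",
    start=1001,
    strand="+",
    divergence=None,
    coverage=None,
    organism="",
):
    """Build an InstanceAlignment, deriving bookkeeping fields."""
    n_res = sum(c not in "-." for c in aligned_instance)
    cols = len(aligned_instance)
    if divergence is None:
        mm = sum(
            1
            for a, b in zip(aligned_instance, aligned_consensus)
            if a in "-." or b in "-." or a.upper() != b.upper()
        )
        divergence = mm / cols
    if coverage is None:
        coverage = 1.0
    return InstanceAlignment(
        instance_id=instance_id,
        source_sequence_id=source,
        start=start,
        end=start + n_res - 1,
        strand=strand,
        aligned_instance=aligned_instance,
        aligned_consensus=aligned_consensus,
        divergence=divergence,
        consensus_coverage=coverage,
        organism=organism,
    )


def random_instance(rng, consensus, instance_id, p_mm=0.08, p_del=0.05, p_ins=0.05):
    """Random instance-vs-consensus alignment over a random window."""
    L = len(consensus)
    a = int(rng.integers(0, max(1, L - 12)))
    b = int(rng.integers(a + 8, min(L, a + 40) + 1))
    ai, ac = [], []
    for ch in consensus[a:b]:
        r = rng.random()
        if r < p_ins:
            ac.append("-")
            ai.append(BASES[rng.integers(4)])
        if rng.random() < p_del:
            ac.append(ch)
            ai.append("-")
        elif rng.random() < p_mm:
            ac.append(ch)
            ai.append(BASES[(BASES.index(ch) + 1 + rng.integers(3)) % 4])
        else:
            ac.append(ch)
            ai.append(ch)
    if not any(c not in "-." for c in ai):
        ai[-1] = consensus[b - 1]
        ac[-1] = consensus[b - 1]
    ai, ac = "".join(ai), "".join(ac)
    return make_instance(
        instance_id, ai, ac, start=int(rng.integers(300, 5000)),
        coverage=(b - a) / L,
    )


def random_sequence(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.random.default_rng(rng).choice(list(BASES), p=p, size=length))


@pytest.fixture(scope="session")
def deep_seed():
    """300 columns x 100 members at 85% identity; the canonical deep seed."""
    return simulate_seed_alignment(length=300, depth=100, identity=0.85,
                                   rng_seed=11)


@pytest.fixture(scope="session")
def fragmented_seed():
    return simulate_seed_alignment(length=400, depth=120, identity=0.85,
                                   fragmented=True, rng_seed=12)


@pytest.fixture(scope="session")
def two_composition_genome():
    """Synthetic training genome with a 30% GC half and a 70% GC half."""
    rng = np.random.default_rng(21)
    low = random_sequence(rng.integers(2**31), 150_000, gc=0.30)
    high = random_sequence(rng.integers(2**31), 150_000, gc=0.70)
    return low + high


@pytest.fixture(scope="session")
def gradient_genome():
    """400 kb with a linear GC ramp 0.2 -> 0.8 across 1 kb windows,
    giving six GC bins with well-separated emission tables."""
    rng = np.random.default_rng(21)
    n_win, w = 400, 1000
    parts = []
    for i in range(n_win):
        gc = 0.2 + 0.6 * i / (n_win - 1)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        parts.append("".join(rng.choice(list(BASES), p=p, size=w)))
    return "".join(parts)


@pytest.fixture(scope="session")
def background_model(gradient_genome):
    return train_background(gradient_genome)
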