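"""Simulate a composition-faithful benchmark genome with planted repeats.

Trains the GC-bin background model on a synthetic genome with a GC
gradient, simulates fresh background, writes in diverged simple-repeat
expansions at per-bin rates, and plants truncated/mutated TE fragments
with an AT-preferring placement bias. Prints the truth bookkeeping.
"""

import numpy as np

from repeatcal import (
    SimpleRepeatMotif,
    insert_simple_repeats,
    plant_te_fragments,
    simulate_background,
    simulate_seed_alignment,
    train_background,
)

rng = np.random.default_rng(3)
parts = []
for i in range(300):
    gc = 0.25 + 0.5 * i / 299
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    parts.append("".join(rng.choice(list("ACGT"), p=p, size=1000)))
training_genome = "".join(parts)

model = train_background(training_genome)
print(f"background model: {model.n_bins} GC bins, "
      f"bounds {np.round(model.bin_bounds, 3)}")

seq = simulate_background(model, 200_000, rng_seed=11)
gc = (seq.count("G") + seq.count("C")) / len(seq)
print(f"simulated {len(seq)} bp, GC={gc:.3f}")

# simple repeats: (AT)n concentrated in the lowest-GC bins
at_rates = np.array([300.0, 150.0, 50.0, 10.0, 0.0, 0.0])  # per Mb per bin
seq, sr_truth = insert_simple_repeats(
    seq, [SimpleRepeatMotif("AT", rates=at_rates, mean_copies=15)],
    model, divergence=0.1, rng_seed=12)
print(f"inserted {len(sr_truth)} (AT)n expansions, "
      f"total {sum(t.length for t in sr_truth)} bp")

family = simulate_seed_alignment(length=400, depth=80, identity=0.85,
                                 rng_seed=13)
pref = np.array([0.5, 0.3, 0.15, 0.05, 0.0, 0.0])  # AT-preferring family
bench = plant_te_fragments(
    seq, {family.family_id: family.consensus}, n_per_family=40,
    gc_preference={family.family_id: pref}, model=model, rng_seed=14,
    existing_truth=sr_truth)

te = [t for t in bench.truth if t.kind == "te_fragment"]
lens = [t.length for t in te]
print(f"planted {len(te)} TE fragments: length "
      f"min={min(lens)} median={int(np.median(lens))} max={max(lens)}, "
      f"mean divergence {np.mean([t.divergence for t in te]):.3f}")
print("first three truth records:")
for t in bench.truth[:3]:
    print(f"  {t.kind:>13} {t.family_id} {t.start}-{t.end} ({t.strand}) "
          f"model {t.model_from}-{t.model_to} div {t.divergence:.3f}")
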