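"""Simulate a misassembled genome with a matched Hi-C contact map.

Cuts two random contigs into 10-50 kb pieces, displaces or flips a few of
them, and synthesises a multi-resolution distance-decay contact store whose
bin permutation carries the corresponding error signatures.
"""

import hic_curator as hc

contigs, clean_doc = hc.make_genome(n_contigs=2, length_range=(400_000, 500_000), seed=1)
shuffled, truth = hc.fragment_and_shuffle(clean_doc, seed=2, n_events=3)
store = hc.synth_contact_map(truth, [5000, 10000, 25000, 50000], hc.ContactModel(noise="poisson", seed=3))

print(f"genome: {clean_doc.total_length:,} bp in {len(contigs)} contigs, "
      f"cut into {len(shuffled.fragments)} pieces")
print("planted events (final assembly coordinates):")
for ev in truth.events:
    tail = f", belongs at {ev.insertion:,}" if ev.insertion is not None else ""
    print(f"  {ev.category:13s} [{ev.start:>9,}, {ev.end:>9,}){tail}")

mat = store.matrix(10_000)
print(f"contact matrix at 10 kb: {mat.shape[0]}x{mat.shape[1]} bins, "
      f"max {mat.max():.0f}, 95th percentile {hc.quantile_threshold(mat, 0.95):.2f}")
print("The events above are what the detector must find back from the map alone.")
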