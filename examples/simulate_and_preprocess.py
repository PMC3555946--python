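"""Simulate a small RNA library and strip 3' adaptors.

Builds the three-tier reference, simulates one sequencing library dominated
by ~22 nt mature miRNA inserts (with adaptor read-through, adaptor dimers
and N-rich reads), clips the 3' adaptor and filters unusable reads.
"""

import isletmir as im

cfg = im.SimulationConfig(seed=1, n_hairpins=10, reads_per_library=5000,
                          n_libraries=1)
ref = im.make_reference(cfg)
libs = im.simulate_reads(ref, {hp.id: 1.0 for hp in ref.hairpins}, cfg)
reads = libs["lib1"]

clean = im.preprocess_reads(reads, cfg.adaptor_sequence)
hist = clean.length_histogram()
mode = max(hist, key=hist.get)

print(f"input reads:        {clean.n_input}")
print(f"adaptor-clipped:    {clean.n_clipped}")
print(f"removed (<16 nt):   {clean.n_removed_short}")
print(f"removed (N-rich):   {clean.n_removed_n}")
print(f"retained:           {len(clean.reads)}")
print(f"length mode:        {mode} nt "
      f"({hist[mode]} reads)")
print()
print("The retained-length mode near 22 nt is the signature of a mature-"
      "miRNA-dominated library; the short-read removals are mostly clipped "
      "adaptor dimers.")
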