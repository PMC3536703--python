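"""Find the planted splicing-factor motif and map its position.

Plants TGCATG (the Rbfox binding element in DNA space) 70-90 nt into the
downstream intron of half of 300 "test" exons, scans all 4096 6-mers for
containment enrichment against 800 background exons, and builds the
positional RNA map with a resampled 95% background band.
"""

import numpy as np

from sepmap import (
    SimulationConfig,
    attach_envelope,
    build_rna_map,
    detect_enriched_windows,
    gen_exon_sequences,
    word_enrichment,
)

cfg = SimulationConfig(plant_prob=0.5, plant_window=(70, 90), seed=3)
records, truth = gen_exon_sequences(cfg, {"test": 300, "background": 800})
test = [r for r in records if r.class_label == "test"]
background = [r for r in records if r.class_label == "background"]

words = word_enrichment(test, background)  # all 4096 6-mers, 150-nt window
print("top five 6-mers by Fisher p:")
print(words.head()[["word", "n_test_with", "n_bg_with", "odds_ratio", "p"]]
      .to_string(index=False))

rna_map = build_rna_map(test, "TGCATG")  # 50-nt windows, 5-nt steps, 150 nt
rna_map = attach_envelope(rna_map, background, sample_size=len(test),
                          rng=np.random.default_rng(3))
runs = detect_enriched_windows(rna_map)
for r in runs:
    print(f"enriched windows spanning {r.interval[0]}-{r.interval[1]} nt "
          f"downstream of the 5' splice site; peak window starts at "
          f"{r.peak_window_start} nt (freq {r.peak_freq:.2f})")
# The planted word tops the ranking and the enriched run covers the
# 70-90 nt planting region, the positional signature of an intronic
# splicing enhancer downstream of the regulated exon.
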