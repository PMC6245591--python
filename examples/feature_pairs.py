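"""Which side-effect pairs drive interactions?  Theta's large entries.

After fitting with the adjacency scaled x1000, entries of Theta with
|theta| > 1 are 'significant': positive ones push drug pairs toward
enhancive interactions, negative ones toward degressive.

Run:  python examples/feature_pairs.py
"""

from tmfuf import (
    SynthConfig,
    fit_tmfuf,
    generate,
    significant_pairs,
    summarize_theta,
)

ds = generate(SynthConfig(seed=7))
model = fit_tmfuf(ds.A, ds.F, r="auto", L=10, scale_factor=1000.0)

summ = summarize_theta(model, bins=40, threshold=1.0)
print(f"Theta has {summ.n_entries} upper-triangle entries; "
      f"{summ.n_significant_positive} significant positive, "
      f"{summ.n_significant_negative} significant negative (|theta| > 1)")
peak = summ.histogram_counts.argmax()
print(f"histogram peak: {summ.histogram_counts[peak]} entries in "
      f"[{summ.histogram_edges[peak]:.2f}, {summ.histogram_edges[peak + 1]:.2f}] "
      f"-- most of Theta sits near zero")

pairs = significant_pairs(model, threshold=1.0, top_k=5)
for direction in ("enhancive", "degressive"):
    print(f"\ntop {direction} feature pairs (by |theta|):")
    for fp in pairs[direction]:
        print(f"  {fp.rank}. ({fp.feature_a}, {fp.feature_b})  theta={fp.theta:+.2f}")

# each listed pair of side effects co-occurring across two drugs is evidence
# for (theta > 0) or against (theta < 0) an enhancive interaction forming.
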