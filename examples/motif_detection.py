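"""Full motif detection on a synthetic sparse regulatory-style network.

Run: python examples/motif_detection.py
"""

from motifquad import FixtureSpec, RunConfig, SwapConfig, generate, run

g = generate(FixtureSpec(kind="powerlaw_directed", n=300, mean_degree=2.5,
                         seed=1))
result = run(RunConfig(graph=g, k=3, n_random=100,
                       swap=SwapConfig(swaps_per_edge=3, seed=1)))

print(result.summary.format())
print("\ntop connected 3-vertex classes by z-score:")
print("class  C      mean      sd        z")
for row in result.report.rows[:5]:
    z = "NA" if row.z is None else f"{row.z:+.2f}"
    print(f"{row.class_id:<6d} {row.original_count:<6d} "
          f"{row.random_mean:<9.2f} {row.random_sd:<9.2f} {z}")
# C is the count in the original network; mean/sd summarize the same
# class across 100 degree-preserving rewirings.  Positive z marks
# patterns over-represented relative to the degree-matched null model.
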