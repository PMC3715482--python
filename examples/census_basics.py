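"""Census a few analytic graphs and compare with closed-form answers.

Run: python examples/census_basics.py
"""

from motifquad import FixtureSpec, census, generate, known_census

for kind, n, k in [("path", 7, 3), ("cycle", 8, 4),
                   ("star", 6, 3), ("complete", 6, 3)]:
    spec = FixtureSpec(kind=kind, n=n, directed=False)
    g = generate(spec)
    c = census(g, k)
    expected = known_census(spec, k)
    print(f"{kind:9s} n={n} k={k}: {c.total:4d} subgraphs in "
          f"{len(c.counts)} class(es)   closed form: {expected}")

# Each line counts the connected induced k-subgraphs of one graph; for
# these shapes every subgraph is isomorphic, so exactly one class appears
# and the total matches the combinatorial closed form.
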