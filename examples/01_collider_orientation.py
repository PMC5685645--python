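"""Orient a v-structure from observational data.

Two independent causes A and B of a common effect C are the observational
signature of causality: A and B are marginally independent but become
dependent given C, which forces the orientations A -> C <- B.
"""

import numpy as np

from causalmi import DataTable, PipelineConfig, run_pipeline

rng = np.random.default_rng(0)
n = 10000
a = rng.integers(0, 2, n)
b = rng.integers(0, 2, n)
# P(C=1) increases with the number of active causes
p_c = 0.15 + 0.35 * (a + b)
c = (rng.random(n) < p_c).astype(int)

data = DataTable(np.column_stack([a, b, c]), ["A", "B", "C"],
                 [["0", "1"]] * 3)
graph, states, report = run_pipeline(data, PipelineConfig(seed=0))

print(f"retained edges: {report['edges_final']}")
for (u, v) in graph.edges():
    print(f"  {u} [{graph.get_mark(u, v, u)}]--[{graph.get_mark(u, v, v)}] {v}"
          f"  ({graph.category(u, v)})")
print("the A-B pair was removed with separating set:",
      states[("A", "B")].sep_set)
# Both edges carry an arrowhead at C and none at A or B: the data alone
# identify C as the common effect. The circle marks at A and B mean those
# ends stay undetermined (cause or latent confounder).
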