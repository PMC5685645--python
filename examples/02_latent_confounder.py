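"""Detect an unobserved common cause as a bidirected edge.

Data are sampled from X -> Z <- L -> Y <- W and the confounder L is then
dropped, as if it had never been measured.  The two v-structures meeting on
the Z-Y edge put arrowheads at both of its ends: Z <-> Y, meaning neither
variable causes the other — their association is due to something latent.
"""

from causalmi import DataTable, PipelineConfig, run_pipeline
from causalmi.benchmarks import fig_latent_collider_bn
from causalmi.simulation import forward_sample

bn = fig_latent_collider_bn()
data = forward_sample(bn, 50000, seed=1)

# hide the latent variable L
keep = [i for i, c in enumerate(data.columns) if c != "L"]
observed = DataTable(data.values[:, keep], [data.columns[i] for i in keep],
                     [data.levels[i] for i in keep])

graph, _, _ = run_pipeline(observed, PipelineConfig(seed=1))
for (u, v) in graph.edges():
    print(f"{u} [{graph.get_mark(u, v, u)}]--[{graph.get_mark(u, v, v)}] {v}"
          f"  ({graph.category(u, v)})")
# Expected output includes "Y [arrow]--[arrow] Z (bidirected)": the latent
# common cause L is inferred from fully observational data.
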