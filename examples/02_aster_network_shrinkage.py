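"""Contract a network of three aster fragments.

Three motility elements are chained into a closed ring by ball joints at
their outer (minus) filament ends; every kinesin multimer pulling its pair
together shrinks the whole mesh — the artificial-muscle demonstration.
"""

from mtmesh import SimConfig, build_aster_network, contraction_ratio, rg_series, simulate

model = build_aster_network(3, "closed")
print(f"scene: {len(model.filaments)} filaments, {len(model.linkers)} kinesin "
      f"multimers, {len(model.joints)} joints")

traj = simulate(model, SimConfig())
rg = rg_series(traj)
print(f"radius of gyration : {rg[0]:.3f} -> {rg[-1]:.3f} sim units")
print(f"contraction ratio  : {contraction_ratio(traj):.3f}  (< 1 means the "
      "network shrank)")
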