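"""Create a stenosis-to-normal transition series of airway skeletons.

Inserts a 50 %-severity stenosis into the trachea of a synthetic tree,
then dilates it back in steps alpha = 0 %, 20 %, ..., 100 % of the way to
the healthy radii.  The minimum lumen radius grows monotonically with
alpha; alpha = 1 recovers the healthy profile exactly.
"""

import airwaykit as ak

tree = ak.make_bifurcating_tree(ak.TreeSpec(generations=3, seed=1))
stenosed, ann = ak.insert_stenosis(tree, tree.root.id, center_mm=30.0,
                                   length_mm=20.0, severity=0.5)
print(f"stenosis on branch {ann.branch_id}, interval "
      f"[{ann.start_mm:.0f}, {ann.end_mm:.0f}] mm, "
      f"min radius {stenosed.root.radii().min():.2f} mm "
      f"(healthy {tree.root.radii().min():.2f} mm)")

series = ak.generate_transition_series(stenosed, ann)
print("alpha   min lumen radius (mm)")
for alpha, skel in series:
    print(f"{alpha:5.0%}   {skel.root.radii().min():.3f}")
# each of these skeletons can be turned into an STL with
# ak.surface_from_skeleton and meshed for CFD externally
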