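"""Generate a synthetic MAPK mutation panel and group it by dominance.

Draws 40 mutations over H-Ras, Raf-1, B-Raf and Mek with log-normal ddG
values, scores each with three-component SIFs from the reduced cascade,
and summarises which pulse feature each protein's mutations dominantly
perturb.
"""

import sifkit as sk

spec = sk.SyntheticSpec(seed=42, n_mutations=40)
panel = sk.generate_mutation_set(spec)
print(f"{len(panel)} synthetic mutations over "
      f"{panel.protein.nunique()} proteins; "
      f"ddG range {panel.ddg_monomer.min():.2f}-"
      f"{panel.ddg_monomer.max():.2f} kcal/mol")

records = [sk.MutationRecord(protein=r.protein,
                             residue_change=r.residue_change,
                             impact_class=r.impact_class,
                             ddg_monomer=float(r.ddg_monomer))
           for r in panel.itertuples()]
scores = sk.batch_score(records, model_key="mapk_reduced", c_source="model")
groups = sk.sif_trajectory_grouping(scores)
print("\nper-protein dominance of |SIF| components:")
print(groups.round(3).to_string(index=False))
print("\nThe shares show which pulse feature each protein's mutations")
print("perturb most; proteins routed through deactivation channels lean")
print("toward duration, those through Mek/Erk activation toward amplitude.")
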