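"""Two-variant steric-occlusion study on synthetic ensembles.

Builds a matched pair of protein variants — a shared compact core plus, in
variant B, a ten-atom loop sitting 3 Å from the pseudo-RNA centroid — fits
every frame onto the reference complex, computes the per-frame summed
protein–RNA sphere-overlap volume, and compares the two distributions.
"""

import rnaocclusion as ro

spec = ro.VariantPairSpec(seed=42, n_frames=200)
ens_a, ens_b, rna = ro.make_variant_pair(spec)
reference = ro.make_reference_complex(spec)

fit_sel = ro.Selection(chains={"A"}, res_range=(406, 465), atom_names={"CA"})
fitted_a, report_a = ro.fit_ensemble(ens_a, reference, fit_sel)
fitted_b, report_b = ro.fit_ensemble(ens_b, reference, fit_sel)

series_a = ro.ensemble_overlap(fitted_a, reference)
series_b = ro.ensemble_overlap(fitted_b, reference)
shift = ro.compare_distributions(series_a, series_b)

print(f"variant A: mean overlap {series_a.volumes.mean():8.3f} Å³ "
      f"over {len(series_a)} frames")
print(f"variant B: mean overlap {series_b.volumes.mean():8.3f} Å³ "
      f"over {len(series_b)} frames")
print(f"median shift (B − A): {shift.median_diff:+.3f} Å³, "
      f"Mann-Whitney p = {shift.p_value:.3g} → {shift.direction}")
print()
print("A positive shift means the loop-bearing variant intrudes more into")
print("the space the RNA occupies when bound, i.e. its conformers occlude")
print("the binding site more strongly.")
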