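# rnaocclusion

Steric occlusion analysis for RNA-binding proteins: does a protein
variant's conformational ensemble intrude into the space its RNA partner
needs to occupy?

## The problem

Splice isoforms of RNA-editing enzymes such as ADAR2 can differ by a short
loop inserted in the catalytic (deaminase) domain, right next to the RNA
binding site, and show markedly different editing activity. One structural
explanation is *steric occlusion*: conformers of the loop-bearing isoform
spend more time inside the volume the double-stranded RNA substrate would
occupy on binding, hindering its approach. This package quantifies that
idea for any pair of protein variants given (a) conformational ensembles
of each apo protein (multi-model PDB, e.g. MD frames) and (b) a
single-model reference complex containing the bound RNA pose.

## The statistic

For each ensemble frame *f*:

1. Superpose the frame onto the reference complex by a Kabsch
   least-squares fit on a chosen atom selection (protein backbone by
   default): the proper rotation **R** and translation **t** minimising
   the RMSD of the paired atoms.
2. Treat every protein atom *i* and RNA atom *j* as van der Waals spheres
   (Bondi radii by default) and sum the exact two-sphere intersection
   volume over all protein–RNA pairs:

   *V*(f) = Σ_{i,j} V_lens(r_i, r_j, d_ij),

   with, for |r_i − r_j| < d < r_i + r_j,

   V_lens = π (r_i + r_j − d)² (d² + 2d(r_i + r_j) − 3(r_i − r_j)²) / (12 d),

   V_lens = 0 for disjoint spheres and the smaller sphere's volume under
   containment. The RNA stays fixed in its bound pose throughout: it
   defines "the space to be occupied on binding".

The per-frame series yields a normalised density distribution; two
variants are compared by mean/median differences and a two-sided
Mann–Whitney rank-sum test. Note the statistic is the *pairwise sum* — it
deliberately over-counts regions covered by several spheres; it is a clash
score, not the volume of the geometric union.

Alongside the core metric the package provides per-residue RMSF
(fluctuation about the time mean after fitting), geometric residue–RNA
hydrogen-bond time averages (donor–acceptor ≤ 3.5 Å, H–D–A angle ≤ 30°),
and the two wet-lab quantification ratios used in editing studies:
editing level 100·G/(A+G) from Sanger peak areas and cassette inclusion
100·long/(long+short) from band molarities.

## Worked example

`examples/occlusion_workflow.py` builds a synthetic matched pair — a
shared 60-atom core plus, in variant B, a ten-atom loop 3 Å from the
pseudo-RNA centroid — and runs the full analysis:

```
$ python examples/occlusion_workflow.py
variant A: mean overlap    0.191 Å³ over 200 frames
variant B: mean overlap    7.868 Å³ over 200 frames
median shift (B − A): +7.726 Å³, Mann-Whitney p = 3.66e-67 → b_higher
```

Variant B's distribution is shifted to higher overlap volumes: its
conformers occlude the RNA-occupied space more strongly, exactly the
signature expected for a loop inserted at the binding interface. The other
examples (`rmsf_recovery.py`, `hbond_schedule.py`, `editing_levels.py`)
demonstrate the remaining capabilities with closed-form checks.

The same pipeline runs from the shell:

```
rnaocclusion synth --outdir study --seed 42     # synthetic study + config
rnaocclusion run-all study/config.yaml          # fit, overlap, RMSF, report
```

For real data, point `config.yaml` at your own multi-model PDBs and
reference complex; selections, radii (CSV table), hydrogen-bond criteria,
zinc/hydrogen handling and binning are all configurable there.

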