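# tcrdock-groove

Support toolkit for protein–protein docking of T cell receptors (TCRs) onto
MHC-class-I-like antigen-presenting molecules (CD1 presenting lipids, MR1
presenting vitamin-B metabolites). The flexible docking search itself is done
by an external engine; this package provides everything around it:

* **Start-pose generation** — rigid placement of an unbound TCR over the
  receptor groove, parameterized by four numbers over an orthonormal *groove
  frame* built from the α1/α2 platform helices: height along the helix-plane
  normal, shift along the groove axis, crossing angle in the helix plane, and
  a tilt toward the groove-axis C-terminus. Four standard sites are shipped:
  `start1` (25 Å, 0 Å, 45°, 0°), `start2` (25, 20, 0°, 25°), `start3`
  (25, 10, 22.5°, 12.5°) and `start4` (25, 25, −15°, 40°).
* **ZRANK-style rescoring** — a weighted sum of 8 interface terms
  (attractive/repulsive Lennard-Jones, short/long-range attractive/repulsive
  Coulomb electrostatics, and the ACE/IFACE atomic contact potentials over 18
  heavy-atom classes), with the general `ZR2` weights and the TCR-retrained
  `ZRT` weights as presets. Lower score = better rank.
* **CAPRI assessment** — fnat, ligand RMSD and interface RMSD against a bound
  reference, with the antigen counted for contacts but excluded from RMSD
  atoms, classification into high/medium/acceptable/incorrect ("hits" =
  medium or high), per-case ranking reports, funnels and multi-start pooling.
* **Weight retraining** — multi-start Nelder–Mead simplex maximizing the mean
  hit/non-hit ROC AUC among each case's top-30 ranked models, with
  TCR-identity-constrained cross-validation, presented as a
  model/results pair (`WeightTraining(...).fit().summary()`).
* **Model comparison** — loop-RMSD distances between docking models over a
  superposed receptor, neighbor-joining trees and single-linkage clusters.
* **Synthetic fixtures** — deterministic toy platforms/TCRs and planted decoy
  sets so everything above is testable without downloading any structure.

## Worked example

```python
from tcrdock import (ToyComplexSpec, make_toy_complex, START_SITES,
                     place_start, measure_start_pose, score, capri_metrics,
                     WeightVector)

case = make_toy_complex(ToyComplexSpec(seed=0))      # bound + unbound toys

placed, _ = place_start(case.tcr, case.receptor, START_SITES["start2"])
m = measure_start_pose(placed, case.receptor)
print(f"height={m.height:.1f} shift={m.shift:.1f} "
      f"cross={m.crossing_angle:.1f} tilt={m.tilt:.1f}")
# height=25.0 shift=20.0 cross=-0.0 tilt=25.0

s, terms = score(case.bound, WeightVector.zrt())
print(f"ZRT score {s:.1f}; ACE {terms.ace:.1f}, IFACE {terms.iface:.1f}")
# ZRT score 8435.0; ACE -33.6, IFACE -51.2

print(capri_metrics(case.bound, case.bound))
# CapriMetrics(fnat=1.0, lrmsd=1.06e-13, irmsd=2.53e-15, accuracy_class='high')
```

The pose readout shows the placement machinery closing its own loop: the
measured four-parameter pose equals the requested `start2` site. The score is
the weighted sum of the 8 interface terms (the toy complex is geometric, not
physical — its absolute score is meaningless, but every invariance the tests
rely on holds). The bound reference assessed against itself is, by
definition, a high-accuracy model with every native contact reproduced.

The same operations are available from the shell:

```bash
tcrdock fixtures toy --seed 0 -o case/
tcrdock place --manifest case/case.json --start start2 -o pose.pdb
tcrdock score --models models/ --manifest case/case.json \
              --weights zrt --mol2 case/antigen.mol2 -o scores.tsv
tcrdock evaluate --models models/ --bound case/bound.pdb \
                 --manifest case/case.json --scores scores.tsv -o report.json
tcrdock retrain --decoys decoys/ --starts 12000 --seed 1 -o weights.json
tcrdock compare --set-a setA/ --set-b setB/ --manifest case/case.json \
                --loops CDR1A,CDR2A -o dist.tsv --tree tree.nwk
```

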