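"""Fold a CA backbone from a predicted inter-residue distance map.

Builds a 40-residue helix-bundle ground truth, derives its exact distance
map (standing in for a perfect distance prediction), folds a model from
flat-bottom restraints, and measures how well the truth is recovered.
"""

from distfold.fixtures import FixtureSpec, make_noisy_map, make_structure
from distfold.folder import fold, restraints_from_map, select_enantiomer
from distfold.metrics import kabsch_rmsd, tm_score

native = make_structure(FixtureSpec(L=40, topology="helix_bundle", seed=1))
pred = make_noisy_map(native, noise_sigma=0.0, corrupt_frac=0.0, seed=0)

restraints = restraints_from_map(pred)  # pairs <= 16 Å plus sequential bonds
result = fold(restraints, seed=7)
model = select_enantiomer(result, hint=native)  # distances cannot fix chirality

print(f"restraints: {len(restraints)}  final energy: {result.restraint_energy:.2e}")
print(f"TM-score to truth: {tm_score(model, native).tm_score:.3f}")
print(f"CA-RMSD to truth:  {kabsch_rmsd(model, native)[0]:.4f} Å")
# With an exact map the fold is essentially perfect: energy ~0 means every
# restraint window is satisfied; TM-score 1.0 / RMSD ~0 Å mean the recovered
# backbone is the ground truth up to rigid motion.
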