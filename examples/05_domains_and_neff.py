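"""Domain splitting from template coverage, and MSA depth via Neff.

A 300-residue target with templates covering [0,120) and [180,300) has a
60-residue uncovered region — longer than the 40-residue rule — so it is
split into TBM / FM / TBM modeling units.  Neff measures how many
effectively non-redundant sequences an alignment contributes.
"""

from distfold.domains import split_domains
from distfold.fixtures import make_hits, make_msa
from distfold.msa_stats import MSA, log_neff, neff

hits = make_hits(300, [(0, 120, 1e-30), (180, 300, 1e-20)])
seg = split_domains(300, hits)
print("segments:", ", ".join(f"{lab}[{s},{e})" for s, e, lab in seg.segments))

query = "ACDEFGHIKLMNPQRSTVWY" * 3
redundant = make_msa(query, n_rows=10, mutation_rate=0.02, seed=4)
diverse = make_msa(query, n_rows=21, mutation_rate=0.4, seed=5)
mixed = MSA(redundant.rows + diverse.rows[1:])
print(f"Neff = {neff(mixed):.2f} over {mixed.n_rows} rows"
      f" (log Neff = {log_neff(mixed):.2f})")
# The 10 nearly identical rows collapse into ~1 effective sequence; the 20
# heavily mutated rows each count fully, so Neff ~ 21 of 30.
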