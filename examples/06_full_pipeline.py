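"""The end-to-end template-free pipeline on a synthetic target.

Writes a target (FASTA + predicted map + native) to a temp directory, folds
a pool of models, ranks them by distance-map agreement, selects the top-k,
and evaluates against the native — the same flow as `distfold run`.
"""

import json
import tempfile
from pathlib import Path

from distfold.distmat import write_map
from distfold.fixtures import FixtureSpec, make_noisy_map, make_structure
from distfold.pipeline import PipelineConfig, run_pipeline
from distfold.structio import write_pdb

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    s = make_structure(FixtureSpec(L=40, topology="helix_bundle", seed=3))
    write_pdb(s, tmp / "native.pdb")
    (tmp / "t.fasta").write_text(f">t\n{s.sequence}\n")
    write_map(make_noisy_map(s, noise_sigma=1.0, seed=2), tmp / "map.txt")

    config = PipelineConfig(
        fasta=str(tmp / "t.fasta"), map_path=str(tmp / "map.txt"),
        out_dir=str(tmp / "run"), native=str(tmp / "native.pdb"),
        method="distance", n_models=5, top_k=3, seed=7,
    )
    manifest = run_pipeline(config)
    print("top models:", ", ".join(manifest["top_models"]))
    print("model seeds:", manifest["model_seeds"])
    ranking = (tmp / "run" / "ranking.tsv").read_text().splitlines()
    print("\n".join(ranking[:4]))
# The manifest pins every seed and parameter: re-running the same config
# reproduces all outputs byte for byte.  The rank-1 model's tm_score_native
# column shows how good the blind selection actually was.
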