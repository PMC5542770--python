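"""Write synthetic fixtures (FASTA + TSV + ground-truth JSON) to disk.

The same generators back the test suite; writing them out gives inputs for
the command-line interface, e.g.:

    pdakit pda --alignment out/planted_msa.fasta \
               --annotations out/planted_msa.annotations.tsv \
               --out-prefix out/run1
"""

import json
import tempfile
from pathlib import Path

from pdakit import (
    PlantedMSASpec,
    PlantedPairedSpec,
    write_msa_fixture,
    write_paired_fixture,
)

outdir = Path(tempfile.mkdtemp(prefix="pdakit_fixtures_"))

msa_paths = write_msa_fixture(
    PlantedMSASpec(
        n_per_group={"A": 50, "B": 50},
        n_positions=25,
        planted_triplet=(3, 11, 19),
        purity=1.0,
        seed=0,
    ),
    outdir,
)
pair_paths = write_paired_fixture(
    PlantedPairedSpec(
        n_organisms=60,
        paralogs_a=1,
        paralogs_b=1,
        n_positions_a=20,
        n_positions_b=20,
        planted_pairs=((3, 7),),
        coupling_strength=0.9,
        seed=0,
    ),
    outdir,
)

for label, paths in (("msa", msa_paths), ("paired", pair_paths)):
    for name, path in paths.items():
        print(f"{label}.{name}: {path}")

truth = json.loads(msa_paths["ground_truth"].read_text())
print(f"planted triplet recorded in the sidecar: {truth['planted_triplet']}")
# The ground-truth sidecar travels with the data so downstream checks never
# have to re-derive which positions carry the signal.
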