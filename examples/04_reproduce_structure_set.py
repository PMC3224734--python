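"""Rebuild the 31-structure crystal seed and validate against it.

Fetches one observed-chain sequence per PDB entry of the crystal-structure
set (network or a warm ``data/pdb_cache`` directory required), reconstructs
a seed alignment by pinning every chain at its ExxR and heme-cysteine
motifs with iterative profile refinement, and runs the leave-one-out
hotspot validation on the result.  The reconstruction is sequence-based, so
agreement with structure-derived annotation is approximate by design.
"""

from cypmod.realdata import (
    RealDataError,
    bootstrap_seed_alignment,
    default_manifest,
    derive_annotation,
    fetch_seed_sequences,
)
from cypmod.validate import leave_one_out

try:
    seqs = fetch_seed_sequences(cache_dir="data/pdb_cache")
except RealDataError as exc:
    raise SystemExit(f"cannot assemble the structure set: {exc}")

seed, excluded = bootstrap_seed_alignment(seqs, refine_rounds=None)
print(f"aligned {len(seed.rows)} chains ({len(excluded)} excluded)")
ann = derive_annotation(
    seed, class_labels={e.pdb: e.class_label for e in default_manifest().entries}
)
report = leave_one_out(seed, ann)
print(f"hold-out hotspot agreement: {report.count('exact')}/{report.n} exact"
      f" ({report.accuracy_exact:.0%}); within 2: {report.accuracy_within_2:.0%}")
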