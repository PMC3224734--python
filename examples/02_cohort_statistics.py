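"""Cohort statistics: hotspot composition and interaction-site bands.

Annotates 60 synthetic queries and summarises the cohort the way a
database-wide survey would: the residue composition at the F87-equivalent
position (bulky aliphatics + phenylalanine dominate heme-facing hotspots)
and the fraction of entries in each reductase-interaction-site length band
(short = class I, long = class II, very long RIS2 = reductase-independent
subgroup).
"""

from cypmod.analyze import composition_at_anchor, ris_distribution
from cypmod.annotate import annotate_sequence
from cypmod.profilehmm import build_profile
from cypmod.synthetic import GeneratorParams, generate_queries, generate_seed

params = GeneratorParams(rng_seed=42)
seed, ann, _ = generate_seed(params)
profile = build_profile(seed, ann)
queries, _ = generate_queries(params, n=60, rng_seed=11)
results = [annotate_sequence(profile, ann, q) for q in queries]

comp = composition_at_anchor(results)
top = sorted(comp.freq.items(), key=lambda kv: -kv[1])[:5]
print("hotspot composition (top 5):",
      ", ".join(f"{aa}={f:.0%}" for aa, f in top))
print("groups:", ", ".join(f"{g}={f:.0%}" for g, f in comp.groups.items()))

for which in ("RIS1", "RIS2"):
    d = ris_distribution(results, which=which)
    bands = ", ".join(f"{b}={f:.0%}" for b, f in d.fractions.items() if f)
    print(f"{which} bands over {d.n} entries: {bands}")
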