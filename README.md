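# cypmod

Structure-anchored annotation transfer for cytochrome P450 monooxygenases
(CYPs).

CYPs share a highly conserved fold but often less than 20% sequence
identity, so the positions that matter for engineering — the
substrate-facing hotspot in the BC-loop and the loops that dock the redox
partner — cannot be located in a plain sequence alignment. `cypmod` solves
this by anchoring everything to structure once: a seed alignment of
crystal-structure chains, annotated with the column spans of the
structurally conserved regions (SCRs) and a handful of universal anchors,
is compiled into a profile hidden Markov model. Any query sequence is then
aligned glocally to that profile (global in the model, free query flanks)
and the annotations are read off the alignment path:

* **SCR intervals** — start/stop of each conserved module (the CYP-fold
  helices αA–L and sheets β1–4, merged into 19 blocks) in query
  coordinates;
* **F87-equivalent position** — the BC-loop residue homologous to Phe87 of
  CYP102A1 (P450 BM-3), a hotspot for activity and regio-/stereoselectivity,
  reported as position + residue or as a gap call;
* **RIS1 and RIS2 lengths** — the residue counts of the two reductase
  interaction sites (the αJ/J′ region, and the insertion between the
  meander loop and the Cys-pocket), measured strictly between conserved
  anchor columns;
* **redox class** — class I (short/short), class II (long/long), the
  reductase-independent very-long-RIS2 subgroup, or
  ambiguous/discordant/unusual calls from the band thresholds;
* an **applicability gate** (forward-score floor plus heme-cysteine check)
  that rejects sequences without a plausible CYP fold.

The model is written for sequence analysts and enzyme engineers who have
query sequences but no structures.

## The model

For a seed alignment with match columns `k = 1..L` (occupancy ≥ 0.5, plus
forced anchor and SCR-boundary columns), emissions are estimated with
background-weighted pseudocounts

    e_k(a) = (n_k(a) + α·q(a)) / (n_k + α),      α = 1 by default,

and transitions from the observed match/insert/delete paths of the seed
rows with the same scheme. Scoring is log-odds in bits against the
background `q`; inserts emit at background odds and free N-/C-flanks let
full-length queries (including fusion proteins, whose reductase domain
simply falls in the C-flank) traverse the whole model. Viterbi gives the
annotation path, the forward score drives the gate; both are exact dynamic
programs validated against brute-force path enumeration.

## Worked example

```
python examples/01_build_and_annotate.py
```

prints

```
profile: 257 match states from 290 columns
Q0000: gate=pass (541 bits)  hotspot=T43  RIS1=21 RIS2=14  class=classII
   truth: hotspot=T43  RIS1=21 RIS2=14  class=classII
Q0001: gate=pass (562 bits)  hotspot=A50  RIS1=22 RIS2=11  class=classII
   truth: hotspot=A50  RIS1=22 RIS2=11  class=classII
Q0002: gate=pass (570 bits)  hotspot=L46  RIS1=5 RIS2=5  class=classI
   truth: hotspot=L46  RIS1=5 RIS2=5  class=classI
```

Each line is one annotated query: the gate verdict with its forward score,
the hotspot call (residue + 1-based position), both interaction-site
lengths, and the redox class — followed by the generating truth, which the
calls reproduce exactly. The other examples cover cohort statistics
(`02`), leave-one-out validation (`03`) and the crystal-structure
reproduction (`04`, network/cache required).

The same pipeline is available from the shell:

```
cypmod simulate --out-dir fix --n-rows 20 --n-queries 200 --seed 42
cypmod build    --aln fix/seed.afa --sidecar fix/seed.json --out profile.json
cypmod annotate --profile profile.json --aln fix/seed.afa \
                --sidecar fix/seed.json --queries fix/queries.fasta \
                --out results.tsv --gff3 results.gff3
cypmod stats    --results results.tsv --out stats.json
cypmod loo      --aln fix/seed.afa --sidecar fix/seed.json --report loo.tsv
```

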