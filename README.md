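# ggyl — Golden Gate assembly designer/simulator for *Yarrowia lipolytica*

`ggyl` is an in-silico companion to the modular Golden Gate cloning standard
for the oleaginous yeast *Yarrowia lipolytica*: a one-pot, BsaI-based system
that assembles up to three transcription units (TUs) together with a
selection marker and genome-integration flanks into a destination vector,
in a single digestion/ligation reaction.

It is written for synthetic biologists and strain engineers who use (or
build) such positional brick collections and want to design, check and
debug constructs before touching a pipette: validate overhang sets and
bricks, predict the exact assembly product, enumerate combinatorial
libraries, domesticate coding sequences, design adapter primers, and print
the bench protocols and QC expectations for each assembly stage.

## The grammar

Thirteen unique 4-nt junction overhangs, lettered A–M, fix the order and
orientation of every part around the circle:

```
Backbone -A- InsUp -B- Marker -C- Prom1 -D- Gene1 -E- Term1 -F-
Prom2 -G- Gene2 -H- Term2 -I- Prom3 -J- Gene3 -K- Term3 -L-
InsDown -M- (Backbone)
```

BsaI (GGTCTC, a Type IIS enzyme cutting 1 nt downstream with a 4-nt 5′
overhang) releases each brick's payload with its two junction overhangs.
Because the recognition sites sit on the *discarded* side of every cut —
in the donor stuffers and in the destination vector's RFP dropout — the
assembled product is the unique circular closure free of BsaI sites, and
repeated digestion/ligation cycling drives the reaction toward it.
Shortcut terminators with E–L or H–L overhangs close 1- and 2-TU designs
without re-cloning any gene brick, so complete pots contain 7, 10 or 13
DNA molecules for 1, 2 or 3 TUs.

The package ships a deterministic synthetic fixture kit mirroring the
published inventory — 64 bricks: 27 promoters (9 characterized promoters ×
3 positions, including erythritol-inducible UAS hybrids), 14 terminators,
6 markers, 10 insertion flanks (ZETA random integration plus LIP2/GSY1/MFE
locus replacement), 5 reporter genes and 2 destination vectors — with all
payloads generated as seeded pseudo-random sequences (no deposited
sequence data is included or fetched).

## Worked example

```python
from ggyl import *

demo = generate_xylose_demo(seed=42)          # kit + mock 3-gene xylose pathway
tk = demo.toolkit
print(count_fragments(demo.design, tk))       # molecules entering the pot

c = simulate_one_pot(demo.design, tk)
print(len(c.plasmid), len(find_recognition_sites(c.plasmid, BSAI)))
print(" -> ".join(f.brick_id for f in c.features if f.slot != "Backbone"))

qc = notI_release(c)
print([f.length for f in qc.notI_fragments], qc.cassette_found)
print(make_protocol("standard_one_pot", 13).render())
```

prints

```
13
12459 0
ZUpNotI -> URA3 -> pTEF_P1 -> ylXDH -> TLip2_T1 -> pTEF_P2 -> ylXR -> TLip2_T2 -> pTEF_P3 -> ylXK -> TLip2_T3 -> ZDNotI
[9957, 2502] True
Stage: standard_one_pot
Fragments: 13 x 50 pmol (equimolar)
BsaI: 5 U   T4 ligase: 200 U
T4 ligase buffer: 2 ul   final volume: 20 ul (ddH2O)
Thermocycler:
  [37 C for 5 min, 16 C for 2 min] x 60
  [55 C for 5 min, 80 C for 5 min] x 1
  15 C hold
```

That is: the 3-TU xylose-pathway design enters the pot as 13 molecules
(12 bricks + destination vector); the simulated product is a single
12 459-bp circle with zero remaining BsaI sites; its insert reads, in
grammar order, exactly like the published construct layout
(ZUp-NotI flank, URA3 marker, then pTEF/gene/TLip2 for each of the three
xylose genes, then the ZDown-NotI flank); NotI digestion releases the
integration cassette as one of exactly two fragments whose sizes sum to
the plasmid length; and the printed recipe is the standard one-pot
programme.

The same functionality is exposed on the command line:

```sh
ggy fixtures --seed 42 --out kit/          # write the 64-brick kit (GenBank + YAML)
ggy validate --toolkit kit/                # overhang-set + per-brick checks
ggy demo xylose --out demo/                # assemble + QC the xylose demo
ggy protocol --stage multigene_final       # print the 40-ul, 50-cycle recipe
```

## Layout

| module | contents |
| --- | --- |
| `ggyl.seqcore` | sequence model, site scanning, Type IIS digestion geometry, canonical circular forms |
| `ggyl.registry` | brick model, A–M grammar, overhang-set validation, manifests, GenBank I/O |
| `ggyl.assembler` | one-pot simulation, preassembly split, combinatorial enumeration |
| `ggyl.domestication` | silent BsaI-site removal, adapter-primer design |
| `ggyl.qc_protocol` | NotI cassette release, colony-PCR sizing, reaction recipes, screening arithmetic |
| `ggyl.fixtures` | deterministic synthetic kit + xylose-pathway demo |
| `ggyl.cli` | the `ggy` command line |

See `docs/methods.md` for the modelling assumptions and design decisions.
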