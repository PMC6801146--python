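# Methods

## The model

`ggyl` models Golden Gate assembly as deterministic sequence algebra rather
than reaction kinetics. Three assumptions carry the whole simulator:

1. **Exact cut geometry.** BsaI is modelled as GGTCTC with a top-strand
   nick 1 nt downstream of the recognition sequence and a bottom-strand
   nick 5 nt downstream, leaving a 4-nt 5′ overhang; NotI as GCGGCCGC cut
   symmetrically within the site. Enzymes are data
   (`seqcore.EnzymeSpec`), so other Type IIS or palindromic cutters can be
   added without code changes. Star activity, methylation sensitivity and
   partial-digestion kinetics are out of scope.
2. **Exact ligation.** Two sticky ends join if and only if their 4-nt
   overhangs are exact Watson–Crick partners. Overhangs are recorded as
   top-strand 5′→3′ text at the junction, so compatibility reduces to
   string equality of an upstream fragment's right overhang with a
   downstream fragment's left overhang. Misligation fidelity is not
   modelled; the published system provides no quantitative misligation
   data, and the overhang-set validator (distinctness, no palindromes, no
   mutual reverse complements) enforces the design rules that make exact
   ligation a reasonable idealization.
3. **Fixed-point selection.** The thermocycling programme alternates
   digestion and ligation, so any circle that still contains a recognition
   site is transient. The simulator therefore keeps only BsaI-free
   fragments (payloads and the vector backbone; stuffers and the RFP
   dropout retain their sites by construction) and returns the unique
   circular closure over them. Uniqueness is part of the contract: zero
   closures raise an open-junction error naming the unmatched letters, two
   or more raise an ambiguity error enumerating the alternatives. This is
   also how the A-overhang "conflict" between the dropout and the InsUp
   brick resolves: the dropout's closure restores BsaI sites and is never
   stable.

Fragment bookkeeping uses a half-open convention in which a fragment's
`core` spans from its own left (top-strand) cut to the next fragment's left
cut. The core therefore contains the fragment's left overhang, the sum of
core lengths equals the parent length for every circular digest, and a
ligation product is simply the concatenation of cores. Linear molecules
treat terminal nicks (a cut event whose second strand cleavage would fall
on or beyond a terminus) as non-fragmenting, which keeps digestion strand
symmetric.

Circular molecules have no natural origin, so all product-equality
assertions go through `canonical_form`: the lexicographically minimal
rotation over both strands, computed with Booth's least-rotation algorithm.
Coordinates are 0-based half-open internally and 1-based inclusive in
GenBank output (Biopython handles the conversion).

## The grammar and the junction letters

The circular walk Backbone–A–InsUp–B–Marker–C–(Prom–Gene–Term)×3–L–InsDown–
M–Backbone assigns each slot a fixed letter pair; shortcut terminators
carry E–L (closing a 1-TU design) or H–L (closing a 2-TU design), giving
junction lists of 7, 10 and 13 letters. The letter assignment is fixed by
the published construct anatomy: the RFP dropout is flanked by A and M,
removing the position-2 gene opens junctions G and H, and shortcut
terminators bridge E–L and H–L.

The actual 4-nt sequences behind the letters live in the physical kit's
documentation, which this package does not reproduce; the shipped default
set is repository-defined, passes the overhang-set validator, and — one
extra constraint — contains no 4-mer that equals an internal window of the
BsaI or NotI recognition sequences (GTCT, AGAC, CGGC, GGCC, GCCG are
excluded). Since a recognition site spanning an assembly junction must
contain the whole 4-nt overhang, this guarantees junction-crossing sites
cannot arise in any product, and per-brick site-freedom checks are
sufficient globally. Users with the authentic sequences substitute them via
the manifest's `overhangs` block.

Destination vectors are bricks whose payload is the kept backbone and whose
stuffer is the RFP dropout. A preassembled vector (GGE114-style: ZETA
flanks and URA3 already fused onto the backbone) simply declares a wider
arc (L→C); the slots inside the arc are treated as satisfied, which is why
a 3-TU assembly on such a vector needs only 10 molecules.

## Parameters that matter

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| BsaI spacer / overhang | 1 / 4 | nt | the enzyme's N1/N5 geometry |
| primer tail spacer | `A`, 1 | nt | minimal tail satisfying the cut geometry |
| minimum annealing length | 18 | nt | common PCR practice floor |
| Tm target / rule | 55 / Wallace (2·AT + 4·GC) | °C | deterministic, dependency-free; swappable (`tm_rule`) |
| dsDNA molar mass | 650 | g·mol⁻¹·bp⁻¹ | standard approximation; configurable in `pmol_to_mass` |
| percent rounding policy | round-half-up | — | explicit per call; truncation kept available because published locus-screen figures match truncation for 11/24 (45%) and rounding for 5/37 (14%) |
| reaction recipes | see `qc_protocol._STAGES` | — | fixed constants per stage, reproduced verbatim |

Domestication edits prefer third-codon-position substitutions, then any
synonymous codon, with lexicographic tie-breaks — a reproducibility choice,
not a biological one. Each edit is accepted only if a full re-scan shows
the targeted site gone and no new forbidden site anywhere; translation
preservation is additionally asserted in tests through an independent
translator rather than the editor's own bookkeeping. Codon *optimization*
(host usage bias) is deliberately out of scope; the codon table is used for
synonymy only.

## What the synthetic kit does and does not emulate

`fixtures.generate_toolkit` reproduces the published *inventory* — 64
bricks: 27 promoters, 14 terminators, 6 markers, 10 insertion flanks, 5
reporter genes, 2 destination vectors — with names, positions, strength
classes and locus annotations matching the described collection. Payloads
are seeded pseudo-random sequences with realistic lengths (promoters
400–1000 nt, terminators 60–150 nt, ORFs 600–1500 nt with start/stop and no
internal stops, backbones ~2.4 kb) and are generated free of BsaI/NotI
sites in their flanking context, except for the deliberate NotI handles on
the outer edges of the ZUpNotI/ZDNotI flanks. The terminator breakdown
(five names spread over positions 1–3 plus the two TLip2 shortcut bricks,
totalling 14) and the gene-brick composition (three reporters at position 1
plus YFP at 2 and mTurquoise at 3) are reconstructions — the totals are
documented but their itemization is not — and are flagged `reconstruction`
in the annotations.

Consequently, passing tests demonstrate the *structural* logic of the
standard: grammar closure, cut/ligation geometry, product uniqueness,
route equivalence, domestication correctness, protocol and screening
arithmetic. They say nothing about sequence-dependent behaviour of real
parts — promoter strength, terminator readthrough, ligation fidelity of
the authentic overhang set, recombination propensity, transformation
efficiency — and no wet-lab yield (white-colony rates, correct-assembly
rates, integration or xylose-positive percentages) is simulated; where
such figures appear they are metadata or arithmetic inputs, never model
outputs.

## Numerical and degenerate-input choices

- Site scanning reports every occurrence on either strand once, scanning
  across the origin of circular molecules; palindromic recognition
  sequences are reported once, on the top strand.
- Two cut events closer than one overhang length raise a degenerate-
  geometry error naming both sites, rather than guessing a fragmentation.
- A digest with zero sites returns the molecule intact as one fragment.
- IUPAC ambiguity codes are rejected at ingest with the offending
  position; bricks are fully specified molecules, and silently expanding
  ambiguity would undermine the exact-ligation model.
- Colony PCR uses exact, zero-mismatch primer matching (≥ 15 nt), measures
  products primer start to primer start inclusive, and emits a warning
  listing all products when a primer matches more than once.
- Enumeration iterates lexicographically by slot name then brick id;
  random design sampling is seeded. All randomness in the package flows
  through explicit seeds.

## Problem sizes

The default test run assembles dozens of full constructs and sweeps the
property suites at sizes chosen to finish in seconds on one core: 1 000
random molecules for digestion conservation/strand symmetry, 50 random
3-TU designs for direct-versus-preassembly route equivalence, 100
planted-site CDSs for domestication, 100 random templates for colony-PCR
sizing, and brute-force Hamiltonian-cycle cross-checks (via networkx) on
pots of 7–13 fragments. The acceptance script regenerates the kit and
simulates one complete design per topology.

## Known limitations

- Exact-match ligation means overhang sets that are merely *similar* (3/4
  matches) are treated as fully orthogonal; fidelity-aware scoring would
  need an empirical mismatch model.
- The one-pot simulator deliberately rejects pots with redundant bricks
  for one slot (ambiguous closures); combinatorial pooling is expressed by
  enumerating designs, not by simulating a mixed pot.
- The preassembly route is only defined for full 12-insert 3-TU designs,
  mirroring the published split.
- GenBank round-trips preserve brick anatomy exactly but normalize record
  dates to a fixed value so fixture output is byte-reproducible.
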