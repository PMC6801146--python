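"""Deterministic synthetic toolkit and demo-pathway generation.

No deposited plasmid sequence is required anywhere in the package: this
module fabricates a complete brick collection whose *inventory* mirrors the
published kit — 64 bricks: 27 promoters (9 names × 3 positions), 14
terminators, 6 markers, 10 genome-insertion sequences, 5 reporter genes and
2 destination vectors — while every payload is a seeded pseudo-random
sequence.  Real promoter/gene identities (pTEF, URA3, YALI loci, …) appear
as names and annotations only.

Payloads are generated free of BsaI and NotI recognition sites (except the
deliberate NotI handles on the ZETA-NotI insertion flanks), so every brick
passes :func:`ggyl.registry.check_brick` and any grammatical design
assembles cleanly.  The same seed always produces byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

from .registry import (
    Brick,
    DEFAULT_OVERHANGS,
    Overhang,
    SlotId,
    Toolkit,
    ToolkitManifest,
    check_brick,
    validate_overhang_set,
)
from .assembler import AssemblyDesign
from .seqcore import NucSequence

__all__ = [
    "FixtureSpec",
    "DEFAULT_COUNTS",
    "generate_toolkit",
    "generate_xylose_demo",
    "XyloseDemo",
    "random_orf",
]

DEFAULT_COUNTS = {
    "promoter": 27,
    "terminator": 14,
    "marker": 6,
    "insertion": 10,
    "gene": 5,
    "destination_vector": 2,
}

_FORBIDDEN = ("GGTCTC", "GAGACC", "GCGGCCGC")
_NOTI = "GCGGCCGC"

PROMOTER_NAMES = [
    ("pTEF", {"strength": "strong", "inducible": False}),
    ("pPGM", {"strength": "weak", "inducible": False}),
    ("pGAP", {"strength": "weak", "inducible": False}),
    ("2UAS-pTEF", {"strength": "strong", "inducible": False}),
    ("4UAS-pTEF", {"strength": "very_strong", "inducible": False}),
    ("8UAS-pTEF", {"strength": "very_strong", "inducible": False}),
    ("3UAS-pEYK1", {"strength": "inducible", "inducible": True}),
    ("4UAS-pEYK1", {"strength": "inducible", "inducible": True}),
    ("5UAS-pEYK1", {"strength": "inducible", "inducible": True}),
]

TERMINATOR_NAMES = ["TLip2", "TTef", "T1Guo", "T2Guo", "TSynth8"]

MARKER_NAMES = [
    ("URA3", {"marker_type": "auxotrophic"}),
    ("LEU2", {"marker_type": "auxotrophic"}),
    ("LYS5", {"marker_type": "auxotrophic"}),
    ("hph", {"marker_type": "antibiotic", "resistance": "hygromycin",
             "embedded_expression": "pTEF/TLip2"}),
    ("nat1", {"marker_type": "antibiotic", "resistance": "nourseothricin",
              "embedded_expression": "pTEF/TLip2"}),
    ("SUC2", {"marker_type": "metabolic", "note": "S. cerevisiae invertase"}),
]

# (name, up/down role, NotI handle at the outer edge?)
INSERTION_NAMES = [
    ("ZetaUp", "up", False, {"locus": "zeta", "mode": "random"}),
    ("ZetaDown", "down", False, {"locus": "zeta", "mode": "random"}),
    ("ZUpNotI", "up", True, {"locus": "zeta", "mode": "random"}),
    ("ZDNotI", "down", True, {"locus": "zeta", "mode": "random"}),
    ("Lip2Up", "up", False, {"locus": "LIP2", "mode": "locus_replacement"}),
    ("Lip2Down", "down", False, {"locus": "LIP2", "mode": "locus_replacement"}),
    ("Gsy1Up", "up", False, {"locus": "GSY1", "mode": "locus_replacement"}),
    ("Gsy1Down", "down", False, {"locus": "GSY1", "mode": "locus_replacement"}),
    ("MfeUp", "up", False, {"locus": "MFE", "mode": "locus_replacement"}),
    ("MfeDown", "down", False, {"locus": "MFE", "mode": "locus_replacement"}),
]

# (name, position) — reporters at position 1 plus the published 3-TU layout
GENE_NAMES = [
    ("RedStarII", 1),
    ("YFP", 1),
    ("mTurquoise", 1),
    ("YFP", 2),
    ("mTurquoise", 3),
]

#: per-category payload length ranges (nt); terminators follow the short
#: (~66 bp) terminators the kit favours
DEFAULT_LENGTHS = {
    "promoter": (400, 1000),
    "terminator": (60, 150),
    "marker": (1000, 2000),
    "insertion": (500, 1200),
    "gene": (600, 1500),
    "backbone": (2200, 2600),
    "dropout": (650, 750),
    "stuffer": (80, 160),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic toolkit (same spec ⇒ identical bytes)."""

    seed: int = 42
    overhangs: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_OVERHANGS))
    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    lengths: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTHS)
    )


def _clean_random_seq(rng: random.Random, length: int, flanks: tuple[str, str],
                      allow_noti: bool = False) -> str:
    """Random ACGT string free of forbidden motifs, *in context*.

    Rejects candidates for which any forbidden motif occurs at a position
    overlapping the generated region of ``flanks[0] + s + flanks[1]``; motifs
    lying wholly inside a flank (e.g. a donor's own BsaI sites) are the
    flank's business and do not trigger rejection.
    """
    bad = _FORBIDDEN[:2] if allow_noti else _FORBIDDEN
    lo = len(flanks[0])
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(length))
        ctx = flanks[0] + s + flanks[1]
        hi = lo + length
        clean = True
        for m in bad:
            start = 0
            while clean:
                i = ctx.find(m, start)
                if i < 0:
                    break
                if i + len(m) > lo and i < hi:
                    clean = False
                start = i + 1
            if not clean:
                break
        if clean:
            return s


_STOPS = {"TAA", "TAG", "TGA"}


def random_orf(rng: random.Random, length: int, flanks: tuple[str, str]) -> str:
    """A mock open reading frame: ATG, no internal stops, stop codon, and no
    BsaI/NotI sites in context.  ``length`` is rounded down to a codon
    multiple (minimum 9 nt)."""
    n_codons = max(length // 3, 3) - 2
    while True:
        body = []
        for _ in range(n_codons):
            while True:
                codon = "".join(rng.choice("ACGT") for _ in range(3))
                if codon not in _STOPS:
                    break
            body.append(codon)
        s = "ATG" + "".join(body) + "TAA"
        ctx = flanks[0] + s + flanks[1]
        if not any(m in ctx for m in _FORBIDDEN):
            return s


def _mk_brick(
    rng: random.Random,
    spec: FixtureSpec,
    brick_id: str,
    category: str,
    slots: tuple[SlotId, ...],
    left: str,
    right: str,
    annotations: dict,
    payload: str | None = None,
    length_key: str | None = None,
) -> Brick:
    oh = spec.overhangs
    if payload is None:
        lo, hi = spec.lengths[length_key or category]
        payload = _clean_random_seq(
            rng, rng.randint(lo, hi), (oh[left], oh[right])
        )
    lo_s, hi_s = spec.lengths["stuffer"]
    stuffer = _clean_random_seq(rng, rng.randint(lo_s, hi_s), ("GAGACC", "GGTCTC"))
    return Brick(
        id=brick_id,
        category=category,
        slots=slots,
        left_letter=left,
        right_letter=right,
        payload=NucSequence(payload, "linear", brick_id),
        stuffer=stuffer,
        annotations=annotations,
    )


_POS_SLOTS = {
    "promoter": {1: SlotId.Prom1, 2: SlotId.Prom2, 3: SlotId.Prom3},
    "gene": {1: SlotId.Gene1, 2: SlotId.Gene2, 3: SlotId.Gene3},
    "terminator": {1: SlotId.Term1, 2: SlotId.Term2, 3: SlotId.Term3},
}

_POS_LETTERS = {
    "promoter": {1: ("C", "D"), 2: ("F", "G"), 3: ("I", "J")},
    "gene": {1: ("D", "E"), 2: ("G", "H"), 3: ("J", "K")},
    "terminator": {1: ("E", "F"), 2: ("H", "I"), 3: ("K", "L")},
}


def _brick_plan(spec: FixtureSpec) -> list[dict]:
    """Ordered generation plan honouring the requested category counts.

    Ordering within a category is chosen so that truncated counts still
    yield a workable kit (e.g. a 1-terminator kit gets the E–L shortcut
    needed by 1-TU designs, a 2-insertion kit gets the ZETA pair).
    """
    plan: list[dict] = []

    # terminators: shortcuts first, then positional sets
    term_entries = [
        dict(id="TLip2_EL", category="terminator", slots=(SlotId.Term1,),
             left="E", right="L",
             ann={"name": "TLip2", "shortcut": "1TU",
                  "reconstruction": True}),
        dict(id="TLip2_HL", category="terminator", slots=(SlotId.Term2,),
             left="H", right="L",
             ann={"name": "TLip2", "shortcut": "2TU",
                  "reconstruction": True}),
    ]
    per_pos = {1: TERMINATOR_NAMES, 2: TERMINATOR_NAMES[:4], 3: TERMINATOR_NAMES[:3]}
    for pos in (1, 2, 3):
        for name in per_pos[pos]:
            l, r = _POS_LETTERS["terminator"][pos]
            term_entries.append(
                dict(id=f"{name}_T{pos}", category="terminator",
                     slots=(_POS_SLOTS["terminator"][pos],), left=l, right=r,
                     ann={"name": name, "position": pos, "reconstruction": True})
            )

    prom_entries = []
    for pos in (1, 2, 3):
        for name, ann in PROMOTER_NAMES:
            l, r = _POS_LETTERS["promoter"][pos]
            prom_entries.append(
                dict(id=f"{name}_P{pos}", category="promoter",
                     slots=(_POS_SLOTS["promoter"][pos],), left=l, right=r,
                     ann={"name": name, "position": pos, **ann})
            )

    marker_entries = [
        dict(id=name, category="marker", slots=(SlotId.Marker,),
             left="B", right="C", ann={"name": name, **ann})
        for name, ann in MARKER_NAMES
    ]

    ins_entries = []
    for name, role, noti, ann in INSERTION_NAMES:
        if role == "up":
            cat, slots, l, r = "insertion_up", (SlotId.InsUp,), "A", "B"
        else:
            cat, slots, l, r = "insertion_down", (SlotId.InsDown,), "L", "M"
        ins_entries.append(
            dict(id=name, category=cat, slots=slots, left=l, right=r,
                 ann={"name": name, "noti_handle": noti, **ann},
                 noti_handle=noti, role=role)
        )

    gene_entries = [
        dict(id=f"{name}_G{pos}", category="gene",
             slots=(_POS_SLOTS["gene"][pos],),
             left=_POS_LETTERS["gene"][pos][0],
             right=_POS_LETTERS["gene"][pos][1],
             ann={"name": name, "position": pos, "reporter": True}, orf=True)
        for name, pos in GENE_NAMES
    ]

    vector_entries = [
        dict(id="GGE029", category="destination_vector", slots=(SlotId.Backbone,),
             left="M", right="A",
             ann={"name": "GGE029", "dropout": "RFP",
                  "note": "AmpR + ColE1 backbone; RFP between BsaI sites A and M"}),
        dict(id="GGE114", category="destination_vector", slots=(SlotId.Backbone,),
             left="L", right="C",
             ann={"name": "GGE114", "dropout": "RFP", "preassembled": "ZETA+URA3",
                  "note": "RFP between the URA3 marker and the ZETA down"}),
    ]

    counts = dict(DEFAULT_COUNTS)
    counts.update(spec.counts)
    for key, entries in (
        ("promoter", prom_entries),
        ("terminator", term_entries),
        ("marker", marker_entries),
        ("insertion", ins_entries),
        ("gene", gene_entries),
        ("destination_vector", vector_entries),
    ):
        want = counts.get(key, len(entries))
        if want > len(entries):
            raise ValueError(f"cannot generate {want} {key} bricks (max {len(entries)})")
        plan.extend(entries[:want])
    return plan


def generate_toolkit(spec: FixtureSpec | None = None) -> Toolkit:
    """Generate the synthetic brick collection described by ``spec``.

    Every generated brick passes ``check_brick``; the default spec yields
    64 bricks in the published category proportions.
    """
    spec = spec or FixtureSpec()
    report = validate_overhang_set(
        [Overhang(k, v) for k, v in sorted(spec.overhangs.items())]
    )
    if not report.passed:
        raise ValueError(f"overhang set invalid: {report.to_dict()['issues']}")
    rng = random.Random(spec.seed)
    oh = spec.overhangs
    bricks: dict[str, Brick] = {}
    for entry in _brick_plan(spec):
        cat = entry["category"]
        lkey = "insertion" if cat.startswith("insertion") else cat
        if cat == "destination_vector":
            # payload = kept E. coli backbone; stuffer = RFP dropout
            lo, hi = spec.lengths["backbone"]
            payload = _clean_random_seq(
                rng, rng.randint(lo, hi), (oh[entry["left"]], oh[entry["right"]])
            )
            if entry["id"] == "GGE114":
                # preassembled ZETA-down .. backbone .. ZETA-up .. URA3 arc;
                # regenerate until the fused seams are also motif-free
                while True:
                    zd = _clean_random_seq(rng, 600, (oh["L"], oh["M"]))
                    zu = _clean_random_seq(rng, 600, (oh["A"], oh["B"]))
                    ura = _clean_random_seq(rng, 1200, (oh["B"], oh["C"]))
                    fused = zd + oh["M"] + payload + oh["A"] + zu + oh["B"] + ura
                    ctx = oh[entry["left"]] + fused + oh[entry["right"]]
                    if not any(m in ctx for m in _FORBIDDEN):
                        payload = fused
                        break
            lo_d, hi_d = spec.lengths["dropout"]
            dropout = _clean_random_seq(
                rng, rng.randint(lo_d, hi_d), ("GAGACC", "GGTCTC")
            )
            brick = Brick(
                id=entry["id"], category=cat, slots=entry["slots"],
                left_letter=entry["left"], right_letter=entry["right"],
                payload=NucSequence(payload, "linear", entry["id"]),
                stuffer=dropout, annotations=entry["ann"],
            )
        elif entry.get("noti_handle"):
            # NotI handle at the genome-facing (outer) edge of the flank
            lo, hi = spec.lengths["insertion"]
            body = _clean_random_seq(
                rng, rng.randint(lo, hi) - len(_NOTI),
                (oh[entry["left"]], oh[entry["right"]]),
            )
            payload = _NOTI + body if entry["role"] == "up" else body + _NOTI
            brick = _mk_brick(rng, spec, entry["id"], cat, entry["slots"],
                              entry["left"], entry["right"], entry["ann"],
                              payload=payload)
        elif entry.get("orf"):
            lo, hi = spec.lengths["gene"]
            payload = random_orf(
                rng, rng.randint(lo, hi), (oh[entry["left"]], oh[entry["right"]])
            )
            brick = _mk_brick(rng, spec, entry["id"], cat, entry["slots"],
                              entry["left"], entry["right"], entry["ann"],
                              payload=payload)
        else:
            brick = _mk_brick(rng, spec, entry["id"], cat, entry["slots"],
                              entry["left"], entry["right"], entry["ann"],
                              length_key=lkey)
        bricks[brick.id] = brick

    manifest = ToolkitManifest(
        entries=[
            {
                "id": b.id,
                "category": b.category,
                "slots": [s.value for s in b.slots],
                "left": b.left_letter,
                "right": b.right_letter,
                "payload_length": len(b.payload.residues),
                "annotations": dict(b.annotations),
            }
            for b in bricks.values()
        ],
        overhangs=dict(oh),
        provenance=(
            "synthetic fixture emulating the published Y. lipolytica Golden "
            "Gate collection (Addgene 120730-120793); all sequences are "
            "seeded pseudo-random stand-ins"
        ),
    )
    toolkit = Toolkit(bricks=bricks, overhangs=dict(oh), manifest=manifest)
    bad = [i for i in toolkit.validate().issues]
    if bad:  # pragma: no cover - generator guarantees clean bricks
        raise AssertionError(f"fixture generation produced invalid bricks: {bad}")
    return toolkit


# ---------------------------------------------------------------------------
# xylose-pathway demo


@dataclass
class XyloseDemo:
    """A mock three-gene xylose-utilization assembly (GGE0106-style layout)."""

    toolkit: Toolkit
    design: AssemblyDesign
    expected_order: list[str]


#: mock pathway genes: (brick id, position, cited locus name)
XYLOSE_GENES = [
    ("ylXDH", 1, "YALI0E12463g"),
    ("ylXR", 2, "YALI0D07634g"),
    ("ylXK", 3, "YALIF10923g"),
]


def generate_xylose_demo(seed: int = 42, toolkit: Toolkit | None = None) -> XyloseDemo:
    """Build the 3-TU xylose demo: ZETA-NotI flanks, URA3, pTEF/TLip2 per TU.

    Adds three mock pathway gene bricks (ylXDH, ylXR, ylXK — the real loci
    are cited as annotations only) to the toolkit and returns the design
    whose product mirrors the published
    ZUpNotI_URA_P1Tef_XDH_T1Lip2_P2Tef_XR_T2Lip2_P3Tef_XK_T3Lip2_ZDNotI
    layout.
    """
    toolkit = toolkit or generate_toolkit(FixtureSpec(seed=seed))
    rng = random.Random(seed + 104729)  # decoupled from the kit's stream
    oh = toolkit.overhangs
    for gene_id, pos, locus in XYLOSE_GENES:
        l, r = _POS_LETTERS["gene"][pos]
        payload = random_orf(rng, rng.randint(900, 1400), (oh[l], oh[r]))
        stuffer = _clean_random_seq(rng, 120, ("GAGACC", "GGTCTC"))
        brick = Brick(
            id=gene_id, category="gene", slots=(_POS_SLOTS["gene"][pos],),
            left_letter=l, right_letter=r,
            payload=NucSequence(payload, "linear", gene_id),
            stuffer=stuffer,
            annotations={"name": gene_id, "locus": locus, "pathway": "xylose",
                         "synthetic": True},
        )
        rep = check_brick(brick, oh)
        assert rep.passed, rep.to_dict()
        toolkit.bricks[gene_id] = brick

    design = AssemblyDesign(
        topology="3TU",
        assignments={
            SlotId.InsUp: "ZUpNotI",
            SlotId.Marker: "URA3",
            SlotId.Prom1: "pTEF_P1",
            SlotId.Gene1: "ylXDH",
            SlotId.Term1: "TLip2_T1",
            SlotId.Prom2: "pTEF_P2",
            SlotId.Gene2: "ylXR",
            SlotId.Term2: "TLip2_T2",
            SlotId.Prom3: "pTEF_P3",
            SlotId.Gene3: "ylXK",
            SlotId.Term3: "TLip2_T3",
            SlotId.InsDown: "ZDNotI",
        },
        vector_id="GGE029",
    )
    expected = [
        "ZUpNotI", "URA3",
        "pTEF_P1", "ylXDH", "TLip2_T1",
        "pTEF_P2", "ylXR", "TLip2_T2",
        "pTEF_P3", "ylXK", "TLip2_T3",
        "ZDNotI",
    ]
    return XyloseDemo(toolkit=toolkit, design=design, expected_order=expected)
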