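"""Brick data model, the A–M junction grammar and toolkit manifests.

The grammar is a fixed circular walk of 4-nt junction overhangs, lettered
A–M, that orders up to three transcription units (promoter + gene +
terminator), a selection marker and a pair of genome-integration flanks
around an *E. coli* destination backbone:

    Backbone –A– InsUp –B– Marker –C– Prom1 –D– Gene1 –E– Term1 –F–
    Prom2 –G– Gene2 –H– Term2 –I– Prom3 –J– Gene3 –K– Term3 –L–
    InsDown –M– (Backbone)

Shorter designs reuse the same gene/promoter bricks: a 1-TU design closes
Gene1 straight onto InsDown through an E–L shortcut terminator, and a 2-TU
design closes Gene2 through an H–L shortcut, so junction lists have 7, 10
and 13 letters for 1, 2 and 3 TUs.

A :class:`Brick` is a donor-plasmid part: its payload sits between two
BsaI recognition sites placed in the donor stuffer and cutting inward, so a
BsaI digest releases the payload with the slot's junction overhangs while
the stuffer fragment retains both recognition sites.  Destination vectors
are the mirror image — the recognition sites travel with the RFP dropout —
which is what leaves the assembled product free of BsaI sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .seqcore import BSAI, DigestFragment, NucSequence, digest, find_recognition_sites, revcomp

__all__ = [
    "LETTERS",
    "DEFAULT_OVERHANGS",
    "Overhang",
    "SlotId",
    "TOPOLOGIES",
    "slot_layout",
    "junctions_for",
    "allowed_letter_pairs",
    "ValidationIssue",
    "ValidationReport",
    "validate_overhang_set",
    "Brick",
    "donor_plasmid",
    "check_brick",
    "ToolkitManifest",
    "load_manifest",
    "save_manifest",
    "Toolkit",
    "write_toolkit_genbank",
    "read_toolkit_genbank",
]

LETTERS = "ABCDEFGHIJKLM"

#: Repository-defined junction overhangs.  The physical kit defines its own
#: thirteen sequences; any substitute set must pass
#: :func:`validate_overhang_set`.  These were additionally chosen so that no
#: overhang equals an internal 4-mer of a BsaI or NotI recognition sequence,
#: which rules out recognition sites spanning an assembly junction.
DEFAULT_OVERHANGS: dict[str, str] = {
    "A": "GGAG",
    "B": "TACT",
    "C": "AATG",
    "D": "AGGT",
    "E": "GCTT",
    "F": "CGCT",
    "G": "TGTT",
    "H": "ACGA",
    "I": "TAGC",
    "J": "CCAT",
    "K": "CAGT",
    "L": "TTCG",
    "M": "TCCA",
}


@dataclass(frozen=True)
class Overhang:
    """A lettered 4-nt junction sequence, the grammar's atomic unit."""

    letter: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != 4:
            raise ValueError(f"overhang {self.letter}: length must be 4")


class SlotId(str, Enum):
    """Positional slots of the circular grammar."""

    InsUp = "InsUp"
    Marker = "Marker"
    Prom1 = "Prom1"
    Gene1 = "Gene1"
    Term1 = "Term1"
    Prom2 = "Prom2"
    Gene2 = "Gene2"
    Term2 = "Term2"
    Prom3 = "Prom3"
    Gene3 = "Gene3"
    Term3 = "Term3"
    InsDown = "InsDown"
    Backbone = "Backbone"


TOPOLOGIES = ("1TU", "2TU", "3TU")

_LAYOUT: dict[str, list[tuple[SlotId, str, str]]] = {
    "3TU": [
        (SlotId.Backbone, "M", "A"),
        (SlotId.InsUp, "A", "B"),
        (SlotId.Marker, "B", "C"),
        (SlotId.Prom1, "C", "D"),
        (SlotId.Gene1, "D", "E"),
        (SlotId.Term1, "E", "F"),
        (SlotId.Prom2, "F", "G"),
        (SlotId.Gene2, "G", "H"),
        (SlotId.Term2, "H", "I"),
        (SlotId.Prom3, "I", "J"),
        (SlotId.Gene3, "J", "K"),
        (SlotId.Term3, "K", "L"),
        (SlotId.InsDown, "L", "M"),
    ],
    "2TU": [
        (SlotId.Backbone, "M", "A"),
        (SlotId.InsUp, "A", "B"),
        (SlotId.Marker, "B", "C"),
        (SlotId.Prom1, "C", "D"),
        (SlotId.Gene1, "D", "E"),
        (SlotId.Term1, "E", "F"),
        (SlotId.Prom2, "F", "G"),
        (SlotId.Gene2, "G", "H"),
        (SlotId.Term2, "H", "L"),
        (SlotId.InsDown, "L", "M"),
    ],
    "1TU": [
        (SlotId.Backbone, "M", "A"),
        (SlotId.InsUp, "A", "B"),
        (SlotId.Marker, "B", "C"),
        (SlotId.Prom1, "C", "D"),
        (SlotId.Gene1, "D", "E"),
        (SlotId.Term1, "E", "L"),
        (SlotId.InsDown, "L", "M"),
    ],
}


def slot_layout(topology: str) -> list[tuple[SlotId, str, str]]:
    """Ordered (slot, left letter, right letter) walk for a topology."""
    try:
        return list(_LAYOUT[topology])
    except KeyError:
        raise ValueError(f"unknown topology {topology!r}; expected one of {TOPOLOGIES}")


def junctions_for(topology: str) -> list[str]:
    """Ordered junction letters consumed by a topology (7, 10 or 13)."""
    return [right for _, _, right in slot_layout(topology)]


def allowed_letter_pairs(slot: SlotId) -> set[tuple[str, str]]:
    """Legal (left, right) letter pairs for a slot across all topologies."""
    pairs = set()
    for layout in _LAYOUT.values():
        for s, l, r in layout:
            if s is slot:
                pairs.add((l, r))
    return pairs


# ---------------------------------------------------------------------------
# validation reports


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str
    subjects: tuple = ()


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str, *subjects) -> None:
        self.issues.append(ValidationIssue(code, message, tuple(subjects)))

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "issues": [
                {"code": i.code, "message": i.message, "subjects": list(i.subjects)}
                for i in self.issues
            ],
        }


def validate_overhang_set(overhangs: Sequence[Overhang]) -> ValidationReport:
    """Check a junction-overhang set for ligation-fidelity hazards.

    A usable set requires every sequence to be 4 nt, all sequences pairwise
    distinct, none self-complementary (a palindromic overhang ligates to
    itself in either orientation) and no two mutually reverse-complementary
    (which would bridge the wrong junctions).  Violations are report
    entries, not exceptions.
    """
    if not overhangs:
        raise ValueError("empty overhang set")
    report = ValidationReport()
    for oh in overhangs:
        if len(oh.sequence) != 4:
            report.add("bad_length", f"{oh.letter}:{oh.sequence} is not 4 nt", oh.letter)
        if oh.sequence == revcomp(oh.sequence):
            report.add(
                "self_complementary",
                f"{oh.letter}:{oh.sequence} equals its own reverse complement",
                oh.letter,
            )
    seen: dict[str, str] = {}
    for oh in overhangs:
        if oh.sequence in seen:
            report.add(
                "duplicate",
                f"{seen[oh.sequence]} and {oh.letter} share sequence {oh.sequence}",
                seen[oh.sequence],
                oh.letter,
            )
        else:
            seen[oh.sequence] = oh.letter
    for oh in overhangs:
        partner = seen.get(revcomp(oh.sequence))
        if partner is not None and partner != oh.letter and oh.letter < partner:
            report.add(
                "mutual_revcomp",
                f"{oh.letter}:{oh.sequence} is the reverse complement of "
                f"{partner}:{revcomp(oh.sequence)}",
                oh.letter,
                partner,
            )
    return report


# ---------------------------------------------------------------------------
# bricks


CATEGORIES = (
    "promoter",
    "gene",
    "terminator",
    "marker",
    "insertion_up",
    "insertion_down",
    "destination_vector",
)

_CATEGORY_SLOTS: dict[str, set[SlotId]] = {
    "promoter": {SlotId.Prom1, SlotId.Prom2, SlotId.Prom3},
    "gene": {SlotId.Gene1, SlotId.Gene2, SlotId.Gene3},
    "terminator": {SlotId.Term1, SlotId.Term2, SlotId.Term3},
    "marker": {SlotId.Marker},
    "insertion_up": {SlotId.InsUp},
    "insertion_down": {SlotId.InsDown},
    "destination_vector": {SlotId.Backbone},
}


@dataclass(frozen=True)
class Brick:
    """A donor-plasmid part of the toolkit.

    ``payload`` is the functional sequence released by BsaI (excluding the
    junction overhangs); ``stuffer`` is the donor backbone filler between
    the two outward recognition sites.  For destination vectors the payload
    is the *E. coli* backbone that is kept and the stuffer is the RFP
    dropout that is lost during assembly.
    """

    id: str
    category: str
    slots: tuple[SlotId, ...]
    left_letter: str
    right_letter: str
    payload: NucSequence
    stuffer: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"brick {self.id}: unknown category {self.category!r}")
        allowed = _CATEGORY_SLOTS[self.category]
        for s in self.slots:
            if s not in allowed:
                raise ValueError(f"brick {self.id}: slot {s.value} illegal for {self.category}")


def donor_plasmid(brick: Brick, overhangs: Mapping[str, str]) -> NucSequence:
    """Synthesize the circular donor plasmid carrying a brick.

    Layout (top strand, circular)::

        [left overhang][payload] [right overhang] A GAGACC [stuffer] GGTCTC A

    The GAGACC (bottom-strand BsaI) cuts at the start of the right overhang
    and the GGTCTC cuts, across the origin, at the start of the left
    overhang, so a digest yields exactly the payload fragment with the
    declared overhangs plus a stuffer fragment retaining both sites.
    """
    l = overhangs[brick.left_letter]
    r = overhangs[brick.right_letter]
    residues = l + brick.payload.residues + r + "A" + "GAGACC" + brick.stuffer + "GGTCTC" + "A"
    return NucSequence(residues, "circular", brick.id)


def payload_fragment(brick: Brick, overhangs: Mapping[str, str]) -> DigestFragment:
    """The sticky-ended insert this brick contributes to the pot."""
    l = overhangs[brick.left_letter]
    r = overhangs[brick.right_letter]
    return DigestFragment(
        NucSequence(l + brick.payload.residues, "linear", brick.id),
        l,
        r,
        provenance=(brick.id, "payload"),
    )


def check_brick(brick: Brick, overhangs: Mapping[str, str]) -> ValidationReport:
    """Verify a brick against the grammar and BsaI geometry.

    Checks that the declared letter pair is legal for the brick's slot(s),
    that the payload is internally BsaI-free, and that a BsaI digest of the
    synthesized donor plasmid releases exactly one fragment whose overhangs
    are the declared letters' sequences.
    """
    report = ValidationReport()
    for letter in (brick.left_letter, brick.right_letter):
        if letter not in overhangs:
            report.add("unknown_letter", f"{brick.id}: letter {letter} not in overhang set", brick.id)
    if report.issues:
        return report

    legal = set()
    for s in brick.slots:
        legal |= allowed_letter_pairs(s)
    pair = (brick.left_letter, brick.right_letter)
    if brick.category == "destination_vector":
        # a (pre)assembled backbone spans the wrap-around arc; its left
        # letter must come later in the A..M walk than its right letter
        if LETTERS.index(brick.left_letter) <= LETTERS.index(brick.right_letter):
            report.add(
                "bad_backbone_arc",
                f"{brick.id}: backbone arc {pair} does not span the origin",
                brick.id,
            )
    elif pair not in legal:
        report.add(
            "illegal_letter_pair",
            f"{brick.id}: letters {pair} not legal for slots "
            f"{[s.value for s in brick.slots]}",
            brick.id,
        )

    for hit in find_recognition_sites(brick.payload, BSAI):
        report.add(
            "internal_bsai",
            f"{brick.id}: internal BsaI site at {hit.position} ({hit.strand})",
            brick.id,
            hit.position,
        )
    if report.issues:
        return report

    frags = digest(donor_plasmid(brick, overhangs), BSAI)
    released = [
        f
        for f in frags
        if f.left_overhang == overhangs[brick.left_letter]
        and f.right_overhang == overhangs[brick.right_letter]
        and f.core.residues == overhangs[brick.left_letter] + brick.payload.residues
    ]
    if len(frags) != 2 or len(released) != 1:
        report.add(
            "bad_release_geometry",
            f"{brick.id}: donor digest yielded {len(frags)} fragments, "
            f"{len(released)} matching the declared overhangs",
            brick.id,
        )
    return report


# ---------------------------------------------------------------------------
# manifest


@dataclass
class ToolkitManifest:
    """Structured inventory of a brick collection.

    The packaged fixture manifest mirrors the published kit: 64 bricks =
    27 promoters + 14 terminators + 6 markers + 10 insertion sequences +
    5 genes + 2 destination vectors (Addgene 120730–120793, recorded as
    provenance metadata only).
    """

    entries: list[dict]
    overhangs: dict[str, str]
    provenance: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.entries)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            out[e["category"]] += 1
        return out

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "overhangs": dict(self.overhangs),
            "bricks": self.entries,
        }


_REQUIRED_ENTRY_FIELDS = ("id", "category", "slots", "left", "right")


def _parse_manifest(data: dict) -> ToolkitManifest:
    if not isinstance(data, dict) or "bricks" not in data:
        raise ValueError("manifest must be a mapping with a 'bricks' list")
    entries = data["bricks"] or []
    overhangs = dict(data.get("overhangs") or DEFAULT_OVERHANGS)
    seen: set[str] = set()
    for e in entries:
        for f in _REQUIRED_ENTRY_FIELDS:
            if f not in e:
                raise ValueError(f"manifest entry missing field {f!r}: {e}")
        if e["category"] not in CATEGORIES:
            raise ValueError(f"manifest entry {e['id']}: unknown category {e['category']!r}")
        for letter in (e["left"], e["right"]):
            if letter not in overhangs:
                raise ValueError(f"manifest entry {e['id']}: unknown letter {letter!r}")
        if e["id"] in seen:
            raise ValueError(f"duplicate brick id {e['id']!r}")
        seen.add(e["id"])
    manifest = ToolkitManifest(
        entries=list(entries),
        overhangs=overhangs,
        provenance=str(data.get("provenance", "")),
    )
    if manifest.counts["destination_vector"] == 0:
        manifest.flags.append("no destination vector")
    return manifest


def load_manifest(path: str | Path) -> ToolkitManifest:
    """Load and validate a YAML toolkit manifest."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _parse_manifest(data)


def save_manifest(manifest: ToolkitManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# toolkit container and GenBank I/O


@dataclass
class Toolkit:
    """A brick collection with its overhang set and manifest."""

    bricks: dict[str, Brick]
    overhangs: dict[str, str]
    manifest: ToolkitManifest

    def brick(self, brick_id: str) -> Brick:
        try:
            return self.bricks[brick_id]
        except KeyError:
            raise KeyError(f"no brick {brick_id!r} in toolkit") from None

    def donor(self, brick_id: str) -> NucSequence:
        return donor_plasmid(self.brick(brick_id), self.overhangs)

    def bricks_in(self, category: str) -> list[Brick]:
        return [b for b in self.bricks.values() if b.category == category]

    def validate(self) -> ValidationReport:
        report = validate_overhang_set(
            [Overhang(k, v) for k, v in sorted(self.overhangs.items())]
        )
        for brick in self.bricks.values():
            sub = check_brick(brick, self.overhangs)
            report.issues.extend(sub.issues)
        return report


_GB_DATE = "01-JAN-2019"  # fixed so fixture output is byte-reproducible


def brick_to_record(brick: Brick, overhangs: Mapping[str, str]) -> SeqRecord:
    """GenBank record of the circular donor plasmid with annotated anatomy."""
    donor = donor_plasmid(brick, overhangs)
    rec = SeqRecord(Seq(donor.residues), id=brick.id, name=brick.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    rec.annotations["date"] = _GB_DATE
    pl = len(brick.payload.residues)
    n = len(donor.residues)
    qual = {
        "label": [brick.id],
        "category": [brick.category],
        "slots": [",".join(s.value for s in brick.slots)],
        "left_letter": [brick.left_letter],
        "right_letter": [brick.right_letter],
        "annotations": [json.dumps(brick.annotations, sort_keys=True)],
    }
    rec.features = [
        SeqFeature(SimpleLocation(4, 4 + pl), type="misc_feature", qualifiers=qual),
        SeqFeature(
            SimpleLocation(0, 4),
            type="misc_feature",
            qualifiers={"label": [f"overhang {brick.left_letter}"]},
        ),
        SeqFeature(
            SimpleLocation(4 + pl, 8 + pl),
            type="misc_feature",
            qualifiers={"label": [f"overhang {brick.right_letter}"]},
        ),
        SeqFeature(
            SimpleLocation(15 + pl, n - 7),
            type="misc_feature",
            qualifiers={"label": ["stuffer"]},
        ),
        SeqFeature(
            SimpleLocation(9 + pl, 15 + pl),
            type="protein_bind",
            qualifiers={"label": ["BsaI"], "direction": ["bottom"]},
        ),
        SeqFeature(
            SimpleLocation(n - 7, n - 1),
            type="protein_bind",
            qualifiers={"label": ["BsaI"], "direction": ["top"]},
        ),
    ]
    return rec


def record_to_brick(rec: SeqRecord) -> Brick:
    """Inverse of :func:`brick_to_record` (exact feature round-trip)."""
    payload_feat = None
    for feat in rec.features:
        if feat.type == "misc_feature" and "category" in feat.qualifiers:
            payload_feat = feat
            break
    if payload_feat is None:
        raise ValueError(f"record {rec.id}: no brick payload feature")
    q = payload_feat.qualifiers
    seq = str(rec.seq)
    start = int(payload_feat.location.start)
    end = int(payload_feat.location.end)
    payload = NucSequence(seq[start:end], "linear", q["label"][0])
    stuffer = seq[end + 11 : len(seq) - 7]
    return Brick(
        id=q["label"][0],
        category=q["category"][0],
        slots=tuple(SlotId(s) for s in q["slots"][0].split(",")),
        left_letter=q["left_letter"][0],
        right_letter=q["right_letter"][0],
        payload=payload,
        stuffer=stuffer,
        annotations=json.loads(q["annotations"][0]),
    )


def write_toolkit_genbank(toolkit: Toolkit, directory: str | Path) -> Path:
    """Write the toolkit as multi-record GenBank + YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gb = directory / "toolkit.gb"
    records = [
        brick_to_record(b, toolkit.overhangs)
        for b in sorted(toolkit.bricks.values(), key=lambda b: b.id)
    ]
    SeqIO.write(records, gb, "genbank")
    save_manifest(toolkit.manifest, directory / "manifest.yaml")
    return gb


def read_toolkit_genbank(directory: str | Path) -> Toolkit:
    directory = Path(directory)
    manifest = load_manifest(directory / "manifest.yaml")
    bricks = {}
    for rec in SeqIO.parse(directory / "toolkit.gb", "genbank"):
        brick = record_to_brick(rec)
        bricks[brick.id] = brick
    return Toolkit(bricks=bricks, overhangs=manifest.overhangs, manifest=manifest)
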