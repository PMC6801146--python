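"""One-pot Golden Gate simulation, split preassembly and design enumeration.

:func:`simulate_one_pot` models the digestion/ligation cycling of a Golden
Gate reaction at its fixed point: every input plasmid is digested with BsaI,
and the product is the unique circular re-closure of sticky-ended fragments
that contains no BsaI recognition site.  Closures that re-create recognition
sites (a dropout re-entering its vector, a payload re-ligating into its
donor stuffer) are unstable under continued cycling and are discarded, which
is exactly the selection the thermocycling programme performs at the bench.

Only exact 4/4 overhang matches ligate; misligation fidelity is not
modelled.  True combinatorial pooling (several bricks competing for one
slot) is expressed through :func:`enumerate_designs`, never by feeding
redundant bricks to :func:`simulate_one_pot`, which keeps the simulator's
uniqueness contract checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct
import random as _random
from typing import Iterator, Mapping, Sequence

from .registry import LETTERS, SlotId, Toolkit, slot_layout
from .seqcore import (
    BSAI,
    DigestFragment,
    NucSequence,
    canonical_form,
    digest,
    find_recognition_sites,
    ligate_cycle,
)

__all__ = [
    "AssemblyDesign",
    "Feature",
    "AssembledConstruct",
    "PreassemblyPlan",
    "OpenJunctionError",
    "AmbiguousClosureError",
    "DesignError",
    "covered_slots",
    "count_fragments",
    "simulate_one_pot",
    "simulate_preassembly_route",
    "plan_preassembly",
    "enumerate_designs",
    "sample_designs",
]

PREASSEMBLY_GROUPS: tuple[tuple[SlotId, ...], ...] = (
    (SlotId.InsUp, SlotId.Marker, SlotId.Prom1, SlotId.Gene1),
    (SlotId.Term1, SlotId.Prom2, SlotId.Gene2, SlotId.Term2),
    (SlotId.Prom3, SlotId.Gene3, SlotId.Term3, SlotId.InsDown),
)


class DesignError(ValueError):
    """An assembly design violates the grammar."""


class OpenJunctionError(ValueError):
    """The pot cannot close a circle; lists the unsatisfied junction letters."""

    def __init__(self, letters: Sequence[str]):
        self.letters = sorted(set(letters))
        super().__init__(f"open junction(s) at letter(s) {', '.join(self.letters)}")


class AmbiguousClosureError(ValueError):
    """More than one stable circular closure exists (bad overhang set)."""

    def __init__(self, closures: Sequence[tuple[str, ...]]):
        self.closures = [tuple(c) for c in closures]
        super().__init__(
            f"{len(closures)} distinct circular closures: "
            + "; ".join(" -> ".join(c) for c in self.closures)
        )


@dataclass(frozen=True)
class AssemblyDesign:
    """A slot → brick-id mapping plus the destination vector."""

    topology: str
    assignments: Mapping[SlotId, str]
    vector_id: str

    def slots_filled(self) -> dict[SlotId, str]:
        return {SlotId(k): v for k, v in self.assignments.items()}


@dataclass(frozen=True)
class Feature:
    slot: str
    brick_id: str
    start: int
    end: int
    strand: int = 1


@dataclass
class AssembledConstruct:
    """A simulated circular assembly product with positional bookkeeping."""

    plasmid: NucSequence
    features: list[Feature]
    junctions: list[tuple[str, str, int]]  # (letter, sequence, position)

    @property
    def canonical(self) -> str:
        return canonical_form(self.plasmid)

    def feature_order(self) -> list[str]:
        return [f.brick_id for f in self.features]


@dataclass(frozen=True)
class PreassemblyPlan:
    """The published 4+4+4 split for a 3-TU assembly."""

    sub_reactions: tuple[tuple[str, ...], ...]
    final_inputs: tuple[str, ...]


def covered_slots(design: AssemblyDesign, toolkit: Toolkit) -> set[SlotId]:
    """Slots already satisfied by the (possibly preassembled) vector.

    A vector whose backbone arc runs from letter ``l`` (late in the walk)
    around the origin to letter ``r`` subsumes every slot whose junction
    pair lies inside that arc — e.g. an arc L→C carries InsDown, Backbone,
    InsUp and Marker preassembled.
    """
    vec = toolkit.brick(design.vector_id)
    layout = slot_layout(design.topology)
    li, ri = LETTERS.index(vec.left_letter), LETTERS.index(vec.right_letter)
    covered = set()
    for slot, l, r in layout:
        a, b = LETTERS.index(l), LETTERS.index(r)
        # arc membership, walking l -> ... -> M -> A -> ... -> r
        inside_left = a >= li or a <= ri
        inside_right = b >= li or b <= ri
        if slot is SlotId.Backbone or (inside_left and inside_right and a != ri and b != li):
            covered.add(slot)
    return covered


def _required_slots(design: AssemblyDesign, toolkit: Toolkit) -> list[tuple[SlotId, str, str]]:
    layout = slot_layout(design.topology)
    covered = covered_slots(design, toolkit)
    return [(s, l, r) for s, l, r in layout if s not in covered]


def validate_design(design: AssemblyDesign, toolkit: Toolkit) -> None:
    """Raise :class:`DesignError` unless every open slot is filled once."""
    toolkit.brick(design.vector_id)
    required = {s for s, _, _ in _required_slots(design, toolkit)}
    filled = set(design.slots_filled())
    missing = required - filled
    extra = filled - required
    if missing:
        raise DesignError(f"unfilled slot(s): {sorted(s.value for s in missing)}")
    if extra:
        raise DesignError(f"slot(s) not in {design.topology} grammar: "
                          f"{sorted(s.value for s in extra)}")
    pairs = {s: (l, r) for s, l, r in slot_layout(design.topology)}
    for slot, brick_id in design.slots_filled().items():
        brick = toolkit.brick(brick_id)
        if slot not in brick.slots:
            raise DesignError(f"brick {brick_id} does not serve slot {slot.value}")
        if (brick.left_letter, brick.right_letter) != pairs[slot]:
            raise DesignError(
                f"brick {brick_id} carries letters "
                f"{brick.left_letter}-{brick.right_letter} but slot {slot.value} "
                f"in a {design.topology} design requires "
                f"{pairs[slot][0]}-{pairs[slot][1]}"
            )


def count_fragments(design: AssemblyDesign, toolkit: Toolkit) -> int:
    """Number of DNA molecules entering the pot (inserts + vector)."""
    validate_design(design, toolkit)
    return len(_required_slots(design, toolkit)) + 1  # inserts + the vector


def _letter_of(overhang_seq: str, overhangs: Mapping[str, str]) -> str:
    for letter, seq in overhangs.items():
        if seq == overhang_seq:
            return letter
    return f"?{overhang_seq}"


def _closures(
    pool: Sequence[DigestFragment], start: DigestFragment
) -> list[tuple[DigestFragment, ...]]:
    """All circular closures from ``start`` using pool fragments at most once."""
    out: list[tuple[DigestFragment, ...]] = []

    def walk(path: list[DigestFragment], used: set[int]):
        tail = path[-1]
        if len(path) > 1 and tail.right_overhang == start.left_overhang:
            out.append(tuple(path))
            # a longer closure through the same point is still possible only
            # if another fragment shares the start's left overhang; keep going
        for i, frag in enumerate(pool):
            if i in used:
                continue
            if frag.right_overhang and tail.right_overhang == frag.left_overhang:
                used.add(i)
                path.append(frag)
                walk(path, used)
                path.pop()
                used.remove(i)

    walk([start], set())
    return out


def _stable(frag: DigestFragment) -> bool:
    return not find_recognition_sites(frag.core, BSAI)


def simulate_one_pot(design: AssemblyDesign, toolkit: Toolkit) -> AssembledConstruct:
    """Simulate the equimolar one-pot BsaI/T4-ligase reaction.

    Digests every input plasmid, then searches the junction graph (edges =
    exact overhang matches) for circular closures built from BsaI-free
    fragments.  Exactly one such closure must exist: it contains the vector
    backbone and every brick payload, and excludes the RFP dropout and all
    donor stuffers, whose fragments retain recognition sites.
    """
    validate_design(design, toolkit)
    slots = design.slots_filled()
    # digest every molecule entering the pot
    pot: list[tuple[SlotId | None, str, DigestFragment]] = []
    for slot, brick_id in sorted(slots.items(), key=lambda kv: kv[0].value):
        for frag in digest(toolkit.donor(brick_id), BSAI):
            pot.append((slot, brick_id, frag))
    for frag in digest(toolkit.donor(design.vector_id), BSAI):
        pot.append((SlotId.Backbone, design.vector_id, frag))

    stable = [(s, b, f) for s, b, f in pot if _stable(f)]
    frag_meta = {id(f): (s, b) for s, b, f in stable}
    pool = [f for _, _, f in stable]

    backbone = None
    vec = toolkit.brick(design.vector_id)
    want_left = toolkit.overhangs[vec.left_letter]
    for s, b, f in stable:
        if b == design.vector_id and f.left_overhang == want_left:
            backbone = f
    if backbone is None:  # pragma: no cover - vector digest always releases it
        raise OpenJunctionError([vec.left_letter])

    closures = [
        c
        for c in _closures([f for f in pool if f is not backbone], backbone)
        if len(c) == len(pool)
    ]
    if not closures:
        # report letters whose in/out degrees over stable fragments disagree
        lefts = [f.left_overhang for f in pool]
        rights = [f.right_overhang for f in pool]
        open_seqs = [s for s in set(lefts) ^ set(rights)]
        unmatched = [s for s in set(lefts + rights)
                     if lefts.count(s) != rights.count(s)]
        letters = [_letter_of(s, toolkit.overhangs) for s in (unmatched or open_seqs)]
        raise OpenJunctionError(letters or ["?"])
    if len(closures) > 1:
        raise AmbiguousClosureError(
            [tuple(frag_meta[id(f)][1] for f in c) for c in closures]
        )

    cycle = closures[0]
    plasmid = ligate_cycle(cycle, name=f"assembly_{design.vector_id}")
    # positional bookkeeping
    features: list[Feature] = []
    junctions: list[tuple[str, str, int]] = []
    inv = {v: k for k, v in toolkit.overhangs.items()}
    pos = 0
    for frag in cycle:
        slot, brick_id = frag_meta[id(frag)]
        parts = getattr(frag, "parts", None) or [
            (slot.value if slot else "", brick_id, len(frag.core))
        ]
        offset = pos
        for slot_name, part_id, length in parts:
            features.append(Feature(slot_name, part_id, offset, offset + length))
            offset += length
        junctions.append((inv.get(frag.left_overhang, "?"), frag.left_overhang, pos))
        pos += len(frag.core)
    assert not find_recognition_sites(plasmid, BSAI), "product must be BsaI-free"
    return AssembledConstruct(plasmid=plasmid, features=features, junctions=junctions)


def plan_preassembly(design: AssemblyDesign, toolkit: Toolkit) -> PreassemblyPlan:
    """Split a 3-TU design into the published three 4-part sub-reactions.

    The split (InsUp-Marker-Prom1-Gene1, Term1-Prom2-Gene2-Term2,
    Prom3-Gene3-Term3-InsDown) is defined only for full 3-TU designs; the
    final reaction receives the three preassemblies plus the destination
    vector.
    """
    if design.topology != "3TU":
        raise DesignError("preassembly split is defined only for 3-TU designs")
    validate_design(design, toolkit)
    slots = design.slots_filled()
    if set(slots) != {s for g in PREASSEMBLY_GROUPS for s in g}:
        raise DesignError("preassembly split requires all twelve insert slots")
    subs = tuple(tuple(slots[s] for s in group) for group in PREASSEMBLY_GROUPS)
    return PreassemblyPlan(
        sub_reactions=subs,
        final_inputs=tuple(f"preassembly_{i+1}" for i in range(3)) + (design.vector_id,),
    )


def _ligate_linear(
    frags: Sequence[DigestFragment], parts: list[tuple[str, str, int]], name: str
) -> DigestFragment:
    for up, down in zip(frags, frags[1:]):
        if up.right_overhang != down.left_overhang:
            raise ValueError("preassembly overhang mismatch")
    core = "".join(f.core.residues for f in frags)
    merged = DigestFragment(
        NucSequence(core, "linear", name),
        frags[0].left_overhang,
        frags[-1].right_overhang,
        provenance=(name,),
    )
    object.__setattr__(merged, "parts", parts)
    return merged


def simulate_preassembly_route(
    design: AssemblyDesign, toolkit: Toolkit
) -> AssembledConstruct:
    """Run the two-stage route: three sub-reactions, then the multigene pot.

    The product is canonical-form identical to the direct one-pot product
    for any valid design (route equivalence).
    """
    plan = plan_preassembly(design, toolkit)
    slots = design.slots_filled()
    linears: list[DigestFragment] = []
    for i, group in enumerate(PREASSEMBLY_GROUPS):
        frags, parts = [], []
        for slot in group:
            brick = toolkit.brick(slots[slot])
            released = [
                f for f in digest(toolkit.donor(brick.id), BSAI) if _stable(f)
            ]
            assert len(released) == 1
            frags.append(released[0])
            parts.append((slot.value, brick.id, len(released[0].core)))
        linears.append(_ligate_linear(frags, parts, f"preassembly_{i+1}"))

    vec_frags = [f for f in digest(toolkit.donor(design.vector_id), BSAI)]
    stable_pool = [f for f in vec_frags if _stable(f)] + linears
    backbone = stable_pool[0]
    closures = [
        c for c in _closures(stable_pool[1:], backbone) if len(c) == len(stable_pool)
    ]
    if len(closures) != 1:
        raise AmbiguousClosureError([tuple(f.core.name for f in c) for c in closures])
    cycle = closures[0]
    plasmid = ligate_cycle(cycle, name=f"assembly_{design.vector_id}")
    inv = {v: k for k, v in toolkit.overhangs.items()}
    features, junctions, pos = [], [], 0
    for frag in cycle:
        parts = getattr(frag, "parts", None) or [
            ("Backbone", design.vector_id, len(frag.core))
        ]
        offset = pos
        for slot_name, part_id, length in parts:
            features.append(Feature(slot_name, part_id, offset, offset + length))
            offset += length
        junctions.append((inv.get(frag.left_overhang, "?"), frag.left_overhang, pos))
        pos += len(frag.core)
    assert not find_recognition_sites(plasmid, BSAI)
    return AssembledConstruct(plasmid=plasmid, features=features, junctions=junctions)


# ---------------------------------------------------------------------------
# combinatorial enumeration


def enumerate_designs(
    topology: str,
    options: Mapping[SlotId, Sequence[str]],
    vector_id: str,
) -> tuple[Iterator[AssemblyDesign], int]:
    """Deterministic iterator over the full combinatorial design space.

    Returns ``(iterator, count)`` where ``count`` is the product of per-slot
    option counts.  Iteration is lexicographic by slot name, then brick id.
    """
    opts = {SlotId(k): sorted(v) for k, v in options.items()}
    for slot, choices in opts.items():
        if not choices:
            raise DesignError(f"no options for slot {slot.value}")
    slot_order = sorted(opts, key=lambda s: s.value)
    count = 1
    for slot in slot_order:
        count *= len(opts[slot])

    def _iter() -> Iterator[AssemblyDesign]:
        for combo in _iterproduct(*(opts[s] for s in slot_order)):
            yield AssemblyDesign(
                topology=topology,
                assignments=dict(zip(slot_order, combo)),
                vector_id=vector_id,
            )

    return _iter(), count


def sample_designs(
    topology: str,
    options: Mapping[SlotId, Sequence[str]],
    vector_id: str,
    k: int,
    seed: int,
) -> list[AssemblyDesign]:
    """Seeded uniform sample of ``k`` designs from the combinatorial space."""
    opts = {SlotId(kk): sorted(v) for kk, v in options.items()}
    rng = _random.Random(seed)
    slot_order = sorted(opts, key=lambda s: s.value)
    out = []
    for _ in range(k):
        out.append(
            AssemblyDesign(
                topology=topology,
                assignments={s: rng.choice(opts[s]) for s in slot_order},
                vector_id=vector_id,
            )
        )
    return out
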