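"""Nucleotide sequence model and Type IIS digestion with exact cut geometry.

The whole toolkit rests on three primitives defined here:

* :class:`NucSequence` — a strictly ACGT, linear or circular double-stranded
  molecule represented by its top strand;
* :func:`find_recognition_sites` / :func:`digest` — restriction scanning and
  cutting for enzymes that either cut downstream of their recognition
  sequence (Type IIS, BsaI) or within it (NotI), producing fragments with
  4-nt 5'-protruding overhangs;
* :func:`canonical_form` — a rotation/strand-invariant string key for
  circular molecules, used for all product-equality assertions.

Overhang convention
-------------------
Every overhang is recorded as top-strand 5'→3' text at the junction.  A
fragment's ``core`` is the top-strand interval from its own left (top-strand)
cut to the next fragment's left cut, so the core *includes* the fragment's
left overhang and the sum of core lengths equals the parent length for a
circular digest.  Two fragments ligate when the upstream fragment's
``right_overhang`` string equals the downstream fragment's ``left_overhang``
(Watson–Crick pairing is implicit in this single-strand convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "NucSequence",
    "EnzymeSpec",
    "SiteHit",
    "DigestFragment",
    "AmbiguousBaseError",
    "DegenerateCutError",
    "BSAI",
    "NOTI",
    "BUILTIN_ENZYMES",
    "revcomp",
    "find_recognition_sites",
    "digest",
    "ligate_cycle",
    "canonical_form",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

Topology = Literal["linear", "circular"]
Strand = Literal["top", "bottom"]


class AmbiguousBaseError(ValueError):
    """Raised when a sequence contains a base outside {A,C,G,T}."""

    def __init__(self, name: str, position: int, base: str):
        self.position = position
        self.base = base
        super().__init__(
            f"sequence {name!r} has non-ACGT base {base!r} at position {position}; "
            "IUPAC ambiguity codes are not accepted"
        )


class DegenerateCutError(ValueError):
    """Raised when two cut events are too close to yield intact overhangs."""


def revcomp(s: str) -> str:
    """Reverse complement of a top-strand string (involution)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A fully specified DNA molecule, represented by its top strand.

    Parameters
    ----------
    residues:
        Top strand, 5'→3', uppercase ACGT only.
    topology:
        ``"linear"`` or ``"circular"``.  Circular molecules have no natural
        origin; compare them via :func:`canonical_form`.
    name:
        Free-text label carried through digests and assemblies.
    """

    residues: str
    topology: Topology = "linear"
    name: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        for i, b in enumerate(self.residues):
            if b not in _VALID:
                raise AmbiguousBaseError(self.name, i, b)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(revcomp(self.residues), self.topology, self.name)

    def window(self, start: int, end: int) -> str:
        """Top-strand slice [start, end), wrapping the origin if circular."""
        n = len(self.residues)
        if self.is_circular:
            length = end - start
            start %= n
            end = start + length
            if end <= n:
                return self.residues[start:end]
            return self.residues[start:] + self.residues[: end - n]
        return self.residues[start:end]


@dataclass(frozen=True)
class EnzymeSpec:
    """Restriction enzyme geometry.

    ``downstream_typeIIS`` enzymes nick the top strand ``spacer_len`` nt
    downstream of the recognition sequence and the bottom strand
    ``spacer_len + overhang_len`` nt downstream, leaving a 5' overhang of
    ``overhang_len`` nt.  ``within_site`` enzymes (palindromic cutters such
    as NotI) cut symmetrically inside the recognition sequence.
    """

    name: str
    recognition: str
    spacer_len: int
    overhang_len: int
    cut_kind: Literal["downstream_typeIIS", "within_site"]

    def __post_init__(self):
        if len(self.recognition) < 6:
            raise ValueError("recognition sequence must be at least 6 nt")
        if self.overhang_len < 0:
            raise ValueError("overhang_len must be non-negative")
        if self.cut_kind == "within_site":
            if (len(self.recognition) - self.overhang_len) % 2:
                raise ValueError("within_site cut must be symmetric")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


BSAI = EnzymeSpec("BsaI", "GGTCTC", 1, 4, "downstream_typeIIS")
NOTI = EnzymeSpec("NotI", "GCGGCCGC", 0, 4, "within_site")

BUILTIN_ENZYMES: dict[str, EnzymeSpec] = {"BsaI": BSAI, "NotI": NOTI}


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence.

    ``position`` is the 0-based start of the occurrence in top-strand
    coordinates (for bottom-strand hits, the start of the reverse-complement
    of the recognition sequence as it reads on the top strand).
    """

    position: int
    strand: Strand


@dataclass(frozen=True)
class DigestFragment:
    """A double-stranded digestion product with sticky ends.

    ``core`` spans top-strand [own left cut, next left cut); it therefore
    starts with this fragment's ``left_overhang``.  ``right_overhang`` is the
    4 nt that the partner fragment contributes at the downstream junction.
    Blunt (uncut linear) ends carry the empty string.
    """

    core: NucSequence
    left_overhang: str
    right_overhang: str
    provenance: tuple = ()

    def __len__(self) -> int:
        return len(self.core)

    def extended(self) -> str:
        """Top strand including the downstream overhang context.

        Under strand flip the extended string maps to its reverse
        complement, which makes ``min(extended, revcomp(extended))`` a
        strand-invariant fragment key.
        """
        return self.core.residues + self.right_overhang

    def duplex_key(self) -> str:
        e = self.extended()
        return min(e, revcomp(e))


def find_recognition_sites(seq: NucSequence, enzyme: EnzymeSpec) -> list[SiteHit]:
    """Every exact occurrence of the recognition sequence on either strand.

    Circular sequences are scanned across the origin.  Palindromic
    recognition sequences are reported once (as top-strand hits), since the
    two strand readings denote the same physical site.
    """
    hits: list[SiteHit] = []
    pats: list[tuple[str, Strand]] = [(enzyme.recognition, "top")]
    if not enzyme.is_palindromic:
        pats.append((revcomp(enzyme.recognition), "bottom"))
    n = len(seq)
    for pat, strand in pats:
        text = seq.residues
        if seq.is_circular:
            text = text + text[: len(pat) - 1]
        start = 0
        while True:
            i = text.find(pat, start)
            if i < 0 or i >= n:
                break
            hits.append(SiteHit(i, strand))
            start = i + 1
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _cut_positions(seq: NucSequence, enzyme: EnzymeSpec) -> list[tuple[int, SiteHit]]:
    """Top-strand cut coordinates (fragment boundaries) for every site.

    For a top-strand Type IIS site starting at p the top strand is cleaved
    at ``p + len(recognition) + spacer_len``; for a bottom-strand site the
    enzyme reads leftward and the top-strand cleavage lands at
    ``p - spacer_len - overhang_len``.  ``within_site`` enzymes cut at the
    symmetric offset inside the site.  Cuts whose overhang would run off a
    linear molecule's end are not made.
    """
    n = len(seq)
    out: list[tuple[int, SiteHit]] = []
    for hit in find_recognition_sites(seq, enzyme):
        if enzyme.cut_kind == "downstream_typeIIS":
            if hit.strand == "top":
                t = hit.position + len(enzyme.recognition) + enzyme.spacer_len
            else:
                t = hit.position - enzyme.spacer_len - enzyme.overhang_len
        else:
            t = hit.position + (len(enzyme.recognition) - enzyme.overhang_len) // 2
        if seq.is_circular:
            out.append((t % n, hit))
        else:
            # both strand cleavages must fall strictly inside a linear
            # molecule; a cut on the terminus is a nick, not a fragmentation
            if 0 < t and t + enzyme.overhang_len < n:
                out.append((t, hit))
    return out


def digest(seq: NucSequence, enzyme: EnzymeSpec) -> list[DigestFragment]:
    """Cut ``seq`` with ``enzyme``, returning sticky-ended fragments.

    Zero sites return the molecule intact as a single fragment.  The
    fragment multiset of a circular molecule is invariant under rotation of
    the input, and total residues are conserved.

    Raises
    ------
    DegenerateCutError
        If two cut events are closer than ``overhang_len`` (overlapping
        overhang regions), naming both sites.
    """
    n = len(seq)
    cuts = _cut_positions(seq, enzyme)
    # distinct cut coordinates, keeping one representative hit per cut
    by_pos: dict[int, SiteHit] = {}
    for t, hit in cuts:
        by_pos.setdefault(t, hit)
    positions = sorted(by_pos)
    if not positions:
        return [
            DigestFragment(seq, "", "", provenance=(seq.name, 0, n))
        ]
    # adjacent cuts must leave room for both overhangs
    ordered = positions + ([positions[0] + n] if seq.is_circular else [])
    for a, b in zip(ordered, ordered[1:]):
        if b - a < enzyme.overhang_len:
            ha, hb = by_pos[a % n], by_pos[b % n]
            raise DegenerateCutError(
                f"{enzyme.name} cuts at {a % n} and {b % n} overlap "
                f"(sites at {ha.position}/{ha.strand} and {hb.position}/{hb.strand})"
            )
    frags: list[DigestFragment] = []
    L = enzyme.overhang_len
    if seq.is_circular:
        for a, b in zip(positions, positions[1:] + [positions[0] + n]):
            core = seq.window(a, b)
            frags.append(
                DigestFragment(
                    NucSequence(core, "linear", seq.name),
                    seq.window(a, a + L),
                    seq.window(b, b + L),
                    provenance=(seq.name, a, b % n),
                )
            )
    else:
        bounds = [0] + positions + [n]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            if a == b:
                continue
            left = seq.residues[a : a + L] if a in by_pos else ""
            right = seq.residues[b : b + L] if b in by_pos else ""
            frags.append(
                DigestFragment(
                    NucSequence(seq.residues[a:b], "linear", seq.name),
                    left,
                    right,
                    provenance=(seq.name, a, b),
                )
            )
    return frags


def ligate_cycle(fragments: Iterable[DigestFragment], name: str = "") -> NucSequence:
    """Ligate fragments in the given order into a circular molecule.

    Adjacent right/left overhangs must match, including the wrap-around
    junction; the product's top strand is the concatenation of the cores.
    """
    frags = list(fragments)
    if not frags:
        raise ValueError("nothing to ligate")
    for up, down in zip(frags, frags[1:] + frags[:1]):
        if not up.right_overhang or up.right_overhang != down.left_overhang:
            raise ValueError(
                f"overhang mismatch at junction: {up.right_overhang!r} vs "
                f"{down.left_overhang!r}"
            )
    return NucSequence("".join(f.core.residues for f in frags), "circular", name)


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically minimal rotation in O(n)."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def canonical_form(seq: NucSequence) -> str:
    """Rotation/strand-invariant key for circular molecules.

    Circular sequences map to the lexicographically minimal rotation over
    both strands, so molecules equal up to rotation and/or strand flip yield
    identical strings.  Linear sequences are returned unchanged.
    """
    if not seq.is_circular:
        return seq.residues
    return min(_least_rotation(seq.residues), _least_rotation(revcomp(seq.residues)))
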