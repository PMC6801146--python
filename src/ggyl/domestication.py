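"""Codon-preserving removal of forbidden restriction sites; adapter primers.

Bricks destined for the toolkit must be free of internal BsaI recognition
sites, since any internal site would be cut during the one-pot reaction.
:func:`domesticate_cds` removes such sites from coding sequences by
synonymous single-codon substitution: for each forbidden occurrence
(either strand), the codons it overlaps are tried left to right, preferring
third-position changes, and the first substitution that destroys the site
without creating a new one anywhere is applied.  The protein sequence is
untouched by construction.

:func:`design_adapter_primers` produces the PCR primers that convert any
linear template into a brick: a 5' tail of BsaI recognition + 1-nt spacer +
the slot's 4-nt junction overhang, followed by a template-annealing region
extended 3'-ward until a target melting temperature is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data import CodonTable as _BioCodonTable

from .seqcore import (
    BSAI,
    EnzymeSpec,
    NucSequence,
    digest,
    find_recognition_sites,
    revcomp,
)

__all__ = [
    "CodonTable",
    "standard_table",
    "Edit",
    "UnresolvableSiteError",
    "domesticate_cds",
    "PrimerPair",
    "wallace_tm",
    "design_adapter_primers",
]


@dataclass(frozen=True)
class CodonTable:
    """Genetic code as codon→amino-acid and amino-acid→codons maps.

    Stop codons are keyed by ``"*"``.  Only synonymy is used here; codon
    *optimization* (host codon-usage bias) is a separate, external concern.
    """

    codon_to_aa: Mapping[str, str]
    aa_to_codons: Mapping[str, tuple[str, ...]]

    def translate(self, cds: str) -> str:
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        return "".join(self.codon_to_aa[cds[i : i + 3]] for i in range(0, len(cds), 3))

    def synonyms(self, codon: str) -> tuple[str, ...]:
        return tuple(c for c in self.aa_to_codons[self.codon_to_aa[codon]] if c != codon)


def standard_table() -> CodonTable:
    """The standard genetic code (64 codons, stops as ``"*"``)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    c2a = dict(bio.forward_table)
    for stop in bio.stop_codons:
        c2a[stop] = "*"
    a2c: dict[str, list[str]] = {}
    for codon in sorted(c2a):
        a2c.setdefault(c2a[codon], []).append(codon)
    return CodonTable(c2a, {aa: tuple(cs) for aa, cs in a2c.items()})


@dataclass(frozen=True)
class Edit:
    """One synonymous codon substitution applied during domestication."""

    codon_index: int
    before: str
    after: str
    enzyme: str
    site_position: int
    site_strand: str


class UnresolvableSiteError(ValueError):
    def __init__(self, enzyme: str, position: int, strand: str):
        self.enzyme = enzyme
        self.position = position
        self.strand = strand
        super().__init__(
            f"{enzyme} site at {position} ({strand} strand) cannot be removed "
            "by any synonymous single-codon substitution"
        )


def _all_sites(seq: str, forbidden: Sequence[EnzymeSpec]):
    nuc = NucSequence(seq, "linear", "cds")
    out = []
    for enz in forbidden:
        for hit in find_recognition_sites(nuc, enz):
            out.append((hit.position, hit.strand, enz))
    out.sort(key=lambda t: (t[0], t[2].name, t[1]))
    return out


def _candidate_codons(codon: str, table: CodonTable) -> list[str]:
    """Synonyms ordered: third-position-only changes first, then the rest,
    lexicographic within each group (deterministic edit preference)."""
    syn = table.synonyms(codon)
    third = sorted(c for c in syn if c[:2] == codon[:2])
    rest = sorted(c for c in syn if c[:2] != codon[:2])
    return third + rest


def domesticate_cds(
    cds: NucSequence,
    forbidden: Sequence[EnzymeSpec] = (BSAI,),
    table: CodonTable | None = None,
) -> tuple[NucSequence, list[Edit]]:
    """Remove all forbidden recognition sites from a CDS, silently.

    Scans left to right; each site is resolved by the first synonymous
    single-codon substitution (third-position changes preferred) that
    removes it without introducing a new forbidden site anywhere, verified
    by a full re-scan after each edit.  The translation of the output is
    identical to the input's.

    Raises
    ------
    UnresolvableSiteError
        If no overlapping codon admits a working synonymous substitution
        (e.g. the site spans only Met/Trp codons).
    """
    table = table or standard_table()
    if len(cds.residues) % 3:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.residues.startswith("ATG"):
        warnings.warn(f"CDS {cds.name!r} does not start with ATG", stacklevel=2)

    seq = cds.residues
    edits: list[Edit] = []
    while True:
        sites = _all_sites(seq, forbidden)
        if not sites:
            break
        pos, strand, enz = sites[0]
        before_set = {(p, s, e.name) for p, s, e in sites}
        span = range(pos // 3, (pos + len(enz.recognition) - 1) // 3 + 1)
        fixed = False
        for ci in span:
            codon = seq[ci * 3 : ci * 3 + 3]
            if len(codon) < 3:
                continue
            for alt in _candidate_codons(codon, table):
                trial = seq[: ci * 3] + alt + seq[ci * 3 + 3 :]
                after = {(p, s, e.name) for p, s, e in _all_sites(trial, forbidden)}
                if (pos, strand, enz.name) not in after and after <= before_set:
                    seq = trial
                    edits.append(Edit(ci, codon, alt, enz.name, pos, strand))
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise UnresolvableSiteError(enz.name, pos, strand)
    return NucSequence(seq, "linear", cds.name), edits


# ---------------------------------------------------------------------------
# adapter primers


#: Spacer between the BsaI recognition sequence and the junction overhang in
#: primer tails; 1 nt matches the BsaI N1/N5 cut geometry with minimal tail.
TAIL_SPACER = "A"

MIN_ANNEAL = 18


def wallace_tm(s: str) -> float:
    """Wallace rule melting temperature: 2 °C per A/T + 4 °C per G/C.

    Deliberately simple and dependency-free; adequate for ranking annealing
    lengths.  Swap in another rule via the ``tm_rule`` argument of
    :func:`design_adapter_primers` if needed.
    """
    return 2.0 * sum(s.count(b) for b in "AT") + 4.0 * sum(s.count(b) for b in "GC")


@dataclass(frozen=True)
class PrimerPair:
    """Adapter primers whose amplicon digests into a slot-ready brick."""

    forward: str
    reverse: str
    forward_anneal: int
    reverse_anneal: int
    forward_tm: float
    reverse_tm: float
    template_name: str = ""

    def amplicon(self, template: NucSequence) -> NucSequence:
        """The simulated PCR product: tails + full template."""
        fwd_tail = self.forward[: len(self.forward) - self.forward_anneal]
        rev_tail = self.reverse[: len(self.reverse) - self.reverse_anneal]
        return NucSequence(
            fwd_tail + template.residues + revcomp(rev_tail),
            "linear",
            f"amplicon_{template.name}",
        )


def design_adapter_primers(
    template: NucSequence,
    left_letter: str,
    right_letter: str,
    overhangs: Mapping[str, str],
    tm_target: float = 55.0,
    tm_rule=wallace_tm,
) -> PrimerPair:
    """Design primers that add BsaI flanks with the slot's junction overhangs.

    The forward primer is ``GGTCTC + A + left overhang + template start``;
    the reverse primer is the bottom-strand mirror carrying the right
    overhang.  Annealing regions start at 18 nt and are extended 3'-ward
    until the estimated melting temperature reaches ``tm_target``.  BsaI
    digestion of the simulated amplicon releases exactly
    ``left overhang + template`` with the right overhang exposed.
    """
    if template.is_circular:
        raise ValueError("template must be linear")
    if len(template) < 2 * MIN_ANNEAL + 4:
        raise ValueError(f"template shorter than {2 * MIN_ANNEAL + 4} nt")
    for letter in (left_letter, right_letter):
        if letter not in overhangs:
            raise ValueError(f"letter {letter!r} not in the junction grammar")
    if find_recognition_sites(template, BSAI):
        warnings.warn(
            f"template {template.name!r} contains internal BsaI site(s); "
            "domesticate before amplification",
            stacklevel=2,
        )

    def anneal_len(seq3: str) -> int:
        n = MIN_ANNEAL
        while n < len(seq3) and tm_rule(seq3[:n]) < tm_target:
            n += 1
        return n

    fwd_seed = template.residues
    rev_seed = revcomp(template.residues)
    fa = anneal_len(fwd_seed)
    ra = anneal_len(rev_seed)
    fwd = BSAI.recognition + TAIL_SPACER + overhangs[left_letter] + fwd_seed[:fa]
    rev = (
        BSAI.recognition
        + TAIL_SPACER
        + revcomp(overhangs[right_letter])
        + rev_seed[:ra]
    )
    return PrimerPair(
        forward=fwd,
        reverse=rev,
        forward_anneal=fa,
        reverse_anneal=ra,
        forward_tm=tm_rule(fwd_seed[:fa]),
        reverse_tm=tm_rule(rev_seed[:ra]),
        template_name=template.name,
    )
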