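"""In-silico construct QC and bench-protocol generation.

QC mirrors what is done after an assembly at the bench: NotI digestion to
release the integration cassette before yeast transformation, colony-PCR
amplicon sizing for screening white colonies, and the bookkeeping of
locus-integration screens (positives over screened transformants as a
percentage).  Protocol generation reproduces the published one-pot,
preassembly and multigene reaction recipes verbatim, as structured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

from .assembler import AssembledConstruct
from .seqcore import NOTI, NucSequence, digest, find_recognition_sites, revcomp

__all__ = [
    "ProgramBlock",
    "ReactionProtocol",
    "make_protocol",
    "pmol_to_mass",
    "integration_rate",
    "IntegrationRecord",
    "NotIFragment",
    "QCReport",
    "notI_release",
    "CannotLinearizeError",
    "colony_pcr",
    "Amplicon",
]

DSDNA_GRAMS_PER_MOLE_PER_BP = 650.0  # average molar mass of one base pair


class CannotLinearizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class ProgramBlock:
    """A thermocycler block: ordered (temperature °C, minutes) × cycles."""

    steps: tuple[tuple[float, float], ...]
    cycles: int


@dataclass(frozen=True)
class ReactionProtocol:
    """One Golden Gate reaction recipe, exactly as published."""

    stage: str
    n_fragments: int
    per_fragment_pmol: float
    bsai_units: float
    ligase_units: float
    buffer_ul: float
    final_volume_ul: float
    programme: tuple[ProgramBlock, ...]
    hold_c: float = 15.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["programme"] = [
            {"steps": [list(s) for s in b.steps], "cycles": b.cycles}
            for b in self.programme
        ]
        return d

    def render(self) -> str:
        lines = [
            f"Stage: {self.stage}",
            f"Fragments: {self.n_fragments} x {self.per_fragment_pmol:g} pmol (equimolar)",
            f"BsaI: {self.bsai_units:g} U   T4 ligase: {self.ligase_units:g} U",
            f"T4 ligase buffer: {self.buffer_ul:g} ul   final volume: {self.final_volume_ul:g} ul (ddH2O)",
            "Thermocycler:",
        ]
        for block in self.programme:
            inner = ", ".join(f"{t:g} C for {m:g} min" for t, m in block.steps)
            lines.append(f"  [{inner}] x {block.cycles}")
        lines.append(f"  {self.hold_c:g} C hold")
        return "\n".join(lines)


_FINAL_STEPS = ((55.0, 5.0), (80.0, 5.0))

_STAGES = {
    "standard_one_pot": dict(
        per_fragment_pmol=50.0,
        bsai_units=5.0,
        ligase_units=200.0,
        buffer_ul=2.0,
        final_volume_ul=20.0,
        programme=(
            ProgramBlock(((37.0, 5.0), (16.0, 2.0)), 60),
            ProgramBlock(_FINAL_STEPS, 1),
        ),
    ),
    "preassembly": dict(
        per_fragment_pmol=50.0,
        bsai_units=5.0,
        ligase_units=200.0,
        buffer_ul=1.0,
        final_volume_ul=10.0,
        programme=(
            ProgramBlock(((37.0, 3.0), (16.0, 2.0)), 30),
            ProgramBlock(_FINAL_STEPS, 1),
        ),
    ),
    "multigene_final": dict(
        per_fragment_pmol=50.0,
        bsai_units=20.0,
        ligase_units=400.0,
        buffer_ul=4.0,
        final_volume_ul=40.0,
        programme=(
            ProgramBlock(((37.0, 5.0), (16.0, 5.0)), 50),
            ProgramBlock(_FINAL_STEPS, 1),
        ),
    ),
}


def make_protocol(stage: str, n_fragments: int) -> ReactionProtocol:
    """The published recipe for an assembly stage.

    ``standard_one_pot``: 50 pmol per fragment, 5 U BsaI, 200 U T4 ligase,
    2 µl buffer, 20 µl final, [37 °C 5'/16 °C 2']×60 then 55 °C 5', 80 °C 5'.
    ``preassembly``: 10 µl final, [37 °C 3'/16 °C 2']×30.
    ``multigene_final``: 20 U BsaI, 400 U ligase, 4 µl buffer, 40 µl final,
    [37 °C 5'/16 °C 5']×50.
    """
    if n_fragments < 2:
        raise ValueError("an assembly needs at least 2 fragments")
    try:
        params = _STAGES[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(_STAGES)}")
    return ReactionProtocol(stage=stage, n_fragments=n_fragments, **params)


def pmol_to_mass(pmol: float, length_bp: int, grams_per_mole_per_bp: float = DSDNA_GRAMS_PER_MOLE_PER_BP) -> float:
    """Convert a molar amount of dsDNA to nanograms.

    ng = pmol × length_bp × (g·mol⁻¹·bp⁻¹) × 10⁻³; the default molar mass
    per base pair is 650 g/mol.
    """
    if pmol < 0 or length_bp < 0:
        raise ValueError("amounts must be non-negative")
    return pmol * length_bp * grams_per_mole_per_bp * 1e-3


def integration_rate(
    positives: int, screened: int, policy: Literal["round", "truncate"] = "round"
) -> int:
    """Integration rate as a whole percent, with an explicit rounding policy.

    ``round`` is round-half-up; ``truncate`` drops the fractional part.
    The two disagree for e.g. 11/24 (45.83% → 46 vs 45), so reports must
    always state which policy produced the figure.
    """
    if screened <= 0:
        raise ValueError("screened must be positive")
    if not 0 <= positives <= screened:
        raise ValueError("need 0 <= positives <= screened")
    percent = 100.0 * positives / screened
    if policy == "round":
        return int(percent + 0.5)
    if policy == "truncate":
        return int(percent)
    raise ValueError(f"unknown policy {policy!r}")


@dataclass(frozen=True)
class IntegrationRecord:
    locus: str
    positives: int
    screened: int
    policy: str
    percent: int

    @classmethod
    def compute(cls, locus: str, positives: int, screened: int, policy: str = "round"):
        return cls(locus, positives, screened, policy,
                   integration_rate(positives, screened, policy))


# ---------------------------------------------------------------------------
# NotI cassette release


@dataclass(frozen=True)
class NotIFragment:
    length: int
    start: int
    end: int
    is_cassette: bool


@dataclass
class QCReport:
    plasmid_name: str
    plasmid_length: int
    notI_fragments: list[NotIFragment] = field(default_factory=list)
    cassette_found: bool = False
    cassette_coords: tuple[int, int] | None = None
    amplicons: list["Amplicon"] = field(default_factory=list)
    integration: list[IntegrationRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "plasmid": self.plasmid_name,
            "plasmid_length": self.plasmid_length,
            "notI_fragment_sizes": [f.length for f in self.notI_fragments],
            "cassette_found": self.cassette_found,
            "cassette_coords": list(self.cassette_coords) if self.cassette_coords else None,
            "amplicon_sizes": [a.length for a in self.amplicons],
            "integration": [asdict(r) for r in self.integration],
            "warnings": list(self.warnings),
        }


def _spans_overlap_circular(a0, a1, b0, b1, n) -> bool:
    """Overlap of [a0,a1) and [b0,b1) on a circle of size n."""
    def unroll(s, e):
        return [(s, e)] if s <= e else [(s, n), (0, e)]

    for x0, x1 in unroll(a0 % n, a1 % n if a1 % n else n):
        for y0, y1 in unroll(b0 % n, b1 % n if b1 % n else n):
            if x0 < y1 and y0 < x1:
                return True
    return False


def notI_release(construct: AssembledConstruct) -> QCReport:
    """Predict the NotI linearization that releases the integration cassette.

    The cassette is the fragment overlapping both the InsUp and the InsDown
    features.  Constructs whose insertion flanks carry NotI sites at their
    outer edges (ZETA-NotI style) yield exactly two fragments: cassette and
    bacterial backbone.
    """
    plasmid = construct.plasmid
    if not plasmid.is_circular:
        raise ValueError("construct must be circular")
    report = QCReport(plasmid_name=plasmid.name, plasmid_length=len(plasmid))
    if not find_recognition_sites(plasmid, NOTI):
        raise CannotLinearizeError(f"{plasmid.name}: no NotI site; cannot linearize")
    frags = digest(plasmid, NOTI)

    ins_feats = [
        f for f in construct.features if f.slot in ("InsUp", "InsDown")
    ]
    n = len(plasmid)
    for frag in frags:
        _, start, end_raw = frag.provenance
        end = end_raw if end_raw > start else end_raw + n
        hit_slots = {
            f.slot
            for f in ins_feats
            if _spans_overlap_circular(start, end, f.start, f.end, n)
        }
        is_cassette = {"InsUp", "InsDown"} <= hit_slots
        report.notI_fragments.append(
            NotIFragment(len(frag.core), start, end_raw, is_cassette)
        )
        if is_cassette:
            report.cassette_found = True
            report.cassette_coords = (start, end_raw)
    if not report.cassette_found and ins_feats:
        report.warnings.append(
            "cassette split: no single NotI fragment spans InsUp..InsDown"
        )
    assert sum(f.length for f in report.notI_fragments) == n
    return report


# ---------------------------------------------------------------------------
# colony PCR


@dataclass(frozen=True)
class Amplicon:
    forward_start: int
    reverse_start: int
    length: int


def colony_pcr(
    template: NucSequence, fwd: str, rev: str
) -> list[Amplicon]:
    """Predict colony-PCR products by exact primer matching.

    A product is defined by a forward-primer match on the top strand and a
    downstream reverse-primer match on the bottom strand; length is measured
    primer start to primer start, inclusive.  Circular templates are scanned
    across the origin.  Degenerate or mismatched priming is out of scope.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")

    def occurrences(pattern: str) -> list[int]:
        text = template.residues
        n = len(text)
        if template.is_circular:
            text = text + text[: len(pattern) - 1]
        out, start = [], 0
        while True:
            i = text.find(pattern, start)
            if i < 0 or i >= n:
                break
            out.append(i)
            start = i + 1
        return out

    fwd_hits = occurrences(fwd)
    rev_hits = occurrences(revcomp(rev))  # bottom-strand primer sites
    n = len(template)
    products: list[Amplicon] = []
    for fp in fwd_hits:
        for rp in rev_hits:
            rev_primer_start = rp + len(rev) - 1  # 5' end of the reverse primer
            if template.is_circular:
                length = (rev_primer_start - fp) % n + 1
                products.append(Amplicon(fp, rev_primer_start % n, length))
            else:
                if rev_primer_start >= fp + len(fwd):
                    products.append(
                        Amplicon(fp, rev_primer_start, rev_primer_start - fp + 1)
                    )
    if len(fwd_hits) > 1 or len(rev_hits) > 1:
        warnings.warn(
            f"primer(s) match multiple sites ({len(fwd_hits)} forward, "
            f"{len(rev_hits)} reverse): {len(products)} products predicted",
            stacklevel=2,
        )
    return sorted(products, key=lambda a: (a.forward_start, a.length))
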