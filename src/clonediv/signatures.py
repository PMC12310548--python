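"""AID hotspot/coldspot mutation signatures, R/S classes and sharing.

Somatic hypermutation driven by AID preferentially targets C within WRC
(W = A/T, R = A/G) on the forward strand and, symmetrically, G within GYW
(Y = C/T) on the reverse strand; SYC and GRS (S = G/C) are the matching
coldspots.  Mutations are called per subclone against the germline window,
classified by motif context (germline context only), replacement/silent
effect under the standard genetic code, IGHV region, and by how widely
they are shared across the clone's subclones — mutations present in every
subclone predate the subclonal expansion, while partially shared or unique
mutations are the ongoing-diversification signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

from .clones import CloneProfile
from .io import GermlineReference

__all__ = [
    "MutationCall",
    "ClassRate",
    "SignatureSummary",
    "call_mutations",
    "classify_motif",
    "classify_rs",
    "classify_sharing",
    "mutability_rates",
    "MOTIF_CLASSES",
]

MOTIF_CLASSES = ("hotspot_WRC", "hotspot_GYW", "coldspot_SYC", "coldspot_GRS", "other")

_W = frozenset("AT")
_R = frozenset("AG")
_Y = frozenset("CT")
_S = frozenset("GC")

_CODON_TABLE = standard_dna_table.forward_table  # stop codons absent -> "*"


@dataclass
class MutationCall:
    position: int  # 0-based germline coordinate
    germline_base: str
    observed_base: str
    motif_class: str = "other"
    rs_class: Optional[str] = None  # "replacement" | "silent" | None (unclassifiable)
    region: str = "other"
    sharing: str = ""  # "shared" | "partially_shared" | "unique"

    def __post_init__(self):
        if self.germline_base == self.observed_base:
            raise ValueError("germline and observed base are identical")


@dataclass
class ClassRate:
    observed: int
    opportunities: int

    @property
    def rate(self) -> Optional[float]:
        """observed/opportunities; None (undefined) when there is no opportunity."""
        if self.opportunities == 0:
            return None
        return self.observed / self.opportunities


@dataclass
class SignatureSummary:
    """Per-motif-class mutability and per-region R/S densities for one sample."""

    rates: dict[str, ClassRate]
    region_r_density: dict[str, float]
    region_s_density: dict[str, float]
    scope: str = "all"  # "all" | "non_shared"
    weighting: str = "freq"  # "freq" | "flat"
    calls: list[list[MutationCall]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-operation classifiers


def call_mutations(subclone_sequence: str, germline_sequence: str) -> list[MutationCall]:
    """One call per mismatching non-N column of two equal-length windows."""
    if len(subclone_sequence) != len(germline_sequence):
        raise ValueError(
            f"sequence length {len(subclone_sequence)} != germline window "
            f"{len(germline_sequence)}")
    return [
        MutationCall(position=i, germline_base=g, observed_base=o)
        for i, (o, g) in enumerate(zip(subclone_sequence, germline_sequence))
        if o != g and o != "N" and g != "N"
    ]


def classify_motif(germline: str, position: int) -> str:
    """Motif class of a germline position, from the germline context alone.

    WRC/SYC require the position to be the C (3' base of the motif); GYW/GRS
    require it to be the G (5' base).  Context running off the window edge
    classifies as "other".  Hotspots take precedence over coldspots — for
    these motif alphabets the overlap is impossible (W and S, R and Y are
    disjoint), but the rule is kept defensively.
    """
    if not 0 <= position < len(germline):
        raise ValueError(f"position {position} outside germline of length "
                         f"{len(germline)}")
    base = germline[position]
    if base == "C" and position >= 2:
        five, three = germline[position - 2], germline[position - 1]
        if five in _W and three in _R:
            return "hotspot_WRC"
        if five in _S and three in _Y:
            return "coldspot_SYC"
    elif base == "G" and position + 2 < len(germline):
        mid, last = germline[position + 1], germline[position + 2]
        if mid in _Y and last in _W:
            return "hotspot_GYW"
        if mid in _R and last in _S:
            return "coldspot_GRS"
    return "other"


def classify_rs(call: MutationCall, germline: GermlineReference) -> Optional[str]:
    """Replacement/silent under the standard genetic code.

    The codon is located from the reference's reading-frame offset; a codon
    truncated by the window edge leaves the call unclassifiable (None).
    Stop codons count as replacement.
    """
    offset = germline.reading_frame_offset
    pos = call.position
    if pos < offset:
        return None
    codon_start = offset + 3 * ((pos - offset) // 3)
    codon = germline.sequence[codon_start:codon_start + 3]
    if len(codon) < 3 or "N" in codon:
        return None
    mutated = list(codon)
    mutated[pos - codon_start] = call.observed_base
    mutated = "".join(mutated)
    aa_germ = _CODON_TABLE.get(codon, "*")
    aa_obs = _CODON_TABLE.get(mutated, "*")
    return "silent" if aa_germ == aa_obs else "replacement"


def classify_sharing(profile: CloneProfile,
                     calls_per_subclone: list[list[MutationCall]]) -> None:
    """Fill the sharing class of every call in place.

    A (position, observed base) pair found in all retained subclones is
    shared; in at least two but not all, partially shared; in exactly one,
    unique.  For a single-subclone profile every mutation is trivially
    shared (present in all = 1 subclones).
    """
    n_subclones = len(profile.subclones)
    if len(calls_per_subclone) != n_subclones:
        raise ValueError("one call list per subclone required")
    carriers: dict[tuple[int, str], int] = {}
    for calls in calls_per_subclone:
        for call in calls:
            key = (call.position, call.observed_base)
            carriers[key] = carriers.get(key, 0) + 1
    for calls in calls_per_subclone:
        for call in calls:
            n = carriers[(call.position, call.observed_base)]
            if n == n_subclones:
                call.sharing = "shared"
            elif n >= 2:
                call.sharing = "partially_shared"
            else:
                call.sharing = "unique"


# ---------------------------------------------------------------------------
# sample-level summary


def classify_profile_mutations(profile: CloneProfile,
                               germline: GermlineReference
                               ) -> list[list[MutationCall]]:
    """Call and fully classify mutations for every subclone of a profile."""
    window = len(germline.sequence)
    calls_per_subclone = []
    for sub in profile.subclones:
        calls = call_mutations(sub.sequence[:window], germline.sequence)
        for call in calls:
            call.motif_class = classify_motif(germline.sequence, call.position)
            call.rs_class = classify_rs(call, germline)
            call.region = germline.region_of(call.position)
        calls_per_subclone.append(calls)
    classify_sharing(profile, calls_per_subclone)
    return calls_per_subclone


def motif_opportunities(germline: str) -> dict[str, int]:
    """Number of germline positions whose context is each motif class."""
    counts = {c: 0 for c in MOTIF_CLASSES}
    for i in range(len(germline)):
        counts[classify_motif(germline, i)] += 1
    return counts


def mutability_rates(profile: CloneProfile,
                     germline: GermlineReference,
                     scope: str = "all",
                     weighting: str = "freq") -> SignatureSummary:
    """Per-motif-class mutability and per-region R/S densities.

    Observed counts are distinct mutated germline positions of each class
    across the clone's subclones (scope "non_shared" drops fully shared
    mutations — the pre-transformation load).  Opportunities are the
    positions of that class in the germline window; a class with zero
    opportunities reports an undefined rate, not 0.  R/S densities are
    mutations per nucleotide of region, weighted by subclone frequency
    ("freq") or unweighted per subclone ("flat").
    """
    if scope not in ("all", "non_shared"):
        raise ValueError(f"unknown scope {scope!r}")
    if weighting not in ("freq", "flat"):
        raise ValueError(f"unknown weighting {weighting!r}")
    calls_per_subclone = classify_profile_mutations(profile, germline)

    def in_scope(call: MutationCall) -> bool:
        return scope == "all" or call.sharing != "shared"

    observed_positions: dict[str, set[int]] = {c: set() for c in MOTIF_CLASSES}
    for calls in calls_per_subclone:
        for call in calls:
            if in_scope(call):
                observed_positions[call.motif_class].add(call.position)
    opportunities = motif_opportunities(germline.sequence)
    rates = {c: ClassRate(observed=len(observed_positions[c]),
                          opportunities=opportunities[c])
             for c in MOTIF_CLASSES}

    r_density = {r: 0.0 for r in germline.regions}
    s_density = {r: 0.0 for r in germline.regions}
    total_weight = 0.0
    for sub, calls in zip(profile.subclones, calls_per_subclone):
        weight = sub.frequency if weighting == "freq" else 1.0
        total_weight += weight
        for call in calls:
            if not in_scope(call) or call.region not in r_density:
                continue
            target = r_density if call.rs_class == "replacement" else s_density
            if call.rs_class is not None:
                target[call.region] += weight
    for region, (start, end) in germline.regions.items():
        length = end - start
        norm = length * (total_weight if weighting == "flat" else 1.0)
        if norm > 0:
            r_density[region] /= norm
            s_density[region] /= norm
    return SignatureSummary(rates=rates, region_r_density=r_density,
                            region_s_density=s_density, scope=scope,
                            weighting=weighting, calls=calls_per_subclone)
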