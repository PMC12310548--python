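"""Pathological-clone identification and subclone enumeration.

The pathological clone is the most expressed clonotype in the sample —
reads sharing IGHV/IGHJ gene calls and CDR3.  A subclone is any retained
sequence of that clone differing from the major sequence by at least one
nucleotide.  Two gates guard the diversity measurement: sequences below
0.1% of the clone's reads are discarded, and samples with fewer than 5000
clone reads are flagged non-evaluable (at 5000 reads a 0.1% subclone still
has >= 5 supporting reads).
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np

from .io import GermlineReference, Rearrangement

__all__ = [
    "CloneDefinition",
    "Subclone",
    "CloneProfile",
    "MutationalStatus",
    "annotate_minimal",
    "identify_pathological_clone",
    "enumerate_subclones",
    "mutational_status",
    "DEFAULT_MIN_CLONE_READS",
    "DEFAULT_MIN_SUBCLONE_FREQ",
    "UNMUTATED_LOAD_CUTOFF_PCT",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLONE_READS = 5000
DEFAULT_MIN_SUBCLONE_FREQ = 0.001
#: IGHV mutational load (100 - germline identity %) at or below which a case is U
UNMUTATED_LOAD_CUTOFF_PCT = 2.0


@dataclass(frozen=True)
class CloneDefinition:
    v_call: str
    d_call: str
    j_call: str
    cdr3_nt: str

    def __post_init__(self):
        if not self.cdr3_nt:
            raise ValueError("cdr3_nt must be non-empty")


@dataclass
class Subclone:
    """One distinct sequence of the clone, in germline-aligned coordinates."""

    sequence: str
    read_count: int
    frequency: float = 0.0
    is_major: bool = False
    #: per-position mean Phred over the collapsed reads (None if unavailable)
    mean_quality: Optional[np.ndarray] = None


@dataclass
class MutationalStatus:
    v_identity_pct: float
    status: str  # "M" or "U"


@dataclass
class CloneProfile:
    """The pathological clone of one sample with its subclone spectrum."""

    definition: CloneDefinition
    subclones: list[Subclone]
    total_sample_reads: int
    clone_reads: int
    retained_reads: int
    filters: list[tuple[str, int]] = field(default_factory=list)
    evaluable: bool = True
    sample_id: str = ""
    mutational_status: Optional[MutationalStatus] = None

    @property
    def major(self) -> Subclone:
        return next(s for s in self.subclones if s.is_major)

    def frequencies(self) -> np.ndarray:
        return np.array([s.frequency for s in self.subclones])


# ---------------------------------------------------------------------------
# minimal annotation

_GENE_RE = re.compile(r"\*.*$")


def _gene(call: str) -> str:
    """Strip the allele suffix from a V/D/J call (IGHV3-23*01 -> IGHV3-23)."""
    return _GENE_RE.sub("", call or "")


def annotate_minimal(read: Rearrangement,
                     references: list[GermlineReference],
                     identity_floor: float = 0.80) -> Rearrangement:
    """Assign a V gene by best global-alignment identity against the references.

    Identity is computed over indel-free aligned columns.  Reads for which
    no reference reaches ``identity_floor`` are left with an empty v_call
    (unassigned), not raised as errors.  The floor sits well above the
    ~0.7 identity that unrelated sequences reach under optimal alignment
    while accepting any plausibly hypermutated IGHV read.  The junction is
    kept if already present on the read.
    """
    if not read.sequence:
        raise ValueError(f"{read.sequence_id}: empty sequence")
    if not references:
        raise ValueError("no germline references supplied")
    best_ref, best_identity = None, -1.0
    for ref in references:
        result = edlib.align(read.sequence, ref.sequence, task="path", mode="NW")
        matches = mismatches = 0
        for n, op in re.findall(r"(\d+)([=XIDM])", result["cigar"]):
            if op == "=":
                matches += int(n)
            elif op == "X":
                mismatches += int(n)
        aligned = matches + mismatches
        identity = matches / aligned if aligned else 0.0
        if identity > best_identity:
            best_ref, best_identity = ref, identity
    read.v_identity = best_identity
    read.v_call = best_ref.gene_name if best_identity >= identity_floor else ""
    return read


# ---------------------------------------------------------------------------
# clone identification


def identify_pathological_clone(
    rearrangements: list[Rearrangement],
    cdr3_mode: str = "exact",
    cdr3_min_identity: float = 0.85,
) -> Optional[tuple[CloneDefinition, list[Rearrangement]]]:
    """Group reads by (V gene, J gene, CDR3) and return the largest group.

    ``cdr3_mode`` "exact" requires identical junctions; "similar" merges
    same-length junctions with >= ``cdr3_min_identity`` into the seed of the
    largest group.  Returns None when no annotated group exists (no
    prevalent clone detected).  Equal-count ties are broken
    lexicographically on (v_call, CDR3) with a warning.
    """
    groups: dict[tuple[str, str, str], list[Rearrangement]] = defaultdict(list)
    for r in rearrangements:
        if not r.v_call or not r.junction:
            continue
        groups[(_gene(r.v_call), _gene(r.j_call), r.junction)].append(r)
    if not groups:
        return None
    if cdr3_mode == "similar":
        groups = _merge_similar_junctions(groups, cdr3_min_identity)
    elif cdr3_mode != "exact":
        raise ValueError(f"unknown cdr3_mode {cdr3_mode!r}")

    def total(key):
        return sum(r.duplicate_count for r in groups[key])

    best_count = max(total(k) for k in groups)
    tied = sorted(k for k in groups if total(k) == best_count)
    if len(tied) > 1:
        logger.warning("clone tie at %d reads between %d groups; "
                       "picking lexicographically smallest", best_count, len(tied))
    key = tied[0]
    members = groups[key]
    rep = max(members, key=lambda r: (r.duplicate_count, r.sequence))
    definition = CloneDefinition(v_call=key[0], d_call=_gene(rep.d_call),
                                 j_call=key[1], cdr3_nt=key[2])
    return definition, members


def _merge_similar_junctions(groups, min_identity):
    """Single-linkage-by-seed merge of same-length junctions into larger groups."""
    merged: dict[tuple[str, str, str], list[Rearrangement]] = {}
    order = sorted(groups, key=lambda k: (-sum(r.duplicate_count for r in groups[k]), k))
    for key in order:
        v, j, cdr3 = key
        target = None
        for mk in merged:
            if mk[0] == v and mk[1] == j and len(mk[2]) == len(cdr3):
                same = sum(a == b for a, b in zip(mk[2], cdr3))
                if same / len(cdr3) >= min_identity:
                    target = mk
                    break
        if target is None:
            merged[key] = list(groups[key])
        else:
            merged[target].extend(groups[key])
    return merged


# ---------------------------------------------------------------------------
# subclone enumeration


def enumerate_subclones(
    members: list[Rearrangement],
    min_clone_reads: int = DEFAULT_MIN_CLONE_READS,
    min_subclone_freq: float = DEFAULT_MIN_SUBCLONE_FREQ,
    total_sample_reads: Optional[int] = None,
    sample_id: str = "",
) -> CloneProfile:
    """Collapse clone members into subclones and apply the frequency gates.

    Identical sequences are collapsed with summed counts; sequences below
    ``min_subclone_freq`` of the clone's reads are removed and frequencies
    renormalized over the retained reads.  Reads containing N are assigned
    by exact match over their non-N positions when that match is unique
    among retained subclones, otherwise dropped and audited.  The profile
    is non-evaluable when clone reads fall below ``min_clone_reads``.
    """
    if not members:
        raise ValueError("no clone members supplied")
    definition_source = members[0]
    clone_reads = sum(r.duplicate_count for r in members)

    clean: dict[str, list[Rearrangement]] = defaultdict(list)
    ambiguous: list[Rearrangement] = []
    for r in members:
        (ambiguous if "N" in r.sequence else clean[r.sequence]).append(r)

    counts = {seq: sum(r.duplicate_count for r in rs) for seq, rs in clean.items()}
    filters: list[tuple[str, int]] = []

    # 0.1% filter against the clone read total (pre-renormalization denominator)
    threshold = min_subclone_freq * clone_reads
    below = {seq for seq, c in counts.items() if c < threshold}
    removed_low = sum(counts[s] for s in below)
    if removed_low:
        filters.append(("min_subclone_freq", removed_low))
    retained = {seq: c for seq, c in counts.items() if seq not in below}
    if not retained:
        raise ValueError("no subclone passes the frequency filter")

    # place N-containing reads onto a uniquely matching retained subclone
    rescued = dropped_n = 0
    for r in ambiguous:
        hits = [seq for seq in retained
                if len(seq) == len(r.sequence)
                and all(a == b for a, b in zip(r.sequence, seq) if a != "N")]
        if len(hits) == 1:
            retained[hits[0]] += r.duplicate_count
            rescued += r.duplicate_count
        else:
            dropped_n += r.duplicate_count
    if dropped_n:
        filters.append(("ambiguous_bases", dropped_n))

    retained_reads = sum(retained.values())
    major_seq = min(retained, key=lambda s: (-retained[s], s))
    subclones = [
        Subclone(sequence=seq, read_count=c, frequency=c / retained_reads,
                 is_major=(seq == major_seq),
                 mean_quality=_mean_quality(clean.get(seq, [])))
        for seq, c in sorted(retained.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    junction = definition_source.junction or "N/A"
    definition = CloneDefinition(
        v_call=_gene(definition_source.v_call) or "unassigned",
        d_call=_gene(definition_source.d_call),
        j_call=_gene(definition_source.j_call),
        cdr3_nt=junction)
    return CloneProfile(
        definition=definition,
        subclones=subclones,
        total_sample_reads=total_sample_reads if total_sample_reads is not None
        else clone_reads,
        clone_reads=clone_reads,
        retained_reads=retained_reads,
        filters=filters,
        evaluable=clone_reads >= min_clone_reads,
        sample_id=sample_id,
    )


def _mean_quality(reads: list[Rearrangement]) -> Optional[np.ndarray]:
    quals = [(r.quality, r.duplicate_count) for r in reads if r.quality is not None]
    if not quals:
        return None
    total = sum(w for _, w in quals)
    return sum(q * w for q, w in quals) / total


# ---------------------------------------------------------------------------
# mutational status


def mutational_status(major_sequence: str,
                      germline: GermlineReference) -> MutationalStatus:
    """Percent germline identity of the major sequence and the M/U call.

    Identity is computed over the germline window columns (positions with N
    in the read are skipped).  A case is unmutated (U) when the mutational
    load, 100 - identity%, is at or below 2%.
    """
    window = min(len(major_sequence), len(germline.sequence))
    pairs = [(major_sequence[i], germline.sequence[i])
             for i in range(window) if major_sequence[i] != "N"]
    if not pairs:
        raise ValueError("no aligned columns between sequence and germline")
    identity_pct = 100.0 * sum(a == b for a, b in pairs) / len(pairs)
    status = "U" if (100.0 - identity_pct) <= UNMUTATED_LOAD_CUTOFF_PCT else "M"
    return MutationalStatus(v_identity_pct=identity_pct, status=status)
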