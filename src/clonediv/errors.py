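"""Systematic sequencing-error detection/correction and the UMI path.

Amplicon sequencing of IGHV libraries shows recurrent, protocol-dependent
artifacts: a specific flanking context repeatedly miscalled as the same
alternative base, at low frequency and low Phred quality, across unrelated
samples.  Such artifacts inflate subclone counts and hence the diversity
measurement, so they are identified across a cohort (context k-mer + alt
base, recurrent in >= min_recurrence clones, variant frequency below
systematic_max_freq, mean Phred below the quality floor) and reverted to
the major-subclone base before the 0.1% filter and iSI calculation.

The UMI functions implement the alternative consensus-based path used to
cross-validate the UMI-free measurement: reads are grouped by a unique
molecular identifier built as fixed-length random blocks interspersed with
short constant spacers, and each sufficiently covered group is collapsed
by per-position majority vote.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clones import CloneProfile, Subclone
from .io import Rearrangement

__all__ = [
    "ErrorBlacklistEntry",
    "UmiPattern",
    "detect_systematic_errors",
    "correct_profile",
    "read_blacklist",
    "write_blacklist",
    "umi_extract",
    "umi_consensus",
    "DEFAULT_QUALITY_FLOOR",
    "DEFAULT_SYSTEMATIC_MAX_FREQ",
    "DEFAULT_MIN_RECURRENCE",
    "CONTEXT_K",
]

logger = logging.getLogger(__name__)

DEFAULT_QUALITY_FLOOR = 20.0
DEFAULT_SYSTEMATIC_MAX_FREQ = 0.02
DEFAULT_MIN_RECURRENCE = 5
CONTEXT_K = 5  # k-mer centered on the error position


@dataclass(frozen=True)
class ErrorBlacklistEntry:
    """One recurrent artifact: a context k-mer and the miscalled base."""

    context: str
    alt_base: str
    mean_quality: float = 0.0
    n_samples: int = 0
    mean_frequency: float = 0.0

    def __post_init__(self):
        if self.alt_base == self.context[len(self.context) // 2]:
            raise ValueError("alt_base equals the context center base")


@dataclass
class UmiPattern:
    """UMI layout: n_blocks random blocks separated by fixed spacers.

    The read starts with ``block spacer block spacer ... block spacer``
    followed by the amplicon payload; the UMI is the concatenation of the
    random blocks.
    """

    block_length: int = 6
    n_blocks: int = 3
    spacers: tuple[str, ...] = ("TCA", "GAT", "CTG")

    def __post_init__(self):
        if len(self.spacers) != self.n_blocks:
            raise ValueError("one spacer required per block")
        if self.total_length <= 0:
            raise ValueError("pattern must have positive length")

    @property
    def total_length(self) -> int:
        return self.n_blocks * self.block_length + sum(len(s) for s in self.spacers)

    def extract(self, sequence: str) -> Optional[tuple[str, str]]:
        """Return (umi, payload) or None when the spacers do not match."""
        if len(sequence) < self.total_length:
            return None
        pos = 0
        blocks = []
        for spacer in self.spacers:
            blocks.append(sequence[pos:pos + self.block_length])
            pos += self.block_length
            if sequence[pos:pos + len(spacer)] != spacer:
                return None
            pos += len(spacer)
        return "".join(blocks), sequence[pos:]


# ---------------------------------------------------------------------------
# systematic-error detection and correction


def _variant_sites(profile: CloneProfile):
    """Yield (subclone, position, alt) for every non-major subclone variant."""
    major = profile.major.sequence
    for sub in profile.subclones:
        if sub.is_major:
            continue
        for pos, (a, b) in enumerate(zip(sub.sequence, major)):
            if a != b and a != "N" and b != "N":
                yield sub, pos, a


def _context(sequence: str, pos: int, k: int) -> Optional[str]:
    half = k // 2
    if pos - half < 0 or pos + half + 1 > len(sequence):
        return None
    return sequence[pos - half:pos + half + 1]


def detect_systematic_errors(
    profiles: list[CloneProfile],
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    systematic_max_freq: float = DEFAULT_SYSTEMATIC_MAX_FREQ,
    k: int = CONTEXT_K,
) -> list[ErrorBlacklistEntry]:
    """Blacklist (context, alt) pairs recurring as low-quality low-frequency
    variants across at least ``min_recurrence`` distinct clones.

    The context is the k-mer of the major-subclone sequence centered on the
    variant position, so it reflects the template the polymerase/sequencer
    saw.  Deterministic given the inputs.
    """
    if len(profiles) < min_recurrence:
        logger.warning("only %d profiles < min_recurrence %d: empty blacklist",
                       len(profiles), min_recurrence)
        return []
    evidence: dict[tuple[str, str], list[tuple[int, float, float]]] = defaultdict(list)
    for idx, profile in enumerate(profiles):
        major = profile.major.sequence
        for sub, pos, alt in _variant_sites(profile):
            if sub.frequency >= systematic_max_freq:
                continue
            if sub.mean_quality is None:
                continue
            qual = float(sub.mean_quality[pos])
            if qual >= quality_floor:
                continue
            ctx = _context(major, pos, k)
            if ctx is None or "N" in ctx:
                continue
            evidence[(ctx, alt)].append((idx, qual, sub.frequency))
    entries = []
    for (ctx, alt), obs in sorted(evidence.items()):
        samples = {i for i, _, _ in obs}
        if len(samples) < min_recurrence:
            continue
        entries.append(ErrorBlacklistEntry(
            context=ctx,
            alt_base=alt,
            mean_quality=float(np.mean([q for _, q, _ in obs])),
            n_samples=len(samples),
            mean_frequency=float(np.mean([f for _, _, f in obs])),
        ))
    return entries


def correct_profile(
    profile: CloneProfile,
    blacklist: list[ErrorBlacklistEntry],
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
    systematic_max_freq: float = DEFAULT_SYSTEMATIC_MAX_FREQ,
    k: int = CONTEXT_K,
) -> CloneProfile:
    """Revert blacklisted / low-quality variants to the major-subclone base.

    Only variants carried by subclones below ``systematic_max_freq`` are
    touched, so genuine subclones at or above that frequency can never be
    merged away.  Reads are conserved: corrected subclones re-merge into
    whichever subclone their corrected sequence now matches.
    """
    major = profile.major
    black = {(e.context, e.alt_base) for e in blacklist}
    merged: dict[str, list[Subclone]] = defaultdict(list)
    n_reverted = 0
    for sub in profile.subclones:
        if sub.is_major or sub.frequency >= systematic_max_freq:
            merged[sub.sequence].append(sub)
            continue
        seq = list(sub.sequence)
        for pos, (a, b) in enumerate(zip(sub.sequence, major.sequence)):
            if a == b or a == "N" or b == "N":
                continue
            ctx = _context(major.sequence, pos, k)
            artifact = (ctx is not None and (ctx, a) in black)
            low_q = (sub.mean_quality is not None
                     and float(sub.mean_quality[pos]) < quality_floor)
            if artifact or low_q:
                seq[pos] = b
                n_reverted += 1
        merged["".join(seq)].append(sub)

    if major.sequence not in merged:
        raise ValueError("correction would delete the major subclone")

    subclones = []
    for seq, parts in merged.items():
        count = sum(p.read_count for p in parts)
        quals = [(p.mean_quality, p.read_count) for p in parts
                 if p.mean_quality is not None]
        mean_q = (sum(q * w for q, w in quals) / sum(w for _, w in quals)
                  if quals else None)
        subclones.append(Subclone(sequence=seq, read_count=count,
                                  mean_quality=mean_q))
    retained = sum(s.read_count for s in subclones)
    major_seq = min(subclones, key=lambda s: (-s.read_count, s.sequence)).sequence
    for s in subclones:
        s.frequency = s.read_count / retained
        s.is_major = s.sequence == major_seq
    subclones.sort(key=lambda s: (-s.read_count, s.sequence))
    filters = list(profile.filters)
    if n_reverted:
        filters.append(("systematic_error_correction", n_reverted))
    return CloneProfile(
        definition=profile.definition,
        subclones=subclones,
        total_sample_reads=profile.total_sample_reads,
        clone_reads=profile.clone_reads,
        retained_reads=retained,
        filters=filters,
        evaluable=profile.evaluable,
        sample_id=profile.sample_id,
        mutational_status=profile.mutational_status,
    )


def write_blacklist(entries: list[ErrorBlacklistEntry], path: str) -> None:
    pd.DataFrame(
        [{"context": e.context, "alt": e.alt_base, "mean_q": e.mean_quality,
          "n_samples": e.n_samples, "mean_freq": e.mean_frequency}
         for e in entries]
    ).to_csv(path, sep="\t", index=False)


def read_blacklist(path: str) -> list[ErrorBlacklistEntry]:
    df = pd.read_csv(path, sep="\t")
    return [ErrorBlacklistEntry(context=r.context, alt_base=r.alt,
                                mean_quality=float(r.mean_q),
                                n_samples=int(r.n_samples),
                                mean_frequency=float(r.mean_freq))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# UMI path


@dataclass
class UmiGroups:
    groups: dict[str, list[Rearrangement]] = field(default_factory=dict)
    n_unmatched: int = 0


def umi_extract(reads: list[Rearrangement], pattern: UmiPattern,
                collapse_distance: int = 1) -> UmiGroups:
    """Partition reads by their extracted UMI.

    Reads failing the spacer pattern (or shorter than the pattern) are
    audited out.  UMIs within ``collapse_distance`` Hamming distance of a
    larger group are merged into it, absorbing UMI sequencing errors.
    """
    raw: dict[str, list[Rearrangement]] = defaultdict(list)
    unmatched = 0
    for read in reads:
        hit = pattern.extract(read.sequence)
        if hit is None:
            unmatched += 1
            continue
        umi, payload = hit
        quality = read.quality[-len(payload):] if read.quality is not None else None
        raw[umi].append(Rearrangement(
            sequence_id=read.sequence_id, sequence=payload,
            v_call=read.v_call, d_call=read.d_call, j_call=read.j_call,
            junction=read.junction if read.junction in payload else "",
            duplicate_count=read.duplicate_count, quality=quality))
    if collapse_distance > 0:
        raw = _collapse_umis(raw, collapse_distance)
    return UmiGroups(groups=dict(raw), n_unmatched=unmatched)


def _collapse_umis(groups, max_distance):
    order = sorted(groups, key=lambda u: (-len(groups[u]), u))
    kept: list[str] = []
    out: dict[str, list[Rearrangement]] = {}
    for umi in order:
        target = None
        for big in kept:
            if len(big) == len(umi) and \
                    sum(a != b for a, b in zip(big, umi)) <= max_distance:
                target = big
                break
        if target is None:
            kept.append(umi)
            out[umi] = list(groups[umi])
        else:
            out[target].extend(groups[umi])
    return out


def umi_consensus(umi_groups: UmiGroups, min_reads_per_umi: int = 3,
                  reference: Optional[str] = None) -> list[Rearrangement]:
    """Per-position majority-vote consensus of each sufficiently covered group.

    Groups with fewer than ``min_reads_per_umi`` reads are dropped.  Vote
    ties fall back to the reference base when provided (else the
    lexicographically smallest tied base).  Each consensus molecule gets
    ``duplicate_count`` 1; consensus quality is the per-position mean.
    """
    out = []
    for umi in sorted(umi_groups.groups):
        reads = umi_groups.groups[umi]
        if len(reads) < min_reads_per_umi:
            continue
        length = min(len(r.sequence) for r in reads)
        mat = np.frombuffer(
            "".join(r.sequence[:length] for r in reads).encode(), dtype=np.uint8
        ).reshape(len(reads), length)
        # vectorized per-position vote over A/C/G/T (alphabetical order makes
        # argmax resolve ties to the lexicographically smallest base)
        counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])
        top = counts.max(axis=0)
        winner = counts.argmax(axis=0)
        if reference is not None:
            ref_idx = np.frombuffer(reference[:length].encode(), dtype=np.uint8)
            ref_map = np.full(256, -1)
            for i, b in enumerate("ACGT"):
                ref_map[ord(b)] = i
            ref_i = np.full(length, -1)  # columns beyond the reference: no tiebreak
            ref_i[:len(ref_idx)] = ref_map[ref_idx]
            tie = (counts == top).sum(axis=0) > 1
            ref_wins = tie & (ref_i >= 0) & \
                (counts[np.clip(ref_i, 0, 3), np.arange(length)] == top)
            winner = np.where(ref_wins, ref_i, winner)
        seq = [("ACGT"[w]) for w in winner]
        quals = [r.quality[:length] for r in reads if r.quality is not None]
        template = reads[0]
        out.append(Rearrangement(
            sequence_id=f"umi_{umi}", sequence="".join(seq),
            v_call=template.v_call, d_call=template.d_call,
            j_call=template.j_call,
            junction=template.junction if template.junction in "".join(seq) else "",
            duplicate_count=1,
            quality=np.mean(quals, axis=0) if quals else None))
    if not out:
        logger.warning("no UMI group reaches min_reads_per_umi=%d", min_reads_per_umi)
    return out
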