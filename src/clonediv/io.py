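"""Reading and writing the standard formats the pipeline touches.

Supported inputs: AIRR Rearrangement TSV (MiAIRR column names), FASTA,
FASTQ (Phred+33), a germline reference FASTA with a tabular FR/CDR region
annotation, and survival CSV tables.  All internal coordinates are 0-based
half-open; columns that are 1-based on disk are converted at this boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GermlineReference",
    "Rearrangement",
    "SurvivalRecord",
    "read_rearrangements",
    "write_rearrangements",
    "read_germline",
    "read_survival",
    "write_report",
    "read_report",
    "REGION_ORDER",
]

#: canonical FR/CDR alternation over the V region (CDR3 is handled as junction)
REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

_AIRR_REQUIRED = ("sequence_id", "sequence", "v_call", "d_call", "j_call",
                  "junction", "duplicate_count")

_VALID_BASES = frozenset("ACGT")


@dataclass
class GermlineReference:
    """A germline IGHV gene with FR/CDR delimitation.

    ``regions`` maps region name to a 0-based half-open ``(start, end)``
    interval on ``sequence``; names must be drawn from :data:`REGION_ORDER`
    and appear in that order, non-overlapping.  ``reading_frame_offset`` is
    the 0-based position of the first complete codon.
    """

    gene_name: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.reading_frame_offset not in (0, 1, 2):
            raise ValueError("reading_frame_offset must be 0, 1 or 2")
        order = [r for r in self.regions]
        expected = [r for r in REGION_ORDER if r in self.regions]
        if order != expected:
            raise ValueError(
                f"regions of {self.gene_name} must follow FR1,CDR1,FR2,CDR2,FR3 "
                f"order; got {order}")
        prev_end = 0
        for name, (start, end) in self.regions.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"region {name} of {self.gene_name}: interval ({start},{end}) "
                    f"outside sequence of length {len(self.sequence)}")
            if start < prev_end:
                raise ValueError(
                    f"region {name} of {self.gene_name} overlaps the previous region")
            prev_end = end

    def region_of(self, position: int) -> str:
        """Region name containing ``position``, or ``"other"``."""
        for name, (start, end) in self.regions.items():
            if start <= position < end:
                return name
        return "other"


@dataclass
class Rearrangement:
    """One sequence read or collapse unit with (possibly partial) annotation."""

    sequence_id: str
    sequence: str
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    junction: str = ""
    duplicate_count: int = 1
    v_identity: Optional[float] = None
    quality: Optional[np.ndarray] = None  # per-base Phred scores
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.junction = (self.junction or "").upper()
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")
        if self.junction and self.junction not in self.sequence:
            raise ValueError(
                f"{self.sequence_id}: junction is not a substring of sequence")
        self.has_ambiguous = not _VALID_BASES.issuperset(self.sequence)


@dataclass
class SurvivalRecord:
    """One patient: time-to-first-treatment in months and the event flag."""

    sample_id: str
    time_months: float
    event: bool  # treated = True, censored = False
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError(f"{self.sample_id}: negative time_months")


# ---------------------------------------------------------------------------
# rearrangement IO


def read_rearrangements(path: str, format: str = "airr_tsv") -> list[Rearrangement]:
    """Read reads/collapse units from an AIRR TSV, FASTA or FASTQ file.

    FASTA/FASTQ records get ``duplicate_count`` 1 and empty annotation
    (to be filled later by minimal annotation); FASTQ quality is kept as
    Phred scores.  Sequences are upper-cased; non-ACGT characters are
    preserved but flagged on the record.
    """
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty file")
    if format == "airr_tsv":
        return _read_airr_tsv(path)
    if format in ("fasta", "fastq"):
        out = []
        try:
            for rec in SeqIO.parse(path, format):
                qual = rec.letter_annotations.get("phred_quality")
                out.append(Rearrangement(
                    sequence_id=rec.id,
                    sequence=str(rec.seq),
                    quality=np.asarray(qual, dtype=float) if qual is not None else None,
                ))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {format} record: {exc}") from exc
        if not out:
            raise ValueError(f"{path}: no {format} records found")
        return out
    raise ValueError(f"unknown format {format!r}")


def _read_airr_tsv(path: str) -> list[Rearrangement]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sequence_id", "sequence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = row._asdict()
        try:
            count = int(d.get("duplicate_count") or 1)
            qual_str = d.get("quality") or ""
            qual = (np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(float) - 33
                    if qual_str else None)
            out.append(Rearrangement(
                sequence_id=d["sequence_id"],
                sequence=d["sequence"],
                v_call=d.get("v_call", ""),
                d_call=d.get("d_call", ""),
                j_call=d.get("j_call", ""),
                junction=d.get("junction", ""),
                duplicate_count=count,
                quality=qual,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no rearrangement rows found")
    return out


def write_rearrangements(rearrangements: list[Rearrangement], path: str) -> None:
    """Write an AIRR Rearrangement TSV (quality as a Phred+33 string column)."""
    rows = []
    for r in rearrangements:
        rows.append({
            "sequence_id": r.sequence_id,
            "sequence": r.sequence,
            "v_call": r.v_call,
            "d_call": r.d_call,
            "j_call": r.j_call,
            "junction": r.junction,
            "duplicate_count": r.duplicate_count,
            "quality": ("".join(chr(int(round(q)) + 33) for q in r.quality)
                        if r.quality is not None else ""),
        })
    pd.DataFrame(rows, columns=list(_AIRR_REQUIRED) + ["quality"]).to_csv(
        path, sep="\t", index=False)


def write_fastq(rearrangements: list[Rearrangement], path: str) -> None:
    """Write read-level FASTQ (collapse units are expanded by duplicate_count)."""
    with open(path, "w") as handle:
        for r in rearrangements:
            qual = ("".join(chr(int(round(q)) + 33) for q in r.quality)
                    if r.quality is not None else "I" * len(r.sequence))
            for i in range(r.duplicate_count):
                suffix = f"/{i}" if r.duplicate_count > 1 else ""
                handle.write(f"@{r.sequence_id}{suffix}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# germline references


def read_germline(path: str, regions_path: str) -> list[GermlineReference]:
    """Read a germline FASTA plus its region table.

    The region table is a TSV with columns ``gene, region, start, end``
    (0-based half-open).  An optional ``frame`` column gives the reading
    frame offset per gene (default 0).  Every FASTA record must have at
    least one region row.
    """
    regions_df = pd.read_csv(regions_path, sep="\t")
    for col in ("gene", "region", "start", "end"):
        if col not in regions_df.columns:
            raise ValueError(f"{regions_path}: missing required column '{col}'")
    refs = []
    for rec in SeqIO.parse(path, "fasta"):
        sub = regions_df[regions_df["gene"] == rec.id]
        if sub.empty:
            raise ValueError(f"{regions_path}: no region rows for gene {rec.id}")
        ordered = {}  # file row order is preserved so order violations surface
        for row in sub.itertuples(index=False):
            name = str(row.region)
            if name not in REGION_ORDER:
                raise ValueError(f"{regions_path}: unknown region name {name!r}")
            ordered[name] = (int(row.start), int(row.end))
        frame = int(sub.iloc[0]["frame"]) if "frame" in sub.columns else 0
        refs.append(GermlineReference(
            gene_name=rec.id, sequence=str(rec.seq), regions=ordered,
            reading_frame_offset=frame))
    if not refs:
        raise ValueError(f"{path}: no FASTA records found")
    return refs


# ---------------------------------------------------------------------------
# survival tables


def read_survival(path: str) -> list[SurvivalRecord]:
    """Read a survival CSV with header ``sample_id,time_months,event,...``.

    Extra columns become categorical ``group_labels``.
    """
    df = pd.read_csv(path)
    for col in ("sample_id", "time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    extra = [c for c in df.columns if c not in ("sample_id", "time_months", "event")]
    return [
        SurvivalRecord(
            sample_id=str(row["sample_id"]),
            time_months=float(row["time_months"]),
            event=bool(int(row["event"])),
            group_labels={c: str(row[c]) for c in extra},
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# reports

_REPORT_COLUMNS = ("sample_id", "total_reads", "clone_reads", "retained_reads",
                   "n_subclones", "isi", "id_class", "v_identity_pct",
                   "mutational_status", "hotspot_rate", "coldspot_rate")


def write_report(entries, out_prefix: str) -> tuple[str, str]:
    """Write the per-sample summary and per-subclone tables.

    ``entries`` is a list of ``(profile, diversity, signatures)`` tuples (a
    single tuple is accepted too); ``signatures`` (or ``diversity``) may be
    None for partially processed samples.  Two files are produced,
    ``<out_prefix>_samples.tsv`` and ``<out_prefix>_subclones.tsv``, rows
    ordered by sample_id; frequencies are written to 6 decimals so the
    subclone table round-trips through :func:`read_report`.
    """
    if not isinstance(entries, list):
        entries = [entries]
    sample_rows, subclone_rows = [], []
    for profile, diversity, signatures in entries:
        hot = cold = float("nan")
        status = ""
        v_id = float("nan")
        if signatures is not None:
            hot = _rate_or_nan(signatures, "hotspot_WRC", "hotspot_GYW")
            cold = _rate_or_nan(signatures, "coldspot_SYC", "coldspot_GRS")
        if profile.mutational_status is not None:
            status = profile.mutational_status.status
            v_id = profile.mutational_status.v_identity_pct
        sample_rows.append({
            "sample_id": profile.sample_id,
            "total_reads": profile.total_sample_reads,
            "clone_reads": profile.clone_reads,
            "retained_reads": profile.retained_reads,
            "n_subclones": len(profile.subclones),
            "isi": diversity.isi if diversity is not None else float("nan"),
            "id_class": diversity.id_class if diversity is not None else "",
            "v_identity_pct": v_id,
            "mutational_status": status,
            "hotspot_rate": hot,
            "coldspot_rate": cold,
        })
        for i, sub in enumerate(profile.subclones):
            subclone_rows.append({
                "sample_id": profile.sample_id,
                "rank": i,
                "sequence": sub.sequence,
                "read_count": sub.read_count,
                "frequency": round(sub.frequency, 6),
                "is_major": sub.is_major,
            })
    samples = pd.DataFrame(sample_rows, columns=_REPORT_COLUMNS).sort_values("sample_id")
    subclones = pd.DataFrame(
        subclone_rows,
        columns=("sample_id", "rank", "sequence", "read_count", "frequency", "is_major"),
    ).sort_values(["sample_id", "rank"])
    sample_path = f"{out_prefix}_samples.tsv"
    subclone_path = f"{out_prefix}_subclones.tsv"
    samples.to_csv(sample_path, sep="\t", index=False, float_format="%.6f")
    subclones.to_csv(subclone_path, sep="\t", index=False, float_format="%.6f")
    return sample_path, subclone_path


def _rate_or_nan(signatures, *classes) -> float:
    rates = [signatures.rates[c].rate for c in classes
             if signatures.rates[c].rate is not None]
    return float(np.mean(rates)) if rates else float("nan")


def read_report(out_prefix: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the two report tables written by :func:`write_report`."""
    samples = pd.read_csv(f"{out_prefix}_samples.tsv", sep="\t")
    subclones = pd.read_csv(f"{out_prefix}_subclones.tsv", sep="\t")
    return samples, subclones
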