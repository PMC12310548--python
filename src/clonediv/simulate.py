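"""Synthetic IGHV repertoires, sequencing noise and survival cohorts.

The generator emulates the data-generating structure of a CLL IGHV
amplicon experiment: one dominant pathological clone per sample whose
major sequence carries a clonal mutation load on a germline template,
a small set of subclones derived from it by additional AID-hotspot-biased
mutations, multinomial read sampling at depths around 15,000 (the scale of
routine diagnostic repertoires), random per-base sequencing errors at high
Phred quality, and context-specific systematic artifacts injected at low
frequency with low Phred quality.  Survival cohorts draw exponential
time-to-first-treatment with group-dependent hazards for the four
IGHV-status x ID-class strata and uniform censoring.

Every function is deterministic given its seed; ground truth is returned
as a manifest so each pipeline stage can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import GermlineReference, Rearrangement
from .signatures import classify_motif

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "default_germline",
    "simulate_repertoire",
    "simulate_umi_reads",
    "simulate_cohort",
    "DEFAULT_HAZARDS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {ord(b): i for i, b in enumerate("ACGT")}

#: monthly exponential hazards per IGHV-status x ID stratum.  Chosen to give
#: median TTFT on the order of reported CLL experience: U-CLL around 31
#: months, U ID_high around 51, M ID_low around 120, M ID_high much longer.
DEFAULT_HAZARDS = {
    "M-ID_low": 0.0057,
    "M-ID_high": 0.0020,
    "U-ID_low": 0.0220,
    "U-ID_high": 0.0136,
}

_DEFAULT_REGIONS = {
    "FR1": (0, 75),
    "CDR1": (75, 99),
    "FR2": (99, 150),
    "CDR2": (150, 174),
    "FR3": (174, 288),
}


def default_germline() -> GermlineReference:
    """A synthetic 300-nt IGHV-like template (not an IMGT sequence).

    Generated once from a fixed seed so the package ships no third-party
    reference data; a random template at this length carries a realistic
    density of WRC/GYW hotspot and SYC/GRS coldspot motifs.
    """
    rng = np.random.default_rng(20200612)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    return GermlineReference(gene_name="IGHVSIM3-23", sequence=seq,
                             regions=dict(_DEFAULT_REGIONS),
                             reading_frame_offset=0)


@dataclass
class SimulationConfig:
    """Knobs of one simulated sample; defaults are the study-scale conditions."""

    germline: Optional[GermlineReference] = None
    n_reads: int = 15_000
    clonal_mutation_load: float = 0.05  # fraction of window positions mutated (M case)
    n_true_subclones: int = 3
    freq_model: str = "dirichlet"  # dirichlet | stick_breaking | explicit
    dirichlet_alpha: float = 0.5
    stick_beta: float = 5.0
    explicit_freqs: Optional[list[float]] = None
    extra_mutations_range: tuple[int, int] = (1, 3)  # per derived subclone
    aid_hotspot_bias: float = 5.0  # relative mutation rate in WRC/GYW contexts
    random_error_rate: float = 1e-3  # per base
    #: (context 5-mer, alt base, per-read rate); None = three template-derived defaults
    systematic_errors: Optional[list[tuple[str, str, float]]] = None
    base_quality: float = 35.0
    systematic_quality: float = 12.0
    junction_length: int = 27

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for rate in (self.clonal_mutation_load, self.random_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.germline is None:
            self.germline = default_germline()
        if self.explicit_freqs is not None:
            self.n_true_subclones = len(self.explicit_freqs)
        if self.systematic_errors is None:
            self.systematic_errors = default_systematic_errors(self.germline)


def default_systematic_errors(germline: GermlineReference,
                              rate: float = 0.012
                              ) -> list[tuple[str, str, float]]:
    """Three protocol-level artifact contexts taken from the template."""
    seq = germline.sequence
    out = []
    for pos in (50, 140, 230):
        context = seq[pos - 2:pos + 3]
        alt = next(b for b in "ACGT" if b != seq[pos])
        out.append((context, alt, rate))
    return out


@dataclass
class TruthManifest:
    """Ground truth of one simulated sample."""

    germline: GermlineReference
    subclone_sequences: list[str]  # germline-window coordinates, index 0 = major
    frequencies: np.ndarray
    isi: float
    id_class: str
    junction: str
    #: per subclone, the (position, alt, motif_class) of its planted mutations
    mutations: list[list[tuple[int, str, str]]]
    systematic_errors: list[tuple[str, str, float]]
    seed: int
    read_counts: Optional[np.ndarray] = None
    survival: dict = field(default_factory=dict)


def _hotspot_weights(germline: str, bias: float) -> np.ndarray:
    classes = [classify_motif(germline, i) for i in range(len(germline))]
    return np.array([bias if c.startswith("hotspot") else 1.0 for c in classes])


def _draw_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    k = config.n_true_subclones
    if config.freq_model == "explicit" or config.explicit_freqs is not None:
        freqs = np.asarray(config.explicit_freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("explicit frequencies must sum to 1")
        return np.sort(freqs)[::-1]
    if config.freq_model == "dirichlet":
        freqs = rng.dirichlet(np.full(k, config.dirichlet_alpha))
    elif config.freq_model == "stick_breaking":
        sticks = rng.beta(1.0, config.stick_beta, size=k)
        remaining = np.concatenate([[1.0], np.cumprod(1.0 - sticks[:-1])])
        freqs = sticks * remaining
        freqs = freqs / freqs.sum()
    else:
        raise ValueError(f"unknown freq_model {config.freq_model!r}")
    return np.sort(freqs)[::-1]


def _plant_mutations(template: np.ndarray, positions, rng) -> list[tuple[int, str]]:
    out = []
    for pos in positions:
        current = template[pos]
        choices = _BASES[_BASES != current]
        alt = rng.choice(choices)
        template[pos] = alt
        out.append((int(pos), chr(alt)))
    return out


def simulate_repertoire(config: SimulationConfig, seed: int
                        ) -> tuple[list[Rearrangement], TruthManifest]:
    """Generate one sample's collapsed AIRR-style reads plus its ground truth.

    Reads are returned already collapsed to unique sequences with summed
    ``duplicate_count`` and per-position mean Phred quality (the form the
    clone caller consumes); sequencing errors live only in the V window,
    the appended junction is error-free so clone membership is unambiguous.
    """
    rng = np.random.default_rng(seed)
    germline = config.germline
    gseq = germline.sequence
    length = len(gseq)
    weights = _hotspot_weights(gseq, config.aid_hotspot_bias)
    germ_arr = np.frombuffer(gseq.encode(), dtype=np.uint8).copy()

    # major clone: clonal load with hotspot bias
    n_clonal = int(round(config.clonal_mutation_load * length))
    p = weights / weights.sum()
    clonal_pos = rng.choice(length, size=n_clonal, replace=False, p=p) \
        if n_clonal else np.array([], dtype=int)
    major = germ_arr.copy()
    clonal_muts = _plant_mutations(major, sorted(clonal_pos), rng)

    # derived subclones: extra hotspot-biased mutations on top of the major
    templates = [major]
    mutations = [clonal_muts]
    seen = {major.tobytes()}
    lo, hi = config.extra_mutations_range
    for _ in range(config.n_true_subclones - 1):
        for _attempt in range(100):
            sub = major.copy()
            free = np.setdiff1d(np.arange(length), clonal_pos)
            k = int(rng.integers(lo, hi + 1))
            pw = weights[free] / weights[free].sum()
            extra = rng.choice(free, size=k, replace=False, p=pw)
            muts = clonal_muts + _plant_mutations(sub, sorted(extra), rng)
            if sub.tobytes() not in seen:
                seen.add(sub.tobytes())
                templates.append(sub)
                mutations.append(muts)
                break
        else:
            raise RuntimeError("could not generate a distinct subclone")

    freqs = _draw_frequencies(config, rng)
    if freqs.size != len(templates):
        raise ValueError("frequency vector length != n_true_subclones")
    counts = rng.multinomial(config.n_reads, freqs)

    # read matrix + quality matrix
    reads = np.empty((config.n_reads, length), dtype=np.uint8)
    quals = np.full((config.n_reads, length), config.base_quality, dtype=np.float32)
    starts = np.concatenate([[0], np.cumsum(counts)])
    for t, (template, start, stop) in enumerate(zip(templates, starts, starts[1:])):
        reads[start:stop] = template

    # random per-base errors at baseline quality
    n_err = rng.binomial(reads.size, config.random_error_rate)
    if n_err:
        flat = rng.choice(reads.size, size=n_err, replace=False)
        rows, cols = np.unravel_index(flat, reads.shape)
        shift = rng.integers(1, 4, size=n_err)
        current = np.array([_BASE_INDEX[b] for b in reads[rows, cols]])
        reads[rows, cols] = _BASES[(current + shift) % 4]

    # systematic context errors at low quality
    for t, (start, stop) in enumerate(zip(starts, starts[1:])):
        template = templates[t].tobytes().decode()
        block = stop - start
        if block == 0:
            continue
        for context, alt, rate in config.systematic_errors:
            half = len(context) // 2
            search = 0
            while True:
                hit = template.find(context, search)
                if hit < 0:
                    break
                pos = hit + half
                n_aff = rng.binomial(block, rate)
                if n_aff:
                    rows = start + rng.choice(block, size=n_aff, replace=False)
                    reads[rows, pos] = ord(alt)
                    quals[rows, pos] = config.systematic_quality
                search = hit + 1

    # collapse identical reads, averaging quality (dict-hash collapse is much
    # faster than a lexicographic row sort at this depth)
    index: dict[bytes, int] = {}
    inverse = np.empty(config.n_reads, dtype=np.intp)
    for i in range(config.n_reads):
        key = reads[i].tobytes()
        inverse[i] = index.setdefault(key, len(index))
    uniq = np.empty((len(index), length), dtype=np.uint8)
    for key, j in index.items():
        uniq[j] = np.frombuffer(key, dtype=np.uint8)
    ucounts = np.bincount(inverse, minlength=len(index))
    qsum = np.zeros((len(index), length), dtype=np.float64)
    np.add.at(qsum, inverse, quals)
    qmean = qsum / ucounts[:, None]

    junction = "".join("ACGT"[i] for i in rng.integers(0, 4, config.junction_length))
    jqual = np.full(config.junction_length, config.base_quality)
    rearrangements = []
    order = np.argsort(-ucounts, kind="stable")
    for rank, idx in enumerate(order):
        seq = uniq[idx].tobytes().decode()
        rearrangements.append(Rearrangement(
            sequence_id=f"s{seed}_{rank}",
            sequence=seq + junction,
            v_call=germline.gene_name + "*01",
            d_call="IGHD3-10*01",
            j_call="IGHJ4*02",
            junction=junction,
            duplicate_count=int(ucounts[idx]),
            quality=np.concatenate([qmean[idx], jqual]),
        ))

    isi = float(1.0 / np.sum(freqs ** 2))
    truth = TruthManifest(
        germline=germline,
        subclone_sequences=[t.tobytes().decode() for t in templates],
        frequencies=freqs,
        isi=isi,
        id_class="ID_high" if isi >= 1.2 else "ID_low",
        junction=junction,
        mutations=[[(pos, alt, classify_motif(gseq, pos)) for pos, alt in muts]
                   for muts in mutations],
        systematic_errors=list(config.systematic_errors),
        seed=seed,
        read_counts=counts,
    )
    return rearrangements, truth


# ---------------------------------------------------------------------------
# UMI-tagged reads


def simulate_umi_reads(truth: TruthManifest, pattern, n_molecules: int = 1200,
                       mean_reads_per_molecule: float = 5.0,
                       random_error_rate: float = 1e-3,
                       systematic_quality: float = 12.0,
                       base_quality: float = 35.0,
                       umi_error_rate: float = 0.002,
                       seed: int = 0) -> list[Rearrangement]:
    """UMI-tagged read set for the same sample a manifest describes.

    Molecules are assigned to the true subclones multinomially; each gets a
    random UMI laid out per ``pattern`` and a Poisson number of reads
    (minimum 1).  Reads carry the same error model as the UMI-free path:
    random errors plus the manifest's systematic context errors at low
    quality; UMI bases themselves err at ``umi_error_rate``.
    """
    rng = np.random.default_rng(seed)
    templates = [np.frombuffer(s.encode(), np.uint8).copy()
                 for s in truth.subclone_sequences]
    length = len(templates[0])
    assignment = rng.multinomial(n_molecules, truth.frequencies)
    reads = []
    mol = 0
    for t, n_mol in enumerate(assignment):
        template = templates[t]
        tstring = template.tobytes().decode()
        sys_sites = []
        for context, alt, rate in truth.systematic_errors:
            half = len(context) // 2
            search = 0
            while True:
                hit = tstring.find(context, search)
                if hit < 0:
                    break
                sys_sites.append((hit + half, ord(alt), rate))
                search = hit + 1
        for _ in range(n_mol):
            umi_blocks = ["".join("ACGT"[i] for i in rng.integers(0, 4,
                                                                  pattern.block_length))
                          for _ in range(pattern.n_blocks)]
            prefix = "".join(b + s for b, s in zip(umi_blocks, pattern.spacers))
            n_reads = max(1, rng.poisson(mean_reads_per_molecule))
            for r in range(n_reads):
                payload = template.copy()
                qual = np.full(length, base_quality)
                n_err = rng.binomial(length, random_error_rate)
                if n_err:
                    cols = rng.choice(length, size=n_err, replace=False)
                    cur = np.array([_BASE_INDEX[b] for b in payload[cols]])
                    payload[cols] = _BASES[(cur + rng.integers(1, 4, n_err)) % 4]
                for pos, alt, rate in sys_sites:
                    if rng.random() < rate:
                        payload[pos] = alt
                        qual[pos] = systematic_quality
                tag = list(prefix)
                n_tag_err = rng.binomial(len(tag), umi_error_rate)
                for pos in rng.choice(len(tag), size=n_tag_err, replace=False):
                    tag[pos] = "ACGT"[rng.integers(0, 4)]
                reads.append(Rearrangement(
                    sequence_id=f"m{mol}_r{r}",
                    sequence="".join(tag) + payload.tobytes().decode()
                    + truth.junction,
                    junction=truth.junction,
                    quality=np.concatenate([
                        np.full(len(tag), base_quality), qual,
                        np.full(len(truth.junction), base_quality)]),
                ))
            mol += 1
    return reads


# ---------------------------------------------------------------------------
# survival cohorts


def simulate_cohort(n_samples: int,
                    id_high_fraction: float = 0.15,
                    m_fraction: float = 0.52,
                    hazards: Optional[dict[str, float]] = None,
                    censor_max_months: float = 180.0,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Clinical cohort: iSI values straddling 1.2 plus exponential TTFT.

    Each sample gets an IGHV status (M with probability ``m_fraction``),
    an ID class (ID_high with probability ``id_high_fraction``), an iSI
    drawn from the class-specific distribution (ID_low in [1, 1.2),
    ID_high 1.2 upward with a long tail), an exponential event time with
    the stratum's hazard and uniform censoring on [0, censor_max_months].
    """
    if not 0 <= id_high_fraction <= 1:
        raise ValueError("id_high_fraction must lie in [0, 1]")
    hazards = dict(DEFAULT_HAZARDS if hazards is None else hazards)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        status = "M" if rng.random() < m_fraction else "U"
        id_class = "ID_high" if rng.random() < id_high_fraction else "ID_low"
        if id_class == "ID_low":
            isi = 1.0 + 0.1999 * rng.beta(1.0, 3.0)
        else:
            isi = 1.2 + rng.exponential(1.0)
        event_time = rng.exponential(1.0 / hazards[f"{status}-{id_class}"])
        censor_time = rng.uniform(0.0, censor_max_months)
        rows.append({
            "sample_id": f"P{i:04d}",
            "mutational_status": status,
            "id_class": id_class,
            "isi": round(isi, 4),
            "time_months": round(min(event_time, censor_time), 2),
            "event": event_time <= censor_time,
        })
    df = pd.DataFrame(rows, columns=["sample_id", "mutational_status", "id_class",
                                     "isi", "time_months", "event"])
    truth = {"hazards": hazards, "id_high_fraction": id_high_fraction,
             "m_fraction": m_fraction, "seed": seed}
    return df, truth
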