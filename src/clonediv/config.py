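"""Pipeline configuration: every stage threshold in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig"]

_EXPLANATIONS = {
    "min_clone_reads": "evaluability gate: clone reads required before iSI is "
                       "computed; 5000 reads make a 0.1% subclone >= 5 reads",
    "min_subclone_freq": "subclone retention gate as a fraction of clone reads "
                         "(0.001 = the 0.1% filter)",
    "isi_cutoff": "inverse Simpson index dichotomizing ID_high vs ID_low "
                  "(maxstat-derived 1.23, rounded to 1.2)",
    "isi_boundary": "'ge' counts iSI equal to the cutoff as ID_high",
    "quality_floor": "Phred score below which a variant base is treated as "
                     "unreliable during artifact detection/correction",
    "systematic_max_freq": "variant frequency above which a subclone is "
                           "considered genuine and never corrected",
    "min_recurrence": "distinct clones an artifact context must recur in "
                      "before blacklisting",
    "context_k": "k-mer width of the artifact context centered on the error",
    "cdr3_mode": "clone grouping: exact junction match or same-length "
                 "similarity",
    "umi_min_reads": "reads per UMI group required to emit a consensus",
    "umi_collapse_distance": "Hamming distance within which UMIs merge",
    "maxstat_window": "inner quantile window searched for survival cutpoints",
    "q_grid_max": "upper bound of the Hill-number order grid",
    "q_grid_step": "step of the Hill-number order grid",
    "seed": "base seed for every stochastic stage",
}


@dataclass
class PipelineConfig:
    min_clone_reads: int = 5000
    min_subclone_freq: float = 0.001
    isi_cutoff: float = 1.2
    isi_boundary: str = "ge"
    quality_floor: float = 20.0
    systematic_max_freq: float = 0.02
    min_recurrence: int = 5
    context_k: int = 5
    cdr3_mode: str = "exact"
    umi_min_reads: int = 3
    umi_collapse_distance: int = 1
    maxstat_window: tuple[float, float] = (0.1, 0.9)
    q_grid_max: float = 4.0
    q_grid_step: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.min_clone_reads <= 0 or self.min_subclone_freq <= 0:
            raise ValueError("thresholds must be positive")
        if self.isi_cutoff < 1:
            raise ValueError("isi_cutoff must be >= 1")
        self.maxstat_window = tuple(self.maxstat_window)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["maxstat_window"] = list(self.maxstat_window)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def explain(self) -> str:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            note = _EXPLANATIONS.get(f.name, "")
            lines.append(f"{f.name} = {value!r}  # {note}")
        return "\n".join(lines)
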