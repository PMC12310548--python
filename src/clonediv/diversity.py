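"""Hill-number diversity profiles and the inverse Simpson index (iSI).

The Hill number of order q for a subclone frequency vector p is
``(sum p_i^q)^(1/(1-q))``, with the Shannon limit ``exp(-sum p ln p)`` at
q = 1 and richness S at q = 0.  The inverse Simpson index is the q = 2
value, ``1 / sum p_i^2`` — the effective number of equally abundant
subclones.  Samples are dichotomized ID_high (iSI >= 1.2) vs ID_low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clones import CloneProfile

__all__ = [
    "DiversityProfile",
    "hill_number",
    "inverse_simpson",
    "classify_id",
    "diversity_profile",
    "DEFAULT_ISI_CUTOFF",
    "DEFAULT_Q_GRID",
]

DEFAULT_ISI_CUTOFF = 1.2
DEFAULT_Q_GRID = np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10)

_NORM_TOL = 1e-9


@dataclass
class DiversityProfile:
    q_grid: np.ndarray
    hill_values: np.ndarray
    isi: float
    p_major: float
    id_class: str  # "ID_high" | "ID_low"
    cutoff: float = DEFAULT_ISI_CUTOFF


def _check_frequencies(frequencies) -> np.ndarray:
    p = np.asarray(frequencies, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("frequencies must be a non-empty 1-D vector")
    if np.any(p <= 0):
        raise ValueError("frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum()!r})")
    return p


def hill_number(frequencies, q: float) -> float:
    """Hill number of order ``q`` of a normalized frequency vector."""
    p = _check_frequencies(frequencies)
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def inverse_simpson(frequencies) -> float:
    """iSI = 1 / sum p_i^2 (Hill number of order 2)."""
    p = _check_frequencies(frequencies)
    return float(1.0 / np.sum(p * p))


def classify_id(isi: float, cutoff: float = DEFAULT_ISI_CUTOFF,
                boundary: str = "ge") -> str:
    """ID_high/ID_low call; the boundary value itself is ID_high by default."""
    if isi < 1.0 - 1e-12:
        raise ValueError(f"iSI must be >= 1 (got {isi})")
    if boundary == "ge":
        return "ID_high" if isi >= cutoff else "ID_low"
    if boundary == "gt":
        return "ID_high" if isi > cutoff else "ID_low"
    raise ValueError(f"unknown boundary policy {boundary!r}")


def diversity_profile(profile: CloneProfile,
                      q_grid=None,
                      cutoff: float = DEFAULT_ISI_CUTOFF,
                      boundary: str = "ge") -> DiversityProfile:
    """Full Hill profile plus the iSI-based ID call for one clone profile."""
    if not profile.evaluable:
        raise ValueError(
            f"sample {profile.sample_id or '?'} is non-evaluable: clone reads "
            f"{profile.clone_reads} fall below the 5000-read gate")
    q_grid = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    p = profile.frequencies()
    p = p / p.sum()  # absorb rounding from renormalized counts
    hill = np.array([hill_number(p, q) for q in q_grid])
    isi = inverse_simpson(p)
    return DiversityProfile(
        q_grid=q_grid,
        hill_values=hill,
        isi=isi,
        p_major=float(p.max()),
        id_class=classify_id(isi, cutoff=cutoff, boundary=boundary),
        cutoff=cutoff,
    )
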