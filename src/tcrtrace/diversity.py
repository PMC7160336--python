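"""Shannon entropy/evenness, Hill diversity, and clonal-expansion profiles.

Definitions (natural log throughout, so that the exponential in the
evenness definition cancels the base):

    Shannon entropy   H(f) = −Σ_i f_i ln f_i
    Shannon evenness  S-E  = exp(H) / SR
    Hill diversity    qD   = (Σ_i f_i^q)^(1/(1−q)),  qD → exp(H) as q → 1,
                      0D   = SR (species richness)

The *clonal-expansion profile* (evenness profile) of a repertoire is the
vector qD/SR over a q grid (default 0..10 in steps of 0.2, 51 points).
S-E is 1 for a perfectly even repertoire and tends to 0 when few clones
dominate; raising q weights high-frequency clones more, so the profile
decays faster for more polarized repertoires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Repertoire, RepertoireError

#: q grid used for clonal-expansion profiles: 0 to 10, step 0.2.
DEFAULT_Q_GRID = np.round(np.arange(0, 10.2, 0.2), 10)

_Q1_TOL = 1e-9  # |q − 1| below this is routed to the analytic limit


def _check_frequencies(frequencies) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise RepertoireError("frequency vector must be 1-D and non-empty")
    if np.any(f <= 0):
        raise RepertoireError("frequencies must be strictly positive")
    if abs(f.sum() - 1.0) > 1e-9:
        raise RepertoireError(f"frequencies must sum to 1, got {f.sum()!r}")
    return f


def shannon_entropy(frequencies) -> float:
    """H = −Σ f_i ln f_i (zero for a single-clone repertoire)."""
    f = _check_frequencies(frequencies)
    return float(-np.sum(f * np.log(f)))


def shannon_evenness(frequencies) -> float:
    """exp(H)/SR: 1 for uniform frequencies, → 0 for polarized repertoires."""
    f = _check_frequencies(frequencies)
    return math.exp(shannon_entropy(f)) / f.size


def hill_diversity(frequencies, q: float) -> float:
    """Hill number of order q; the q = 1 singularity takes the exp(H) limit."""
    f = _check_frequencies(frequencies)
    if q < 0:
        raise RepertoireError(f"Hill order q must be >= 0, got {q}")
    if q == 0:
        return float(f.size)
    if abs(q - 1.0) < _Q1_TOL:
        return math.exp(shannon_entropy(f))
    return float(np.sum(f ** q) ** (1.0 / (1.0 - q)))


@dataclass(slots=True)
class EvennessProfile:
    """qD/SR over a q grid: a repertoire's state of clonal expansion."""

    sample_id: str
    q_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.q_grid.shape != self.values.shape:
            raise RepertoireError("q_grid and values must have identical shape")


def evenness_profile(r: Repertoire, q_grid=None) -> EvennessProfile:
    """Hill diversity profile scaled by species richness, per grid point."""
    q_grid = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    f = r.frequencies()
    sr = f.size
    values = np.array([hill_diversity(f, q) / sr for q in q_grid])
    return EvennessProfile(sample_id=r.sample_id, q_grid=q_grid, values=values)


def profile_correlation_matrix(profiles) -> pd.DataFrame:
    """Pairwise Pearson r between evenness profiles, as a labeled square matrix.

    Pairs where either profile has zero variance across q are undefined and
    reported as NaN; the diagonal is 1 by convention.  All profiles must
    share one q grid.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise RepertoireError("need at least 2 profiles")
    grid = profiles[0].q_grid
    for p in profiles[1:]:
        if p.q_grid.shape != grid.shape or not np.allclose(p.q_grid, grid):
            raise RepertoireError(
                f"profile {p.sample_id!r} is on a different q grid"
            )
    ids = [p.sample_id for p in profiles]
    mat = np.vstack([p.values for p in profiles])
    return _pearson_matrix(mat, ids)


def _pearson_matrix(rows: np.ndarray, ids) -> pd.DataFrame:
    """Row-wise Pearson correlation with NaN for zero-variance rows; diag 1."""
    n = rows.shape[0]
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    out = np.empty((n, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(norms, norms)
        out = centered @ centered.T / denom
    out[denom == 0] = np.nan
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=ids, columns=ids)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Wide table (samples × q) of evenness-profile values, for TSV export."""
    profiles = list(profiles)
    cols = [f"q={q:g}" for q in profiles[0].q_grid]
    return pd.DataFrame(
        [p.values for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=cols,
    )
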