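"""Ensemble statistics over pseudorotation phases.

Turns a series of per-conformer pucker states (e.g. from an MD trajectory)
into a circular histogram with hemisphere and named-bin occupancies plus
circular summaries (mean direction and mean resultant length). Planar
(degenerate) conformers carry no phase and are excluded from all
distributions; their count is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import directional_stats

from .pucker import DEFAULT_SCHEME, ClassificationScheme, Hemisphere, \
    NamedBin, PuckerState, _wrap360

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 5.0


def _phases(series) -> tuple[np.ndarray, int]:
    """Extract finite phases from PuckerStates (or bare angles)."""
    if len(series) == 0:
        raise ValueError("empty pucker series")
    raw = [s.P if isinstance(s, PuckerState) else float(s) for s in series]
    arr = np.asarray(raw, dtype=float)
    finite = np.isfinite(arr)
    n_degenerate = int((~finite).sum())
    if n_degenerate:
        logger.info("excluding %d degenerate (planar) conformer(s)",
                    n_degenerate)
    return _wrap360(arr[finite]), n_degenerate


@dataclass(frozen=True)
class PuckerDistribution:
    """Circular histogram of pseudorotation phases with occupancies.

    probabilities sum to 1; hemisphere fractions (northern/southern) and
    named-bin fractions (C3'-endo / C2'-endo / other) are count-based over
    the same conformers; circular_mean is the mean direction in degrees
    and resultant_length the mean resultant (1 = fully concentrated).
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n: int
    hemisphere_fractions: dict
    bin_fractions: dict
    circular_mean: float
    resultant_length: float
    n_degenerate: int = 0
    scheme: ClassificationScheme = field(default=DEFAULT_SCHEME,
                                         compare=False)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "probability": self.probabilities})

    def summary(self) -> dict:
        return {
            "n": self.n,
            "n_degenerate": self.n_degenerate,
            "hemisphere_fractions": dict(self.hemisphere_fractions),
            "bin_fractions": dict(self.bin_fractions),
            "circular_mean": self.circular_mean,
            "resultant_length": self.resultant_length,
        }


def circular_summary(series) -> tuple[float, float]:
    """Mean direction (degrees, [0, 360)) and mean resultant length.

    The mean direction is the angle of the vector resultant of unit
    vectors at each phase; its length divided by n is the resultant
    length. For a perfectly antipodal sample the resultant vanishes and
    the mean is undefined: NaN is returned with resultant_length 0.
    """
    phases, n_deg = _phases(series)
    if phases.size == 0:
        raise ValueError("all conformers are degenerate; no phases to "
                         "summarise")
    vectors = np.column_stack([np.cos(np.radians(phases)),
                               np.sin(np.radians(phases))])
    res = directional_stats(vectors)
    length = float(np.linalg.norm(np.mean(vectors, axis=0)))
    if length < 1e-12:
        return float("nan"), 0.0
    mean = float(_wrap360(np.degrees(
        np.arctan2(res.mean_direction[1], res.mean_direction[0]))))
    return mean, length


def pucker_histogram(series, bin_width: float = DEFAULT_BIN_WIDTH,
                     scheme: ClassificationScheme = DEFAULT_SCHEME,
                     ) -> PuckerDistribution:
    """Probability-normalised circular histogram of pseudorotation phases.

    ``bin_width`` must divide 360 so the bins tile the circle exactly and
    no mass is lost at the 0/360 wrap; edges are aligned to multiples of
    the bin width. Degenerate conformers are excluded (count reported).
    """
    if not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError(f"bin width {bin_width} does not divide 360")
    phases, n_degenerate = _phases(series)
    if phases.size == 0:
        raise ValueError("all conformers are degenerate; nothing to bin")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    probabilities = counts / phases.size

    hemi = np.array([scheme.hemisphere(p).value for p in phases])
    named = np.array([scheme.named_bin(p).value for p in phases])
    n = phases.size
    hemisphere_fractions = {
        "northern": float(np.sum(hemi == Hemisphere.NORTHERN.value) / n),
        "southern": float(np.sum(hemi == Hemisphere.SOUTHERN.value) / n),
    }
    bin_fractions = {
        "C3_endo": float(np.sum(named == NamedBin.C3_ENDO.value) / n),
        "C2_endo": float(np.sum(named == NamedBin.C2_ENDO.value) / n),
        "other": float(np.sum(named == NamedBin.NONE.value) / n),
    }
    mean, length = circular_summary(list(phases))
    return PuckerDistribution(
        bin_edges=edges, probabilities=probabilities, n=n,
        hemisphere_fractions=hemisphere_fractions,
        bin_fractions=bin_fractions, circular_mean=mean,
        resultant_length=length, n_degenerate=n_degenerate, scheme=scheme)


def compare_ensembles(a: PuckerDistribution, b: PuckerDistribution) -> dict:
    """Descriptive per-bin and occupancy differences between two ensembles.

    Purely descriptive (differences a - b); requires identical binning.
    No significance test is attached: occupancy shifts between ensembles
    are reported as-is.
    """
    if a.bin_edges.shape != b.bin_edges.shape or \
            not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("ensembles use different binning; rebin first")
    return {
        "bin_centers": a.bin_centers.tolist(),
        "probability_difference": (a.probabilities - b.probabilities).tolist(),
        "hemisphere_difference": {
            k: a.hemisphere_fractions[k] - b.hemisphere_fractions[k]
            for k in a.hemisphere_fractions
        },
        "bin_difference": {
            k: a.bin_fractions[k] - b.bin_fractions[k]
            for k in a.bin_fractions
        },
        "n": {"a": a.n, "b": b.n},
    }
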