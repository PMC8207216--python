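"""Pseudorotation phase, amplitude and sugar-pucker classification.

The furanose ring conformation is summarised on the Altona-Sundaralingam
pseudorotation wheel by a phase angle P (degrees, [0, 360)) and an amplitude
nu_max (degrees, >= 0). The five endocyclic torsions of an ideally
pseudorotating ring obey

    nu_j = nu_max * cos(P + 144 * (j - 2)),   j = 0..4

from which P is recovered as

    tan P = (nu4 + nu1 - nu3 - nu0) / (2 * nu2 * (sin 36 + sin 72))

with 180 degrees added when nu2 < 0. Internally the atan2 form of the same
expression is used, which is stable through nu2 = 0 and provably identical
to the tangent-plus-correction recipe wherever nu2 != 0 (see the test
suite). C3'-endo puckers sit near P = 18 (RNA-like, northern hemisphere)
and C2'-endo near P = 162 (B-DNA-like, southern hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import SchemeError
from .geometry import TorsionSet

_SIN36_PLUS_SIN72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))

#: below this max|nu| (degrees) a ring is treated as planar; P undefined
PLANARITY_THRESHOLD = 1.0

#: |cos P| below which amplitude falls back to a least-squares estimate
_COSP_CUTOFF = 0.1

#: phase offsets 144*(j-2) degrees of the five torsions
_PHASE_OFFSETS = np.array([-288.0, -144.0, 0.0, 144.0, 288.0])


class Hemisphere(str, Enum):
    NORTHERN = "northern"
    SOUTHERN = "southern"


class NamedBin(str, Enum):
    C3_ENDO = "C3_endo"
    C2_ENDO = "C2_endo"
    NONE = "none"


def _wrap360(angle):
    """Map angle(s) in degrees onto [0, 360); 360.0 itself folds to 0."""
    wrapped = np.mod(angle, 360.0)
    # np.mod(-1e-16, 360) rounds to 360.0; fold it back
    return np.where(wrapped >= 360.0, 0.0, wrapped) if np.ndim(wrapped) \
        else (0.0 if wrapped >= 360.0 else wrapped)


def _in_circular_interval(p: float, lo: float, hi: float,
                          closed_hi: bool = False) -> bool:
    """Membership of angle p in the circular arc from lo to hi (degrees)."""
    p = float(_wrap360(p))
    lo = float(_wrap360(lo))
    hi = float(_wrap360(hi))
    span = _wrap360(hi - lo)
    off = _wrap360(p - lo)
    if closed_hi:
        return off <= span
    return off < span


@dataclass(frozen=True)
class ClassificationScheme:
    """Hemisphere and named-bin boundaries on the pseudorotation wheel.

    Hemispheres are half-open arcs [lo, hi) partitioning the circle.
    Named bins are closed arcs [lo, hi]; each must lie inside one
    hemisphere. Defaults follow the usual wheel: northern (-90, +90),
    southern (+90, +270), C3'-endo (-10, +40), C2'-endo (+140, +185).
    """

    northern: tuple = (-90.0, 90.0)
    southern: tuple = (90.0, 270.0)
    c3_endo: tuple = (-10.0, 40.0)
    c2_endo: tuple = (140.0, 185.0)

    def __post_init__(self):
        n_span = _wrap360(self.northern[1] - self.northern[0])
        s_span = _wrap360(self.southern[1] - self.southern[0])
        if not np.isclose(n_span + s_span, 360.0):
            raise SchemeError(
                "hemisphere arcs must partition the circle "
                f"(spans {n_span} + {s_span} != 360)"
            )
        if not np.isclose(_wrap360(self.northern[1]),
                          _wrap360(self.southern[0])):
            raise SchemeError("southern arc must start where northern ends")
        for name, (lo, hi), hemi in (
            ("C3_endo", self.c3_endo, self.northern),
            ("C2_endo", self.c2_endo, self.southern),
        ):
            for endpoint in (lo, hi):
                if not _in_circular_interval(endpoint, hemi[0], hemi[1],
                                             closed_hi=True):
                    raise SchemeError(
                        f"named bin {name} [{lo}, {hi}] crosses its "
                        f"hemisphere boundary {hemi}"
                    )

    def hemisphere(self, p: float) -> Hemisphere:
        if _in_circular_interval(p, *self.northern):
            return Hemisphere.NORTHERN
        return Hemisphere.SOUTHERN

    def named_bin(self, p: float) -> NamedBin:
        if _in_circular_interval(p, *self.c3_endo, closed_hi=True):
            return NamedBin.C3_ENDO
        if _in_circular_interval(p, *self.c2_endo, closed_hi=True):
            return NamedBin.C2_ENDO
        return NamedBin.NONE


DEFAULT_SCHEME = ClassificationScheme()


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase, amplitude and classification for one conformer.

    P is NaN and ``degenerate`` is True for (near-)planar rings, where the
    phase is undefined.
    """

    P: float
    nu_max: float
    hemisphere: Hemisphere | None
    named_bin: NamedBin | None
    degenerate: bool = False
    torsions: TorsionSet | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.degenerate:
            if not (0.0 <= self.P < 360.0):
                raise ValueError(f"P={self.P} outside [0, 360)")
            if self.nu_max < 0:
                raise ValueError(f"nu_max={self.nu_max} negative")


def pseudorotation_phase(t: TorsionSet,
                         scheme: ClassificationScheme = DEFAULT_SCHEME,
                         ) -> PuckerState:
    """Pseudorotation phase P, amplitude nu_max and classification.

    Uses P = atan2(nu4 + nu1 - nu3 - nu0, 2*nu2*(sin36 + sin72)) wrapped to
    [0, 360); equivalent to arctan of the ratio plus 180 degrees when
    nu2 < 0. A ring with max|nu| below ``PLANARITY_THRESHOLD`` is flagged
    degenerate rather than assigned a phase. The amplitude is nu2 / cos P
    when |cos P| > 0.1, otherwise a least-squares projection of all five
    torsions onto the cosine wave at the computed phase.
    """
    nu = t.as_array()
    if np.max(np.abs(nu)) < PLANARITY_THRESHOLD:
        return PuckerState(P=float("nan"), nu_max=float("nan"),
                           hemisphere=None, named_bin=None,
                           degenerate=True, torsions=t)
    num = t.v4 + t.v1 - t.v3 - t.v0
    den = 2.0 * t.v2 * _SIN36_PLUS_SIN72
    p = float(_wrap360(np.degrees(np.arctan2(num, den))))
    cos_p = np.cos(np.radians(p))
    if abs(cos_p) > _COSP_CUTOFF:
        nu_max = t.v2 / cos_p
    else:
        basis = np.cos(np.radians(p + _PHASE_OFFSETS))
        nu_max = float(np.dot(nu, basis) / np.dot(basis, basis))
    nu_max = abs(float(nu_max))
    return PuckerState(P=p, nu_max=nu_max,
                       hemisphere=scheme.hemisphere(p),
                       named_bin=scheme.named_bin(p),
                       degenerate=False, torsions=t)


def pseudorotation_phase_literal(t: TorsionSet) -> float:
    """The tangent-plus-correction recipe for P, wrapped to [0, 360).

    Computes arctan of the torsion ratio and adds 180 degrees when nu2 is
    negative. Undefined at nu2 = 0. Kept as the published reference form;
    the atan2 implementation must agree with it everywhere it is defined.
    """
    if t.v2 == 0:
        raise ZeroDivisionError("literal recipe undefined at nu2 = 0")
    num = t.v4 + t.v1 - t.v3 - t.v0
    den = 2.0 * t.v2 * _SIN36_PLUS_SIN72
    p = np.degrees(np.arctan(num / den))
    if t.v2 < 0:
        p += 180.0
    return float(_wrap360(p))


def classify_pucker(p: float,
                    scheme: ClassificationScheme = DEFAULT_SCHEME,
                    ) -> tuple[Hemisphere, NamedBin]:
    """Hemisphere and named-bin labels for a pseudorotation phase.

    Membership is circular, so -10 and 350 degrees are the same angle.
    Total over finite P: every phase receives a hemisphere.
    """
    if not np.isfinite(p):
        raise ValueError(f"P must be finite, got {p!r}")
    return scheme.hemisphere(p), scheme.named_bin(p)
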