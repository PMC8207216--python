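"""Synthetic ground-truth generators for every pipeline input.

Emulates the study conditions end to end with known truth: torsion sets and
3D rings at a prescribed pseudorotation phase, conformer ensembles drawn
from von Mises mixtures on the pseudorotation wheel (northern- vs
southern-dominated, mimicking RNA-like rAP-substrate vs B-DNA-like deoxy-AP
ensembles), biphasic product-formation time courses, and tight-binding
titrations. Every generator is deterministic under its seed and stochastic
outputs carry ground-truth sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RING_ATOMS, RingAtomSet, TorsionSet
from .pucker import _PHASE_OFFSETS

# ring-bond length used by the 3D embedder; analysis depends only on
# torsions, so an idealized C-C value serves all five bonds
RING_BOND_LENGTH = 1.54

# one-time numeric calibration of the embedder: the analyzed pseudorotation
# phase of a ring with out-of-plane wave phase phi is phi + 126 degrees,
# within +-1 degree for puckering amplitudes q <= 0.5 A
_EMBED_PHASE_OFFSET = 126.0

# default kinetic time grid: 12 log-spaced points over 0.1-10 s
DEFAULT_TIMEPOINTS = np.geomspace(0.1, 10.0, 12)

# default EMSA-style titrant grid, nM: 0-20 nM protein bracketing a
# low-nM K_D at 2 nM probe DNA
DEFAULT_A_T_GRID = np.array(
    [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 15.0, 20.0]
)


def gen_torsion_set(p: float, nu_max: float) -> TorsionSet:
    """Endocyclic torsions of an ideally pseudorotating ring.

    Constructs nu_j = nu_max * cos(P + 144*(j-2)) degrees, the exact inverse
    of the phase-angle formula: analysing the result returns P to machine
    precision and the five torsions sum to zero.
    """
    if nu_max < 0:
        raise ValueError(f"nu_max must be >= 0, got {nu_max}")
    nus = nu_max * np.cos(np.radians(p + _PHASE_OFFSETS))
    return TorsionSet(*nus)


def torsion_sets_at(p_values: np.ndarray, nu_max: float) -> np.ndarray:
    """Vectorised torsion construction: (n, 5) array for an array of P."""
    p_values = np.asarray(p_values, dtype=float)
    return nu_max * np.cos(np.radians(p_values[:, None] + _PHASE_OFFSETS))


def gen_ring_coords(p: float, q: float = 0.38, **provenance) -> RingAtomSet:
    """Closed 3D furanose ring with analyzed pseudorotation phase near P.

    A regular pentagon of bond length 1.54 A carries out-of-plane
    displacements z_j = sqrt(2/5) * q * cos(phi + 4*pi*j/5), with phi set
    from a one-time numeric calibration so the analyzed phase lands within
    +-2 degrees of the request (the exact wobble depends weakly on q).
    q = 0 yields a planar pentagon, flagged degenerate downstream.
    q = 0.38 A corresponds to an amplitude nu_max of roughly 37 degrees.
    """
    if q < 0:
        raise ValueError(f"puckering amplitude q must be >= 0, got {q}")
    phi = np.radians(p - _EMBED_PHASE_OFFSET)
    radius = RING_BOND_LENGTH / (2.0 * np.sin(np.pi / 5.0))
    j = np.arange(5)
    theta = 2.0 * np.pi * j / 5.0
    z = np.sqrt(2.0 / 5.0) * q * np.cos(phi + 4.0 * np.pi * j / 5.0)
    coords = {
        name: np.array([radius * np.cos(t), radius * np.sin(t), zz])
        for name, t, zz in zip(RING_ATOMS, theta, z)
    }
    return RingAtomSet(coords, **provenance)


@dataclass(frozen=True)
class PuckerMixtureSpec:
    """A von Mises mixture on the pseudorotation wheel.

    components: list of (center P in degrees, concentration kappa, weight);
    weights must sum to 1 and every kappa must be positive.
    """

    components: tuple
    n: int
    seed: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("conformer count n must be >= 1")
        comps = tuple(tuple(map(float, c)) for c in self.components)
        if not comps:
            raise ValueError("at least one mixture component required")
        weights = np.array([c[2] for c in comps])
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError(f"component weights sum to {weights.sum()}, not 1")
        if np.any(weights < 0):
            raise ValueError("component weights must be nonnegative")
        if any(c[1] <= 0 for c in comps):
            raise ValueError("every concentration kappa must be > 0")
        object.__setattr__(self, "components", comps)


def sample_pucker_phases(spec: PuckerMixtureSpec) -> np.ndarray:
    """Draw n pseudorotation phases (degrees, [0, 360)) from the mixture."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[2] for c in spec.components])
    which = rng.choice(len(spec.components), size=spec.n, p=weights)
    phases = np.empty(spec.n)
    for i, (center, kappa, _) in enumerate(spec.components):
        mask = which == i
        phases[mask] = np.degrees(
            rng.vonmises(np.radians(center), kappa, size=int(mask.sum()))
        )
    return np.mod(phases, 360.0)


@dataclass(frozen=True)
class TrajectoryResult:
    """In-memory trajectory plus paths of any files written."""

    true_p: np.ndarray
    torsions: np.ndarray          # (n, 5) degrees
    torsion_table: Path | None = None
    pdb_file: Path | None = None
    sidecar: Path | None = None


def gen_pucker_trajectory(spec: PuckerMixtureSpec,
                          nu_max: float = 38.0,
                          q: float = 0.38,
                          out_dir: str | Path | None = None,
                          stem: str = "trajectory",
                          write_pdb: bool = False,
                          ) -> TrajectoryResult:
    """Synthetic conformer ensemble with per-conformer ground truth.

    Phases are drawn from the von Mises mixture; each conformer is realised
    as an exact torsion set (and, when ``write_pdb`` is set, as a 3D ring in
    a multi-model PDB). When ``out_dir`` is given, a TSV torsion table and a
    JSON ground-truth sidecar (true per-conformer P) are written beside any
    PDB output. Deterministic under ``spec.seed``.
    """
    phases = sample_pucker_phases(spec)
    torsions = torsion_sets_at(phases, nu_max)
    table_path = pdb_path = sidecar_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table_path = out_dir / f"{stem}_torsions.tsv"
        df = pd.DataFrame(torsions, columns=["v0", "v1", "v2", "v3", "v4"])
        df.to_csv(table_path, sep="\t", index=False, float_format="%.9g")
        sidecar_path = out_dir / f"{stem}_truth.json"
        sidecar_path.write_text(json.dumps({
            "seed": spec.seed,
            "n": spec.n,
            "nu_max": nu_max,
            "components": [list(c) for c in spec.components],
            "true_P": [round(float(p), 9) for p in phases],
        }, indent=1))
        if write_pdb:
            pdb_path = out_dir / f"{stem}.pdb"
            write_ring_trajectory_pdb(phases, pdb_path, q=q)
    return TrajectoryResult(true_p=phases, torsions=torsions,
                            torsion_table=table_path, pdb_file=pdb_path,
                            sidecar=sidecar_path)


def write_ring_trajectory_pdb(phases: np.ndarray, path: str | Path,
                              q: float = 0.38, chain_id: str = "A",
                              residue_number: int = 7,
                              residue_name: str = "RAB") -> Path:
    """Write one embedded ring per phase as a multi-model PDB file.

    Uses gemmi for the record formatting; the het residue name defaults to
    a synthetic abasic-site code.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic pucker trajectory"
    for m, p in enumerate(np.atleast_1d(phases), start=1):
        ring = gen_ring_coords(float(p), q=q, model_index=m,
                               chain_id=chain_id,
                               residue_number=residue_number)
        model = gemmi.Model(m)
        chain = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = residue_name
        res.seqid = gemmi.SeqId(residue_number, " ")
        res.het_flag = "H"
        for name in RING_ATOMS:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.occ = 1.0
            x, y, z = ring.coords[name]
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))
    return Path(path)


def gen_time_course(amplitude: float, k_obs: float, v_ss: float,
                    timepoints: np.ndarray | None = None,
                    noise_sd: float = 0.0, replicates: int = 3,
                    seed: int = 0):
    """Synthetic product-formation time course with Gaussian noise.

    Evaluates product = A(1 - exp(-k_obs t)) + v_ss t on the timepoint grid
    (default 12 log-spaced points over 0.1-10 s), adds additive Gaussian
    noise of standard deviation ``noise_sd`` (nM) truncated at zero, and
    repeats for each replicate. Deterministic under ``seed``.
    """
    from .enzymology import TimeCourse, burst_model_eval

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = DEFAULT_TIMEPOINTS if timepoints is None else np.asarray(timepoints,
                                                                 dtype=float)
    rng = np.random.default_rng(seed)
    rows_t, rows_p, rows_r = [], [], []
    clean = burst_model_eval(amplitude, k_obs, v_ss, t)
    for rep in range(1, replicates + 1):
        noisy = clean + rng.normal(0.0, noise_sd, size=t.shape) \
            if noise_sd > 0 else clean.copy()
        rows_t.append(t)
        rows_p.append(np.maximum(noisy, 0.0))
        rows_r.append(np.full(t.shape, rep, dtype=int))
    return TimeCourse(t=np.concatenate(rows_t),
                      product=np.concatenate(rows_p),
                      replicate=np.concatenate(rows_r))


def gen_titration(k_d: float, b_total: float,
                  a_t_grid: np.ndarray | None = None,
                  noise_sd: float = 0.0, seed: int = 0):
    """Synthetic binding titration: fraction bound vs total protein.

    Fraction bound is AB/B_T from the quadratic tight-binding solution,
    plus Gaussian noise clipped to [0, 1]. Deterministic under ``seed``.
    """
    from .enzymology import Titration, quadratic_bound_eval

    if k_d <= 0 or b_total <= 0:
        raise ValueError("k_d and b_total must be > 0")
    a_t = DEFAULT_A_T_GRID if a_t_grid is None else np.asarray(a_t_grid,
                                                               dtype=float)
    frac = quadratic_bound_eval(a_t, b_total, k_d) / b_total
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = frac + rng.normal(0.0, noise_sd, size=a_t.shape)
    return Titration(a_total=a_t, fraction_bound=np.clip(frac, 0.0, 1.0),
                     b_total=b_total)
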