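"""Structure and table I/O: multi-model PDB files and torsion tables.

Reads crystal structures or trajectory snapshots stored as multi-model PDB
(MODEL/ENDMDL), locates a nucleotide's furanose ring atoms per model —
normalising both the primed (C1') and star (C1*) atom-name dialects and
accepting HETATM records, since abasic-site analogs are het groups — and
emits one pucker state per model. Plain TSV torsion tables (columns
v0..v4, degrees) provide a coordinate-free entry point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd

from .exceptions import (DataQualityWarning, MissingAtomError,
                         PuckerfitError, ResidueNotFoundError,
                         StructureParseError)
from .geometry import RING_ATOMS, RingAtomSet, TorsionSet, endocyclic_torsions
from .pucker import (DEFAULT_SCHEME, ClassificationScheme, PuckerState,
                     pseudorotation_phase)

TORSION_COLUMNS = ("v0", "v1", "v2", "v3", "v4")


@dataclass(frozen=True)
class ResidueSelector:
    """Selects one nucleotide by chain and residue number.

    Residue name is deliberately not part of the selector: abasic THF
    analogs carry inconsistent het codes across depositions. ``altloc``
    chooses among alternate locations: ``highest_occupancy`` (default,
    warns when alternates are discarded), ``all`` (one ring per altloc) or
    ``specified`` (requires ``altloc_id``).
    """

    chain_id: str
    residue_number: int
    altloc: str = "highest_occupancy"
    altloc_id: str = ""

    def __post_init__(self):
        if self.altloc not in ("highest_occupancy", "specified", "all"):
            raise ValueError(f"unknown altloc policy {self.altloc!r}")
        if self.altloc == "specified" and not self.altloc_id:
            raise ValueError("altloc policy 'specified' needs an altloc_id")


def _normalize_atom_name(name: str) -> str:
    """Map the star dialect (C1*) onto the primed dialect (C1')."""
    return name.strip().replace("*", "'")


def read_models(path: str | Path) -> list[gemmi.Model]:
    """Read a (multi-model) PDB file; models are returned in file order.

    Raises :class:`StructureParseError` for missing/unreadable files or
    files without any ATOM/HETATM record.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"structure file not found: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}")
    models = list(st)
    if not models or all(
        sum(len(res) for ch in m for res in ch) == 0 for m in models
    ):
        raise StructureParseError(
            f"{path} contains no atom records (zero models)")
    return models


def _find_residue(model: gemmi.Model, sel: ResidueSelector) -> gemmi.Residue:
    matches = []
    for chain in model:
        if chain.name != sel.chain_id:
            continue
        for res in chain:
            if res.seqid.num == sel.residue_number:
                matches.append(res)
    if not matches:
        raise ResidueNotFoundError(
            f"no residue {sel.chain_id}/{sel.residue_number} in model "
            f"{model.num}")
    if len(matches) > 1:
        raise ResidueNotFoundError(
            f"selector {sel.chain_id}/{sel.residue_number} is ambiguous: "
            f"{len(matches)} residues match in model {model.num}")
    return matches[0]


def _group_by_altloc(res: gemmi.Residue) -> dict[str, dict]:
    """Ring atoms grouped per altloc; blank-altloc atoms join every group."""
    shared: dict[str, gemmi.Atom] = {}
    groups: dict[str, dict[str, gemmi.Atom]] = {}
    for atom in res:
        name = _normalize_atom_name(atom.name)
        if name not in RING_ATOMS:
            continue
        alt = atom.altloc if atom.altloc else ""
        if alt == "":
            shared[name] = atom
        else:
            groups.setdefault(alt, {})[name] = atom
    if not groups:
        return {"": shared}
    for alt in groups:
        for name, atom in shared.items():
            groups[alt].setdefault(name, atom)
    return groups


def _ring_from_atoms(atoms: dict, model_num: int, sel: ResidueSelector,
                     altloc_id: str) -> RingAtomSet:
    missing = [n for n in RING_ATOMS if n not in atoms]
    if missing:
        raise MissingAtomError(
            f"atom(s) {', '.join(missing)} missing for residue "
            f"{sel.chain_id}/{sel.residue_number}"
            f"{' altloc ' + altloc_id if altloc_id else ''} "
            f"in model {model_num}")
    occ = [atoms[n].occ for n in RING_ATOMS]
    coords = {n: np.array([atoms[n].pos.x, atoms[n].pos.y, atoms[n].pos.z])
              for n in RING_ATOMS}
    return RingAtomSet(coords, model_index=model_num,
                       chain_id=sel.chain_id,
                       residue_number=sel.residue_number,
                       altloc_id=altloc_id,
                       occupancy_used=float(np.mean(occ)))


def extract_ring(model: gemmi.Model, sel: ResidueSelector,
                 ) -> list[RingAtomSet]:
    """Ring atom sets of the selected residue — one per selected altloc.

    With the default ``highest_occupancy`` policy a single ring is
    returned (the altloc with the largest summed occupancy, ties broken
    alphabetically) and a warning lists the discarded alternates.
    """
    res = _find_residue(model, sel)
    groups = _group_by_altloc(res)

    if sel.altloc == "all":
        return [_ring_from_atoms(groups[alt], model.num, sel, alt)
                for alt in sorted(groups)]
    if sel.altloc == "specified":
        if sel.altloc_id not in groups:
            raise ResidueNotFoundError(
                f"altloc {sel.altloc_id!r} not present for residue "
                f"{sel.chain_id}/{sel.residue_number} (available: "
                f"{sorted(groups)})")
        return [_ring_from_atoms(groups[sel.altloc_id], model.num, sel,
                                 sel.altloc_id)]

    # highest_occupancy: largest summed occupancy, alphabetical tiebreak
    def occ_sum(alt):
        return sum(a.occ for a in groups[alt].values())

    best = sorted(groups, key=lambda alt: (-occ_sum(alt), alt))[0]
    others = sorted(set(groups) - {best})
    if others:
        tied = [alt for alt in others if np.isclose(occ_sum(alt),
                                                    occ_sum(best))]
        note = " (occupancy tie broken alphabetically)" if tied else ""
        warnings.warn(
            f"residue {sel.chain_id}/{sel.residue_number} has alternate "
            f"location(s) {others}; using altloc {best!r} with summed "
            f"occupancy {occ_sum(best):.2f}{note}",
            DataQualityWarning, stacklevel=2)
    return [_ring_from_atoms(groups[best], model.num, sel, best)]


def pucker_series(path: str | Path, sel: ResidueSelector,
                  scheme: ClassificationScheme = DEFAULT_SCHEME,
                  ) -> list[PuckerState]:
    """Per-model pucker states for one residue of a multi-model PDB file.

    The composition read -> extract ring -> endocyclic torsions ->
    pseudorotation phase, applied model by model in file order. With the
    ``all`` altloc policy each model may contribute several states.
    """
    states = []
    for model in read_models(path):
        try:
            for ring in extract_ring(model, sel):
                states.append(
                    pseudorotation_phase(endocyclic_torsions(ring), scheme))
        except PuckerfitError as exc:
            raise type(exc)(f"model {model.num}: {exc}") from exc
    return states


def read_torsion_table(path: str | Path) -> list[TorsionSet]:
    """Read a TSV torsion table (columns v0..v4, degrees), row order kept."""
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"torsion table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TORSION_COLUMNS if c not in df.columns]
    if missing:
        raise StructureParseError(
            f"{path}: missing torsion column(s) {missing}")
    sets = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = [getattr(row, c) for c in TORSION_COLUMNS]
        try:
            sets.append(TorsionSet(*[float(v) for v in values]))
        except (TypeError, ValueError) as exc:
            raise StructureParseError(
                f"{path}: non-numeric torsion in data row {i + 1}: {exc}")
    return sets


def write_torsion_table(sets: list[TorsionSet], path: str | Path) -> Path:
    """Write torsion sets as TSV at 9 significant digits (lossless re-read)."""
    df = pd.DataFrame([t.as_array() for t in sets], columns=TORSION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return Path(path)


def pucker_series_frame(states: list[PuckerState]) -> pd.DataFrame:
    """Tabulate pucker states: torsions, P, nu_max and classification."""
    rows = []
    for i, s in enumerate(states, start=1):
        row = {"model_index": i}
        if s.torsions is not None:
            row.update(zip(TORSION_COLUMNS, s.torsions.as_array()))
        row.update(P=s.P, nu_max=s.nu_max,
                   hemisphere=s.hemisphere.value if s.hemisphere else "",
                   named_bin=s.named_bin.value if s.named_bin else "",
                   degenerate=s.degenerate)
        rows.append(row)
    return pd.DataFrame(rows)


def write_pucker_series(states: list[PuckerState], tsv_path: str | Path,
                        json_path: str | Path | None = None) -> None:
    """Write a pucker series as TSV and an optional JSON summary."""
    frame = pucker_series_frame(states)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.9g")
    if json_path is not None:
        from .ensembles import circular_summary
        valid = [s for s in states if not s.degenerate]
        summary = {
            "n_models": len(states),
            "n_degenerate": len(states) - len(valid),
        }
        if valid:
            mean, length = circular_summary(valid)
            summary["circular_mean_P"] = mean
            summary["resultant_length"] = length
        Path(json_path).write_text(json.dumps(summary, indent=1))
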