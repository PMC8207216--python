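import textwrap

import numpy as np
import pytest

from puckerfit import PuckerMixtureSpec, gen_pucker_trajectory
from puckerfit.simulate import write_ring_trajectory_pdb


@pytest.fixture
def three_model_pdb(tmp_path):
    """Synthetic 3-model PDB: rings embedded at P = 19, 160, 173 degrees."""
    path = tmp_path / "three_model.pdb"
    write_ring_trajectory_pdb(np.array([19.0, 160.0, 173.0]), path)
    return path


@pytest.fixture
def star_dialect_pdb(three_model_pdb, tmp_path):
    """The same file with C1' renamed C1* etc. (old PDB atom dialect)."""
    text = three_model_pdb.read_text().replace("'", "*")
    path = tmp_path / "star_dialect.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """Synthetic single-model structure whose ring has altlocs A (0.75)
    and B (0.25), mirroring a minor second conformation at 25% occupancy."""
    import gemmi

    from puckerfit import RING_ATOMS
    from puckerfit.simulate import gen_ring_coords

    st = gemmi.Structure()
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "RAB"
    res.seqid = gemmi.SeqId(7, " ")
    res.het_flag = "H"
    for alt, occ, p in (("A", 0.75, 19.0), ("B", 0.25, 160.0)):
        ring = gen_ring_coords(p)
        for name in RING_ATOMS:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.altloc = alt
            atom.occ = occ
            x, y, z = ring.coords[name]
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    path = tmp_path / "altloc.pdb"
    st.write_pdb(str(path))
    return path


@pytest.fixture
def protein_pdb(tmp_path):
    """A lone glycine residue: no furanose ring atoms at all."""
    path = tmp_path / "protein.pdb"
    path.write_text(textwrap.dedent("""\
        ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
        ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
        ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
        ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
        END
        """))
    return path


@pytest.fixture
def mixed_trajectory(tmp_path):
    """10k-conformer two-component ensemble (0.8 northern / 0.2 southern)."""
    spec = PuckerMixtureSpec(components=((19.0, 50.0, 0.8),
                                         (160.0, 50.0, 0.2)),
                             n=10_000, seed=42)
    return gen_pucker_trajectory(spec, out_dir=tmp_path, stem="mixed")
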