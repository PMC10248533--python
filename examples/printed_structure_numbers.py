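"""Recompute published structural numbers from deposited coordinates.

The numbers printed for the two Get3d crystal structures (backbone RMSD
2.33 A between the plant and cyanobacterial dimers; ~1270/1280 A^2 buried
at the alpha-crystallin-domain interface; the R209-D425 salt bridge; the
cis-proline at residue 340/265; 31% pairwise sequence identity) can be
recomputed with this package once the public entries are downloaded:

    mkdir -p data/reference_structures
    curl -o data/reference_structures/8elf.pdb https://files.rcsb.org/download/8ELF.pdb
    curl -o data/reference_structures/8egk.pdb https://files.rcsb.org/download/8EGK.pdb
    # and the sequences (UniProt Q6DYE4 + the 3IGF chain) concatenated into
    # data/reference_structures/get3d_sequences.fasta

Coordinate files are not redistributed inside the repository.
"""
from pathlib import Path

import get3atlas as g

REF = Path(__file__).resolve().parent.parent / "data" / "reference_structures"
ACD_START = {"8elf": 352, "8egk": 277}   # first aCD residue, author numbering

if not (REF / "8elf.pdb").exists():
    raise SystemExit(f"download the reference entries into {REF} first "
                     "(see module docstring)")

at = g.read_pdb_subset((REF / "8elf.pdb").read_text())
nos = g.read_pdb_subset((REF / "8egk.pdb").read_text())

print(f"backbone RMSD (plant vs cyanobacterial dimer): "
      f"{g.backbone_rmsd(at, nos):.2f} A")

for model, key, label in ((at, "8elf", "plant"), (nos, "8egk", "cyanobacterial")):
    acd = [(c.id, r.number) for c in model.chains for r in c.residues
           if r.number >= ACD_START[key]]
    rest = [(c.id, r.number) for c in model.chains for r in c.residues
            if r.number < ACD_START[key]]
    rep = g.buried_interface_area(model, acd, rest)
    print(f"{label} aCD interface: half-dSASA {rep.delta_sasa_half:.0f} A^2; "
          f"salt bridges {rep.salt_bridges}")

for model, label in ((at, "plant"), (nos, "cyanobacterial")):
    cis = g.detect_cis_peptides(model)
    print(f"{label} cis peptides: {[(c, n, name) for c, n, name, _ in cis]}")

fasta = REF / "get3d_sequences.fasta"
if fasta.exists():
    a, b = g.read_fasta(str(fasta))[:2]
    print(f"pairwise identity: {100 * g.pairwise_identity(a, b):.1f}%")
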