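#!/usr/bin/env python
"""Build the reference-geometry quadruplex coordinates.

Constructs the idealized [d(G4C2)]4 monomer (four G-quartets, a C-quartet,
syn 5' quartet, ammonium ions in the three channel sites) and the 5'-5'
stacked dimer with a K+ ion at the interface, and writes both as PDB files
under results/ for the downstream geometry scripts.
"""

from pathlib import Path

from g4kit.structure_io import write_pdb
from g4kit.synthetic import BuilderSpec, build_quadruplex

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    monomer = build_quadruplex(BuilderSpec())
    write_pdb(monomer, RESULTS / "monomer.pdb")
    print(f"monomer: {monomer.n_atoms} atoms, chains {monomer.chains()}")

    dimer = build_quadruplex(
        BuilderSpec(n_cores=2, ions=(("O5", "K"), ("I", "K"), ("O3", "K"), ("OGG", "K")))
    )
    write_pdb(dimer, RESULTS / "dimer.pdb")
    print(f"dimer:   {dimer.n_atoms} atoms, chains {dimer.chains()}")
    print(f"wrote {RESULTS/'monomer.pdb'} and {RESULTS/'dimer.pdb'}")


if __name__ == "__main__":
    main()
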