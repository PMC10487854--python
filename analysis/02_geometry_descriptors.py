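#!/usr/bin/env python
"""Measure the structural descriptors of the built structures.

Reads the PDB files from 01_build_structures.py, detects quartets, and
tabulates chi angles, step parameters (d, rise, twist, stacking mode),
groove widths, quartet polarity and ion binding-site assignments.
Key findings at the defaults: the three inter-quartet offsets d are
0.4/0.5/0.6 A (smallest at the fully occupied 5' site), all four grooves
are medium, the dimer interface stacks five-membered rings at 3.57 A with
a 14.8-degree twist, and the interface K+ sits ~6.8 A from the inner ion.
"""

from pathlib import Path

import pandas as pd

import g4kit.quartet_geometry as qg
from g4kit.structure_io import read_pdb

RESULTS = Path(__file__).resolve().parent.parent / "results"


def analyse(name: str) -> None:
    ens = read_pdb(RESULTS / f"{name}.pdb")
    quartets = qg.detect_quartets(ens, 0)

    steps = []
    for a, b in zip(quartets, quartets[1:]):
        s = qg.step_geometry(a, b)
        steps.append(
            {
                "step": f"{a.base_type}{a.residues[0].res_seq}/{b.base_type}{b.residues[0].res_seq}",
                "d_A": round(s.d, 4), "rise_A": round(s.rise, 4),
                "twist_deg": round(s.twist, 4), "stacking": s.stacking_mode,
            }
        )
    steps_df = pd.DataFrame(steps)
    steps_df.to_csv(RESULTS / f"{name}_steps.tsv", sep="\t", index=False)

    chi_rows = [
        {"residue": str(g.residue), "chi_deg": round(g.chi, 2), "conf": g.conformation}
        for chain, seq, rn in ens.residues(0)
        if qg.base_type(rn)
        for g in [qg.compute_chi(ens, 0, (chain, seq))]
    ]
    pd.DataFrame(chi_rows).to_csv(RESULTS / f"{name}_chi.tsv", sep="\t", index=False)

    ions = qg.assign_ions(ens, 0, quartets)
    ion_rows = [
        {"ion": f"{a.ion_atom.res_name}{a.ion_atom.res_seq}", "site": a.site,
         "axial_A": round(a.axial_coordinate, 3), "radial_A": round(a.radial_distance, 3)}
        for a in ions
    ]
    pd.DataFrame(ion_rows).to_csv(RESULTS / f"{name}_ions.tsv", sep="\t", index=False)

    print(f"== {name}: {len(quartets)} quartets "
          f"({sum(q.base_type=='G' for q in quartets)} G, "
          f"{sum(q.base_type=='C' for q in quartets)} C)")
    print(steps_df.to_string(index=False))
    if name == "monomer":
        grooves = qg.classify_grooves(ens, 0, [q for q in quartets if q.base_type == "G"])
        print("grooves:", [(r.chains, round(r.width, 2), r.groove_class) for r in grooves])
    for (x, y), v in qg.ion_pair_distances(ions).items():
        print(f"ion distance {x} -- {y}: {v:.2f} A")


def main() -> None:
    for name in ("monomer", "dimer"):
        if not (RESULTS / f"{name}.pdb").exists():
            raise SystemExit("run 01_build_structures.py first")
        analyse(name)


if __name__ == "__main__":
    main()
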