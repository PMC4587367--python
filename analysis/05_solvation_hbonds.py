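"""Solvation structure and hydrogen-bond network differences per system.

The reference system carries a full depletion shell around its start-point
atom (a buried, solvent-protected site), the bulky-hydrophobic mutant a
partial one, and the shared-basin mutants open access; every mutant also
carries one scheduled hydrogen bond the reference lacks.  The g(r) profiles,
coordination numbers and network diffs land under results/.
"""

import json

from _common import RESULTS, SEED, make_systems

from mdtop import synthetic
from mdtop.hbonds import hbond_occupancy, network_difference
from mdtop.solvation import coordination_number, rdf


def main():
    topology, systems = make_systems()
    labels = [s.label for s in systems]
    RESULTS.mkdir(exist_ok=True)

    shells = {label: () for label in labels}
    shells["WT"] = ((0.0, 4.0, 0.0),)
    shells["F429L"] = ((0.0, 4.0, 0.25),)
    coord = {}
    for i, label in enumerate(labels):
        spec = synthetic.SolventShellSpec(
            bulk_density=0.0334, box=(30.0, 30.0, 30.0), shells=shells[label]
        )
        sf = synthetic.generate_solvated_frames(
            topology, spec, 200, seed=SEED + 100 + i
        )
        rdf(sf, bin_width=0.2, r_max=12.0).to_tsv(RESULTS / f"05_rdf_{label}.tsv")
        mean = coordination_number(sf, cutoff=7.0)
        coord[label] = {"mean": round(mean, 1), "rounded": int(round(mean))}
    (RESULTS / "05_coordination.json").write_text(json.dumps(coord, indent=1))
    print("waters within 7 A of the start-point atom:")
    for label, v in coord.items():
        print(f"  {label:>6}: {v['mean']:5.1f}  (~{v['rounded']})")

    base = synthetic.HBondPairSpec(0, topology.acceptors[-1], 0.9)
    extra = synthetic.HBondPairSpec(1, topology.acceptors[-2], 0.8)
    tables = {}
    for i, label in enumerate(labels):
        pairs = (base,) if label == "WT" else (base, extra)
        traj = synthetic.generate_hbond_series(
            topology,
            synthetic.HBondSeriesSpec(pairs=pairs, n_frames=400, seed=SEED + 200 + i),
        )
        traj.label = label
        tables[label] = hbond_occupancy(traj)
        tables[label].to_tsv(RESULTS / f"05_hbonds_{label}.tsv")
    diffs = {}
    for label in labels[1:]:
        d = network_difference(tables[label], tables["WT"], threshold=0.5)
        diffs[label] = {
            "unique_to_mutant": len(d.unique_to_a),
            "unique_to_wt": len(d.unique_to_b),
        }
    (RESULTS / "05_hbond_diffs.json").write_text(json.dumps(diffs, indent=1))
    print(f"network diffs vs WT (bonds above 50% occupancy): {diffs}")


if __name__ == "__main__":
    main()
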