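"""Shared setup for the analysis drivers.

All drivers run the same desk-scale study: the canonical five-system design
(WT and F429L in their own conformational basins; F429A/E/H sharing one) with
durations shortened from the full study (150 ns + 2x10 ns per system) to
4 ns + 2x0.6 ns so every driver finishes in seconds.  The full-duration frame
counts are recomputed by scripts/acceptance.py.
"""

from pathlib import Path

from mdtop import synthetic
from mdtop.trajectory import SamplingProtocol, build_artificial_trajectory

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

DESK = dict(
    long_ns=4.0,
    restart_ns=(0.6, 0.6),
    restart_branch_ns=(1.0, 3.0),
    interval_ps=10.0,
)
DISCARD_NS = 1.0  # desk-scale analogue of discarding the relaxation prefix


def make_systems(seed=SEED, n_residues=12):
    topology = synthetic.generate_topology(n_residues, seed)
    spec = synthetic.five_system_spec(topology, seed=seed, **DESK)
    return topology, synthetic.generate_ensemble(topology, spec)


def frame_sets(systems, seed=SEED):
    from mdtop.trajectory import SystemTrajectories

    base = dict(exclusion=0.10, discard_ns=DISCARD_NS)
    longs = [SystemTrajectories(label=s.label, long=s.long) for s in systems]
    return {
        "set1": build_artificial_trajectory(
            systems, SamplingProtocol(80.0, seed=seed + 1, **base)
        ),
        "set2": build_artificial_trajectory(
            systems, SamplingProtocol(40.0, seed=seed + 2, **base)
        ),
        "set3": build_artificial_trajectory(
            longs, SamplingProtocol(80.0, seed=seed + 3, **base)
        ),
    }
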