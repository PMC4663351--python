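"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from bilayerbind.core import AtomGroup, Frame, Topology, select
from bilayerbind.synthetic import (BilayerSpec, PeptideSpec, ScriptSpec,
                                   generate_bilayer, generate_peptide,
                                   generate_scripted_trajectory)


@pytest.fixture(scope="session")
def neat_bilayer():
    """Zero-jitter 36-lipid-per-leaflet bilayer at the study targets."""
    spec = BilayerSpec(lipids_per_leaflet=36, headgroup_jitter=0.0, seed=11)
    top, traj = generate_bilayer(spec)
    return spec, top, traj


@pytest.fixture(scope="session")
def helix():
    """Ideal hIAPP helix at phase 0."""
    spec = PeptideSpec(seed=5)
    top, frame = generate_peptide(spec)
    return spec, top, frame


@pytest.fixture(scope="session")
def scripted_run():
    """C-terminal-first adsorption trajectory with 5 planted phosphate
    H-bonds per frame."""
    bspec = BilayerSpec(lipids_per_leaflet=36, seed=1)
    pspec = PeptideSpec()
    sspec = ScriptSpec(n_frames=60, plant={"phosphate": 5}, seed=1)
    top, traj, truth = generate_scripted_trajectory(bspec, pspec, sspec)
    return top, traj, truth


@pytest.fixture(scope="session")
def hovering_run():
    """Bound-but-hovering trajectory where planted H-bond counts are the
    only peptide-lipid H-bonds."""
    bspec = BilayerSpec(lipids_per_leaflet=36, seed=2)
    sspec = ScriptSpec(
        n_frames=6, keyframes=((0.0, 0.9, 0.9, 0.0), (1e9, 0.9, 0.9, 0.0)),
        plant={"phosphate": 5, "ester": 2}, seed=2)
    top, traj, truth = generate_scripted_trajectory(bspec, PeptideSpec(),
                                                    sspec)
    return top, traj, truth


def toy_topology(n, charges=None, donors=None, acceptors=None,
                 elements=None, names=None, c6=None, c12=None):
    """Minimal n-atom topology for hand-built geometric cases."""
    return Topology(
        names=np.array(names if names is not None
                       else [f"A{i}" for i in range(n)], dtype=object),
        elements=np.array(elements if elements is not None
                          else ["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["TOY"] * n, dtype=object),
        molids=np.arange(n),
        molkinds=np.array(["solvent"] * n, dtype=object),
        charges=np.asarray(charges if charges is not None
                           else np.zeros(n), dtype=float),
        c6=np.asarray(c6 if c6 is not None else np.zeros(n), dtype=float),
        c12=np.asarray(c12 if c12 is not None else np.zeros(n), dtype=float),
        n_implicit_h=np.zeros(n, dtype=int),
        donor=np.asarray(donors if donors is not None
                         else np.zeros(n, bool)),
        acceptor=np.asarray(acceptors if acceptors is not None
                            else np.zeros(n, bool)),
    )
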