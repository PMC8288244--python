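import itertools

import pytest

from rgroupnet.compound_io import make_record
from rgroupnet.fragmentation import (
    Decomposition,
    FragmentationConfig,
    decompose,
    eligible_cut_bonds,
)
from rgroupnet.pipeline import RunConfig, run_pipeline
from rgroupnet.synthetic import LibrarySpec, ScaffoldSpec, generate_library


def naive_enumerate(record, config=None):
    """Brute-force decomposition oracle: try every cut subset up to max_sites.

    Independent of the pruned enumeration path: hydrogen cuts are combined
    blindly with every heavy-cut subset and rejected sets are simply dropped.
    """
    cfg = config or FragmentationConfig()
    cuts = eligible_cut_bonds(record)
    if not cfg.hydrogen_cuts:
        cuts = [c for c in cuts if c.kind == "bond"]
    found = {}
    for n in range(1, cfg.max_sites + 1):
        for subset in itertools.combinations(cuts, n):
            for out in decompose(record, subset, cfg):
                if isinstance(out, Decomposition):
                    found.setdefault(out.sort_key, out)
    return sorted(found.values(), key=lambda d: d.sort_key)


def edge_weights(net):
    """Canonical {sorted pair: weight} view of a weighted graph."""
    return {tuple(sorted((a, b))): d["weight"] for a, b, d in net.edges(data=True)}


@pytest.fixture(scope="session")
def four_substituent_library():
    """One rigid scaffold, one site, pool {H, F, Cl, Br}: the worked example."""
    spec = LibrarySpec(
        scaffolds=(ScaffoldSpec("[*:1]c1cc2ccccc2o1", (("H", "*F", "*Cl", "*Br"),)),),
        fill=1.0,
        seed=7,
    )
    return generate_library(spec)


@pytest.fixture(scope="session")
def four_substituent_result(four_substituent_library):
    records, _ = four_substituent_library
    return run_pipeline(records, RunConfig())


@pytest.fixture(scope="session")
def two_site_library():
    """A two-site quinoline library with hydrogen in both pools."""
    spec = LibrarySpec(
        scaffolds=(
            ScaffoldSpec(
                "[*:1]c1ccc2ncc([*:2])cc2c1",
                (("H", "*F", "*OC"), ("H", "*Cl", "*C")),
            ),
        ),
        fill=1.0,
        seed=11,
        decoys=2,
    )
    return generate_library(spec)


@pytest.fixture
def phenol_record():
    return make_record("phenol", "c1ccccc1O")
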