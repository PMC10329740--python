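import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from domcross.core_model import BackboneStructure, SourceDB, StructuralInstance
from domcross.synthgen import CORE_FOLD, ScenarioSpec, generate_scenario, make_fold


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(scale=20.0, size=3)


def helix(n=30, noise=0.0, seed=0, structure_id="helix"):
    return make_fold(CORE_FOLD, n, noise, seed, structure_id)


def make_instance(
    pdb_id="1ABC",
    chain_id="A",
    side=SourceDB.PFAM_SIDE,
    family=None,
    start=10,
    end=99,
    uniprot="P12345",
    label="dom",
):
    family = family or ("PF00076" if side is SourceDB.PFAM_SIDE else "3.30.70.330")
    if side is SourceDB.PFAM_SIDE:
        return StructuralInstance(
            pdb_id=pdb_id,
            chain_id=chain_id,
            domain_label=label,
            family_id=family,
            source_db=side,
            uniprot_id=uniprot,
            uniprot_start=start,
            uniprot_end=end,
        )
    return StructuralInstance(
        pdb_id=pdb_id,
        chain_id=chain_id,
        domain_label=label,
        family_id=family,
        source_db=side,
        uniprot_id=None,
        pdb_start=start,
        pdb_end=end,
    )


def mapped_instance(**kw):
    """A fully residue-mapped instance with identity numbering."""
    sti = make_instance(**kw)
    start, end = sti.native_span
    sti.pdb_start, sti.pdb_end = start, end
    sti.uniprot_start, sti.uniprot_end = start, end
    if sti.uniprot_id is None:
        sti.uniprot_id = "P12345"
    return sti


@pytest.fixture(scope="session")
def four_category_bundle(tmp_path_factory):
    """The planted 4-category scenario, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    spec = ScenarioSpec(seed=11)
    result = generate_scenario(spec, out)
    return out, spec, result


@pytest.fixture(scope="session")
def four_category_run(four_category_bundle, tmp_path_factory):
    """The planted scenario run to convergence, once per session."""
    from domcross.classify_iterate import run_workflow
    from domcross.synthgen import run_config_for_bundle

    bundle_dir, spec, result = four_category_bundle
    out = tmp_path_factory.mktemp("run")
    runner = run_workflow(run_config_for_bundle(bundle_dir, out))
    return runner, spec, result, out


@pytest.fixture
def simple_structure():
    return helix(20, noise=0.0, seed=0)
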