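import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


TOY_FASTA = """\
>seq1
MKTLLVAGGSWTRCCAAHHN
>seq2
MKALLVSGG-WTRCCAVHHN
"""


@pytest.fixture(scope="session")
def toy_alignment():
    from pocketpharm.alignment import parse_alignment

    return parse_alignment(TOY_FASTA)


@pytest.fixture(scope="session")
def scenario():
    from pocketpharm.fixtures import make_planted_scenario

    return make_planted_scenario(seed=0)


@pytest.fixture(scope="session")
def scenario_chain(scenario):
    """Model, ensemble, pocket, lining and profile of the planted scenario."""
    from pocketpharm.alignment import assign_bw_numbers
    from pocketpharm.conservation import ConservationProfile, rank_pocket_residues
    from pocketpharm.receptor import (
        attach_rotamers,
        detect_pocket,
        lining_residues,
        model_heavy_atoms,
        thread_target,
    )

    bw_map = assign_bw_numbers(scenario.family, scenario.target_id, scenario.layout)
    profile = ConservationProfile.from_alignments(
        scenario.family, scenario.subfamily, bw_map, scenario.target_id
    )
    model, unmatched = thread_target(scenario.template, bw_map)
    ensemble = attach_rotamers(model)
    coords, elements, helices = model_heavy_atoms(model, ensemble)
    pocket = detect_pocket(coords, 8.0, elements=elements, atom_helices=helices)
    lining = lining_residues(pocket, model, ensemble)
    return {
        "bw_map": bw_map,
        "profile": profile,
        "model": model,
        "ensemble": ensemble,
        "pocket": pocket,
        "lining": lining,
    }


@pytest.fixture(scope="session")
def generated_pharmacophore(scenario_chain):
    from pocketpharm.conservation import rank_pocket_residues
    from pocketpharm.pharmacophore import (
        build_pharmacophore,
        collect_interaction_points,
        fuzzy_cluster,
    )

    ranked = rank_pocket_residues(
        scenario_chain["profile"], sorted(scenario_chain["lining"])
    )
    points = collect_interaction_points(
        scenario_chain["model"],
        scenario_chain["ensemble"],
        scenario_chain["pocket"],
        scenario_chain["profile"],
        set(ranked[:20]),
    )
    return build_pharmacophore(fuzzy_cluster(points))


@pytest.fixture(scope="session")
def pipeline_bundle():
    """One full end-to-end planted run, reused across validation tests."""
    from pocketpharm.pipeline import RunConfig, run_planted

    return run_planted(RunConfig(seed=0))


@pytest.fixture
def simple_pharmacophore():
    """Hand-built 9-feature pharmacophore with well-separated centers."""
    from pocketpharm.alignment import ResidueRef
    from pocketpharm.pharmacophore import Feature, Pharmacophore

    centers = np.array(
        [
            [0.0, 0.0, 0.0],   # acceptor 0
            [6.0, 0.0, 0.0],   # acceptor 1
            [0.0, 6.0, 0.0],   # acceptor 2
            [0.0, 0.0, 6.0],   # donor 3
            [6.0, 6.0, 0.0],   # donor 4
            [6.0, 0.0, 6.0],   # donor 5
            [0.0, 6.0, 6.0],   # hydrophobic 6
            [6.0, 6.0, 6.0],   # hydrophobic 7
            [3.0, 3.0, 9.0],   # hydrophobic 8
        ]
    )
    types = ["acceptor"] * 3 + ["donor"] * 3 + ["hydrophobic"] * 3
    ref = ResidueRef("3.36", 0, "N")
    features = [
        Feature(index=i, type=t, center=c, radius=1.0, contributions=[(ref, 1.0)])
        for i, (t, c) in enumerate(zip(types, centers))
    ]
    return Pharmacophore(features=features)
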