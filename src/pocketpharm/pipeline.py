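"""End-to-end orchestration: align -> score -> model -> pocket ->
pharmacophore -> screen -> validate, with config provenance.

All parameter defaults are the pipeline's published operating point
(tetrahedron edge cutoff 8.0 A, clustering Rc 2.5 A, 5- and 6-feature
subsets, recall filter 0.5, conformation limit 200).  Every output carries
a hash of the serialized config so runs are comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import metrics as vm
from .alignment import Alignment, TMLayout, assign_bw_numbers
from .conservation import ConservationProfile
from .fixtures import PlantedScenario, make_planted_library, make_planted_scenario
from .pharmacophore import (
    Pharmacophore,
    build_pharmacophore,
    collect_interaction_points,
    fuzzy_cluster,
    write_pharmacophore,
)
from .receptor import (
    attach_rotamers,
    detect_pocket,
    lining_residues,
    model_heavy_atoms,
    thread_target,
)
from .screening import Compound, screen_library, write_hit_table


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name and any partial results."""

    def __init__(self, stage: str, cause: Exception, partial: dict | None = None):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial or {}


@dataclass
class RunConfig:
    edge_cutoff: float = 8.0
    rc: float = 2.5
    k_values: tuple[int, ...] = (5, 6)
    recall_min: float = 0.5
    contact_distance: float = 4.5
    hbond_length: float = 2.9
    min_feature_radius: float = 0.8
    gamma: float = 2.0
    probe_radius: float = 1.4
    n_binding_residues: int = 20  # top-ranked residues seeding features
    conformation_limit: int = 200
    mm_iteration_limit: int = 200
    seed: int = 0
    screen_only: bool = False
    output_dir: str | None = None

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    config: RunConfig
    config_hash: str
    pharmacophore: Pharmacophore
    hit_table: pd.DataFrame
    results: list | None
    report: pd.DataFrame | None
    lining: set
    log: list[str] = field(default_factory=list)


def run_pipeline(
    config: RunConfig,
    family: Alignment,
    subfamily: Alignment,
    layout: TMLayout,
    target_id: str,
    template,
    compounds: list[Compound] | None = None,
    labels: dict[str, str] | None = None,
    hit_subset: tuple[int, ...] = (0, 3, 6, 7, 8),
) -> ReportBundle:
    """Execute every stage; on failure raise :class:`PipelineError` naming
    the stage, with partial results attached."""
    partial: dict = {}
    log: list[str] = [f"config_hash={config.hash()}", f"seed={config.seed}"]

    def stage(name, fn):
        try:
            value = fn()
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, e, partial) from e
        partial[name] = value
        log.append(f"stage {name}: ok")
        return value

    bw_map = stage("align", lambda: assign_bw_numbers(family, target_id, layout))
    profile = stage(
        "score",
        lambda: ConservationProfile.from_alignments(
            family, subfamily, bw_map, target_id, gamma=config.gamma
        ),
    )
    model_unmatched = stage("model", lambda: thread_target(template, bw_map))
    model, unmatched = model_unmatched
    if unmatched:
        log.append(f"unmatched template labels: {len(unmatched)}")
    ensemble = stage("rotamers", lambda: attach_rotamers(model))

    def _pocket():
        coords, elements, helices = model_heavy_atoms(model, ensemble)
        return detect_pocket(
            coords,
            edge_cutoff=config.edge_cutoff,
            elements=elements,
            atom_helices=helices,
            probe_radius=config.probe_radius,
        )

    pocket = stage("pocket", _pocket)
    lining = stage(
        "lining",
        lambda: lining_residues(pocket, model, ensemble, config.contact_distance),
    )
    from .conservation import rank_pocket_residues

    ranked = rank_pocket_residues(profile, sorted(lining))
    seeding = set(ranked[: config.n_binding_residues])
    pharm = stage(
        "pharmacophore",
        lambda: build_pharmacophore(
            fuzzy_cluster(
                collect_interaction_points(
                    model, ensemble, pocket, profile, seeding, config.hbond_length
                ),
                rc=config.rc,
                min_radius=config.min_feature_radius,
            ),
            metadata={
                "config_hash": config.hash(),
                "rc": config.rc,
                "seed": config.seed,
            },
        ),
    )

    if compounds is None:
        compounds, lib_manifest = make_planted_library(
            pharm, hit_subset=hit_subset, seed=config.seed
        )
        log.append(f"planted library: {lib_manifest}")
    hits = stage(
        "screen",
        lambda: screen_library(
            compounds, pharm, k_values=config.k_values, seed=config.seed
        ),
    )

    results = report = None
    if labels is None:
        labels = {c.parent_id: c.activity for c in compounds}
    if not config.screen_only:
        results = stage(
            "validate", lambda: vm.evaluate_all_subsets(hits, labels)
        )
        report = vm.rank_feature_sets(results, recall_threshold=config.recall_min)

    bundle = ReportBundle(
        config=config,
        config_hash=config.hash(),
        pharmacophore=pharm,
        hit_table=hits,
        results=results,
        report=report,
        lining=lining,
        log=log,
    )
    if config.output_dir:
        _write_outputs(bundle)
    return bundle


def run_planted(config: RunConfig, scenario: PlantedScenario | None = None) -> ReportBundle:
    """Run the full pipeline on the planted synthetic scenario."""
    scenario = scenario or make_planted_scenario(seed=config.seed)
    return run_pipeline(
        config,
        family=scenario.family,
        subfamily=scenario.subfamily,
        layout=scenario.layout,
        target_id=scenario.target_id,
        template=scenario.template,
        hit_subset=scenario.hit_subset,
    )


def _write_outputs(bundle: ReportBundle) -> None:
    outdir = bundle.config.output_dir
    os.makedirs(outdir, exist_ok=True)
    header = f"# config_hash {bundle.config_hash}\n"
    with open(os.path.join(outdir, "pharmacophore.txt"), "w") as fh:
        fh.write(header + write_pharmacophore(bundle.pharmacophore))
    write_hit_table(bundle.hit_table, os.path.join(outdir, "hits.tsv"))
    if bundle.report is not None:
        with open(os.path.join(outdir, "report.tsv"), "w") as fh:
            fh.write(header)
            bundle.report.to_csv(fh, sep="\t", index=False)
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(header + "\n".join(bundle.log) + "\n")
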