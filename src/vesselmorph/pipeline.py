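"""End-to-end orchestration: generate/ingest → filter → measure →
classify → test, with deterministic, auditable outputs.

A run is described by a :class:`RunConfig` (loadable from YAML or JSON)
and produces, inside its output directory:

* ``truth.csv`` (synthetic mode) — generator ground truth,
* ``measurements.csv`` — one morphometry record per input vessel,
* ``classifications.csv`` — assigned classes for non-excluded vessels,
* ``summaries.json`` — per-group descriptive statistics,
* ``tests.json`` — rank-test results and range-overlap analyses,
* ``manifest.json`` — config hash, seed, version and exclusion
  accounting, so every number is traceable to an input vessel.

Outputs contain no timestamps: the same config and seed give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from . import __version__
from .classification import (
    ARTERIOLE,
    INDETERMINATE,
    VENULE,
    DecisionRule,
    classify_area_ratio,
    classify_diameter_ratio,
    range_overlap,
)
from .errors import DomainError, VesselMorphError
from .mask_io import read_manifest, read_mask, write_mask
from .morphometry import (
    DEFAULT_AREA_FLOOR,
    MorphometryRecord,
    measure,
    records_to_frame,
)
from .stats import below_threshold_retest, mann_whitney_u, summarize
from .synthetic import PopulationSpec, sample_population, truth_table

logger = logging.getLogger("vesselmorph")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "masks"
    population: PopulationSpec = field(default_factory=PopulationSpec)
    manifest: str | None = None  # masks mode: CSV of raster/sidecar pairs
    exclusion_area_floor: float = DEFAULT_AREA_FLOOR
    decision_rule: DecisionRule = field(default_factory=DecisionRule)
    thickness_rays: int = 360
    threshold_retest: float = 4.97
    master_seed: int = 0
    save_masks: bool = False  # synthetic mode: also write PNG/JSON pairs

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "masks"):
            raise DomainError(f"unknown run mode {self.mode!r}")
        if self.mode == "masks" and not self.manifest:
            raise DomainError("masks mode requires a manifest path")

    def to_dict(self) -> dict:
        # JSON round-trip turns nested tuples into lists (YAML/JSON-safe)
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "population" in d and isinstance(d["population"], dict):
            pop = dict(d["population"])
            from .synthetic import GroupGeometry, RatioSampler

            for key in ("ratio_sampler_group1", "ratio_sampler_group2"):
                if isinstance(pop.get(key), dict):
                    pop[key] = RatioSampler(**pop[key])
            for key in ("geometry_group1", "geometry_group2"):
                if isinstance(pop.get(key), dict):
                    g = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in pop[key].items()
                    }
                    pop[key] = GroupGeometry(**g)
            d["population"] = PopulationSpec(**pop)
        if isinstance(d.get("decision_rule"), dict):
            d["decision_rule"] = DecisionRule(**d["decision_rule"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """In-memory results of a pipeline run (files are also on disk)."""

    config: RunConfig
    records: list[MorphometryRecord]
    group_of: dict[str, str]  # vessel_id -> group label ("group1"/"group2")
    classifications: list
    summaries: dict
    tests: dict
    manifest: dict
    output_dir: str


def _measured_groups(
    records: list[MorphometryRecord], group_of: dict[str, str]
) -> tuple[list[MorphometryRecord], list[MorphometryRecord]]:
    g1 = [r for r in records if not r.excluded and group_of.get(r.vessel_id) == "group1"]
    g2 = [r for r in records if not r.excluded and group_of.get(r.vessel_id) == "group2"]
    return g1, g2


def run(config: RunConfig, output_dir: str | os.PathLike) -> RunReport:
    """Execute the full pipeline and write all reports.

    In synthetic mode the comparison groups are the generator's true
    group labels; in masks mode (no ground truth) they are the assigned
    classes.  Any stage failure is re-raised with the stage name and the
    offending vessel id.
    """
    outdir = str(output_dir)
    os.makedirs(outdir, exist_ok=True)

    # ---- stage 1: acquire vessels -------------------------------------
    group_of: dict[str, str] = {}
    truth_df = None
    if config.mode == "synthetic":
        pop = dataclasses.replace(config.population, master_seed=config.master_seed)
        logger.info("generate: %d + %d vessels, seed %d",
                    pop.n_group1, pop.n_group2, pop.master_seed)
        pairs = sample_population(pop)
        vessels = [v for v, _ in pairs]
        truth_df = truth_table(pairs)
        truth_df.to_csv(os.path.join(outdir, "truth.csv"), index=False)
        for v, t in pairs:
            group_of[v.vessel_id] = (
                "group1" if t.spec.group_label == "venule_like" else "group2"
            )
        if config.save_masks:
            mask_dir = os.path.join(outdir, "masks")
            os.makedirs(mask_dir, exist_ok=True)
            for v in vessels:
                write_mask(
                    v,
                    os.path.join(mask_dir, f"{v.vessel_id}.png"),
                    os.path.join(mask_dir, f"{v.vessel_id}.json"),
                )
    else:
        pairs_paths = read_manifest(config.manifest)
        if not pairs_paths:
            raise DomainError(f"manifest {config.manifest!r} lists no vessels")
        vessels = []
        for raster, sidecar in pairs_paths:
            try:
                vessels.append(read_mask(raster, sidecar))
            except VesselMorphError as exc:
                raise type(exc)(f"ingest stage, raster {raster!r}: {exc}") from exc

    # ---- stage 2: measure + filter ------------------------------------
    records: list[MorphometryRecord] = []
    for v in vessels:
        try:
            records.append(
                measure(
                    v,
                    area_floor=config.exclusion_area_floor,
                    n_rays=config.thickness_rays,
                )
            )
        except VesselMorphError as exc:
            raise type(exc)(f"measure stage, vessel {v.vessel_id!r}: {exc}") from exc
    meas_df = records_to_frame(records)
    meas_df.to_csv(os.path.join(outdir, "measurements.csv"), index=False)

    kept = [r for r in records if not r.excluded]
    exclusion_counts: dict[str, int] = {}
    for r in records:
        if r.excluded:
            exclusion_counts[r.exclusion_reason] = (
                exclusion_counts.get(r.exclusion_reason, 0) + 1
            )
    logger.info("measure: %d vessels, %d excluded", len(records), len(records) - len(kept))

    # ---- stage 3: classify --------------------------------------------
    classifications = []
    for r in kept:
        try:
            classifications.append(classify_area_ratio(r, config.decision_rule))
        except VesselMorphError as exc:
            raise type(exc)(f"classify stage, vessel {r.vessel_id!r}: {exc}") from exc
    diam_classifications = [classify_diameter_ratio(r, config.threshold_retest) for r in kept]
    import pandas as pd

    cls_df = pd.DataFrame(
        [
            {**c.as_row(), "diameter_criterion_class": d.assigned_class}
            for c, d in zip(classifications, diam_classifications)
        ]
    )
    cls_df.to_csv(os.path.join(outdir, "classifications.csv"), index=False)
    class_counts = {
        label: sum(1 for c in classifications if c.assigned_class == label)
        for label in (VENULE, ARTERIOLE, INDETERMINATE)
    }

    # ---- stage 4: group statistics ------------------------------------
    if config.mode == "synthetic":
        g1, g2 = _measured_groups(records, group_of)
    else:
        by_class = {c.vessel_id: c.assigned_class for c in classifications}
        g1 = [r for r in kept if by_class.get(r.vessel_id) == VENULE]
        g2 = [r for r in kept if by_class.get(r.vessel_id) == ARTERIOLE]

    summaries: dict = {}
    tests: dict = {}
    if g1 and g2:
        for metric in ("area_ratio", "diameter_ratio"):
            v1 = [getattr(r, metric) for r in g1]
            v2 = [getattr(r, metric) for r in g2]
            summaries[metric] = {
                "group1": summarize(v1, "group1", metric).as_dict(),
                "group2": summarize(v2, "group2", metric).as_dict(),
            }
            overlaps, interval = range_overlap(v1, v2)
            mwu = mann_whitney_u(v1, v2)
            tests[metric] = {
                "mann_whitney": mwu.as_dict(),
                "range_overlap": {
                    "overlaps": overlaps,
                    "interval": list(interval) if interval else None,
                },
            }
        try:
            retest = below_threshold_retest(g1, g2, config.threshold_retest)
            tests["diameter_ratio_below_threshold"] = {
                "threshold": config.threshold_retest,
                "mann_whitney": retest.as_dict(),
            }
        except DomainError as exc:
            tests["diameter_ratio_below_threshold"] = {
                "threshold": config.threshold_retest,
                "error": str(exc),
            }

    with open(os.path.join(outdir, "summaries.json"), "w") as fh:
        json.dump(summaries, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "tests.json"), "w") as fh:
        json.dump(tests, fh, indent=1, sort_keys=True)
        fh.write("\n")

    # ---- stage 5: manifest / accounting -------------------------------
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "mode": config.mode,
        "n_input": len(records),
        "n_excluded": len(records) - len(kept),
        "exclusion_counts": exclusion_counts,
        "n_classified": len(classifications),
        "class_counts": class_counts,
    }
    assert manifest["n_input"] == manifest["n_excluded"] + manifest["n_classified"]
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return RunReport(
        config=config,
        records=records,
        group_of=group_of,
        classifications=classifications,
        summaries=summaries,
        tests=tests,
        manifest=manifest,
        output_dir=outdir,
    )
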