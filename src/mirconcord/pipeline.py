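"""End-to-end orchestration: filters -> DE -> targets -> concordance -> report.

A :class:`PipelineConfig` either points at real input files (expression
tables, prediction files, annotation) or carries a simulation config; the
run writes a report bundle to its output directory:

* per-source fraction-summary tables (per-miRNA percentages + aggregate rows),
* a method-average row across prediction sources,
* the full concordance record table,
* a target-enrichment table (hypergeometric, BH-corrected),
* recovery metrics against planted truth (simulation mode),
* ``manifest.yaml`` echoing config, seed and per-stage counts.

Identical config + seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import concordance as cc
from . import diffexpr as de
from . import expression_io as eio
from . import synthetic_data as sd
from . import target_maps as tmaps

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and outputs for a full run.

    Exactly one of ``simulation`` (a :class:`~mirconcord.synthetic_data.
    SimulationConfig`) or ``inputs`` (paths for expression tables,
    prediction files and annotation) must be provided.  ``sources`` selects
    prediction maps; ``intersections`` lists tuples of source names to
    intersect (e.g. ``["M", "TS", "PT"]``).
    """

    out_dir: str
    simulation: sd.SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    sources: tuple[str, ...] = ("M", "TS", "PT")
    intersections: tuple[tuple[str, ...], ...] = (("M", "TS", "PT"),)
    mirna_thresholds: de.ThresholdConfig = field(default_factory=lambda: de.TISSUE_MIRNA)
    mrna_thresholds: de.ThresholdConfig = field(default_factory=lambda: de.TISSUE_MRNA)
    case_group: str = "CEPI"
    control_group: str = "OSE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and not self.inputs:
            raise ValueError("config needs either a simulation block or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim = None
        if "simulation" in raw:
            sim_raw = dict(raw["simulation"])
            if "targets_per_mirna" in sim_raw:
                sim_raw["targets_per_mirna"] = tuple(sim_raw["targets_per_mirna"])
            sim = sd.SimulationConfig(**sim_raw)
        presets = de.PRESETS
        return cls(
            out_dir=raw["out_dir"],
            simulation=sim,
            inputs=raw.get("inputs", {}),
            sources=tuple(raw.get("sources", ("M", "TS", "PT"))),
            intersections=tuple(tuple(x) for x in raw.get("intersections", [["M", "TS", "PT"]])),
            mirna_thresholds=presets[raw.get("mirna_preset", "tissue_mirna")],
            mrna_thresholds=presets[raw.get("mrna_preset", "tissue_mrna")],
            case_group=raw.get("case_group", "CEPI"),
            control_group=raw.get("control_group", "OSE"),
            seed=int(raw.get("seed", 0)),
        )


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[eio.ExpressionMatrix, eio.ExpressionMatrix, dict[str, tmaps.TargetMap], tmaps.AnnotationTable, sd.RegulatoryTruth | None]:
    if cfg.simulation is not None:
        sim = cfg.simulation
        base, variants = sd.generate_target_map(sim)
        truth = sd.plant_regulation(base, sim)
        mirna_m, mrna_m = sd.simulate_tissue_experiment(truth, sim)
        maps = {"M": base, **variants}
        ann = sd.annotation_for(sim)
        return mirna_m, mrna_m, maps, ann, truth
    paths = cfg.inputs
    for key in ("mirna_expression", "mrna_expression", "annotation"):
        if key not in paths:
            raise PipelineError(f"stage inputs: missing required input {key!r}")
        if not Path(paths[key]).exists():
            raise PipelineError(f"stage inputs: file not found: {paths[key]}")
    mirna_m = eio.read_expression_table(paths["mirna_expression"])
    mrna_m = eio.read_expression_table(paths["mrna_expression"])
    ann = tmaps.read_annotation(paths["annotation"])
    maps: dict[str, tmaps.TargetMap] = {}
    if "targets_M" in paths:
        maps["M"] = tmaps.read_miranda_targets(paths["targets_M"])
    if "targets_TS" in paths:
        fam = {}
        if "ts_families" in paths:
            fam_df = pd.read_csv(paths["ts_families"], sep="\t", dtype=str)
            fam = fam_df.groupby("miR_family")["member"].apply(list).to_dict()
        maps["TS"] = tmaps.read_targetscan_targets(paths["targets_TS"], fam)
    if "targets_PT" in paths:
        maps["PT"] = tmaps.read_pictar_targets(paths["targets_PT"])
    return mirna_m, mrna_m, maps, ann, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis graph and write the report bundle.

    Returns a dict with the per-source summaries, the method average, the
    enrichment table and (in simulation mode) recovery metrics.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mirna_m, mrna_m, maps, ann, truth = _load_inputs(cfg)
    counts: dict[str, object] = {
        "mrna_probes_in": mrna_m.n_probes,
        "mirna_probes_in": mirna_m.n_probes,
    }

    # --- filter stage ---------------------------------------------------
    try:
        mrna_f = eio.filter_all_absent(mrna_m)
        mirna_f = eio.filter_all_absent(mirna_m)
    except Exception as exc:
        raise PipelineError(f"stage filter: {exc}") from exc
    counts["mrna_probes_after_absent_filter"] = mrna_f.n_probes
    counts["mirna_probes_after_absent_filter"] = mirna_f.n_probes

    # --- differential expression ----------------------------------------
    try:
        mirna_de = de.call_de(
            de.ttest_two_sample(mirna_f, cfg.case_group, cfg.control_group),
            cfg.mirna_thresholds,
            calls=mirna_f.calls,
        )
        mrna_de = de.call_de(
            de.ttest_two_sample(mrna_f, cfg.case_group, cfg.control_group),
            cfg.mrna_thresholds,
            calls=mrna_f.calls,
        )
    except Exception as exc:
        raise PipelineError(f"stage de: {exc}") from exc
    directions = mirna_de.directions()
    counts["mirna_de_flagged"] = len(directions)
    counts["mrna_de_flagged"] = int(mrna_de.table["de_flag"].sum())
    if not directions:
        raise PipelineError("stage de: no miRNA passed the DE thresholds")
    de.write_de_table(mirna_de, out / "mirna_de.tsv")
    de.write_de_table(mrna_de, out / "mrna_de.tsv")

    # --- target maps -----------------------------------------------------
    requested = list(cfg.sources) + ["_".join(ix) for ix in cfg.intersections]
    try:
        all_maps: dict[str, tmaps.TargetMap] = {
            s: maps[s] for s in cfg.sources if s in maps
        }
        for ix in cfg.intersections:
            missing = [s for s in ix if s not in maps]
            if missing:
                logger.warning("intersection %s skipped, missing sources %s", ix, missing)
                continue
            all_maps["_".join(ix)] = tmaps.intersect_target_maps([maps[s] for s in ix])
    except Exception as exc:
        raise PipelineError(f"stage targets: {exc}") from exc

    # --- classification + summaries --------------------------------------
    summaries: dict[str, cc.FractionSummary] = {}
    concordance_frames = []
    surviving_probes = set(mrna_de.table.index)
    for name, tm in all_maps.items():
        probe_map = tmaps.map_symbols_to_probesets(tm, ann)
        probe_map = probe_map.restrict_to_probesets(surviving_probes)
        usable = [m for m in probe_map.mirnas if m in directions]
        skipped = [m for m in directions if m not in probe_map.mirnas]
        if skipped:
            logger.info(
                "source %s: %d DE miRNA(s) had no predictions and were excluded: %s",
                name, len(skipped), skipped,
            )
        probe_map = probe_map.restrict_to_mirnas(usable)
        if len(probe_map) == 0:
            logger.warning("source %s: no classifiable pairs; excluded", name)
            continue
        try:
            table = cc.classify_concordance(
                probe_map, directions, mrna_de, cfg.mrna_thresholds, calls=mrna_f.calls
            )
            summary = cc.summarize_fractions(table)
        except Exception as exc:
            raise PipelineError(f"stage classify ({name}): {exc}") from exc
        summaries[name] = summary
        rendered = summary.to_table()
        rendered.to_csv(out / f"fractions_{name}.tsv", sep="\t", index=False)
        recs = table.records.copy()
        recs.insert(0, "source", name)
        concordance_frames.append(recs)
        counts[f"pairs_{name}"] = len(table)
    if not summaries:
        raise PipelineError("stage classify: no prediction source yielded pairs")
    pd.concat(concordance_frames, ignore_index=True).to_csv(
        out / "concordance_records.tsv", sep="\t", index=False
    )

    method_avg = None
    if len(summaries) >= 2:
        method_avg = cc.average_across_methods(summaries)
        pd.DataFrame([method_avg]).to_csv(out / "method_average.tsv", sep="\t", index=False)

    # --- enrichment -------------------------------------------------------
    try:
        de_probes = set(mrna_de.flagged().index)
        background = set(mrna_de.table.index)
        target_sets = {}
        first_source = cfg.sources[0] if cfg.sources[0] in all_maps else next(iter(all_maps))
        base_probe_map = tmaps.map_symbols_to_probesets(all_maps[first_source], ann)
        for m in base_probe_map.mirnas:
            sub = base_probe_map.pairs[base_probe_map.pairs["mirna"] == m]
            target_sets[m] = set(sub["probeset"]) & background
        enrich = de.hypergeometric_enrichment(de_probes, target_sets, background)
        enrich.to_csv(out / "enrichment.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage enrich: {exc}") from exc

    # --- recovery vs planted truth (simulation only) ----------------------
    recovery = None
    if truth is not None:
        truth_classes = truth.truth_classes()
        table_all = cc.classify_concordance(
            tmaps.map_symbols_to_probesets(all_maps["M"], ann)
            .restrict_to_probesets(surviving_probes)
            .restrict_to_mirnas([m for m in directions if m in truth.mirna_directions]),
            directions,
            mrna_de,
            cfg.mrna_thresholds,
            calls=mrna_f.calls,
        )
        recovery = cc.evaluate_recovery(table_all, truth_classes)
        recovery["confusion"].to_csv(out / "recovery_confusion.tsv", sep="\t")

    manifest = {
        "seed": cfg.seed,
        "sources": list(requested),
        "thresholds": {
            "mirna": vars(cfg.mirna_thresholds).copy(),
            "mrna": vars(cfg.mrna_thresholds).copy(),
        },
        "counts": {k: int(v) if isinstance(v, (int, float)) else v for k, v in counts.items()},
    }
    if cfg.simulation is not None:
        simd = vars(cfg.simulation).copy()
        simd["targets_per_mirna"] = list(simd["targets_per_mirna"])
        manifest["simulation"] = simd
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return {
        "summaries": summaries,
        "method_average": method_avg,
        "enrichment": enrich,
        "recovery": recovery,
        "counts": counts,
        "mirna_de": mirna_de,
        "mrna_de": mrna_de,
    }
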