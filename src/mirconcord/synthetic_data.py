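"""Synthetic regulatory networks and expression data with known ground truth.

The generators emulate the study design the pipeline analyzes: a two-group
tissue comparison (cancer epithelium vs normal surface epithelium) profiled
on log2-scale arrays with Present/Marginal/Absent detection calls, a
mimic-vs-negative-control transfection experiment, multi-algorithm target
prediction maps with partial overlap, and qPCR Ct tables.  Regulation is
planted per (miRNA, target) pair in one of three classes — inversely
correlated (IC), positively correlated (PC) or null (NC) — so every
downstream stage can be scored against ground truth.

All generators are pure functions of (config, seed): each operation draws
from its own pseudorandom stream derived from ``cfg.seed`` plus an
operation-specific offset, so regenerating one artifact never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .expression_io import ExpressionMatrix, write_expression_table
from .qpcr_rest import QpcrDataset
from .target_maps import AnnotationTable, TargetMap, write_target_map

# per-operation stream offsets (see module docstring)
_STREAM_TARGETS = 1
_STREAM_PLANT = 2
_STREAM_TISSUE = 3
_STREAM_TRANSFECT = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generators.

    Sample sizes and class fractions default to the analyzed design: 3 cases
    vs 3 controls, planted IC/PC fractions 0.11/0.10, a 2-log2-unit
    regulatory effect, and triplicate transfections.  ``noise_sd`` is the
    per-measurement Gaussian sd on the log2 scale; ``baseline_sd`` the
    spread of per-probe baseline intensities; ``absent_rate`` the fraction
    of probe x sample cells marked Absent (lowest intensities first).
    """

    n_mirnas: int = 10
    n_genes: int = 2000
    targets_per_mirna: tuple[int, int] = (150, 250)
    ic_frac: float = 0.11
    pc_frac: float = 0.10
    n_case: int = 3
    n_control: int = 3
    n_reps: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    effect_lfc: float = 2.0
    absent_rate: float = 0.05
    variant_overlap: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic_frac + self.pc_frac > 1:
            raise ValueError("ic_frac + pc_frac must be <= 1")
        for name in ("n_mirnas", "n_genes", "n_case", "n_control", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.targets_per_mirna
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_mirna must be an increasing range >= 1")


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=(stream,)))


def mirna_name(i: int) -> str:
    return f"hsa-miR-s{i + 1}"


def gene_name(i: int) -> str:
    return f"GENE{i + 1:05d}"


def probeset_name(gene: str) -> str:
    return f"{gene}_at"


@dataclass
class RegulatoryTruth:
    """Planted regulation: per-pair class labels and per-miRNA directions.

    ``pairs``: DataFrame with columns mirna, gene, cls (IC/PC/NC) and
    effect_lfc (0 for NC).  ``mirna_directions``: mirna -> up/down.
    """

    pairs: pd.DataFrame
    mirna_directions: dict[str, str]

    def truth_classes(self) -> dict[tuple[str, str], str]:
        return {
            (m, g): c
            for m, g, c in zip(self.pairs["mirna"], self.pairs["gene"], self.pairs["cls"])
        }

    def planted_fractions(self) -> dict[str, float]:
        n = len(self.pairs)
        return {c: float((self.pairs["cls"] == c).sum()) / n for c in ("IC", "NC", "PC")}


def generate_target_map(
    cfg: SimulationConfig,
) -> tuple[TargetMap, dict[str, TargetMap]]:
    """Base prediction map plus two partially-overlapping algorithm variants.

    Each miRNA targets a uniform-random gene subset of size drawn from
    ``cfg.targets_per_mirna``.  Each variant keeps every base pair
    independently with probability ``cfg.variant_overlap`` and replaces
    dropped pairs with fresh random pairs for the same miRNA, so variant
    sizes match the base per miRNA.  Deterministic per seed.
    """
    lo, hi = cfg.targets_per_mirna
    if hi > cfg.n_genes:
        raise ValueError(
            f"targets_per_mirna upper bound {hi} exceeds n_genes {cfg.n_genes}"
        )
    rng = _rng(cfg.seed, _STREAM_TARGETS)
    genes = [gene_name(i) for i in range(cfg.n_genes)]
    base_rows = []
    per_mirna_targets: dict[str, list[str]] = {}
    for i in range(cfg.n_mirnas):
        mid = mirna_name(i)
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(cfg.n_genes, size=k, replace=False)
        targets = [genes[j] for j in chosen]
        per_mirna_targets[mid] = targets
        # plausible "good" mirSVR scores so the maps survive score filters
        base_rows.extend(
            {"mirna": mid, "gene": g, "score": float(rng.uniform(-2.0, -0.15))}
            for g in targets
        )
    base = TargetMap(pd.DataFrame(base_rows), source="M")

    variants: dict[str, TargetMap] = {}
    for source in ("TS", "PT"):
        rows = []
        for mid, targets in per_mirna_targets.items():
            keep = rng.random(len(targets)) < cfg.variant_overlap
            kept = [g for g, k in zip(targets, keep) if k]
            n_new = len(targets) - len(kept)
            pool = [g for g in genes if g not in set(targets)]
            if n_new > len(pool):
                raise ValueError("not enough genes to refill variant map")
            new = (
                [pool[j] for j in rng.choice(len(pool), size=n_new, replace=False)]
                if n_new
                else []
            )
            rows.extend(
                {"mirna": mid, "gene": g, "score": float(rng.uniform(-2.0, -0.15))}
                for g in kept + new
            )
        variants[source] = TargetMap(pd.DataFrame(rows), source=source)
    return base, variants


def plant_regulation(tm: TargetMap, cfg: SimulationConfig) -> RegulatoryTruth:
    """Label each predicted pair IC/PC/NC and give each miRNA a direction.

    Pairs are labeled independently: IC with probability ``cfg.ic_frac``, PC
    with ``cfg.pc_frac``, NC otherwise.  Non-NC pairs carry the configured
    effect magnitude on the log2 scale.
    """
    rng = _rng(cfg.seed, _STREAM_PLANT)
    u = rng.random(len(tm))
    cls = np.where(u < cfg.ic_frac, "IC", np.where(u < cfg.ic_frac + cfg.pc_frac, "PC", "NC"))
    pairs = pd.DataFrame(
        {
            "mirna": tm.pairs["mirna"].to_numpy(),
            "gene": tm.pairs["gene"].to_numpy(),
            "cls": cls,
            "effect_lfc": np.where(cls == "NC", 0.0, cfg.effect_lfc),
        }
    )
    directions = {
        m: ("up" if rng.random() < 0.5 else "down")
        for m in sorted(tm.pairs["mirna"].unique())
    }
    return RegulatoryTruth(pairs, directions)


def _assign_absent_calls(values: np.ndarray, absent_rate: float) -> np.ndarray:
    """Mark the ``absent_rate`` lowest-intensity cells Absent, the rest Present."""
    calls = np.full(values.shape, "P", dtype=object)
    n_absent = int(round(absent_rate * values.size))
    if n_absent > 0:
        flat = values.ravel()
        idx = np.argsort(flat, kind="stable")[:n_absent]
        calls.ravel()[idx] = "A"
    return calls


def _gene_effects(truth: RegulatoryTruth) -> dict[str, float]:
    """Net log2 group effect per gene: sum of per-pair planted effects.

    An IC pair pushes its gene opposite to the miRNA's direction, a PC pair
    with it; genes hit by several regulating miRNAs accumulate the sum.
    """
    effects: dict[str, float] = {}
    for _, row in truth.pairs.iterrows():
        if row["cls"] == "NC":
            continue
        sign = 1.0 if truth.mirna_directions[row["mirna"]] == "up" else -1.0
        delta = -sign * row["effect_lfc"] if row["cls"] == "IC" else sign * row["effect_lfc"]
        effects[row["gene"]] = effects.get(row["gene"], 0.0) + delta
    return effects


def simulate_tissue_experiment(
    truth: RegulatoryTruth, cfg: SimulationConfig
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two-group tissue experiment: (miRNA matrix, mRNA matrix).

    Case samples (group ``CEPI``) receive the planted group effects on top
    of per-probe baselines; controls (``OSE``) are baseline only.  miRNAs
    shift by +/- ``effect_lfc`` per their planted direction; target genes by
    the summed pair effects from :func:`_gene_effects`.  Gaussian noise of
    sd ``cfg.noise_sd`` is added per measurement and Absent calls go to the
    lowest-intensity cells at rate ``cfg.absent_rate``.
    """
    if cfg.n_case < 2 or cfg.n_control < 2:
        raise ValueError("need >= 2 samples per group")
    rng = _rng(cfg.seed, _STREAM_TISSUE)
    case_samples = [f"CEPI_{i + 1}" for i in range(cfg.n_case)]
    ctrl_samples = [f"OSE_{i + 1}" for i in range(cfg.n_control)]
    samples = case_samples + ctrl_samples
    groups = {s: "CEPI" for s in case_samples} | {s: "OSE" for s in ctrl_samples}
    case_mask = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)

    mirnas = sorted(truth.mirna_directions)
    mi_base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(mirnas))
    mi_dir = np.array(
        [1.0 if truth.mirna_directions[m] == "up" else -1.0 for m in mirnas]
    )
    mi_vals = (
        mi_base[:, None]
        + cfg.effect_lfc * mi_dir[:, None] * case_mask[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(mirnas), len(samples)))
    )
    mirna_m = ExpressionMatrix.from_arrays(
        mi_vals, mirnas, samples, groups, calls=_assign_absent_calls(mi_vals, cfg.absent_rate)
    )

    genes = [gene_name(i) for i in range(cfg.n_genes)]
    effects = _gene_effects(truth)
    g_base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    g_eff = np.array([effects.get(g, 0.0) for g in genes])
    g_vals = (
        g_base[:, None]
        + g_eff[:, None] * case_mask[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), len(samples)))
    )
    probes = [probeset_name(g) for g in genes]
    mrna_m = ExpressionMatrix.from_arrays(
        g_vals, probes, samples, groups, calls=_assign_absent_calls(g_vals, cfg.absent_rate)
    )
    return mirna_m, mrna_m


def simulate_transfection_experiment(
    truth: RegulatoryTruth, mirna: str, cfg: SimulationConfig
) -> ExpressionMatrix:
    """Mimic-vs-negative-control transfection for one miRNA.

    The mimic arm represses exactly that miRNA's IC-class targets by
    ``cfg.effect_lfc``; PC/NC targets and non-targets have expected log2
    change 0.  ``cfg.n_reps`` replicates per arm; groups ``mimic``/``NC``.
    """
    if cfg.n_reps < 2:
        raise ValueError("need >= 2 replicates per transfection arm")
    if mirna not in truth.mirna_directions:
        raise ValueError(f"unknown miRNA id {mirna!r}")
    rng = _rng(cfg.seed, _STREAM_TRANSFECT)
    mimic = [f"mimic_{i + 1}" for i in range(cfg.n_reps)]
    nc = [f"NC_{i + 1}" for i in range(cfg.n_reps)]
    samples = mimic + nc
    groups = {s: "mimic" for s in mimic} | {s: "NC" for s in nc}
    mimic_mask = np.array([1.0] * cfg.n_reps + [0.0] * cfg.n_reps)

    repressed = set(
        truth.pairs.loc[
            (truth.pairs["mirna"] == mirna) & (truth.pairs["cls"] == "IC"), "gene"
        ]
    )
    genes = [gene_name(i) for i in range(cfg.n_genes)]
    g_base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    g_eff = np.array([-cfg.effect_lfc if g in repressed else 0.0 for g in genes])
    vals = (
        g_base[:, None]
        + g_eff[:, None] * mimic_mask[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), len(samples)))
    )
    probes = [probeset_name(g) for g in genes]
    return ExpressionMatrix.from_arrays(
        vals, probes, samples, groups, calls=_assign_absent_calls(vals, cfg.absent_rate)
    )


def annotation_for(cfg: SimulationConfig) -> AnnotationTable:
    """The companion probeset -> gene-symbol annotation for simulated data."""
    genes = [gene_name(i) for i in range(cfg.n_genes)]
    return AnnotationTable.from_dict({probeset_name(g): g for g in genes})


def simulate_qpcr(
    true_ratio: float,
    n_per_group: int = 3,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    efficiency: float = 2.0,
    n_technical: int = 3,
) -> QpcrDataset:
    """Ct table with a known case-vs-control expression ratio.

    Reference-gene Cts are constant in expectation; case-group target Cts
    are offset by ``-log(true_ratio)/log(efficiency)`` cycles (higher
    expression amplifies earlier).  Gaussian noise of sd ``ct_noise_sd`` is
    added per technical replicate.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    rng = np.random.default_rng(seed)
    ref_ct, target_ct = 20.0, 25.0
    shift = -np.log(true_ratio) / np.log(efficiency)
    rows = []
    for grp, n in (("case", n_per_group), ("control", n_per_group)):
        for i in range(n):
            sample = f"{grp}_{i + 1}"
            for gene, base in (("target", target_ct), ("reference", ref_ct)):
                mu = base + (shift if (gene == "target" and grp == "case") else 0.0)
                for rep in range(n_technical):
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": grp,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct": mu + rng.normal(0.0, ct_noise_sd),
                        }
                    )
    return QpcrDataset(
        pd.DataFrame(rows),
        target_gene="target",
        reference_gene="reference",
        efficiency={"target": efficiency, "reference": efficiency},
    )


def write_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate and write a full fixture set with a YAML manifest.

    Emits the miRNA and mRNA expression tables, the three prediction maps,
    the annotation CSV, the planted truth, and ``manifest.yaml`` recording
    the config and seed.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base, variants = generate_target_map(cfg)
    truth = plant_regulation(base, cfg)
    mirna_m, mrna_m = simulate_tissue_experiment(truth, cfg)

    paths = {
        "mirna_expression": str(out / "mirna_expression.tsv"),
        "mrna_expression": str(out / "mrna_expression.tsv"),
        "targets_M": str(out / "targets_miranda.tsv"),
        "targets_TS": str(out / "targets_targetscan.tsv"),
        "targets_PT": str(out / "targets_pictar.tsv"),
        "annotation": str(out / "annotation.csv"),
        "truth": str(out / "truth.tsv"),
        "manifest": str(out / "manifest.yaml"),
    }
    write_expression_table(mirna_m, paths["mirna_expression"])
    write_expression_table(mrna_m, paths["mrna_expression"])
    write_target_map(base, paths["targets_M"])
    write_target_map(variants["TS"], paths["targets_TS"])
    write_target_map(variants["PT"], paths["targets_PT"])
    annotation_for(cfg).mapping.to_csv(paths["annotation"], index=False)
    truth_df = truth.pairs.copy()
    truth_df["mirna_direction"] = truth_df["mirna"].map(truth.mirna_directions)
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    cfg_dict = asdict(cfg)
    cfg_dict["targets_per_mirna"] = list(cfg_dict["targets_per_mirna"])
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump({"config": cfg_dict, "paths": paths}, fh, sort_keys=True)
    return paths
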