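"""IC/NC/PC concordance classification and its aggregation rules.

Each (miRNA, target probeset) pair is classified from two differential-
expression results — one for the miRNAs, one for the mRNAs — measured over
the same two-group contrast:

* NC (no change): the target fails the DE thresholds;
* IC (inversely correlated): the target passes and moves opposite to its
  regulating miRNA;
* PC (positively correlated): the target passes and moves with its miRNA.

Fractions are aggregated per miRNA (percent of that miRNA's surviving
targets), then as the unweighted mean of per-miRNA percentages within the
up-regulated and down-regulated miRNA groups, and finally as the mean of
those two group means.  The same mean-of-group-means rule is applied when
averaging across prediction algorithms and across validation methods, so a
printed summary row can always be recomputed from the rows above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DEResult, ThresholdConfig, call_de
from .target_maps import ProbeTargetMap

CLASSES = ("IC", "NC", "PC")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (what printed summary tables use)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


@dataclass
class ConcordanceTable:
    """Per-(miRNA, probeset) classification records.

    ``records`` columns: mirna, probeset, gene, mirna_direction (up/down),
    target_de_flag (bool), target_direction (up/down/none), cls (IC/NC/PC).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "mirna",
            "probeset",
            "gene",
            "mirna_direction",
            "target_de_flag",
            "target_direction",
            "cls",
        }
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"ConcordanceTable missing columns: {sorted(missing)}")
        r = self.records
        bad = ~r["cls"].isin(CLASSES)
        if bad.any():
            raise ValueError(f"invalid class labels: {r.loc[bad, 'cls'].unique()}")
        # class is fully determined by flag+directions; verify the invariant
        nc_ok = (r["cls"] == "NC") == ~r["target_de_flag"]
        if not nc_ok.all():
            raise ValueError("NC class must coincide with unflagged targets")
        self.records = r.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> pd.DataFrame:
        """Per-miRNA counts of IC/NC/PC plus total."""
        counts = (
            self.records.groupby(["mirna", "cls"]).size().unstack(fill_value=0)
        )
        for c in CLASSES:
            if c not in counts.columns:
                counts[c] = 0
        counts = counts[list(CLASSES)]
        counts["total"] = counts.sum(axis=1)
        dirs = self.records.groupby("mirna")["mirna_direction"].first()
        counts["mirna_direction"] = dirs
        return counts

    def overall_fractions(self) -> dict[str, float]:
        """Pooled class fractions over all records (not the table aggregate)."""
        n = len(self.records)
        return {c: float((self.records["cls"] == c).sum()) / n for c in CLASSES}


@dataclass
class FractionSummary:
    """Per-miRNA IC/NC/PC percentages plus group and overall aggregates.

    ``per_mirna`` columns: total, pct_IC, pct_NC, pct_PC, mirna_direction.
    ``group_means``/``overall``: {"IC": ..., "NC": ..., "PC": ...} values in
    percent; group means are unweighted means of member-miRNA percentages and
    the overall row is the mean of the up- and down-group means.
    """

    per_mirna: pd.DataFrame
    group_means: dict[str, dict[str, float]]
    overall: dict[str, float]

    @classmethod
    def from_per_mirna(cls, per_mirna: pd.DataFrame) -> "FractionSummary":
        """Aggregate a per-miRNA percentage table.

        Requires columns pct_IC/pct_NC/pct_PC and mirna_direction; any miRNA
        with zero total targets should already be excluded by the caller.
        """
        groups: dict[str, dict[str, float]] = {}
        for direction in ("up", "down"):
            sub = per_mirna[per_mirna["mirna_direction"] == direction]
            if len(sub):
                groups[direction] = {
                    c: float(sub[f"pct_{c}"].mean()) for c in CLASSES
                }
        if not groups:
            raise ValueError("no miRNA groups to aggregate")
        overall = {
            c: float(np.mean([g[c] for g in groups.values()])) for c in CLASSES
        }
        return cls(per_mirna=per_mirna, group_means=groups, overall=overall)

    def to_table(self, ndigits: int = 2) -> pd.DataFrame:
        """Render with aggregate rows appended, percentages rounded."""
        rows = []
        for mirna, row in self.per_mirna.iterrows():
            rows.append(
                {
                    "miRNA": mirna,
                    "total_targets": row["total"],
                    "pct_IC": round_half_up(row["pct_IC"], ndigits),
                    "pct_NC": round_half_up(row["pct_NC"], ndigits),
                    "pct_PC": round_half_up(row["pct_PC"], ndigits),
                }
            )
        for direction, label in (("up", "Average (for up-regulated miRNAs)"),
                                 ("down", "Average (for down-regulated miRNAs)")):
            if direction in self.group_means:
                g = self.group_means[direction]
                sub = self.per_mirna[self.per_mirna["mirna_direction"] == direction]
                rows.append(
                    {
                        "miRNA": label,
                        "total_targets": float(sub["total"].mean()),
                        "pct_IC": round_half_up(g["IC"], ndigits),
                        "pct_NC": round_half_up(g["NC"], ndigits),
                        "pct_PC": round_half_up(g["PC"], ndigits),
                    }
                )
        rows.append(
            {
                "miRNA": "Average (for Up and Down)",
                "total_targets": float(self.per_mirna["total"].mean()),
                "pct_IC": round_half_up(self.overall["IC"], ndigits),
                "pct_NC": round_half_up(self.overall["NC"], ndigits),
                "pct_PC": round_half_up(self.overall["PC"], ndigits),
            }
        )
        return pd.DataFrame(rows)


def _resolve_directions(mirna_de: DEResult | Mapping[str, str]) -> dict[str, str]:
    if isinstance(mirna_de, DEResult):
        return mirna_de.directions()
    return dict(mirna_de)


def classify_concordance(
    targets: ProbeTargetMap,
    mirna_de: DEResult | Mapping[str, str],
    mrna_de: DEResult,
    cfg: ThresholdConfig,
    calls: pd.DataFrame | None = None,
) -> ConcordanceTable:
    """Classify every (miRNA, probeset) pair as IC, NC or PC.

    ``targets`` should already be restricted to probesets surviving the
    Absent-in-all-samples filter (pairs whose probeset is missing from
    ``mrna_de`` are dropped, since such probes never entered testing).
    ``mirna_de`` supplies each miRNA's direction, either as a flagged
    :class:`DEResult` or as a plain mirna -> up/down mapping; a miRNA in
    ``targets`` without a direction is an error.
    """
    directions = _resolve_directions(mirna_de)
    missing = [m for m in targets.mirnas if m not in directions]
    if missing:
        raise ValueError(f"miRNA(s) lacking a DE direction: {missing}")

    # re-call flags under cfg; any flags already on mrna_de are not trusted
    called = call_de(mrna_de, cfg, calls=calls)
    tbl = called.table

    pairs = targets.pairs
    pairs = pairs[pairs["probeset"].isin(tbl.index)]
    flag = tbl["de_flag"].reindex(pairs["probeset"]).to_numpy()
    tdir = tbl["direction"].reindex(pairs["probeset"]).to_numpy()
    mdir = pairs["mirna"].map(directions).to_numpy()
    cls = np.where(~flag, "NC", np.where(tdir == mdir, "PC", "IC"))
    records = pd.DataFrame(
        {
            "mirna": pairs["mirna"].to_numpy(),
            "probeset": pairs["probeset"].to_numpy(),
            "gene": pairs["gene"].to_numpy(),
            "mirna_direction": mdir,
            "target_de_flag": flag,
            "target_direction": tdir,
            "cls": cls,
        }
    )
    return ConcordanceTable(records)


def summarize_fractions(table: ConcordanceTable) -> FractionSummary:
    """Per-miRNA percentages and the mean-of-group-means aggregates.

    Percentages are 100 * count / total per miRNA; miRNAs with zero records
    never appear (they are excluded upstream).  Raises on an empty table.
    """
    if len(table) == 0:
        raise ValueError("empty concordance table")
    counts = table.class_counts()
    per = pd.DataFrame(index=counts.index)
    per["total"] = counts["total"]
    for c in CLASSES:
        per[f"pct_{c}"] = 100.0 * counts[c] / counts["total"]
    per["mirna_direction"] = counts["mirna_direction"]
    return FractionSummary.from_per_mirna(per)


def average_across_methods(
    summaries: Mapping[str, FractionSummary | Mapping[str, float]]
) -> dict[str, float]:
    """Unweighted mean of each summary's overall IC/NC/PC percentages.

    Used to combine per-prediction-algorithm summaries into a single
    method-average row.  Accepts FractionSummary objects or plain
    {"IC": ..., "NC": ..., "PC": ...} dicts.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to average")
    overall_rows = [
        s.overall if isinstance(s, FractionSummary) else dict(s)
        for s in summaries.values()
    ]
    return {c: float(np.mean([r[c] for r in overall_rows])) for c in CLASSES}


def aggregate_over_methods(
    per_mirna_method_values: Mapping[str, Sequence[float]]
) -> tuple[dict[str, float], float]:
    """Mean per miRNA over prediction methods, then the overall mean.

    ``per_mirna_method_values`` maps a miRNA to the per-method percentage
    values for one class; returns ({miRNA: mean}, mean of those means) —
    the rule behind the validated-target cross-tabulation summary rows.
    """
    per = {m: float(np.mean(v)) for m, v in per_mirna_method_values.items()}
    return per, float(np.mean(list(per.values())))


def derive_validated_targets(
    transfection_de: DEResult,
    predicted: ProbeTargetMap,
    cfg: ThresholdConfig,
    mirna: str,
    calls: pd.DataFrame | None = None,
) -> ProbeTargetMap:
    """Predicted targets down-regulated after transfecting the miRNA's mimic.

    The transfection contrast (mimic minus negative control) is thresholded
    with ``cfg`` (FDR, fold-change, detection-call conditions); a predicted
    pair is "experimentally validated" when its probeset is flagged with
    direction down.  Raises if ``predicted`` has no pairs for the miRNA.
    """
    from .target_maps import normalize_mirna_id

    key = normalize_mirna_id(mirna)
    mine = predicted.restrict_to_mirnas([key])
    if len(mine) == 0:
        raise ValueError(f"no predicted targets for transfected miRNA {key!r}")
    called = call_de(transfection_de, cfg, calls=calls)
    down = called.table[(called.table["de_flag"]) & (called.table["direction"] == "down")]
    return mine.restrict_to_probesets(down.index)


def cross_tabulate_validated(
    validated_by_method: Mapping[str, Mapping[str, ProbeTargetMap]],
    mirna_de: DEResult | Mapping[str, str],
    mrna_de: DEResult,
    cfg: ThresholdConfig,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tissue-level IC/NC/PC fractions of experimentally validated targets.

    ``validated_by_method`` maps miRNA -> prediction method -> validated
    probe-level map.  Each (miRNA, method) cell is classified against the
    tissue contrast with ``cfg``; the output has one row per cell plus
    per-miRNA "all methods" mean rows and a final overall row (mean of the
    per-miRNA means), mirroring the validated-target summary layout.
    """
    if not any(len(methods) for methods in validated_by_method.values()):
        raise ValueError("no validated targets supplied")
    rows = []
    per_mirna_means: dict[str, dict[str, float]] = {}
    for mirna, methods in validated_by_method.items():
        method_pcts: dict[str, list[float]] = {c: [] for c in CLASSES}
        for method, vmap in methods.items():
            tab = classify_concordance(vmap, mirna_de, mrna_de, cfg, calls=calls)
            n = len(tab)
            pcts = {c: 100.0 * f for c, f in tab.overall_fractions().items()}
            rows.append(
                {
                    "miRNA": mirna,
                    "method": method,
                    "total_targets": n,
                    **{f"pct_{c}": pcts[c] for c in CLASSES},
                }
            )
            for c in CLASSES:
                method_pcts[c].append(pcts[c])
        per_mirna_means[mirna] = {c: float(np.mean(method_pcts[c])) for c in CLASSES}
        rows.append(
            {
                "miRNA": mirna,
                "method": "all methods (mean)",
                "total_targets": float(
                    np.mean([r["total_targets"] for r in rows if r["miRNA"] == mirna
                             and r["method"] != "all methods (mean)"])
                ),
                **{f"pct_{c}": per_mirna_means[mirna][c] for c in CLASSES},
            }
        )
    rows.append(
        {
            "miRNA": "overall",
            "method": "mean of miRNA means",
            "total_targets": float(
                np.mean([r["total_targets"] for r in rows if r["method"] == "all methods (mean)"])
            ),
            **{
                f"pct_{c}": float(np.mean([m[c] for m in per_mirna_means.values()]))
                for c in CLASSES
            },
        }
    )
    return pd.DataFrame(rows)


def evaluate_recovery(
    table: ConcordanceTable, truth: Mapping[tuple[str, str], str]
) -> dict:
    """Compare estimated classes against planted ground truth.

    ``truth`` maps (mirna, gene) -> planted class.  Returns the 3x3 confusion
    matrix (rows = truth, columns = estimate), per-class sensitivity and
    precision, and the absolute error of the estimated pooled class
    fractions versus the planted fractions.  Raises if the table contains a
    pair absent from the truth.
    """
    recs = table.records
    keys = list(zip(recs["mirna"], recs["gene"]))
    missing = [k for k in keys if k not in truth]
    if missing:
        raise ValueError(f"{len(missing)} pair(s) absent from truth, e.g. {missing[0]}")
    true_cls = np.array([truth[k] for k in keys])
    est_cls = recs["cls"].to_numpy()
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for t, e in zip(true_cls, est_cls):
        confusion.loc[t, e] += 1
    metrics = {}
    for c in CLASSES:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        metrics[c] = {
            "sensitivity": float(tp / (tp + fn)) if (tp + fn) else float("nan"),
            "precision": float(tp / (tp + fp)) if (tp + fp) else float("nan"),
        }
    n = len(recs)
    frac_err = {}
    for c in CLASSES:
        est = float((est_cls == c).sum()) / n
        planted = float((true_cls == c).sum()) / n
        frac_err[c] = abs(est - planted)
    return {"confusion": confusion, "per_class": metrics, "fraction_abs_error": frac_err}
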