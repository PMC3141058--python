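"""miRNA target-prediction maps: parsing, filtering, intersection, projection.

Three prediction-source dialects are supported, mirroring the flat files the
major public predictors distribute:

* microrna.org / miRanda: tab-delimited with header, columns
  ``mirna_name``, ``gene_symbol``, ``mirsvr_score`` (extra columns ignored).
  Only "good" mirSVR scores (strictly below -0.1 by default) are kept —
  mirSVR is more negative for stronger predicted down-regulation.
* TargetScan: ``miR_family``, ``gene_symbol``; family names are expanded to
  member miRNAs via a family table.
* PicTar (UCSC bulk or two-column manual curation): ``mirna_name``,
  ``gene_symbol``.

Maps intersect at the gene-symbol level and are then projected onto
probesets through an annotation table, because the sources share symbols
while expression is measured per probeset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: provenance tags: miRanda, TargetScan, PicTar, synthetic
SOURCES = ("M", "TS", "PT", "synthetic")


class TargetParseError(ValueError):
    """Malformed target-prediction file."""


def normalize_mirna_id(name: str) -> str:
    """Normalize a miRNA name to lowercase-prefix ``hsa-miR-...`` form.

    Case differences in the species prefix and the ``miR`` stem are folded;
    star forms (``miR-93*``) are kept verbatim, with no -3p/-5p modernizing.
    """
    s = name.strip()
    low = s.lower()
    if not low.startswith("hsa-") and low.startswith("mir-"):
        low = "hsa-" + low
    # restore canonical 'miR' capitalization after the species prefix
    if "-mir-" in low:
        idx = low.index("-mir-")
        low = low[: idx + 1] + "miR" + low[idx + 4 :]
    return low


@dataclass
class TargetMap:
    """Set of (miRNA, gene symbol) predicted pairs with provenance.

    ``pairs`` is a DataFrame with columns ``mirna``, ``gene``, ``score``
    (mirSVR score or NaN) and ``source``; (mirna, gene) is unique per source.
    """

    pairs: pd.DataFrame
    source: str = "synthetic"

    def __post_init__(self) -> None:
        required = {"mirna", "gene"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"TargetMap missing columns: {sorted(missing)}")
        df = self.pairs.copy()
        if "score" not in df.columns:
            df["score"] = float("nan")
        if "source" not in df.columns:
            df["source"] = self.source
        df["mirna"] = df["mirna"].map(normalize_mirna_id)
        df = df.drop_duplicates(subset=["mirna", "gene", "source"]).reset_index(drop=True)
        self.pairs = df[["mirna", "gene", "score", "source"]]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["mirna"], self.pairs["gene"]))

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.pairs["mirna"].unique())

    def targets_of(self, mirna: str) -> set[str]:
        key = normalize_mirna_id(mirna)
        return set(self.pairs.loc[self.pairs["mirna"] == key, "gene"])

    def restrict_to_mirnas(self, mirnas: Iterable[str]) -> "TargetMap":
        keys = {normalize_mirna_id(m) for m in mirnas}
        return TargetMap(self.pairs[self.pairs["mirna"].isin(keys)], self.source)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        source: str = "synthetic",
        scores: Mapping[tuple[str, str], float] | None = None,
    ) -> "TargetMap":
        records = []
        for mirna, gene in pairs:
            score = scores.get((mirna, gene), float("nan")) if scores else float("nan")
            records.append({"mirna": mirna, "gene": gene, "score": score})
        df = pd.DataFrame(records, columns=["mirna", "gene", "score"])
        return cls(df, source)


@dataclass
class AnnotationTable:
    """probeset id -> gene symbol map (many-to-one allowed both ways)."""

    mapping: pd.DataFrame  # columns: probeset_id, gene_symbol

    def __post_init__(self) -> None:
        df = self.mapping[["probeset_id", "gene_symbol"]].copy()
        if df["probeset_id"].duplicated().any():
            dupes = df.loc[df["probeset_id"].duplicated(), "probeset_id"].tolist()
            raise ValueError(f"duplicate probeset ids in annotation: {dupes[:5]}")
        if (df["gene_symbol"].astype(str).str.len() == 0).any():
            raise ValueError("annotation contains empty gene symbols")
        self.mapping = df.reset_index(drop=True)

    def probesets_for(self, symbol: str) -> list[str]:
        hit = self.mapping["gene_symbol"] == symbol
        return self.mapping.loc[hit, "probeset_id"].tolist()

    def symbol_of(self, probeset: str) -> str | None:
        hit = self.mapping.loc[self.mapping["probeset_id"] == probeset, "gene_symbol"]
        return None if hit.empty else hit.iloc[0]

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "AnnotationTable":
        return cls(pd.DataFrame({"probeset_id": list(d), "gene_symbol": list(d.values())}))


@dataclass
class ProbeTargetMap:
    """(miRNA, probeset) pairs derived from a symbol-level map + annotation."""

    pairs: pd.DataFrame  # columns: mirna, probeset, gene

    def __post_init__(self) -> None:
        required = {"mirna", "probeset", "gene"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"ProbeTargetMap missing columns: {sorted(missing)}")
        self.pairs = (
            self.pairs[["mirna", "probeset", "gene"]]
            .drop_duplicates(subset=["mirna", "probeset"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.pairs["mirna"].unique())

    def restrict_to_mirnas(self, mirnas: Iterable[str]) -> "ProbeTargetMap":
        keys = {normalize_mirna_id(m) for m in mirnas}
        return ProbeTargetMap(self.pairs[self.pairs["mirna"].isin(keys)])

    def restrict_to_probesets(self, probesets: Iterable[str]) -> "ProbeTargetMap":
        keep = set(probesets)
        return ProbeTargetMap(self.pairs[self.pairs["probeset"].isin(keep)])


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise TargetParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TargetParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_miranda_targets(path: str | Path, mirsvr_max: float = -0.1) -> TargetMap:
    """Read a microrna.org-style prediction file, keeping good mirSVR scores.

    Rows with score strictly below ``mirsvr_max`` are retained; a score of
    exactly -0.1 is dropped.  Duplicate (miRNA, gene) rows collapse to the
    most negative (strongest) score.
    """
    df = _read_table(path, ["mirna_name", "gene_symbol", "mirsvr_score"])
    scores = pd.to_numeric(df["mirsvr_score"], errors="coerce")
    bad = scores.isna() & df["mirsvr_score"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise TargetParseError(
            f"{path}: unparsable mirsvr_score {df.loc[bad.idxmax(), 'mirsvr_score']!r} "
            f"at line {line}"
        )
    out = pd.DataFrame(
        {
            "mirna": df["mirna_name"].map(normalize_mirna_id),
            "gene": df["gene_symbol"],
            "score": scores,
        }
    )
    out = out[out["score"] < mirsvr_max]
    out = out.sort_values("score").drop_duplicates(subset=["mirna", "gene"], keep="first")
    return TargetMap(out.reset_index(drop=True), source="M")


def read_targetscan_targets(
    path: str | Path, family_members: Mapping[str, Sequence[str]]
) -> TargetMap:
    """Read a TargetScan predicted-targets file, expanding miRNA families.

    ``family_members`` maps a family name (e.g. ``miR-141/200a``) to its
    member miRNA ids.  Families absent from the table are logged and skipped.
    """
    df = _read_table(path, ["miR_family", "gene_symbol"])
    records: list[dict[str, str]] = []
    skipped: set[str] = set()
    for fam, gene in zip(df["miR_family"], df["gene_symbol"]):
        members = family_members.get(fam)
        if members is None:
            skipped.add(fam)
            continue
        for m in members:
            records.append({"mirna": m, "gene": gene})
    if skipped:
        logger.warning("skipped %d unknown miR families: %s", len(skipped), sorted(skipped))
    out = pd.DataFrame(records, columns=["mirna", "gene"])
    return TargetMap(out, source="TS")


def read_pictar_targets(path: str | Path) -> TargetMap:
    """Read PicTar predictions (UCSC-table dialect or two-column curation).

    A miRNA simply absent from the file yields an empty target set, not an
    error — some miRNAs have no PicTar predictions at all.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
    if "mirna_name" in first:
        df = _read_table(path, ["mirna_name", "gene_symbol"])
        out = pd.DataFrame({"mirna": df["mirna_name"], "gene": df["gene_symbol"]})
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise TargetParseError(f"{path}: need >= 2 columns in headerless dialect")
        out = pd.DataFrame({"mirna": df[0], "gene": df[1]})
    return TargetMap(out, source="PT")


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    """Write in a header dialect all three readers accept (round-trippable)."""
    df = tm.pairs.rename(
        columns={"mirna": "mirna_name", "gene": "gene_symbol", "score": "mirsvr_score"}
    )
    df[["mirna_name", "gene_symbol", "mirsvr_score"]].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a probeset->symbol annotation CSV with columns probeset_id, gene_symbol."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("probeset_id", "gene_symbol") if c not in df.columns]
    if missing:
        raise TargetParseError(f"{path}: missing annotation column(s) {missing}")
    return AnnotationTable(df)


def intersect_target_maps(maps: Sequence[TargetMap]) -> TargetMap:
    """Pairs predicted by every input map, keyed on (miRNA, gene symbol).

    Provenance records all contributing sources (e.g. ``M+TS+PT``); the best
    (most negative) score among inputs is carried when any input has one.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to intersect")
    common = set.intersection(*(m.pair_set for m in maps))
    rows = []
    source = "+".join(m.source for m in maps)
    for mirna, gene in sorted(common):
        scores = [
            s
            for m in maps
            for s in m.pairs.loc[
                (m.pairs["mirna"] == mirna) & (m.pairs["gene"] == gene), "score"
            ]
            if pd.notna(s)
        ]
        rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "score": min(scores) if scores else float("nan"),
                "source": source,
            }
        )
    df = pd.DataFrame(rows, columns=["mirna", "gene", "score", "source"])
    return TargetMap(df, source=source)


def map_symbols_to_probesets(tm: TargetMap, ann: AnnotationTable) -> ProbeTargetMap:
    """Expand each (miRNA, symbol) pair to one pair per annotated probeset.

    Symbols with no probeset in the annotation are dropped; the count of
    dropped symbols is logged.
    """
    sym_to_probes = ann.mapping.groupby("gene_symbol")["probeset_id"].apply(list)
    records = []
    dropped: set[str] = set()
    for mirna, gene in zip(tm.pairs["mirna"], tm.pairs["gene"]):
        probes = sym_to_probes.get(gene)
        if probes is None:
            dropped.add(gene)
            continue
        for p in probes:
            records.append({"mirna": mirna, "probeset": p, "gene": gene})
    if dropped:
        logger.info("%d symbol(s) had no probeset annotation", len(dropped))
    df = pd.DataFrame(records, columns=["mirna", "probeset", "gene"])
    return ProbeTargetMap(df)
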