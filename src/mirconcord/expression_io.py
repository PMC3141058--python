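"""Expression matrices with Affymetrix-style detection calls.

The central container is :class:`ExpressionMatrix`: a probe-by-sample table of
log2-scale intensities, a parallel table of Present/Marginal/Absent (P/M/A)
detection calls, and a sample-to-group label map.  The module also provides
the matrix-level filters used ahead of differential-expression testing
(drop probes Absent everywhere, drop near-constant probes), per-probe z-score
normalization, and complete-linkage hierarchical clustering of samples under
a correlation similarity measure.

File format
-----------
Tab-delimited, UTF-8, ``#`` comment lines ignored.  Column 1 is the probe id.
In the ``signal+call`` dialect every sample contributes a ``<sample>`` signal
column followed by a ``<sample>_call`` detection column; in ``signal-only``
each sample is a single signal column and every call defaults to Present.
Group labels travel in a ``# groups: sample=label ...`` comment line so a
write/read round trip preserves the full object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

VALID_CALLS = frozenset("PMA")


class ExpressionParseError(ValueError):
    """Malformed expression table (bad header, ragged row, bad value)."""


@dataclass
class ExpressionMatrix:
    """Log2 intensities plus detection calls for probes x samples.

    Parameters
    ----------
    values
        DataFrame of log2-scale intensities, probes as index, samples as
        columns.  All entries must be finite.
    calls
        DataFrame of detection calls, same shape/labels as ``values``,
        entries in ``{"P", "M", "A"}``.
    groups
        Mapping from every sample id to its group label (e.g. CEPI/OSE,
        mimic/NC).
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dupes[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.calls.shape != self.values.shape:
            raise ValueError(
                f"calls shape {self.calls.shape} != values shape {self.values.shape}"
            )
        self.calls = self.calls.reindex(
            index=self.values.index, columns=self.values.columns
        )
        bad = set(np.unique(self.calls.to_numpy())) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")
        self.groups = dict(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        probes = list(probes)
        return ExpressionMatrix(
            self.values.loc[probes], self.calls.loc[probes], self.groups
        )

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
        groups: Mapping[str, str],
        calls: np.ndarray | None = None,
    ) -> "ExpressionMatrix":
        vals = pd.DataFrame(values, index=list(probe_ids), columns=list(sample_ids))
        if calls is None:
            call_df = pd.DataFrame("P", index=vals.index, columns=vals.columns)
        else:
            call_df = pd.DataFrame(calls, index=vals.index, columns=vals.columns)
        return cls(vals, call_df, dict(groups))


@dataclass
class Dendrogram:
    """Agglomerative clustering result in scipy linkage form.

    ``merges`` is an (n-1, 4) linkage matrix: each row joins two clusters at a
    given height; heights are non-decreasing for complete linkage.
    """

    merges: np.ndarray
    leaf_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_names)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows of 4")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.leaf_names[i] for i in order]

    def to_newick(self) -> str:
        """Render the tree as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length:.6g}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        inner = ",".join(fmt(c, tree.dist) for c in (tree.left, tree.right))
        return f"({inner});"


def read_expression_table(
    path: str | Path,
    dialect: str = "signal+call",
    groups: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    ``dialect`` is ``"signal+call"`` (paired ``<sample>`` / ``<sample>_call``
    columns) or ``"signal-only"`` (every call set to P).  Group labels are
    taken from a ``# groups:`` comment line unless ``groups`` is supplied.
    """
    if dialect not in ("signal+call", "signal-only"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    header: list[str] | None = None
    file_groups: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("groups:"):
                    for token in body[len("groups:"):].split():
                        if "=" not in token:
                            raise ExpressionParseError(
                                f"{path}:{lineno}: bad groups token {token!r}"
                            )
                        sample, label = token.split("=", 1)
                        file_groups[sample] = label
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append((lineno, fields))
    if header is None:
        raise ExpressionParseError(f"{path}: no header row found")

    if dialect == "signal+call":
        sample_ids = []
        cols = header[1:]
        if len(cols) % 2 != 0:
            raise ExpressionParseError(
                f"{path}: signal+call dialect needs paired columns, got {len(cols)}"
            )
        for i in range(0, len(cols), 2):
            sig, call = cols[i], cols[i + 1]
            if call != f"{sig}_call":
                raise ExpressionParseError(
                    f"{path}: expected call column '{sig}_call' after '{sig}', got {call!r}"
                )
            sample_ids.append(sig)
    else:
        sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ExpressionParseError(f"{path}: duplicate sample ids in header")

    probe_ids: list[str] = []
    values: list[list[float]] = []
    calls: list[list[str]] = []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise ExpressionParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        probe_ids.append(fields[0])
        if dialect == "signal+call":
            sig_fields = fields[1::2]
            call_fields = fields[2::2]
        else:
            sig_fields = fields[1:]
            call_fields = ["P"] * len(sig_fields)
        try:
            values.append([float(v) for v in sig_fields])
        except ValueError as exc:
            raise ExpressionParseError(f"{path}:{lineno}: non-numeric signal: {exc}")
        for c in call_fields:
            if c not in VALID_CALLS:
                raise ExpressionParseError(
                    f"{path}:{lineno}: unknown detection call {c!r}"
                )
        calls.append(call_fields)

    resolved_groups = dict(groups) if groups is not None else file_groups
    if not resolved_groups:
        # no labels anywhere: place every sample in one group so invariants hold
        resolved_groups = {s: "all" for s in sample_ids}
    return ExpressionMatrix.from_arrays(
        np.asarray(values, dtype=float),
        probe_ids,
        sample_ids,
        resolved_groups,
        calls=np.asarray(calls, dtype=object) if calls else None,
    )


def write_expression_table(
    m: ExpressionMatrix, path: str | Path, dialect: str = "signal+call"
) -> None:
    """Write ``m`` in a dialect :func:`read_expression_table` reads back."""
    if dialect not in ("signal+call", "signal-only"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# groups: " + " ".join(f"{s}={g}" for s, g in m.groups.items()) + "\n")
        if dialect == "signal+call":
            cols = []
            for s in m.sample_ids:
                cols.extend([s, f"{s}_call"])
        else:
            cols = list(m.sample_ids)
        fh.write("\t".join(["probe_id"] + cols) + "\n")
        for probe in m.probe_ids:
            fields = [probe]
            for s in m.sample_ids:
                fields.append(repr(float(m.values.at[probe, s])))
                if dialect == "signal+call":
                    fields.append(str(m.calls.at[probe, s]))
            fh.write("\t".join(fields) + "\n")


def filter_all_absent(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop probes whose detection call is Absent in every sample.

    Probes with at least one P or M call anywhere survive; survivor order is
    preserved.  Idempotent.
    """
    if m.n_probes == 0:
        return m
    keep = (m.calls != "A").any(axis=1)
    return ExpressionMatrix(m.values.loc[keep], m.calls.loc[keep], m.groups)


def filter_low_sd(m: ExpressionMatrix, sd_min: float = 0.5, ddof: int = 1) -> ExpressionMatrix:
    """Drop probes whose across-sample standard deviation is below ``sd_min``.

    Sample (n-1) standard deviation by default.  Requires >= 2 samples.
    """
    if m.n_samples < 2:
        raise ValueError("standard deviation undefined with fewer than 2 samples")
    if m.n_probes == 0:
        return m
    sd = m.values.std(axis=1, ddof=ddof)
    keep = sd >= sd_min
    return ExpressionMatrix(m.values.loc[keep], m.calls.loc[keep], m.groups)


def zscore_probes(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Center and scale each probe row to mean 0, sd 1 (sample sd).

    Zero-sd probes are an error: apply :func:`filter_low_sd` (or any positive
    sd threshold) first.
    """
    if m.n_samples < 2:
        raise ValueError("z-score undefined with fewer than 2 samples")
    sd = m.values.std(axis=1, ddof=ddof)
    zero = sd[sd == 0]
    if len(zero) > 0:
        raise ValueError(
            f"{len(zero)} probe(s) have zero standard deviation "
            f"(e.g. {zero.index[0]!r}); filter constant probes first"
        )
    z = m.values.sub(m.values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, m.calls.copy(), m.groups)


def cluster_samples(m: ExpressionMatrix) -> Dendrogram:
    """Complete-linkage clustering of samples on 1 - Pearson correlation.

    Missing values are replaced by 0 before computing correlations.  A
    constant sample column makes the correlation undefined and raises.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = m.values.to_numpy(dtype=float)
    x = np.nan_to_num(x, nan=0.0)
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = [m.sample_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant sample column(s), correlation undefined: {bad}")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    merges = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return Dendrogram(merges, list(m.sample_ids))
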