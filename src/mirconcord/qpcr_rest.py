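"""Relative qPCR quantification (ΔΔCt) and a fixed-reallocation
randomization test.

Technical replicates are averaged to one Ct per (sample, gene); per sample
ΔCt = Ct(target) - Ct(reference); ΔΔCt is the case-group mean ΔCt minus the
control-group mean; the expression ratio is efficiency^(-ΔΔCt), where
efficiency is the amplification factor per cycle (2.0 for perfect doubling).
Significance comes from reallocating sample group labels at fixed group
sizes and recomputing the ratio each time — exhaustive enumeration when the
number of distinct allocations is small, Monte-Carlo otherwise — with a
two-sided p-value on |log ratio| that counts the observed allocation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class QpcrDataset:
    """Ct measurements for one target gene and one reference gene.

    ``data`` columns: sample_id, group (case/control), gene, replicate, ct.
    Every sample must have Cts for both the target and the reference gene,
    with >= 2 biological samples per group; amplification efficiency is per
    gene, defaulting to 2.0 per cycle.
    """

    data: pd.DataFrame
    target_gene: str
    reference_gene: str
    efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        d = self.data.copy()
        d["ct"] = d["ct"].astype(float)
        if (d["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad_groups = set(d["group"]) - {"case", "control"}
        if bad_groups:
            raise ValueError(f"group labels must be case/control, got {bad_groups}")
        self.data = d
        per = self._per_sample_ct()
        for gene in (self.target_gene, self.reference_gene):
            if gene not in per.columns:
                raise ValueError(f"no Ct measurements for gene {gene!r}")
        if per[[self.target_gene, self.reference_gene]].isna().any().any():
            incomplete = per.index[
                per[[self.target_gene, self.reference_gene]].isna().any(axis=1)
            ].tolist()
            raise ValueError(f"samples missing target or reference Ct: {incomplete}")
        for grp in ("case", "control"):
            n = len(set(d.loc[d["group"] == grp, "sample_id"]))
            if n < 2:
                raise ValueError(f"need >= 2 biological samples in {grp!r}, got {n}")

    def _per_sample_ct(self) -> pd.DataFrame:
        """Average technical replicates: sample x gene mean Ct."""
        return self.data.pivot_table(
            index="sample_id", columns="gene", values="ct", aggfunc="mean"
        )

    def delta_ct(self) -> pd.Series:
        """Per-sample ΔCt = Ct(target) - Ct(reference)."""
        per = self._per_sample_ct()
        return per[self.target_gene] - per[self.reference_gene]

    def sample_groups(self) -> pd.Series:
        return self.data.groupby("sample_id")["group"].first()

    def gene_efficiency(self, gene: str) -> float:
        return self.efficiency.get(gene, 2.0)


def read_ct_table(
    path: str | Path,
    target_gene: str,
    reference_gene: str,
    efficiency: dict[str, float] | None = None,
) -> QpcrDataset:
    """Load a Ct CSV with columns sample_id, group, gene, replicate, ct."""
    df = pd.read_csv(path)
    return QpcrDataset(df, target_gene, reference_gene, efficiency or {})


def _ratio_from_dct(
    dct: np.ndarray, is_case: np.ndarray, eff: float
) -> float:
    ddct = dct[is_case].mean() - dct[~is_case].mean()
    return eff ** (-ddct)


def ddct_ratio(d: QpcrDataset) -> float:
    """Case-vs-control relative expression via the ΔΔCt method.

    ratio = efficiency^(-ΔΔCt); with efficiency 2, a target 3 cycles earlier
    in cases (reference unchanged) gives ratio 8.
    """
    dct = d.delta_ct()
    groups = d.sample_groups().reindex(dct.index)
    eff = d.gene_efficiency(d.target_gene)
    return float(
        _ratio_from_dct(dct.to_numpy(), (groups == "case").to_numpy(), eff)
    )


@dataclass
class RandomizationResult:
    ratio: float
    p_value: float
    n_rand: int
    mode: str  # "exhaustive" | "monte-carlo"


def randomization_test(
    d: QpcrDataset,
    n_rand: int = 5000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> RandomizationResult:
    """Fixed-reallocation randomization test on the ΔΔCt ratio.

    Group labels are reassigned to samples at fixed group sizes; the ratio is
    recomputed for each allocation.  Two-sided p = proportion of allocations
    with |log ratio| >= the observed |log ratio|; in Monte-Carlo mode the
    observed allocation is counted so p >= 1/(n_rand+1).  All C(n, n_case)
    allocations are enumerated when there are at most ``n_rand`` of them,
    unless ``force_monte_carlo`` disables the exhaustive shortcut.
    """
    dct = d.delta_ct().to_numpy()
    groups = d.sample_groups().reindex(d.delta_ct().index)
    is_case = (groups == "case").to_numpy()
    n, n_case = len(dct), int(is_case.sum())
    eff = d.gene_efficiency(d.target_gene)

    obs_ratio = _ratio_from_dct(dct, is_case, eff)
    obs_stat = abs(math.log(obs_ratio))

    total = math.comb(n, n_case)
    tol = 1e-12
    if total <= n_rand and not force_monte_carlo:
        exceed = 0
        for combo in itertools.combinations(range(n), n_case):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            stat = abs(math.log(_ratio_from_dct(dct, mask, eff)))
            if stat >= obs_stat - tol:
                exceed += 1
        return RandomizationResult(
            ratio=float(obs_ratio),
            p_value=exceed / total,
            n_rand=total,
            mode="exhaustive",
        )

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_rand):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_case]] = True
        stat = abs(math.log(_ratio_from_dct(dct, mask, eff)))
        if stat >= obs_stat - tol:
            exceed += 1
    # count the observed allocation itself
    p = (exceed + 1) / (n_rand + 1)
    return RandomizationResult(
        ratio=float(obs_ratio), p_value=min(p, 1.0), n_rand=n_rand, mode="monte-carlo"
    )
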