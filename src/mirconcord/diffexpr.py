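"""Differential-expression statistics for two-group microarray designs.

Three pieces:

* a pooled-variance (equal-variance) two-sample t-test per probe, reporting
  the log2 group-mean difference as the fold-change statistic;
* threshold-based DE calling with the named presets used throughout the
  pipeline (tissue mRNA: p<0.005 and |log2 diff| >= 1, i.e. fold change >= 2;
  tissue miRNA: p<0.01 and |log2 diff| >= 1; transfection: SAM q <= 5%,
  |log2 diff| >= 0.5, i.e. fold change >= 1.4, plus a Present/Marginal call
  in at least one sample);
* a SAM-style permutation false-discovery rate (relative-difference statistic
  d = r/(s+s0) with the fudge factor s0 chosen to stabilize the coefficient
  of variation of d across the spread of s) and an upper-tail hypergeometric
  enrichment test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-probe two-group comparison results.

    ``table`` columns: ``lfc`` (log2 mean difference, case - control), ``t``,
    ``p`` (two-sided), optional ``q``, ``de_flag`` (bool) and ``direction``
    in {"up", "down", "none"}; probes as index.
    """

    table: pd.DataFrame
    group_a: str = "case"
    group_b: str = "control"

    def __post_init__(self) -> None:
        required = {"lfc", "t", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult missing columns: {sorted(missing)}")
        t = self.table.copy()
        if "de_flag" not in t.columns:
            t["de_flag"] = False
        if "direction" not in t.columns:
            t["direction"] = "none"
        if ((t["p"] < 0) | (t["p"] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if "q" in t.columns and ((t["q"].dropna() < 0) | (t["q"].dropna() > 1)).any():
            raise ValueError("q-values outside [0, 1]")
        self.table = t

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def has_q(self) -> bool:
        return "q" in self.table.columns

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["de_flag"]]

    def directions(self) -> dict[str, str]:
        """probe -> direction for flagged probes only."""
        f = self.flagged()
        return dict(zip(f.index, f["direction"]))

    def with_q(self, q: pd.Series) -> "DEResult":
        t = self.table.copy()
        t["q"] = q.reindex(t.index)
        return replace(self, table=t)


@dataclass(frozen=True)
class ThresholdConfig:
    """DE calling thresholds.

    ``abs_lfc_min`` is on the log2 scale: a raw fold change of 2 corresponds
    to 1.0, a fold change of 1.4 to ~0.5.  ``q_max`` (when set) is an FDR
    ceiling applied on top of (or instead of) the p ceiling.
    """

    p_max: float | None = None
    abs_lfc_min: float = 0.0
    q_max: float | None = None
    require_present_in_one: bool = False

    def __post_init__(self) -> None:
        if self.p_max is not None and self.p_max <= 0:
            raise ValueError("p_max must be positive")
        if self.q_max is not None and self.q_max <= 0:
            raise ValueError("q_max must be positive")
        if self.abs_lfc_min < 0:
            raise ValueError("abs_lfc_min must be >= 0")


#: tissue mRNA comparison (CEPI vs OSE): p<0.005 and fold change >= 2
TISSUE_MRNA = ThresholdConfig(p_max=0.005, abs_lfc_min=1.0)
#: tissue miRNA comparison: p<0.01 and log2 difference >= 1
TISSUE_MIRNA = ThresholdConfig(p_max=0.01, abs_lfc_min=1.0)
#: mimic-vs-negative-control transfection: SAM FDR 5%, fold change >= 1.4,
#: Present/Marginal in at least one sample
TRANSFECTION = ThresholdConfig(
    q_max=0.05, abs_lfc_min=0.5, require_present_in_one=True
)

PRESETS: dict[str, ThresholdConfig] = {
    "tissue_mrna": TISSUE_MRNA,
    "tissue_mirna": TISSUE_MIRNA,
    "transfection": TRANSFECTION,
}


def _group_arrays(
    m: ExpressionMatrix, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    sa = m.samples_in_group(group_a)
    sb = m.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(sa)} in {group_a!r} "
            f"and {len(sb)} in {group_b!r}"
        )
    return m.values[sa].to_numpy(float), m.values[sb].to_numpy(float)


def ttest_two_sample(
    m: ExpressionMatrix, group_a: str, group_b: str
) -> DEResult:
    """Equal-variance two-sample t-test per probe (two-sided).

    ``lfc`` is mean(group_a) - mean(group_b) on the log2 scale and
    df = n_a + n_b - 2.  Probes with zero pooled variance use the convention
    p = 1 when the means are equal and p = 0 otherwise.
    """
    a, b = _group_arrays(m, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    df = na + nb - 2
    pooled_var = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    with np.errstate(invalid="ignore"):
        t[zero] = np.where(lfc[zero] == 0, 0.0, np.sign(lfc[zero]) * np.inf)
    p[zero] = np.where(lfc[zero] == 0, 1.0, 0.0)
    table = pd.DataFrame({"lfc": lfc, "t": t, "p": p}, index=m.values.index)
    return DEResult(table, group_a=group_a, group_b=group_b)


def call_de(
    res: DEResult,
    cfg: ThresholdConfig,
    calls: pd.DataFrame | None = None,
) -> DEResult:
    """Apply thresholds to a :class:`DEResult`, setting flags and directions.

    A probe is flagged iff every configured condition holds: p < p_max,
    |lfc| >= abs_lfc_min, q <= q_max (when ``q_max`` is set) and at least one
    Present/Marginal detection call (when ``require_present_in_one``).
    Direction is the sign of the flagged probe's lfc.
    """
    t = res.table.copy()
    flag = pd.Series(True, index=t.index)
    if cfg.p_max is not None:
        flag &= t["p"] < cfg.p_max
    flag &= t["lfc"].abs() >= cfg.abs_lfc_min
    if cfg.q_max is not None:
        if "q" not in t.columns or t["q"].isna().all():
            raise ValueError("q_max configured but no q-values present; run sam_qvalues")
        flag &= t["q"] <= cfg.q_max
    if cfg.require_present_in_one:
        if calls is None:
            raise ValueError("require_present_in_one set but no detection calls given")
        present = (calls.reindex(t.index) != "A").any(axis=1)
        flag &= present
    t["de_flag"] = flag
    t["direction"] = np.where(
        ~flag, "none", np.where(t["lfc"] >= 0, "up", "down")
    )
    return replace(res, table=t)


def _sam_statistic(
    a: np.ndarray, b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative difference d = r/(s+s0) with its numerator r and gene scatter s."""
    na, nb = a.shape[1], b.shape[1]
    r = a.mean(axis=1) - b.mean(axis=1)
    pooled = (
        ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (na + nb - 2)
    s = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return r / (s + s0), r, s


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Pick the fudge factor on a percentile grid of s.

    Candidate s0 values are the 0,5,...,100 percentiles of s; for each, the
    median absolute deviation of d is computed within each 5%-wide window of
    s, and the s0 minimizing the coefficient of variation of those MADs wins.
    """
    qs = np.percentile(s, np.arange(0, 101, 5))
    edges = np.percentile(s, np.arange(0, 101, 5))
    windows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (s >= lo) & (s <= hi)
        if mask.sum() >= 2:
            windows.append(mask)
    best_s0, best_cv = 0.0, np.inf
    for s0 in np.unique(qs):
        d = r / (s + s0)
        mads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) / 0.64 for w in windows]
        )
        if mads.mean() == 0:
            continue
        cv = mads.std(ddof=0) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(
    n: int, na: int, n_perm: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], bool]:
    """Index sets for group A under permuted labels (exhaustive when small)."""
    total = math.comb(n, na)
    if total <= n_perm:
        combos = [np.array(c) for c in itertools.combinations(range(n), na)]
        return combos, True
    seen: set[tuple[int, ...]] = set()
    out: list[np.ndarray] = []
    while len(out) < n_perm:
        perm = rng.permutation(n)
        key = tuple(sorted(perm[:na]))
        out.append(np.array(key))
        seen.add(key)
    return out, False


def sam_qvalues(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 200,
    seed: int | None = None,
    s0: float | None = None,
) -> pd.Series:
    """SAM-style permutation q-values per probe.

    The observed relative difference d_i = r_i/(s_i+s0) is compared against
    the same statistic under label permutations (exhaustive enumeration when
    the number of distinct label assignments is at most ``n_perm``, logged
    when that fallback triggers).  For each probe the false-positive count is
    the median over permutations of the number of permuted |d*| at or above
    |d_i|; q_i = pi0 * median_count / #{|d| >= |d_i|}, with pi0 estimated
    from the fraction of observed d inside the permutation interquartile
    range, then made monotone in |d| and clipped to [0, 1].
    """
    if n_perm < 25:
        raise ValueError("n_perm must be >= 25")
    a, b = _group_arrays(m, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    x = np.hstack([a, b])
    _, r, s = _sam_statistic(a, b, 0.0)
    if s0 is None:
        s0 = _choose_s0(r, s)
    d_obs, _, _ = _sam_statistic(a, b, s0)

    rng = np.random.default_rng(seed)
    index_sets, exhaustive = _label_permutations(na + nb, na, n_perm, rng)
    if exhaustive:
        logger.info(
            "exhaustive enumeration of %d label assignments (<= n_perm=%d)",
            len(index_sets),
            n_perm,
        )
    all_idx = np.arange(na + nb)
    d_perm = np.empty((len(index_sets), len(d_obs)))
    for k, ia in enumerate(index_sets):
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        d_perm[k], _, _ = _sam_statistic(x[:, ia], x[:, ib], s0)

    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(d_perm)
    # pi0: fraction of observed d within the permutation null's IQR
    q25, q75 = np.percentile(d_perm, [25, 75])
    pi0 = min(1.0, np.mean((d_obs > q25) & (d_obs < q75)) / 0.5)

    order = np.argsort(-abs_obs)
    sorted_abs = abs_obs[order]
    # called at threshold |d_i|: number of observed |d| >= |d_i|
    n_called = np.arange(1, len(sorted_abs) + 1)
    perm_sorted = np.sort(abs_perm.ravel())
    # median over permutations of count(|d*| >= cutoff)
    med_counts = np.empty(len(sorted_abs))
    counts_per_perm = np.empty(len(index_sets))
    for i, cutoff in enumerate(sorted_abs):
        counts_per_perm = (abs_perm >= cutoff).sum(axis=1)
        med_counts[i] = np.median(counts_per_perm)
    q_sorted = np.clip(pi0 * med_counts / n_called, 0.0, 1.0)
    # enforce monotone non-decreasing q as the threshold relaxes
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.Series(q, index=m.values.index, name="q")


def hypergeometric_enrichment(
    de_set: Iterable[str],
    target_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test per named target set.

    With N = |background|, K = |target set ∩ background|, n = |de_set| and
    k the observed overlap, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    Benjamini-Hochberg q-values are computed across the named sets.  The DE
    set must be a subset of the background; each target set is intersected
    with the background before testing.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background set is empty")
    de = set(de_set)
    if not de <= bg:
        raise ValueError(f"{len(de - bg)} DE element(s) not in background")
    N, n = len(bg), len(de)
    rows = []
    for name, tset in target_sets.items():
        targets = set(tset) & bg
        K = len(targets)
        k = len(de & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "N": N, "K": K, "n": n, "k": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("set")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def write_de_table(res: DEResult, path, symbols: Mapping[str, str] | None = None) -> None:
    """Write a DE result as a tab-delimited table (probe, symbol, means in
    lfc form, p, q in percent, flag)."""
    t = res.table.copy()
    out = pd.DataFrame(index=t.index)
    out["probe_id"] = t.index
    out["gene_symbol"] = (
        [symbols.get(p, "") for p in t.index] if symbols else ""
    )
    out["log2_difference"] = t["lfc"]
    out["t"] = t["t"]
    out["p_value"] = t["p"]
    out["q_value_pct"] = (t["q"] * 100.0) if "q" in t.columns else np.nan
    out["de_flag"] = t["de_flag"]
    out["direction"] = t["direction"]
    out.to_csv(path, sep="\t", index=False)
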