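"""Goodness-of-fit diagnostics for the CJS homogeneity assumptions.

Two classical contingency-table components are computed natively from the
encounter histories of one population (or of all populations pooled):

* transience (TEST3.SR): at each occasion, individuals encountered there are
  split into newly marked vs previously marked and cross-classified by
  whether they are ever seen again.  An excess of new animals never seen
  again indicates transients.
* trap-dependence (TEST2.CT): among individuals known to be alive at an
  occasion and seen again afterwards, detection at that occasion is
  cross-classified against whether the next detection is immediate (t+1) or
  delayed.  An association indicates trap-happiness or trap-shyness.

Per-occasion 2x2 tables are tested with Pearson chi-square and summed; tables
with any expected count below 2 are pooled into the following occasion's
table, and occasions that remain degenerate are dropped from the degrees of
freedom.  A signed z statistic (positive = transience excess / trap
happiness) accompanies the chi-squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import StudyDataset

__all__ = ["GofResult", "test3_sr", "test2_ct", "overall_gof"]


@dataclass
class GofResult:
    """One GOF component: summed chi-square, df, p-value and the tables used."""

    component: str
    statistic: float
    df: int
    p_value: float
    tables: list[np.ndarray] = field(default_factory=list)
    z: float | None = None
    testable: bool = True
    n_pooled: int = 0

    def __repr__(self) -> str:
        if not self.testable:
            return f"GofResult({self.component}: untestable)"
        return (f"GofResult({self.component}: chi2={self.statistic:.3f}, "
                f"df={self.df}, p={self.p_value:.4f})")


def _full_histories(dataset: StudyDataset, population_id: str | None) -> list[np.ndarray]:
    """Histories as full-window 0/1 vectors (zeros before entry)."""
    out = []
    if population_id is None:
        pops = sorted(dataset.populations)
    else:
        if population_id not in dataset.populations:
            raise KeyError(f"unknown population {population_id!r}")
        pops = [population_id]
    for p in pops:
        K = dataset.populations[p].n_occasions
        for h in dataset.histories_for(p):
            v = np.zeros(K, dtype=int)
            v[h.entry_occasion - 1 :] = h.detections
            out.append(v)
    return out


def _pearson_2x2(t: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square and signed z for a 2x2 table (z from cell [0,0])."""
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if n == 0 or (row == 0).any() or (col == 0).any():
        return np.nan, np.nan
    e = np.outer(row, col) / n
    chi2 = float(((t - e) ** 2 / e).sum())
    # hypergeometric variance of cell (0,0) under independence
    var = row[0] * row[1] * col[0] * col[1] / (n**2 * (n - 1)) if n > 1 else 0.0
    z = (t[0, 0] - e[0, 0]) / np.sqrt(var) if var > 0 else 0.0
    return chi2, float(z)


def _sum_component(tables: list[np.ndarray], component: str) -> GofResult:
    """Pool sparse tables forward, sum Pearson chi-squares over informative ones."""
    pooled: list[np.ndarray] = []
    carry = np.zeros((2, 2), dtype=float)
    n_pooled = 0
    for t in tables:
        t = t + carry
        carry = np.zeros((2, 2), dtype=float)
        n = t.sum()
        row, col = t.sum(axis=1), t.sum(axis=0)
        if n == 0:
            continue
        degenerate = (row == 0).any() or (col == 0).any()
        e = np.outer(row, col) / n if not degenerate else np.zeros((2, 2))
        if degenerate or (e < 2).any():
            carry = t
            n_pooled += 1
            continue
        pooled.append(t)
    if carry.sum() > 0:
        n = carry.sum()
        row, col = carry.sum(axis=1), carry.sum(axis=0)
        if not ((row == 0).any() or (col == 0).any()) and (np.outer(row, col) / n >= 2).all():
            pooled.append(carry)
    if not pooled:
        return GofResult(component=component, statistic=0.0, df=0, p_value=1.0,
                         tables=[], testable=False, n_pooled=n_pooled)
    chi2 = 0.0
    z_num = 0.0
    z_den = 0.0
    for t in pooled:
        c, z = _pearson_2x2(t)
        chi2 += c
        n = t.sum()
        row, col = t.sum(axis=1), t.sum(axis=0)
        e00 = row[0] * col[0] / n
        var = row[0] * row[1] * col[0] * col[1] / (n**2 * (n - 1)) if n > 1 else 0.0
        z_num += t[0, 0] - e00
        z_den += var
    df = len(pooled)
    z = float(z_num / np.sqrt(z_den)) if z_den > 0 else 0.0
    return GofResult(component=component, statistic=float(chi2), df=df,
                     p_value=float(stats.chi2.sf(chi2, df)), tables=pooled,
                     z=z, n_pooled=n_pooled)


def test3_sr(dataset: StudyDataset, population_id: str | None = None) -> GofResult:
    """Transience test: newly vs previously marked, seen again or not.

    Row 0 = newly marked at the occasion, column 0 = never seen again, so a
    positive z means an excess of new animals never reencountered
    (transience).  Occasions are the interior ones (2..K-1 have both cohort
    types possible and a future to be seen in); with a population_id of None
    all populations' tables are summed into one statistic.
    """
    hists = _full_histories(dataset, population_id)
    tables: list[np.ndarray] = []
    if hists:
        K = max(len(v) for v in hists)
        for t in range(1, K - 1):  # occasions 2..K-1 (0-based t)
            tab = np.zeros((2, 2), dtype=float)
            for v in hists:
                if t >= len(v) or v[t] != 1:
                    continue
                new = v[:t].sum() == 0
                seen_again = v[t + 1 :].sum() > 0
                tab[0 if new else 1, 1 if seen_again else 0] += 1
            tables.append(tab)
    res = _sum_component(tables, "test3_sr")
    if res.testable:
        informative = any((t.sum(axis=1) > 0).all() for t in res.tables)
        if not informative:
            return GofResult("test3_sr", 0.0, 0, 1.0, [], testable=False)
    return res


def test2_ct(dataset: StudyDataset, population_id: str | None = None) -> GofResult:
    """Trap-dependence test: detection at t vs immediacy of the next detection.

    Conditions on individuals known to be alive at occasion t (detected at t,
    or detected both before and after t) that are detected again after t.
    Row 0 = detected at t, column 0 = next detection at t+1, so a positive z
    means trap-happiness.  Needs at least 3 occasions; a two-occasion study
    is untestable.
    """
    hists = _full_histories(dataset, population_id)
    tables: list[np.ndarray] = []
    if hists:
        K = max(len(v) for v in hists)
        for t in range(1, K - 2):  # occasions 2..K-2 (0-based)
            tab = np.zeros((2, 2), dtype=float)
            for v in hists:
                if t >= len(v):
                    continue
                before = v[:t].sum() > 0
                later = np.flatnonzero(v[t + 1 :])
                if later.size == 0:
                    continue
                at_t = v[t] == 1
                if not (at_t or before):
                    continue  # not yet marked / not known alive at t
                immediate = later[0] == 0  # next detection is at t+1
                tab[0 if at_t else 1, 0 if immediate else 1] += 1
            tables.append(tab)
    return _sum_component(tables, "test2_ct")


def overall_gof(dataset: StudyDataset, population_id: str | None = None) -> dict[str, GofResult]:
    """Both components plus their sum for one population (or pooled)."""
    r3 = test3_sr(dataset, population_id)
    r2 = test2_ct(dataset, population_id)
    stat = (r3.statistic if r3.testable else 0.0) + (r2.statistic if r2.testable else 0.0)
    df = (r3.df if r3.testable else 0) + (r2.df if r2.testable else 0)
    overall = GofResult(
        component="overall", statistic=stat, df=max(df, 0),
        p_value=float(stats.chi2.sf(stat, df)) if df > 0 else 1.0,
        tables=[], testable=df > 0)
    return {"test3_sr": r3, "test2_ct": r2, "overall": overall}
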