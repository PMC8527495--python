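"""Per-stripe two-genotype comparison statistics.

For each stripe the pipeline compares the per-embryo integrations (or
widths, or centroid positions) of a mutant genotype against wild type:

* group summaries: n, mean, sample SD (n−1 denominator);
* percent-of-wild-type, defined as the ratio of group means,
  ``pct = 100 · mean_mut / mean_wt``, with its SD from first-order error
  propagation of the ratio,
  ``pct_sd = pct · sqrt((sd_mut/mean_mut)² + (sd_wt/mean_wt)²)``;
* a two-sided Welch (unequal-variance) t-test with Welch–Satterthwaite
  degrees of freedom;
* Holm step-down adjustment of the raw p-values across the seven stripe
  tests, controlling family-wise error.

Welch and Holm are inferences about the published analysis: recomputing the
printed table from its own group summaries reproduces every raw and
adjusted p-value with these choices (a pooled-variance t-test and
Benjamini–Hochberg do not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD of one (stripe, genotype) group."""

    stripe: int
    genotype: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise StatsError(f"stripe {self.stripe} {self.genotype}: n < 2, SD undefined")
        if self.sd < 0:
            raise StatsError("sd must be nonnegative")


@dataclass(frozen=True)
class ComparisonRow:
    """One stripe's two-genotype comparison (one printed table row)."""

    stripe: int
    wt: GroupSummary
    mut: GroupSummary
    pct: float
    pct_sd: float
    t: float
    df: float
    p_raw: float
    p_adj: float


def summarize_groups(
    table: pd.DataFrame, value_col: str = "integration"
) -> list[GroupSummary]:
    """Per-(stripe, genotype) n/mean/sample-SD summaries of a tidy
    per-embryo table with columns ``embryo_id, genotype, stripe`` and
    ``value_col``."""
    out = []
    for (stripe, genotype), grp in table.groupby(["stripe", "genotype"], sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise StatsError(
                f"stripe {stripe} {genotype}: need >= 2 embryos, got {len(vals)}"
            )
        out.append(
            GroupSummary(
                stripe=int(stripe),
                genotype=str(genotype),
                n=len(vals),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)),
            )
        )
    return out


def percent_of_wildtype(wt: GroupSummary, mut: GroupSummary) -> tuple[float, float]:
    """Ratio of group means as a percentage, with first-order propagated SD.

    Written in a form finite at ``mut.mean == 0``, where the propagated SD
    reduces to ``100 · sd_mut / mean_wt``.
    """
    if wt.mean <= 0:
        raise StatsError("wild-type mean must be positive for a percentage")
    pct = 100.0 * mut.mean / wt.mean
    pct_sd = (100.0 / wt.mean) * np.hypot(mut.sd, mut.mean * wt.sd / wt.mean)
    return float(pct), float(pct_sd)


def welch_t_test(wt: GroupSummary, mut: GroupSummary) -> tuple[float, float, float]:
    """Two-sided Welch t-test from group summaries.

    Returns ``(t, df, p_raw)`` with Welch–Satterthwaite degrees of freedom.
    Both SDs zero: equal means give ``p = 1`` by convention, unequal means
    are degenerate and raise.
    """
    v_wt = wt.sd**2 / wt.n
    v_mut = mut.sd**2 / mut.n
    if v_wt + v_mut == 0:
        if wt.mean == mut.mean:
            return 0.0, float(wt.n + mut.n - 2), 1.0
        raise StatsError("degenerate variance: both SDs zero with unequal means")
    se = np.sqrt(v_wt + v_mut)
    t = (wt.mean - mut.mean) / se
    df = (v_wt + v_mut) ** 2 / (
        v_wt**2 / (wt.n - 1) + v_mut**2 / (mut.n - 1)
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def holm_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    With the raw p-values sorted ascending, the i-th adjusted value is the
    running maximum of ``min(1, (m − j + 1) · p_(j))`` for ``j ≤ i``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or ((p < 0) | (p > 1)).any():
        raise StatsError("p-values must be a 1D vector in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def build_comparison_table(
    table: pd.DataFrame,
    wt_genotype: str,
    mut_genotype: str,
    value_col: str = "integration",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stripe comparison of two genotypes from a per-embryo table.

    Returns a frame with columns ``stripe, wt_n, wt_mean, wt_sd, mut_n,
    mut_mean, mut_sd, pct, pct_sd, t, df, p_raw, p_adj, significant`` —
    the shape of the published quantification table.  Holm adjustment is
    applied across exactly the stripes present (seven for a full pattern);
    significance is called at ``p_adj < alpha``.
    """
    summaries = summarize_groups(table, value_col=value_col)
    by_key = {(s.stripe, s.genotype): s for s in summaries}
    stripes = sorted({s.stripe for s in summaries})
    rows = []
    for stripe in stripes:
        wt = by_key.get((stripe, wt_genotype))
        mut = by_key.get((stripe, mut_genotype))
        if wt is None or mut is None:
            missing = wt_genotype if wt is None else mut_genotype
            raise StatsError(f"stripe {stripe}: genotype {missing!r} missing")
        pct, pct_sd = percent_of_wildtype(wt, mut)
        t, df, p_raw = welch_t_test(wt, mut)
        rows.append(
            {
                "stripe": stripe,
                "wt_n": wt.n,
                "wt_mean": wt.mean,
                "wt_sd": wt.sd,
                "mut_n": mut.n,
                "mut_mean": mut.mean,
                "mut_sd": mut.sd,
                "pct": pct,
                "pct_sd": pct_sd,
                "t": t,
                "df": df,
                "p_raw": p_raw,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def compare_summaries(
    summaries: pd.DataFrame,
    wt_genotype: str,
    mut_genotype: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Comparison table straight from group summaries (columns ``stripe,
    genotype, n, mean, sd``) — for recomputing a published table without
    per-embryo data."""
    by_key = {
        (int(r.stripe), str(r.genotype)): GroupSummary(
            stripe=int(r.stripe), genotype=str(r.genotype),
            n=int(r.n), mean=float(r.mean), sd=float(r.sd),
        )
        for r in summaries.itertuples()
    }
    stripes = sorted({k[0] for k in by_key})
    rows = []
    for stripe in stripes:
        wt = by_key.get((stripe, wt_genotype))
        mut = by_key.get((stripe, mut_genotype))
        if wt is None or mut is None:
            missing = wt_genotype if wt is None else mut_genotype
            raise StatsError(f"stripe {stripe}: genotype {missing!r} missing")
        pct, pct_sd = percent_of_wildtype(wt, mut)
        t, df, p_raw = welch_t_test(wt, mut)
        rows.append(
            {
                "stripe": stripe,
                "wt_n": wt.n, "wt_mean": wt.mean, "wt_sd": wt.sd,
                "mut_n": mut.n, "mut_mean": mut.mean, "mut_sd": mut.sd,
                "pct": pct, "pct_sd": pct_sd, "t": t, "df": df, "p_raw": p_raw,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def compare_widths_and_centers(
    table: pd.DataFrame,
    wt_genotype: str,
    mut_genotype: str,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run the same comparison machinery on stripe widths and centroid
    positions (%EL).  Returns ``{"width": ..., "centroid": ...}``."""
    return {
        "width": build_comparison_table(
            table, wt_genotype, mut_genotype, value_col="width_pct_el", alpha=alpha
        ),
        "centroid": build_comparison_table(
            table, wt_genotype, mut_genotype, value_col="centroid_pct_el", alpha=alpha
        ),
    }
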