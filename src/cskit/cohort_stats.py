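"""Cohort-level contingency statistics: enrichment, co-occurrence, FDR.

Operations on a samples-by-flags cohort table: 2x2 cross-tabulation with
explicit missing-data accounting, odds ratios with Woolf (log-scale) 95%
confidence intervals and Haldane-Anscombe +0.5 correction for zero cells,
Fisher's exact test, Benjamini-Hochberg FDR, pairwise gene co-occurrence /
mutual-exclusivity matrices, and per-exposure enrichment scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clonality import VariantRecord

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "PairwiseMatrix",
    "build_contingency",
    "odds_ratio_woolf",
    "fisher_exact",
    "bh_fdr",
    "cooccurrence_matrix",
    "exposure_enrichment",
    "mutation_frequency",
]

#: z for a 95% two-sided normal interval, fixed rather than recomputed.
Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts with fixed orientation.

    a = factor+/outcome+, b = factor-/outcome+,
    c = factor+/outcome-, d = factor-/outcome-.
    """

    a: int
    b: int
    c: int
    d: int
    labels: tuple[str, str] = ("factor", "outcome")
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be >= 0")
        if self.total == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class AssociationResult:
    """Odds ratio with Woolf CI, exact and asymptotic p, optional FDR q."""

    factor: str
    table: ContingencyTable2x2
    odds_ratio: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    p_exact: float
    p_asymptotic: float
    corrected: bool
    q: float | None = None
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable and not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("ci_low <= odds_ratio <= ci_high violated")


@dataclass
class PairwiseMatrix:
    """Symmetric log-OR / p / q matrices over a list of lesions.

    Positive log-OR = co-occurrence, negative = mutual exclusivity; the
    diagonal is NaN-masked.
    """

    items: list[str]
    log_or: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    corrected: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def _binary_series(table: pd.DataFrame, column: str) -> pd.Series:
    if column not in table.columns:
        raise ValueError(f"column {column!r} not in table")
    col = table[column]
    values = set(col.dropna().unique().tolist())
    if not values <= {0, 1, True, False}:
        bad = sorted(values - {0, 1, True, False}, key=str)
        raise ValueError(f"column {column!r} is not binary; offending values: {bad}")
    return col


def build_contingency(
    cohort: pd.DataFrame, factor: str, outcome: str
) -> ContingencyTable2x2:
    """Cross-tabulate two binary columns; rows missing either are excluded.

    The exclusion count is carried on the returned table (clinical cohorts
    routinely have incomplete chart data, and downstream reports surface it).
    """
    f = _binary_series(cohort, factor)
    o = _binary_series(cohort, outcome)
    mask = f.notna() & o.notna()
    fb = f[mask].astype(bool)
    ob = o[mask].astype(bool)
    return ContingencyTable2x2(
        a=int((fb & ob).sum()),
        b=int((~fb & ob).sum()),
        c=int((fb & ~ob).sum()),
        d=int((~fb & ~ob).sum()),
        labels=(factor, outcome),
        n_excluded=int((~mask).sum()),
    )


def odds_ratio_woolf(
    t: ContingencyTable2x2, zero_correction: bool = True, factor: str | None = None
) -> AssociationResult:
    """OR = ad/bc with Woolf 95% CI exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).

    When any cell is zero and ``zero_correction`` is on, 0.5 is added to
    every cell (Haldane-Anscombe) and the result is flagged ``corrected``;
    with correction off a zero cell raises.  The exact p is always computed
    on the uncorrected counts.
    """
    cells = t.cells
    corrected = False
    if any(c == 0 for c in cells):
        if not zero_correction:
            raise ValueError(
                f"zero cell in table {cells}; enable zero_correction to proceed"
            )
        corrected = True
    a, b, c, d = (x + 0.5 for x in cells) if corrected else cells
    odds_ratio = (a * d) / (b * c)
    log_or = math.log(odds_ratio)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    p_asym = 2.0 * stats.norm.sf(abs(log_or) / se)
    return AssociationResult(
        factor=factor if factor is not None else t.labels[0],
        table=t,
        odds_ratio=odds_ratio,
        log_or=log_or,
        se_log_or=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_exact=fisher_exact(t),
        p_asymptotic=float(p_asym),
        corrected=corrected,
    )


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided exact p: sum of hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed one."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def bh_fdr(p: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Step-up adjusted values q(i) = min_{j>=i} p(j) * m / j, input order kept.

    ``method`` is 'fdr_bh' (Benjamini-Hochberg, default) or 'fdr_by'
    (Benjamini-Yekutieli) for dependence-robust adjustment.
    """
    p = list(p)
    if not p:
        return []
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("all p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "fdr_by"):
        raise ValueError(f"method must be 'fdr_bh' or 'fdr_by', got {method!r}")
    return multipletests(arr, method=method)[1].tolist()


def mutation_frequency(
    cohort: pd.DataFrame, gene: str, by: str | None = None
) -> dict[str, tuple[int, int, float]]:
    """Mutation frequency of one gene: overall and optionally per group.

    Returns {label: (n_mutated, n_samples, fraction)} with an 'overall' key.
    """
    flags = _binary_series(cohort, gene)
    valid = flags.dropna().astype(bool)
    out = {"overall": (int(valid.sum()), int(valid.size), float(valid.mean()))}
    if by is not None:
        if by not in cohort.columns:
            raise ValueError(f"column {by!r} not in table")
        for label, grp in valid.groupby(cohort.loc[valid.index, by]):
            out[str(label)] = (int(grp.sum()), int(grp.size), float(grp.mean()))
    return out


def cooccurrence_matrix(
    variants: Sequence[VariantRecord],
    cohort: pd.DataFrame,
    genes: Sequence[str],
    clonal_only_for: Mapping[str, float] | None = None,
    fdr_method: str = "fdr_bh",
) -> PairwiseMatrix:
    """Pairwise co-occurrence / mutual-exclusivity matrix across samples.

    For each unordered pair of lesions, builds the presence/absence 2x2
    (a = both present), computes the log odds ratio (+0.5 to all cells when
    any is zero, flagged), Fisher's exact p, and BH q over all pairs.
    ``clonal_only_for`` adds derived items like "PPM1D clonal": samples
    whose variant in that gene has VAF strictly above the given threshold.
    """
    missing = [g for g in genes if g not in cohort.columns]
    if missing:
        raise ValueError(f"genes absent from cohort table: {missing}")

    presence = pd.DataFrame(index=cohort.index)
    for g in genes:
        presence[g] = _binary_series(cohort, g).fillna(0).astype(bool)

    if clonal_only_for:
        sample_ids = cohort["sample_id"] if "sample_id" in cohort.columns else cohort.index
        for gene, threshold in clonal_only_for.items():
            hit = {
                rec.sample_id
                for rec in variants
                if rec.gene == gene and rec.vaf > threshold
            }
            presence[f"{gene} clonal"] = pd.Series(sample_ids).isin(hit).to_numpy()

    items = list(presence.columns)
    m = len(items)
    log_or = np.full((m, m), np.nan)
    pmat = np.full((m, m), np.nan)
    corr = np.full((m, m), False, dtype=object)
    pairs: list[tuple[int, int]] = []
    pvals: list[float] = []
    for i in range(m):
        for j in range(i + 1, m):
            x = presence[items[i]].to_numpy()
            y = presence[items[j]].to_numpy()
            table = ContingencyTable2x2(
                a=int((x & y).sum()),
                b=int((~x & y).sum()),
                c=int((x & ~y).sum()),
                d=int((~x & ~y).sum()),
                labels=(items[i], items[j]),
            )
            res = odds_ratio_woolf(table, zero_correction=True)
            log_or[i, j] = log_or[j, i] = res.log_or
            pmat[i, j] = pmat[j, i] = res.p_exact
            corr[i, j] = corr[j, i] = res.corrected
            pairs.append((i, j))
            pvals.append(res.p_exact)

    qvals = bh_fdr(pvals, method=fdr_method)
    qmat = np.full((m, m), np.nan)
    for (i, j), q in zip(pairs, qvals):
        qmat[i, j] = qmat[j, i] = q

    def frame(x: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(x, index=items, columns=items)

    return PairwiseMatrix(
        items=items, log_or=frame(log_or), p=frame(pmat), q=frame(qmat),
        corrected=frame(corr),
    )


def exposure_enrichment(
    cohort: pd.DataFrame,
    outcome_gene: str,
    exposures: Sequence[str],
    fdr_method: str = "fdr_bh",
) -> list[AssociationResult]:
    """Per-exposure 2x2 enrichment of a mutation, with family-wise BH FDR.

    Rows missing an exposure are dropped listwise for that agent (the
    per-agent exclusion count rides on the result's table).  Exposures with
    zero or full prevalence after exclusions are flagged non-estimable and
    excluded from the FDR family.  Results are sorted by (q, p).
    """
    if not exposures:
        raise ValueError("exposure list must be non-empty")
    results: list[AssociationResult] = []
    estimable: list[AssociationResult] = []
    for exp in exposures:
        table = build_contingency(cohort, factor=exp, outcome=outcome_gene)
        n_pos = table.a + table.c
        n_neg = table.b + table.d
        if n_pos == 0 or n_neg == 0:
            results.append(
                AssociationResult(
                    factor=exp, table=table, odds_ratio=math.nan, log_or=math.nan,
                    se_log_or=math.nan, ci_low=math.nan, ci_high=math.nan,
                    p_exact=math.nan, p_asymptotic=math.nan, corrected=False,
                    estimable=False,
                )
            )
            continue
        res = odds_ratio_woolf(table, zero_correction=True, factor=exp)
        results.append(res)
        estimable.append(res)

    for res, q in zip(estimable, bh_fdr([r.p_exact for r in estimable], method=fdr_method)):
        res.q = q

    def sort_key(r: AssociationResult) -> tuple:
        return (
            not r.estimable,
            r.q if r.q is not None else math.inf,
            r.p_exact if not math.isnan(r.p_exact) else math.inf,
        )

    return sorted(results, key=sort_key)
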