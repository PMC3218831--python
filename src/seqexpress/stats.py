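"""Count-based significance machinery for two-sample comparisons.

Gene-level changes are modelled by treating the second-sample count g2 of a
gene as Binomial(g, q2) with g = g1 + g2 and q2 = n2/(n1 + n2), where n1 and
n2 are *effective* per-sample read totals.  The effective totals are chosen
by the "minimize significant changes" (MSC) rule: q2 is the point of [0, 1]
covered by the most per-gene 95% confidence intervals for g2/g, which
approximately minimizes the number of genes called changed.  This is a
robust normalization — a handful of very highly expressed or truly changed
genes contributes only a few intervals and cannot move the vote.

Two-isoform RNA-processing events are tested on 2x2 contingency tables of
isoform-A vs isoform-B read counts in the two samples, with Fisher's exact
test (conservative in this regime) or, when all four expected values exceed
5, the chi-squared test with a capped continuity correction.

P-values are two-tailed, defined as the total probability of outcomes no
more likely than the observed one, and are not adjusted for multiple
testing unless Benjamini-Hochberg adjustment is requested explicitly.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

# Relative tolerance for "no more probable than observed" two-tailed sums,
# so ties in the pmf are included despite floating-point rounding.
_REL_TOL = 1 + 1e-7

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclasses.dataclass(frozen=True)
class NormalizationResult:
    q2: float
    N: int
    window_width: float
    winning_count: int

    @property
    def n2(self) -> float:
        return self.q2 * self.N

    @property
    def n1(self) -> float:
        return self.N - self.n2


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Chosen for its coverage at extreme proportions, where the MSC optimizer
    mostly operates.  ``trials = 0`` returns the uninformative [0, 1].
    """
    if trials == 0:
        return (0.0, 1.0)
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(
        successes, trials, alpha=1 - confidence, method="wilson"
    )
    return float(lo), float(hi)


def minimize_significant_changes(
    g1,
    g2,
    confidence: float = 0.95,
    window_width: float = 1e-4,
    total: int | None = None,
) -> NormalizationResult:
    """Estimate the effective second-sample read fraction q2 by window voting.

    For every gene with at least one read, the Wilson ``confidence`` interval
    of g2/(g1+g2) marks the q2 range in which that gene would not be called
    changed.  The unit interval is split into windows of ``window_width``;
    q2 is the midpoint of the window overlapped by the most intervals, or
    the mean of the tied windows' midpoints.  Genes with zero reads carry a
    [0, 1] interval that votes for every window equally and are excluded.
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    if g1.shape != g2.shape:
        raise ValueError("g1 and g2 must have equal length")
    if np.any(g1 < 0) or np.any(g2 < 0):
        raise ValueError("negative counts")
    g = g1 + g2
    keep = g >= 1
    if not np.any(keep):
        raise ValueError("no genes with reads; cannot estimate q2")
    lo, hi = proportion_confint(
        g2[keep], g[keep], alpha=1 - confidence, method="wilson"
    )
    n_win = int(round(1.0 / window_width))
    first = np.clip((lo / window_width).astype(np.int64), 0, n_win - 1)
    last = np.clip((hi / window_width).astype(np.int64), 0, n_win - 1)
    votes = np.zeros(n_win + 1, dtype=np.int64)
    np.add.at(votes, first, 1)
    np.add.at(votes, last + 1, -1)
    counts = np.cumsum(votes)[:n_win]
    best = int(counts.max())
    tied = np.flatnonzero(counts == best)
    q2 = float(np.mean((tied + 0.5) * window_width))
    N = int(total) if total is not None else int(g.sum())
    return NormalizationResult(
        q2=q2, N=N, window_width=window_width, winning_count=best
    )


def binomial_change_test(g1: int, g2: int, n1: float, n2: float) -> float:
    """Two-tailed binomial P-value for a change in a gene's read count.

    Models g2 as Binomial(g, q2) with g = g1 + g2 and q2 = n2/(n1 + n2);
    the P-value sums the probabilities of all outcomes no more probable
    than the observed g2.
    """
    if g1 < 0 or g2 < 0:
        raise ValueError("negative counts")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("effective totals must be positive")
    g = g1 + g2
    if g == 0:
        return 1.0
    q2 = n2 / (n1 + n2)
    pmf = sps.binom.pmf(np.arange(g + 1), g, q2)
    include = pmf <= pmf[g2] * _REL_TOL
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def fold_change(g1: float, g2: float, n1: float, n2: float) -> float:
    """(g2/n2) / (g1/n1); 0 or inf at zero counts, NaN when both are zero."""
    if g1 == 0 and g2 == 0:
        return float("nan")
    if g1 == 0:
        return float("inf")
    return (g2 / n2) / (g1 / n1)


def event_test(a1: int, b1: int, a2: int, b2: int) -> tuple[float, str]:
    """Two-by-two isoform contingency test.

    Uses the chi-squared test with a capped continuity correction
    ``min(0.5, |O - E|)`` when all four expected values exceed 5, and
    Fisher's exact test (two-sided, minimum-likelihood convention)
    otherwise.
    """
    table = np.array([[a1, b1], [a2, b2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative counts")
    total = table.sum()
    if total == 0:
        return 1.0, "fisher"
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.all(expected > 5):
        dev = np.abs(table - expected)
        dev = dev - np.minimum(0.5, dev)
        stat = float((dev**2 / expected).sum())
        return float(sps.chi2.sf(stat, df=1)), "chisq"
    p = float(sps.fisher_exact(table.astype(int), alternative="two-sided")[1])
    return min(p, 1.0), "fisher"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_change(p: float, fold: float, p_cutoff: float, fold_cutoff: float) -> str:
    """Significance call from a P-value and fold change.

    ``up`` needs p <= p_cutoff and fold >= fold_cutoff; ``down`` needs
    p <= p_cutoff and fold <= 1/fold_cutoff.  Infinite and zero folds
    participate; NaN folds are never called.
    """
    if fold_cutoff < 1:
        raise ValueError("fold_cutoff must be >= 1")
    if math.isnan(fold) or p > p_cutoff:
        return UNCHANGED
    if fold >= fold_cutoff:
        return UP
    if fold <= 1.0 / fold_cutoff:
        return DOWN
    return UNCHANGED


def expected_false_positives(n_tests: int, p_cutoff: float) -> float:
    """Upper bound on expected false positives under the global null."""
    if n_tests < 1 or not 0 < p_cutoff <= 1:
        raise ValueError("invalid arguments")
    return n_tests * p_cutoff


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def gene_tests(
    g1,
    g2,
    norm: NormalizationResult | None = None,
    p_cutoff: float = 1e-4,
    fold_cutoff: float = 2.0,
    bh: bool = False,
) -> pd.DataFrame:
    """Binomial change tests for all genes of a two-sample comparison.

    ``g1``/``g2`` are per-gene count Series sharing an index.  The effective
    totals come from ``norm`` (computed here by MSC when omitted).
    """
    g1 = pd.Series(g1).astype(int)
    g2 = pd.Series(g2).astype(int)
    if norm is None:
        norm = minimize_significant_changes(g1.to_numpy(), g2.to_numpy())
    n1, n2 = norm.n1, norm.n2
    p = np.array(
        [binomial_change_test(int(a), int(b), n1, n2) for a, b in zip(g1, g2)]
    )
    fold = np.array(
        [fold_change(int(a), int(b), n1, n2) for a, b in zip(g1, g2)]
    )
    out = pd.DataFrame(
        {"g1": g1, "g2": g2, "fold_change": fold, "p": p}, index=g1.index
    )
    if bh:
        out["p_bh"] = bh_adjust(p)
    p_for_call = out["p_bh"] if bh else out["p"]
    out["call"] = [
        call_change(pv, fc, p_cutoff, fold_cutoff)
        for pv, fc in zip(p_for_call, fold)
    ]
    return out


def _ratio(a: float, b: float) -> float:
    if a == 0 and b == 0:
        return float("nan")
    if b == 0:
        return float("inf")
    return a / b


def event_tests(
    event_counts: pd.DataFrame,
    sample1: str,
    sample2: str,
    p_cutoff: float = 1e-4,
    fold_cutoff: float = 2.0,
    bh: bool = False,
) -> pd.DataFrame:
    """Contingency tests for all events between two samples (or groups).

    ``event_counts`` columns follow ``<sample>_a`` / ``<sample>_b``; the
    ratio change is (a2/b2)/(a1/b1), with explicit infinities where a side
    has zero reads.
    """
    a1 = event_counts[f"{sample1}_a"].astype(int)
    b1 = event_counts[f"{sample1}_b"].astype(int)
    a2 = event_counts[f"{sample2}_a"].astype(int)
    b2 = event_counts[f"{sample2}_b"].astype(int)
    res = [event_test(w, x, y, z) for w, x, y, z in zip(a1, b1, a2, b2)]
    p = np.array([r[0] for r in res])
    method = [r[1] for r in res]
    ratio1 = np.array([_ratio(x, y) for x, y in zip(a1, b1)])
    ratio2 = np.array([_ratio(x, y) for x, y in zip(a2, b2)])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_change = np.array(
            [_ratio(r2, r1) if not (math.isnan(r1) or math.isnan(r2))
             else float("nan")
             for r1, r2 in zip(ratio1, ratio2)]
        )
    out = pd.DataFrame(
        {
            "a1": a1, "b1": b1, "a2": a2, "b2": b2,
            "ratio1": ratio1, "ratio2": ratio2, "ratio_change": ratio_change,
            "p": p, "method": method,
        },
        index=event_counts.index,
    )
    if bh:
        out["p_bh"] = bh_adjust(p)
    p_for_call = out["p_bh"] if bh else out["p"]
    out["call"] = [
        call_change(pv, rc, p_cutoff, fold_cutoff)
        for pv, rc in zip(p_for_call, ratio_change)
    ]
    return out


# ---------------------------------------------------------------------------
# QC and set utilities
# ---------------------------------------------------------------------------

def correlation_matrix(rpkm: pd.DataFrame):
    """Pairwise Pearson correlation of log2(RPKM + 1) expression profiles.

    Returns ``(corr, order)`` where ``order`` is the sample ordering from
    average-linkage clustering on distance 1 - r.  Zero-variance samples
    yield missing correlations and are appended at the end of the order.
    """
    if rpkm.shape[1] < 2 or rpkm.shape[0] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    logged = np.log2(rpkm.astype(float) + 1.0)
    corr = logged.corr(method="pearson")
    ok = logged.std(axis=0) > 0
    order = list(corr.columns[~ok])
    good = corr.loc[ok, ok]
    if ok.sum() >= 2:
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        dist = 1.0 - good.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        leaves = hierarchy.leaves_list(link)
        order = [good.columns[i] for i in leaves] + order
    else:
        order = list(corr.columns)
    return corr, order


def background_set(
    candidates: dict[str, float], targets: dict[str, float]
) -> list[str]:
    """Expression-matched background: one unchanged gene per changed gene.

    Greedy pass over targets in descending count order; each target takes
    the unused candidate minimizing |log((c+1)/(t+1))|.  Ties break to the
    lexicographically smaller gene id.  Counts may be raw read numbers
    (recommended, to avoid transcript-length bias) or RPKM.
    """
    if len(candidates) < len(targets):
        raise ValueError("candidate pool smaller than target set")
    pool = sorted(candidates.items())
    chosen: list[str] = []
    for tid, tcount in sorted(targets.items(), key=lambda kv: (-kv[1], kv[0])):
        best_i = min(
            range(len(pool)),
            key=lambda i: (abs(math.log((pool[i][1] + 1) / (tcount + 1))),
                           pool[i][0]),
        )
        chosen.append(pool.pop(best_i)[0])
    return chosen


def summarize_probes(
    intensities: pd.DataFrame, probe_to_gene: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Median-of-detected-probes gene levels for microarray data.

    Detected probes have positive background-subtracted intensity in every
    array; each gene's level per array is the median over its detected
    probes.  Genes without any detected probe are absent from the result.
    """
    mapping = pd.Series(probe_to_gene)
    detected = intensities.loc[(intensities > 0).all(axis=1)]
    detected = detected.loc[detected.index.intersection(mapping.index)]
    if detected.empty:
        return pd.DataFrame(columns=intensities.columns)
    genes = mapping.loc[detected.index]
    return detected.groupby(genes.to_numpy()).median()


def two_sample_t(group1, group2) -> float:
    """Two-sided Welch t-test P-value for log-level vectors."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
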