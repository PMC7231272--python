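"""TFBS enrichment statistics for promoter sets.

For each matrix and each target gene set the module computes, against a
reference promoter set:

* a one-sided Fisher exact test on the number of promoters carrying at least
  one site,
* a one-sided binomial test on the collapsed site frequency (sites per bp,
  reference rate as the null),
* the *adjusted fold enrichment* (AFE): the lower bound of the 99% confidence
  interval of the odds ratio, computed on the log scale with
  Haldane-Anscombe +0.5 cells, maximised over the grid of score thresholds
  whose reference site frequency stays under a cap (default 1 per 2000 bp),
* Benjamini-Hochberg FDR over the binomial p-values within each gene set.

A matrix is called significantly enriched when AFE > 1 and FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._scan import top_scores_pair
from .motifs import DEFAULT_SITE_FREQUENCY_CAP, PWM, _collapsed_count, batch_window_scores
from .promoters import PromoterSet

@dataclass(frozen=True)
class EnrichmentResult:
    """Per (matrix, gene set) enrichment record at the AFE-maximising threshold."""

    matrix_id: str
    cluster_id: str
    threshold: float
    a: int              # target promoters with >=1 site
    b: int              # target promoters without a site
    c: int              # reference promoters with >=1 site
    d: int              # reference promoters without a site
    sites_per_kb_target: float
    sites_per_kb_reference: float
    fisher_p: float
    fisher_odds_ratio: float
    binom_p: float
    afe: float
    fdr: float = float("nan")
    significant: bool = False
    cap_unreachable: bool = False


def _validate_counts(*counts) -> None:
    for x in counts:
        if np.any(np.asarray(x) < 0):
            raise ValueError("negative count in 2x2 table")


def fisher_promoter_test(a, b, c, d):
    """One-sided (enrichment) Fisher exact test on a 2x2 promoter-count table.

    Rows are target/reference sets, columns promoters with/without a site.
    Returns ``(p, odds_ratio)``; the odds ratio uses the Haldane-Anscombe
    +0.5 correction when any cell is zero.  Accepts scalars or arrays.
    """
    _validate_counts(a, b, c, d)
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    p = stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        plain = (a * d) / (b * c)
    corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    odds = np.where(zero, corrected, plain)
    if np.ndim(p) == 0:
        return float(p), float(odds)
    return p, odds


def binomial_site_test(s_t: int, b_t: int, s_r: int, b_r: int) -> float:
    """One-sided binomial test of the target site count against the reference rate.

    The null per-bp rate is ``s_r / b_r``, floored at ``1 / (2 * b_r)`` when
    the reference set has no sites; the p-value is ``P(X >= s_t)`` for
    ``X ~ Binomial(b_t, rate)``.
    """
    if b_t <= 0 or b_r <= 0:
        raise ValueError("base-pair totals must be positive")
    _validate_counts(s_t, s_r)
    rate = s_r / b_r if s_r > 0 else 1.0 / (2.0 * b_r)
    return float(stats.binom.sf(s_t - 1, b_t, rate))


def adjusted_fold_enrichment(a, b, c, d, confidence: float = 0.99):
    """Confidence-adjusted odds ratio: lower bound of the CI on the log-odds scale.

    All four cells receive the Haldane-Anscombe +0.5 correction; the returned
    value is ``exp(ln OR+ - z * SE)`` with ``SE = sqrt(sum 1/(cell+0.5))`` and
    ``z`` the two-sided normal quantile for ``confidence``.  Accepts arrays.
    """
    _validate_counts(a, b, c, d)
    a, b, c, d = (np.asarray(x, dtype=np.float64) + 0.5 for x in (a, b, c, d))
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    afe = np.exp(log_or - z * se)
    return float(afe) if np.ndim(afe) == 0 else afe


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class ScanProfile:
    """Cached window scores of one matrix over one promoter set."""

    plus: np.ndarray
    minus: np.ndarray
    per_promoter_max: np.ndarray
    total_bp: int
    score_bounds: tuple[float, float] = (float("-inf"), float("inf"))

    @classmethod
    def build(cls, sequences: Sequence[str] | PromoterSet, pwm: PWM) -> "ScanProfile":
        if isinstance(sequences, PromoterSet):
            pset = sequences
            plus, minus, _ = batch_window_scores(pset.sequences, pwm, encoded=pset.encoded())
            total = pset.total_bp
        else:
            plus, minus, _ = batch_window_scores(sequences, pwm)
            total = sum(len(s) for s in sequences)
        if plus.shape[1] == 0:
            best = np.full(plus.shape[0], -np.inf)
        else:
            best = np.maximum(plus.max(axis=1), minus.max(axis=1))
        return cls(plus, minus, best, total, (pwm.min_score, pwm.max_score))


def _threshold_grid(profile: ScanProfile, cap: float) -> tuple[np.ndarray, bool]:
    """Descending unique reference window scores whose raw hit count obeys the cap."""
    if not np.isfinite(cap):
        top, _ = top_scores_pair(profile.plus, profile.minus, profile.plus.size * 3,
                                 *profile.score_bounds)
        return np.unique(top)[::-1], False
    cap_count = int(np.floor(cap * profile.total_bp))
    if cap_count < 1:
        return np.empty(0), True
    top, finite_n = top_scores_pair(profile.plus, profile.minus, cap_count,
                                    *profile.score_bounds)
    if top.size == 0:
        return np.empty(0), True
    if finite_n <= cap_count:
        return np.unique(top)[::-1], False
    bound = top[cap_count]
    admissible = top[:cap_count][top[:cap_count] > bound]
    if admissible.size == 0:
        return np.empty(0), True
    return np.unique(admissible)[::-1], False


def sweep_max_afe(pwm: PWM, targets: PromoterSet | Sequence[str],
                  references: PromoterSet | Sequence[str],
                  cap: float = DEFAULT_SITE_FREQUENCY_CAP,
                  *, cluster_id: str = "",
                  target_profile: ScanProfile | None = None,
                  reference_profile: ScanProfile | None = None) -> EnrichmentResult:
    """Maximise adjusted fold enrichment over admissible score thresholds.

    Candidate thresholds are the descending unique window scores observed on
    the reference set, restricted to those whose raw reference hit frequency
    does not exceed ``cap``; ties in AFE resolve to the stricter (higher)
    threshold.  The Fisher and binomial tests are evaluated at the argmax.
    If no threshold satisfies the cap, the matrix's maximum attainable score
    is used and the result flagged ``cap_unreachable``.
    """
    if len(targets) == 0 or len(references) == 0:
        raise ValueError("promoter sets must be non-empty")
    tp = target_profile or ScanProfile.build(targets, pwm)
    rp = reference_profile or ScanProfile.build(references, pwm)
    n_t = len(targets.sequences if isinstance(targets, PromoterSet) else targets)
    n_r = len(references.sequences if isinstance(references, PromoterSet) else references)
    grid, cap_unreachable = _threshold_grid(rp, cap)
    if cap_unreachable or grid.size == 0:
        grid = np.array([pwm.max_score])
        cap_unreachable = True
    tmax = np.sort(tp.per_promoter_max)
    rmax = np.sort(rp.per_promoter_max)
    a = n_t - np.searchsorted(tmax, grid, side="left")
    c = n_r - np.searchsorted(rmax, grid, side="left")
    afe = adjusted_fold_enrichment(a, n_t - a, c, n_r - c)
    afe = np.atleast_1d(afe)
    best = int(np.argmax(afe))  # grid is descending: first max = strictest threshold
    thr = float(grid[best])
    a_b, c_b = int(a[best]), int(c[best])
    fisher_p, fisher_or = fisher_promoter_test(a_b, n_t - a_b, c_b, n_r - c_b)
    s_t = _collapsed_count(tp.plus, tp.minus, thr, len(pwm))
    s_r = _collapsed_count(rp.plus, rp.minus, thr, len(pwm))
    binom_p = binomial_site_test(s_t, tp.total_bp, s_r, rp.total_bp)
    return EnrichmentResult(
        matrix_id=pwm.matrix_id, cluster_id=cluster_id, threshold=thr,
        a=a_b, b=n_t - a_b, c=c_b, d=n_r - c_b,
        sites_per_kb_target=1000.0 * s_t / tp.total_bp,
        sites_per_kb_reference=1000.0 * s_r / rp.total_bp,
        fisher_p=fisher_p, fisher_odds_ratio=fisher_or,
        binom_p=binom_p, afe=float(afe[best]), cap_unreachable=cap_unreachable,
    )


def enrich_report(clusters: Mapping[str, Sequence[str]], matrices: Sequence[PWM],
                  promoters: PromoterSet, references: PromoterSet,
                  cap: float = DEFAULT_SITE_FREQUENCY_CAP) -> pd.DataFrame:
    """One enrichment row per (matrix, cluster), FDR-adjusted per cluster.

    ``clusters`` maps cluster names to gene-id lists; every cluster gene must
    have a promoter in ``promoters``.  The FDR family is all matrices within
    one cluster, and a row is significant when AFE > 1 and FDR < 0.05.
    """
    cluster_sets = {name: promoters.subset(list(genes))
                    for name, genes in clusters.items()}
    results: list[EnrichmentResult] = []
    for pwm in matrices:
        ref_profile = ScanProfile.build(references, pwm)
        for name, pset in cluster_sets.items():
            results.append(sweep_max_afe(
                pwm, pset, references, cap, cluster_id=name,
                reference_profile=ref_profile))
    if results:
        by_cluster: dict[str, list[int]] = {}
        for i, r in enumerate(results):
            by_cluster.setdefault(r.cluster_id, []).append(i)
        for idxs in by_cluster.values():
            fdrs = bh_fdr([results[i].binom_p for i in idxs])
            for i, fdr in zip(idxs, fdrs):
                sig = bool(results[i].afe > 1.0 and fdr < 0.05)
                results[i] = replace(results[i], fdr=float(fdr), significant=sig)
    cols = ["matrix_id", "cluster_id", "threshold", "a", "b", "c", "d",
            "sites_per_kb_target", "sites_per_kb_reference", "fisher_p",
            "fisher_odds_ratio", "binom_p", "afe", "fdr", "significant",
            "cap_unreachable"]
    return pd.DataFrame([{k: getattr(r, k) for k in cols} for r in results], columns=cols)
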