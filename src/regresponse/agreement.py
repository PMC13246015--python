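"""Inter-reader agreement and survival-association statistics.

Implements the statistical toolbox of a multi-reader reliability study:

- generalized conformity index (GCI), the multi-rater generalization of
  Jaccard overlap for segmentations;
- Lin's concordance correlation coefficient (CCC) and its overall
  multi-rater form (OCCC), with the conventional poor/fair/moderate/strong
  interpretation bands;
- a Z-test for differences between CCCs, with subject-level bootstrap
  standard errors on the Fisher (atanh) scale;
- Fleiss' kappa for categorical response agreement;
- Harrell's concordance index for censored survival association;
- the Wilcoxon signed-rank test (exact null distribution up to n = 25).

Bootstrap confidence intervals resample subjects (not readers), which
respects the repeated-measures structure of reader studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .imaging import LabelMask, SurvivalRecord

__all__ = [
    "AgreementResult",
    "gci",
    "lin_ccc",
    "occc",
    "ccc_bands",
    "ccc_z_test",
    "fleiss_kappa",
    "harrell_c",
    "wilcoxon_signed_rank",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class AgreementResult:
    """A named agreement statistic with its bootstrap confidence interval."""

    statistic: str
    value: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_readers: int
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
            raise ValueError(
                f"{self.statistic}: value {self.value} outside CI [{self.ci_low}, {self.ci_high}]"
            )


# ---------------------------------------------------------------------------
# overlap agreement
# ---------------------------------------------------------------------------


def gci(masks: Sequence[LabelMask | np.ndarray]) -> float:
    """Generalized conformity index of two or more segmentations.

    ``sum_{i<j} |A_i ∩ A_j| / sum_{i<j} |A_i ∪ A_j|`` over voxel counts;
    equals the Jaccard index for two masks, 1 for perfect conformity and 0
    for pairwise-disjoint segmentations.
    """
    arrays = [m.voxels.astype(bool) if isinstance(m, LabelMask) else np.asarray(m, dtype=bool) for m in masks]
    if len(arrays) < 2:
        raise ValueError("GCI requires at least 2 masks")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all masks must share one grid")
    if not any(a.any() for a in arrays):
        raise ValueError("GCI undefined: all masks empty")
    inter = 0
    union = 0
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            inter += int(np.count_nonzero(arrays[i] & arrays[j]))
            union += int(np.count_nonzero(arrays[i] | arrays[j]))
    return inter / union


# ---------------------------------------------------------------------------
# concordance correlation
# ---------------------------------------------------------------------------


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``2 cov(x, y) / (var(x) + var(y) + (mean x − mean y)²)`` with 1/n
    normalization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    if len(x) < 2:
        raise ValueError("CCC requires n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero variance and equal means")
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / denom)


def occc(data: np.ndarray) -> float:
    """Overall CCC for J ≥ 2 readers (n_subjects × J matrix).

    ``2 Σ_{j<k} s_jk / [(J−1) Σ_j s_j² + Σ_{j<k} (m_j − m_k)²]`` with
    population (1/n) moments; reduces exactly to :func:`lin_ccc` for J = 2
    and equals a weighted average of the pairwise CCCs in general.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n_subjects x n_readers matrix")
    n, j = data.shape
    if j < 2 or n < 2:
        raise ValueError("OCCC requires >= 2 readers and >= 2 subjects")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing or non-finite cells in reader matrix")
    m = data.mean(axis=0)
    centered = data - m
    cov = centered.T @ centered / n  # J x J population covariance
    iu = np.triu_indices(j, k=1)
    sum_cov = cov[iu].sum()
    sum_var = np.diag(cov).sum()
    sum_msq = ((m[:, None] - m[None, :]) ** 2)[iu].sum()
    denom = (j - 1) * sum_var + sum_msq
    if denom == 0:
        raise ValueError("OCCC undefined: constant readings with equal means")
    return float(2.0 * sum_cov / denom)


def ccc_bands(value: float) -> str:
    """Interpretation band: <0.3 poor, [0.3,0.6) fair, [0.6,0.8) moderate, ≥0.8 strong."""
    if value < 0.3:
        return "poor"
    if value < 0.6:
        return "fair"
    if value < 0.8:
        return "moderate"
    return "strong"


def _atanh_clipped(v: float) -> float:
    return float(np.arctanh(np.clip(v, -1 + 1e-12, 1 - 1e-12)))


def _bootstrap_occc_z(data: np.ndarray, reps: int, rng: np.random.Generator) -> np.ndarray:
    n = data.shape[0]
    out = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            out[r] = _atanh_clipped(occc(data[idx]))
        except ValueError:
            out[r] = np.nan
    return out


def ccc_z_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    paired_subjects: bool = True,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Z-test for a difference between two (O)CCCs.

    Both CCCs are Fisher-transformed; standard errors come from a
    subject-level bootstrap.  With ``paired_subjects`` the two reader
    matrices must index the same subjects and the difference of
    transformed CCCs is bootstrapped jointly; otherwise the two groups are
    resampled independently.  Returns ``(z, two-sided p)``.
    """
    if reps < 100:
        raise ValueError("bootstrap reps must be >= 100")
    data_a = np.asarray(data_a, dtype=float)
    data_b = np.asarray(data_b, dtype=float)
    if min(data_a.shape[0], data_b.shape[0]) < 5:
        raise ValueError("Z-test requires at least 5 subjects per group")
    za = _atanh_clipped(occc(data_a))
    zb = _atanh_clipped(occc(data_b))
    rng = np.random.default_rng(seed)
    if paired_subjects:
        if data_a.shape[0] != data_b.shape[0]:
            raise ValueError("paired comparison requires equal subject counts")
        n = data_a.shape[0]
        diffs = np.empty(reps)
        for r in range(reps):
            idx = rng.integers(0, n, size=n)
            try:
                diffs[r] = _atanh_clipped(occc(data_a[idx])) - _atanh_clipped(occc(data_b[idx]))
            except ValueError:
                diffs[r] = np.nan
        se = float(np.nanstd(diffs, ddof=1))
    else:
        ba = _bootstrap_occc_z(data_a, reps, rng)
        bb = _bootstrap_occc_z(data_b, reps, rng)
        se = float(np.sqrt(np.nanvar(ba, ddof=1) + np.nanvar(bb, ddof=1)))
    if se == 0:
        z = 0.0
    else:
        z = (za - zb) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# categorical agreement
# ---------------------------------------------------------------------------


def _fleiss_point(counts: np.ndarray) -> float:
    """Fleiss' kappa from an n_subjects × n_categories count table."""
    n, _ = counts.shape
    j = counts.sum(axis=1)
    if not np.all(j == j[0]):
        raise ValueError("all subjects must be rated by the same number of readers")
    jj = int(j[0])
    p_c = counts.sum(axis=0) / (n * jj)
    p_bar = ((counts**2).sum(axis=1) - jj).sum() / (n * jj * (jj - 1))
    p_e = float((p_c**2).sum())
    if p_e >= 1.0:
        return np.nan  # degenerate: a single category everywhere
    return float((p_bar - p_e) / (1.0 - p_e))


def fleiss_kappa(
    ratings: np.ndarray,
    categories: Sequence[str] | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> AgreementResult:
    """Fleiss' kappa for an n_subjects × J matrix of categorical labels.

    Chance-corrected multi-rater agreement; the CI is a subject-level
    percentile bootstrap.  If every rating in the table is one single
    category, chance agreement is 1 and kappa is undefined: a
    perfect-agreement sentinel (value 1.0) is returned with
    ``metadata["degenerate"] = True``.
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an n_subjects x J matrix with J >= 2")
    n, j = ratings.shape
    cats = list(categories) if categories is not None else sorted({str(c) for c in ratings.ravel()})
    cat_index = {c: i for i, c in enumerate(cats)}
    try:
        codes = np.vectorize(lambda c: cat_index[str(c)])(ratings)
    except KeyError as e:
        raise ValueError(f"rating outside category set: {e}") from None
    counts = np.zeros((n, len(cats)), dtype=np.int64)
    for c in range(len(cats)):
        counts[:, c] = (codes == c).sum(axis=1)
    value = _fleiss_point(counts)
    if np.isnan(value):
        return AgreementResult(
            statistic="fleiss_kappa",
            value=1.0,
            ci_low=1.0,
            ci_high=1.0,
            n_subjects=n,
            n_readers=j,
            metadata={"degenerate": True, "note": "single category in every cell; kappa undefined"},
        )
    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        boots[r] = _fleiss_point(counts[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if len(boots) else (value, value))
    return AgreementResult(
        statistic="fleiss_kappa",
        value=value,
        ci_low=min(float(lo), value),
        ci_high=max(float(hi), value),
        n_subjects=n,
        n_readers=j,
        metadata={"bootstrap_reps": reps, "seed": seed, "categories": cats},
    )


# ---------------------------------------------------------------------------
# survival association
# ---------------------------------------------------------------------------


def harrell_c(scores: np.ndarray, survival: Sequence[SurvivalRecord] | tuple) -> float:
    """Harrell's concordance index; higher score ⇒ predicted shorter survival.

    Usable pairs: the subject with the shorter time had the event, or the
    times are tied with exactly one event (the event subject should score
    higher).  Concordant pairs count 1, score ties 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    if isinstance(survival, tuple) and len(survival) == 2:
        times = np.asarray(survival[0], dtype=float)
        events = np.asarray(survival[1], dtype=int)
    else:
        times = np.array([r.time for r in survival], dtype=float)
        events = np.array([r.event for r in survival], dtype=int)
    if len(scores) != len(times):
        raise ValueError("scores and survival records must align")
    # orient each usable pair so the row index is the "short" (event) member
    t_i, t_j = times[:, None], times[None, :]
    e_i, e_j = events[:, None], events[None, :]
    short = ((t_i < t_j) & (e_i == 1)) | ((t_i == t_j) & (e_i == 1) & (e_j == 0))
    usable = int(short.sum())
    if usable == 0:
        raise ValueError("no usable pairs for concordance")
    conc = scores[:, None] > scores[None, :]
    tied = scores[:, None] == scores[None, :]
    num = float((short & conc).sum()) + 0.5 * float((short & tied).sum())
    return num / usable


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments of the (tie-averaged) ranks.

    Ranks are half-integers at worst, so doubling gives an integer
    convolution; the distribution is built by dynamic programming.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    mean = total / 2
    lo_tail = dist[: w2 + 1].sum()
    hi_tail = dist[w2:].sum()
    p = 2.0 * min(lo_tail, hi_tail)
    if w2 == mean:
        p = 1.0
    return float(min(p, 1.0))


def wilcoxon_signed_rank(differences: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The exact null distribution is used for n ≤ 25, otherwise a
    normal approximation with tie correction.  All-zero differences are
    degenerate and raise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return _signed_rank_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# generic bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Subject-level percentile bootstrap CI for ``statistic(data)``.

    ``data`` is resampled along its first axis.  Replicates on which the
    statistic is undefined are dropped.
    """
    data = np.asarray(data)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(statistic(data[idx]))
        except ValueError:
            continue
    if not vals:
        raise ValueError("statistic undefined on every bootstrap replicate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
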