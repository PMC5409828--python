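"""Statistical layer: normality-gated two-sample tests and two-way
repeated-measures ANOVA with the Huynh–Feldt sphericity correction.

The two-sample path is normality-gated: an Anderson–Darling test on each
sample first; if
either rejects, a Wilcoxon rank-sum test is used, otherwise a t test (paired
when the samples are paired).  The rmANOVA is a standard fully-within
two-factor decomposition (subjects × factor A × factor B); each effect's F
test is corrected by the Huynh–Feldt epsilon estimated from the covariance
of the within-subject contrast scores, truncated at 1.

Post-hoc note: per-frequency pairwise comparisons with Holm correction are
offered as a convenience (`pairwise_holm`); they are a substitute for, not a
reimplementation of, Tukey HSD post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "TwoSampleResult",
    "RmAnovaResult",
    "compare_two_samples",
    "rm_anova_hf",
    "pairwise_holm",
]


@dataclass
class TwoSampleResult:
    test_used: str  # "rank_sum" or "paired_t" / "t"
    statistic: float
    p: float
    normality_rejected: tuple[bool, bool]
    note: str = ""


@dataclass
class RmAnovaResult:
    effect: str
    F: float
    df: tuple[float, float]  # raw (numerator, denominator)
    epsilon_hf: float  # untruncated HF epsilon estimate
    p_uncorrected: float
    p_corrected: float

    @property
    def epsilon_used(self) -> float:
        return min(self.epsilon_hf, 1.0)

    @property
    def df_corrected(self) -> tuple[float, float]:
        e = self.epsilon_used
        return (self.df[0] * e, self.df[1] * e)


def _anderson_rejects(x: np.ndarray, alpha: float) -> bool:
    """Anderson–Darling normality rejection at the given significance level."""
    res = sstats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float) / 100.0
    i = int(np.argmin(np.abs(levels - alpha)))
    return bool(res.statistic > res.critical_values[i])


def compare_two_samples(
    x, y, paired: bool = False, alpha_normality: float = 0.05
) -> TwoSampleResult:
    """Normality-gated two-sample comparison.

    Anderson–Darling on each sample; if either rejects normality the Wilcoxon
    rank-sum test is used (note: rank-sum treats the samples as independent
    even when ``paired`` — the pairing mismatch is flagged in ``note`` rather
    than silently resolved).  Otherwise a paired or two-sample t test.
    Two identical zero-variance samples return p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or y.size < 4:
        raise ValueError("need at least 4 observations per sample")
    if paired and x.size != y.size:
        raise ValueError("paired comparison requires equal-length samples")

    degenerate = (np.std(x) == 0 and np.std(y) == 0 and x.size == y.size
                  and np.allclose(x, y))
    if paired and x.size == y.size and np.allclose(x, y):
        degenerate = True  # all paired differences zero: t = 0/0
    if degenerate:
        return TwoSampleResult(
            test_used="paired_t" if paired else "t",
            statistic=0.0,
            p=1.0,
            normality_rejected=(False, False),
            note="degenerate: identical samples",
        )

    rej = (_anderson_rejects(x, alpha_normality), _anderson_rejects(y, alpha_normality))
    if any(rej):
        stat, p = sstats.ranksums(x, y)
        note = "rank-sum applied to paired data" if paired else ""
        return TwoSampleResult("rank_sum", float(stat), float(p), rej, note)
    if paired:
        stat, p = sstats.ttest_rel(x, y)
        return TwoSampleResult("paired_t", float(stat), float(p), rej)
    stat, p = sstats.ttest_ind(x, y)
    return TwoSampleResult("t", float(stat), float(p), rej)


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA with Huynh–Feldt correction
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _hf_epsilon(scores: np.ndarray) -> float:
    """Huynh–Feldt epsilon from subject × contrast score matrix.

    ``scores`` has one row per subject and one column per orthonormal
    contrast of the effect.  Returns the untruncated HF estimate (may
    exceed 1; the caller truncates for the correction).
    """
    n, k1 = scores.shape  # k1 = (levels - 1) effective contrasts
    if k1 == 1:
        return 1.0  # single contrast: sphericity holds trivially
    s = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    gg = tr * tr / (k1 * tr2)
    hf = (n * k1 * gg - 2.0) / (k1 * (n - 1.0 - k1 * gg))
    return float(hf)


def rm_anova_hf(data: np.ndarray) -> dict[str, RmAnovaResult]:
    """Two-way fully-within ANOVA on a (subjects, A levels, B levels) array.

    Returns results for the two main effects ("A", "B") and the interaction
    ("AxB"), each with the HF-corrected p value.  The design must be complete
    (no NaNs) and have at least 3 subjects.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be subjects x A x B")
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least 2 levels")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported (no imputation)")

    mean = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - mean) ** 2)
    ss_b = n * a * np.sum((m_b - mean) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + mean) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + mean) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + mean) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - mean
    )
    ss_abs = np.sum(resid**2)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)

    effects = {
        "A": (ss_a, (a - 1), ss_as, (a - 1) * (n - 1), m_sa @ ca.T),
        "B": (ss_b, (b - 1), ss_bs, (b - 1) * (n - 1), m_sb @ cb.T),
        "AxB": (
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
            np.einsum("ia,sab,jb->sij", ca, y, cb).reshape(n, (a - 1) * (b - 1)),
        ),
    }
    out: dict[str, RmAnovaResult] = {}
    for name, (ss_eff, df1, ss_err, df2, scores) in effects.items():
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err
        eps = _hf_epsilon(scores)
        e_used = min(eps, 1.0)
        p_raw = float(sstats.f.sf(f, df1, df2))
        # the sphericity correction must never be anti-conservative; for
        # F < 1 the df-scaled p can dip fractionally below the raw p
        p_corr = max(float(sstats.f.sf(f, df1 * e_used, df2 * e_used)), p_raw)
        out[name] = RmAnovaResult(
            effect=name,
            F=float(f),
            df=(float(df1), float(df2)),
            epsilon_hf=eps,
            p_uncorrected=p_raw,
            p_corrected=p_corr,
        )
    return out


def pairwise_holm(x_by_level: np.ndarray, y_by_level: np.ndarray) -> list[dict]:
    """Per-level paired t tests with Holm step-down correction.

    ``x_by_level``/``y_by_level`` are (subjects, levels) matrices of paired
    measurements (e.g. two conditions across modulation frequencies).  A
    convenience substitute for post-hoc testing.
    """
    x = np.asarray(x_by_level, dtype=float)
    y = np.asarray(y_by_level, dtype=float)
    if x.shape != y.shape:
        raise ValueError("matrices must share shape")
    n_levels = x.shape[1]
    raw = []
    for j in range(n_levels):
        t, p = sstats.ttest_rel(x[:, j], y[:, j])
        raw.append((j, float(t), float(p)))
    order = np.argsort([r[2] for r in raw])
    adj = {}
    running = 0.0
    for rank_i, idx in enumerate(order):
        j, t, p = raw[idx]
        running = max(running, p * (n_levels - rank_i))
        adj[j] = min(1.0, running)
    return [
        {"level": j, "t": t, "p_raw": p, "p_holm": adj[j]} for j, t, p in raw
    ]
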