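"""Within-subject inference: repeated-measures ANOVA (one- and two-way) with
Greenhouse-Geisser correction, Sidak-adjusted pairwise comparisons, simple
main effects, and scan-repeatability estimation.

All sums of squares are computed from scratch (the decomposition is checked
against brute-force oracles in the test suite). Greenhouse-Geisser epsilon is
the Box epsilon of the effect's orthonormal-contrast covariance matrix; the
corrected p-value is reported and used when epsilon < 0.75, a common rule of
thumb for "if appropriate".
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

GG_EPSILON_RULE = 0.75


class DesignError(ValueError):
    """Raised for unbalanced or too-small designs."""


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f: float
    df_num: float
    df_den: float
    p_uncorrected: float
    gg_epsilon: float | None = None
    p_gg: float | None = None

    @property
    def p(self) -> float:
        """Greenhouse-Geisser p when the correction is deemed appropriate."""
        if (self.gg_epsilon is not None and self.p_gg is not None
                and self.gg_epsilon < GG_EPSILON_RULE):
            return self.p_gg
        return self.p_uncorrected


@dataclass(frozen=True)
class PairwiseComparison:
    pair: str
    mean_difference: float
    std_error: float
    p_uncorrected: float
    p_sidak: float
    ci_low: float
    ci_high: float


def sidak_adjust(p: float, m: int) -> float:
    """Dunn-Sidak family-wise adjustment: 1 - (1 - p)^m, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def _helmert_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast matrix (rows orthonormal, sum to zero)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, :i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _box_epsilon(scores: np.ndarray) -> float:
    """Box/Greenhouse-Geisser epsilon from subject scores on orthonormal
    contrasts of the effect (columns = contrasts)."""
    df = scores.shape[1]
    if df == 1:
        return 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(s)
    denom = df * np.trace(s @ s)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr ** 2 / denom, 1.0 / df, 1.0))


def _snap(ss: float, ss_total: float) -> float:
    """Clamp sums of squares that are numerical noise (relative to the total
    variation) to exact zero, so constructed-null designs report F = 0."""
    return 0.0 if ss <= 1e-12 * max(ss_total, 1e-300) else ss


def _f_p(ss_num: float, df_num: float, ss_den: float, df_den: float,
         epsilon: float = 1.0) -> tuple[float, float]:
    if ss_den <= 0:
        # degenerate: a zero error term; F defined as 0 when the effect SS is
        # also zero (constructed null designs), infinite otherwise
        f = 0.0 if ss_num <= 1e-300 else float("inf")
        return f, (1.0 if f == 0.0 else 0.0)
    f = (ss_num / df_num) / (ss_den / df_den)
    p = float(stats.f.sf(f, epsilon * df_num, epsilon * df_den))
    return float(f), p


def _paired_comparisons(data: np.ndarray, labels: list[str],
                        alpha: float = 0.05) -> list[PairwiseComparison]:
    """All pairwise paired-t comparisons with Sidak-adjusted p and CIs."""
    n, k = data.shape
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    alpha_sidak = 1.0 - (1.0 - alpha) ** (1.0 / m)
    tcrit = stats.t.ppf(1.0 - alpha_sidak / 2.0, n - 1)
    out = []
    for i, j in pairs:
        d = data[:, i] - data[:, j]
        mean = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        if se == 0:
            p = 1.0 if mean == 0 else 0.0
        else:
            t = mean / se
            p = float(2.0 * stats.t.sf(abs(t), n - 1))
        out.append(PairwiseComparison(
            pair=f"{labels[i]}-{labels[j]}",
            mean_difference=mean,
            std_error=se,
            p_uncorrected=p,
            p_sidak=sidak_adjust(p, m),
            ci_low=mean - tcrit * se,
            ci_high=mean + tcrit * se,
        ))
    return out


# ---------------------------------------------------------------------------
# One-way repeated measures
# ---------------------------------------------------------------------------

def rm_anova_oneway(data: np.ndarray, labels: list[str] | None = None
                    ) -> tuple[AnovaResult, list[PairwiseComparison]]:
    """One within-subject factor. ``data`` is (n_subjects, k_levels)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DesignError("data must be a (subjects x levels) matrix")
    n, k = data.shape
    if k < 2 or n < 2:
        raise DesignError("need >= 2 subjects and >= 2 levels")
    labels = labels or [f"level{i + 1}" for i in range(k)]

    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    ss_subject = float(k * ((data.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((data.mean(axis=0) - grand) ** 2).sum())
    ss_resid = ss_total - ss_subject - ss_cond
    ss_cond = _snap(ss_cond, ss_total)
    ss_resid = _snap(ss_resid, ss_total)

    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    f, p = _f_p(ss_cond, df_num, ss_resid, df_den)
    eps = _box_epsilon(data @ _helmert_contrasts(k).T)
    _, p_gg = _f_p(ss_cond, df_num, ss_resid, df_den, epsilon=eps)
    result = AnovaResult("condition", f, df_num, df_den, p,
                         gg_epsilon=eps, p_gg=p_gg)
    return result, _paired_comparisons(data, labels)


# ---------------------------------------------------------------------------
# Two-way repeated measures
# ---------------------------------------------------------------------------

def rm_anova_twoway(data: np.ndarray,
                    factor_names: tuple[str, str] = ("A", "B")
                    ) -> dict[str, AnovaResult]:
    """Two crossed within-subject factors. ``data`` is (n, a, b).

    Returns results for both main effects and the interaction, each tested
    against its own subject-interaction error term, with Greenhouse-Geisser
    epsilon computed from the effect's contrast covariance.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise DesignError("data must be a (subjects x A-levels x B-levels) array")
    n, a, b = data.shape
    if n < 2 or a < 2 or b < 2:
        raise DesignError("need >= 2 subjects and >= 2 levels per factor")

    grand = data.mean()
    m_s = data.mean(axis=(1, 2))           # subject means
    m_a = data.mean(axis=(0, 2))           # A marginal means
    m_b = data.mean(axis=(0, 1))           # B marginal means
    m_ab = data.mean(axis=0)               # cell means (a, b)
    m_sa = data.mean(axis=2)               # (n, a)
    m_sb = data.mean(axis=1)               # (n, b)

    ss_a = float(n * b * ((m_a - grand) ** 2).sum())
    ss_b = float(n * a * ((m_b - grand) ** 2).sum())
    ss_ab = float(n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_as = float(b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = float(a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    resid = (data - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = float((resid ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_a, ss_b, ss_ab = (_snap(x, ss_total) for x in (ss_a, ss_b, ss_ab))
    ss_as, ss_bs, ss_abs = (_snap(x, ss_total) for x in (ss_as, ss_bs, ss_abs))

    ka = _helmert_contrasts(a)
    kb = _helmert_contrasts(b)
    flat = data.reshape(n, a * b)
    contrasts = {
        factor_names[0]: np.kron(ka, np.ones((1, b)) / np.sqrt(b)),
        factor_names[1]: np.kron(np.ones((1, a)) / np.sqrt(a), kb),
        f"{factor_names[0]}x{factor_names[1]}": np.kron(ka, kb),
    }
    tables = {
        factor_names[0]: (ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        factor_names[1]: (ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        f"{factor_names[0]}x{factor_names[1]}":
            (ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    }
    out = {}
    for effect, (ssn, dfn, ssd, dfd) in tables.items():
        f, p = _f_p(ssn, dfn, ssd, dfd)
        eps = _box_epsilon(flat @ contrasts[effect].T)
        _, p_gg = _f_p(ssn, dfn, ssd, dfd, epsilon=eps)
        out[effect] = AnovaResult(effect, f, dfn, dfd, p,
                                  gg_epsilon=eps, p_gg=p_gg)
    return out


def simple_main_effects(data: np.ndarray, modality_labels: list[str],
                        level_labels: list | None = None
                        ) -> dict[object, list[PairwiseComparison]]:
    """Pairwise modality comparisons at each level of the second factor.

    ``data`` is (n_subjects, n_modalities, n_levels); comparisons at each
    level are Sidak-corrected over the modality pairs at that level. Meant to
    follow a significant interaction (not enforced here).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise DesignError("data must be (subjects x modalities x levels)")
    n, a, b = data.shape
    if len(modality_labels) != a:
        raise DesignError("modality_labels length mismatch")
    level_labels = level_labels if level_labels is not None else list(range(b))
    if len(level_labels) != b:
        raise DesignError(f"unknown levels: expected {b} labels")
    return {level_labels[j]: _paired_comparisons(data[:, :, j], modality_labels)
            for j in range(b)}


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------

def repeatability(meshes: list, icp=None, seed: int = 0
                  ) -> tuple[float, float]:
    """Repeated-scan agreement over all ordered mesh pairs.

    Each of the n meshes serves in turn as the reference for the other n-1
    (n * (n-1) ordered pairs; 10 scans give 90). Every pair is finely
    registered and its deviation distribution summarised. Returns the mean of
    the per-pair mean deviations and the mean of the per-pair SDs.
    """
    from .metrics import face_deviations
    from .registration import ICPConfig, icp_register
    from ._spatial import SurfaceQuery

    if len(meshes) < 2:
        raise DesignError("repeatability needs at least 2 meshes")
    icp = icp or ICPConfig(n_sample_pairs=5000, rng_seed=seed)
    queries = [SurfaceQuery(m) for m in meshes]
    pair_means, pair_sds = [], []
    for j, ref in enumerate(meshes):
        for i, test in enumerate(meshes):
            if i == j:
                continue
            rt, _ = icp_register(test, ref, icp, query=queries[j])
            sample = face_deviations(test.transformed(rt), ref, query=queries[j])
            pair_means.append(float(np.mean(sample.distances)))
            pair_sds.append(float(np.std(sample.distances, ddof=1)))
    return float(np.mean(pair_means)), float(np.mean(pair_sds))
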