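"""Inter-rater agreement statistics for quality-control label tables.

Implements Fleiss' (1971) kappa for a fixed number of raters over the three
nominal categories, both overall and category-wise, with the null-hypothesis
standard errors used for significance testing; Holm step-down adjustment of
p-value families; pairwise percent agreement; Krippendorff's alpha for
nominal data with missing cells, with a subject-level bootstrap for
confidence intervals; majority classification across raters; and the
Landis-Koch verbal interpretation bands.

Fleiss' kappa requires a constant number of ratings per subject, so overall
and category-wise statistics for a rater subset are computed on the
complete cases — subjects rated by every rater in the subset — and the
number used is reported. Krippendorff's alpha has no such restriction: it
pairs whatever values are observed within each subject.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UndefinedStatisticError
from .types import LABELS, RatingsTable

__all__ = [
    "ReliabilityResult",
    "AlphaResult",
    "fleiss_kappa",
    "categorywise_kappa",
    "holm_adjust",
    "percent_agreement",
    "krippendorff_alpha",
    "majority_classification",
    "interpret_kappa",
    "pairwise_kappa_table",
    "LANDIS_KOCH_BANDS",
]


@dataclass
class ReliabilityResult:
    """A kappa-type agreement statistic with its test against chance."""

    kappa: float
    z: float
    p: float
    n_subjects_used: int
    category: str | None = None
    p_adjusted: float | None = None

    @property
    def interpretation(self) -> str:
        return interpret_kappa(self.kappa)


@dataclass
class AlphaResult:
    """Krippendorff's alpha with a bootstrap percentile confidence interval."""

    alpha: float
    ci_low: float | None
    ci_high: float | None
    n_subjects_used: int
    bootstrap_n: int = 0


# ---------------------------------------------------------------------------
# Fleiss' kappa

def _count_table(table: RatingsTable, raters: list | None) -> np.ndarray:
    """Subjects x categories count matrix over complete cases; constant row sum."""
    use = table.restrict(raters if raters is not None else table.raters)
    frame = use.frame
    if frame.shape[0] < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects rated by all of {list(frame.columns)}, "
            f"got {frame.shape[0]}"
        )
    counts = np.zeros((frame.shape[0], len(LABELS)), dtype=float)
    for j, lab in enumerate(LABELS):
        counts[:, j] = (frame == lab).sum(axis=1).to_numpy()
    return counts


def _fleiss_from_counts(counts: np.ndarray) -> tuple[float, float, float]:
    """Overall Fleiss kappa, z and two-sided p from a counts matrix."""
    ns, _ = counts.shape
    nr = int(counts[0].sum())
    pj = counts.sum(axis=0) / (ns * nr)
    qj = 1.0 - pj
    p_e = float(np.sum(pj**2))
    if p_e == 1.0:
        raise UndefinedStatisticError(
            "a single category is used everywhere: expected agreement is 1, "
            "kappa is undefined"
        )
    p_o = float(np.sum((counts**2).sum(axis=1) - nr) / (ns * nr * (nr - 1)))
    kappa = (p_o - p_e) / (1.0 - p_e)
    spq = float(np.sum(pj * qj))
    var = (2.0 / (spq**2 * ns * nr * (nr - 1))) * (
        spq**2 - float(np.sum(pj * qj * (qj - pj)))
    )
    z = kappa / np.sqrt(var)
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return kappa, float(z), float(p)


def fleiss_kappa(table: RatingsTable, raters: list | None = None) -> ReliabilityResult:
    """Overall Fleiss' kappa for a rater subset (complete cases only).

    z is the kappa divided by its standard error under the null hypothesis
    of chance agreement; p is two-sided.
    """
    counts = _count_table(table, raters)
    kappa, z, p = _fleiss_from_counts(counts)
    return ReliabilityResult(kappa=kappa, z=z, p=p, n_subjects_used=counts.shape[0])


def categorywise_kappa(
    table: RatingsTable, category: str, raters: list | None = None
) -> ReliabilityResult:
    """Fleiss' category-wise kappa: agreement specifically on one category.

    Uses the Fleiss (1971) per-category statistic and its null standard
    error sqrt(2 / (N n (n - 1))).
    """
    if category not in LABELS:
        raise UndefinedStatisticError(f"unknown category {category!r}")
    counts = _count_table(table, raters)
    ns = counts.shape[0]
    nr = int(counts[0].sum())
    j = LABELS.index(category)
    pj = float(counts[:, j].sum() / (ns * nr))
    if pj == 0.0:
        raise UndefinedStatisticError(f"category {category!r} never used")
    if pj == 1.0:
        raise UndefinedStatisticError(
            f"category {category!r} used everywhere: kappa undefined"
        )
    pjk = float((np.sum(counts[:, j] ** 2) - ns * nr * pj) / (ns * nr * (nr - 1) * pj))
    kappa = (pjk - pj) / (1.0 - pj)
    se = np.sqrt(2.0 / (ns * nr * (nr - 1)))
    z = kappa / se
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return ReliabilityResult(
        kappa=float(kappa), z=float(z), p=float(p), n_subjects_used=ns, category=category
    )


def pairwise_kappa_table(
    table: RatingsTable, category: str | None = None, holm: bool = True
) -> pd.DataFrame:
    """Overall (or one category's) Fleiss kappa for every pair of raters.

    The six pairwise tests form one Holm family (per category when
    ``category`` is given). Returns a frame with one row per pair.
    """
    raters = table.raters
    rows = []
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            pair = [raters[i], raters[j]]
            if category is None:
                res = fleiss_kappa(table, raters=pair)
            else:
                res = categorywise_kappa(table, category, raters=pair)
            rows.append(
                {
                    "rater_a": raters[i],
                    "rater_b": raters[j],
                    "category": category or "overall",
                    "kappa": res.kappa,
                    "z": res.z,
                    "p": res.p,
                    "n_subjects_used": res.n_subjects_used,
                    "interpretation": res.interpretation,
                }
            )
    out = pd.DataFrame(rows)
    if holm and len(out):
        out["p_adjusted"] = holm_adjust(out["p"].tolist())
    return out


# ---------------------------------------------------------------------------
# Multiple testing

def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1].tolist()


# ---------------------------------------------------------------------------
# Percent agreement

def percent_agreement(table: RatingsTable) -> pd.DataFrame:
    """Rater x rater matrix of percentage agreement on co-rated subjects.

    Entry (a, b) is 100 x (subjects where a and b gave the same label) /
    (subjects both rated); the diagonal and pairs with no shared subjects
    are NaN.
    """
    frame = table.frame
    raters = table.raters
    out = pd.DataFrame(np.nan, index=raters, columns=raters, dtype=float)
    for i, a in enumerate(raters):
        for b in raters[i + 1 :]:
            both = frame[a].notna() & frame[b].notna()
            n = int(both.sum())
            if n == 0:
                continue
            agree = int((frame.loc[both, a] == frame.loc[both, b]).sum())
            out.loc[a, b] = out.loc[b, a] = 100.0 * agree / n
    return out


# ---------------------------------------------------------------------------
# Krippendorff's alpha

def _unit_counts(frame: pd.DataFrame) -> np.ndarray:
    """Per-subject category counts (n_subjects x n_categories)."""
    counts = np.zeros((frame.shape[0], len(LABELS)))
    for j, lab in enumerate(LABELS):
        counts[:, j] = (frame == lab).sum(axis=1).to_numpy()
    return counts


def _alpha_from_counts(counts: np.ndarray) -> float:
    """Nominal-metric alpha from per-subject category counts.

    Builds the coincidence matrix over all pairable values within subjects
    (subjects with fewer than two ratings drop out) and returns
    1 - D_o / D_e. A unit with counts n_uc contributes
    n_uc * (n_uk - [c == k]) / (m_u - 1) coincidences to cell (c, k).
    """
    m_u = counts.sum(axis=1)
    use = counts[m_u >= 2]
    m_u = m_u[m_u >= 2]
    if use.shape[0] == 0:
        raise UndefinedStatisticError("no pairable values: alpha undefined")
    w = 1.0 / (m_u - 1.0)
    coincidence = np.einsum("u,uc,uk->ck", w, use, use) - np.diag(
        (use * w[:, None]).sum(axis=0)
    )
    n_total = coincidence.sum()
    if n_total <= 1:
        raise UndefinedStatisticError("no pairable values: alpha undefined")
    n_c = coincidence.sum(axis=1)
    d_o = n_total - np.trace(coincidence)
    d_e = (n_total**2 - np.sum(n_c**2)) / (n_total - 1.0)
    if d_e == 0.0:
        # only one category appears among pairable values: perfect agreement
        return 1.0
    return float(1.0 - d_o / d_e)


def krippendorff_alpha(
    table: RatingsTable,
    bootstrap_n: int = 1000,
    seed: int | np.random.Generator | None = None,
    ci: float = 95.0,
) -> AlphaResult:
    """Krippendorff's alpha (nominal metric) with a subject bootstrap CI.

    The confidence interval is the percentile interval of ``bootstrap_n``
    recomputations on subject samples drawn with replacement (fixed by
    ``seed``); resamples whose alpha is undefined are skipped.
    """
    frame = table.frame
    usable = frame.notna().sum(axis=1) >= 2
    if usable.sum() < 2:
        raise InsufficientDataError("alpha needs >= 2 subjects with >= 2 ratings")
    counts = _unit_counts(frame)
    alpha = _alpha_from_counts(counts)
    ci_low = ci_high = None
    if bootstrap_n > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = frame.shape[0]
        stats = []
        for _ in range(bootstrap_n):
            pick = rng.integers(0, n, size=n)
            try:
                stats.append(_alpha_from_counts(counts[pick]))
            except UndefinedStatisticError:
                continue
        if stats:
            tail = (100.0 - ci) / 2.0
            ci_low, ci_high = np.percentile(stats, [tail, 100.0 - tail])
            ci_low, ci_high = float(ci_low), float(ci_high)
    return AlphaResult(
        alpha=alpha,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects_used=int(usable.sum()),
        bootstrap_n=bootstrap_n,
    )


# ---------------------------------------------------------------------------
# Majority classification

def majority_classification(table: RatingsTable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each subject every label given by at least two raters.

    Subjects where no label reaches two votes are flagged unresolved.
    Returns a per-subject frame (one row per subject, columns ``labels``
    — semicolon-joined — and ``unresolved``) plus counts per label.
    """
    rows = []
    counts = {lab: 0 for lab in LABELS}
    for subject, row in table.frame.iterrows():
        votes = row.dropna().value_counts()
        majority = [lab for lab in LABELS if votes.get(lab, 0) >= 2]
        for lab in majority:
            counts[lab] += 1
        rows.append(
            {
                "subject": subject,
                "labels": ";".join(majority),
                "unresolved": len(majority) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("subject"), counts


# ---------------------------------------------------------------------------
# Interpretation bands

#: Landis-Koch verbal bands, upper-inclusive: poor < 0, slight [0, 0.2],
#: fair (0.2, 0.4], moderate (0.4, 0.6], substantial (0.6, 0.8],
#: almost perfect (0.8, 1].
LANDIS_KOCH_BANDS = (
    (0.00, "slight"),
    (0.20, "fair"),
    (0.40, "moderate"),
    (0.60, "substantial"),
    (0.80, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch verbal interpretation of a kappa value in [-1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.0:
        return "poor"
    label = "slight"
    for edge, name in LANDIS_KOCH_BANDS:
        if kappa > edge:
            label = name
    return label
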