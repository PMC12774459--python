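"""Observer-study statistics for clinical acceptability ratings.

Two (or more) raters score each case on a 5-point Likert scale
(5 = strongly agree that the output is clinically accurate, 1 = strongly
disagree).  This module computes the standard agreement and
acceptability battery for such studies:

* Pearson r and Spearman ρ between the two raters' scores,
* quadratic-weighted Cohen's κ (ordinal agreement),
* ICC(2,1) — two-way random effects, absolute agreement, single measure
  — with its 95% F-based confidence interval,
* Bland–Altman mean difference and limits of agreement,
* acceptability indices: AAS (mean Likert score), AR (% of ratings at or
  above the accept threshold, default 4), NAS ((#accept − #reject)/N
  with reject meaning a rating of 1 or 2),
* unweighted Cohen's κ on the dichotomized accept/reject decisions.

Pooled AR is computed over all ratings (equivalently the
ratings-weighted mean of per-rater rates), not the plain mean of
per-rater percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObserverStudy",
    "Correlations",
    "ICCResult",
    "BlandAltman",
    "Acceptability",
    "AgreementReport",
    "correlations",
    "quadratic_weighted_kappa",
    "icc21",
    "bland_altman",
    "acceptability",
    "binary_accept_kappa",
    "agreement_report",
]

LIKERT_LEVELS = (1, 2, 3, 4, 5)
REJECT_MAX = 2  # Likert 1-2 are the "disagree" levels


@dataclass
class ObserverStudy:
    """Case x rater matrix of Likert scores in {1..5}."""

    ratings: np.ndarray
    rater_names: tuple[str, ...] | None = None
    accept_threshold: int = 4

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=int)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be a 2-D case x rater matrix")
        n_cases, n_raters = self.ratings.shape
        if n_cases < 2 or n_raters < 2:
            raise ValueError(
                f"need at least 2 cases and 2 raters, got {n_cases} x {n_raters}"
            )
        if not np.isin(self.ratings, LIKERT_LEVELS).all():
            bad = self.ratings[~np.isin(self.ratings, LIKERT_LEVELS)]
            raise ValueError(f"ratings must be in {{1..5}}, found {sorted(set(bad.tolist()))}")
        if not 2 <= self.accept_threshold <= 5:
            raise ValueError("accept_threshold must be in {2..5}")
        if self.rater_names is None:
            self.rater_names = tuple(f"rater_{i + 1}" for i in range(n_raters))
        elif len(self.rater_names) != n_raters:
            raise ValueError("rater_names length must match number of raters")

    @property
    def n_cases(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def pair(self) -> tuple[np.ndarray, np.ndarray]:
        """The two rating vectors, for pairwise metrics."""
        if self.n_raters != 2:
            raise ValueError(
                f"pairwise metric requires exactly 2 raters, got {self.n_raters}"
            )
        return self.ratings[:, 0], self.ratings[:, 1]


@dataclass(frozen=True)
class Correlations:
    pearson_r: float
    spearman_rho: float


def correlations(study: ObserverStudy) -> Correlations:
    """Pearson and Spearman correlation between the two raters' scores.

    Zero variance in either rating vector makes the correlation
    undefined; that is reported as an error rather than a silent NaN.
    """
    a, b = study.pair()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: a rater's scores have zero variance")
    r = stats.pearsonr(a, b).statistic
    rho = stats.spearmanr(a, b).statistic
    return Correlations(pearson_r=float(r), spearman_rho=float(rho))


def quadratic_weighted_kappa(study: ObserverStudy) -> float:
    """Cohen's κ with quadratic distance weights on the 5 Likert levels.

    Disagreement cells are penalized by (i−j)²/(k−1)²; the expected table
    comes from the marginal products.  When both raters use a single
    identical category there is no possible disagreement and κ is
    defined as 1.
    """
    from sklearn.metrics import cohen_kappa_score

    a, b = study.pair()
    if len(set(a) | set(b)) == 1:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kappa = cohen_kappa_score(a, b, weights="quadratic", labels=list(LIKERT_LEVELS))
    return float(kappa)


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci_low: float
    ci_high: float


def icc21(study: ObserverStudy) -> ICCResult:
    """ICC(2,1): two-way random, absolute agreement, single measure.

    Confidence interval is the standard 95% F-based interval.  A ratings
    matrix with no variance at all leaves the ICC undefined and raises.
    """
    import pingouin as pg

    r = study.ratings
    if r.std() == 0:
        raise ValueError("ICC undefined: all ratings identical (no variance)")
    df = pd.DataFrame(
        {
            "case": np.repeat(np.arange(study.n_cases), study.n_raters),
            "rater": np.tile(np.asarray(study.rater_names), study.n_cases),
            "score": r.astype(float).ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=df, targets="case", raters="rater", ratings="score"
        )
    row = table[table["Type"] == "ICC(A,1)"]
    if row.empty:  # older pingouin naming
        row = table[table["Type"] == "ICC2"]
    row = row.iloc[0]
    ci_low, ci_high = np.asarray(row["CI95"], dtype=float)
    return ICCResult(value=float(row["ICC"]), ci_low=float(ci_low), ci_high=float(ci_high))


@dataclass(frozen=True)
class BlandAltman:
    """Paired-difference bias analysis; differences are rater1 − rater2."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(study: ObserverStudy) -> BlandAltman:
    """Mean bias and 95% limits of agreement (mean ± 1.96 sd, sd with ddof=1)."""
    a, b = study.pair()
    diffs = (a - b).astype(float)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
    )


@dataclass(frozen=True)
class Acceptability:
    aas_per_rater: tuple[float, ...]
    aas_pooled: float
    ar_per_rater_pct: tuple[float, ...]
    ar_pooled_pct: float
    nas: float


def acceptability(study: ObserverStudy) -> Acceptability:
    """AAS, AR and NAS, per rater and pooled over all ratings.

    AR counts ratings ≥ accept_threshold (percent).  NAS counts a rating
    ≥ threshold as acceptance and ≤ 2 as rejection (a neutral 3 counts in
    neither), normalized by the total number of ratings.
    """
    r = study.ratings
    accept = r >= study.accept_threshold
    reject = r <= REJECT_MAX
    return Acceptability(
        aas_per_rater=tuple(float(m) for m in r.mean(axis=0)),
        aas_pooled=float(r.mean()),
        ar_per_rater_pct=tuple(float(100 * m) for m in accept.mean(axis=0)),
        ar_pooled_pct=float(100 * accept.mean()),
        nas=float((int(accept.sum()) - int(reject.sum())) / r.size),
    )


def binary_accept_kappa(study: ObserverStudy) -> float:
    """Unweighted Cohen's κ on dichotomized accept/reject decisions.

    Dichotomization is rating ≥ accept_threshold.  If both raters make
    the same constant decision everywhere (degenerate marginals with
    perfect observed agreement), κ is defined as 1.
    """
    from sklearn.metrics import cohen_kappa_score

    a, b = study.pair()
    x = (a >= study.accept_threshold).astype(int)
    y = (b >= study.accept_threshold).astype(int)
    if np.array_equal(x, y) and len(set(x)) == 1:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kappa = cohen_kappa_score(x, y, labels=[0, 1])
    return float(kappa)


@dataclass
class AgreementReport:
    """Full agreement/acceptability battery for a two-rater study."""

    correlations: Correlations
    weighted_kappa: float
    icc21: ICCResult
    bland_altman: BlandAltman
    acceptability: Acceptability
    binary_kappa: float
    rater_names: tuple[str, ...] = field(default_factory=tuple)
    accept_threshold: int = 4

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.correlations.pearson_r,
            "spearman_rho": self.correlations.spearman_rho,
            "weighted_kappa": self.weighted_kappa,
            "icc21": {
                "value": self.icc21.value,
                "ci95_low": self.icc21.ci_low,
                "ci95_high": self.icc21.ci_high,
            },
            "bland_altman": {
                "direction": f"{self.rater_names[0]} - {self.rater_names[1]}",
                "mean_diff": self.bland_altman.mean_diff,
                "sd_diff": self.bland_altman.sd_diff,
                "loa_low": self.bland_altman.loa_low,
                "loa_high": self.bland_altman.loa_high,
            },
            "aas": {
                "per_rater": list(self.acceptability.aas_per_rater),
                "pooled": self.acceptability.aas_pooled,
            },
            "ar_pct": {
                "per_rater": list(self.acceptability.ar_per_rater_pct),
                "pooled": self.acceptability.ar_pooled_pct,
            },
            "nas": self.acceptability.nas,
            "binary_accept_kappa": self.binary_kappa,
            "accept_threshold": self.accept_threshold,
        }

    def to_text(self) -> str:
        acc = self.acceptability
        ba = self.bland_altman
        per_aas = ", ".join(
            f"{n}: {v:.2f}" for n, v in zip(self.rater_names, acc.aas_per_rater)
        )
        per_ar = ", ".join(
            f"{n}: {v:.1f}%" for n, v in zip(self.rater_names, acc.ar_per_rater_pct)
        )
        lines = [
            f"{'Metric':<34}Value",
            f"{'Pearson r':<34}{self.correlations.pearson_r:.3f}",
            f"{'Spearman rho':<34}{self.correlations.spearman_rho:.3f}",
            f"{'Weighted kappa (quadratic)':<34}{self.weighted_kappa:.3f}",
            f"{'ICC(2,1)':<34}{self.icc21.value:.3f} "
            f"(95% CI: {self.icc21.ci_low:.2f}-{self.icc21.ci_high:.2f})",
            f"{'Mean difference (Bland-Altman)':<34}{ba.mean_diff:+.3f} ± {ba.sd_diff:.2f}",
            f"{'Limits of agreement':<34}[{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]",
            f"{'AAS (mean Likert)':<34}{acc.aas_pooled:.2f} ({per_aas})",
            f"{f'AR (accept >= {self.accept_threshold})':<34}"
            f"{acc.ar_pooled_pct:.1f}% ({per_ar})",
            f"{'NAS':<34}{acc.nas:+.2f}",
            f"{'Cohen kappa (accept/reject)':<34}{self.binary_kappa:.3f}",
        ]
        return "\n".join(lines)


def agreement_report(study: ObserverStudy) -> AgreementReport:
    """Compute the full metric battery for a two-rater observer study."""
    return AgreementReport(
        correlations=correlations(study),
        weighted_kappa=quadratic_weighted_kappa(study),
        icc21=icc21(study),
        bland_altman=bland_altman(study),
        acceptability=acceptability(study),
        binary_kappa=binary_accept_kappa(study),
        rater_names=tuple(study.rater_names),
        accept_threshold=study.accept_threshold,
    )
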