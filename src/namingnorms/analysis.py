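"""Inferential analyses over the image-level norms.

Covers the study's statistics: Welch's t contrasts between natural and
artefact objects under a Bonferroni-adjusted alpha, within-object
consistency of naming uncertainty, the H -> RT validation regression,
Bayes factors derived from BIC, the hierarchical modal-name versus
weighted-average model comparison, and a suppression-artefact diagnostic
for sign-flipped regression coefficients.

All regressions are ordinary least squares at the image level (one
observation per image), with an intercept.  Bayes factors follow the
BIC approximation BF10 = exp((BIC_0 - BIC_1) / 2), which is valid only
when both models are fit to identical observations; complete-case
filtering is therefore applied on the union of predictors before any
model in a comparison is fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "ModelComparisonResult",
    "GroupContrast",
    "ConsistencyResult",
    "SuppressionReport",
    "welch_contrasts",
    "within_object_consistency",
    "fit_linear",
    "bf_from_bic",
    "hierarchical_comparison",
    "suppression_check",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# OLS fits
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Summary of one OLS fit: coefficients, inference, fit indices."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    ci_half_width: dict[str, float]
    se: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r2: float
    adjusted_r2: float
    f_stat: float
    df_model: int
    df_resid: int
    bic: float
    n: int

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "ci_half_width": self.ci_half_width,
            "se": self.se,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "f_stat": self.f_stat,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "bic": self.bic,
            "n": self.n,
        }


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    mat = X.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    tol = s.max() * max(mat.shape) * np.finfo(float).eps
    null_vecs = vt[s <= tol]
    involved: set[str] = set()
    for v in null_vecs:
        involved |= {c for c, w in zip(X.columns, v) if abs(w) > 1e-8}
    return sorted(involved)


def fit_linear(
    data: pd.DataFrame,
    response: str,
    predictors: list[str] | tuple[str, ...] = (),
    alpha: float = 0.05,
) -> ModelFit:
    """Fit an OLS regression (with intercept) on complete cases.

    Reports unstandardised coefficients with 95% CI half-widths, t and
    two-tailed p values, adjusted R-squared, the model F statistic with
    its degree-of-freedom pair, and BIC.  An empty predictor list fits
    the intercept-only (null) model.  Raises on a rank-deficient design,
    naming the collinear columns.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    frame = data[cols].dropna()
    y = frame[response].astype(float)
    X = sm.add_constant(frame[predictors].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(X)}"
        )
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=alpha)
    half = ((ci[1] - ci[0]) / 2.0).to_dict()
    return ModelFit(
        response=response,
        predictors=tuple(predictors),
        coefficients=res.params.to_dict(),
        ci_half_width=half,
        se=res.bse.to_dict(),
        t_values=res.tvalues.to_dict(),
        p_values=res.pvalues.to_dict(),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue) if predictors else float("nan"),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        bic=float(res.bic),
        n=int(res.nobs),
    )


def bf_from_bic(bic_null: float, bic_alt: float) -> float:
    """Bayes factor BF10 for the alternative model from the two BICs.

    BF10 = exp((BIC_null - BIC_alt) / 2): a lower-BIC alternative yields
    BF10 > 1.  Both models must have been fit on identical observations.
    """
    return math.exp((bic_null - bic_alt) / 2.0)


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

@dataclass
class GroupContrast:
    """One Welch's t contrast between natural and artefact images."""

    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    alpha_adjusted: float
    alpha_adjusted_reported: float
    significant: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def welch_contrasts(
    norms: pd.DataFrame,
    variables: list[str],
    family_alpha: float = 0.05,
    n_tests: int | None = None,
    group_col: str = "kind",
    groups: tuple[str, str] = ("artefact", "natural"),
) -> list[GroupContrast]:
    """Two-tailed Welch's unequal-variance t tests per normed variable.

    The Bonferroni-adjusted alpha is ``family_alpha / n_tests``
    (``n_tests`` defaults to the number of variables); significance is
    decided on the unrounded alpha while ``alpha_adjusted_reported``
    carries the 3-decimal value used in write-ups.
    """
    if n_tests is None:
        n_tests = len(variables)
    alpha = family_alpha / n_tests
    out = []
    for var in variables:
        a = norms.loc[norms[group_col] == groups[0], var].dropna().astype(float)
        b = norms.loc[norms[group_col] == groups[1], var].dropna().astype(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"variable {var!r}: each group needs >= 2 images "
                f"(got {len(a)} and {len(b)})"
            )
        res = sps.ttest_ind(a, b, equal_var=False)
        out.append(
            GroupContrast(
                variable=var,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                group_a=groups[0],
                group_b=groups[1],
                t=float(res.statistic),
                df=float(res.df),
                p=float(res.pvalue),
                alpha_adjusted=alpha,
                alpha_adjusted_reported=round(alpha, 3),
                significant=bool(res.pvalue < alpha),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Within-object consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    """Within-object agreement of naming uncertainty across an object's images."""

    r_min_max: float
    n_objects: int
    n_single_modal: int
    pct_single_modal: float
    n_excluded_single_image: int
    diagnostic: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def within_object_consistency(
    norms: pd.DataFrame,
    h_col: str = "h_normalised",
) -> ConsistencyResult:
    """Correlate per-object minimum and maximum normalised H across images.

    A strong positive correlation indicates that naming uncertainty
    varies at the object rather than the image level.  Also reports how
    many objects keep a single modal name across all their images.
    Objects with one image are excluded (and counted); zero-variance
    input yields a missing correlation with a diagnostic.
    """
    groups = norms.groupby("object_id")
    sizes = groups.size()
    excluded = int((sizes < 2).sum())
    if excluded:
        logger.info("%d object(s) with a single image excluded", excluded)
    multi = norms[norms["object_id"].map(sizes) >= 2]
    g = multi.groupby("object_id")
    mins = g[h_col].min()
    maxs = g[h_col].max()
    diagnostic = ""
    if len(mins) < 2 or mins.std() == 0 or maxs.std() == 0:
        r = float("nan")
        diagnostic = "correlation undefined: zero variance in per-object H"
    else:
        r = float(sps.pearsonr(mins, maxs).statistic)
    modal_counts = g["modal_name"].nunique()
    n_single = int((modal_counts == 1).sum())
    n_objects = int(len(modal_counts))
    return ConsistencyResult(
        r_min_max=r,
        n_objects=n_objects,
        n_single_modal=n_single,
        pct_single_modal=round(100.0 * n_single / n_objects, 2) if n_objects else 0.0,
        n_excluded_single_image=excluded,
        diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# Hierarchical modal-name vs weighted-average comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonResult:
    """Hierarchical modal-name vs weighted-average regression comparison.

    ``step_bfs`` holds the BF10 for each added predictor against the
    preceding step; ``final_bf_vs_null`` the Step-2 models' BF10 against
    the intercept-only model; ``nonnested_bf`` the BF10 of the
    weighted-average model over the modal-name model computed from their
    Step-2 BICs.
    """

    step_bfs: dict[str, float]
    final_bf_vs_null: dict[str, float]
    nonnested_bf: float
    winner: str
    n: int
    n_dropped: int
    fits: dict[str, ModelFit] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "step_bfs": self.step_bfs,
            "final_bf_vs_null": self.final_bf_vs_null,
            "nonnested_bf": self.nonnested_bf,
            "winner": self.winner,
            "n": self.n,
            "n_dropped": self.n_dropped,
            "fits": {k: f.as_dict() for k, f in self.fits.items()},
        }


def hierarchical_comparison(
    norms: pd.DataFrame,
    response: str = "mean_rt_ms",
    modal_predictors: tuple[str, str] = ("modal_zipf", "modal_length_letters"),
    weighted_predictors: tuple[str, str] = ("weighted_zipf", "weighted_length_letters"),
) -> ModelComparisonResult:
    """Compare modal-name and weighted-average models of recognition RT.

    Both two-step hierarchical regressions (frequency at Step 1, length
    at Step 2) are fit on the complete cases of the union of predictors,
    so all BICs — and hence all Bayes factors, including the final
    non-nested comparison — refer to identical observations.
    """
    cols = [response, *modal_predictors, *weighted_predictors]
    frame = norms[cols].dropna()
    n_dropped = len(norms) - len(frame)
    if n_dropped:
        logger.info(
            "hierarchical comparison dropped %d image(s) with missing values",
            n_dropped,
        )
    if len(frame) <= len(cols):
        raise ValueError(f"too few complete cases ({len(frame)}) for comparison")

    null = fit_linear(frame, response, [])
    fits = {"null": null}
    bics = {}
    for label, preds in [("modal", modal_predictors), ("weighted", weighted_predictors)]:
        step1 = fit_linear(frame, response, [preds[0]])
        step2 = fit_linear(frame, response, list(preds))
        fits[f"{label}_step1"] = step1
        fits[f"{label}_step2"] = step2
        bics[label] = (step1.bic, step2.bic)
    if not all(
        f.n == null.n for f in fits.values()
    ):  # pragma: no cover - guarded by shared complete-case frame
        raise ValueError("models were fit on differing observation counts")

    step_bfs = {}
    final = {}
    for label in ("modal", "weighted"):
        b1, b2 = bics[label]
        step_bfs[f"{label}_step1_vs_null"] = bf_from_bic(null.bic, b1)
        step_bfs[f"{label}_step2_vs_step1"] = bf_from_bic(b1, b2)
        final[label] = bf_from_bic(null.bic, b2)
    nonnested = bf_from_bic(bics["modal"][1], bics["weighted"][1])
    return ModelComparisonResult(
        step_bfs=step_bfs,
        final_bf_vs_null=final,
        nonnested_bf=nonnested,
        winner="weighted" if nonnested > 1 else "modal",
        n=null.n,
        n_dropped=n_dropped,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# Suppression diagnostic
# ---------------------------------------------------------------------------

@dataclass
class SuppressionReport:
    """Diagnostic for suppression artefacts in a two-predictor regression."""

    flagged: list[str]
    r_y_x1: float
    r_y_x2: float
    r_x1_x2: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def suppression_check(
    data: pd.DataFrame,
    response: str,
    x1: str,
    x2: str,
    fit: ModelFit,
    r_threshold: float = 0.5,
) -> SuppressionReport:
    """Flag predictors whose coefficient sign contradicts their zero-order r.

    A predictor is flagged as a likely suppression artefact when the sign
    of its regression coefficient differs from the sign of its zero-order
    correlation with the response while the two predictors correlate
    strongly (|r| > ``r_threshold``) with each other.
    """
    frame = data[[response, x1, x2]].dropna()
    r_y_x1 = float(sps.pearsonr(frame[response], frame[x1]).statistic)
    r_y_x2 = float(sps.pearsonr(frame[response], frame[x2]).statistic)
    r_x1_x2 = float(sps.pearsonr(frame[x1], frame[x2]).statistic)
    flagged = []
    if abs(r_x1_x2) > r_threshold:
        for pred, r in [(x1, r_y_x1), (x2, r_y_x2)]:
            coef = fit.coefficients.get(pred)
            if coef is not None and r != 0 and np.sign(coef) != np.sign(r):
                flagged.append(pred)
    return SuppressionReport(
        flagged=flagged, r_y_x1=r_y_x1, r_y_x2=r_y_x2, r_x1_x2=r_x1_x2
    )
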