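"""Group × condition inference on trial-level synchronization consistency.

The analysis models trial-level logit vector length with a linear mixed
model: fixed effects of group (CI vs HC), condition (A, V, AVsync,
AVasync) and their interaction under sum-to-zero coding; a random
intercept per participant plus random condition slopes (unstructured
covariance, falling back to diagonal and then intercept-only on
convergence failure).  Omnibus type-3 Wald F tests use Satterthwaite
denominator df by default.  Eleven pre-registered post-hoc contrasts on
the estimated marginal (cell) means are Bonferroni-corrected for the
family size of 11.  Clinical regressions relate per-participant mean
consistency of CI users to deafness onset age (pre-linguistic coded as
2 years) and deafness duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, is_dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
import statsmodels.api as sm

from .kenward_roger import KenwardRogerEngine
from .satterthwaite import SatterthwaiteEngine, VarianceStructure
from .simulate import ParticipantRecord
from .stimuli import CONDITION_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "ModelFit",
    "ContrastResult",
    "RegressionResult",
    "CONTRAST_FAMILY_SIZE",
    "CONTRAST_NAMES",
    "aggregate_scores",
    "fit_mixed_model",
    "omnibus_tests",
    "posthoc_contrasts",
    "regress_clinical",
]

FIXED_FORMULA = "logit_consistency ~ C(group, Sum) * C(condition, Sum)"
RE_FORMULA = "1 + C(condition, Sum)"

#: the pre-registered post-hoc family; Bonferroni uses this printed size
CONTRAST_FAMILY_SIZE = 11

# each contrast is a weighted sum of (group, condition) cell means
CONTRAST_CELLS: dict[str, list[tuple[str, str, float]]] = {
    "V_CI - V_HC": [("CI", "V", 1), ("HC", "V", -1)],
    "A_CI - A_HC": [("CI", "A", 1), ("HC", "A", -1)],
    "A_CI - V_CI": [("CI", "A", 1), ("CI", "V", -1)],
    "A_HC - V_HC": [("HC", "A", 1), ("HC", "V", -1)],
    "(A_CI - V_CI) - (A_HC - V_HC)": [
        ("CI", "A", 1), ("CI", "V", -1), ("HC", "A", -1), ("HC", "V", 1)],
    "AVsync_CI - V_CI": [("CI", "AVsync", 1), ("CI", "V", -1)],
    "AVsync_HC - V_HC": [("HC", "AVsync", 1), ("HC", "V", -1)],
    "(AVsync_CI - V_CI) - (AVsync_HC - V_HC)": [
        ("CI", "AVsync", 1), ("CI", "V", -1), ("HC", "AVsync", -1), ("HC", "V", 1)],
    "AVasync_CI - V_CI": [("CI", "AVasync", 1), ("CI", "V", -1)],
    "AVasync_HC - V_HC": [("HC", "AVasync", 1), ("HC", "V", -1)],
    "(AVasync_CI - V_CI) - (AVasync_HC - V_HC)": [
        ("CI", "AVasync", 1), ("CI", "V", -1), ("HC", "AVasync", -1), ("HC", "V", 1)],
}
CONTRAST_NAMES = tuple(CONTRAST_CELLS)


@dataclass(frozen=True)
class ScoreTable:
    """Usable (non-excluded) trial scores plus exclusion bookkeeping."""

    data: pd.DataFrame  # participant_id, group, condition, trial, logit_consistency
    exclusion_counts: pd.DataFrame  # group, condition, n_excluded, n_total

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ModelFit:
    """A fitted mixed model plus the metadata inference needs."""

    result: object  # statsmodels MixedLMResults
    data: pd.DataFrame
    structure: str  # "unstructured" | "diagonal" | "intercept"
    converged: bool
    notes: list[str] = field(default_factory=list)
    #: indices of full-design columns kept in the fit (aliased columns of a
    #: rank-deficient design, e.g. with an empty cell, are dropped)
    kept_cols: Optional[np.ndarray] = None

    _engine: Optional[SatterthwaiteEngine] = None
    _kr_engine: Optional[KenwardRogerEngine] = None
    _design_info: Optional[object] = None

    @property
    def loglike(self) -> float:
        return float(self.result.llf)

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    @property
    def design_info(self):
        if self._design_info is None:
            self._design_info = patsy.dmatrix(
                FIXED_FORMULA.split("~", 1)[1], self.data, return_type="dataframe"
            ).design_info
        return self._design_info

    def _re_layout(self):
        model = self.result.model
        k = model.exog_re.shape[1]
        kind = "diagonal" if self.structure == "diagonal" else "unstructured"
        structure = VarianceStructure(k=k, kind=kind)
        rows = [model.row_indices[g] for g in model.group_labels]
        cov_re = np.atleast_2d(np.asarray(self.result.cov_re))
        return model, rows, cov_re, structure

    @property
    def engine(self) -> SatterthwaiteEngine:
        if self._engine is None:
            model, rows, cov_re, structure = self._re_layout()
            self._engine = SatterthwaiteEngine(
                y=model.endog, X=model.exog, Z=model.exog_re, group_rows=rows,
                G=cov_re, scale=self.result.scale, structure=structure,
            )
        return self._engine

    @property
    def kr_engine(self) -> KenwardRogerEngine:
        if self._kr_engine is None:
            model, rows, cov_re, structure = self._re_layout()
            self._kr_engine = KenwardRogerEngine(
                y=model.endog, X=model.exog, Z=model.exog_re, group_rows=rows,
                G=cov_re, scale=self.result.scale, structure=structure,
            )
        return self._kr_engine

    def cell_vector(self, group: str, condition: str) -> np.ndarray:
        """Design row giving the estimated marginal mean of one cell.

        Restricted to the fitted columns; valid only for cells observed in
        the data (aliased-column coefficients are implicitly zero, the
        usual convention for rank-deficient factorials).
        """
        row = pd.DataFrame({"group": [group], "condition": [condition]})
        full = np.asarray(patsy.dmatrix(self.design_info, row))[0]
        return full if self.kept_cols is None else full[self.kept_cols]

    def contrast_vector(self, cells: Sequence[tuple[str, str, float]]) -> np.ndarray:
        c = np.zeros(len(self.result.fe_params))
        for g, cond, w in cells:
            c = c + w * self.cell_vector(g, cond)
        return c


@dataclass(frozen=True)
class ContrastResult:
    """One post-hoc comparison on the estimated marginal means."""

    name: str
    estimate: float
    se: float
    df: float
    t: float
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class RegressionResult:
    """A simple clinical-covariate regression within the CI group."""

    outcome: str
    predictor: str
    n: int
    slope: float
    se: float
    t: float
    df: int
    p: float


def aggregate_scores(scores) -> ScoreTable:
    """Filter excluded trials into a modelling table with exclusion counts.

    ``scores`` is an iterable of :class:`~tapsync.scoring.TrialScore` or an
    equivalent DataFrame.  Participants whose trials were all excluded are
    logged and retained only in the bookkeeping.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores.copy()
    else:
        df = pd.DataFrame([asdict(s) if is_dataclass(s) else s for s in scores])
    if df.empty:
        raise ValueError("no scored trials")
    df["excluded"] = df["excluded"].astype(bool)
    totals = df.groupby(["group", "condition"], sort=False).size().rename("n_total")
    excl = (
        df.groupby(["group", "condition"], sort=False)["excluded"].sum().rename("n_excluded")
    )
    counts = pd.concat([excl, totals], axis=1).reset_index()
    kept = df.loc[~df["excluded"]].copy()
    for pid in sorted(set(df["participant_id"]) - set(kept["participant_id"])):
        logger.warning("participant %s has no usable trials", pid)
    kept = kept.rename(columns={"trial_index": "trial"})
    cols = ["participant_id", "group", "condition", "trial", "logit_consistency"]
    return ScoreTable(data=kept[cols].reset_index(drop=True), exclusion_counts=counts)


def _full_design(df: pd.DataFrame):
    """Fixed design matrix plus the indices of independent columns."""
    y, X = patsy.dmatrices(FIXED_FORMULA, df, return_type="dataframe")
    Xv = np.asarray(X)
    from scipy.linalg import qr

    _, R, piv = qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum())
    kept = np.sort(piv[:rank])
    return np.asarray(y).ravel(), X, kept


def _attempt(df: pd.DataFrame, structure: str):
    yv, X, kept = _full_design(df)
    exog = np.asarray(X)[:, kept]
    names = [X.columns[i] for i in kept]
    if structure == "intercept":
        exog_re = np.ones((len(df), 1))
    else:
        exog_re = np.asarray(patsy.dmatrix(RE_FORMULA, df))
    free = None
    model = MixedLM(yv, exog, groups=np.asarray(df["participant_id"]), exog_re=exog_re)
    model.data.xnames = names
    if structure == "diagonal":
        free = MixedLMParams.from_components(
            fe_params=np.ones(exog.shape[1]), cov_re=np.eye(exog_re.shape[1])
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs", maxiter=200, free=free)
    ok = bool(res.converged) and np.all(np.isfinite(np.asarray(res.bse_fe))) and res.scale > 0
    dropped = None if len(kept) == X.shape[1] else kept
    return res, ok, dropped


def fit_mixed_model(table) -> ModelFit:
    """Fit logit consistency ~ group × condition with participant random
    effects (intercept + condition slopes), sum-to-zero coding, REML.

    Falls back from an unstructured random-slope covariance to a diagonal
    one, and finally to a random intercept only, when a richer structure
    fails to converge; each downgrade is recorded in ``notes``.
    """
    df = table.data if isinstance(table, ScoreTable) else table
    df = df.copy()
    if df["group"].nunique() < 2 or df["condition"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 conditions")
    per_group = df.groupby("group")["participant_id"].nunique()
    if (per_group < 2).any():
        raise ValueError("need at least 2 participants per group")

    notes: list[str] = []
    res = kept = None
    for structure in ("unstructured", "diagonal", "intercept"):
        try:
            res, ok, kept = _attempt(df, structure)
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover - rare
            notes.append(f"{structure} fit raised {exc!r}")
            continue
        if ok:
            if notes:
                logger.warning("random-effect structure downgraded to %s", structure)
            if kept is not None:
                notes.append("rank-deficient fixed design: aliased columns dropped")
                logger.warning(notes[-1])
            return ModelFit(
                result=res, data=df, structure=structure, converged=True,
                notes=notes, kept_cols=kept,
            )
        notes.append(f"{structure} fit did not converge")
    if res is None:
        raise np.linalg.LinAlgError(f"mixed model could not be fit: {notes}")
    # last resort: return the intercept-only fit unconverged, flagged
    return ModelFit(
        result=res, data=df, structure="intercept", converged=False,
        notes=notes, kept_cols=kept,
    )


_TERMS = {
    "group": "C(group, Sum)",
    "condition": "C(condition, Sum)",
    "group:condition": "C(group, Sum):C(condition, Sum)",
}


def _between_within_df(fit: ModelFit, term: str) -> float:
    """Containment-style denominator df: between-participant terms test
    against participants, within-participant terms against observations."""
    n_obs = len(fit.data)
    n_p = fit.n_participants
    if term == "group":
        return float(n_p - 2)
    return float(n_obs - n_p - 6)  # 3 condition + 3 interaction fixed params


def omnibus_tests(fit: ModelFit, df_method: str = "kenward_roger") -> pd.DataFrame:
    """Type-3 Wald F tests of group, condition and group × condition.

    Under sum-to-zero coding each term's type-3 test is the joint Wald test
    of its coefficients.  ``df_method`` is ``"kenward_roger"`` (the default:
    adjusted covariance, moment-matched df and F scaling),
    ``"satterthwaite"``, or ``"between_within"``.
    """
    if not fit.converged:
        logger.warning("omnibus tests on a non-converged fit")
    beta = np.asarray(fit.result.fe_params)
    cov = fit.engine.fe_cov(fit.engine.theta_hat)
    slices = fit.design_info.term_name_slices
    n_full = len(fit.design_info.column_names)
    rows = []
    for term, patsy_name in _TERMS.items():
        sl = slices[patsy_name]
        cols = np.arange(n_full)[sl]
        if fit.kept_cols is not None:
            if not np.isin(cols, fit.kept_cols).all():
                rows.append({"term": term, "F": np.nan, "df1": len(cols), "df2": np.nan,
                             "p": np.nan, "warning": True})
                continue
            cols = np.searchsorted(fit.kept_cols, cols)
        L = np.eye(len(beta))[cols]
        q = L.shape[0]
        if df_method == "kenward_roger":
            F, q, df2, p = fit.kr_engine.test_term(L, beta)
        elif df_method in ("satterthwaite", "between_within"):
            M = L @ cov @ L.T
            est = L @ beta
            F = float(est @ np.linalg.solve(M, est)) / q
            if df_method == "satterthwaite":
                df2 = fit.engine.term_df(L)
            else:
                df2 = _between_within_df(fit, term)
            p = float(stats.f.sf(F, q, df2))
        else:
            raise ValueError(f"unknown df_method {df_method!r}")
        rows.append(
            {
                "term": term,
                "F": F,
                "df1": q,
                "df2": df2,
                "p": p,
                "warning": not fit.converged,
            }
        )
    return pd.DataFrame(rows)


def posthoc_contrasts(fit: ModelFit, df_method: str = "kenward_roger") -> list[ContrastResult]:
    """The 11 pre-registered contrasts on estimated marginal means, each
    with Bonferroni-adjusted p = min(1, 11 × p_raw)."""
    assert len(CONTRAST_CELLS) == CONTRAST_FAMILY_SIZE
    beta = np.asarray(fit.result.fe_params)
    cov = fit.engine.fe_cov(fit.engine.theta_hat)
    observed = set(zip(fit.data["group"], fit.data["condition"]))
    out = []
    for name, cells in CONTRAST_CELLS.items():
        if any((g, c) not in observed for g, c, _ in cells):
            out.append(
                ContrastResult(name, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
            )
            continue
        c = fit.contrast_vector(cells)
        if df_method == "kenward_roger":
            est, se, df, t, p = fit.kr_engine.test_contrast(c, beta)
        elif df_method in ("satterthwaite", "between_within"):
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            if df_method == "satterthwaite":
                df = fit.engine.contrast_df(c)
            else:
                df = float(fit.n_participants - 2)
            t = est / se
            p = float(2 * stats.t.sf(abs(t), df))
        else:
            raise ValueError(f"unknown df_method {df_method!r}")
        out.append(
            ContrastResult(
                name=name, estimate=est, se=se, df=df, t=t,
                p_raw=p, p_bonferroni=min(1.0, CONTRAST_FAMILY_SIZE * p),
            )
        )
    return out


_OUTCOMES = ("V_CI", "A_CI", "AVsync_minus_V")
_PREDICTORS = ("onset_age", "deafness_duration")


def participant_means(table) -> pd.DataFrame:
    """Per-participant mean logit consistency, one column per condition."""
    df = table.data if isinstance(table, ScoreTable) else table
    wide = df.pivot_table(
        index=["participant_id", "group"], columns="condition",
        values="logit_consistency", aggfunc="mean",
    ).reset_index()
    wide.columns.name = None
    return wide


def regress_clinical(
    table,
    participants: Sequence[ParticipantRecord],
    outcome: str,
    predictor: str,
) -> RegressionResult:
    """OLS of a CI-group consistency outcome on a deafness-history predictor.

    Outcomes: ``V_CI`` and ``A_CI`` (per-participant mean logit consistency
    in the visual / auditory condition) and ``AVsync_minus_V`` (the
    multisensory congruence effect).  Predictors: ``onset_age`` (with
    pre-linguistic onset coded as 2 years) and ``deafness_duration``.
    """
    if outcome not in _OUTCOMES:
        raise ValueError(f"outcome must be one of {_OUTCOMES}")
    if predictor not in _PREDICTORS:
        raise ValueError(f"predictor must be one of {_PREDICTORS}")
    wide = participant_means(table)
    wide = wide[wide["group"] == "CI"]
    pred_map = {}
    for p in participants:
        if p.group != "CI":
            continue
        pred_map[p.id] = (
            p.onset_age_coded() if predictor == "onset_age" else p.deafness_duration
        )
    wide = wide[wide["participant_id"].isin(pred_map)].copy()
    if outcome == "AVsync_minus_V":
        y = wide["AVsync"] - wide["V"]
    else:
        y = wide[outcome[0]]  # "V_CI" -> "V", "A_CI" -> "A"
    x = wide["participant_id"].map(pred_map).astype(float)
    keep = y.notna() & x.notna()
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 4:
        raise ValueError(f"need at least 4 CI participants, got {n}")
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError("predictor has zero variance")
    res = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    return RegressionResult(
        outcome=outcome,
        predictor=predictor,
        n=n,
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        t=float(res.tvalues[1]),
        df=n - 2,
        p=float(res.pvalues[1]),
    )
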