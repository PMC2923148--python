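"""Multivariate regression of gene expression on protein composition.

Per-gene predictors are per-residue averages over the encoded protein
(biosynthetic cost, atomic carbon/nitrogen/sulphur content, tRNA gene
number) together with the codon adaptation index (CAI).  Expression —
transcript or protein level — is regressed on these predictors plus
experimental-condition fixed effects and predictor-by-condition interaction
terms.  Interaction terms are pruned by backward stepwise selection on AIC,
and each focal predictor's importance is the AIC increase caused by
removing it (with its interactions) from the full model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .properties import ONE_TO_THREE, AminoAcidPropertyTable

FOCAL_PREDICTORS = ("cost", "cai", "trna", "carbon", "nitrogen", "sulphur")

#: Importance values beyond this are reported capped (perfect-fit guard).
IMPORTANCE_CAP = 1e6


class RankDeficientDesignError(ValueError):
    """The design matrix is rank deficient (collinear columns named)."""


@dataclass
class GeneFeatureRecord:
    """Per-gene response and per-residue predictor averages."""

    gene: str
    length: int
    cai: float
    mean_cost: float
    mean_carbon: float
    mean_nitrogen: float
    mean_sulphur: float
    mean_trna: float
    response: float | None = None
    condition: str | None = None


def compute_features(protein: str, cai: float,
                     properties: AminoAcidPropertyTable,
                     cost: pd.Series, gene: str = "") -> GeneFeatureRecord:
    """Per-residue feature averages for one protein sequence.

    ``cost`` maps residues (1- or 3-letter, lower-case 3-letter index as in
    cost tables) to the chosen cost measure.  Averages are totals divided by
    protein length; stop codons must already be excluded.
    """
    seq = protein.strip().upper().rstrip("*")
    if not seq:
        raise ValueError("empty protein sequence")
    if not (0 < cai <= 1):
        raise ValueError(f"CAI must be in (0, 1], got {cai}")
    unknown = sorted(set(seq) - set(ONE_TO_THREE))
    if unknown:
        raise ValueError(f"unknown residue characters {unknown} in {gene or 'sequence'}")
    from .properties import RESIDUES_1, THREE_TO_ONE
    cost_by_one = {}
    for key, value in cost.items():
        one = THREE_TO_ONE[key.lower()] if len(key) == 3 else key.upper()
        cost_by_one[one] = value
    missing_cost = set(seq) - set(cost_by_one)
    if missing_cost:
        raise ValueError(f"cost table lacks residues {sorted(missing_cost)}")
    n = len(seq)
    # residue counts via byte-level histogram (fast for long proteins)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    counts = np.bincount(codes, minlength=128)[
        [ord(ch) for ch in RESIDUES_1]].astype(float)
    prop = properties.frame.loc[list(RESIDUES_1)]
    cost_vec = np.array([cost_by_one[ch] for ch in RESIDUES_1], dtype=float)
    return GeneFeatureRecord(
        gene=gene, length=n, cai=cai,
        mean_cost=float(counts @ cost_vec) / n,
        mean_carbon=float(counts @ prop["carbon"].to_numpy(float)) / n,
        mean_nitrogen=float(counts @ prop["nitrogen"].to_numpy(float)) / n,
        mean_sulphur=float(counts @ prop["sulphur"].to_numpy(float)) / n,
        mean_trna=float(counts @ prop["trna_genes"].to_numpy(float)) / n,
    )


def transform_and_scale(column: Sequence[float], log_first: bool = False) -> np.ndarray:
    """Center a column and divide by the root mean square of the centered values.

    With ``log_first`` the natural logarithm is applied before scaling
    (requires strictly positive values).  The output has mean 0 and RMS 1.
    """
    x = np.asarray(column, dtype=float)
    if log_first:
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
    centered = x - x.mean()
    rms = np.sqrt(np.mean(centered ** 2))
    if rms == 0:
        raise ValueError("zero-variance column cannot be scaled")
    return centered / rms


def log_scale_column(column: Sequence[float]) -> np.ndarray:
    """Log-transform then scale, tolerating zeros with a pseudocount.

    Per-residue averages such as sulphur content can be exactly zero for
    proteins lacking cysteine and methionine; those columns get a
    pseudocount of half the smallest positive value before the log.
    """
    x = np.asarray(column, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative values cannot be log-transformed")
    if np.any(x == 0):
        positive = x[x > 0]
        if len(positive) == 0:
            raise ValueError("all-zero column cannot be log-transformed")
        x = x + positive.min() / 2.0
    return transform_and_scale(x, log_first=True)


def records_to_frame(records: Iterable[GeneFeatureRecord]) -> pd.DataFrame:
    """Raw (untransformed) feature table from records."""
    rows = []
    for r in records:
        rows.append({"gene": r.gene, "response": r.response, "cai": r.cai,
                     "cost": r.mean_cost, "carbon": r.mean_carbon,
                     "nitrogen": r.mean_nitrogen, "sulphur": r.mean_sulphur,
                     "trna": r.mean_trna, "condition": r.condition})
    return pd.DataFrame(rows)


def prepare_features(frame: pd.DataFrame, response_kind: str = "protein",
                     predictors: Sequence[str] = FOCAL_PREDICTORS) -> pd.DataFrame:
    """Model-ready table: log+scale predictors; scale the response.

    Protein responses are log-transformed before scaling; transcript
    responses are scaled only (they arrive already on a log-like scale from
    upstream normalization).
    """
    if response_kind not in ("protein", "transcript"):
        raise ValueError("response_kind must be 'protein' or 'transcript'")
    out = frame.copy()
    for col in predictors:
        out[col] = log_scale_column(frame[col])
    out["response"] = transform_and_scale(
        frame["response"], log_first=response_kind == "protein")
    return out


@dataclass
class ModelSpec:
    """What enters the regression formula."""

    response: str = "response"
    predictors: tuple[str, ...] = FOCAL_PREDICTORS
    condition_cols: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()  # e.g. ("cost:C(condition)",)

    def formula(self, drop: str | None = None,
                drop_interactions: Sequence[str] = ()) -> str:
        terms = [p for p in self.predictors if p != drop]
        terms += [f"C({c})" for c in self.condition_cols]
        for term in self.interactions:
            if term in drop_interactions:
                continue
            if drop is not None and term.split(":")[0] == drop:
                continue
            terms.append(term)
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class RegressionReport:
    """Fit summary: adjusted R^2, coefficients, AIC, importance by removal."""

    spec: ModelSpec
    data: pd.DataFrame = field(repr=False)
    adj_r2: float
    aic: float
    params: pd.Series
    retained_interactions: tuple[str, ...]
    result: object = field(repr=False)
    importance: pd.Series | None = None
    importance_capped: dict[str, bool] | None = None


def _check_rank(result) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = result.model.exog_names
        _, r = np.linalg.qr(exog)
        dependent = [names[j] for j in range(exog.shape[1])
                     if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {exog.shape[1]}; "
            f"collinear columns: {dependent or names}")


def _fit(spec: ModelSpec, data: pd.DataFrame, drop: str | None = None,
         drop_interactions: Sequence[str] = (), check_rank: bool = True):
    result = smf.ols(spec.formula(drop, drop_interactions), data=data).fit()
    if check_rank:
        _check_rank(result)
    return result


def fit_expression_model(data: pd.DataFrame,
                         predictors: Sequence[str] = FOCAL_PREDICTORS,
                         condition_cols: Sequence[str] = (),
                         interactions: Sequence[str] | str = "all",
                         response: str = "response") -> RegressionReport:
    """OLS fit of expression on composition predictors and condition effects.

    ``interactions="all"`` starts from every predictor-by-condition term;
    pass an explicit list (``"cost:C(condition)"`` style) or ``()`` to
    control the initial set.  ``data`` must already be transformed/scaled
    (see :func:`prepare_features`).
    """
    n_params_upper = len(predictors) + 2
    if len(data) < n_params_upper:
        raise ValueError(f"need at least {n_params_upper} observations")
    if data[list(predictors) + [response]].isna().any().any():
        raise ValueError("missing values in predictors or response")
    if interactions == "all":
        interactions = tuple(f"{p}:C({c})" for p in predictors
                             for c in condition_cols)
    spec = ModelSpec(response=response, predictors=tuple(predictors),
                     condition_cols=tuple(condition_cols),
                     interactions=tuple(interactions))
    result = _fit(spec, data)
    return RegressionReport(
        spec=spec, data=data, adj_r2=float(result.rsquared_adj),
        aic=float(result.aic), params=result.params,
        retained_interactions=spec.interactions, result=result,
    )


def prune_interactions(report: RegressionReport) -> RegressionReport:
    """Backward stepwise removal of interaction terms by AIC.

    Main effects are never dropped.  At each step the removal that most
    decreases AIC is applied (ties broken by term name order) until no
    removal decreases it.
    """
    spec = report.spec
    data = report.data
    retained = list(spec.interactions)
    removed: list[str] = []
    current = _fit(spec, data, drop_interactions=removed, check_rank=False)
    while retained:
        candidates = []
        for term in sorted(retained):
            trial = _fit(spec, data, drop_interactions=removed + [term],
                         check_rank=False)
            candidates.append((trial.aic, term))
        best_aic, best_term = min(candidates)  # name order breaks AIC ties
        if best_aic >= current.aic:
            break
        removed.append(best_term)
        retained.remove(best_term)
        current = _fit(spec, data, drop_interactions=removed, check_rank=False)
    new_spec = ModelSpec(response=spec.response, predictors=spec.predictors,
                         condition_cols=spec.condition_cols,
                         interactions=tuple(t for t in spec.interactions
                                            if t not in removed))
    result = _fit(new_spec, data, check_rank=False)
    return RegressionReport(
        spec=new_spec, data=data, adj_r2=float(result.rsquared_adj),
        aic=float(result.aic), params=result.params,
        retained_interactions=new_spec.interactions, result=result,
    )


def variable_importance(report: RegressionReport) -> RegressionReport:
    """Removal-based importance: dAIC = AIC(model without term) - AIC(full).

    Each focal predictor is removed together with its interaction terms;
    positive dAIC means the predictor contributes explanatory power.
    Divergent values (perfect-fit degeneracy) are capped and flagged.
    """
    spec = report.spec
    full_aic = report.aic
    endog = np.asarray(report.result.model.endog, dtype=float)
    tss = float(np.sum((endog - endog.mean()) ** 2))
    # an (effectively) zero-residual fit makes the AIC of the full model
    # diverge to -inf up to round-off; differences against it are meaningless
    perfect_fit = report.result.ssr <= 1e-10 * max(tss, 1e-300)
    importance = {}
    capped = {}
    for predictor in spec.predictors:
        reduced = _fit(spec, report.data, drop=predictor, check_rank=False)
        delta = float(reduced.aic - full_aic)
        diverged = (not np.isfinite(delta) or abs(delta) > IMPORTANCE_CAP
                    or (perfect_fit and delta > 100.0))
        if diverged:
            capped[predictor] = True
            delta = IMPORTANCE_CAP if (not np.isfinite(delta) or delta > 0) \
                else -IMPORTANCE_CAP
        else:
            capped[predictor] = False
        importance[predictor] = delta
    report.importance = pd.Series(importance)
    report.importance_capped = capped
    return report
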