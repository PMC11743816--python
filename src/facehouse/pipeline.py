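"""Association models linking cohort behavior to brain summaries.

Implements the analysis families of the study: behavioral QC of reaction
times, social-competence models (subscale ~ age + sex, permutation p,
Bonferroni m=4), emotion-labeling models (accuracy/RT ~ age + sex
[+ subscales], permutation p, Bonferroni m=10), ROI extraction and
task-activation tests (one-sample t, BH-FDR within contrast), and
segment/ROI association models (BH-FDR within contrast family).

Behavioral outcomes are skewed, so their families use residual-based
permutation p values; brain summary outcomes use parametric p values (both
switchable per call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EMOTIONS, SUBSCALES
from .inference import (
    adjust_bonferroni,
    adjust_fdr_bh,
    fit_ols,
    residual_permutation_test,
)

#: Which emotion-labeling measures feed the brain models of each contrast.
CONTRAST_EMOTION = {
    "happy>neutral": "happy",
    "fearful>neutral": "fearful",
    "fearful>happy": "fearful",
    "faces>houses": "overall",
}


@dataclass
class AtlasLabelMap:
    """Integer parcellation (0 = background) with region names."""

    labels: np.ndarray
    names: dict  # label int -> region name


@dataclass
class AssociationReport:
    """One adjustment family of linear-model tests.

    ``table`` has one row per (outcome, term) with columns: outcome, term,
    beta, se, t, df, p, p_method, m, threshold/p_adj, significant.
    """

    family: str
    predictor_set: str
    table: pd.DataFrame
    adjust_method: str
    m: int
    alpha: float

    def summary(self) -> str:
        head = (
            f"Family {self.family!r} (predictors: {self.predictor_set}; "
            f"adjustment: {self.adjust_method}, m={self.m}, alpha={self.alpha})"
        )
        with pd.option_context("display.width", 120):
            return head + "\n" + self.table.to_string(index=False)


def qc_reaction_times(
    cohort: pd.DataFrame, sd_threshold: float = 10.0, min_trials: int = 2
) -> tuple:
    """Exclude children with extreme single-trial-based median RTs.

    A child is excluded when, for any emotion, the median RT rests on fewer
    than ``min_trials`` correct trials AND lies more than ``sd_threshold``
    group standard deviations from the group mean.  Returns the filtered
    table and an exclusion log.
    """
    drop = []
    log_rows = []
    for emo in EMOTIONS:
        rt = cohort[f"rt_{emo}"]
        basis = cohort[f"n_correct_basis_{emo}"]
        mean, sd = rt.mean(), rt.std()
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (rt - mean) / sd
        flag = (basis < min_trials) & (z.abs() > sd_threshold) & rt.notna()
        for i in cohort.index[flag]:
            drop.append(i)
            log_rows.append(
                {
                    "child_id": cohort.loc[i, "child_id"],
                    "emotion": emo,
                    "rt_ms": float(rt[i]),
                    "n_trials": int(basis[i]),
                    "z": float(z[i]),
                }
            )
    filtered = cohort.drop(index=sorted(set(drop))).reset_index(drop=True)
    return filtered, pd.DataFrame(log_rows, columns=["child_id", "emotion", "rt_ms", "n_trials", "z"])


def _model_rows(
    cohort,
    outcome,
    predictors,
    terms,
    permutation=True,
    n_perm=10_000,
    seed=0,
):
    """Fit one model; return a result row per tested term."""
    rows = []
    for k, term in enumerate(terms):
        if permutation:
            fit, perm = residual_permutation_test(
                cohort[outcome], predictors, term, n_perm=n_perm, seed=seed + k
            )
            p = perm.p_permuted
            method = "permutation"
        else:
            fit = fit_ols(cohort[outcome], predictors)
            p = 2.0 * stats.t.sf(abs(float(fit.tvalues[term])), fit.df_resid)
            method = "parametric"
        rows.append(
            {
                "outcome": outcome,
                "term": term,
                "beta": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "t": float(fit.tvalues[term]),
                "df": int(fit.df_resid),
                "p": float(p),
                "p_method": method,
            }
        )
    return rows


def run_social_competence_models(
    cohort: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    permutation: bool = True,
) -> AssociationReport:
    """Subscale ~ age + sex, one model per subscale (Bonferroni m=4)."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 children")
    rows = []
    for i, subscale in enumerate(SUBSCALES):
        rows += _model_rows(
            cohort,
            subscale,
            cohort[["age", "sex"]],
            ("age", "sex"),
            permutation=permutation,
            n_perm=n_perm,
            seed=seed + 100 * i,
        )
    m = len(SUBSCALES)
    thr = adjust_bonferroni(alpha, m)
    table = pd.DataFrame(rows)
    table["threshold"] = thr
    table["significant"] = table["p"] < thr
    return AssociationReport(
        family="social_competence",
        predictor_set="age_sex",
        table=table,
        adjust_method="bonferroni_threshold",
        m=m,
        alpha=alpha,
    )


def run_emotion_labeling_models(
    cohort: pd.DataFrame,
    include_social_competence: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    permutation: bool = True,
) -> AssociationReport:
    """Accuracy and RT ~ age + sex [+ subscales], 10 models (Bonferroni m=10).

    RT models use listwise deletion, so their residual df varies with the
    number of children lacking any correct trial for that emotion.
    """
    predictors = ["age", "sex"] + (list(SUBSCALES) if include_social_competence else [])
    terms = tuple(predictors)
    rows = []
    outcomes = [f"acc_{e}" for e in EMOTIONS] + [f"rt_{e}" for e in EMOTIONS]
    for i, outcome in enumerate(outcomes):
        rows += _model_rows(
            cohort,
            outcome,
            cohort[predictors],
            terms,
            permutation=permutation,
            n_perm=n_perm,
            seed=seed + 100 * i,
        )
    m = len(outcomes)
    thr = adjust_bonferroni(alpha, m)
    table = pd.DataFrame(rows)
    table["threshold"] = thr
    table["significant"] = table["p"] < thr
    return AssociationReport(
        family="emotion_labeling",
        predictor_set="age_sex" + ("+social_competence" if include_social_competence else ""),
        table=table,
        adjust_method="bonferroni_threshold",
        m=m,
        alpha=alpha,
    )


def rectangular_parcellation(shape: tuple, splits: tuple = (2, 2, 2)) -> AtlasLabelMap:
    """Split a grid into labeled rectangular regions (synthetic atlas)."""
    labels = np.zeros(shape, dtype=np.int32)
    names = {}
    edges = [np.linspace(0, s, n + 1).astype(int) for s, n in zip(shape, splits)]
    lab = 1
    for i in range(splits[0]):
        for j in range(splits[1]):
            for k in range(splits[2]):
                labels[
                    edges[0][i] : edges[0][i + 1],
                    edges[1][j] : edges[1][j + 1],
                    edges[2][k] : edges[2][k + 1],
                ] = lab
                names[lab] = f"roi_{i}{j}{k}"
                lab += 1
    return AtlasLabelMap(labels=labels, names=names)


def extract_roi_means(atlas: AtlasLabelMap, contrast_maps: dict) -> pd.DataFrame:
    """Mean contrast value per subject x ROI (NaN when ROI misses the mask)."""
    labs = sorted(atlas.names)
    rows = {}
    for sid, vol in contrast_maps.items():
        vol = np.asarray(vol, dtype=float)
        if vol.shape != atlas.labels.shape:
            raise ValueError(f"grid mismatch for subject {sid!r}")
        row = []
        for lab in labs:
            vals = vol[atlas.labels == lab]
            vals = vals[np.isfinite(vals)]
            row.append(vals.mean() if len(vals) else np.nan)
        rows[sid] = row
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[atlas.names[lab] for lab in labs]
    )


def roi_task_activation(roi_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t test of mean activation vs 0 per ROI, BH-FDR adjusted."""
    if len(roi_table) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for roi in roi_table.columns:
        vals = roi_table[roi].dropna().to_numpy()
        if len(vals) < 2:
            t = p = np.nan
            zero_var = False
        else:
            sd = vals.std(ddof=1)
            zero_var = sd == 0
            if zero_var:
                t = np.inf * np.sign(vals.mean()) if vals.mean() else 0.0
                p = 0.0 if vals.mean() else 1.0
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
        rows.append(
            {
                "roi": roi,
                "n": int(roi_table[roi].notna().sum()),
                "t": float(t),
                "p": float(p),
                "zero_variance": bool(zero_var),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = adjust_fdr_bh(out["p"].fillna(1.0))
    out["significant"] = out["p_fdr"] < alpha
    return out


def _overall_labeling(cohort: pd.DataFrame) -> pd.DataFrame:
    """Valence-independent labeling skill: total correct and the median of
    the per-emotion median RTs."""
    acc = cohort[[f"acc_{e}" for e in EMOTIONS]].sum(axis=1)
    rt = cohort[[f"rt_{e}" for e in EMOTIONS]].median(axis=1)
    return pd.DataFrame({"acc_overall": acc, "rt_overall": rt})


def run_brain_association_models(
    brain_means: pd.DataFrame,
    cohort: pd.DataFrame,
    contrast: str,
    predictor_set: str = "age_sex",
    alpha: float = 0.05,
    permutation: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AssociationReport:
    """Per segment/ROI: mean beta ~ age + sex [+ labeling | + subscales].

    ``brain_means`` is subjects x segments/ROIs (index = child_id).  The
    emotion-labeling predictor pair is matched to the contrast (happy
    measures for happy>neutral, fearful for the fearful contrasts, overall
    for faces>houses).  P values are BH-FDR adjusted within the contrast
    family; parametric by default.
    """
    if contrast not in CONTRAST_EMOTION:
        raise ValueError(f"unknown contrast tag {contrast!r}")
    cohort = cohort.set_index("child_id") if "child_id" in cohort.columns else cohort
    common = brain_means.index.intersection(cohort.index)
    if len(common) < 4:
        raise ValueError("too few subjects shared between brain and cohort tables")
    brain = brain_means.loc[common]
    beh = cohort.loc[common].copy()

    predictors = beh[["age", "sex"]].copy()
    if predictor_set == "age_sex":
        pass
    elif predictor_set == "emotion_labeling":
        emo = CONTRAST_EMOTION[contrast]
        if emo == "overall":
            overall = _overall_labeling(beh)
            predictors["acc_overall"] = overall["acc_overall"]
            predictors["rt_overall"] = overall["rt_overall"]
        else:
            predictors[f"acc_{emo}"] = beh[f"acc_{emo}"]
            predictors[f"rt_{emo}"] = beh[f"rt_{emo}"]
    elif predictor_set == "social_competence":
        for s in SUBSCALES:
            predictors[s] = beh[s]
    else:
        raise ValueError(f"unknown predictor_set {predictor_set!r}")

    terms = [c for c in predictors.columns]
    rows = []
    for i, target in enumerate(brain.columns):
        df_model = predictors.copy()
        df_model["_y"] = brain[target]
        rows += [
            dict(r, outcome=target)
            for r in _model_rows(
                df_model,
                "_y",
                df_model[terms],
                tuple(terms),
                permutation=permutation,
                n_perm=n_perm,
                seed=seed + 100 * i,
            )
        ]
    table = pd.DataFrame(rows)
    # FDR within the contrast family, per tested term
    table["p_fdr"] = np.nan
    for term in terms:
        sel = table["term"] == term
        table.loc[sel, "p_fdr"] = adjust_fdr_bh(table.loc[sel, "p"])
    table["significant"] = table["p_fdr"] < alpha
    return AssociationReport(
        family=f"brain:{contrast}",
        predictor_set=predictor_set,
        table=table,
        adjust_method="bh_fdr",
        m=int(brain.shape[1]),
        alpha=alpha,
    )
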