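"""Labeling, nested cross-validated linear-SVM evaluation and comparisons.

Each subject's ordered stages are split in half: first half (with the
baseline) labeled normal, second half abnormal, with the final stage
(decompensation onset) excluded from training. A continuous severity
index runs from 0 at baseline to 0.8 at the last retained stage,
quantized to the five levels {0, 0.2, 0.4, 0.6, 0.8}.

Evaluation uses subject-wise outer 10-fold cross-validation with an
inner 10-fold grid search over the SVM cost parameter by mean AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.svm import LinearSVC

from .datatypes import META_COLUMNS
from .features.hrv import TYPICAL_HRV_FEATURES
from . import extract as extract_mod
from . import selection as selection_mod

SEVERITY_LEVELS = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-10, 5, 2))
N_FOLDS = 10


@dataclass
class LabelScheme:
    """Per-subject window labeling derived from the ordered stage list."""

    n_stages: int
    labels: dict            # stage -> "normal" | "abnormal" | None (excluded)
    severity: dict          # stage -> quantized level (final stage -> 1.0)
    usable: bool            # False when the abnormal class is empty


@dataclass
class CvReport:
    folds: pd.DataFrame                       # fold, auc, accuracy, sensitivity, specificity, C
    aggregates: dict = field(default_factory=dict)  # metric -> (mean, ci_halfwidth)
    n: int = 0

    def summary(self) -> dict:
        out = {"n": self.n}
        for metric, (mean, ci) in self.aggregates.items():
            out[metric] = mean
            out[f"{metric}_ci"] = ci
        return out


def _snap_severity(value: float) -> float:
    diffs = np.abs(SEVERITY_LEVELS - value)
    idx = np.flatnonzero(diffs == diffs.min())[-1]  # ties round up
    return float(SEVERITY_LEVELS[idx])


def make_labels(stages) -> LabelScheme:
    """Half-split labels and quantized severity for one subject's stages."""
    stages = list(stages)
    L = len(stages)
    if L < 2:
        raise ValueError("need at least 2 stages (baseline + one stress stage)")
    n_normal = math.ceil(L / 2)
    labels, severity = {}, {}
    for i, stage in enumerate(stages):
        if i < n_normal:
            labels[stage] = "normal"
        elif i <= L - 2:
            labels[stage] = "abnormal"
        else:
            labels[stage] = None           # final stage excluded from training
        if i == L - 1:
            severity[stage] = 1.0          # collapse point
        elif L == 2:
            severity[stage] = 0.0
        else:
            severity[stage] = _snap_severity(0.8 * i / (L - 2))
    usable = any(v == "abnormal" for v in labels.values())
    return LabelScheme(n_stages=L, labels=labels, severity=severity, usable=usable)


def label_table(table: pd.DataFrame, n_stages: dict[str, int] | None = None) -> pd.DataFrame:
    """Fill label/severity columns from per-subject stage schemes.

    Windows of each subject's final stage (and subjects with no abnormal
    stage) are dropped — they carry no training label.
    """
    n_stages = n_stages or table.attrs.get("n_stages")
    if n_stages is None:
        raise ValueError("per-subject stage counts unavailable")
    if table.empty:
        raise ValueError("feature table is empty; nothing to label")
    out = table.copy()
    keep = np.ones(len(out), dtype=bool)
    for sid, grp in out.groupby("subject_id", sort=False):
        scheme = make_labels(range(n_stages[sid]))
        if not scheme.usable:
            warnings.warn(f"subject {sid!r} unusable for classification (too few stages)")
            keep[grp.index] = False
            continue
        for idx, stage in zip(grp.index, grp["stage"]):
            lbl = scheme.labels.get(int(stage))
            if lbl is None:
                keep[out.index.get_loc(idx)] = False
            else:
                out.loc[idx, "label"] = lbl
                out.loc[idx, "severity"] = scheme.severity[int(stage)]
    out = out[keep].reset_index(drop=True)
    out.attrs["n_stages"] = n_stages
    return out


def _impute_standardize(X_train, X_other):
    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)

    def fill(X):
        X = X.copy()
        mask = ~np.isfinite(X)
        X[mask] = np.broadcast_to(med, X.shape)[mask]
        return X

    X_train = fill(X_train)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (fill(X_other) - mu) / sd


def _fit_eval(X_tr, y_tr, X_va, y_va, C):
    clf = LinearSVC(C=C, loss="squared_hinge", dual=True, max_iter=50000, tol=1e-5,
                    random_state=0)
    clf.fit(X_tr, y_tr)
    score = clf.decision_function(X_va)
    pred = (score > 0).astype(int)
    auc = roc_auc_score(y_va, score)
    acc = 100.0 * float(np.mean(pred == y_va))
    pos, neg = y_va == 1, y_va == 0
    sens = 100.0 * float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    spec = 100.0 * float(np.mean(pred[neg] == 0)) if neg.any() else float("nan")
    return auc, acc, sens, spec


def _two_class_folds(subjects, subj_col, y, n_folds, seed, max_tries=50):
    """Subject-wise fold split where every fold sees both classes."""
    for t in range(max_tries):
        folds = selection_mod._subject_fold_split(subjects, n_folds, seed + t)
        ok = all(len(np.unique(y[np.isin(subj_col, f)])) == 2 for f in folds)
        if ok:
            if t:
                warnings.warn(f"single-class fold; reshuffled {t} time(s)")
            return folds
    raise RuntimeError("could not build two-class subject-wise folds")


def nested_cv_svm(table: pd.DataFrame, feature_group: list[str], seed: int = 0,
                  C_grid=DEFAULT_C_GRID, n_folds: int = N_FOLDS) -> CvReport:
    """Outer 10-fold subject-wise CV with inner 10-fold cost tuning by AUC."""
    y = (table["label"].to_numpy() == "abnormal").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    subj = table["subject_id"].to_numpy()
    subjects = np.unique(subj)
    if len(subjects) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects for {n_folds}-fold CV")
    X = table[list(feature_group)].to_numpy(dtype=float)

    outer = _two_class_folds(subjects, subj, y, n_folds, seed)
    rows = []
    for fold_id, val_subjects in enumerate(outer):
        val_mask = np.isin(subj, val_subjects)
        train_mask = ~val_mask
        assert not np.any(val_mask & train_mask), "subject leaked across folds"
        tr_subjects = subjects[~np.isin(subjects, val_subjects)]

        if len(C_grid) == 1:
            best_C = C_grid[0]
        else:
            inner = _two_class_folds(tr_subjects, subj[train_mask], y[train_mask],
                                     n_folds, seed + 1000 + fold_id)
            mean_aucs = []
            for C in C_grid:
                aucs = []
                for inner_val in inner:
                    iv = np.isin(subj, inner_val) & train_mask
                    it = train_mask & ~iv
                    Xi, Xv = _impute_standardize(X[it], X[iv])
                    auc, *_ = _fit_eval(Xi, y[it], Xv, y[iv], C)
                    aucs.append(auc)
                mean_aucs.append(np.mean(aucs))
            best_C = C_grid[int(np.argmax(mean_aucs))]

        X_tr, X_va = _impute_standardize(X[train_mask], X[val_mask])
        auc, acc, sens, spec = _fit_eval(X_tr, y[train_mask], X_va, y[val_mask], best_C)
        rows.append({"fold": fold_id, "auc": auc, "accuracy": acc,
                     "sensitivity": sens, "specificity": spec, "C": best_C})

    folds = pd.DataFrame(rows)
    aggregates = {}
    for metric in ("auc", "accuracy", "sensitivity", "specificity"):
        vals = folds[metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        mean = float(np.mean(vals))
        if len(vals) > 1:
            ci = float(sps.t.ppf(0.975, len(vals) - 1) * np.std(vals, ddof=1) / np.sqrt(len(vals)))
        else:
            ci = float("nan")
        aggregates[metric] = (mean, ci)
    return CvReport(folds=folds, aggregates=aggregates, n=len(table))


def compare_feature_sets(report_a: CvReport, report_b: CvReport, metric: str = "auc",
                         alpha: float = 0.01) -> dict:
    """Two-sided Mann-Whitney U on fold-level metrics of two reports."""
    a = report_a.folds[metric].to_numpy(dtype=float)
    b = report_b.folds[metric].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 folds per side")
    if np.array_equal(a, b):
        return {"metric": metric, "u_statistic": len(a) * len(b) / 2.0,
                "p_value": 1.0, "significant": False}
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic" if has_ties else "exact")
    return {"metric": metric, "u_statistic": float(res.statistic),
            "p_value": float(res.pvalue), "significant": bool(res.pvalue < alpha)}


def reduced_featureset_curve(table: pd.DataFrame, ranked_features: list[str],
                             sizes=(2, 4, 6, 8, 10), seed: int = 0,
                             C_grid=DEFAULT_C_GRID) -> dict[int, CvReport]:
    """Nested CV on each prefix of the feature ranking."""
    if len(ranked_features) < max(sizes):
        raise ValueError("ranking shorter than the largest requested size")
    return {size: nested_cv_svm(table, ranked_features[:size], seed=seed, C_grid=C_grid)
            for size in sizes}


def fit_severity_regression(table: pd.DataFrame, selected: list[str]) -> pd.DataFrame:
    """OLS of severity on the selected features; per-level predictions + CIs."""
    X = table[list(selected)].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    mask = ~np.isfinite(X)
    X[mask] = np.broadcast_to(med, X.shape)[mask]
    design = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    y = table["severity"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ beta
    rows = []
    for level in SEVERITY_LEVELS:
        sel = np.isclose(y, level)
        if not sel.any():
            continue
        vals = pred[sel]
        ci = (sps.t.ppf(0.975, len(vals) - 1) * np.std(vals, ddof=1) / np.sqrt(len(vals))
              if len(vals) > 1 else float("nan"))
        rows.append({"level": float(level), "n": int(sel.sum()),
                     "predicted_mean": float(vals.mean()), "ci_halfwidth": float(ci)})
    return pd.DataFrame(rows)


def evaluate_window_size_sweep(records, sizes=tuple(range(30, 241, 30)), seed: int = 0,
                               k: int = 10, C_grid=DEFAULT_C_GRID,
                               config: "extract_mod.ExtractConfig | None" = None) -> pd.DataFrame:
    """Re-run extraction + selection + nested CV per window size and feature set.

    Returns a table shaped like the published comparison: one row per
    (size, feature set) with fold-averaged metrics. Sizes exceeding a
    record's beat count are skipped with a warning.
    """
    records = list(records)
    rows = []
    for size in sizes:
        cfg = extract_mod.ExtractConfig(**{**(config.__dict__ if config else {}),
                                           "beats_per_window": size})
        try:
            table = extract_mod.build_feature_table(records, cfg)
        except ValueError as err:
            warnings.warn(f"window size {size} skipped: {err}")
            continue
        if table.empty:
            warnings.warn(f"window size {size} skipped: no complete windows")
            continue
        table = label_table(table)
        report = selection_mod.select_features(table, response="severity", k=k, seed=seed)
        presented = nested_cv_svm(table, report.selected, seed=seed, C_grid=C_grid)
        typical = nested_cv_svm(table, TYPICAL_HRV_FEATURES, seed=seed, C_grid=C_grid)
        for name, rep in (("presented", presented), ("typical_hrv", typical)):
            row = {"size": size, "features": name, **rep.summary()}
            rows.append(row)
    return pd.DataFrame(rows)


def presented_feature_columns(table: pd.DataFrame) -> list[str]:
    """All feature columns except the traditional HRV baseline group."""
    return [c for c in table.columns
            if c not in META_COLUMNS and c not in TYPICAL_HRV_FEATURES]
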