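"""Two-stage feature selection.

Stage 1 removes redundant features greedily from the subject-averaged
absolute correlation matrix (threshold 0.9). Stage 2 runs forward
stepwise selection maximizing mean training-fold R-squared under 10-fold
subject-wise cross-validation, then refits on all data for coefficient
statistics and variance inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import META_COLUMNS

REDUNDANCY_THRESHOLD = 0.9


@dataclass
class SelectionReport:
    removed: list[tuple[str, int]]            # (feature, redundancy count at removal)
    selected: list[str]                        # in order of entry
    stats: pd.DataFrame = None                 # Term/Estimate/StdError/tRatio/p/VIF
    step_r2: list[float] = field(default_factory=list)  # mean train R2 per step


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def mean_correlation_matrix(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Subject-averaged absolute Pearson correlation between features.

    Subjects contribute their within-subject |correlation|; entries that
    are undefined for a subject (constant feature there) are excluded
    from the average. A feature undefined for every subject is flagged
    maximally redundant (row/column forced to 1).
    """
    features = features or feature_columns(table)
    p = len(features)
    acc = np.zeros((p, p))
    cnt = np.zeros((p, p))
    for _, sub in table.groupby("subject_id", sort=True):
        if len(sub) < 2:
            warnings.warn(f"subject {sub['subject_id'].iloc[0]!r} has <2 windows; skipped")
            continue
        X = sub[features].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(np.corrcoef(X, rowvar=False))
        ok = np.isfinite(c)
        acc[ok] += c[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = acc / cnt
    dead = cnt.diagonal() == 0
    mean[dead, :] = 1.0
    mean[:, dead] = 1.0
    np.fill_diagonal(mean, 1.0)
    mean[np.isnan(mean)] = 0.0  # pair never jointly defined: no evidence of redundancy
    return pd.DataFrame(mean, index=features, columns=features)


def greedy_redundancy_removal(corr: pd.DataFrame, threshold: float = REDUNDANCY_THRESHOLD):
    """Iteratively drop the feature with the most above-threshold partners.

    Ties break by manifest (column) order, earliest removed first. Returns
    ``(kept, removed)`` with removal-time redundancy counts.
    """
    names = list(corr.columns)
    C = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(C, 0.0)
    alive = np.ones(len(names), dtype=bool)
    removed: list[tuple[str, int]] = []
    while True:
        counts = ((C >= threshold) & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        worst = int(np.argmax(counts))
        if counts[worst] == 0:
            break
        alive[worst] = False
        removed.append((names[worst], int(counts[worst])))
    kept = [n for n, a in zip(names, alive) if a]
    return kept, removed


def _subject_fold_split(subjects: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.asarray(subjects))
    return [f for f in np.array_split(order, n_folds) if len(f)]


def _fold_train_r2(X_sel, y, candidates_mat):
    """R-squared of OLS(y ~ [1, X_sel, c]) for every candidate column c.

    Uses orthogonalization against the current design: residualize each
    candidate and the response, then score the univariate improvement.
    """
    n = len(y)
    Q, _ = np.linalg.qr(X_sel)
    y_res = y - Q @ (Q.T @ y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return np.zeros(candidates_mat.shape[1])
    rss0 = float(y_res @ y_res)
    C = candidates_mat - Q @ (Q.T @ candidates_mat)
    norms = np.einsum("ij,ij->j", C, C)
    proj = C.T @ y_res
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(norms > 1e-12 * n, proj ** 2 / norms, 0.0)
    return 1.0 - (rss0 - gain) / tss


def forward_select(table: pd.DataFrame, response: str = "severity", k: int = 10,
                   folds: int = 10, seed: int = 0,
                   candidates: list[str] | None = None) -> SelectionReport:
    """Forward stepwise selection by mean training-fold R-squared.

    At each step the candidate maximizing the mean R-squared across the
    ``folds`` subject-wise training folds joins the model; after ``k``
    steps the model is refit on all rows for Table-style statistics.
    ``response`` is ``"severity"`` (continuous) or ``"label"`` (0/1).
    """
    feats = candidates or feature_columns(table)
    if k > len(feats):
        raise ValueError(f"k={k} exceeds {len(feats)} candidate features")
    X_all = table[feats].to_numpy(dtype=float)
    med = np.nanmedian(X_all, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    nan_mask = ~np.isfinite(X_all)
    X_all[nan_mask] = np.broadcast_to(med, X_all.shape)[nan_mask]

    if response == "label":
        y_all = (table["label"].to_numpy() == "abnormal").astype(float)
    else:
        y_all = table[response].to_numpy(dtype=float)
    subj = table["subject_id"].to_numpy()

    fold_subjects = _subject_fold_split(np.unique(subj), folds, seed)
    if response == "label":
        tries = 0
        while any(len(np.unique(y_all[~np.isin(subj, f)])) < 2 for f in fold_subjects):
            tries += 1
            if tries > 50:
                raise RuntimeError("could not build two-class training folds")
            warnings.warn("single-class training fold; reshuffling with incremented seed")
            fold_subjects = _subject_fold_split(np.unique(subj), folds, seed + tries)
    train_masks = [~np.isin(subj, f) for f in fold_subjects]

    selected: list[str] = []
    selected_idx: list[int] = []
    step_r2: list[float] = []
    remaining = list(range(len(feats)))
    for _ in range(k):
        scores = np.zeros(len(remaining))
        for mask in train_masks:
            Xs = np.column_stack([np.ones(mask.sum())] +
                                 [X_all[mask, j] for j in selected_idx])
            scores += _fold_train_r2(Xs, y_all[mask], X_all[mask][:, remaining])
        scores /= len(train_masks)
        best = int(np.argmax(scores))  # ties: earliest manifest order
        step_r2.append(float(scores[best]))
        selected_idx.append(remaining[best])
        selected.append(feats[remaining[best]])
        remaining.pop(best)

    stats = fit_selected_model(table, selected, response=response,
                               _X=X_all[:, selected_idx], _y=y_all)
    return SelectionReport(removed=[], selected=selected, stats=stats, step_r2=step_r2)


def fit_selected_model(table: pd.DataFrame, selected: list[str], response: str = "severity",
                       _X: np.ndarray | None = None, _y: np.ndarray | None = None) -> pd.DataFrame:
    """Full-data OLS refit: estimates, SEs, t-ratios, p-values and VIFs."""
    if _X is None:
        _X = table[selected].to_numpy(dtype=float)
        med = np.nanmedian(_X, axis=0)
        inds = ~np.isfinite(_X)
        _X[inds] = np.broadcast_to(med, _X.shape)[inds]
    if _y is None:
        _y = ((table["label"].to_numpy() == "abnormal").astype(float)
              if response == "label" else table[response].to_numpy(dtype=float))
    model = sm.OLS(_y, sm.add_constant(pd.DataFrame(_X, columns=selected)))
    fit = model.fit()
    vifs = compute_vif_matrix(_X, selected) if len(selected) >= 2 else {s: np.nan for s in selected}
    rows = [{"term": "Intercept", "estimate": fit.params.iloc[0],
             "std_error": fit.bse.iloc[0], "t_ratio": fit.tvalues.iloc[0],
             "p_value": fit.pvalues.iloc[0], "vif": np.nan}]
    for i, name in enumerate(selected, start=1):
        rows.append({"term": name, "estimate": fit.params.iloc[i],
                     "std_error": fit.bse.iloc[i], "t_ratio": fit.tvalues.iloc[i],
                     "p_value": fit.pvalues.iloc[i], "vif": vifs[name]})
    return pd.DataFrame(rows)


def compute_vif_matrix(X: np.ndarray, names: list[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R2_j) from regressing column j on the others."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for VIF")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than features for VIF")
    out = {}
    for j, name in enumerate(names):
        others = np.column_stack([np.ones(len(X))] + [X[:, i] for i in range(X.shape[1]) if i != j])
        yj = X[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float(resid @ resid) / tss
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"perfect collinearity: {name}")
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


def compute_vif(table: pd.DataFrame, selected: list[str]) -> dict[str, float]:
    """VIF diagnostics for a set of selected features of a table."""
    X = table[selected].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    inds = ~np.isfinite(X)
    X[inds] = np.broadcast_to(med, X.shape)[inds]
    return compute_vif_matrix(X, selected)


def select_features(table: pd.DataFrame, response: str = "severity", k: int = 10,
                    folds: int = 10, seed: int = 0,
                    threshold: float = REDUNDANCY_THRESHOLD) -> SelectionReport:
    """Full two-stage pipeline: redundancy removal then forward selection."""
    corr = mean_correlation_matrix(table)
    kept, removed = greedy_redundancy_removal(corr, threshold)
    report = forward_select(table, response=response, k=k, folds=folds,
                            seed=seed, candidates=kept)
    report.removed = removed
    return report
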