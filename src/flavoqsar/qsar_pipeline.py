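"""Activity transform, descriptor selection and stepwise MLR with LOO q².

The modelling chain mirrors classic descriptor-based QSAR practice:

1. activities: FAR → pFAR = −log10(FAR) (negative = efflux inhibition);
2. z-score standardization of the descriptor matrix (sample SD, ddof=1);
3. relevance filter: drop descriptors with |Pearson r| to the activity
   below ``corr_min`` (default 0.1);
4. redundancy filter: among descriptor pairs correlated above ``pair_max``
   (default 0.85), keep the one more correlated with the activity;
5. stepwise multiple linear regression: forward entry of the candidate with
   the largest partial F when its p < p_enter (default 0.05), backward
   removal of entered descriptors whose partial p > p_remove (default
   0.10), iterated to a fixed point;
6. ordinary fit statistics (R, R², adjusted R², SEE, F) and leave-one-out
   cross-validated q² = 1 − PRESS/SST;
7. model-quality gate: compounds/descriptors ratio within 3–6, R² > 0.7,
   q² > 0.5.

The relevance cut uses |r|: a signed cut would discard strong *negative*
correlates, which the final published model demonstrably retains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord", "QSARModel", "SelectionTrace", "FitStats",
    "far_to_pfar", "standardize", "correlation_filter", "redundancy_filter",
    "stepwise_mlr", "fit_stats", "loo_q2", "validate_model",
]


# ---------------------------------------------------------------------------
# activities
# ---------------------------------------------------------------------------

@dataclass
class ActivityRecord:
    """One compound's measured P-gp modulation."""

    compound_id: str
    far: float
    pfar: float = None
    observed_class: str | None = None

    def __post_init__(self):
        if self.far is not None:
            if self.far <= 0:
                raise ValueError(f"{self.compound_id}: FAR must be > 0")
            self.pfar = far_to_pfar(self.far)


def far_to_pfar(far):
    """pFAR = −log10(FAR); strictly decreasing; defined for FAR > 0."""
    far = np.asarray(far, dtype=float)
    if np.any(far <= 0):
        raise ValueError("FAR must be strictly positive")
    out = -np.log10(far)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# standardization and the two correlation filters
# ---------------------------------------------------------------------------

def standardize(X: pd.DataFrame):
    """z-score columns (sample SD, ddof=1); drop zero-variance columns.

    Returns ``(Z, means, sds, dropped)`` where ``dropped`` lists the
    flagged constant columns.  Raises if every column is constant.
    """
    X = pd.DataFrame(X)
    if len(X) < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds <= 0
    dropped = list(X.columns[constant])
    if constant.all():
        raise ValueError("all descriptor columns are constant")
    if dropped:
        logger.info("dropping %d zero-variance columns", len(dropped))
    keep = X.columns[~constant]
    Z = (X[keep] - means[keep]) / sds[keep]
    return Z, means[keep], sds[keep], dropped


def _corr_with_y(Z: pd.DataFrame, y: np.ndarray) -> pd.Series:
    y = np.asarray(y, dtype=float)
    if len(y) != len(Z):
        raise ValueError("y length does not match descriptor matrix")
    if np.std(y) == 0:
        raise ValueError("activity vector is constant; correlation undefined")
    yc = (y - y.mean()) / y.std()
    Zc = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    return pd.Series((Zc.to_numpy().T @ yc) / len(y), index=Z.columns)


def correlation_filter(Z: pd.DataFrame, y, threshold: float = 0.1) -> list:
    """Keep columns with |Pearson r| to the activity ≥ ``threshold``.

    Column order is preserved.
    """
    r = _corr_with_y(Z, y)
    kept = [c for c in Z.columns if abs(r[c]) >= threshold]
    logger.info("correlation filter (|r| >= %.3g): %d -> %d columns",
                threshold, Z.shape[1], len(kept))
    return kept


def redundancy_filter(Z: pd.DataFrame, y, threshold: float = 0.85) -> list:
    """Greedy redundancy elimination at pairwise |r| > ``threshold``.

    Columns are visited in descending |r to activity| (ties by column
    order); a column is kept only if its pairwise correlation with every
    already-kept column is ≤ threshold.  Within any conflicting pair this
    keeps the better activity-correlate.  Deterministic; returns kept
    columns in the original column order.
    """
    r_y = _corr_with_y(Z, y).abs()
    cols = list(Z.columns)
    order = sorted(range(len(cols)), key=lambda i: (-r_y.iloc[i], i))
    C = np.abs(np.corrcoef(Z.to_numpy(), rowvar=False))
    kept_idx = []
    for i in order:
        if all(C[i, j] <= threshold for j in kept_idx):
            kept_idx.append(i)
    kept_set = set(kept_idx)
    kept = [c for i, c in enumerate(cols) if i in kept_set]
    logger.info("redundancy filter (pairwise |r| > %.3g): %d -> %d columns",
                threshold, len(cols), len(kept))
    return kept


# ---------------------------------------------------------------------------
# stepwise multiple linear regression
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Stage counts and the stepwise add/remove event log."""

    n_initial: int = 0
    n_after_correlation: int | None = None
    n_after_redundancy: int | None = None
    n_selected: int = 0
    events: list = field(default_factory=list)  # (step, action, name, F, p)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class QSARModel:
    """A fitted MLR model on z-scaled descriptors.

    ``coefficients`` act on z-scores; ``means``/``sds`` carry the training
    standardization so raw descriptor vectors can be projected later.
    """

    descriptor_names: list
    coefficients: np.ndarray
    intercept: float
    means: pd.Series
    sds: pd.Series
    n: int
    statistics: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.descriptor_names) != len(np.atleast_1d(self.coefficients)):
            raise ValueError("one coefficient per descriptor name required")

    @property
    def k(self) -> int:
        return len(self.descriptor_names)

    @property
    def compounds_per_descriptor(self) -> float:
        return self.n / self.k if self.k else np.inf

    def predict_z(self, Z) -> np.ndarray:
        Z = pd.DataFrame(Z)[self.descriptor_names].to_numpy(dtype=float)
        return Z @ np.asarray(self.coefficients) + self.intercept

    def predict_raw(self, X) -> np.ndarray:
        X = pd.DataFrame(X)[self.descriptor_names]
        Z = (X - self.means[self.descriptor_names]) / self.sds[self.descriptor_names]
        return self.predict_z(Z)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "descriptor_names": list(self.descriptor_names),
            "coefficients": [float(c) for c in np.atleast_1d(self.coefficients)],
            "intercept": float(self.intercept),
            "means": {str(k): float(v) for k, v in self.means.items()},
            "sds": {str(k): float(v) for k, v in self.sds.items()},
            "n": int(self.n),
            "statistics": {k: (float(v) if np.isscalar(v) else v)
                           for k, v in self.statistics.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QSARModel":
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            means=pd.Series(d["means"], dtype=float),
            sds=pd.Series(d["sds"], dtype=float),
            n=int(d["n"]),
            statistics=dict(d.get("statistics", {})),
        )


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (beta_with_intercept, residuals, rank)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, resid, rank, design


def stepwise_mlr(Z: pd.DataFrame, y, p_enter: float = 0.05,
                 p_remove: float = 0.10, compute_q2: bool = True,
                 trace: SelectionTrace | None = None):
    """Forward-entry/backward-removal OLS variable selection.

    Forward: among candidates, residualize each against the current design
    and add the one with the largest partial F if its p-value < p_enter.
    Backward: refit and drop any entered descriptor whose partial p >
    p_remove (worst first).  Iterates to a fixed point; ``p_enter <
    p_remove`` is enforced to rule out entry/removal cycling.  Entry is
    also stopped while it would leave fewer than 2 residual degrees of
    freedom.

    Returns ``(QSARModel, SelectionTrace)``.
    """
    if p_enter >= p_remove:
        raise ValueError(
            f"p_enter ({p_enter}) must be < p_remove ({p_remove}) "
            "to prevent cycling")
    Z = pd.DataFrame(Z)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = list(Z.columns)
    Znp = Z.to_numpy(dtype=float)
    if trace is None:
        trace = SelectionTrace(n_initial=len(cols))
    selected: list = []
    step = 0
    max_steps = 4 * len(cols) + 16
    changed = True
    while changed and step < max_steps:
        changed = False
        step += 1
        # ---- forward ----
        k = len(selected)
        dof = n - k - 2  # residual dof after adding one more column
        if dof >= 2:
            Xsel = Znp[:, [cols.index(c) for c in selected]]
            _, resid, rank, design = _ols(Xsel, y)
            if rank < design.shape[1]:
                raise np.linalg.LinAlgError(
                    f"singular design among selected columns {selected}")
            candidates = [c for c in cols if c not in selected]
            if candidates:
                Cnp = Znp[:, [cols.index(c) for c in candidates]]
                # residualize candidates against current design
                coefs, _, _, _ = np.linalg.lstsq(design, Cnp, rcond=None)
                Cperp = Cnp - design @ coefs
                norms = np.linalg.norm(Cperp, axis=0)
                rnorm = np.linalg.norm(resid)
                ok = (norms > 1e-10 * np.sqrt(n)) & (rnorm > 0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r_part = (Cperp.T @ resid) / (norms * rnorm)
                r_part = np.where(ok, r_part, 0.0)
                r2 = np.clip(r_part ** 2, 0.0, 1.0 - 1e-15)
                F = r2 * dof / (1.0 - r2)
                best = int(np.argmax(F))
                p_best = float(stats.f.sf(F[best], 1, dof))
                if ok[best] and p_best < p_enter:
                    name = candidates[best]
                    selected.append(name)
                    trace.events.append(
                        {"step": step, "action": "add", "descriptor": name,
                         "F": float(F[best]), "p": p_best})
                    changed = True
        # ---- backward ----
        while len(selected) > 0:
            Xsel = Znp[:, [cols.index(c) for c in selected]]
            beta, resid, rank, design = _ols(Xsel, y)
            if rank < design.shape[1]:
                raise np.linalg.LinAlgError(
                    f"singular design among selected columns {selected}")
            dof = n - len(selected) - 1
            if dof <= 0:
                break
            sigma2 = resid @ resid / dof
            XtX_inv = np.linalg.inv(design.T @ design)
            se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
            t = beta / se
            p_vals = 2 * stats.t.sf(np.abs(t[1:]), dof)  # skip intercept
            worst = int(np.argmax(p_vals))
            if p_vals[worst] > p_remove:
                name = selected.pop(worst)
                trace.events.append(
                    {"step": step, "action": "remove", "descriptor": name,
                     "F": float(t[1 + worst] ** 2), "p": float(p_vals[worst])})
                changed = True
            else:
                break
    if step >= max_steps:
        raise RuntimeError("stepwise selection failed to terminate")

    # final fit on the selected set
    Xsel = Znp[:, [cols.index(c) for c in selected]]
    beta, resid, rank, design = _ols(Xsel, y)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design among selected columns {selected}")
    yhat = design @ beta
    statistics = {}
    if selected and n > len(selected) + 1:
        fs = fit_stats(y, yhat, len(selected))
        statistics.update(R=fs.R, R2=fs.R2, R2_adj=fs.R2_adj,
                          SEE=fs.SEE, F=fs.F, p=fs.p)
        if compute_q2 and n > len(selected) + 2:
            statistics["q2"] = loo_q2(Z[selected], y)
    model = QSARModel(
        descriptor_names=list(selected),
        coefficients=np.asarray(beta[1:], dtype=float),
        intercept=float(beta[0]),
        means=pd.Series(0.0, index=list(selected)),
        sds=pd.Series(1.0, index=list(selected)),
        n=n,
        statistics=statistics,
    )
    trace.n_selected = len(selected)
    logger.info("stepwise selection: %d candidates -> %d descriptors",
                trace.n_initial, len(selected))
    return model, trace


# ---------------------------------------------------------------------------
# fit statistics and internal validation
# ---------------------------------------------------------------------------

@dataclass
class FitStats:
    R: float
    R2: float
    R2_adj: float
    SEE: float
    F: float
    p: float
    n: int
    k: int


def fit_stats(y_obs, y_pred, k: int) -> FitStats:
    """Regression summary for n observed/predicted pairs with k predictors.

    R is the Pearson correlation of observed with predicted; R² = 1 −
    SSE/SST; SEE = √(SSE/(n−k−1)); F = (SSR/k)/(SSE/(n−k−1)).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted lengths differ")
    n = len(y_obs)
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    sse = float(np.sum((y_obs - y_pred) ** 2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    ssr = sst - sse
    r2 = 1.0 - sse / sst
    if sse == 0.0:
        R, F, p = 1.0, np.inf, 0.0
    else:
        R = float(np.corrcoef(y_obs, y_pred)[0, 1])
        F = (ssr / k) / (sse / (n - k - 1)) if k else np.nan
        p = float(stats.f.sf(F, k, n - k - 1)) if k else np.nan
    return FitStats(
        R=R, R2=r2,
        R2_adj=1.0 - (1.0 - r2) * (n - 1) / (n - k - 1),
        SEE=float(np.sqrt(sse / (n - k - 1))),
        F=float(F), p=p, n=n, k=k,
    )


def loo_q2(Z_selected: pd.DataFrame, y) -> float:
    """Leave-one-out cross-validated q² = 1 − PRESS/SST.

    Each compound is left out in turn, the equation is refit on the
    remaining n−1 rows with the *same* descriptor set, and the held-out
    activity predicted; SST uses the full-set mean.
    """
    Z = pd.DataFrame(Z_selected).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = Z.shape
    if n <= k + 2:
        raise ValueError(f"LOO refit needs n > k+2 (n={n}, k={k})")
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        design = np.column_stack([np.ones(n - 1), Z[mask]])
        beta, _, rank, _ = np.linalg.lstsq(design, y[mask], rcond=None)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError(
                f"singular design when leaving out row {i}")
        pred_i = float(np.concatenate([[1.0], Z[i]]) @ beta)
        press += (y[i] - pred_i) ** 2
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


def validate_model(model: QSARModel) -> dict:
    """Apply the model-quality gate; returns per-criterion verdicts.

    Gated: compounds per descriptor within 3–6; R² > 0.7; q² > 0.5.
    SEE and F are echoed without thresholds (smaller SEE / larger F is
    better, but no hard cut is defensible).
    """
    s = model.statistics
    ratio = model.compounds_per_descriptor
    checks = {
        "ratio_3_to_6": bool(3.0 <= ratio <= 6.0),
        "r2_gt_0.7": bool(s.get("R2", np.nan) > 0.7),
        "q2_gt_0.5": bool(s.get("q2", np.nan) > 0.5),
    }
    return {
        "checks": checks,
        "passed": all(checks.values()),
        "ratio": float(ratio),
        "R2": s.get("R2"),
        "q2": s.get("q2"),
        "SEE": s.get("SEE"),
        "F": s.get("F"),
    }
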