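"""The published 6-descriptor pFAR equation, class rule and table fixtures.

The shipped model predicts pFAR from six z-scaled charge-weighted 3D
descriptors:

    pFAR = −0.613·RDF_PiChg_86 + 0.461·RDF_SigChg_76 − 0.283·3DACorr_TotChg_9
           + 0.207·RDF_LpEN_54 − 0.284·3DACorr_PiChg_9 − 0.197·RDF_SigChg_57
           − 0.416

fit on 23 flavonoids (R = 0.963, R² = 0.927, SEE = 0.197).  Predictions are
classified by the pFAR axis: pFAR < −1 strong inhibitor (FAR > 10),
−1 ≤ pFAR < 0 active (weak) inhibitor (1 < FAR < 10), pFAR ≥ 0 inducer.
The boundary points −1 and 0 are assigned to the milder class on each
side (left-closed convention; override via ``classify``'s ``boundaries``).

Fixtures shipped as package data: the training-set observed/predicted
pFAR table, the external 11-compound test table with observed classes, and
the 6×6 descriptor intercorrelation matrix.
"""

from __future__ import annotations

import hashlib
import json
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd

from .qsar_pipeline import fit_stats, FitStats

__all__ = [
    "ActivityClass", "EQUATION_TERMS", "EQUATION_INTERCEPT",
    "EQUATION_CHECKSUM", "load_equation", "predict_pfar", "classify",
    "concordance", "load_table2", "load_table3", "load_table4",
    "table3_metrics", "table4_concordance",
]


class ActivityClass(str, Enum):
    """P-gp modulation classes partitioning the pFAR axis."""

    inducer = "inducer"
    active_inhibitor = "active_inhibitor"
    strong_inhibitor = "strong_inhibitor"


#: the six (descriptor, z-scale coefficient) terms, in equation order
EQUATION_TERMS = (
    ("RDF_PiChg_86", -0.613),
    ("RDF_SigChg_76", 0.461),
    ("3DACorr_TotChg_9", -0.283),
    ("RDF_LpEN_54", 0.207),
    ("3DACorr_PiChg_9", -0.284),
    ("RDF_SigChg_57", -0.197),
)
EQUATION_INTERCEPT = -0.416

#: SHA-256 over the canonical term/intercept serialization; the packaged
#: JSON copy must reproduce it (guards against silent edits).
EQUATION_CHECKSUM = (
    "a3053ec540ccbaffad19adbf846d23b28974c628613b3a748a5e47297e49a968")


def _canonical_equation_string(terms, intercept) -> str:
    return json.dumps({"terms": [[n, c] for n, c in terms],
                       "intercept": intercept}, separators=(",", ":"))


def equation_checksum(terms=EQUATION_TERMS,
                      intercept=EQUATION_INTERCEPT) -> str:
    return hashlib.sha256(
        _canonical_equation_string(terms, intercept).encode()).hexdigest()


def _data_path(name: str):
    return resources.files("flavoqsar.data").joinpath(name)


def load_equation() -> dict:
    """Load the packaged equation JSON, verifying it against the checksum."""
    with _data_path("published_equation.json").open() as fh:
        payload = json.load(fh)
    terms = tuple((n, float(c)) for n, c in payload["terms"])
    if equation_checksum(terms, float(payload["intercept"])) != EQUATION_CHECKSUM:
        raise ValueError("packaged equation data does not match checksum")
    return payload


def predict_pfar(z) -> float:
    """Evaluate the equation at a standardized 6-vector.

    ``z`` must be ordered as :data:`EQUATION_TERMS` (RDF_PiChg_86,
    RDF_SigChg_76, 3DACorr_TotChg_9, RDF_LpEN_54, 3DACorr_PiChg_9,
    RDF_SigChg_57).  Accepts a single vector or an (n, 6) array.
    """
    z = np.asarray(z, dtype=float)
    coeffs = np.array([c for _, c in EQUATION_TERMS])
    if z.shape[-1] != len(coeffs):
        raise ValueError(
            f"expected {len(coeffs)} descriptor values, got {z.shape[-1]}")
    out = z @ coeffs + EQUATION_INTERCEPT
    return float(out) if out.ndim == 0 else out


def classify(pfar, boundaries=(-1.0, 0.0)) -> ActivityClass:
    """Map a pFAR value to its modulation class.

    ``pfar < boundaries[0]`` → strong inhibitor; ``boundaries[0] ≤ pfar <
    boundaries[1]`` → active inhibitor; ``pfar ≥ boundaries[1]`` → inducer.
    Vectorized over array input.
    """
    arr = np.asarray(pfar, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("pFAR must be finite")
    lo, hi = boundaries
    if arr.ndim == 0:
        if arr < lo:
            return ActivityClass.strong_inhibitor
        return ActivityClass.active_inhibitor if arr < hi else ActivityClass.inducer
    return np.array([classify(float(v), boundaries) for v in arr], dtype=object)


def concordance(predicted, observed) -> tuple:
    """Element-wise class agreement: (n_correct, n_total)."""
    predicted = list(predicted)
    observed = list(observed)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed class lists differ in length")
    correct = sum(str(ActivityClass(p).value) == str(ActivityClass(o).value)
                  for p, o in zip(predicted, observed))
    return correct, len(observed)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def load_table2() -> pd.DataFrame:
    """6×6 intercorrelation matrix of the model descriptors."""
    with _data_path("table2_corr.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def load_table3() -> pd.DataFrame:
    """Training-set observed/predicted pFAR pairs with printed residuals."""
    with _data_path("table3_train.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def load_table4() -> pd.DataFrame:
    """External 11-compound test set: observed classes and calculated pFAR."""
    with _data_path("table4_external.csv").open() as fh:
        return pd.read_csv(fh)


def table3_metrics(residual_tolerance: float = 0.015) -> dict:
    """Refit statistics on the printed training pairs (k = 6).

    Also verifies that every printed residual equals observed − predicted
    within ``residual_tolerance`` (printed values are rounded to 2 d.p.).
    """
    t3 = load_table3()
    fs: FitStats = fit_stats(t3["observed_pfar"], t3["predicted_pfar"], k=6)
    resid_dev = (t3["observed_pfar"] - t3["predicted_pfar"]
                 - t3["residual"]).abs()
    return {
        "stats": fs,
        "n": len(t3),
        "max_residual_deviation": float(resid_dev.max()),
        "residuals_consistent": bool((resid_dev <= residual_tolerance).all()),
    }


def table4_concordance(boundaries=(-1.0, 0.0)) -> dict:
    """Classify the printed calculated pFARs and score against observed."""
    t4 = load_table4()
    predicted = [classify(v, boundaries) for v in t4["calculated_pfar"]]
    observed = list(t4["observed_class"])
    n_correct, n_total = concordance(predicted, observed)
    return {
        "n_correct": n_correct,
        "n_total": n_total,
        "predicted_classes": [p.value for p in predicted],
        "matches_printed_classes": [
            p.value == q for p, q in zip(predicted, t4["predicted_class"])],
    }
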