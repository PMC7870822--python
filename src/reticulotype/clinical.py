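"""Association of per-patient network features with clinical variables.

A network feature (typically the number of unique fibrosis edges) is
correlated with hemodynamic / morphological variables such as LV
end-diastolic volume, stroke volume, indexed pulmonary vascular resistance
or cardiac output.  Pearson r (t-based two-sided p) or Spearman rho (exact
permutation p for n <= 8, t approximation otherwise) are reported; the
choice of method is an explicit analyst decision per variable, never an
automatic normality gate.  Missing clinical values are pairwise-deleted and
the effective n is reported alongside every coefficient.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "read_clinical",
    "associate",
    "association_report",
    "feature_from_reports",
]


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    method: str
    coefficient: float
    p: float
    n_used: int
    undefined: bool = False


def read_clinical(path) -> pd.DataFrame:
    """Clinical CSV: one row per patient, first column = patient id."""
    table = pd.read_csv(path, index_col=0)
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate patient id in {path}: {dup!r}")
    return table


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    target = abs(rho_obs) - 1e-12
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        hits += abs(rho) >= target
        total += 1
    return hits / total


def associate(
    feature: Mapping[str, float],
    clinical: pd.DataFrame,
    variable_name: str,
    method: str = "pearson",
) -> AssociationResult:
    """Correlate a per-patient feature with one clinical variable.

    Patients missing from either side, or with a missing value for the
    variable, are dropped (pairwise deletion).  Fewer than 3 complete pairs
    is a hard error; zero variance yields an undefined-flagged result.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    if variable_name not in clinical.columns:
        raise KeyError(f"variable {variable_name!r} absent from clinical table")
    shared = [pid for pid in feature if pid in clinical.index]
    dropped = set(feature) - set(shared)
    if dropped:
        logger.info("%d patient(s) absent from the clinical table dropped", len(dropped))
    x, y = [], []
    for pid in shared:
        v = clinical.loc[pid, variable_name]
        if pd.notna(v) and pd.notna(feature[pid]):
            x.append(float(feature[pid]))
            y.append(float(v))
    n = len(x)
    if n < 3:
        raise ValueError(
            f"need >= 3 complete pairs for {variable_name!r}, got {n}"
        )
    x_arr, y_arr = np.asarray(x), np.asarray(y)
    if x_arr.std() == 0 or y_arr.std() == 0:
        return AssociationResult(variable_name, method, math.nan, math.nan, n, True)
    if method == "pearson":
        r, p = stats.pearsonr(x_arr, y_arr)
        return AssociationResult(variable_name, method, float(r), float(p), n)
    rho = stats.spearmanr(x_arr, y_arr).statistic
    if n <= 8:
        p = _spearman_exact_p(x_arr, y_arr, rho)
    else:
        p = float(stats.spearmanr(x_arr, y_arr).pvalue)
    return AssociationResult(variable_name, "spearman", float(rho), float(p), n)


def association_report(
    feature: Mapping[str, float],
    clinical: pd.DataFrame,
    variables: Sequence[str],
    methods: Mapping[str, str] | str = "pearson",
) -> pd.DataFrame:
    """One association row per requested clinical variable.

    ``methods`` is either one method for all variables or a per-variable
    mapping.  Missing variables and all-missing variables are reported as
    flagged rows rather than aborting the whole report.
    """
    rows = []
    for var in variables:
        method = methods if isinstance(methods, str) else methods.get(var, "pearson")
        try:
            res = associate(feature, clinical, var, method=method)
            rows.append(res.__dict__ | {"error": ""})
        except (KeyError, ValueError) as exc:
            rows.append(
                {
                    "variable": var, "method": method, "coefficient": math.nan,
                    "p": math.nan, "n_used": 0, "undefined": True, "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


def feature_from_reports(reports) -> dict[str, float]:
    """Per-patient unique-feature-edge counts from UniqueEdgeReport rows."""
    return {r.patient_id: float(r.n_unique_feature_edges) for r in reports}
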