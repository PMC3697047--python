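"""Published constant linear models over tetranucleotide features.

These models map precomputed weighted-tetranucleotide features to
activities.  Their coefficients are shipped verbatim as published
constants — the feature columns they were trained on used weight curves
that are not reproducible, so no fitting path in this package claims to
re-derive them:

* Arabidopsis ln-abundance from [WRHW]_F1 (centre) and [DRYD]_F2 (3').
* Human ln-affinity for Ago2 and Ago3 from [RHHK]_F3 (centre) and
  [YRHB]_F4 (3'); their difference isolates Ago2-vs-Ago3 preference as
  1.04 * RHHK - 1.14.
* HEK293T ln-abundance under normal growth and under actinomycin-D
  transcription arrest (inverse-problem reductions of the Ago model).
* The limiting-stage estimator: abundance limited by the weaker of the
  two Ago affinities, exp(min(ago2, ago3) - 4.97).

Generic least-squares fitting for user datasets is provided separately
(:func:`fit_linear`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PublishedModel:
    """A named constant linear model: intercept + coefficients."""

    name: str
    intercept: float
    coefficients: dict[str, float]

    def predict(self, **features: float) -> float:
        missing = set(self.coefficients) - set(features)
        if missing:
            raise ValueError(f"{self.name}: missing features {sorted(missing)}")
        return self.intercept + sum(
            coef * features[name] for name, coef in self.coefficients.items()
        )


ARABIDOPSIS_EQ3 = PublishedModel(
    "ARABIDOPSIS_EQ3", 0.78, {"wrhw": 1.31, "dryd": 0.76}
)
AGO2_EQ5 = PublishedModel("AGO2_EQ5", 4.97, {"rhhk": 0.52, "yrhb": 1.35})
AGO3_EQ5 = PublishedModel("AGO3_EQ5", 6.11, {"rhhk": -0.52, "yrhb": 1.35})
DIFF_EQ6 = PublishedModel("DIFF_EQ6", -1.14, {"rhhk": 1.04})
HEK_NORM_EQ10 = PublishedModel("HEK_NORM_EQ10", -2.74, {"rhhk": 1.32, "yrhb": -1.71})
HEK_ACTD_EQ11 = PublishedModel("HEK_ACTD_EQ11", -4.56, {"rhhk": 2.20, "yrhb": -1.90})

PUBLISHED_MODELS: dict[str, PublishedModel] = {
    m.name: m
    for m in (ARABIDOPSIS_EQ3, AGO2_EQ5, AGO3_EQ5, DIFF_EQ6, HEK_NORM_EQ10, HEK_ACTD_EQ11)
}

# Internal consistency of the shipped constants: the preference model is
# the coefficient-wise difference of the two Ago models.
assert DIFF_EQ6.intercept == round(AGO2_EQ5.intercept - AGO3_EQ5.intercept, 2)
assert DIFF_EQ6.coefficients["rhhk"] == round(
    AGO2_EQ5.coefficients["rhhk"] - AGO3_EQ5.coefficients["rhhk"], 2
)


def predict_arabidopsis(wrhw: float, dryd: float) -> float:
    """Plant ln-abundance from the two Arabidopsis feature values."""
    return ARABIDOPSIS_EQ3.predict(wrhw=wrhw, dryd=dryd)


def predict_ago(rhhk: float, yrhb: float) -> tuple[float, float]:
    """(ln-affinity for Ago2, ln-affinity for Ago3)."""
    return (
        AGO2_EQ5.predict(rhhk=rhhk, yrhb=yrhb),
        AGO3_EQ5.predict(rhhk=rhhk, yrhb=yrhb),
    )


def ago_preference(rhhk: float) -> float:
    """Ago2 minus Ago3 ln-affinity; positive favours Ago2 loading."""
    return DIFF_EQ6.predict(rhhk=rhhk)


def predict_hek(rhhk: float, yrhb: float, condition: str = "normal") -> float:
    """HEK293T ln-abundance under ``"normal"`` growth or
    ``"actinomycin"`` transcription arrest."""
    if condition == "normal":
        return HEK_NORM_EQ10.predict(rhhk=rhhk, yrhb=yrhb)
    if condition == "actinomycin":
        return HEK_ACTD_EQ11.predict(rhhk=rhhk, yrhb=yrhb)
    raise ValueError(f"unknown condition {condition!r}")


def limiting_stage(rhhk: float, yrhb: float) -> float:
    """Limiting-stage abundance estimate.

    exp of the smaller of the two linear forms
    0.52*rhhk + 1.35*yrhb and 1.14 - 0.52*rhhk + 1.35*yrhb,
    identically equal to exp(min(ago2, ago3) - 4.97): the scarcer Ago
    complex limits how much of the miRNA is stabilized.
    """
    a = 0.52 * rhhk + 1.35 * yrhb
    b = 1.14 - 0.52 * rhhk + 1.35 * yrhb
    return float(np.exp(min(a, b)))


@dataclass
class FittedLinearModel:
    """OLS fit of activity on named feature columns, with fit-quality
    correlations between fitted and observed values."""

    intercept: float
    coefficients: dict[str, float]
    fitted: np.ndarray
    pearson_r: float
    spearman_r: float
    kendall_tau: float

    def predict(self, **features: float) -> float:
        return self.intercept + sum(
            c * features[name] for name, c in self.coefficients.items()
        )


def fit_linear(
    features: dict[str, np.ndarray], activity: np.ndarray
) -> FittedLinearModel:
    """Ordinary least squares of activity on the given feature columns."""
    names = list(features)
    y = np.asarray(activity, dtype=float)
    X = np.column_stack([np.asarray(features[n], dtype=float) for n in names])
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("activity length mismatch")
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations for {p} features")
    for i in range(p):
        for j in range(i + 1, p):
            if np.ptp(X[:, i]) > 0 and np.ptp(X[:, j]) > 0:
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                if abs(r) > 1 - 1e-12:
                    raise ValueError(f"collinear features: {names[i]} and {names[j]}")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        pear = spear = tau = 0.0
    else:
        pear = float(sps.pearsonr(fitted, y)[0])
        spear = float(sps.spearmanr(fitted, y)[0])
        tau = float(sps.kendalltau(fitted, y)[0])
    return FittedLinearModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(names, beta[1:])},
        fitted=fitted,
        pearson_r=pear,
        spearman_r=spear,
        kendall_tau=tau,
    )
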