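"""Leverage-based applicability domain and Williams-plot data.

The applicability domain of a descriptor-space regression is assessed by
hat-matrix leverage: with X the intercept-augmented design of the compounds
defining the domain, a compound with descriptor row x has

    h = x (X'X)^(-1) x'

and is inside the domain when h is below the warning leverage
h* = 3(p+1)/n (p descriptors, n compounds in the domain design) and, when a
residual is available, its standardized residual lies within +/-3.

For the study reproduction the domain design comprises all 31 modeling
compounds (training and test) — the convention implied by the reported
h* = 3*7/31 = 0.677 — while arbitrary query compounds (e.g. designed
candidates) can be scored against any fitted domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datasets import MODEL_TERMS
from .regression import _design


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3(p + 1)/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * (p + 1) / n


class LeverageAD(BaseEstimator):
    """Hat-matrix applicability domain.

    ``fit`` takes the compounds that define the domain; ``leverage`` and
    ``in_domain`` score arbitrary compounds against it.

    Attributes
    ----------
    xtx_inv_ : ndarray of shape (p+1, p+1)
        Inverse Gram matrix of the intercept-augmented domain design.
    h_star_ : float
        Warning leverage 3(p+1)/n for the fitted domain.
    leverages_ : ndarray
        Leverage of each fitted compound (diagonal of the hat matrix;
        sums to p+1).
    """

    def __init__(self, terms=None):
        self.terms = terms

    @property
    def terms_(self):
        return list(self.terms) if self.terms is not None else list(MODEL_TERMS)

    def fit(self, X, y=None):
        Xd = _design(X, self.terms_)
        n, p = Xd.shape
        A = np.column_stack([np.ones(n), Xd])
        gram = A.T @ A
        if np.linalg.matrix_rank(gram) < p + 1:
            raise np.linalg.LinAlgError("singular X'X: domain design not full rank")
        self.xtx_inv_ = np.linalg.inv(gram)
        self.n_ = n
        self.p_ = p
        self.h_star_ = warning_leverage(p, n)
        self.leverages_ = self.leverage(X)
        return self

    def leverage(self, X):
        """Leverage of each query compound against the fitted domain."""
        check_is_fitted(self, "xtx_inv_")
        Xd = _design(X, self.terms_)
        A = np.column_stack([np.ones(len(Xd)), Xd])
        return np.einsum("ij,jk,ik->i", A, self.xtx_inv_, A)

    def in_domain(self, X, std_residuals=None):
        """Domain membership: h < h*, and |standardized residual| <= 3
        where residuals are supplied."""
        inside = self.leverage(X) < self.h_star_
        if std_residuals is not None:
            inside = inside & (np.abs(np.asarray(std_residuals, dtype=float)) <= 3.0)
        return inside


@dataclass
class LeverageReport:
    """Per-compound leverage/residual table with the domain parameters."""

    table: pd.DataFrame  # compound_id, leverage, std_residual, set, in_domain
    h_star: float
    p: int
    n: int
    conventions: dict = field(default_factory=lambda: {
        "std_residual": "residual / RMSE of the training fit",
        "h_star": "3(p+1)/n over the domain design"})

    def to_dict(self) -> dict:
        return {"h_star": self.h_star, "p": self.p, "n": self.n,
                "compounds": self.table.to_dict(orient="records"),
                "conventions": self.conventions}


def leverages(domain_records: pd.DataFrame, query_records: pd.DataFrame | None = None,
              terms=None, model=None) -> LeverageReport:
    """Leverage report for the domain-defining records and optional queries.

    When ``model`` (a fitted activity model) is given, standardized
    residuals (residual / training RMSE, denominator n) are included for
    every record with an observed activity.
    """
    ad = LeverageAD(terms=terms).fit(domain_records)
    frames = [(domain_records, "domain")]
    if query_records is not None:
        frames.append((query_records, "query"))

    scale = None
    if model is not None:
        resid_fit = (domain_records["pIC50_obs"].to_numpy(dtype=float)
                     - model.predict(domain_records))
        scale = float(np.sqrt(np.mean(resid_fit ** 2)))
        obs_scale = float(np.abs(domain_records["pIC50_obs"]).max())
        if scale <= 1e-12 * max(1.0, obs_scale):
            raise ValueError("zero residual scale: cannot standardize residuals")

    rows = []
    for records, label in frames:
        h = ad.leverage(records)
        ids = (records["compound_id"].astype(str).tolist()
               if "compound_id" in records else [str(i) for i in range(len(records))])
        std_resid = np.full(len(records), np.nan)
        if scale is not None and "pIC50_obs" in records and records["pIC50_obs"].notna().all():
            std_resid = (records["pIC50_obs"].to_numpy(dtype=float)
                         - model.predict(records)) / scale
        inside = (h < ad.h_star_) & (np.isnan(std_resid) | (np.abs(std_resid) <= 3.0))
        rows.append(pd.DataFrame({
            "compound_id": ids, "leverage": h, "std_residual": std_resid,
            "set": label, "in_domain": inside}))
    return LeverageReport(table=pd.concat(rows, ignore_index=True),
                          h_star=ad.h_star_, p=ad.p_, n=ad.n_)


def williams_data(report: LeverageReport) -> dict:
    """Plottable Williams data: (leverage, standardized residual) points
    plus the boundary lines at h* and +/-3 standard units."""
    pts = report.table.dropna(subset=["std_residual"])
    return {
        "points": pts.loc[:, ["compound_id", "leverage", "std_residual", "set"]],
        "h_star": report.h_star,
        "residual_bounds": (-3.0, 3.0),
    }
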