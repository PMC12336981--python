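"""Synthetic QSAR datasets with known ground truth.

Emulates the statistical structure the linear activity model assumes:
descriptors drawn independently and uniformly within realistic per-term
ranges (matching the study's modeling table), activity generated as a
linear combination plus homoscedastic Gaussian noise. The defaults mirror
the study conditions: 31 compounds, the published linear coefficients as
truth, and a residual noise level (sd 0.13 activity units) that places
refit R-squared near the study's 0.91.

An optional correlation matrix induces dependence between descriptors via a
Gaussian copula, since real descriptor panels are collinear and leverage /
applicability-domain behavior is sensitive to that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MODEL_TERMS
from .regression import PUBLISHED_MLR, LinearQSAR
from .validation import loo_q2

#: Per-descriptor uniform ranges, spanning the modeling table.
DEFAULT_RANGES = {
    "S": (2.3, 3.9),
    "Tor": (1.8, 14.5),
    "MP": (1106.0, 1270.0),
    "NRB": (6, 11),          # integer-valued
    "repul": (3580.0, 5171.0),
    "eta": (0.0730, 0.0869),
}


@dataclass
class SyntheticConfig:
    """Generator settings; a config fully determines the dataset."""

    n_compounds: int = 31
    term_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    true_intercept: float = PUBLISHED_MLR["intercept"]
    true_coefficients: dict = field(default_factory=lambda: dict(
        zip(MODEL_TERMS, PUBLISHED_MLR["coefficients"])))
    noise_sd: float = 0.13
    seed: int = 0
    test_fraction: float = 0.2
    correlation: np.ndarray | None = None

    def validate(self):
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.test_fraction < 1:
            raise ValueError("test_fraction must lie in [0, 1)")
        for term, (lo, hi) in self.term_ranges.items():
            if lo >= hi:
                raise ValueError(f"degenerate range for {term!r}: [{lo}, {hi}]")

    def truth_json(self) -> str:
        return json.dumps({
            "intercept": self.true_intercept,
            "coefficients": self.true_coefficients,
            "noise_sd": self.noise_sd, "seed": self.seed}, indent=1)


def generate_dataset(config: SyntheticConfig | None = None, **overrides) -> pd.DataFrame:
    """Generate a modeling-table-shaped DataFrame with known truth.

    Returns a DataFrame in the package record dialect (compound_id,
    descriptors, pIC50_obs, split) with an extra ``pIC50_true`` column
    holding the noise-free activity. Deterministic given the config.
    """
    config = config or SyntheticConfig()
    if overrides:
        config = SyntheticConfig(**{**config.__dict__, **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)
    terms = list(config.term_ranges)
    n, p = config.n_compounds, len(terms)

    if config.correlation is not None:
        corr = np.asarray(config.correlation, dtype=float)
        z = rng.multivariate_normal(np.zeros(p), corr, size=n, method="cholesky")
        from scipy.stats import norm
        u = norm.cdf(z)
    else:
        u = rng.uniform(size=(n, p))

    cols = {}
    for j, term in enumerate(terms):
        lo, hi = config.term_ranges[term]
        x = lo + (hi - lo) * u[:, j]
        if term == "NRB":
            x = np.floor(lo + (hi - lo + 1) * u[:, j]).clip(lo, hi).astype(int)
        cols[term] = x
    df = pd.DataFrame(cols)

    coeffs = np.array([config.true_coefficients[t] for t in terms])
    y_true = config.true_intercept + df.to_numpy(dtype=float) @ coeffs
    y = y_true + rng.normal(0.0, config.noise_sd, size=n)

    n_test = int(round(config.test_fraction * n))
    split = np.array(["train"] * n, dtype=object)
    if n_test:
        split[rng.choice(n, size=n_test, replace=False)] = "test"

    df.insert(0, "compound_id", [f"S{i+1}" for i in range(n)])
    df["pIC50_obs"] = y
    df["pIC50_true"] = y_true
    df["split"] = split
    return df


@dataclass
class RecoveryResult:
    """Aggregate of a seeded parameter-recovery experiment."""

    terms: list
    bias: np.ndarray           # mean(coef_hat - coef_true) per term
    rmse: np.ndarray           # root mean squared coefficient error per term
    mean_r2: float
    mean_q2: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {"terms": self.terms, "bias": self.bias.tolist(),
                "rmse": self.rmse.tolist(), "mean_r2": self.mean_r2,
                "mean_q2": self.mean_q2, "n_replicates": self.n_replicates}


def recovery_experiment(config: SyntheticConfig | None = None,
                        n_replicates: int = 100,
                        compute_q2: bool = True) -> RecoveryResult:
    """Repeatedly generate, refit and cross-validate to measure coefficient
    recovery (bias, RMSE) and the training-vs-LOO optimism gap.

    Replicate r uses seed ``config.seed + r``; a failing replicate fit is
    reported with its seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    config = config or SyntheticConfig()
    terms = list(config.term_ranges)
    truth = np.array([config.true_coefficients[t] for t in terms])
    errors = np.empty((n_replicates, len(terms)))
    r2s = np.empty(n_replicates)
    q2s = np.empty(n_replicates) if compute_q2 else None
    for r in range(n_replicates):
        seed = config.seed + r
        data = generate_dataset(config, seed=seed)
        train = data[data["split"] == "train"]
        try:
            model = LinearQSAR(terms=terms).fit(train, train["pIC50_obs"])
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"replicate with seed {seed} failed to fit: {exc}") from exc
        errors[r] = model.coef_ - truth
        r2s[r] = model.stats_.r2
        if compute_q2:
            q2s[r] = loo_q2(train, LinearQSAR(terms=terms)).q2
    return RecoveryResult(
        terms=terms,
        bias=errors.mean(axis=0),
        rmse=np.sqrt((errors ** 2).mean(axis=0)),
        mean_r2=float(r2s.mean()),
        mean_q2=float(q2s.mean()) if compute_q2 else float("nan"),
        n_replicates=n_replicates)
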