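"""Designed-candidate scoring: activity prediction, domain membership,
and threshold-based drug-likeness screening.

Rule sets (bounds recorded in ``RULESETS``):

* Lipinski — MW <= 500 Da, LogP <= 5, HBA <= 10, HBD <= 5; conventional
  verdict allows at most one violation and the violation count is reported.
* Veber — rotatable bonds <= 10 and TPSA <= 140 A^2.
* Egan — LogP <= 5.88 and TPSA <= 148.1 A^2 (the 99% confidence ellipse of
  Egan's passive-absorption model; see the methods note).
* Muegge — over the six available properties: MW in [200, 600],
  LogP in [-2, 5], TPSA <= 150, rotatable bonds <= 15, HBA <= 10, HBD <= 5.
  (Ring/atom-count bounds require structures, which are not part of the
  dataset.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import LeverageAD

PROPERTY_KEYS = ["TPSA", "n_rotatable", "MW", "LogP", "n_HBA", "n_HBD"]

#: Per-ruleset predicate bounds. Each entry: (property, kind, bound(s)).
RULESETS = {
    "lipinski": [("MW", "max", 500.0), ("LogP", "max", 5.0),
                 ("n_HBA", "max", 10.0), ("n_HBD", "max", 5.0)],
    "veber": [("n_rotatable", "max", 10.0), ("TPSA", "max", 140.0)],
    "egan": [("LogP", "max", 5.88), ("TPSA", "max", 148.1)],
    "muegge": [("MW", "range", (200.0, 600.0)), ("LogP", "range", (-2.0, 5.0)),
               ("TPSA", "max", 150.0), ("n_rotatable", "max", 15.0),
               ("n_HBA", "max", 10.0), ("n_HBD", "max", 5.0)],
}

#: Violations tolerated per ruleset for a passing verdict.
MAX_VIOLATIONS = {"lipinski": 1, "veber": 0, "egan": 0, "muegge": 0}


@dataclass
class DruglikenessVerdict:
    candidate_id: str
    properties: dict
    rule_results: dict          # ruleset -> bool
    violation_counts: dict      # ruleset -> int
    annotations: dict = field(default_factory=dict)

    @property
    def lipinski_violation_count(self) -> int:
        return self.violation_counts["lipinski"]

    @property
    def all_pass(self) -> bool:
        return all(self.rule_results.values())

    def to_dict(self) -> dict:
        return {"candidate_id": self.candidate_id, "properties": self.properties,
                "rule_results": self.rule_results,
                "violation_counts": self.violation_counts,
                "lipinski_violation_count": self.lipinski_violation_count,
                "all_pass": self.all_pass, "annotations": self.annotations}


def _violations(props: dict, rules) -> int:
    count = 0
    for prop, kind, bound in rules:
        v = props[prop]
        if kind == "max":
            count += v > bound
        else:
            lo, hi = bound
            count += not (lo <= v <= hi)
    return int(count)


def apply_druglikeness_rules(properties, candidate_id="", annotations=None) -> DruglikenessVerdict:
    """Evaluate the four rule sets on one property row.

    ``properties`` is a mapping (or Series) with TPSA (A^2), n_rotatable,
    MW (Da), LogP, n_HBA, n_HBD. All six must be present.
    """
    if isinstance(properties, pd.Series):
        properties = properties.to_dict()
    missing = [k for k in PROPERTY_KEYS if k not in properties or pd.isna(properties[k])]
    if missing:
        raise ValueError(f"missing drug-likeness propert{'y' if len(missing)==1 else 'ies'}: {missing}")
    props = {k: float(properties[k]) for k in PROPERTY_KEYS}
    counts = {name: _violations(props, rules) for name, rules in RULESETS.items()}
    results = {name: counts[name] <= MAX_VIOLATIONS[name] for name in RULESETS}
    return DruglikenessVerdict(candidate_id=str(candidate_id), properties=props,
                               rule_results=results, violation_counts=counts,
                               annotations=annotations or {})


@dataclass
class CandidatePrediction:
    candidate_id: str
    descriptors: dict
    predicted_pIC50: float
    in_domain: bool | None
    improvement_vs_best: float | None

    def to_dict(self) -> dict:
        return {"candidate_id": self.candidate_id, "descriptors": self.descriptors,
                "predicted_pIC50": self.predicted_pIC50, "in_domain": self.in_domain,
                "improvement_vs_best": self.improvement_vs_best}


def predict_candidates(model, candidates: pd.DataFrame,
                       baseline: float | None = None,
                       domain: LeverageAD | None = None) -> list[CandidatePrediction]:
    """Score designed candidates with a fitted (or published) activity model.

    Parameters
    ----------
    model : fitted LinearQSAR (or any estimator with matching terms)
    candidates : DataFrame with the model's descriptor columns and
        ``compound_id``.
    baseline : float, optional
        Reference activity (e.g. the best observed pIC50 in the modeling
        table) for the improvement column.
    domain : fitted LeverageAD, optional
        When given, candidates are flagged for applicability-domain
        membership (leverage only; candidates have no observed residual).
    """
    preds = np.asarray(model.predict(candidates), dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ValueError("non-finite candidate prediction")
    inside = domain.in_domain(candidates) if domain is not None else [None] * len(preds)
    terms = model.terms_
    out = []
    for i, (_, row) in enumerate(candidates.iterrows()):
        out.append(CandidatePrediction(
            candidate_id=str(row.get("compound_id", i)),
            descriptors={t: float(row[t]) for t in terms},
            predicted_pIC50=float(preds[i]),
            in_domain=None if inside[i] is None else bool(inside[i]),
            improvement_vs_best=None if baseline is None else float(preds[i] - baseline)))
    return out


def screen_candidates(model, candidates: pd.DataFrame, properties: pd.DataFrame,
                      baseline: float | None = None,
                      domain: LeverageAD | None = None) -> pd.DataFrame:
    """Combined ranking report: prediction, AD flag, and rule verdicts."""
    preds = {p.candidate_id: p for p in predict_candidates(
        model, candidates, baseline=baseline, domain=domain)}
    rows = []
    for _, row in properties.iterrows():
        cid = str(row["candidate_id"])
        verdict = apply_druglikeness_rules(row, candidate_id=cid)
        pred = preds.get(cid)
        rows.append({
            "candidate_id": cid,
            "predicted_pIC50": pred.predicted_pIC50 if pred else np.nan,
            "improvement_vs_best": pred.improvement_vs_best if pred else np.nan,
            "in_domain": pred.in_domain if pred else None,
            **{f"{name}_pass": ok for name, ok in verdict.rule_results.items()},
            "lipinski_violations": verdict.lipinski_violation_count,
        })
    return (pd.DataFrame(rows)
            .sort_values("predicted_pIC50", ascending=False)
            .reset_index(drop=True))
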