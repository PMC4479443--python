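"""Patient-level diagnosis by majority vote over cell-sample predictions.

A patient contributes several cell samples.  Two schemes turn per-sample
classifier predictions into one family (ALL/AML) and one subtype
(L1/L2/M2/M3/M5) call:

* **cascade** — the family is decided first by majority over the samples;
  only the winning family's subtype classifier is then consulted.  Its
  documented failure mode: a wrong family call forces the subtype call into
  the wrong family's subtypes.
* **fused** — every classifier in the ensemble (the multiclass subtype
  model, the three one-vs-rest myeloblastic models, the L1-vs-L2 model and
  the family model) votes on every sample; a vote supporting m candidate
  subtypes contributes 1/m to each, so tallies sum to
  n_samples x n_classifiers.  The winner needs a strict plurality; a tie
  (or a margin below ``min_margin``) yields "not determined".

The evaluation table mirrors the correct / not-determined / failed
percentage layout, each row summing to 100%.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FAMILY_OF, SUBTYPES

__all__ = [
    "PatientDiagnosis",
    "SubtypeVoter",
    "cascade_diagnose",
    "fused_diagnose",
    "evaluate_diagnosis",
    "majority",
]

NOT_DETERMINED = "not_determined"
_FAMILY_SUBTYPES = {"ALL": ("L1", "L2"), "AML": ("M2", "M3", "M5")}


@dataclass
class PatientDiagnosis:
    """Family and subtype calls for one patient, with the vote evidence."""

    patient_id: str
    family_votes: dict[str, float] = field(default_factory=dict)
    subtype_votes: dict[str, float] = field(default_factory=dict)
    family_call: str = NOT_DETERMINED
    subtype_call: str = NOT_DETERMINED
    family_margin: float = 0.0
    subtype_margin: float = 0.0
    per_sample: dict = field(default_factory=dict)


def majority(votes: dict[str, float], min_margin: float = 1e-9) -> tuple[str, float]:
    """Strict-plurality winner of a vote tally.

    Returns ``(label, margin)`` where margin = winner votes - runner-up
    votes; a tie at the top or a margin below ``min_margin`` yields
    ``not_determined``.  Empty tallies are not determined.
    """
    if not votes:
        return NOT_DETERMINED, 0.0
    items = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(items) == 1:
        return items[0][0], items[0][1]
    margin = items[0][1] - items[1][1]
    if margin < min_margin:
        return NOT_DETERMINED, margin
    return items[0][0], margin


@dataclass
class SubtypeVoter:
    """One ensemble member: a fitted model plus its vote interpretation.

    ``model.predict`` maps a feature matrix to per-sample labels;
    ``support`` maps each predicted label to the candidate subtypes it
    endorses (e.g. an ALL-vs-AML prediction of "ALL" endorses L1 and L2; a
    one-vs-rest prediction of "M3&M5" endorses M3 and M5).
    """

    name: str
    model: object
    support: dict[str, tuple[str, ...]]

    def subtype_support(self, X) -> list[tuple[str, ...]]:
        return [tuple(self.support[str(p)]) for p in self.model.predict(np.asarray(X, dtype=np.float64))]


def cascade_diagnose(
    patient_id: str,
    X,
    family_model,
    subtype_models: dict[str, object],
    min_margin: float = 1e-9,
) -> PatientDiagnosis:
    """Family-first cascade diagnosis of one patient's samples.

    ``family_model`` predicts ALL/AML per sample; majority over samples
    decides the family.  Only the winning family's model in
    ``subtype_models`` is then consulted, and the subtype is the majority of
    its per-sample predictions.  A family tie stops the cascade with both
    calls not determined.

    Raises
    ------
    ValueError : when no samples are supplied.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("patient has no samples")
    fam_pred = [str(p) for p in family_model.predict(X)]
    fam_votes: dict[str, float] = defaultdict(float)
    for p in fam_pred:
        fam_votes[p] += 1.0
    family_call, fam_margin = majority(dict(fam_votes), min_margin)
    diag = PatientDiagnosis(
        patient_id=patient_id,
        family_votes=dict(fam_votes),
        family_call=family_call,
        family_margin=fam_margin,
        per_sample={"family": fam_pred},
    )
    if family_call == NOT_DETERMINED:
        return diag
    sub_pred = [str(p) for p in subtype_models[family_call].predict(X)]
    sub_votes: dict[str, float] = defaultdict(float)
    for p in sub_pred:
        sub_votes[p] += 1.0
    diag.subtype_votes = dict(sub_votes)
    diag.subtype_call, diag.subtype_margin = majority(dict(sub_votes), min_margin)
    diag.per_sample["subtype"] = sub_pred
    return diag


def fused_diagnose(
    patient_id: str,
    X,
    voters: list[SubtypeVoter],
    min_margin: float = 1e-9,
) -> PatientDiagnosis:
    """Classifier-fusion diagnosis of one patient's samples.

    Every voter votes on every sample; a vote endorsing m candidate subtypes
    adds 1/m to each of their tallies.  Pooling is hierarchical, because the
    ensemble is asymmetric — most members can only ever name myeloblastic
    subtypes, so a flat plurality across all candidates would be
    structurally biased toward the family with more dedicated classifiers:

    * the family tally pools the family implications of the voters whose
      support spans both families (each such vote adds 1/#families to the
      families it endorses), and the family call is its strict plurality;
    * the subtype tally pools every vote's subtype support (1/m each);
      the subtype call is the strict plurality *within the winning family*,
      counting only votes from voters able to discriminate inside it.

    Tallies therefore sum to n_samples x n_contributing_voters at each
    level.  A tie (margin below ``min_margin``) at either level yields
    "not determined"; an undetermined family leaves the subtype
    undetermined as well.

    Raises
    ------
    ValueError : when no samples or no voters are supplied.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("patient has no samples")
    if not voters:
        raise ValueError("fusion requires at least one voter")
    sub_votes: dict[str, float] = defaultdict(float)
    fam_votes: dict[str, float] = defaultdict(float)
    per_sample: dict[str, list] = {}
    all_supports: dict[str, list[tuple[str, ...]]] = {}

    def _spans_both(voter: SubtypeVoter) -> bool:
        fams = {FAMILY_OF[s] for supp in voter.support.values() for s in supp}
        return len(fams) > 1

    for voter in voters:
        supports = voter.subtype_support(X)
        per_sample[voter.name] = supports
        all_supports[voter.name] = supports
        for supp in supports:
            w = 1.0 / len(supp)
            for s in supp:
                sub_votes[s] += w
        if _spans_both(voter):
            for supp in supports:
                fams = {FAMILY_OF[s] for s in supp}
                fw = 1.0 / len(fams)
                for f in fams:
                    fam_votes[f] += fw
    if not fam_votes:  # no family-competent voter: fall back to all implications
        for supports in all_supports.values():
            for supp in supports:
                fams = {FAMILY_OF[s] for s in supp}
                fw = 1.0 / len(fams)
                for f in fams:
                    fam_votes[f] += fw
    family_call, fam_margin = majority(dict(fam_votes), min_margin)

    subtype_call, sub_margin = NOT_DETERMINED, 0.0
    if family_call != NOT_DETERMINED:
        fam_subs = set(_FAMILY_SUBTYPES[family_call])
        within: dict[str, float] = defaultdict(float)
        for voter in voters:
            # a voter helps within the family if it can tell its subtypes apart
            distinguishable = {
                tuple(sorted(set(supp) & fam_subs)) for supp in voter.support.values()
            } - {()}
            if len(distinguishable) < 2:
                continue
            for supp in all_supports[voter.name]:
                in_fam = [s for s in supp if s in fam_subs]
                if not in_fam:
                    continue
                w = 1.0 / len(in_fam)
                for s in in_fam:
                    within[s] += w
        subtype_call, sub_margin = majority(dict(within), min_margin)
    return PatientDiagnosis(
        patient_id=patient_id,
        family_votes=dict(fam_votes),
        subtype_votes=dict(sub_votes),
        family_call=family_call,
        subtype_call=subtype_call,
        family_margin=fam_margin,
        subtype_margin=sub_margin,
        per_sample=per_sample,
    )


def evaluate_diagnosis(
    manifest: pd.DataFrame, diagnoses: dict[str, PatientDiagnosis]
) -> pd.DataFrame:
    """Summarize diagnoses against truth as correct / not determined / failed %.

    The manifest carries one row per sample with ``patient_id``, ``family``
    and ``subtype`` truth columns.  The summary has one row per family and
    per subtype plus 'Types' and 'Subtypes' totals; each row's three
    percentages sum to 100.

    Raises
    ------
    ValueError : for a diagnosis of a patient absent from the manifest.
    """
    truth = manifest.drop_duplicates("patient_id").set_index("patient_id")
    unknown = set(diagnoses) - set(truth.index)
    if unknown:
        raise ValueError(f"unknown patient ids: {sorted(unknown)}")

    def _tally(rows: pd.DataFrame, call_attr: str, truth_col: str) -> tuple[int, int, int, int]:
        n = correct = nd = failed = 0
        for pid, row in rows.iterrows():
            if pid not in diagnoses:
                continue
            call = getattr(diagnoses[pid], call_attr)
            n += 1
            if call == NOT_DETERMINED:
                nd += 1
            elif call == row[truth_col]:
                correct += 1
            else:
                failed += 1
        return n, correct, nd, failed

    records = []

    def _row(name: str, rows: pd.DataFrame, call_attr: str, truth_col: str) -> None:
        n, correct, nd, failed = _tally(rows, call_attr, truth_col)
        if n == 0:
            return
        records.append(
            {
                "classification": name,
                "n": n,
                "correct_pct": 100.0 * correct / n,
                "not_determined_pct": 100.0 * nd / n,
                "failed_pct": 100.0 * failed / n,
            }
        )

    _row("Types", truth, "family_call", "family")
    for fam in ("ALL", "AML"):
        _row(fam, truth[truth["family"] == fam], "family_call", "family")
    _row("Subtypes", truth, "subtype_call", "subtype")
    for sub in SUBTYPES:
        _row(sub, truth[truth["subtype"] == sub], "subtype_call", "subtype")
    return pd.DataFrame.from_records(records)
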