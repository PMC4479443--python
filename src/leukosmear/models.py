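"""Fitting the classifier ensemble that feeds the diagnosis schemes.

From one labeled feature table this builds the models both diagnosis
schemes need: a family classifier (ALL vs AML) plus per-family subtype
classifiers for the cascade, and the fusion voter set — the three-way
myeloblastic classifier, the three one-vs-rest myeloblastic classifiers,
the L1-vs-L2 classifier and the family classifier, each with the mapping
from its predictions to the candidate subtypes they endorse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import TASKS, build_task_dataset, make_learner
from .diagnosis import SubtypeVoter

__all__ = ["fit_task_model", "fit_diagnosis_models"]


def fit_task_model(table: pd.DataFrame, task_name: str, learner: str = "rf", seed: int = 0):
    """Fit one roster learner on the full table mapped onto a task."""
    task = TASKS[task_name]
    X, y = build_task_dataset(table, task)
    model = make_learner(learner, seed=seed)
    model.fit(np.asarray(X, dtype=np.float64), y.to_numpy())
    return model


def fit_diagnosis_models(
    table: pd.DataFrame, learner: str = "rf", seed: int = 0
) -> tuple[object, dict[str, object], list[SubtypeVoter]]:
    """Fit every model the diagnosis stage consumes.

    Returns ``(family_model, subtype_models, voters)``: the cascade uses the
    first two, the fusion scheme the voter list.
    """
    family_model = fit_task_model(table, "ALLvsAML", learner, seed)
    l_model = fit_task_model(table, "L1vsL2", learner, seed + 1)
    m_model = fit_task_model(table, "M2vsM3vsM5", learner, seed + 2)
    subtype_models = {"ALL": l_model, "AML": m_model}

    voters = [
        SubtypeVoter("M2vsM3vsM5", m_model, {"M2": ("M2",), "M3": ("M3",), "M5": ("M5",)}),
        SubtypeVoter("L1vsL2", l_model, {"L1": ("L1",), "L2": ("L2",)}),
        SubtypeVoter(
            "ALLvsAML", family_model, {"ALL": ("L1", "L2"), "AML": ("M2", "M3", "M5")}
        ),
    ]
    for m in ("M2", "M3", "M5"):
        rest = tuple(s for s in ("M2", "M3", "M5") if s != m)
        task_name = f"{m}vs({rest[0]}&{rest[1]})"
        model = fit_task_model(table, task_name, learner, seed + 3)
        voters.append(SubtypeVoter(task_name, model, {m: (m,), f"{rest[0]}&{rest[1]}": rest}))
    return family_model, subtype_models, voters
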