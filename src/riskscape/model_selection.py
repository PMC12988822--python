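"""AICc ranking with the parsimony rule, shared by all candidate sets.

AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1).  Models are ranked by AICc, but a
model within two delta-AICc of the minimum with fewer parameters is
preferred ("parsimony rule").  Candidate sets follow the same template in
every stage: all non-empty combinations of three focal covariates (7
models) plus two interaction models (prey x risk, with and without ice),
plus a null; a structural covariate (bathymetry, or dive depth) appears in
every model including the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = ["aicc", "CandidateModel", "candidate_set", "rank_models"]


def aicc(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class CandidateModel:
    name: str
    terms: tuple            # covariate columns; "a:b" denotes an interaction

    @property
    def k_extra(self) -> int:
        return len(self.terms)


def candidate_set(focal=("ice", "prey", "risk"),
                  interaction=("prey", "risk")) -> list[CandidateModel]:
    """The 9-model candidate set plus a null (10 total)."""
    a, b = interaction
    models = []
    for r in (1, 2, 3):
        for combo in combinations(focal, r):
            models.append(CandidateModel("+".join(combo), tuple(combo)))
    models.append(CandidateModel(f"{a}*{b}", (a, b, f"{a}:{b}")))
    models.append(CandidateModel(f"ice+{a}*{b}", ("ice", a, b, f"{a}:{b}")))
    models.append(CandidateModel("null", ()))
    assert len(models) == 10
    return models


def rank_models(fits: list) -> pd.DataFrame:
    """Rank fitted candidates; returns a table with delta-AICc and the
    parsimony-selected model flagged.

    ``fits`` items need attributes ``name``, ``aicc``, ``k``.  The selected
    model is the one with the fewest parameters among those within two
    delta-AICc of the minimum (AICc breaks ties).
    """
    rows = pd.DataFrame({
        "model": [f.name for f in fits],
        "k": [f.k for f in fits],
        "aicc": [f.aicc for f in fits],
    })
    rows["delta_aicc"] = rows["aicc"] - rows["aicc"].min()
    rows = rows.sort_values(["aicc"]).reset_index(drop=True)
    within = rows[rows["delta_aicc"] <= 2.0]
    best = within.sort_values(["k", "aicc"]).iloc[0]["model"]
    rows["selected"] = rows["model"] == best
    return rows
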