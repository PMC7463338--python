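"""Origin assignment against a reference panel.

Two engines score query specimens: the DAPC Gaussian posterior, and a
maximum-margin (SVM) classifier with calibrated probabilities trained on the
same retained PC scores as the DAPC.  Both feed the relative-probability
decision rule: a specimen is assigned to its best group only when the ratio
between the highest and second-highest membership probability reaches the
threshold (2 by default); otherwise it is inconclusive.  Sibling eggs from
one egg mass are summarized by a consensus rule, and panel diagnostic power
is measured by stratified Monte-Carlo cross-validation.

Note the SVM path's probabilities are calibrated scores rather than true
posteriors; the decision rule consumes them identically, which is why the
ratio threshold can behave differently between engines.
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .core import (
    ASSIGNED,
    INCONCLUSIVE,
    AssignmentDecision,
    GenotypeTable,
    MembershipMatrix,
)
from .dapc import DAPC, AlleleEncoder
from .popstats import top_fst_loci

log = logging.getLogger(__name__)

ENGINES = ("dapc", "svm")


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------

def decide(
    row: pd.Series | np.ndarray,
    groups: Sequence[str] | None = None,
    individual: str = "",
    threshold: float = 2.0,
) -> AssignmentDecision:
    """Apply the relative-probability rule to one membership row.

    relative probability = highest / second-highest membership (+inf when the
    second-highest is zero).  ASSIGNED iff the ratio reaches ``threshold``;
    an exact tie for the maximum is inconclusive.
    """
    if isinstance(row, pd.Series):
        groups = list(row.index)
        vals = row.to_numpy(dtype=float)
    else:
        vals = np.asarray(row, dtype=float)
        if groups is None:
            groups = [str(k) for k in range(len(vals))]
    if len(vals) < 2:
        raise ValueError("need at least two groups to decide")
    order = np.argsort(vals)[::-1]
    best, second = vals[order[0]], vals[order[1]]
    ratio = np.inf if second == 0 else best / second
    status = ASSIGNED if ratio >= threshold else INCONCLUSIVE
    return AssignmentDecision(
        individual=individual,
        best_group=str(groups[order[0]]),
        relative_probability=float(ratio),
        status=status,
    )


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

class ReferencePanel:
    """Reference genotypes with group labels plus fitted assignment engines.

    The SVM engine trains on the same retained PC scores as the DAPC model,
    with Platt-calibrated probabilities.
    """

    def __init__(
        self,
        table: GenotypeTable,
        loci_subset: Sequence[str] | None = None,
        n_pcs: int | None = None,
        min_group_size: int = 5,
        svm_kernel: str = "rbf",
    ):
        if table.group is None:
            raise ValueError("reference table needs group labels")
        if loci_subset is not None:
            table = table.subset(loci=list(loci_subset))
        counts = table.group.value_counts()
        if len(counts) < 2:
            raise ValueError("reference panel needs at least two groups")
        if (counts < min_group_size).any():
            small = counts[counts < min_group_size].index.tolist()
            raise ValueError(f"groups below minimum size {min_group_size}: {small}")
        self.table = table
        self.n_pcs = n_pcs
        self.svm_kernel = svm_kernel

    def fit(self, seed: int = 0) -> "ReferencePanel":
        y = self.table.group.loc[self.table.individuals].to_numpy()
        self.encoder_ = AlleleEncoder().fit(self.table)
        X = self.encoder_.transform(self.table)
        n_pcs = self.n_pcs or min(X.shape[0] - 1, X.shape[1], 50)
        self.dapc_ = DAPC(n_pcs=n_pcs).fit(X, y)
        scores = self.dapc_._pc_scores(X)[:, : self.dapc_.n_pcs_]
        self.svm_ = CalibratedClassifierCV(
            SVC(kernel=self.svm_kernel, random_state=seed),
            ensemble=False, cv=3,
        ).fit(scores, y)
        return self

    @property
    def groups(self) -> list[str]:
        return list(self.dapc_.classes_)

    def membership(
        self, queries: GenotypeTable, engine: str = "dapc"
    ) -> MembershipMatrix:
        if engine not in ENGINES:
            raise ValueError(f"unknown engine {engine!r}")
        X = self.encoder_.transform(queries)
        if engine == "dapc":
            probs = self.dapc_.predict_proba(X)
            cols = list(self.dapc_.classes_)
        else:
            scores = self.dapc_._pc_scores(X)[:, : self.dapc_.n_pcs_]
            probs = self.svm_.predict_proba(scores)
            cols = list(self.svm_.classes_)
        return MembershipMatrix(
            pd.DataFrame(probs, index=queries.individuals, columns=cols)
        )

    def _typed_fraction(self, queries: GenotypeTable) -> np.ndarray:
        return 1.0 - queries.missing_fraction()


def assign(
    panel: ReferencePanel,
    queries: GenotypeTable,
    engine: str = "dapc",
    threshold: float = 2.0,
) -> tuple[pd.DataFrame, MembershipMatrix]:
    """Score queries against the panel and apply the decision rule.

    Returns a per-query table (best group, relative probability, status,
    engine, reliability flag) and the membership matrix.  Queries typed at
    fewer than half of the panel loci are flagged UNRELIABLE but still scored.
    """
    if queries.n_individuals == 0:
        empty = pd.DataFrame(
            columns=["best_group", "relative_probability", "status", "engine",
                     "unreliable"]
        )
        return empty, MembershipMatrix(pd.DataFrame(columns=panel.groups))
    m = panel.membership(queries, engine=engine)
    typed = panel._typed_fraction(queries)
    rows = []
    for i, ind in enumerate(queries.individuals):
        d = decide(m.df.loc[ind], individual=ind, threshold=threshold)
        unreliable = typed[i] < 0.5
        if unreliable:
            log.warning("query %s typed at %.0f%% of loci: UNRELIABLE", ind,
                        100 * typed[i])
        rows.append(
            {
                "individual": ind,
                "best_group": d.best_group,
                "relative_probability": d.relative_probability,
                "status": d.status,
                "engine": engine,
                "unreliable": bool(unreliable),
            }
        )
    return pd.DataFrame(rows).set_index("individual"), m


# ---------------------------------------------------------------------------
# Egg-mass consensus
# ---------------------------------------------------------------------------

IDENTICAL = "IDENTICAL"
CONGRUENT = "CONGRUENT"
CONFLICT = "CONFLICT"


def eggmass_consensus(
    decisions: pd.DataFrame, eggmass: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Summarize per-egg decisions by egg mass.

    IDENTICAL: every egg decisively assigned to the same group.  CONGRUENT:
    the assigned eggs agree and the inconclusive ones point to the same group
    (their argmax).  CONFLICT: decisive assignments to different groups, or an
    inconclusive egg pointing elsewhere.
    """
    eggmass = pd.Series(dict(eggmass)) if not isinstance(eggmass, pd.Series) else eggmass
    rows = []
    for mass, inds in eggmass.groupby(eggmass).groups.items():
        sub = decisions.loc[[i for i in inds if i in decisions.index]]
        if sub.empty:
            continue
        assigned = sub[sub["status"] == ASSIGNED]["best_group"].unique().tolist()
        tops = sub["best_group"].unique().tolist()
        if len(assigned) > 1 or len(tops) > 1:
            status, label = CONFLICT, None
        elif len(assigned) == 1 and len(sub[sub["status"] == ASSIGNED]) == len(sub):
            status, label = IDENTICAL, assigned[0]
        elif len(assigned) == 1:
            status, label = CONGRUENT, assigned[0]
        else:  # no decisive egg at all
            status, label = CONGRUENT, None
        rows.append(
            {"eggmass": mass, "n_eggs": len(sub), "status": status,
             "consensus": label}
        )
    return pd.DataFrame(rows).set_index("eggmass")


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class XvalResult:
    per_rep: pd.DataFrame          # rep, group, n_test, accuracy, accuracy_argmax
    overall: float                 # mean decisive accuracy (or argmax, per flag)
    overall_argmax: float
    per_group: pd.Series
    loci_used: dict[int, list[str]]


def montecarlo_xval(
    table: GenotypeTable,
    engine: str = "dapc",
    scheme: str = "leave_n",
    n_or_frac: float = 10,
    reps: int = 20,
    loci: str = "all",
    n_pcs: int | None = None,
    threshold: float = 2.0,
    inconclusive_as_error: bool = True,
    seed: int = 0,
) -> XvalResult:
    """Stratified Monte-Carlo cross-validation of panel diagnostic power.

    Per replicate: hold out ``n_or_frac`` individuals (count for ``leave_n``,
    proportion for ``fraction``) from each reference group, refit everything -
    including the F_ST locus ranking when ``loci='top_half_fst'`` - on the
    training split only, and score the held-out individuals.  Accuracy counts
    an inconclusive test individual as incorrect by default (the argmax-only
    convention is also reported).
    """
    if table.group is None:
        raise ValueError("reference table needs group labels")
    rng = np.random.default_rng(seed)
    groups = table.group.loc[table.individuals]
    by_group = {g: list(groups.index[groups == g]) for g in dict.fromkeys(groups)}
    rows = []
    loci_used: dict[int, list[str]] = {}
    for rep in range(reps):
        test_ids: list[str] = []
        for g, inds in by_group.items():
            k = (
                int(n_or_frac)
                if scheme == "leave_n"
                else max(1, int(round(n_or_frac * len(inds))))
            )
            if k >= len(inds):
                raise ValueError(f"group {g!r} too small for holdout of {k}")
            test_ids.extend(rng.choice(inds, size=k, replace=False))
        train_ids = [i for i in table.individuals if i not in set(test_ids)]
        train = table.subset(individuals=train_ids)
        if loci == "top_half_fst":
            keep = top_fst_loci(train, by="group", fraction=0.5)
        elif loci == "all":
            keep = None
        else:
            raise ValueError(f"unknown loci scheme {loci!r}")
        loci_used[rep] = keep if keep is not None else list(table.panel.ids)
        panel = ReferencePanel(train, loci_subset=keep, n_pcs=n_pcs).fit(
            seed=int(rng.integers(0, 2**31 - 1))
        )
        test = table.subset(
            individuals=test_ids, loci=keep if keep is not None else None
        )
        dec, _ = assign(panel, test, engine=engine, threshold=threshold)
        truth = table.group.loc[test_ids]
        for g in by_group:
            mask = truth == g
            sub = dec.loc[truth.index[mask]]
            correct_argmax = (sub["best_group"] == g).mean()
            correct_decisive = (
                ((sub["best_group"] == g) & (sub["status"] == ASSIGNED)).mean()
            )
            rows.append(
                {
                    "rep": rep,
                    "group": g,
                    "n_test": int(mask.sum()),
                    "accuracy": float(
                        correct_decisive if inconclusive_as_error else correct_argmax
                    ),
                    "accuracy_decisive": float(correct_decisive),
                    "accuracy_argmax": float(correct_argmax),
                }
            )
    per_rep = pd.DataFrame(rows)
    return XvalResult(
        per_rep=per_rep,
        overall=float(per_rep["accuracy"].mean()),
        overall_argmax=float(per_rep["accuracy_argmax"].mean()),
        per_group=per_rep.groupby("group")["accuracy"].mean(),
        loci_used=loci_used,
    )
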