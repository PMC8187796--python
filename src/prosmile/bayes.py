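"""Conditional-probability model of prosocial behavior.

The analysis reduces each walking/falling episode to binary flags —
smiling ``S``, heading toward the robot ``H``, prompting ``P``,
approaching ``A`` and the outcome, prosocial behavior ``PB`` — and asks
how well the first three predict the outcome.  The machinery is a small
discrete Bayesian network: a joint probability table over the flags,
conditionals obtained by Bayes' rule

    P(PB | S) = P(S, PB) / P(S),

and per-predictor-subset conditional probability tables scored by
subject-wise leave-one-out cross-validation (every fold holds out all
cases of one participant).

Two arithmetic modes exist side by side.  *Exact* mode works on the
integer counts.  *Rounded* mode first rounds each cell proportion
half-up to a fixed number of decimals and does all arithmetic on those
rounded values — this is how small-sample tables are conventionally
reported, and the two modes can differ visibly at n = 36 (e.g. 0.42/0.50
= 0.84 rounded vs 15/18 = 0.833 exact), so results always carry both.

The public face follows the fitted-model idiom:
``SmileProsocialModel(cases).fit()`` returns a
:class:`SmileProsocialResults` with the tables, conditionals, a
``summary()`` and cross-validation — the module-level functions it
delegates to remain available for direct use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CaseRecord, classify_case

PREDICTORS = ("S", "H", "P")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (0.425 -> 0.43)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _flags(case) -> dict[str, int]:
    if isinstance(case, Mapping):
        return {k: int(case[k]) for k in case}
    return {k: getattr(case, k) for k in ("S", "H", "A", "P", "PB")}


# ---------------------------------------------------------------------------
# joint probability tables


@dataclass
class JointProbabilityTable:
    """Counts and (rounded) proportions over binary variables.

    ``counts[v1, ..., vk]`` is the number of cases in which variable ``i``
    took value ``vi`` (1 = flag set).  Rounded proportions are a
    presentation layer: the integer counts stay the source of truth.
    """

    variables: tuple[str, ...]
    counts: np.ndarray
    round_decimals: int = 2

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2,) * len(self.variables):
            raise ValueError("counts shape must be (2,)*k for k variables")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table needs at least one case")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def rounded(self) -> np.ndarray:
        vec = [round_half_up(p, self.round_decimals) for p in self.proportions.ravel()]
        return np.array(vec).reshape(self.counts.shape)

    def _table(self, use_rounded: bool) -> np.ndarray:
        return self.rounded if use_rounded else self.proportions

    def probability(self, assignment: Mapping[str, int], use_rounded: bool = False) -> float:
        """P(assignment), marginalizing over unmentioned variables."""
        unknown = set(assignment) - set(self.variables)
        if unknown:
            raise KeyError(f"variables {sorted(unknown)} not in table {self.variables}")
        table = self._table(use_rounded)
        idx = tuple(
            assignment.get(v, slice(None)) for v in self.variables
        )
        return float(np.asarray(table[idx]).sum())

    def marginal(self, variable: str, value: int = 1, use_rounded: bool = False) -> float:
        return self.probability({variable: value}, use_rounded=use_rounded)

    def to_dataframe(self, use_rounded: bool = True) -> pd.DataFrame:
        """2-variable table in the published layout (first variable on rows,
        'Yes' before 'No', with marginal totals)."""
        if len(self.variables) != 2:
            raise ValueError("dataframe layout is defined for 2-variable tables")
        t = self._table(use_rounded)
        rows, cols = self.variables
        df = pd.DataFrame(
            [[t[1, 1], t[1, 0]], [t[0, 1], t[0, 0]]],
            index=pd.Index(["Yes", "No"], name=rows),
            columns=pd.Index(["Yes", "No"], name=cols),
        )
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        return df


def build_joint_table(
    cases: Sequence, variables: Sequence[str] = ("S", "PB"), round_decimals: int = 2
) -> JointProbabilityTable:
    """Tally cases into a joint table over the given binary variables."""
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    variables = tuple(variables)
    counts = np.zeros((2,) * len(variables), dtype=int)
    for case in cases:
        f = _flags(case)
        counts[tuple(f[v] for v in variables)] += 1
    return JointProbabilityTable(variables=variables, counts=counts, round_decimals=round_decimals)


def conditional_probability(
    table: JointProbabilityTable,
    target: str = "PB",
    given: Mapping[str, int] | None = None,
    use_rounded: bool = True,
) -> float:
    """P(target = 1 | given) by Bayes' rule on the table.

    In rounded mode both numerator and denominator are sums of *rounded*
    cell proportions, reproducing published-table arithmetic; in exact
    mode they are count ratios.
    """
    given = dict(given or {})
    den = table.probability(given, use_rounded=use_rounded) if given else 1.0
    if den <= 0:
        raise ZeroDivisionError(
            f"conditioning event {given} has zero probability"
        )
    num = table.probability({**given, target: 1}, use_rounded=use_rounded)
    return num / den


def smile_share_of_pb(table: JointProbabilityTable, use_rounded: bool = True) -> int:
    """Percent of all prosocial behavior preceded by a smile.

    ``100 × P(S∧PB)/P(PB)`` rounded half-up to a whole percent.
    """
    p_pb = table.probability({"PB": 1}, use_rounded=use_rounded)
    if p_pb <= 0:
        return 0
    share = table.probability({"S": 1, "PB": 1}, use_rounded=use_rounded) / p_pb
    return int(round_half_up(100.0 * share, 0))


# ---------------------------------------------------------------------------
# predictor CPTs and subject-wise LOO-CV


@dataclass
class PredictorModel:
    """P(PB | predictor pattern) from training relative frequencies."""

    predictors: tuple[str, ...]
    table: dict[tuple[int, ...], float]
    fallback: float                      # training PB rate, for unseen patterns
    majority: int                        # training-majority PB class (tie -> 1)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for p in list(self.table.values()) + [self.fallback]:
            if not (0.0 <= p <= 1.0):
                raise ValueError("stored probabilities must lie in [0, 1]")

    def probability(self, case) -> float:
        f = _flags(case)
        return self.table.get(tuple(f[p] for p in self.predictors), self.fallback)

    def predict(self, case) -> int:
        p = self.probability(case)
        if p > self.threshold:
            return 1
        if p < self.threshold:
            return 0
        return self.majority


def fit_predictor_model(
    training_cases: Sequence,
    predictor_set: Sequence[str] = ("S",),
    smoothing: float = 0.0,
    threshold: float = 0.5,
) -> PredictorModel:
    """Estimate P(PB | predictors) per observed pattern.

    ``smoothing`` adds that many pseudo-counts to each of the two outcome
    cells of every observed pattern (0 by default — small-sample tables
    here are reported unsmoothed).
    """
    cases = list(training_cases)
    if not cases:
        raise ValueError("training cases must be non-empty")
    predictors = tuple(predictor_set)
    tallies: dict[tuple[int, ...], list[int]] = {}
    pb_total = 0
    for case in cases:
        f = _flags(case)
        key = tuple(f[p] for p in predictors)
        cell = tallies.setdefault(key, [0, 0])
        cell[f["PB"]] += 1
        pb_total += f["PB"]
    table = {
        key: (pos + smoothing) / (neg + pos + 2 * smoothing)
        for key, (neg, pos) in tallies.items()
    }
    rate = pb_total / len(cases)
    majority = 1 if rate >= 0.5 else 0
    return PredictorModel(
        predictors=predictors,
        table=table,
        fallback=rate,
        majority=majority,
        threshold=threshold,
    )


def all_predictor_subsets(
    predictors: Sequence[str] = PREDICTORS,
) -> list[tuple[str, ...]]:
    """Non-empty subsets: singletons, pairs, the full set."""
    out = []
    for r in range(1, len(predictors) + 1):
        out.extend(itertools.combinations(predictors, r))
    return out


def loo_cv(
    cases: Sequence,
    predictor_subsets: Sequence[Sequence[str]] | None = None,
    group_filter: str | None = None,
    smoothing: float = 0.0,
    threshold: float = 0.5,
    average: str = "participant",
) -> pd.DataFrame:
    """Subject-wise leave-one-out cross-validation accuracy per subset.

    Each fold holds out every case of one participant, fits the
    conditional table on the remainder, and scores the held-out cases.
    ``average="participant"`` (default) reports the unweighted mean of
    per-participant accuracies; ``"case"`` pools all held-out cases.
    """
    if average not in ("participant", "case"):
        raise ValueError("average must be 'participant' or 'case'")
    cases = list(cases)
    if group_filter is not None:
        cases = [c for c in cases if _group(c) == group_filter]
    if not cases:
        raise ValueError(f"no cases (group_filter={group_filter!r})")
    by_participant: dict[str, list] = {}
    for c in cases:
        by_participant.setdefault(_participant(c), []).append(c)
    if len(by_participant) < 2:
        raise ValueError("subject-wise LOO-CV needs at least 2 participants")
    for pid, owned in by_participant.items():
        if len(owned) == len(cases):
            raise ValueError(f"participant {pid} owns every case; no training data in their fold")
    subsets = (
        [tuple(s) for s in predictor_subsets]
        if predictor_subsets is not None
        else all_predictor_subsets()
    )
    rows = []
    for subset in subsets:
        per_participant = []
        hits = total = 0
        for pid, held in by_participant.items():
            training = [c for c in cases if _participant(c) != pid]
            model = fit_predictor_model(training, subset, smoothing=smoothing, threshold=threshold)
            correct = [int(model.predict(c) == _flags(c)["PB"]) for c in held]
            per_participant.append(sum(correct) / len(correct))
            hits += sum(correct)
            total += len(correct)
        acc = float(np.mean(per_participant)) if average == "participant" else hits / total
        rows.append(
            {
                "subset": "+".join(subset),
                "predictors": subset,
                "accuracy": acc,
                "n_participants": len(by_participant),
                "n_cases": len(cases),
            }
        )
    return pd.DataFrame(rows)


def _participant(case) -> str:
    if isinstance(case, Mapping):
        return str(case.get("participant_id", ""))
    return case.participant_id


def _group(case) -> str:
    if isinstance(case, Mapping):
        return str(case.get("group", ""))
    return case.group


def _case_id(case) -> str:
    if isinstance(case, Mapping):
        return str(case.get("participant_id", "?"))
    return f"{case.participant_id}/s{case.session}/{case.situation}"


def voluntary_consistency_check(cases: Sequence) -> dict:
    """Tabulate support for the two observed regularities.

    Claim 1: a child who smiled *and* helped did so voluntarily (no
    prompting) — conditioning on helping matters, since smiling without
    helping also occurs.  Claim 2: a child who helped without smiling
    had been prompted.  Pure description per group — counts plus the
    violating cases listed; no test statistic.
    """
    report: dict[str, dict] = {}
    for case in cases:
        grp = _group(case) or "all"
        sec = report.setdefault(
            grp,
            {
                "smile_pb_implies_voluntary": {"support": 0, "violations": 0, "violating_cases": []},
                "no_smile_pb_implies_prompt": {"support": 0, "violations": 0, "violating_cases": []},
            },
        )
        f = _flags(case)
        if f["S"] == 1 and f["PB"] == 1:
            c1 = sec["smile_pb_implies_voluntary"]
            if f["P"] == 0:
                c1["support"] += 1
            else:
                c1["violations"] += 1
                c1["violating_cases"].append(_case_id(case))
        if f["S"] == 0 and f["PB"] == 1:
            c2 = sec["no_smile_pb_implies_prompt"]
            if f["P"] == 1:
                c2["support"] += 1
            else:
                c2["violations"] += 1
                c2["violating_cases"].append(_case_id(case))
    return report


# ---------------------------------------------------------------------------
# case-table I/O

_CASE_COLUMNS = ["participant", "group", "session", "situation", "S", "H", "A", "P", "PB"]


def cases_to_dataframe(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": c.participant_id,
                "group": c.group,
                "session": c.session,
                "situation": c.situation,
                "S": c.S,
                "H": c.H,
                "A": c.A,
                "P": c.P,
                "PB": c.PB,
            }
            for c in cases
        ],
        columns=_CASE_COLUMNS,
    )


def dataframe_to_cases(df: pd.DataFrame) -> list[CaseRecord]:
    missing = [c for c in _CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case table missing columns {missing}")
    return [
        CaseRecord(
            participant_id=str(r.participant),
            group=str(r.group),
            session=int(r.session),
            situation=str(r.situation),
            S=int(r.S),
            H=int(r.H),
            A=int(r.A),
            P=int(r.P),
            PB=int(r.PB),
        )
        for r in df.itertuples()
    ]


def write_case_table(cases: Sequence[CaseRecord], path: str | Path) -> None:
    cases_to_dataframe(cases).to_csv(path, sep="\t", index=False)


def read_case_table(path: str | Path) -> list[CaseRecord]:
    return dataframe_to_cases(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# fitted-model interface


class SmileProsocialModel:
    """Discrete predictors → prosocial-behavior model over a case table.

    Parameters
    ----------
    cases : sequence of CaseRecord (or flag mappings)
        One record per walking/falling episode.

    Examples
    --------
    >>> from prosmile.synth import generate_case_table
    >>> results = SmileProsocialModel(generate_case_table(36)).fit()
    >>> round(results.p_pb_given_smile, 2)
    0.84
    """

    def __init__(self, cases: Sequence):
        self.cases = list(cases)
        if not self.cases:
            raise ValueError("need at least one case")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SmileProsocialModel":
        return cls(dataframe_to_cases(df))

    def fit(self, round_decimals: int = 2, smoothing: float = 0.0) -> "SmileProsocialResults":
        joint = build_joint_table(self.cases, ("S", "PB"), round_decimals=round_decimals)
        return SmileProsocialResults(self, joint, smoothing=smoothing)


class SmileProsocialResults:
    """Estimates, tables and cross-validation for a fitted model."""

    def __init__(self, model: SmileProsocialModel, joint: JointProbabilityTable, smoothing: float = 0.0):
        self.model = model
        self.joint = joint
        self.smoothing = smoothing

    # conditionals ---------------------------------------------------------
    def p_pb_given(self, given: Mapping[str, int], use_rounded: bool = True) -> float:
        return conditional_probability(self.joint, "PB", given, use_rounded=use_rounded)

    @property
    def p_pb_given_smile(self) -> float:
        return self.p_pb_given({"S": 1})

    @property
    def p_pb_given_no_smile(self) -> float:
        return self.p_pb_given({"S": 0})

    def smile_share_of_pb(self, use_rounded: bool = True) -> int:
        return smile_share_of_pb(self.joint, use_rounded=use_rounded)

    # cross-validation and diagnostics ------------------------------------
    def loo_cv(self, predictor_subsets=None, group_filter=None, average="participant") -> pd.DataFrame:
        return loo_cv(
            self.model.cases,
            predictor_subsets=predictor_subsets,
            group_filter=group_filter,
            smoothing=self.smoothing,
            average=average,
        )

    def voluntary_consistency(self) -> dict:
        return voluntary_consistency_check(self.model.cases)

    def case_classes(self) -> pd.Series:
        return pd.Series([classify_case(c) for c in self.model.cases], name="case_class")

    # presentation ---------------------------------------------------------
    def to_report(self) -> dict:
        """JSON-serializable bundle of every estimate, both modes."""
        j = self.joint
        return {
            "n_cases": j.n,
            "variables": list(j.variables),
            "counts": {
                "S&PB": int(j.counts[1, 1]),
                "S&!PB": int(j.counts[1, 0]),
                "!S&PB": int(j.counts[0, 1]),
                "!S&!PB": int(j.counts[0, 0]),
            },
            "rounding": {"decimals": j.round_decimals, "mode": "half-up"},
            "joint_rounded": {
                "S&PB": j.rounded[1, 1],
                "S&!PB": j.rounded[1, 0],
                "!S&PB": j.rounded[0, 1],
                "!S&!PB": j.rounded[0, 0],
            },
            "marginals_rounded": {
                "P(S)": j.marginal("S", use_rounded=True),
                "P(PB)": j.marginal("PB", use_rounded=True),
            },
            "conditionals": {
                "rounded": {
                    "P(PB|S)": self.p_pb_given({"S": 1}, use_rounded=True),
                    "P(PB|!S)": self.p_pb_given({"S": 0}, use_rounded=True),
                },
                "exact": {
                    "P(PB|S)": self.p_pb_given({"S": 1}, use_rounded=False),
                    "P(PB|!S)": self.p_pb_given({"S": 0}, use_rounded=False),
                },
            },
            "smile_share_of_pb_pct": {
                "rounded": self.smile_share_of_pb(True),
                "exact": self.smile_share_of_pb(False),
            },
            "case_classes": self.case_classes().value_counts().sort_index().to_dict(),
        }

    def summary(self) -> str:
        j = self.joint
        rep = self.to_report()
        lines = [
            "Smile → prosocial behavior model",
            "=" * 48,
            f"cases: {j.n}    rounding: {j.round_decimals} decimals, half-up",
            "",
            "Joint probability table (rounded | exact counts):",
        ]
        for key in ("S&PB", "S&!PB", "!S&PB", "!S&!PB"):
            lines.append(
                f"  {key:<7} {rep['joint_rounded'][key]:>5.2f}   ({rep['counts'][key]})"
            )
        lines += [
            f"  P(S)  = {rep['marginals_rounded']['P(S)']:.2f}"
            f"    P(PB) = {rep['marginals_rounded']['P(PB)']:.2f}",
            "",
            "Conditionals (rounded mode | exact mode):",
            f"  P(PB|S)  = {rep['conditionals']['rounded']['P(PB|S)']:.2f} | "
            f"{rep['conditionals']['exact']['P(PB|S)']:.3f}",
            f"  P(PB|S̄)  = {rep['conditionals']['rounded']['P(PB|!S)']:.2f} | "
            f"{rep['conditionals']['exact']['P(PB|!S)']:.3f}",
            f"  smile share of PB = {rep['smile_share_of_pb_pct']['rounded']}% | "
            f"{rep['smile_share_of_pb_pct']['exact']}%",
            "",
            "Case quadrants: "
            + ", ".join(f"{k}={v}" for k, v in rep["case_classes"].items()),
        ]
        return "\n".join(lines)

    def plot_joint(self, ax=None):
        """Bar chart of the four joint cells (rounded mode)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        rep = self.to_report()
        keys = ["S&PB", "S&!PB", "!S&PB", "!S&!PB"]
        ax.bar(range(4), [rep["joint_rounded"][k] for k in keys], color="#4477aa")
        ax.set_xticks(range(4), ["S∧PB", "S∧¬PB", "¬S∧PB", "¬S∧¬PB"])
        ax.set_ylabel("probability")
        ax.set_title(f"Smile × prosocial behavior (n={rep['n_cases']})")
        return ax
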