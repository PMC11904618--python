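"""Iterative refinement of identifiable parameter subsets.

The PSS ladder provides nested candidate subsets; for each threshold, the
posterior is sampled with DRAM and judged against three criteria:

C1  no algebraically related pairs — a near single-valued pairwise posterior
    (|correlation| at or above a threshold on raw or log samples) indicates a
    dependence the data cannot break; one member of the pair is fixed at its
    nominal value, guided by the dimensional-analysis relation and the PSS
    elimination order;
C2  informed posteriors — a marginal indistinguishable from its uniform prior
    (small Kolmogorov–Smirnov distance) means the data do not inform the
    parameter, which is then fixed at its nominal value;
C3  convergence — every per-parameter effective sample size must reach a
    threshold (default 1000); one chain-length escalation (x4) is attempted
    before a row is declared unresolved.

A parameter fixed once stays excluded from all later (larger) subsets; the
final refined subset is the largest one over all thresholds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import kstest

from .dimensional import AlgebraicRelation, DimensionalReduction, algebraic_relation
from .models import ModelSpec, TimeGrid
from .pss import EliminationTrace, SubsetLadder
from .sampling import (
    BayesianCalibration,
    CalibrationResults,
    PriorSpec,
    effective_sample_size,
)

__all__ = [
    "CriterionVerdict",
    "RefinementRow",
    "RefinementReport",
    "detect_single_valued_pairs",
    "prior_informed",
    "choose_fix_parameter",
    "run_refinement",
]

logger = logging.getLogger("pkident")


# ---------------------------------------------------------------------------
# Criterion detectors
# ---------------------------------------------------------------------------

def detect_single_valued_pairs(
    samples: np.ndarray,
    names: Sequence[str],
    threshold: float = 0.995,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Flag parameter pairs whose joint posterior is nearly single-valued.

    For each pair the absolute Pearson correlation is computed on the raw
    samples and, for strictly positive parameters, on the log samples; the
    pair is flagged when either reaches ``threshold``.  Degenerate
    (zero-variance) marginals are reported separately, not as pairs.

    Returns (flagged_pairs, degenerate_parameters); pairs are ordered by
    parameter index.
    """
    X = np.asarray(samples, dtype=float)
    if X.shape[0] < 200:
        raise ValueError("need at least 200 post-burn-in samples")
    if X.shape[1] != len(names):
        raise ValueError("names do not match sample columns")
    sd = X.std(axis=0)
    scale = np.maximum(np.abs(X.mean(axis=0)), 1e-300)
    degenerate = [names[j] for j in range(X.shape[1]) if sd[j] <= 1e-12 * scale[j]]
    ok = [j for j in range(X.shape[1]) if names[j] not in degenerate]

    flagged = []
    for i, j in itertools.combinations(ok, 2):
        xi, xj = X[:, i], X[:, j]
        r = abs(np.corrcoef(xi, xj)[0, 1])
        if r < threshold and np.all(xi > 0) and np.all(xj > 0):
            r = max(r, abs(np.corrcoef(np.log(xi), np.log(xj))[0, 1]))
        if r >= threshold:
            flagged.append((names[i], names[j]))
    return flagged, degenerate


def prior_informed(
    samples: np.ndarray,
    prior_bounds: tuple[float, float],
    delta: float = 0.1,
) -> bool:
    """True when the marginal posterior differs from its uniform prior.

    Computes the Kolmogorov–Smirnov distance between the empirical marginal
    and the uniform law on ``prior_bounds``; the parameter is *uninformed*
    (returns False) when the distance is strictly below ``delta``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 200:
        raise ValueError("need at least 200 post-burn-in samples")
    low, high = prior_bounds
    if np.any(x < low) or np.any(x > high):
        raise ValueError(
            "samples fall outside the prior bounds; the sampler violated "
            "its support"
        )
    dist = kstest(x, "uniform", args=(low, high - low)).statistic
    return not dist < delta


def choose_fix_parameter(
    pair: tuple[str, str],
    relation: Optional[AlgebraicRelation] = None,
    trace: Optional[EliminationTrace] = None,
    override: Optional[str] = None,
) -> tuple[str, str]:
    """Pick which member of a flagged pair to fix at its nominal value.

    Precedence: an explicit user override; else the member eliminated earlier
    in the PSS trace (the less identifiable one); else the later-listed
    member.  Returns (parameter, reason); the dimensional relation, when
    available, is attached to the report for justification only.
    """
    a, b = pair
    if override is not None:
        if override not in pair:
            raise ValueError(f"override {override!r} is not in the pair {pair}")
        return override, "user override"
    if trace is not None and (
        a in trace.parameter_names and b in trace.parameter_names
    ):
        ka, kb = trace.eliminated_before(a), trace.eliminated_before(b)
        if ka != kb:
            pick = a if ka < kb else b
            return pick, "eliminated earlier in the PSS trace"
    return b, "later-listed pair member"


# ---------------------------------------------------------------------------
# Verdicts and report
# ---------------------------------------------------------------------------

@dataclass
class CriterionVerdict:
    """Outcome of the three refinement criteria for one DRAM run."""

    c1_pairs: list[tuple[str, str]]
    c1_degenerate: list[str]
    c2_uninformed: list[str]
    c3_ess: dict[str, float]
    ess_threshold: float

    @property
    def c1_pass(self) -> bool:
        return not self.c1_pairs and not self.c1_degenerate

    @property
    def c2_pass(self) -> bool:
        return not self.c2_uninformed

    @property
    def c3_pass(self) -> bool:
        return all(e >= self.ess_threshold for e in self.c3_ess.values())

    @property
    def passed(self) -> bool:
        return self.c1_pass and self.c2_pass and self.c3_pass

    def to_dict(self) -> dict:
        return {
            "c1_pairs": [list(p) for p in self.c1_pairs],
            "c1_degenerate": self.c1_degenerate,
            "c2_uninformed": self.c2_uninformed,
            "c3_ess": {k: float(v) for k, v in self.c3_ess.items()},
            "passed": self.passed,
        }


@dataclass
class RefinementRow:
    """One threshold's worth of refinement: starting candidates, what was
    excluded and why, and the verdict of each rerun."""

    eta: float
    starting: list[str]
    refined: list[str]
    excluded: dict[str, str]          # parameter -> criterion ("C1"/"C2")
    verdicts: list[CriterionVerdict]
    resolved: bool
    relations: list[AlgebraicRelation] = field(default_factory=list)
    results: Optional[CalibrationResults] = None

    def __post_init__(self) -> None:
        if set(self.refined) | set(self.excluded) != set(self.starting):
            raise ValueError("refined ∪ excluded must equal the starting candidates")

    def to_dict(self) -> dict:
        return {
            "eta": self.eta,
            "starting": self.starting,
            "refined": self.refined,
            "excluded": self.excluded,
            "verdicts": [v.to_dict() for v in self.verdicts],
            "resolved": self.resolved,
            "relations": [r.to_dict() for r in self.relations],
        }


@dataclass
class RefinementReport:
    """Full refinement report: one row per threshold plus the final subset."""

    rows: list[RefinementRow]
    final: list[str]

    def to_dict(self) -> dict:
        return {"rows": [r.to_dict() for r in self.rows], "final": self.final}

    def to_text(self) -> str:
        lines = [
            f"{'eta':>10}  {'refined candidates':<40} C1 C2 C3  excluded",
            "-" * 80,
        ]
        for row in self.rows:
            v = row.verdicts[-1] if row.verdicts else None
            marks = (
                "  ".join("+" if ok else "x" for ok in
                          (v.c1_pass, v.c2_pass, v.c3_pass))
                if v is not None else " -  -  -"
            )
            excl = ", ".join(f"{p}({c})" for p, c in row.excluded.items()) or "—"
            lines.append(
                f"{row.eta:>10.3g}  {', '.join(row.refined):<40} {marks}  {excl}"
            )
        lines.append(f"final refined subset: {', '.join(self.final)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Algorithm driver
# ---------------------------------------------------------------------------

def _verdict(
    results: CalibrationResults,
    priors: PriorSpec,
    c1_threshold: float,
    c2_delta: float,
    ess_threshold: float,
) -> CriterionVerdict:
    post = results.chain.post_burn_in
    names = results.param_names
    pairs, degenerate = detect_single_valued_pairs(post, names, c1_threshold)
    uninformed = []
    for j, name in enumerate(names):
        bounds = (priors.lows[j], priors.highs[j])
        if not prior_informed(post[:, j], bounds, c2_delta):
            uninformed.append(name)
    ess = {name: float(e) for name, e in zip(names, results.ess)}
    return CriterionVerdict(
        c1_pairs=pairs,
        c1_degenerate=degenerate,
        c2_uninformed=uninformed,
        c3_ess=ess,
        ess_threshold=ess_threshold,
    )


def run_refinement(
    model: ModelSpec,
    data_times: np.ndarray,
    data_values: np.ndarray,
    ladder: SubsetLadder,
    *,
    draws: int = 50_000,
    seed: Optional[int] = None,
    trace: Optional[EliminationTrace] = None,
    reduction: Optional[DimensionalReduction] = None,
    overrides: Optional[dict[frozenset, str]] = None,
    priors: Optional[PriorSpec] = None,
    c1_threshold: float = 0.995,
    c2_delta: float = 0.1,
    ess_threshold: float = 1000.0,
    max_reruns: int = 5,
    grid: Optional[TimeGrid] = None,
    keep_results: bool = False,
    **fit_options,
) -> RefinementReport:
    """Iterate DRAM over the subset ladder, fixing parameters that fail the
    criteria, and report the largest refined subset.

    For each threshold (largest first) the starting candidates are the
    ladder subset minus everything excluded at earlier thresholds.  Within a
    row: sample, evaluate the verdict; on a C1 failure fix one member of the
    first flagged pair (see :func:`choose_fix_parameter`); on a C2 failure
    fix all uninformed parameters at once; on a C3 failure escalate the
    chain length once (x4); stop when the verdict passes or after
    ``max_reruns`` resamplings (row marked unresolved).
    """
    ss = np.random.SeedSequence(seed)
    excluded_global: dict[str, str] = {}
    rows: list[RefinementRow] = []

    for row_idx, (eta, subset0, _) in enumerate(ladder.rows()):
        starting = [p for p in subset0 if p not in excluded_global]
        if not starting:
            raise ValueError(f"no parameters to sample at threshold {eta}")
        current = list(starting)
        excluded_here: dict[str, str] = {}
        verdicts: list[CriterionVerdict] = []
        relations: list[AlgebraicRelation] = []
        row_draws = draws
        escalated = False
        resolved = False
        results = None

        for attempt in range(max_reruns + 1):
            run_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            sub_priors = (
                PriorSpec(
                    names=current,
                    lows=np.array([priors.lows[priors.names.index(n)]
                                   for n in current]),
                    highs=np.array([priors.highs[priors.names.index(n)]
                                    for n in current]),
                )
                if priors is not None
                else None
            )
            calib = BayesianCalibration(
                data_values, data_times, model, current,
                priors=sub_priors, grid=grid,
            )
            results = calib.fit(draws=row_draws, seed=run_seed, **fit_options)
            verdict = _verdict(
                results, calib.priors, c1_threshold, c2_delta, ess_threshold
            )
            verdicts.append(verdict)
            logger.info(
                "eta=%g attempt=%d subset=%s C1=%s C2=%s C3=%s",
                eta, attempt, current,
                verdict.c1_pass, verdict.c2_pass, verdict.c3_pass,
            )
            if verdict.passed:
                resolved = True
                break
            if not verdict.c1_pass:
                to_fix: list[tuple[str, str]] = []
                if verdict.c1_pairs:
                    pair = verdict.c1_pairs[0]
                    override = (overrides or {}).get(frozenset(pair))
                    relation = (
                        algebraic_relation(reduction, pair)
                        if reduction is not None else None
                    )
                    if relation is not None:
                        relations.append(relation)
                    pick, reason = choose_fix_parameter(
                        pair, relation=relation, trace=trace, override=override
                    )
                    to_fix.append((pick, f"C1 ({reason})"))
                else:
                    # a degenerate marginal is itself a C1 exclusion
                    to_fix.append((verdict.c1_degenerate[0], "C1 (degenerate)"))
                for pick, why in to_fix:
                    excluded_here[pick] = "C1"
                    excluded_global[pick] = "C1"
                    current = [p for p in current if p != pick]
                    logger.info("fixing %s at nominal: %s", pick, why)
            elif not verdict.c2_pass:
                for name in verdict.c2_uninformed:
                    excluded_here[name] = "C2"
                    excluded_global[name] = "C2"
                current = [p for p in current if p not in verdict.c2_uninformed]
            elif not verdict.c3_pass:
                if escalated:
                    logger.warning(
                        "eta=%g unresolved: ESS below %g after escalation",
                        eta, ess_threshold,
                    )
                    break
                row_draws *= 4
                escalated = True
            if not current:
                break

        rows.append(
            RefinementRow(
                eta=eta,
                starting=starting,
                refined=current if resolved else
                        [p for p in starting if p not in excluded_here],
                excluded=excluded_here,
                verdicts=verdicts,
                resolved=resolved,
                relations=relations,
                results=results if keep_results else None,
            )
        )

    candidates = [r.refined for r in rows if r.resolved]
    if not candidates or all(len(c) == 0 for c in candidates):
        raise RuntimeError(
            "no subset consistent with successful inference; revisit the PSS "
            "screening"
        )
    final = max(reversed(candidates), key=len)
    return RefinementReport(rows=rows, final=final)
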