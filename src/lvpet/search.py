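"""Data-driven structural model building with FDR-controlled Wald tests.

Mirrors the study's model-building loop: first prune latent predictors
that are not supported (largest Wald p above alpha, refitting after each
removal; genotype terms are protected), then greedily add one path per
iteration — the candidate with the smallest Wald p, admitted only while
its Benjamini–Hochberg q-value across *all* remaining candidates stays
below the threshold (q < 0.05 by default).  Candidates are every absent
covariate->region direct path plus every absent residual-covariance pair;
all remaining candidates are re-tested each iteration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .sem import LatentFactorModel, LatentFactorResults, ModelError, ModelSpec, prepare_design

__all__ = [
    "PathCandidate",
    "bh_adjust",
    "prune_latent_predictors",
    "enumerate_candidates",
    "step",
    "search",
    "SearchTrace",
]

#: Latent predictors never dropped by pruning (the genotype questions).
PROTECTED_PREDICTORS = ("bdnf_group", "shttlpr_group")


@dataclass(frozen=True)
class PathCandidate:
    """One testable model extension."""

    kind: str  # "direct" or "resid_cov"
    ids: tuple[str, str]  # (covariate, region) or (region, region)
    wald_p: float = np.nan
    q_value: float = np.nan
    converged: bool = True

    @property
    def param_name(self) -> str:
        if self.kind == "direct":
            return f"delta_{self.ids[0]}__{self.ids[1]}"
        return f"thetacov_{self.ids[0]}__{self.ids[1]}"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    input order.  NaN entries (non-converged candidates) stay NaN but
    still count in the denominator m.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q = np.full(m, np.nan)
    idx = np.argsort(p[finite])
    ps = p[finite][idx]
    k = ps.size
    raw = ps * m / (np.arange(k) + 1)
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty(k)
    out[idx] = np.minimum(adj, 1.0)
    q[finite] = out
    return q


def enumerate_candidates(
    spec: ModelSpec, candidate_covariates: tuple[str, ...] = ()
) -> list[PathCandidate]:
    """All admissible single-path extensions of a spec, deterministic order.

    Direct candidates pair each candidate covariate (the modelled ones by
    default; pass ``candidate_covariates`` to also offer covariates pruned
    from the latent regression) with each region, excluding paths already
    present and — to protect identification of the reference scale —
    paths from current latent predictors onto the reference outcome.
    Residual-covariance candidates are the absent region pairs.
    """
    pool: dict[str, None] = {}
    for cov in spec.covariates:
        pool.setdefault(cov, None)
    for cov in candidate_covariates:
        pool.setdefault(cov, None)
    existing = set(spec.all_direct_paths)
    out: list[PathCandidate] = []
    for cov in pool:
        for region in spec.outcomes:
            if (cov, region) in existing:
                continue
            if spec.latent and cov in spec.latent_predictors and region == spec.reference_outcome:
                continue
            out.append(PathCandidate("direct", (cov, region)))
    present_pairs = set(spec.resid_cov_pairs)
    for a, b in combinations(sorted(spec.outcomes), 2):
        if (a, b) not in present_pairs:
            out.append(PathCandidate("resid_cov", (a, b)))
    return out


def _augment(spec: ModelSpec, cand: PathCandidate) -> ModelSpec:
    if cand.kind == "direct":
        return replace(spec, direct_paths=spec.direct_paths + (cand.ids,))
    return replace(spec, resid_cov_pairs=spec.resid_cov_pairs + (cand.ids,))


def _fit(spec: ModelSpec, data: pd.DataFrame, start_hint: pd.Series | None = None) -> LatentFactorResults:
    model = LatentFactorModel(data, spec)
    start = None
    if start_hint is not None:
        start = model.start_params()
        for i, name in enumerate(model.par.names):
            if name in start_hint.index:
                start[i] = start_hint[name]
    return model.fit(start_params=start)


def prune_latent_predictors(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    protected: tuple[str, ...] = PROTECTED_PREDICTORS,
) -> tuple[ModelSpec, LatentFactorResults]:
    """Iteratively drop the least-supported latent predictor.

    Refits after each removal; stops when every remaining unprotected
    predictor has Wald p <= alpha.  Returns the pruned spec and its fit.
    """
    fit = _fit(spec, data)
    while True:
        droppable = [c for c in spec.latent_predictors if c not in protected]
        if not droppable:
            return spec, fit
        pvals = {c: fit.wald_test(f"beta_{c}").p for c in droppable}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            return spec, fit
        spec = replace(
            spec, latent_predictors=tuple(c for c in spec.latent_predictors if c != worst)
        )
        fit = _fit(spec, data, start_hint=fit.params)


@dataclass
class StepReport:
    """Candidate table and action of one forward-search iteration."""

    candidates: list[PathCandidate]
    added: PathCandidate | None
    stopped: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [c.kind for c in self.candidates],
                "id_a": [c.ids[0] for c in self.candidates],
                "id_b": [c.ids[1] for c in self.candidates],
                "p": [c.wald_p for c in self.candidates],
                "q": [c.q_value for c in self.candidates],
                "converged": [c.converged for c in self.candidates],
            }
        )


def step(
    spec: ModelSpec,
    data: pd.DataFrame,
    q_threshold: float = 0.05,
    base_fit: LatentFactorResults | None = None,
    candidate_covariates: tuple[str, ...] = (),
) -> tuple[ModelSpec, StepReport]:
    """One greedy forward-search iteration.

    Fits each single-candidate augmentation, Wald-tests the added
    parameter, BH-adjusts across all candidates, and adds the smallest-p
    candidate if its q-value clears the threshold (ties broken by
    enumeration order).  Non-converged candidate fits are skipped with
    p recorded as missing; they still count in the BH denominator.
    """
    if base_fit is None:
        base_fit = _fit(spec, data)
    candidates = enumerate_candidates(spec, candidate_covariates)
    if not candidates:
        return spec, StepReport([], None, stopped=True)
    scored: list[PathCandidate] = []
    for cand in candidates:
        try:
            fit = _fit(_augment(spec, cand), data, start_hint=base_fit.params)
            if not fit.converged:
                raise ModelError("candidate fit did not converge")
            p = fit.wald_test(cand.param_name).p
            scored.append(dataclasses.replace(cand, wald_p=p))
        except (ModelError, np.linalg.LinAlgError):
            scored.append(dataclasses.replace(cand, converged=False))
    q = bh_adjust([c.wald_p for c in scored])
    scored = [dataclasses.replace(c, q_value=qv) for c, qv in zip(scored, q)]
    finite = [c for c in scored if not np.isnan(c.wald_p)]
    if not finite:
        return spec, StepReport(scored, None, stopped=True)
    best = min(finite, key=lambda c: c.wald_p)  # min is stable: ties keep enumeration order
    if best.q_value < q_threshold:
        return _augment(spec, best), StepReport(scored, best, stopped=False)
    return spec, StepReport(scored, None, stopped=True)


@dataclass
class SearchTrace:
    """Iteration-by-iteration record of a forward search."""

    iterations: list[StepReport]
    initial_spec: ModelSpec
    final_spec: ModelSpec

    @property
    def added_paths(self) -> list[PathCandidate]:
        return [it.added for it in self.iterations if it.added is not None]

    def replay(self) -> ModelSpec:
        """Re-apply the recorded additions to the initial spec."""
        spec = self.initial_spec
        for cand in self.added_paths:
            spec = _augment(spec, cand)
        return spec

    def to_jsonl(self, path: str | Path | None = None) -> str:
        lines = []
        for i, it in enumerate(self.iterations):
            lines.append(
                json.dumps(
                    {
                        "iteration": i + 1,
                        "candidates": it.to_frame().to_dict(orient="records"),
                        "action": (
                            {"added": {"kind": it.added.kind, "ids": list(it.added.ids)}}
                            if it.added
                            else {"stopped": True}
                        ),
                    }
                )
            )
        text = "\n".join(lines) + ("\n" if lines else "")
        if path is not None:
            Path(path).write_text(text)
        return text


def search(
    spec: ModelSpec,
    data: pd.DataFrame,
    q_threshold: float = 0.05,
    max_iter: int = 10,
    candidate_covariates: tuple[str, ...] = (),
) -> tuple[ModelSpec, LatentFactorResults, SearchTrace]:
    """Greedy forward search: repeat :func:`step` until no candidate clears
    the q-threshold or ``max_iter`` additions were made; the final model is
    refitted.  Returns (final spec, final fit, trace)."""
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    initial = spec
    reports: list[StepReport] = []
    fit = _fit(spec, data)
    for _ in range(max_iter):
        new_spec, report = step(
            spec, data, q_threshold=q_threshold, base_fit=fit,
            candidate_covariates=candidate_covariates,
        )
        reports.append(report)
        if report.stopped:
            break
        spec = new_spec
        fit = _fit(spec, data, start_hint=fit.params)
    return spec, fit, SearchTrace(reports, initial, spec)


def build_model(
    cohort: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    prune_alpha: float = 0.05,
    q_threshold: float = 0.05,
    max_iter: int = 10,
) -> tuple[ModelSpec, LatentFactorResults, SearchTrace]:
    """Full model-building pipeline on a raw cohort: prepare the design,
    prune latent predictors, then forward-search additional paths."""
    data = prepare_design(cohort)
    spec = base_spec or ModelSpec.base()
    pool = spec.covariates  # pruned covariates stay eligible for direct paths
    spec, _ = prune_latent_predictors(spec, data, alpha=prune_alpha)
    spec, fit, trace = search(
        spec, data, q_threshold=q_threshold, max_iter=max_iter, candidate_covariates=pool
    )
    # final pruning pass: a latent predictor retained only because its
    # region-specific effect had no direct path yet (e.g. sex before the
    # caudate path is added) is released once the search has run
    spec, final_fit = prune_latent_predictors(spec, data, alpha=prune_alpha)
    if spec != trace.final_spec:
        fit = final_fit  # the trace keeps the pre-pruning search record
    return spec, fit, trace
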