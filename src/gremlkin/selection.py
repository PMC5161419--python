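"""Stepwise selection of variance components with dual LRT/Wald criteria.

Backward selection starts from the full model (e.g. GKFSC) and
repeatedly removes the component that (1) fails to reach significance at
level alpha in *both* the boundary LRT and the one-sided Wald test and
(2) has the highest Wald p among those, stopping when every remaining
component is significant in at least one test.

Forward selection starts from the null model (fixed effects only) and
repeatedly adds the candidate that (1) is itself significant in both
tests, (2) does not push any component already in the model to
non-significance in both tests, and (3) has the lowest Wald p among
candidates passing (1) and (2), stopping when no candidate qualifies.

Ties in Wald p resolve by the fixed component order G, K, F, S, C.
Candidate refits that fail to converge are logged and treated as failing
significance rather than aborting the selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .reml import (
    REMLError,
    REMLFit,
    REMLOptions,
    VarianceComponentSpec,
    fit_reml,
    lrt_component,
    wald_component,
)

__all__ = ["SelectionTrace", "backward_select", "forward_select"]

logger = logging.getLogger(__name__)

COMPONENT_ORDER = "GKFSC"


def _order_key(label: str):
    i = COMPONENT_ORDER.find(label)
    return (i if i >= 0 else len(COMPONENT_ORDER), label)


@dataclass
class SelectionTrace:
    """Ordered record of add/remove/stop steps and the final model."""

    steps: list[dict] = field(default_factory=list)
    final_model: str = ""
    final_fit: REMLFit | None = None

    def record(self, action: str, component: str | None, lrt_p, wald_p,
               before: str, after: str) -> None:
        self.steps.append({
            "action": action, "component": component,
            "lrt_p": lrt_p, "wald_p": wald_p,
            "model_before": before, "model_after": after,
        })


class _FitCache:
    """Memoize fits by component-label set (fit is order-invariant)."""

    def __init__(self, y, X, full_spec, sample_ids, options):
        self.y, self.X = y, X
        self.by_label = dict(full_spec.components)
        self.sample_ids = sample_ids
        self.options = options
        self._cache: dict[frozenset, REMLFit | None] = {}

    def spec(self, labels) -> VarianceComponentSpec:
        ordered = sorted(labels, key=_order_key)
        return VarianceComponentSpec([(lab, self.by_label[lab]) for lab in ordered])

    def fit(self, labels) -> REMLFit | None:
        """Fit the model with the given label set; None on failure."""
        key = frozenset(labels)
        if key not in self._cache:
            try:
                f = fit_reml(self.y, self.X, self.spec(labels),
                             sample_ids=self.sample_ids, options=self.options)
                if not f.converged:
                    logger.warning("fit %s did not converge", "".join(sorted(labels)))
                    f = None
            except REMLError as exc:
                logger.warning("fit %s failed: %s", "".join(sorted(labels)), exc)
                f = None
            self._cache[key] = f
        return self._cache[key]

    def component_pvalues(self, labels, component) -> tuple[float, float] | None:
        """(lrt_p, wald_p) for one component inside the given model."""
        full = self.fit(labels)
        reduced = self.fit(set(labels) - {component})
        if full is None or reduced is None:
            return None
        lrt = lrt_component(full, reduced, component)
        wald = wald_component(full, component)
        return lrt.lrt_p, wald.wald_p


def backward_select(
    y,
    X,
    full_spec: VarianceComponentSpec,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
    options: REMLOptions | None = None,
) -> SelectionTrace:
    """Backward stepwise elimination from the full model."""
    if sample_ids is None:
        sample_ids = full_spec.components[0][1].sample_ids
    cache = _FitCache(y, X, full_spec, sample_ids, options or REMLOptions())
    current = set(full_spec.labels)
    if cache.fit(current) is None:
        raise REMLError(f"full model {full_spec.model_code} failed to converge")
    trace = SelectionTrace()
    while current:
        removable = []
        for lab in sorted(current, key=_order_key):
            pv = cache.component_pvalues(current, lab)
            if pv is None:
                logger.info("component %s: candidate refit failed; kept", lab)
                continue
            lrt_p, wald_p = pv
            if lrt_p >= alpha and wald_p >= alpha:
                removable.append((lab, lrt_p, wald_p))
        if not removable:
            break
        # highest Wald p removed first; ties by fixed component order
        lab, lrt_p, wald_p = max(
            removable, key=lambda t: (t[2], tuple(-x for x in _order_key(t[0])[0:1]))
        )
        before = "".join(sorted(current, key=_order_key))
        current = current - {lab}
        after = "".join(sorted(current, key=_order_key))
        trace.record("remove", lab, lrt_p, wald_p, before, after)
    code = "".join(sorted(current, key=_order_key))
    trace.record("stop", None, None, None, code, code)
    trace.final_model = code
    trace.final_fit = cache.fit(current) if current else None
    return trace


def forward_select(
    y,
    X,
    full_spec: VarianceComponentSpec,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
    options: REMLOptions | None = None,
) -> SelectionTrace:
    """Forward stepwise addition from the null (fixed-effects-only) model."""
    if sample_ids is None:
        sample_ids = full_spec.components[0][1].sample_ids
    cache = _FitCache(y, X, full_spec, sample_ids, options or REMLOptions())
    current: set[str] = set()
    trace = SelectionTrace()
    while True:
        eligible = []
        for cand in sorted(set(full_spec.labels) - current, key=_order_key):
            labels = current | {cand}
            pv = cache.component_pvalues(labels, cand)
            if pv is None:
                logger.info("candidate %s: refit failed; treated as non-significant", cand)
                continue
            lrt_p, wald_p = pv
            if not (lrt_p < alpha and wald_p < alpha):
                continue
            # criterion (2): existing components must stay significant
            # in at least one test after the addition
            ok = True
            for lab in current:
                pv2 = cache.component_pvalues(labels, lab)
                if pv2 is None or (pv2[0] >= alpha and pv2[1] >= alpha):
                    ok = False
                    break
            if ok:
                eligible.append((cand, lrt_p, wald_p))
        if not eligible:
            break
        cand, lrt_p, wald_p = min(
            eligible, key=lambda t: (t[2], _order_key(t[0]))
        )
        before = "".join(sorted(current, key=_order_key))
        current = current | {cand}
        after = "".join(sorted(current, key=_order_key))
        trace.record("add", cand, lrt_p, wald_p, before, after)
    code = "".join(sorted(current, key=_order_key))
    trace.record("stop", None, None, None, code, code)
    trace.final_model = code
    trace.final_fit = cache.fit(current) if current else None
    return trace
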