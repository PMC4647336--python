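"""Cross-model backward stepwise selection over three linked regressions.

Three models share one term list: GP density and specialist density (both
with a population offset) and the GP/specialist mix, realized as GP counts
with the log specialist count as offset so the exponentiated linear
predictor is the GP-per-specialist ratio.  A term is kept while it is
significant at the 0.05 level in at least one model; otherwise the term
whose smallest p-value across the models is largest is dropped, all three
models are refit, and the procedure repeats.  Main effects are never
dropped while one of their interactions remains, and region dummies and
the intercept are never candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ztnb
from .errors import ConfigError, FitError
from .ztnb import FitSettings, ModelSpec, ZTNBFit

__all__ = [
    "MODELS",
    "TripleModelState",
    "SelectionReport",
    "full_model_specs",
    "fit_state",
    "keep_rule",
    "backward_stepwise",
    "selection_report",
    "significance_stars",
]

MODELS = ("gp", "sp", "ratio")
DEFAULT_ALPHA = 0.05


def _column_for(term: str) -> str:
    """Design-matrix column name of a selectable term (identity mapping)."""
    return term


def _split_terms(terms, table: pd.DataFrame):
    """Partition term names into metric, binary and interaction tuples."""
    metric, binary, interactions = [], [], []
    for term in terms:
        if ":" in term:
            left, right = term.split(":", 1)
            interactions.append((left, right))
        elif term in table.columns and table[term].isin([0, 1]).all():
            binary.append(term)
        else:
            metric.append(term)
    return tuple(metric), tuple(binary), tuple(interactions)


@dataclass(frozen=True)
class TripleModelState:
    """Shared term list, three specs and (optionally) their fits."""

    terms: tuple[str, ...]
    specs: dict[str, ModelSpec]
    fits: dict[str, ZTNBFit] = field(default_factory=dict)
    history: tuple[dict, ...] = ()
    bic_first: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        for name in MODELS:
            if name not in self.specs:
                raise ConfigError(f"missing spec for model {name!r}")
            if self.specs[name].term_names != self.terms:
                raise ConfigError(f"spec {name!r} does not match the shared term list")

    @property
    def fitted(self) -> bool:
        return set(self.fits) == set(MODELS)

    def bic_final(self) -> dict[str, float]:
        return {name: self.fits[name].bic for name in MODELS}


def full_model_specs(
    table: pd.DataFrame,
    terms,
    *,
    region_col: str = "region",
    reference_region: str | None = None,
) -> TripleModelState:
    """Initial state: all three specs over the identical full term list."""
    metric, binary, interactions = _split_terms(terms, table)
    ordered = (*metric, *binary, *(f"{a}:{b}" for a, b in interactions))
    missing = [t for t in (*metric, *binary) if t not in table.columns]
    if missing:
        raise ConfigError(f"terms missing from table: {missing}")
    common = dict(
        metric=metric,
        binary=binary,
        interactions=interactions,
        region_col=region_col,
        reference_region=reference_region,
    )
    specs = {
        "gp": ModelSpec(response="gp_count", offset=ztnb.OFFSET_POPULATION, **common),
        "sp": ModelSpec(response="sp_count", offset=ztnb.OFFSET_POPULATION, **common),
        "ratio": ModelSpec(response="gp_count", offset=ztnb.OFFSET_SP_COUNT, **common),
    }
    return TripleModelState(terms=ordered, specs=specs)


def fit_state(
    state: TripleModelState,
    table: pd.DataFrame,
    settings: FitSettings = FitSettings(),
) -> TripleModelState:
    """Fit all three models of a state on the given table."""
    fits = {
        name: ztnb.fit_table(table, spec, settings=settings)
        for name, spec in state.specs.items()
    }
    bic_first = state.bic_first or {name: fits[name].bic for name in MODELS}
    return replace(state, fits=fits, bic_first=bic_first)


def _live_interaction_parents(terms) -> set[str]:
    parents: set[str] = set()
    for term in terms:
        if ":" in term:
            parents.update(term.split(":", 1))
    return parents


def keep_rule(
    term: str, fits: dict[str, ZTNBFit], alpha: float = DEFAULT_ALPHA
) -> bool:
    """True iff the term must stay.

    Kept when significant at ``alpha`` in at least one model, or when it is
    a parent of an interaction still present (hierarchy).
    """
    any_fit = next(iter(fits.values()))
    if any_fit.spec is None or term not in any_fit.spec.term_names:
        raise ConfigError(f"term {term!r} not present in the fitted models")
    if term in _live_interaction_parents(any_fit.spec.term_names):
        return True
    pvals = [fit.pvalue(_column_for(term)) for fit in fits.values()]
    return min(pvals) < alpha


def _min_pvalue(term: str, fits: dict[str, ZTNBFit]) -> float:
    return min(fit.pvalue(_column_for(term)) for fit in fits.values())


def _drop_term(state: TripleModelState, term: str) -> TripleModelState:
    new_terms = tuple(t for t in state.terms if t != term)
    specs = {}
    for name, spec in state.specs.items():
        if ":" in term:
            pair = tuple(term.split(":", 1))
            specs[name] = replace(
                spec, interactions=tuple(p for p in spec.interactions if p != pair)
            )
        elif term in spec.metric:
            specs[name] = replace(spec, metric=tuple(t for t in spec.metric if t != term))
        else:
            specs[name] = replace(spec, binary=tuple(t for t in spec.binary if t != term))
    return replace(state, terms=new_terms, specs=specs, fits={})


def backward_stepwise(
    state: TripleModelState,
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    settings: FitSettings = FitSettings(),
) -> TripleModelState:
    """Run the cross-model backward elimination to completion.

    Each step drops, among the droppable terms, the one with the largest
    minimum-across-models p-value (ties broken by reverse entry order) and
    refits all three models.  Terminates when every remaining term is kept.
    A refit failure aborts with the history preserved on the raised error.
    """
    if not state.fitted:
        state = fit_state(state, table, settings=settings)
    step = 0
    while True:
        droppable = [t for t in state.terms if not keep_rule(t, state.fits, alpha)]
        if not droppable:
            break
        # largest min-p; ties -> the term entered last goes first
        order = {t: i for i, t in enumerate(state.terms)}
        victim = max(droppable, key=lambda t: (_min_pvalue(t, state.fits), order[t]))
        record = {
            "step": step,
            "dropped": victim,
            "p_values": {m: float(state.fits[m].pvalue(_column_for(victim))) for m in MODELS},
            "min_p": float(_min_pvalue(victim, state.fits)),
        }
        new_state = _drop_term(state, victim)
        new_state = replace(new_state, history=(*state.history, record),
                            bic_first=state.bic_first)
        try:
            new_state = fit_state(new_state, table, settings=settings)
        except FitError as err:
            err.diagnostics["history"] = [*state.history, record]
            raise
        state = new_state
        step += 1
    return state


def significance_stars(p: float) -> str:
    """Star code: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class SelectionReport:
    """Tabular summary of a completed selection run."""

    term_table: pd.DataFrame
    bic_table: pd.DataFrame
    history: tuple[dict, ...]

    def to_markdown(self) -> str:
        return (
            self.term_table.to_markdown(floatfmt=".3f")
            + "\n\n"
            + self.bic_table.to_markdown(floatfmt=".1f")
        )


def selection_report(state: TripleModelState) -> SelectionReport:
    """Per-term estimates, p-values and stars per model, plus first/final BIC."""
    if not state.fitted:
        raise ConfigError("state must be fitted before reporting")
    rows = []
    for term in ("intercept", *state.terms):
        row: dict = {"term": term}
        for model in MODELS:
            fit = state.fits[model]
            row[f"{model}_estimate"] = fit.coef(_column_for(term))
            p = fit.pvalue(_column_for(term))
            row[f"{model}_p"] = p
            row[f"{model}_sig"] = significance_stars(p)
        rows.append(row)
    term_table = pd.DataFrame(rows).set_index("term")
    bic_table = pd.DataFrame(
        {
            "bic_first": {m: state.bic_first.get(m, np.nan) for m in MODELS},
            "bic_final": state.bic_final(),
        }
    )
    bic_table.index.name = "model"
    return SelectionReport(term_table=term_table, bic_table=bic_table, history=state.history)
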