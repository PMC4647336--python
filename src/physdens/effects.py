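"""Back-transformation of fitted coefficients to reported quantities.

Coefficients of the count models live on the log-density scale; this module
converts them to the numbers a reader sees: predicted densities per 10 000
inhabitants, the density change implied by a two-standard-deviation
covariate increase, net coefficients where an interaction modifies a main
effect, and ratio-scale entries for the GP/specialist mix model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .selection import MODELS, SelectionReport, significance_stars
from .ztnb import ZTNBFit

__all__ = [
    "EffectSummary",
    "density_from_eta",
    "two_sd_effect",
    "net_effect_with_interaction",
    "effect_table",
    "render_report",
]

COEF_DECIMALS = 3
DENSITY_DECIMALS = 2


def density_from_eta(eta: float) -> float:
    """Density per 10 000 inhabitants implied by a log density."""
    if not np.isfinite(eta):
        raise ConfigError("eta must be finite")
    return float(np.exp(eta))


def two_sd_effect(baseline_eta: float, beta: float) -> float:
    """Density change for a two-SD covariate increase from the baseline.

    ``exp(eta) * (exp(beta) - 1)``, identical to
    ``density_from_eta(eta + beta) - density_from_eta(eta)``.
    """
    if not (np.isfinite(baseline_eta) and np.isfinite(beta)):
        raise ConfigError("inputs must be finite")
    return float(np.exp(baseline_eta) * np.expm1(beta))


def net_effect_with_interaction(beta_main: float, beta_interaction: float) -> float:
    """Effect of a metric term where the interacting indicator equals 1."""
    if not (np.isfinite(beta_main) and np.isfinite(beta_interaction)):
        raise ConfigError("inputs must be finite")
    return float(beta_main + beta_interaction)


@dataclass(frozen=True)
class EffectSummary:
    """Back-transformed report for one fitted model."""

    model: str
    baseline_eta: float
    baseline_density: float
    table: pd.DataFrame  # per term: estimate, p, stars, density effect, net

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "baseline_eta": self.baseline_eta,
            "baseline_density": round(self.baseline_density, DENSITY_DECIMALS),
            "terms": [
                {
                    "term": term,
                    **{
                        key: (None if pd.isna(val) else round(float(val), 6))
                        if key != "sig"
                        else val
                        for key, val in row.items()
                    },
                }
                for term, row in self.table.iterrows()
            ],
        }


def effect_table(fit: ZTNBFit, model: str = "gp") -> EffectSummary:
    """Assemble the per-term effect summary for one fit.

    The baseline district has all metric terms at their sample mean (scaled
    zero), all binaries zero and sits in the reference region, so the
    baseline log density is the intercept.  For metric terms the scaling
    record must be present so the two-SD reading is meaningful.
    """
    if fit.spec is None:
        raise ConfigError("fit carries no model spec")
    eta0 = fit.coef("intercept")
    base = density_from_eta(eta0)
    interaction_of = {a: f"{a}:{b}" for a, b in fit.spec.interactions}
    rows = []
    for term in fit.spec.term_names:
        beta = fit.coef(term)
        p = fit.pvalue(term)
        if ":" not in term and term in fit.spec.metric and term not in fit.scaling:
            raise ConfigError(f"missing scaling record for metric term {term!r}")
        net = np.nan
        if term in interaction_of:
            net = net_effect_with_interaction(beta, fit.coef(interaction_of[term]))
        rows.append(
            {
                "term": term,
                "estimate": beta,
                "p": p,
                "sig": significance_stars(p),
                "density_effect": two_sd_effect(eta0, beta),
                "net_estimate": net,
            }
        )
    columns = ["term", "estimate", "p", "sig", "density_effect", "net_estimate"]
    table = pd.DataFrame(rows, columns=columns).set_index("term")
    return EffectSummary(
        model=model, baseline_eta=eta0, baseline_density=base, table=table
    )


def render_report(
    summaries: dict[str, EffectSummary],
    selection: SelectionReport | None = None,
    *,
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
    markdown_path: str | Path | None = None,
) -> dict:
    """Render the combined report; returns the JSON-ready payload.

    Output ordering is fixed (models in canonical order, terms in entry
    order), so re-rendering the same artifacts is byte-identical.
    """
    payload: dict = {
        "models": [
            summaries[m].to_dict() for m in MODELS if m in summaries
        ],
    }
    if selection is not None:
        payload["bic"] = {
            model: {
                "first": round(float(selection.bic_table.loc[model, "bic_first"]), 1),
                "final": round(float(selection.bic_table.loc[model, "bic_final"]), 1),
            }
            for model in selection.bic_table.index
        }
        payload["drop_history"] = list(selection.history)

    frames = []
    for model in MODELS:
        if model not in summaries:
            continue
        frame = summaries[model].table.copy()
        frame.insert(0, "model", model)
        frames.append(frame.reset_index())
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not combined.empty:
        combined["estimate"] = combined["estimate"].round(COEF_DECIMALS)
        combined["net_estimate"] = combined["net_estimate"].round(COEF_DECIMALS)
        combined["density_effect"] = combined["density_effect"].round(DENSITY_DECIMALS)

    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    if csv_path is not None:
        combined.to_csv(csv_path, index=False)
    if markdown_path is not None:
        parts = [combined.to_markdown(index=False)]
        if selection is not None:
            parts.append(selection.bic_table.to_markdown(floatfmt=".1f"))
        Path(markdown_path).write_text("\n\n".join(parts) + "\n")
    return payload
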