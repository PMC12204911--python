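"""Model comparison and reporting for fitted twin models.

The full model family (ACE vs ADE) is chosen by AIC; the nested AE and CE
reductions are then tested against the chosen full model by likelihood-
ratio tests, and the most parsimonious adequately fitting model is
reported.  Output tables mirror the usual twin-study layout: one row per
model with variance components (95% CI), AIC, df, the LRT p-value and the
MZ/DZ correlations.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .continuous import TwinModelFit


def aic(fit: TwinModelFit) -> float:
    """Akaike Information Criterion, 2k - 2 log L (lower is better)."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik


def lrt(full: TwinModelFit, nested: TwinModelFit,
        boundary_mixture: bool = False) -> float:
    """Likelihood-ratio test p-value of a nested against a full model.

    The statistic 2*(logL_full - logL_nested) is referred to chi-square
    with df equal to the parameter-count difference.  Dropping a variance
    component tests a boundary hypothesis; the conventional plain
    chi-square test is the default, ``boundary_mixture`` uses the 50:50
    chi2(0):chi2(df) mixture instead (halving the p-value).
    """
    if nested.n_params >= full.n_params:
        raise ValueError("nested model must have fewer parameters")
    if nested.loglik > full.loglik + 1e-6:
        raise ValueError(
            f"nested model loglik {nested.loglik:.6f} exceeds full model "
            f"{full.loglik:.6f}: optimizer failure")
    statistic = max(2.0 * (full.loglik - nested.loglik), 0.0)
    df = full.n_params - nested.n_params
    p = float(stats.chi2.sf(statistic, df))
    if boundary_mixture:
        p = 0.5 * p if statistic > 0 else 1.0
    return min(p, 1.0)


@dataclass
class SelectionResult:
    """Outcome of the ACE/ADE -> AE/CE selection with a full audit trail."""

    selected_label: str
    selected: TwinModelFit
    full_label: str
    audit: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "selected": self.selected_label,
            "full_model": self.full_label,
            "audit": self.audit,
        }, indent=2)


def select_model(fits: dict[str, TwinModelFit], alpha: float = 0.05,
                 boundary_mixture: bool = False) -> SelectionResult:
    """Pick the reported (parsimonious) model.

    1. Between ACE and ADE, the full model is the one with the lower AIC.
    2. The nested AE and CE models are tested against that full model by
       LRT; candidates with non-significant p (>= alpha) are admissible.
    3. Among admissible nested models the one with the lowest AIC wins
       (ties: fewer parameters, then lower AIC, then label order); if no
       nested model is admissible the full model is reported.

    Every candidate appears exactly once in the audit trail.
    """
    for lbl in ("ACE", "ADE", "AE", "CE"):
        if lbl not in fits:
            raise ValueError(f"select_model requires an {lbl} fit")
    audit: list[dict] = []
    full_label = min(("ACE", "ADE"), key=lambda l: (aic(fits[l]), l))
    for lbl in ("ACE", "ADE"):
        audit.append({"model": lbl, "aic": aic(fits[lbl]),
                      "role": "full", "chosen_full": lbl == full_label})
    full = fits[full_label]

    admissible: list[str] = []
    for lbl in ("AE", "CE"):
        p = lrt(full, fits[lbl], boundary_mixture=boundary_mixture)
        ok = p >= alpha
        audit.append({"model": lbl, "aic": aic(fits[lbl]), "role": "nested",
                      "lrt_p": p, "admissible": ok})
        if ok:
            admissible.append(lbl)

    if admissible:
        selected_label = min(
            admissible,
            key=lambda l: (aic(fits[l]), fits[l].n_params, l))
    else:
        selected_label = full_label
    for entry in audit:
        entry["selected"] = entry["model"] == selected_label
    return SelectionResult(selected_label, fits[selected_label],
                           full_label, audit)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.2775 -> 0.28), as printed in reports."""
    if x != x:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float, nd: int = 2) -> str:
    if x != x:
        return ""
    return f"{round_half_up(x, nd):.{nd}f}"


def _fmt_ci(est: float, ci: tuple[float, float] | None, nd: int = 2) -> str:
    if est != est:
        return ""
    if not ci or any(v != v for v in ci):
        return _fmt(est, nd)
    return f"{_fmt(est, nd)} ({_fmt(ci[0], nd)}–{_fmt(ci[1], nd)})"


def render_results(fits: dict[str, TwinModelFit],
                   selection: SelectionResult | None = None,
                   style: str = "table2") -> pd.DataFrame:
    """Arrange fitted models as a report table.

    ``style`` picks the layout family: "table2" for continuous traits
    (model-implied twin correlations), "table3"/"table4" for binary traits
    (tetrachoric-style correlation columns).  Components and correlations
    are half-up rounded to 2 decimals, AIC to 1; the LRT p-value is shown
    for the selected (parsimonious) model only, which is flagged.
    """
    if style not in ("table2", "table3", "table4"):
        raise ValueError(f"unknown style {style!r}")
    order = [l for l in ("SAT", "ACE", "ADE", "AE", "CE", "E") if l in fits]
    lrt_p = {}
    if selection is not None:
        for entry in selection.audit:
            if entry.get("role") == "nested":
                lrt_p[entry["model"]] = entry["lrt_p"]
    rows = []
    for lbl in order:
        fit = fits[lbl]
        ci = fit.ci95 or {}
        c = fit.components
        preferred = selection is not None and lbl == selection.selected_label
        if c is None:
            a = cd = e = ""
        else:
            a = _fmt_ci(c.a2, ci.get("a2")) if c.a2 or lbl in ("ACE", "ADE", "AE") else ""
            if lbl in ("ACE", "CE"):
                cd = _fmt_ci(c.c2, ci.get("c2"))
            elif lbl == "ADE":
                cd = _fmt_ci(c.d2, ci.get("d2"))
            else:
                cd = ""
            e = _fmt_ci(c.e2, ci.get("e2"))
        rows.append({
            "trait": fit.trait,
            "model": lbl,
            "A": a,
            "C_or_D": cd,
            "E": e,
            "AIC": _fmt(aic(fit), 1),
            "df": fit.n_params,
            "p": (_fmt(lrt_p[lbl], 2)
                  if preferred and lbl in lrt_p else ""),
            "r_MZ": _fmt_ci(fit.implied_r_mz, ci.get("r_mz")),
            "r_DZ": _fmt_ci(fit.implied_r_dz, ci.get("r_dz")),
            "preferred": preferred,
        })
    return pd.DataFrame(rows)


def render_text(table: pd.DataFrame) -> str:
    """Human-readable rendition of a results table."""
    if table.empty:
        return "(no fitted models)\n"
    return table.to_string(index=False) + "\n"
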