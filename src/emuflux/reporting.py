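"""Result files, flux-map rendering and diagnostic plots.

The flux map is an SVG drawn by the user (e.g. in Inkscape) in which any
text node whose entire content equals a reaction id acts as a placeholder;
rendering replaces it with the fitted flux formatted to two decimals.  For a
reversible pair, the placeholder carrying the forward (FR) reaction's id
receives the net flux (forward minus reverse); a placeholder with the
reverse (R) id receives the directional reverse flux.

``write_results`` emits delimited-text tables (flux values and CIs,
calculated vs measured MIDs, the per-start fit log, a goodness-of-fit
report) plus the raw Monte-Carlo sample matrix both as CSV and as a pickle
(the pickle is a convenience copy and is not portable across library
versions).
"""

from __future__ import annotations

import logging
import os
import pickle
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from . import uncertainty
from .estimation import FitResult
from .model_io import MeasuredFragment, MetabolicModel
from .uncertainty import MonteCarloSummary

__all__ = ["render_flux_map", "write_results", "plot_residuals_and_boxes"]

log = logging.getLogger("emuflux")

SVG_NS = "http://www.w3.org/2000/svg"


# ---------------------------------------------------------------------------
# flux map
# ---------------------------------------------------------------------------

def _display_values(model: MetabolicModel, fit: FitResult) -> dict[str, float]:
    """Reaction id -> value printed on the map (net flux for FR ids)."""
    v = dict(zip(fit.reaction_ids, fit.v))
    out = dict(v)
    for rxn in model.mass_balance_reactions:
        if rxn.rtype == "FR" and rxn.pair_id in v:
            out[rxn.id] = v[rxn.id] - v[rxn.pair_id]
    return out


def render_flux_map(template, model: MetabolicModel, fit: FitResult) -> str:
    """Substitute fitted flux values into an SVG template.

    ``template`` is a path or the SVG text itself.  Returns the rendered SVG
    as a string; a template without placeholders is returned byte-identical.
    """
    if hasattr(template, "read"):
        text = template.read()
    elif isinstance(template, str) and "<" in template:
        text = template
    else:
        with open(os.fspath(template)) as fh:
            text = fh.read()

    ET.register_namespace("", SVG_NS)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ValueError(f"malformed SVG template: {exc}")

    values = _display_values(model, fit)
    replaced = set()
    n_replaced = 0
    for elem in root.iter():
        t = (elem.text or "").strip()
        if t in values:
            if t in replaced:
                log.warning("placeholder %s matched more than once", t)
                continue
            elem.text = f"{values[t]:.2f}"
            replaced.add(t)
            n_replaced += 1
    for rid in values:
        if rid not in replaced:
            log.debug("reaction %s has no placeholder in the template", rid)
    if n_replaced == 0:
        return text
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------

def _formula(rxn) -> str:
    def side(refs):
        return " + ".join(
            (f"{r.coef:g} {r.metabolite}" if r.coef != 1.0 else r.metabolite)
            for r in refs)
    return f"{side(rxn.reactants)} -> {side(rxn.products)}"


def flux_table(model: MetabolicModel, fit: FitResult,
               summary: MonteCarloSummary | None = None) -> pd.DataFrame:
    """Per-reaction flux table with net values for reversible pairs and
    bootstrap CI columns when a Monte-Carlo summary is available."""
    v = dict(zip(fit.reaction_ids, fit.v))
    rows = []
    for rxn in model.mass_balance_reactions:
        net = v[rxn.id]
        if rxn.rtype == "FR" and rxn.pair_id in v:
            net = v[rxn.id] - v[rxn.pair_id]
        elif rxn.rtype == "R" and rxn.pair_id in v:
            net = v[rxn.pair_id] - v[rxn.id]
        row = {"id": rxn.id, "formula": _formula(rxn), "type": rxn.rtype,
               "flux": v[rxn.id], "net_flux": net,
               "free": rxn.id in fit.free_reaction_ids}
        if summary is not None:
            for pc, val in zip(summary.percentiles, summary.row(rxn.id)):
                row[f"p{pc:g}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def mid_table(fit: FitResult, measurements: list[MeasuredFragment]) -> pd.DataFrame:
    rows = []
    for f in measurements:
        calc = fit.mids[f.fragment_id]
        for k in range(f.n_points):
            rows.append({"fragment": f.fragment_id, "mass": f"M+{k}",
                         "measured": f.mid[k], "calculated": calc[k],
                         "sd": f.sd[k],
                         "residual": (calc[k] - f.mid[k]) / f.sd[k]})
    return pd.DataFrame(rows)


def write_results(fit: FitResult, summary: MonteCarloSummary | None,
                  out_dir, model: MetabolicModel,
                  measurements: list[MeasuredFragment],
                  alpha: float = 0.05) -> dict[str, str]:
    """Write all result files into ``out_dir``; returns the file manifest."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, str] = {}

    def path(name):
        p = os.path.join(out_dir, name)
        manifest[name] = p
        return p

    flux_table(model, fit, summary).to_csv(path("fluxes.csv"), index=False)
    mid_table(fit, measurements).to_csv(path("mids.csv"), index=False)

    pd.DataFrame([
        {"start": i, "ssr": r.ssr, "penalized_cost": r.cost,
         "n_evaluations": r.n_evaluations, "success": r.success}
        for i, r in enumerate(fit.starts)
    ]).to_csv(path("fit_log.csv"), index=False)

    gof = uncertainty.gof_range(fit.n, fit.p, alpha=alpha)
    # verdict applies the upper limit only: an SSR below the lower quantile
    # means an unexpectedly good fit (e.g. overestimated errors), not a
    # model rejection; the full range is still reported.
    pd.DataFrame([{
        "ssr": fit.ssr, "n": fit.n, "p": fit.p, "df": gof.df,
        "alpha": gof.alpha, "lower": gof.lower, "upper": gof.upper,
        "verdict": "accepted" if fit.ssr <= gof.upper else "rejected",
    }]).to_csv(path("gof.csv"), index=False)

    if summary is not None and summary.samples.size:
        df = pd.DataFrame(summary.samples, columns=summary.reaction_ids)
        df.to_csv(path("mc_samples.csv"), index=False)
        with open(path("mc_samples.pckl"), "wb") as fh:  # non-portable copy
            pickle.dump(df, fh)
    else:
        manifest["mc_samples"] = "absent (no Monte-Carlo summary)"
    return manifest


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_residuals_and_boxes(fit: FitResult,
                             measurements: list[MeasuredFragment],
                             summary: MonteCarloSummary | None,
                             out_dir,
                             reactions: list[str] | None = None) -> list[str]:
    """Residual bar chart per measured MID entry plus bootstrap box plots
    (boxes 16–84, whiskers 2.5–97.5 percentiles) for selected reactions."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    files = []

    df = mid_table(fit, measurements)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(df)), 4))
    labels = df["fragment"] + " " + df["mass"]
    ax.bar(range(len(df)), df["calculated"] - df["measured"])
    ax.set_xticks(range(len(df)), labels, rotation=90, fontsize=7)
    ax.set_ylabel("calculated - measured MID")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    p = os.path.join(out_dir, "residuals.png")
    fig.savefig(p, dpi=150)
    plt.close(fig)
    files.append(p)

    if summary is not None:
        if reactions is None:
            reactions = summary.reaction_ids
        unknown = set(reactions) - set(summary.reaction_ids)
        if unknown:
            raise ValueError(f"unknown reaction ids in selection: {sorted(unknown)}")
        stats = []
        for rid in reactions:
            lo95, lo68, med, hi68, hi95 = summary.row(rid)
            stats.append({"label": rid, "med": med, "q1": lo68, "q3": hi68,
                          "whislo": lo95, "whishi": hi95, "fliers": []})
        fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(stats)), 4))
        ax.bxp(stats, showfliers=False)
        ax.set_ylabel("flux (basis units)")
        fig.tight_layout()
        p = os.path.join(out_dir, "flux_boxes.png")
        fig.savefig(p, dpi=150)
        plt.close(fig)
        files.append(p)
    return files
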