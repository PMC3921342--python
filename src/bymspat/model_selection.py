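"""Forward covariate selection by DIC over repeated seeded runs.

At each step every remaining candidate is added to the current model and
fitted with ``n_seeds`` different seeds; a candidate is accepted when it
gives the largest mean-DIC decrease, the decrease exceeds the tolerance
(runs whose DIC varies by no more than one are treated as ties), its own
coefficient is significant at the 95% credible level, and no previously
accepted coefficient loses significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from bymspat.bym_mcmc import BYMConfig, dic, fit_bym, summarize_posterior
from bymspat.ecological_indices import OutcomeTable
from bymspat.geo_adjacency import AdjacencyMatrix


@dataclass
class SelectionStep:
    candidate: str
    pD: float
    dic_mean: float
    dic_per_seed: list[float]
    significant: bool
    all_significant: bool
    accepted: bool
    note: str = ""
    step: int = 0
    model_so_far: str = "(base)"


@dataclass
class SelectionTrace:
    base_dic: float
    base_pD: float
    steps: list[SelectionStep] = field(default_factory=list)
    final_model: list[str] = field(default_factory=list)
    final_dic: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "model_so_far": s.model_so_far,
                    "candidate": s.candidate,
                    "pD": s.pD,
                    "dic_mean": s.dic_mean,
                    "significant": s.significant,
                    "accepted": s.accepted,
                    "note": s.note,
                }
                for s in self.steps
            ]
        )


def _fit_and_score(outcomes, X, adj, config, names, n_seeds):
    """Mean DIC over seeds plus the significance pattern of the last fit."""
    dics, pds = [], []
    summary = None
    for s in range(n_seeds):
        cfg = replace(config, seed=config.seed + 101 * s)
        draws = fit_bym(outcomes, X, adj, cfg, covariate_names=names)
        fit = dic(draws, outcomes, X)
        dics.append(fit.dic)
        pds.append(fit.pD)
        summary = summarize_posterior(draws)
    coef = summary[summary["scale"] == "coefficient"].set_index("parameter")
    sig = {n: bool(coef.loc[n, "significant"]) for n in names}
    return float(np.mean(dics)), dics, float(np.mean(pds)), sig


def forward_select(
    outcomes: OutcomeTable,
    candidates: pd.DataFrame,
    adj: AdjacencyMatrix,
    config: Optional[BYMConfig] = None,
    dic_tolerance: float = 1.0,
    n_seeds: int = 3,
) -> SelectionTrace:
    """Greedy forward selection with the DIC-decrease / significance rule.

    ``candidates`` is a DataFrame of standardized covariate columns
    (an ``area_id`` column is ignored).  The base model is the
    spatial-residual-only CAR model implied by ``config``.
    """
    config = config or BYMConfig(include_unstructured=False)
    cols = [c for c in candidates.columns if c != "area_id"]
    if not cols:
        raise ValueError("no candidate covariates")
    if len(candidates) != outcomes.n:
        raise ValueError("candidate rows != number of areas")
    Xall = {c: candidates[c].to_numpy(dtype=float) for c in cols}

    base_dic, _, base_pd, _ = _fit_and_score(
        outcomes, np.zeros((outcomes.n, 0)), adj, config, [], n_seeds
    )
    trace = SelectionTrace(base_dic=base_dic, base_pD=base_pd)
    current: list[str] = []
    current_dic = base_dic
    remaining = list(cols)
    round_no = 0

    while remaining:
        model_label = "+".join(current) if current else "(base)"
        evaluations = []
        for cand in remaining:
            names = current + [cand]
            X = np.column_stack([Xall[c] for c in names])
            try:
                dmean, dseeds, pd_mean, sig = _fit_and_score(
                    outcomes, X, adj, config, names, n_seeds
                )
            except Exception as exc:  # pragma: no cover - defensive
                trace.steps.append(
                    SelectionStep(cand, float("nan"), float("nan"), [],
                                  False, False, False, note=f"fit failed: {exc}",
                                  step=round_no, model_so_far=model_label)
                )
                continue
            evaluations.append((cand, dmean, dseeds, pd_mean, sig))

        if not evaluations:
            break
        evaluations.sort(key=lambda e: e[1])
        # choose the best-DIC candidate that clears the decrease bar and
        # keeps every coefficient (its own and the earlier ones) significant
        chosen = None
        for cand, dmean, dseeds, pd_mean, sig in evaluations:
            decrease = current_dic - dmean
            if decrease <= dic_tolerance:
                break  # sorted by DIC: nothing further can clear the bar
            if sig.get(cand, False) and all(sig.get(c, False) for c in current):
                chosen = cand
                break
        for cand, dmean, dseeds, pd_mean, sig in evaluations:
            decrease = current_dic - dmean
            ok_drop = decrease > dic_tolerance
            ok_sig = sig.get(cand, False)
            ok_others = all(sig.get(c, False) for c in current)
            note = []
            if not ok_drop:
                note.append(f"DIC decrease {decrease:.2f} <= tolerance")
            if not ok_sig:
                note.append("coefficient not significant")
            if not ok_others:
                note.append("earlier coefficient lost significance")
            trace.steps.append(
                SelectionStep(cand, pd_mean, dmean, dseeds, ok_sig,
                              ok_sig and ok_others, cand == chosen,
                              note="; ".join(note), step=round_no,
                              model_so_far=model_label)
            )
        if chosen is None:
            break
        current.append(chosen)
        remaining.remove(chosen)
        current_dic = next(e[1] for e in evaluations if e[0] == chosen)
        round_no += 1

    trace.final_model = current
    trace.final_dic = current_dic
    return trace
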